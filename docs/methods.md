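# Methods

`sbrteval` evaluates prostate SBRT plan quality for a five-fraction
whole-gland prescription (35 Gy to PTV_prostate, 30 Gy to PTV_SV) with an
iso-toxic focal boost of 40–50 Gy to the MRI-visible lesion(s).  The
package covers the full evaluation chain — DVH metrics, conformity and
intermediate-dose spillage, radiobiological complication probabilities,
gamma-index delivery QA, and a paired nonparametric comparison of
planning techniques — and ships a synthetic virtual-cohort generator so
every stage is testable without clinical data.

## DVH engine

DVHs are voxel-counting histograms over binary masks (no partial-volume
weighting; membership is unambiguous and every metric has an exact
voxel-sorting oracle).  Default bin width is 0.01 Gy — fine enough that
the near-maximum dose D_0.035cc is insensitive to binning.  Cumulative
curves are read with linear interpolation in both axes; on flat
segments ties break toward the higher dose, which is conservative when
checking "≤" constraints.  D_0.035cc is read from the interpolated
cumulative curve (volume-based near-max, the TPS convention), not from
the single hottest voxel.

Degenerate inputs: empty masks and geometry mismatches raise; requested
volumes beyond the structure volume raise rather than clamp.

## Plan-level metrics

**Renormalization.** Every plan is scaled by one global factor so the
prescription dose covers 95% of PTV_prostate.  The factor comes from the
exact in-PTV voxel quantile — making it exactly equivariant under global
rescaling, so CI and D2cm of a renormalized plan cannot depend on any
pre-scaling — and is then refined against the binned-DVH readout until
the reported D_95% sits within 0.005 Gy of the prescription.  The factor
is returned so recalculation audits (|factor−1| < 2% is the usual
acceptance) can be reported.

**Conformity index.** RTOG-style ratio: body volume receiving at least
the prescription dose divided by PTV volume.  Values slightly above 1
indicate a prescription isodose hugging the PTV with a small margin.
The Paddick index is available as a clearly separate secondary output.

**D2cm.** Maximum dose among voxels ≥ 20 mm (Euclidean, metric — not
voxel-count) from the PTV surface, as % of prescription.  Distances come
from `scipy.ndimage.distance_transform_edt` with physical sampling and
are verified against brute-force pairwise distances in the tests.

**Constraint audit.** The shipped constraint table is the five-fraction
focal-boost protocol: target coverage rows (GTV_boost D_99% ≥ 40 Gy with
a ≤ 52 Gy D_0.1cc goal, CTV/PTV coverage) and OAR rows for rectum (8
rows plus the PRV max-dose row), bladder, urethra and its PRV, anal
canal, penile bulb and femoral heads.  "If possible" goals are reported
as warnings, never failures.  Achieved values are rounded to 0.01
(Gy/cc/%) before comparison so pass/fail is reproducible at float
boundaries.  Missing or empty structures produce explicit report rows.

## Radiobiology

NTCP uses the Lyman–Kutcher–Burman model with Niemierko's generalized
EUD: `NTCP = Φ((gEUD − TD50)/(m·TD50))`, `gEUD = (Σ vᵢ Dᵢᵃ)^(1/a)` with
`a = 1/n` over fractional differential-DVH volumes.  Large exponents
(n ≈ 0.01 → a ≈ 100) are handled by factoring the maximum bin dose out
of the power sum.

Fractionation correction maps each DVH bin dose to its equivalent dose
in 2 Gy fractions, `EQD2(D) = D·(D/n_fx + α/β)/(2 + α/β)`; bin volumes
are untouched.  At 2 Gy per fraction the map is the identity; 35 Gy in
5 fractions at α/β = 3 Gy maps to exactly 70 Gy.

Shipped parameter sets (data, overridable, each carrying its citation):

| endpoint | TD50 [Gy] | m | n | correction |
|---|---|---|---|---|
| rectum, late grade ≥2 toxicity/bleeding (QUANTEC best estimate) | 76.9 | 0.13 | 0.09 | EQD2, α/β = 3 Gy |
| bladder, late urinary symptom flare after 5-fx SBRT (Kole et al.) | 42.3 | 0.08 | 0.01 | none (fit is 5-fraction) |

The bladder values are a transcription that could not be re-verified
against the source in this build; treat them as defaults to audit before
any clinical use.

## Gamma-index QA

Local-normalization gamma with the 2%/2 mm criteria, a 20%-of-maximum
exclusion threshold, and the per-arc ≥ 95% agreement-score tolerance of
measurement-based verification QA.  The search iterates candidate
offsets sorted by distance and stops per point once the distance term
alone exceeds the current minimum — lossless, so in voxel-sampling mode
the map is bit-equal to exhaustive search (asserted to 1e-6 in the
tests against an independent brute-force minimizer).  Sub-voxel search
uses linear interpolation of the evaluated distribution on an offset
lattice (default step = distance criterion / 10, search radius = 3 ×
distance criterion).  The exclusion threshold applies to the reference
(measured-role) distribution's maximum; with a positive threshold,
zero-dose reference points can never enter a local-normalization
denominator.  2D planar (portal-image surrogate) and 3D volumetric
comparisons share the one implementation.

## Statistics

Per metric: Kruskal–Wallis omnibus (tie-corrected, chi-square p;
all-identical input reported as H = 0, p = 1), all pairwise two-sided
Wilcoxon matched-pairs signed-rank tests, and Benjamini–Hochberg
step-up FDR control at q = 0.05.  Wilcoxon drops zero differences
(classic convention), uses the exact null distribution for n ≤ 12
without ties and the normal approximation with continuity and tie
correction otherwise.  The BH family defaults to the pairwise
comparisons within one metric (configurable to one global family);
omnibus p-values are reported but do not gate the pairwise tests unless
strict gating is requested.  Median paired differences accompany every
comparison so "significant and consistent" statements can be checked
for direction.

## Synthetic cohort

The generator emulates the study conditions a paired technique
comparison needs: 20 virtual patients × 5 technique labels (two C-arm
dual-arc references, manual dual/triple-arc and automated triple-arc on
the O-ring linac), each patient contributing one anatomy shared by all
of their plans.

**Anatomy.** Analytic shapes voxelized on a 2.5 mm isotropic 80³ grid:
prostate ellipsoid (~35 cc), proximal seminal vesicles (~6 cc), 1–3
boost lesions inside the gland (~1 cc), rectum cylinder abutting the
gland posteriorly (45 cc), bladder overlapping the PTV at its base
(~79 cc), urethra, anal canal, penile bulb, femoral heads, body.
Margins are metric dilations via the Euclidean distance transform:
PTV = CTV + 4 mm, PRV = OAR + 2 mm.  Per-patient size variation is one
truncated log-normal linear factor (σ = 0.07, clipped at 2σ —
mimicking cohort inclusion bounds) so 20-patient volumes stay inside
published anatomy ranges (PTV_prostate 39–134 cc).  The urethra has no
published volume row; its 3 mm radius is a free modeling choice.

**Dose.** Not a beam model — the evaluation consumes dose, and
distance-driven plateaus give controllable DVH shapes.  The dose is the
voxelwise maximum of: logistic plateaus over PTV_prostate (35 Gy),
PTV_SV (30 Gy with 2% headroom so SV coverage survives the
prostate-anchored renormalization), a mild 105% hotspot over the CTV
(plans are not flat), the focal-boost plateau over the GTV, and a
spillage halo active strictly outside the PTV with two components: a
steep isotropic shoulder at ~100% of prescription (puts the
prescription isodose just outside the PTV → CI ≈ 1.1–1.3, and the
anterior rectal wall near prescription) and a slow tail carried by the
lateral direction only (entrance/exit dose, decay length 30 mm → D2cm
≈ 55–65%), with fast posterior/vertical falloff like a rectal avoidance
sector.  Noise is spatially correlated Gaussian noise (5 mm
correlation, 0.4 Gy SD).

**Technique effects.** Controllable per-label perturbations: a distal
halo inflation that ramps in over the first 2 cm outside the PTV (so
coverage and normalization are untouched while D2cm scales fully),
smooth multiplicative organ dose scaling, and smooth additive target
shifts.  Defaults encode the study's contrasts: the automated technique
gets distal_scale 1.15 (≈ +8 D2cm percentage points after
renormalization), slight bladder hot-spot deflation, and +0.5 Gy SV
coverage; the other techniques differ from the high-resolution
reference by 2–5% distal scale.

**Randomness.** One root `SeedSequence` split hierarchically per
patient (anatomy) and per technique (noise): same seed → bit-identical
cohort; the paired design is exact.

**What the generator does not emulate** — and hence what passing tests
do not show about clinical data: no fluence/MLC/arc transport, no CT
density or heterogeneity corrections, no contouring variability, no
systematic inter-engine dose differences (the recalculation audit is
exercised with constructed perturbations), and simplified bladder-base
geometry — the bladder NTCP median (~1%) sits below the published ~4%
scale for this endpoint while the rectum NTCP band is reproduced.

## Operating characteristics

The null-FDR and power simulations run the actual pipeline (synthetic
dose → renormalization → DVH metrics → Wilcoxon + BH) end to end on a
compact 32³/5 mm geometry: anatomy generated once per cohort
(20 patients) and held fixed, noise redrawn per repetition for each of
the 100 plans, metrics D2cm, rectum V32 and bladder V32.  Problem
sizes: 200 repetitions for the null (rejection behaviour of the
per-metric BH family vs q = 0.05), 60 for power (all four pairwise
comparisons against the distal-inflated technique significant).  At
5 mm spacing a 4 mm margin cannot reach a neighbouring voxel centre, so
PTV ≡ CTV on that grid; this does not affect the noise-driven
comparison being characterized.

## Numerical choices

- All geometry in mm; arrays indexed (x, y, z) with world coordinate =
  origin + index × spacing; DICOM's (frame, row, col) order is
  transposed at the boundary.
- Distance transforms use physical sampling; "2 cm" and margin
  dilations are metric quantities.
- Gamma pass test uses γ ≤ 1 + 1e-9 so analytically boundary cases
  (uniform 2% local rescale) score as designed.
- Constraint comparison after rounding to 0.01; DVH interpolation ties
  toward the higher dose.
- NRRD written uncompressed through SimpleITK; manifests are sorted
  JSON without timestamps, so a fixed seed reproduces byte-identical
  artifacts.

## Known limitations

- Binary voxel membership: no partial-volume DVH weighting (documented
  non-goal); metrics on very small structures (GTV, urethra) carry
  voxelization error at 2.5 mm.
- The dose model's anisotropy is a two-direction caricature of arc
  delivery; per-arc portal-image predictions are synthetic planar
  surrogates.
- The bladder NTCP parameter transcription is unverified (see above);
  parameters are config data precisely so they can be replaced.
- DICOM support is read-only (RT Dose, RTSTRUCT rasterization);
  RT Plan (beams/MLC) is out of scope.
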