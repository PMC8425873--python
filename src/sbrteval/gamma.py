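"""Gamma-index comparison of two dose distributions (2D planar or 3D).

For every non-excluded reference point ``r`` the gamma index is

    gamma(r) = min over r' of sqrt( |r - r'|^2 / dta^2
                                    + (D_e(r') - D_r(r))^2 / dD(r)^2 )

with ``dta`` the distance criterion and ``dD(r)`` the dose criterion:
``dose_pct/100 * D_r(r)`` for local normalization, or
``dose_pct/100 * max(D_r)`` for global.  Points whose reference dose falls
below ``exclusion_threshold_fraction`` of the reference maximum are
excluded from the map and the agreement score.

The search over ``r'`` iterates candidate offsets sorted by distance and
terminates per point as soon as the distance term alone exceeds the
current minimum, which is lossless: in voxel-sampling mode
(``interpolation_step_mm=None``) the result is bit-equal to an exhaustive
search over every evaluated voxel within the search radius.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import DoseGrid, GeometryError

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "qa_decision"]

_PASS_EPS = 1e-9  # pass test gamma <= 1 robust to roundoff at the boundary


@dataclass(frozen=True)
class GammaCriteria:
    """Criteria of a gamma analysis; defaults are the 2%(local)/2 mm
    protocol with a 20%-of-maximum exclusion threshold."""

    dose_criterion_pct: float = 2.0
    distance_criterion_mm: float = 2.0
    normalization: str = "local"  # "local" | "global"
    exclusion_threshold_fraction: float = 0.20
    search_radius_mm: float | None = None  # default: 3 x distance criterion
    interpolation_step_mm: float | None = None  # None -> evaluated voxel lattice

    def __post_init__(self) -> None:
        if self.dose_criterion_pct <= 0 or self.distance_criterion_mm <= 0:
            raise ValueError("gamma criteria must be positive")
        if not 0 <= self.exclusion_threshold_fraction < 1:
            raise ValueError("exclusion threshold must be in [0, 1)")
        if self.normalization not in ("local", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.search_radius_mm is not None and (
            self.search_radius_mm < self.distance_criterion_mm
        ):
            raise ValueError("search radius must cover the distance criterion")
        if self.interpolation_step_mm is not None and self.interpolation_step_mm <= 0:
            raise ValueError("interpolation step must be positive")

    @property
    def radius_mm(self) -> float:
        return self.search_radius_mm or 3.0 * self.distance_criterion_mm


@dataclass
class GammaResult:
    """Gamma map plus the agreement score.

    ``gamma`` is NaN at excluded points; ``agreement_score_pct`` is the
    percentage of evaluated points with gamma <= 1.
    """

    gamma: np.ndarray
    criteria: GammaCriteria
    n_evaluated: int
    n_excluded: int

    @property
    def agreement_score_pct(self) -> float:
        finite = self.gamma[np.isfinite(self.gamma)]
        if finite.size == 0:
            raise ValueError("no evaluated points")
        return 100.0 * float(np.mean(finite <= 1.0 + _PASS_EPS))

    @property
    def pass_map(self) -> np.ndarray:
        return np.isfinite(self.gamma) & (self.gamma <= 1.0 + _PASS_EPS)


def _voxel_offsets(spacing, radius_mm):
    """Integer voxel offsets within the search radius, sorted by distance."""
    ranges = [np.arange(-int(radius_mm // s), int(radius_mm // s) + 1) for s in spacing]
    offs, d2 = [], []
    for combo in itertools.product(*ranges):
        dist2 = sum((c * s) ** 2 for c, s in zip(combo, spacing))
        if dist2 <= radius_mm**2 + 1e-12:
            offs.append(combo)
            d2.append(dist2)
    order = np.argsort(d2, kind="stable")
    return [offs[i] for i in order], np.asarray(d2)[order]


def _mm_offsets(ndim, step_mm, radius_mm):
    """Sub-voxel mm offsets within the search radius, sorted by distance."""
    n = int(np.floor(radius_mm / step_mm))
    axis = step_mm * np.arange(-n, n + 1)
    offs, d2 = [], []
    for combo in itertools.product(*([axis] * ndim)):
        dist2 = sum(c**2 for c in combo)
        if dist2 <= radius_mm**2 + 1e-12:
            offs.append(combo)
            d2.append(dist2)
    order = np.argsort(d2, kind="stable")
    return [offs[i] for i in order], np.asarray(d2)[order]


def _shifted_voxel_dose(values, offset):
    """Evaluated dose at every point shifted by an integer voxel offset;
    NaN where the shift leaves the grid."""
    out = np.full_like(values, np.nan)
    src = []
    dst = []
    for o, n in zip(offset, values.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = values[tuple(src)]
    return out


def gamma_map(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference`` at every
    non-excluded reference point.

    In voxel mode (``interpolation_step_mm=None``) both grids must share
    geometry and candidates are the evaluated voxels within the search
    radius.  With a finite interpolation step the evaluated distribution
    is linearly interpolated on a sub-voxel offset lattice; the grids may
    then differ in geometry as long as they overlap.
    """
    if reference.ndim != evaluated.ndim:
        raise GeometryError("reference and evaluated dimensionality differ")
    ref = reference.values
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference distribution has no dose")

    threshold = criteria.exclusion_threshold_fraction * ref_max
    eval_mask = ref >= threshold
    if criteria.normalization == "local":
        # threshold > 0 guarantees no zero denominators at evaluated points
        if criteria.exclusion_threshold_fraction == 0 and np.any(ref[eval_mask] == 0):
            raise ValueError(
                "local normalization with zero-dose reference points requires "
                "a positive exclusion threshold"
            )
        dd = criteria.dose_criterion_pct / 100.0 * ref
    else:
        dd = np.full_like(ref, criteria.dose_criterion_pct / 100.0 * ref_max)
    if not eval_mask.any():
        raise ValueError("all reference points fall below the exclusion threshold")

    dta2 = criteria.distance_criterion_mm**2
    gamma2 = np.full(ref.shape, np.inf)

    if criteria.interpolation_step_mm is None:
        if not reference.same_geometry(evaluated):
            raise GeometryError(
                "voxel-sampling gamma requires identical grid geometry; "
                "set interpolation_step_mm for resampled comparison"
            )
        offsets, d2 = _voxel_offsets(reference.spacing_mm, criteria.radius_mm)
        sample = lambda off: _shifted_voxel_dose(evaluated.values, off)  # noqa: E731
    else:
        offsets, d2 = _mm_offsets(
            reference.ndim, criteria.interpolation_step_mm, criteria.radius_mm
        )
        base = np.stack(
            np.meshgrid(
                *[reference.axis_coords(ax) for ax in range(reference.ndim)],
                indexing="ij",
            )
        )

        def sample(off):
            coords = [
                (base[ax] + off[ax] - evaluated.origin_mm[ax])
                / evaluated.spacing_mm[ax]
                for ax in range(reference.ndim)
            ]
            return map_coordinates(
                evaluated.values, coords, order=1, mode="constant", cval=np.nan
            )

    for off, dist2 in zip(offsets, d2):
        dist_term = dist2 / dta2
        active = eval_mask & (gamma2 > dist_term)
        if not active.any():
            break
        de = sample(off)
        valid = active & np.isfinite(de)
        if not valid.any():
            continue
        g2 = dist_term + ((de[valid] - ref[valid]) / dd[valid]) ** 2
        gamma2[valid] = np.minimum(gamma2[valid], g2)

    if not np.isfinite(gamma2[eval_mask]).all():
        raise GeometryError(
            "some evaluated points have no candidate within the search radius "
            "(disjoint or barely overlapping geometries)"
        )

    gamma = np.full(ref.shape, np.nan)
    gamma[eval_mask] = np.sqrt(gamma2[eval_mask])
    n_eval = int(np.count_nonzero(eval_mask))
    return GammaResult(gamma, criteria, n_eval, ref.size - n_eval)


def qa_decision(
    results: list[GammaResult | float], tolerance_pct: float = 95.0
) -> tuple[list[bool], bool]:
    """Per-field and overall QA pass/fail.

    A plan is deliverable only if every field's agreement score meets the
    tolerance (per-field rule of measurement-based verification QA).
    Accepts ``GammaResult`` objects or raw scores in percent.
    """
    if not results:
        raise ValueError("need at least one field result")
    scores = [
        r.agreement_score_pct if isinstance(r, GammaResult) else float(r)
        for r in results
    ]
    per_field = [s >= tolerance_pct for s in scores]
    return per_field, all(per_field)
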