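"""Radiobiological layer: LQ fractionation correction, Niemierko gEUD,
and the Lyman-Kutcher-Burman NTCP model.

The NTCP of an endpoint is computed as

    NTCP = Phi(t),   t = (gEUD - TD50) / (m * TD50)

with ``Phi`` the standard normal CDF and

    gEUD = ( sum_i v_i * D_i^a )^(1/a),   a = 1 / n

over the differential DVH with fractional volumes ``v_i`` summing to 1.
For endpoints whose parameter fits assume conventional 2 Gy fractionation
the DVH is first mapped bin-by-bin to the equivalent dose in 2 Gy
fractions (EQD2) under the linear-quadratic model:

    EQD2(D) = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n_fractions

Parameter sets are data, not code: each shipped default carries its
literature citation and can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .dvh import DVHCurve

__all__ = [
    "NTCPParams",
    "eqd2_dose",
    "eqd2_correct_dvh",
    "geud",
    "lkb_ntcp",
    "endpoint_ntcp",
    "RECTUM_QUANTEC",
    "BLADDER_KOLE",
    "DEFAULT_ENDPOINTS",
]


@dataclass(frozen=True)
class NTCPParams:
    """LKB parameter set for one complication endpoint.

    ``n`` is the volume-effect parameter (gEUD exponent ``a = 1/n``);
    small ``n`` means near-maximum-dose behaviour.  ``dvh_correction`` is
    ``"eqd2"`` when the fit assumes 2 Gy fractions, else ``"none"``.
    """

    td50_gy: float
    m: float
    n: float
    alpha_beta_gy: float | None = None
    n_fractions: int = 5
    endpoint: str = ""
    dvh_correction: str = "none"  # "none" | "eqd2"
    source: str = ""

    def __post_init__(self) -> None:
        if self.td50_gy <= 0:
            raise ValueError("TD50 must be positive")
        if self.m <= 0:
            raise ValueError("slope parameter m must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("volume parameter n must be in (0, 1]")
        if self.dvh_correction not in ("none", "eqd2"):
            raise ValueError(f"unknown dvh_correction {self.dvh_correction!r}")
        if self.dvh_correction == "eqd2":
            if self.alpha_beta_gy is None or self.alpha_beta_gy <= 0:
                raise ValueError("EQD2 correction requires alpha/beta > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def a(self) -> float:
        return 1.0 / self.n

    def with_(self, **kwargs) -> "NTCPParams":
        return replace(self, **kwargs)


#: Late grade >=2 rectal toxicity / rectal bleeding, QUANTEC best estimate
#: (Michalski JM et al., Int J Radiat Oncol Biol Phys 2010;76:S123-S129).
#: Fit assumes conventional fractionation, hence the EQD2 correction with
#: alpha/beta = 3 Gy recommended by the same review.
RECTUM_QUANTEC = NTCPParams(
    td50_gy=76.9,
    m=0.13,
    n=0.09,
    alpha_beta_gy=3.0,
    n_fractions=5,
    endpoint="rectum_late_grade2_toxicity",
    dvh_correction="eqd2",
    source="QUANTEC best estimate, Michalski et al. IJROBP 2010",
)

#: Late urinary symptom flare after five-fraction prostate SBRT
#: (Kole TP et al., Acta Oncol 2016).  Fit on physical five-fraction
#: bladder DVHs, so no fractionation correction is applied.  Transcribed
#: values should be verified against the source before clinical use; they
#: are configuration data and can be replaced via ``NTCPParams``.
BLADDER_KOLE = NTCPParams(
    td50_gy=42.3,
    m=0.08,
    n=0.01,
    alpha_beta_gy=None,
    n_fractions=5,
    endpoint="bladder_late_urinary_symptom_flare",
    dvh_correction="none",
    source="Kole et al. Acta Oncol 2016 (five-fraction SBRT fit)",
)

DEFAULT_ENDPOINTS: dict[str, NTCPParams] = {
    "rectum": RECTUM_QUANTEC,
    "bladder": BLADDER_KOLE,
}


def eqd2_dose(dose_gy, n_fractions: int, alpha_beta_gy: float):
    """Equivalent dose in 2 Gy fractions for total dose delivered in
    ``n_fractions`` equal fractions."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta_gy <= 0:
        raise ValueError("alpha/beta must be positive")
    d = np.asarray(dose_gy, dtype=float)
    per_fraction = d / n_fractions
    out = d * (per_fraction + alpha_beta_gy) / (2.0 + alpha_beta_gy)
    return float(out) if np.isscalar(dose_gy) else out


def eqd2_correct_dvh(
    dvh: DVHCurve, n_fractions: int, alpha_beta_gy: float
) -> DVHCurve:
    """Map each DVH bin dose to its EQD2; bin volumes are unchanged.

    The map is strictly increasing for non-negative dose, so bin edges
    stay ordered and the cumulative curve keeps its shape.
    """
    edges = eqd2_dose(dvh.bin_edges_gy, n_fractions, alpha_beta_gy)
    return DVHCurve(edges, dvh.differential_volume_cc.copy(), dvh.structure_name)


def geud(dvh: DVHCurve, a: float) -> float:
    """Generalized equivalent uniform dose of a DVH.

    Computed from the differential DVH with fractional volumes; the
    maximum bin dose is factored out before exponentiation so large
    exponents (small volume parameters, e.g. n ~ 0.01 -> a ~ 100) do not
    overflow.
    """
    if a == 0:
        raise ValueError("gEUD exponent a must be non-zero")
    v = dvh.differential_volume_cc
    total = v.sum()
    if total <= 0:
        raise ValueError("gEUD of an empty DVH is undefined")
    d = dvh.bin_centers_gy
    occ = v > 0
    d, v = d[occ], v[occ]
    if np.any(d < 0):
        raise ValueError("negative doses in DVH")
    frac = v / total
    d_max = d.max()
    if d_max == 0:
        return 0.0
    if a < 0 and np.any(d == 0):
        raise ValueError("gEUD with negative exponent undefined for zero dose")
    s = np.sum(frac * (d / d_max) ** a)
    return float(d_max * s ** (1.0 / a))


def lkb_ntcp(geud_gy: float, params: NTCPParams) -> float:
    """LKB complication probability for a given gEUD."""
    t = (geud_gy - params.td50_gy) / (params.m * params.td50_gy)
    return float(norm.cdf(t))


def endpoint_ntcp(dvh: DVHCurve, params: NTCPParams) -> float:
    """NTCP of one endpoint: optional EQD2 correction, then gEUD, then LKB."""
    if params.dvh_correction == "eqd2":
        if params.alpha_beta_gy is None:
            raise ValueError("EQD2 correction requested without alpha/beta")
        dvh = eqd2_correct_dvh(dvh, params.n_fractions, params.alpha_beta_gy)
    return lkb_ntcp(geud(dvh, params.a), params)
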