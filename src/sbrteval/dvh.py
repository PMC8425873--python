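"""Dose-volume histogram engine.

DVHs are voxel-counting histograms with binary mask membership (no
partial-volume weighting).  The cumulative curve ``V(d)`` is the volume in
cc receiving at least ``d`` Gy, tabulated at bin edges; ``Dx`` and ``Vx``
metrics are read off the curve with linear interpolation, ties broken
toward the higher dose so constraint checking stays conservative.

The near-maximum dose ``D_0.035cc`` used in SBRT constraint tables is
simply :func:`dose_at_volume` at 0.035 cc on the interpolated curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, GeometryError

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "mask_volume",
    "DEFAULT_BIN_WIDTH_GY",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVHCurve:
    """Differential + cumulative DVH for one structure.

    ``bin_edges_gy`` has ``n+1`` entries for ``n`` bins; bins need not be
    uniform (fractionation-corrected curves are not).  ``differential_volume_cc``
    holds the absolute volume per bin and sums to the structure volume.
    """

    bin_edges_gy: np.ndarray
    differential_volume_cc: np.ndarray
    structure_name: str = ""

    def __post_init__(self) -> None:
        self.bin_edges_gy = np.asarray(self.bin_edges_gy, dtype=float)
        self.differential_volume_cc = np.asarray(
            self.differential_volume_cc, dtype=float
        )
        if self.bin_edges_gy.size != self.differential_volume_cc.size + 1:
            raise ValueError("need n+1 edges for n differential bins")
        if np.any(np.diff(self.bin_edges_gy) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.differential_volume_cc < 0):
            raise ValueError("bin volumes must be non-negative")
        if self.bin_edges_gy[0] < 0:
            raise ValueError("negative dose bins are not allowed")

    @property
    def total_volume_cc(self) -> float:
        return float(self.differential_volume_cc.sum())

    @property
    def bin_centers_gy(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_gy[:-1] + self.bin_edges_gy[1:])

    @property
    def cumulative_volume_cc(self) -> np.ndarray:
        """V(edge) in cc at each bin edge (volume with dose >= edge)."""
        total = self.total_volume_cc
        return np.concatenate(
            [[total], total - np.cumsum(self.differential_volume_cc)]
        )

    @property
    def cumulative_volume_pct(self) -> np.ndarray:
        total = self.total_volume_cc
        if total == 0:
            return np.zeros_like(self.cumulative_volume_cc)
        return 100.0 * self.cumulative_volume_cc / total


def mask_volume(mask: np.ndarray, spacing_mm) -> float:
    """Volume of a binary mask in cc (voxel count x voxel volume)."""
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def compute_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    structure_name: str = "",
) -> DVHCurve:
    """Voxel-counting DVH of ``dose`` restricted to ``mask``.

    Raises on an empty mask or a geometry mismatch: silent zero-volume
    curves hide contouring errors.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match dose grid {dose.shape}"
        )
    if not mask.any():
        raise ValueError(f"empty mask for structure {structure_name!r}")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")

    doses = dose.values[mask]
    top = float(doses.max()) + 2 * bin_width_gy
    n_bins = max(1, int(np.ceil(top / bin_width_gy)))
    edges = bin_width_gy * np.arange(n_bins + 1)
    counts, _ = np.histogram(doses, bins=edges)
    return DVHCurve(edges, counts * dose.voxel_volume_cc, structure_name)


def _resolve_volume_cc(dvh: DVHCurve, volume: float, percent: bool) -> float:
    total = dvh.total_volume_cc
    v_cc = volume * total / 100.0 if percent else float(volume)
    if v_cc <= 0:
        raise ValueError("requested volume must be positive")
    if v_cc > total * (1 + 1e-9):
        raise ValueError(
            f"requested volume {v_cc:.3f} cc exceeds structure volume {total:.3f} cc"
        )
    return min(v_cc, total)


def dose_at_volume(dvh: DVHCurve, volume: float, percent: bool = False) -> float:
    """Minimum dose (Gy) received by the hottest ``volume`` of the structure.

    ``D_x%`` with ``percent=True``; ``D_x cc`` otherwise.  Linear
    interpolation on the cumulative curve; on flat segments the higher
    dose is returned.
    """
    v = _resolve_volume_cc(dvh, volume, percent)
    edges = dvh.bin_edges_gy
    cum = dvh.cumulative_volume_cc
    # largest edge index with cum >= v  (ties -> highest dose)
    idx = np.where(cum >= v - 1e-12)[0]
    j = int(idx[-1])
    if j == len(edges) - 1:
        return float(edges[-1])
    c0, c1 = cum[j], cum[j + 1]
    if c0 - c1 <= 0:
        return float(edges[j + 1])
    frac = (c0 - v) / (c0 - c1)
    return float(edges[j] + frac * (edges[j + 1] - edges[j]))


def volume_at_dose(dvh: DVHCurve, dose_gy: float) -> tuple[float, float]:
    """Volume receiving at least ``dose_gy``, as ``(cc, % of structure)``."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    edges = dvh.bin_edges_gy
    cum = dvh.cumulative_volume_cc
    if dose_gy >= edges[-1]:
        return 0.0, 0.0
    v_cc = float(np.interp(dose_gy, edges, cum))
    total = dvh.total_volume_cc
    return v_cc, 100.0 * v_cc / total if total > 0 else 0.0
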