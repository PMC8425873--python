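"""Core spatial containers shared by the whole pipeline.

All geometry is handled in millimetres.  Arrays are indexed ``(i, j, k)``
mapping to patient-like axes ``(x, y, z)``:

* axis 0 / x: patient left (+) – right (−)
* axis 1 / y: posterior (+) – anterior (−)
* axis 2 / z: superior (+) – inferior (−)

World coordinate of voxel ``(i, j, k)`` is ``origin_mm + index * spacing_mm``.
Planar (2D) grids use the same convention restricted to two axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "StructureSet", "GeometryError"]


class GeometryError(ValueError):
    """Raised when grids/masks do not share geometry or a structure does not fit."""


def _as_tuple(x, ndim: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, ndim)
    if arr.size != ndim:
        raise GeometryError(f"expected {ndim} components, got {arr.size}")
    return tuple(float(v) for v in arr)


@dataclass
class DoseGrid:
    """Absorbed dose on a regular grid.

    Parameters
    ----------
    values : ndarray
        Dose in Gy, non-negative, 2D (planar) or 3D (volumetric).
    spacing_mm : sequence of float
        Per-axis voxel size in mm.
    origin_mm : sequence of float
        World coordinate of voxel ``(0, ..., 0)`` in mm.
    """

    values: np.ndarray
    spacing_mm: tuple[float, ...]
    origin_mm: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise GeometryError("dose grid must be 2D or 3D")
        self.spacing_mm = _as_tuple(self.spacing_mm, self.values.ndim)
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError("spacing must be positive")
        if self.origin_mm is None:
            self.origin_mm = tuple(0.0 for _ in self.spacing_mm)
        self.origin_mm = _as_tuple(self.origin_mm, self.values.ndim)
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Voxel volume in cc (only meaningful for 3D grids)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def geometry(self):
        return (self.shape, self.spacing_mm, self.origin_mm)

    def same_geometry(self, other: "DoseGrid | StructureSet") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing_mm, self.origin_mm)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    spacing_mm: tuple[float, ...] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError(f"masks have inconsistent shapes: {shapes}")
        ndim = next(iter(shapes and [len(next(iter(shapes)))])) if shapes else 3
        self.spacing_mm = _as_tuple(self.spacing_mm, ndim)
        if self.origin_mm is None:
            self.origin_mm = tuple(0.0 for _ in self.spacing_mm)
        self.origin_mm = _as_tuple(self.origin_mm, ndim)
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, ...]:
        if not self.masks:
            raise GeometryError("empty structure set has no shape")
        return next(iter(self.masks.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not in set (have: {sorted(self.masks)})"
            ) from None

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if self.masks and mask.shape != self.shape:
            raise GeometryError("mask shape does not match structure set")
        self.masks[name] = mask

    def volume_cc(self, name: str) -> float:
        return float(np.count_nonzero(self[name])) * self.voxel_volume_cc
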