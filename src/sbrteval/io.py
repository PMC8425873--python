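"""Readers/writers tying the pipeline together.

The internal canonical on-disk format is NRRD for dose grids and masks
plus a JSON manifest describing the cohort layout (patients, techniques,
file paths, grid geometry, seed and config provenance).  DICOM support
is a reader adapter only: RT Dose grids (DoseGridScaling applied) and
RT Structure Sets (planar contours rasterized slice-wise with even-odd
fill onto a target grid).

Axis convention at every boundary: internal arrays are (x, y, z) indexed
with world coordinate = origin + index * spacing, all in mm.  DICOM
pixel arrays arrive as (frame=z, row=y, col=x) and are transposed on
read; SimpleITK images are converted likewise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
import yaml
from skimage.draw import polygon2mask

from . import synthetic as _syn
from .grids import DoseGrid, GeometryError, StructureSet

__all__ = [
    "read_dose",
    "write_dose",
    "read_mask",
    "write_mask",
    "read_structures",
    "write_cohort",
    "read_cohort",
    "load_config",
    "file_sha256",
]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# NRRD (canonical) via SimpleITK


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image):
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return values, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_dose(path, dose: DoseGrid) -> None:
    if dose.ndim != 3:
        raise GeometryError("only 3D dose grids are written to NRRD")
    sitk.WriteImage(_to_sitk(dose.values, dose.spacing_mm, dose.origin_mm),
                    str(path), useCompression=False)


def write_mask(path, mask: np.ndarray, spacing_mm, origin_mm) -> None:
    sitk.WriteImage(
        _to_sitk(np.asarray(mask, dtype=np.uint8), spacing_mm, origin_mm),
        str(path), useCompression=False,
    )


def read_mask(path):
    values, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return values.astype(bool), spacing, origin


# ---------------------------------------------------------------------------
# DICOM adapters


def _read_dicom_dose(path) -> DoseGrid:
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"not an RT Dose file: modality {getattr(ds, 'Modality', None)!r}")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise ValueError("RT Dose without DoseGridScaling")
    if str(getattr(ds, "DoseUnits", "GY")).upper() != "GY":
        raise ValueError(f"unsupported dose units {ds.DoseUnits!r}")
    values = ds.pixel_array.astype(float) * float(scaling)  # (z, y, x)
    values = values.transpose(2, 1, 0)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row=y, col=x
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform frame spacing is not supported")
    z_sp = float(dz[0]) if offsets.size > 1 else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (col_sp, row_sp, abs(z_sp)), origin)


def read_dose(path, fmt: str | None = None) -> DoseGrid:
    """Read a dose grid from NRRD or DICOM RT Dose (Gy, scaling applied).

    ``fmt`` may be ``"nrrd"`` or ``"dicom"``; inferred from the suffix
    when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "dicom" if path.suffix.lower() == ".dcm" else "nrrd"
    if fmt == "dicom":
        return _read_dicom_dose(path)
    if fmt == "nrrd":
        values, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
        return DoseGrid(values, spacing, origin)
    raise ValueError(f"unsupported dose format {fmt!r}")


def _rasterize_contours(contours, grid_shape, spacing, origin) -> np.ndarray:
    """Slice-wise even-odd rasterization of planar contours (mm triplets)
    onto the target grid; overlapping rings XOR, so inner rings are holes."""
    mask = np.zeros(grid_shape, dtype=bool)
    for pts in contours:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        k = int(round((pts[0, 2] - origin[2]) / spacing[2]))
        if not 0 <= k < grid_shape[2]:
            continue
        poly = np.column_stack(
            [(pts[:, 0] - origin[0]) / spacing[0],
             (pts[:, 1] - origin[1]) / spacing[1]]
        )
        layer = polygon2mask(grid_shape[:2], poly)
        mask[:, :, k] ^= layer
    return mask


def read_structures(path, target_grid: DoseGrid, fmt: str | None = None) -> StructureSet:
    """Read structures from DICOM RT Structure Set, rasterized onto
    ``target_grid``.  Empty structures yield empty masks with a warning."""
    path = Path(path)
    if fmt is None:
        fmt = "dicom" if path.suffix.lower() == ".dcm" else fmt
    if fmt != "dicom":
        raise ValueError("read_structures reads DICOM RTSTRUCT; use the manifest "
                         "reader for NRRD mask sets")
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError("not an RT Structure Set")
    names = {int(roi.ROINumber): str(roi.ROIName)
             for roi in ds.StructureSetROISequence}
    out = StructureSet({}, spacing_mm=target_grid.spacing_mm,
                       origin_mm=target_grid.origin_mm)
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        contours = [c.ContourData for c in getattr(roi, "ContourSequence", [])]
        mask = _rasterize_contours(contours, target_grid.shape,
                                   target_grid.spacing_mm, target_grid.origin_mm)
        if not mask.any():
            warnings.warn(f"structure {name!r} rasterized to an empty mask")
        out.add(name, mask)
    return out


# ---------------------------------------------------------------------------
# cohort manifest


def _spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d))  # tuples -> lists, plain types only


def _effects_from_dict(d: dict) -> dict[str, _syn.TechniqueEffect]:
    return {k: _syn.TechniqueEffect(**v) for k, v in d.items()}


def phantom_spec_from_dict(d: dict) -> _syn.PhantomSpec:
    return _syn.PhantomSpec(**d)


def plan_spec_from_dict(d: dict) -> _syn.PlanSpec:
    d = dict(d)
    if "technique_effects" in d:
        d["technique_effects"] = _effects_from_dict(d["technique_effects"])
    return _syn.PlanSpec(**d)


def cohort_spec_from_dict(d: dict) -> _syn.CohortSpec:
    d = dict(d)
    if "technique_labels" in d:
        d["technique_labels"] = tuple(d["technique_labels"])
    return _syn.CohortSpec(**d)


def load_config(path):
    """Load a YAML config with optional ``cohort``, ``phantom`` and
    ``plan`` sections into the three spec objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return (
        cohort_spec_from_dict(raw.get("cohort", {})),
        phantom_spec_from_dict(raw.get("phantom", {})),
        plan_spec_from_dict(raw.get("plan", {})),
    )


def write_cohort(cohort: _syn.Cohort, out_dir) -> Path:
    """Write a cohort as NRRD volumes plus a JSON manifest; returns the
    manifest path.  Output is deterministic for a fixed cohort (no
    timestamps), so reruns with one seed are byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for patient in cohort.patients:
        pdir = out_dir / patient.patient_id
        pdir.mkdir(exist_ok=True)
        struct_paths = {}
        st = patient.structures
        for name, mask in st.masks.items():
            p = pdir / f"mask_{name}.nrrd"
            write_mask(p, mask, st.spacing_mm, st.origin_mm)
            struct_paths[name] = str(p.relative_to(out_dir))
        dose_paths = {}
        for tech, dose in patient.doses.items():
            p = pdir / f"dose_{tech}.nrrd"
            write_dose(p, dose)
            dose_paths[tech] = str(p.relative_to(out_dir))
        entries.append(dict(patient_id=patient.patient_id,
                            structures=struct_paths, doses=dose_paths))
    manifest = dict(
        format_version=1,
        seed=cohort.cohort_spec.seed,
        technique_labels=list(cohort.technique_labels),
        geometry=dict(
            shape=list(cohort.patients[0].structures.shape),
            spacing_mm=list(cohort.patients[0].structures.spacing_mm),
            origin_mm=list(cohort.patients[0].structures.origin_mm),
        ),
        specs=dict(
            cohort=_spec_to_dict(cohort.cohort_spec),
            phantom=_spec_to_dict(cohort.phantom_spec),
            plan=_spec_to_dict(cohort.plan_spec),
        ),
        patients=entries,
    )
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def read_cohort(manifest_path) -> _syn.Cohort:
    """Load a cohort back from its manifest, validating geometry."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    specs = manifest["specs"]
    geom = manifest["geometry"]
    patients = []
    for entry in manifest["patients"]:
        masks, doses = {}, {}
        spacing = origin = None
        for name, rel in entry["structures"].items():
            p = base / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
            masks[name], spacing, origin = read_mask(p)
        st = StructureSet(masks, spacing_mm=spacing, origin_mm=origin)
        if list(st.shape) != geom["shape"]:
            raise GeometryError("mask geometry does not match manifest")
        for tech, rel in entry["doses"].items():
            p = base / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
            dose = read_dose(p)
            if not dose.same_geometry(st):
                raise GeometryError("dose geometry does not match structures")
            doses[tech] = dose
        patients.append(_syn.CohortPatient(entry["patient_id"], st, doses))
    return _syn.Cohort(
        patients,
        cohort_spec_from_dict(specs["cohort"]),
        phantom_spec_from_dict(specs["phantom"]),
        plan_spec_from_dict(specs["plan"]),
    )
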