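"""Plan-quality metrics and the constraint audit: renormalization,
conformity, D2cm against brute-force distances, crafted violations."""

import numpy as np
import pytest

import sbrteval as sv
from sbrteval.grids import DoseGrid, GeometryError, StructureSet
from sbrteval.quality import (
    conformity_index,
    d2cm,
    default_constraint_table,
    evaluate_constraints,
    normalize_plan,
    paddick_index,
    voxelwise_dose_error,
)


class TestNormalizePlan:
    def test_already_normalized_factor_one(self):
        values = np.zeros((12, 12, 12))
        ptv = np.zeros((12, 12, 12), bool)
        ptv[3:9, 3:9, 3:9] = True
        values[ptv] = 35.0
        dose = DoseGrid(values, (4.0,) * 3)
        _, factor = normalize_plan(dose, ptv)
        assert factor == pytest.approx(1.0, abs=1e-3)

    def test_scaling_from_low_coverage(self):
        values = np.zeros((12, 12, 12))
        ptv = np.zeros((12, 12, 12), bool)
        ptv[3:9, 3:9, 3:9] = True
        values[ptv] = 33.25
        dose = DoseGrid(values, (4.0,) * 3)
        normalized, factor = normalize_plan(dose, ptv)
        assert factor == pytest.approx(35.0 / 33.25, rel=1e-3)
        curve = sv.compute_dvh(normalized, ptv)
        assert sv.dose_at_volume(curve, 95, percent=True) == pytest.approx(
            35.0, abs=0.01
        )

    def test_synthetic_plan_d95_within_centigray(self, small_structures,
                                                  small_plan):
        dose = sv.make_plan_dose(small_structures, small_plan,
                                 rng=np.random.default_rng(3))
        normalized, factor = normalize_plan(dose,
                                            small_structures["PTV_prostate"])
        curve = sv.compute_dvh(normalized, small_structures["PTV_prostate"])
        assert sv.dose_at_volume(curve, 95, percent=True) == pytest.approx(
            35.0, abs=0.01
        )

    def test_small_perturbation_small_factor(self, small_structures,
                                             small_plan):
        # a recalculation-like perturbation at <= 2% scale renormalizes
        # with |factor - 1| < 2%
        dose = sv.make_plan_dose(small_structures, small_plan,
                                 rng=np.random.default_rng(3))
        dose, _ = normalize_plan(dose, small_structures["PTV_prostate"])
        recalc = dose.with_values(dose.values * 1.018)
        _, factor = normalize_plan(recalc, small_structures["PTV_prostate"])
        assert abs(factor - 1.0) < 0.02

    def test_zero_dose_rejected(self):
        dose = DoseGrid(np.zeros((6, 6, 6)), (4.0,) * 3)
        ptv = np.ones((6, 6, 6), bool)
        with pytest.raises(ValueError):
            normalize_plan(dose, ptv)


class TestConformity:
    def test_isodose_equal_to_ptv(self):
        ptv = np.zeros((16, 16, 16), bool)
        ptv[4:12, 4:12, 4:12] = True
        values = np.where(ptv, 36.0, 10.0)
        dose = DoseGrid(values, (2.5,) * 3)
        assert conformity_index(dose, ptv) == pytest.approx(1.0)

    def test_dilated_isodose_ratio(self):
        ptv = np.zeros((20, 20, 20), bool)
        ptv[5:15, 5:15, 5:15] = True
        iso = np.zeros_like(ptv)
        iso[5:15, 5:15, 5:16] = True  # one extra slab: 1100/1000 voxels
        dose = DoseGrid(np.where(iso, 35.0, 0.0), (2.0,) * 3)
        assert conformity_index(dose, ptv) == pytest.approx(1.1)

    def test_invariant_under_rescale_then_renormalize(self, small_structures,
                                                      small_plan):
        dose = sv.make_plan_dose(small_structures, small_plan,
                                 rng=np.random.default_rng(1))
        ptv = small_structures["PTV_prostate"]
        body = small_structures["body"]
        norm1, _ = normalize_plan(dose, ptv)
        rescaled = dose.with_values(dose.values * 1.3)
        norm2, _ = normalize_plan(rescaled, ptv)
        assert conformity_index(norm1, ptv, body) == pytest.approx(
            conformity_index(norm2, ptv, body), rel=1e-9
        )
        assert d2cm(norm1, ptv) == pytest.approx(d2cm(norm2, ptv), rel=1e-9)

    def test_paddick_bounded_by_one(self):
        ptv = np.zeros((16, 16, 16), bool)
        ptv[4:12, 4:12, 4:12] = True
        dose = DoseGrid(np.where(ptv, 36.0, 0.0), (2.5,) * 3)
        assert paddick_index(dose, ptv) == pytest.approx(1.0)


class TestD2cm:
    def test_zero_dose_beyond_two_cm(self):
        ptv = np.zeros((24, 24, 24), bool)
        ptv[10:14, 10:14, 10:14] = True
        dose = DoseGrid(np.where(ptv, 35.0, 0.0), (4.0,) * 3)
        assert d2cm(dose, ptv) == 0.0

    def test_constructed_half_prescription_shell(self):
        from scipy.ndimage import distance_transform_edt

        ptv = np.zeros((24, 24, 24), bool)
        ptv[10:14, 10:14, 10:14] = True
        dt = distance_transform_edt(~ptv, sampling=(4.0,) * 3)
        values = np.where(ptv, 35.0, np.where(dt >= 20.0, 17.5, 30.0))
        dose = DoseGrid(values, (4.0,) * 3)
        assert d2cm(dose, ptv) == pytest.approx(50.0)

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        ptv = np.zeros((16, 16, 16), bool)
        ptv[6:10, 6:10, 6:10] = True
        values = rng.uniform(0, 35, size=(16, 16, 16))
        spacing = (3.0, 3.0, 3.0)
        dose = DoseGrid(values, spacing)
        # oracle: pairwise Euclidean point distances to PTV voxel centres
        pts = np.argwhere(~ptv) * np.asarray(spacing)
        ptv_pts = np.argwhere(ptv) * np.asarray(spacing)
        d = np.sqrt(((pts[:, None, :] - ptv_pts[None, :, :]) ** 2).sum(-1)).min(1)
        shell_vals = values[~ptv][d >= 20.0]
        expect = 100.0 * shell_vals.max() / 35.0
        assert d2cm(dose, ptv) == pytest.approx(expect, rel=1e-9)

    def test_no_shell_raises(self):
        ptv = np.ones((8, 8, 8), bool)
        dose = DoseGrid(np.full((8, 8, 8), 35.0), (2.0,) * 3)
        with pytest.raises(GeometryError):
            d2cm(dose, ptv)


class TestVoxelwiseError:
    def test_identical_inputs(self, small_dose):
        out = voxelwise_dose_error(small_dose, small_dose)
        assert out["median_gy"] == 0.0 and out["max_gy"] == 0.0

    def test_constant_offset(self, small_dose):
        other = small_dose.with_values(small_dose.values + 0.1)
        out = voxelwise_dose_error(small_dose, other)
        assert out["median_gy"] == pytest.approx(0.1)

    def test_scale_bound(self, small_dose):
        other = small_dose.with_values(small_dose.values * 1.01)
        out = voxelwise_dose_error(small_dose, other)
        assert out["max_gy"] <= 0.01 * small_dose.values.max() + 1e-9

    def test_geometry_mismatch(self, small_dose):
        other = DoseGrid(np.ones((4, 4, 4)), (2.0,) * 3)
        with pytest.raises(GeometryError):
            voxelwise_dose_error(small_dose, other)


# ---------------------------------------------------------------------------
# crafted constraint-audit fixtures


def _box(shape, lo, hi):
    m = np.zeros(shape, bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def crafted_plan(violations=()):
    """A compliant nested-box plan, then selected named violations.

    1 mm voxels, so cc values are exact voxel counts / 1000.
    Recognized violations: 'rectum_v38', 'bladder_v42', 'anal_canal_v21'.
    """
    shape = (60, 60, 60)
    spacing = (1.0, 1.0, 1.0)
    gtv = _box(shape, (27, 27, 27), (33, 33, 33))
    ctv = _box(shape, (22, 22, 22), (38, 38, 38))
    ptv = _box(shape, (20, 20, 20), (40, 40, 40))
    ctv_sv = _box(shape, (25, 42, 25), (35, 46, 35))
    ptv_sv = _box(shape, (24, 41, 24), (36, 48, 36))
    rectum = _box(shape, (10, 48, 0), (30, 58, 58))  # 11.6 cc
    bladder = _box(shape, (30, 2, 5), (50, 14, 50))  # 10.8 cc
    urethra = _box(shape, (29, 29, 12), (32, 32, 48))
    masks = {
        "GTV_boost": gtv, "CTV_prostate": ctv, "PTV_prostate": ptv,
        "CTV_SV": ctv_sv, "PTV_SV": ptv_sv,
        "rectum": rectum, "PRV_rectum": rectum.copy(),
        "bladder": bladder,
        "urethra": urethra, "PRV_urethra": urethra.copy(),
        "anal_canal": _box(shape, (2, 48, 5), (12, 58, 25)),  # 2.0 cc
        "penile_bulb": _box(shape, (2, 2, 5), (10, 10, 15)),
        "femoral_heads": _box(shape, (52, 25, 20), (58, 35, 40)),
        "body": np.ones(shape, bool),
    }
    st = StructureSet(masks, spacing_mm=spacing)

    values = np.zeros(shape)
    values[ptv] = 34.0
    values[ptv_sv] = 30.5
    values[ctv_sv] = 30.5
    values[ctv] = 35.5
    values[gtv] = 41.0
    if "rectum_v38" in violations:
        # 1.5 cc of an 11.6 cc rectum at 39 Gy: V38 = 1.5 cc > 1 cc fails;
        # V35 = 1.5 <= 2 cc holds (its 1 cc goal is a warning only);
        # V32 = 12.9% < 15%, D_0.035cc = 39 < 40 all hold
        hot = _box(shape, (10, 48, 0), (20, 51, 50))  # 10x3x50 = 1500 voxels
        values[hot & rectum] = 39.0
    if "bladder_v42" in violations:
        # 1.2 cc at 43 Gy: V42 = 1.2 cc > 1 cc fails; V37 = 1.2 <= 5 cc,
        # V32 = 11.1% < 15% hold
        hot = _box(shape, (30, 2, 5), (40, 5, 45))  # 10x3x40 = 1200 voxels
        values[hot & bladder] = 43.0
    if "anal_canal_v21" in violations:
        # half the canal at 22 Gy: V21.4 = 50% > 40% fails; V19.2 = 50%
        # <= 60% holds
        half = _box(shape, (2, 48, 5), (12, 53, 25))
        values[half & st["anal_canal"]] = 22.0
    return DoseGrid(values, spacing), st


class TestConstraintAudit:
    def test_table_covers_protocol(self):
        table = default_constraint_table()
        structures = {c.structure for c in table}
        assert structures == {
            "GTV_boost", "CTV_prostate", "PTV_prostate", "CTV_SV", "PTV_SV",
            "rectum", "PRV_rectum", "bladder", "urethra", "PRV_urethra",
            "anal_canal", "penile_bulb", "femoral_heads",
        }
        # one row per protocol entry: 6 target rows + 9 rectum (incl. the
        # 1 cc goal) + 1 rectum PRV + 4 bladder + 2 urethra + 3 anal canal
        # + penile bulb + femoral heads
        assert len(table) == 27

    def test_zero_dose_all_oars_pass_targets_fail(self, small_structures):
        dose = DoseGrid(np.zeros(small_structures.shape),
                        small_structures.spacing_mm,
                        small_structures.origin_mm)
        report = evaluate_constraints(dose, small_structures)
        target_rows = report.rows[report.rows.direction == ">="]
        oar_rows = report.rows[report.rows.direction == "<="]
        assert (target_rows.status == "fail").all()
        assert set(oar_rows.status) <= {"pass", "warning"}
        assert (oar_rows.status == "pass").all()

    def test_missing_structure_explicit_row(self, small_structures):
        st = StructureSet({k: v for k, v in small_structures.masks.items()
                           if k != "penile_bulb"},
                          small_structures.spacing_mm,
                          small_structures.origin_mm)
        dose = DoseGrid(np.zeros(st.shape), st.spacing_mm, st.origin_mm)
        report = evaluate_constraints(dose, st)
        missing = report.rows[report.rows.status == "missing"]
        assert list(missing.structure) == ["penile_bulb"]

    @pytest.mark.parametrize("violations,expected", [
        ((), 0),
        (("rectum_v38",), 1),
        (("rectum_v38", "bladder_v42", "anal_canal_v21"), 3),
    ])
    def test_crafted_violations_flagged_exactly(self, violations, expected):
        dose, st = crafted_plan(violations)
        report = evaluate_constraints(dose, st)
        assert report.n_failed == expected
        failed_structures = set(report.failed.structure)
        lookup = {"rectum_v38": "rectum", "bladder_v42": "bladder",
                  "anal_canal_v21": "anal_canal"}
        assert failed_structures == {lookup[v] for v in violations}
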