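"""Virtual-cohort generator: mask consistency, anatomy envelopes,
dose-model limits, pairing structure, determinism."""

import dataclasses

import numpy as np
import pytest

import sbrteval as sv
from sbrteval.grids import GeometryError


class TestPhantomMasks:
    def test_nesting_invariants(self, small_structures):
        st = small_structures
        assert not np.any(st["CTV_prostate"] & ~st["PTV_prostate"])
        assert not np.any(st["CTV_SV"] & ~st["PTV_SV"])
        assert not np.any(st["rectum"] & ~st["PRV_rectum"])
        assert not np.any(st["urethra"] & ~st["PRV_urethra"])
        for name in st.names:
            if name != "body":
                assert not np.any(st[name] & ~st["body"])

    def test_gtv_inside_prostate(self, small_structures):
        st = small_structures
        assert not np.any(st["GTV_boost"] & ~st["prostate"])

    def test_zero_margin_ptv_equals_ctv(self, small_spec):
        spec = dataclasses.replace(small_spec, ptv_margin_mm=0.0)
        st = sv.make_phantom(spec)
        np.testing.assert_array_equal(st["PTV_prostate"], st["CTV_prostate"])

    def test_rectum_abuts_ptv_with_measured_overlap(self):
        # needs the 2.5 mm grid: a 4 mm margin cannot reach the next voxel
        # centre on the coarse 5 mm test grid
        spec = dataclasses.replace(sv.PhantomSpec(), rectum_gap_mm=0.0)
        st = sv.make_phantom(spec)
        overlap_cc = (
            np.count_nonzero(st["rectum"] & st["PTV_prostate"])
            * st.voxel_volume_cc
        )
        assert overlap_cc > 0

    def test_lesion_outside_prostate_rejected(self, small_spec):
        spec = dataclasses.replace(small_spec,
                                   gtv_centers_mm=((30.0, 0.0, 0.0),))
        with pytest.raises(ValueError, match="outside the prostate"):
            sv.make_phantom(spec)

    def test_grid_too_small_raises_geometry_error(self, small_spec):
        spec = dataclasses.replace(small_spec, grid_shape=(16, 16, 16))
        with pytest.raises(GeometryError):
            sv.make_phantom(spec)

    def test_dilation_is_metric_not_voxel(self):
        mask = np.zeros((21, 21, 21), bool)
        mask[10, 10, 10] = True
        out = sv.dilate_mm(mask, (2.0, 2.0, 2.0), 5.0)
        # 5 mm at 2 mm spacing: 2 voxels along axes, not 5
        assert out[12, 10, 10] and not out[13, 10, 10]
        assert out[11, 11, 11]  # diagonal sqrt(12) mm < ... within 5? sqrt(4+4+4)=3.46 yes


class TestDoseModel:
    def test_sharp_falloff_plateau_limit(self, small_structures):
        plan = sv.PlanSpec(falloff_mm=1e-3, noise_sd_gy=0.0,
                           hotspot_factor=1.0, halo_amp=0.5)
        dose = sv.make_plan_dose(small_structures, plan)
        curve = sv.compute_dvh(dose, small_structures["PTV_prostate"])
        assert sv.dose_at_volume(curve, 99, percent=True) == pytest.approx(
            35.0, abs=0.05
        )

    def test_boost_peak_inside_gtv(self, small_structures):
        plan = sv.PlanSpec(boost_dose_gy=45.0, noise_sd_gy=0.0)
        dose = sv.make_plan_dose(small_structures, plan)
        gtv = small_structures["GTV_boost"]
        assert dose.values[gtv].max() >= dose.values[~gtv].max()

    def test_distal_inflation_raises_d2cm(self, small_structures):
        plan = sv.PlanSpec(noise_sd_gy=0.0)
        base = sv.make_plan_dose(small_structures, plan)
        inflated = sv.make_plan_dose(
            small_structures, plan, sv.TechniqueEffect(distal_scale=1.08)
        )
        ptv = small_structures["PTV_prostate"]
        assert sv.d2cm(inflated, ptv) > sv.d2cm(base, ptv)

    def test_dose_nonnegative_with_noise(self, small_structures):
        plan = sv.PlanSpec(noise_sd_gy=2.0)
        dose = sv.make_plan_dose(small_structures, plan,
                                 rng=np.random.default_rng(0))
        assert np.all(dose.values >= 0)

    def test_organ_scale_and_target_shift(self, small_structures):
        plan = sv.PlanSpec(noise_sd_gy=0.0)
        base = sv.make_plan_dose(small_structures, plan)
        eff = sv.TechniqueEffect(organ_dose_scale={"bladder": 0.9},
                                 target_dose_shift_gy={"PTV_SV": 1.0})
        mod = sv.make_plan_dose(small_structures, plan, eff)
        bladder = small_structures["bladder"]
        sv_ptv = small_structures["PTV_SV"] & ~bladder
        assert mod.values[bladder].mean() < base.values[bladder].mean()
        assert mod.values[sv_ptv].mean() > base.values[sv_ptv].mean()


class TestCohort:
    def test_layout_and_pairing(self, small_spec):
        cspec = sv.CohortSpec(n_patients=3, seed=5)
        cohort = sv.make_cohort(cspec, small_spec)
        assert len(cohort) == 3
        n_plans = sum(len(p.doses) for p in cohort.patients)
        assert n_plans == 3 * len(sv.DEFAULT_TECHNIQUES)
        # paired design: one anatomy per patient, shared by techniques
        for p in cohort.patients:
            shapes = {d.shape for d in p.doses.values()}
            assert shapes == {p.structures.shape}

    def test_same_seed_bit_identical(self, small_spec):
        cspec = sv.CohortSpec(n_patients=2, seed=11)
        c1 = sv.make_cohort(cspec, small_spec)
        c2 = sv.make_cohort(cspec, small_spec)
        for p1, p2 in zip(c1.patients, c2.patients):
            for name in p1.structures.names:
                np.testing.assert_array_equal(p1.structures[name],
                                              p2.structures[name])
            for tech in p1.doses:
                np.testing.assert_array_equal(p1.doses[tech].values,
                                              p2.doses[tech].values)

    def test_different_seed_differs(self, small_spec):
        c1 = sv.make_cohort(sv.CohortSpec(n_patients=2, seed=1), small_spec)
        c2 = sv.make_cohort(sv.CohortSpec(n_patients=2, seed=2), small_spec)
        assert not np.array_equal(
            c1.patients[0].doses["TB2-SL2.5"].values,
            c2.patients[0].doses["TB2-SL2.5"].values,
        )

    def test_anatomy_varies_between_patients(self, small_spec):
        cohort = sv.make_cohort(sv.CohortSpec(n_patients=4, seed=3), small_spec)
        vols = [p.structures.volume_cc("prostate") for p in cohort.patients]
        assert len(set(np.round(vols, 2))) > 1

    def test_null_effects_differences_are_noise_only(self, small_spec):
        plan = sv.PlanSpec(
            technique_effects={t: sv.TechniqueEffect()
                               for t in sv.DEFAULT_TECHNIQUES},
            noise_sd_gy=0.0,
        )
        cohort = sv.make_cohort(sv.CohortSpec(n_patients=2, seed=9),
                                small_spec, plan)
        p = cohort.patients[0]
        ref = p.doses["TB2-SL2.5"].values
        for tech, dose in p.doses.items():
            np.testing.assert_allclose(dose.values, ref, atol=1e-12)


class TestPerturbDose:
    def test_identity(self, small_dose):
        out = sv.perturb_dose(small_dose, shift_mm=0.0, scale=1.0)
        np.testing.assert_array_equal(out.values, small_dose.values)

    def test_scale_only(self, small_dose):
        out = sv.perturb_dose(small_dose, scale=1.02)
        np.testing.assert_allclose(out.values, 1.02 * small_dose.values)

    def test_shift_moves_distribution(self):
        values = np.zeros((10, 10, 10))
        values[4, 4, 4] = 10.0
        dose = sv.DoseGrid(values, (2.0, 2.0, 2.0))
        out = sv.perturb_dose(dose, shift_mm=(2.0, 0.0, 0.0))
        assert out.values[5, 4, 4] == pytest.approx(10.0)

    def test_shift_beyond_extent_rejected(self, small_dose):
        with pytest.raises(GeometryError):
            sv.perturb_dose(small_dose, shift_mm=(1e4, 0.0, 0.0))


class TestSpecValidation:
    def test_boost_range_enforced(self):
        with pytest.raises(ValueError):
            sv.PlanSpec(boost_dose_gy=55.0)
        with pytest.raises(ValueError):
            sv.PlanSpec(boost_dose_gy=39.0)

    def test_cohort_minimums(self):
        with pytest.raises(ValueError):
            sv.CohortSpec(n_patients=1)
        with pytest.raises(ValueError):
            sv.CohortSpec(technique_labels=("only-one",))

    def test_lesion_count_bounds(self):
        with pytest.raises(ValueError):
            sv.PhantomSpec(gtv_centers_mm=(), gtv_radii_mm=())
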