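import math

import numpy as np
import pytest

from conftest import noise_free_spec
from vamorph.errors import InvalidParameterError
from vamorph.morpho import voxel_volume
from vamorph.phantom import (
    GROUPS,
    CohortSpec,
    RadiusProfile,
    RaterJitter,
    analytic_tube_volume,
    build_radius_profile,
    classify_archetype,
    perturb_for_rater,
    rasterize_phantom,
    sample_cohort,
)

STUDY_MEDIANS = {  # group -> (operculum diameter, midpoint diameter) in mm
    "control": (0.9, 0.6),
    "CH": (1.1, 0.8),
    "IPI": (1.4, 1.6),
    "IPII": (3.4, 2.1),
    "EVAS": (3.4, 2.2),
}


class TestRadiusProfile:
    def test_constant_profile(self):
        prof = build_radius_profile("uniform", 0.5, 0.5, 0.5)
        s = np.linspace(0, 1, 33)
        assert np.allclose(prof(s), 0.5)

    def test_central_dilatation_shape(self):
        prof = build_radius_profile("central_dilatation", 0.4, 1.6, 0.5)
        assert prof(0.5) == pytest.approx(1.6)
        assert prof(0.5) > prof(0.0) and prof(0.5) > prof(1.0)

    def test_funnel_monotone_toward_operculum(self):
        prof = build_radius_profile("funnel", 0.4, 0.5, 1.5)
        assert prof(1.0) > prof(0.0)
        s = np.linspace(0, 1, 101)
        assert np.all(np.diff(prof(s)) >= -1e-12)

    def test_no_overshoot_bounded_by_controls(self):
        prof = RadiusProfile(0.4, 1.6, 0.5)
        s = np.linspace(0, 1, 501)
        r = prof(s)
        assert r.min() >= 0.4 - 1e-12 and r.max() <= 1.6 + 1e-12

    def test_control_point_interpolation(self):
        prof = RadiusProfile(0.3, 0.9, 0.6)
        assert prof(0.0) == pytest.approx(0.3)
        assert prof(0.5) == pytest.approx(0.9)
        assert prof(1.0) == pytest.approx(0.6)

    @pytest.mark.parametrize("radii", [(0.0, 1, 1), (1, -0.2, 1), (1, 1, 0)])
    def test_nonpositive_radius_rejected(self, radii):
        with pytest.raises(InvalidParameterError):
            RadiusProfile(*radii)

    def test_archetype_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            build_radius_profile("central_dilatation", 1.0, 0.5, 0.4)
        with pytest.raises(InvalidParameterError):
            build_radius_profile("funnel", 1.5, 1.0, 0.5)

    def test_classify_archetype(self):
        assert classify_archetype(0.4, 1.6, 0.5) == "central_dilatation"
        assert classify_archetype(0.4, 0.5, 1.5) == "funnel"
        assert classify_archetype(0.5, 0.5, 0.5) == "uniform"


class TestAnalyticVolume:
    def test_cylinder_closed_form(self):
        prof = RadiusProfile(1.5, 1.5, 1.5)
        assert analytic_tube_volume(prof, 10) == pytest.approx(math.pi * 1.5**2 * 10, rel=1e-6)
        assert analytic_tube_volume(prof, 10) == pytest.approx(70.686, abs=5e-4)

    def test_narrow_cylinder(self):
        assert analytic_tube_volume(RadiusProfile(0.5, 0.5, 0.5), 10) == pytest.approx(
            7.854, abs=5e-4
        )

    def test_conical_frustum(self):
        # PCHIP through (1, 1.5, 2) is exactly linear -> frustum closed form
        prof = RadiusProfile(1.0, 1.5, 2.0)
        expected = math.pi * 3 * (1 + 1 * 2 + 4) / 3.0
        assert analytic_tube_volume(prof, 3) == pytest.approx(expected, rel=1e-6)
        assert analytic_tube_volume(prof, 3) == pytest.approx(21.991, abs=5e-4)

    def test_invalid_length(self):
        with pytest.raises(InvalidParameterError):
            analytic_tube_volume(RadiusProfile(1, 1, 1), 0)


class TestRasterize:
    def test_digitized_cylinder_volume(self, cylinder):
        spec, _image, truth_lumen, gt = cylinder
        vol = voxel_volume(truth_lumen)
        assert vol == pytest.approx(gt.volume_mm3, rel=0.03)
        assert gt.volume_mm3 == pytest.approx(70.686, abs=5e-3)

    def test_truth_lumen_hu_construction(self):
        """Pre-noise HU in the truth lumen reflects majority fluid coverage:
        every truth voxel lies below the bone/fluid midpoint, the interior
        is pure fluid, and the bulk of the lumen falls inside the -1024..700
        segmentation band."""
        spec = noise_free_spec(RadiusProfile(0.6, 0.8, 1.0))
        image, truth_lumen, _gt = rasterize_phantom(spec)
        assert spec.hu_fluid == 30 and spec.hu_bone == 1800
        lumen_hu = image.data[truth_lumen.as_bool()]
        midpoint_hu = 0.5 * (spec.hu_bone + spec.hu_fluid)
        assert np.all(lumen_hu < midpoint_hu)  # coverage > 0.5 by construction
        assert lumen_hu.min() == pytest.approx(spec.hu_fluid)
        assert np.mean(lumen_hu <= 700) > 0.8

    def test_seeded_determinism_bit_identical(self):
        spec = noise_free_spec(
            RadiusProfile(0.5, 0.8, 0.6), blur_sigma_mm=0.3, noise_sd_hu=40.0, seed=42
        )
        a, la, _ = rasterize_phantom(spec)
        b, lb, _ = rasterize_phantom(spec)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(la.data, lb.data)

    @pytest.mark.parametrize("archetype,radii", [
        ("uniform", (0.8, 0.8, 0.8)),
        ("central_dilatation", (0.4, 1.6, 0.5)),
        ("funnel", (0.4, 0.5, 1.5)),
    ])
    def test_truth_count_matches_analytic_all_archetypes(self, archetype, radii):
        spec = noise_free_spec(build_radius_profile(archetype, *radii))
        _image, truth_lumen, gt = rasterize_phantom(spec)
        assert voxel_volume(truth_lumen) == pytest.approx(gt.volume_mm3, rel=0.05)

    def test_volume_convergence_under_refinement(self):
        prof = RadiusProfile(0.6, 0.9, 0.7)
        errs = []
        for h in (0.4, 0.2, 0.1):
            spec = noise_free_spec(prof, spacing=(h, h, h))
            _img, truth_lumen, gt = rasterize_phantom(spec)
            errs.append(abs(voxel_volume(truth_lumen) - gt.volume_mm3) / gt.volume_mm3)
        # monotone decrease with 10% slack, down to the sub-0.5% level where
        # digitization error is dominated by grid-phase fluctuation
        assert errs[1] <= max(errs[0] * 1.10, 0.005)
        assert errs[2] <= max(errs[1] * 1.10, 0.005)

    def test_landmarks_consistent_with_geometry(self):
        spec = noise_free_spec(RadiusProfile(0.5, 0.8, 0.6))
        _img, _lab, gt = rasterize_phantom(spec)
        lm = gt.landmarks
        chord = np.linalg.norm(lm.operculum - lm.vestibule_exit)
        assert chord <= spec.length_mm  # arc is longer than its chord
        assert chord >= 0.9 * spec.length_mm
        assert gt.midpoint_diameter_mm == pytest.approx(2 * spec.profile(0.5))
        assert gt.operculum_diameter_mm == pytest.approx(2 * spec.profile(1.0))


class TestCohort:
    def test_medians_match_study_population(self):
        cohort = CohortSpec(group_sizes={g: 200 for g in GROUPS}, master_seed=101)
        members = sample_cohort(cohort)
        for group, (oper_t, mid_t) in STUDY_MEDIANS.items():
            sub = [m for m in members if m.group == group]
            oper = np.median([m.truth.operculum_diameter_mm for m in sub])
            mid = np.median([m.truth.midpoint_diameter_mm for m in sub])
            assert abs(oper - oper_t) / oper_t <= 0.15, (group, "operculum", oper)
            assert abs(mid - mid_t) / mid_t <= 0.15, (group, "midpoint", mid)

    def test_empty_group_allowed(self):
        cohort = CohortSpec(group_sizes={"control": 3, "EVAS": 0}, master_seed=0)
        members = sample_cohort(cohort)
        assert sum(m.group == "EVAS" for m in members) == 0
        assert sum(m.group == "control" for m in members) == 3

    def test_deterministic_given_master_seed(self):
        c = CohortSpec(group_sizes={"control": 4, "EVAS": 3}, master_seed=7)
        a = sample_cohort(c)
        b = sample_cohort(c)
        assert [(m.ear_id, m.spec.seed, m.truth.volume_mm3) for m in a] == [
            (m.ear_id, m.spec.seed, m.truth.volume_mm3) for m in b
        ]

    def test_evas_volumes_separated_from_controls(self):
        members = sample_cohort(CohortSpec(master_seed=3))
        ctrl = [m.truth.volume_mm3 for m in members if m.group == "control"]
        evas = [m.truth.volume_mm3 for m in members if m.group == "EVAS"]
        assert max(ctrl) < min(evas)


class TestRaterPerturbation:
    def _landmarks(self):
        spec = noise_free_spec(RadiusProfile(0.5, 0.8, 0.6))
        from vamorph.phantom import ground_truth_for

        return ground_truth_for(spec).landmarks

    def test_zero_jitter_is_identity(self):
        lm = self._landmarks()
        pert = perturb_for_rater(lm, RaterJitter(0.0, 0.0, 0), seed=5)
        assert np.allclose(pert.landmarks.seed_point, lm.seed_point)
        assert pert.angle_offset_mid_deg == 0.0
        assert pert.slice_offset_mid == 0

    def test_displacement_bounded_by_radius(self):
        lm = self._landmarks()
        for seed in range(50):
            pert = perturb_for_rater(lm, RaterJitter(0.3, 10.0, 1), seed=seed)
            assert np.linalg.norm(pert.landmarks.seed_point - lm.seed_point) <= 0.3 + 1e-12
            assert abs(pert.angle_offset_mid_deg) <= 10.0
            assert pert.slice_offset_oper in (-1, 0, 1)

    def test_different_seeds_differ(self):
        lm = self._landmarks()
        a = perturb_for_rater(lm, RaterJitter(), seed=1)
        b = perturb_for_rater(lm, RaterJitter(), seed=2)
        assert not np.allclose(a.landmarks.seed_point, b.landmarks.seed_point)

    def test_negative_jitter_rejected(self):
        with pytest.raises(InvalidParameterError):
            RaterJitter(seed_radius_mm=-0.1)
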