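import numpy as np
import pytest

from eritwin import (
    AnalysisRegion,
    GeometryError,
    LabelRule,
    SyntheticCaseSpec,
    cohort_to_frame,
    generate_aorta,
    generate_case,
    generate_cohort,
    generate_deployed_graft,
    radial_sampling,
)
from eritwin.synthetic import GapDefect, _analytic_features, _wall_radius


class TestSpecValidation:
    def test_sac_smaller_than_neck_rejected(self):
        with pytest.raises(ValueError, match="self-intersect"):
            SyntheticCaseSpec(neck_radius_distal=12.0, sac_max_radius=10.0)

    def test_ovalization_bounds(self):
        with pytest.raises(ValueError):
            SyntheticCaseSpec(ovalization=1.2)

    def test_defect_beyond_graft_rejected(self):
        with pytest.raises(ValueError, match="beyond the graft"):
            SyntheticCaseSpec(
                graft_length=20.0,
                gap_defects=[GapDefect(18.0, 5.0, 0.0, 90.0, 1.0)],
            )

    def test_excessive_gap_depth_raises_at_generation(self):
        spec = SyntheticCaseSpec(
            neck_radius_proximal=8.0, neck_radius_distal=8.0,
            gap_defects=[GapDefect(4.0, 10.0, 0.0, 120.0, 8.0)],
        )
        with pytest.raises(GeometryError, match="exceeds"):
            generate_deployed_graft(spec)

    def test_roundtrip_dict(self):
        spec = SyntheticCaseSpec(
            gap_defects=[GapDefect(2.0, 5.0, 45.0, 90.0, 1.5)], seed=3
        )
        assert SyntheticCaseSpec.from_dict(spec.to_dict()) == spec


class TestGeneratedGeometry:
    def test_uniform_neck_is_cylindrical(self, straight_field):
        mean_r = straight_field.r_aorta.mean(axis=1)
        assert np.ptp(mean_r) < 0.02

    def test_linear_taper_mid_neck_radius(self):
        spec = SyntheticCaseSpec(
            neck_radius_proximal=12.0, neck_radius_distal=10.0, neck_length=20.0,
            seed=2,
        )
        aorta, path = generate_aorta(spec)
        from eritwin import polar_discretize, slice_mesh

        t, u, v = path.frame_at(10.0)
        c = slice_mesh(aorta, path.point_at(10.0), t, u=u)
        _, r = polar_discretize(c, c.centroid, 64)
        assert r.mean() == pytest.approx(11.0, abs=0.05)

    def test_same_seed_reproduces_mesh_exactly(self):
        spec = SyntheticCaseSpec(angulation_deg=20.0, seed=9)
        a1, _ = generate_aorta(spec)
        a2, _ = generate_aorta(SyntheticCaseSpec(angulation_deg=20.0, seed=9))
        assert np.array_equal(a1.vertices, a2.vertices)
        assert np.array_equal(a1.faces, a2.faces)

    def test_generated_meshes_watertight(self, defect_case):
        _, aorta, graft, _ = defect_case
        assert aorta.is_watertight
        assert graft.is_watertight

    def test_perfect_apposition_without_defects(self, straight_field):
        assert np.abs(straight_field.gap).max() < 0.05

    def test_declared_defect_depth_recovered(self, defect_field, defect_case):
        spec = defect_case[0]
        assert defect_field.gap.max() == pytest.approx(2.0, abs=0.1)
        # argmax of the gap lies inside the declared defect footprint
        i, j = np.unravel_index(defect_field.gap.argmax(), defect_field.gap.shape)
        s_hit = defect_field.s[i] - spec.graft_start
        phi_hit = np.degrees(defect_field.phi[j])
        d = spec.gap_defects[0]
        assert d.start_s <= s_hit <= d.start_s + d.length
        assert abs(phi_hit - d.angular_center_deg) <= d.angular_span_deg / 2

    def test_ovalization_amplitude_recovered(self):
        spec = SyntheticCaseSpec(ovalization=2.0 / 11.0, seed=4)
        aorta, graft, path = generate_case(spec)
        field = radial_sampling(aorta, graft, path)
        per_slice = (field.rg_max - field.rg_min) / field.rg_max
        assert per_slice.mean() == pytest.approx(2.0 / 11.0, abs=0.01)


class TestCohort:
    def test_seed_reproducibility(self):
        r1, s1 = generate_cohort(100, leak_fraction=0.3, seed=5)
        r2, s2 = generate_cohort(100, leak_fraction=0.3, seed=5)
        assert [r.leak for r in r1] == [r.leak for r in r2]
        assert s1 == s2

    def test_leak_fraction_approximate(self):
        recs, _ = generate_cohort(1000, leak_fraction=0.3, seed=1)
        rate = np.mean([r.leak for r in recs])
        assert 0.2 < rate < 0.4

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(5, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(100, leak_fraction=1.5, seed=0)

    def test_label_rule_negative_without_gaps(self):
        rule = LabelRule()
        benign = SyntheticCaseSpec(seed=0)  # no defects, no taper, no ovalization
        assert not rule.applies(benign)

    def test_label_rule_mechanisms(self):
        rule = LabelRule()
        assert rule.applies(SyntheticCaseSpec(
            gap_defects=[GapDefect(2.0, 6.0, 0.0, 90.0, 1.5)], seed=0))
        assert not rule.applies(SyntheticCaseSpec(
            gap_defects=[GapDefect(2.0, 3.0, 0.0, 90.0, 1.5)], seed=0))  # too short
        assert rule.applies(SyntheticCaseSpec(
            neck_radius_proximal=12.0, neck_radius_distal=8.0, seed=0))  # conical

    def test_confounding_shifts_group_composition(self):
        null, _ = generate_cohort(1000, confounding=0.0, seed=3)
        conf, _ = generate_cohort(1000, confounding=2.0, seed=3)
        df0, df1 = cohort_to_frame(null), cohort_to_frame(conf)

        def smoking_gap(df):
            return abs(df[df.group == 1].smoking.mean() - df[df.group == 0].smoking.mean())

        assert smoking_gap(df1) > smoking_gap(df0) + 0.1

    def test_frame_has_covariates_and_features(self):
        from eritwin import COVARIATE_COLUMNS

        recs, _ = generate_cohort(50, seed=2)
        df = cohort_to_frame(recs)
        for col in COVARIATE_COLUMNS + ["ac", "sgs2", "sgm2", "leak", "group"]:
            assert col in df.columns
        assert df[["ac", "sgs2", "sgm2"]].to_numpy().min() >= 0
        assert df[["ac", "sgs2", "sgm2"]].to_numpy().max() <= 1


class TestAnalyticFeatures:
    def test_agree_with_mesh_measurement(self, defect_case, defect_field):
        from eritwin import extract_features

        spec = defect_case[0]
        ac_a, sgs_a, sgm_a = _analytic_features(spec)
        feats = extract_features(defect_field)
        # conicity over the 20-mm region of a 30-mm 12->10 neck
        assert feats.ac == pytest.approx(ac_a, abs=0.01)
        assert feats.sgm2 == pytest.approx(sgm_a, abs=0.05)

    def test_wall_radius_profile(self):
        spec = SyntheticCaseSpec(
            neck_radius_proximal=12.0, neck_radius_distal=10.0, neck_length=20.0
        )
        r = _wall_radius(spec, np.array([0.0, 10.0, 20.0]))
        assert np.allclose(r, [12.0, 11.0, 10.0])
        mid_sac = spec.neck_length + spec.sac_length / 2
        assert _wall_radius(spec, np.array([mid_sac]))[0] == pytest.approx(
            spec.sac_max_radius
        )
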