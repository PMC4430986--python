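import numpy as np
import pytest

from survcutpoint import (
    MarkerScenarioLaw,
    ObjectiveKind,
    Scenario,
    SurvivalSample,
    candidate_cutpoints,
    empirical_roc,
    find_cutpoint,
    generate_sample,
    operating_point_ellipse,
    se_sp_at_cutpoint,
    se_sp_curve,
    theoretical_se_sp,
)
from survcutpoint.exceptions import (
    ConstantMarkerError,
    LogitBoundaryError,
    NoEventsBeforeHorizonError,
)

from conftest import make_sample, random_uncensored_before_tau
from oracles import brute_force_cutpoint, naive_se_sp

NORMAL_HIGH = MarkerScenarioLaw("normal_homoscedastic", 2.56)


class TestCandidates:
    @pytest.mark.parametrize(
        "markers,expected",
        [
            ([1, 2, 2, 3], [1, 2]),
            ([0.5, 1.0, 1.5, 2.0], [0.5, 1.0, 1.5]),
        ],
    )
    def test_distinct_values_minus_maximum(self, markers, expected):
        sample = make_sample(markers, np.ones(len(markers)), np.ones(len(markers), int))
        assert candidate_cutpoints(sample).tolist() == expected

    def test_constant_marker_rejected(self):
        sample = make_sample([5, 5, 5], [1, 2, 3], [1, 1, 0])
        with pytest.raises(ConstantMarkerError):
            candidate_cutpoints(sample)


class TestFindCutpoint:
    def test_perfect_separation_smallest_tie_wins(self, four_record_sample):
        # candidates 0.5, 1.0, 1.5; both 1.0 and 1.5 reach J = 1
        r = find_cutpoint(four_record_sample, 1.0, ObjectiveKind.YOUDEN)
        assert r.cutpoint == 1.0
        assert r.objective_value == pytest.approx(1.0)
        assert r.n_candidates == 3

    def test_perfect_separation_corner_distance(self, four_record_sample):
        r = find_cutpoint(four_record_sample, 1.0, ObjectiveKind.CORNER_DISTANCE)
        assert r.cutpoint == 1.0
        assert r.objective_value == pytest.approx(0.0)

    def test_result_internally_consistent(self, four_record_sample):
        for kind in ObjectiveKind:
            r = find_cutpoint(four_record_sample, 1.0, kind)
            assert r.objective_value == pytest.approx(
                float(kind.evaluate(r.operating_point.se, r.operating_point.sp))
            )

    def test_consistency_on_large_simulated_sample(self):
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, None, 4000), seed=7)
        for kind in ObjectiveKind:
            assert find_cutpoint(sample, 0.35, kind).cutpoint == pytest.approx(1.28, abs=0.15)

    def test_invariant_to_record_order_and_duplication(self):
        rng = np.random.default_rng(5)
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, 1.0, 80), seed=12)
        perm = rng.permutation(sample.n)
        doubled = sample.subset(np.concatenate([np.arange(sample.n)] * 2))
        for kind in ObjectiveKind:
            ref = find_cutpoint(sample, 0.35, kind)
            assert find_cutpoint(sample.subset(perm), 0.35, kind).cutpoint == ref.cutpoint
            dup = find_cutpoint(doubled, 0.35, kind)
            assert dup.cutpoint == ref.cutpoint
            assert dup.operating_point.se == pytest.approx(ref.operating_point.se, abs=1e-12)
            assert dup.operating_point.sp == pytest.approx(ref.operating_point.sp, abs=1e-12)

    def test_matches_binary_brute_force_without_censoring(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            sample = random_uncensored_before_tau(rng, tau=0.35)
            for kind in ObjectiveKind:
                assert find_cutpoint(sample, 0.35, kind).cutpoint == brute_force_cutpoint(
                    sample, 0.35, kind
                )

    def test_each_objective_dominates_at_its_own_optimum(self):
        for seed in range(5):
            sample = generate_sample(Scenario(MarkerScenarioLaw("gamma", 1.97), 0.35, 1.0, 120), seed=seed)
            results = {k: find_cutpoint(sample, 0.35, k) for k in ObjectiveKind}
            for kind, r in results.items():
                for other in results.values():
                    v_other = float(kind.evaluate(other.operating_point.se, other.operating_point.sp))
                    if kind.direction == "maximize":
                        assert r.objective_value >= v_other - 1e-8
                    else:
                        assert r.objective_value <= v_other + 1e-8

    def test_no_events_before_horizon_propagates(self):
        sample = make_sample([1, 2, 3, 4], [5, 6, 7, 8], [1, 1, 0, 0])
        with pytest.raises(NoEventsBeforeHorizonError):
            find_cutpoint(sample, 1.0, ObjectiveKind.YOUDEN)


class TestCurveConsistency:
    def test_curve_equals_pointwise_estimator_under_censoring(self):
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, 0.66, 150), seed=3)
        candidates, se, sp = se_sp_curve(sample, 0.35)
        for i in range(0, candidates.size, 7):
            point = se_sp_at_cutpoint(sample, float(candidates[i]), 0.35)
            assert se[i] == pytest.approx(point.se, abs=1e-12)
            assert sp[i] == pytest.approx(point.sp, abs=1e-12)


class TestEmpiricalRoc:
    def test_perfect_separation_reaches_the_corner(self, four_record_sample):
        curve = empirical_roc(four_record_sample, 1.0)
        assert any((f == 0.0) and (t == 1.0) for f, t in zip(curve.fpf, curve.tpf))

    def test_uninformative_marker_hugs_the_diagonal(self):
        # diseased and disease-free markers share the same law
        sample = generate_sample(
            Scenario(MarkerScenarioLaw("normal_homoscedastic", 0.0), 0.35, None, 5000), seed=9
        )
        curve = empirical_roc(sample, 0.35)
        assert np.max(np.abs(curve.tpf - curve.fpf)) < 0.1

    def test_single_candidate_curve(self):
        sample = make_sample([1, 1, 2, 2], [0.2, 3.0, 0.1, 2.5], [1, 0, 1, 1])
        curve = empirical_roc(sample, 1.0)
        assert len(curve) == 1

    def test_bounds_and_ordering(self):
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, 1.0, 200), seed=2)
        curve = empirical_roc(sample, 0.35)
        assert np.all(np.diff(curve.cutpoints) > 0)
        assert np.all((curve.fpf >= 0) & (curve.fpf <= 1))
        assert np.all((curve.tpf >= 0) & (curve.tpf <= 1))


class TestOperatingPointEllipse:
    def test_center_contained_in_own_ellipse(self):
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, 1.0, 200), seed=4)
        c = find_cutpoint(sample, 0.35, ObjectiveKind.YOUDEN).cutpoint
        ell = operating_point_ellipse(sample, c, 0.35, seed=0)
        point = se_sp_at_cutpoint(sample, c, 0.35)
        assert ell.contains(1.0 - point.sp, point.se)
        assert np.all((ell.boundary > 0.0) & (ell.boundary < 1.0))
        assert ell.covariance.shape == (2, 2)
        assert ell.covariance[0, 1] == pytest.approx(ell.covariance[1, 0])

    def test_near_zero_correlation_without_censoring(self):
        # without censoring the two proportions come from disjoint binomial strata
        sample = generate_sample(Scenario(NORMAL_HIGH, 0.35, None, 800), seed=6)
        ell = operating_point_ellipse(sample, 1.28, 0.35, n_boot=500, seed=1)
        corr = ell.covariance[0, 1] / np.sqrt(ell.covariance[0, 0] * ell.covariance[1, 1])
        assert abs(corr) < 0.1

    def test_boundary_operating_point_rejected(self, four_record_sample):
        with pytest.raises(LogitBoundaryError):
            operating_point_ellipse(four_record_sample, 1.2, 1.0, seed=0)

    def test_nominal_coverage_under_normal_scenario(self):
        # true (FPF, TPF) at the fixed true cut-point falls inside the 95%
        # ellipse at close to the nominal rate
        law = MarkerScenarioLaw("normal_homoscedastic", 1.68)
        c_true = 0.84
        truth = theoretical_se_sp(law, c_true)
        fpf_true, tpf_true = 1.0 - truth.sp, truth.se
        scenario = Scenario(law, 0.35, 1.0, 200)
        hits = 0
        n_data = 500
        for i in range(n_data):
            sample = generate_sample(scenario, seed=[991, i])
            ell = operating_point_ellipse(sample, c_true, 0.35, n_boot=200, seed=[992, i])
            hits += ell.contains(fpf_true, tpf_true)
        assert 0.92 <= hits / n_data <= 0.98
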