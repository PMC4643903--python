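"""Omega-sweep tests: exhaustive p-value oracle, exact step integration."""

import itertools
import math

import numpy as np
import pytest

from resistwoc import (InvalidInputError, ResistSweepPoint, geometric_mean,
                       resist1, resist2, resist3, resist_analysis,
                       subgroup_pvalue, sweep_omega)


def exhaustive_subgroup_pvalue(estimates, k, observed_gm):
    """Oracle: enumerate every size-k subset and count log-distances >= obs."""
    logs = np.log(np.asarray(estimates, dtype=float))
    woc = logs.mean()
    obs = abs(math.log(observed_gm) - woc)
    dists = [abs(np.mean(sub) - woc)
             for sub in itertools.combinations(logs, k)]
    return np.mean([d >= obs - 1e-12 for d in dists])


class TestSubgroupPvalue:
    def test_full_crowd_is_never_significant(self):
        est = [3.0, 7.0, 11.0, 13.0]
        assert subgroup_pvalue(est, 4, geometric_mean(est),
                               n_resamples=100, seed=0) == 1.0

    def test_subgroup_at_woc_has_p_one(self):
        est = [1.0, 4.0, 4.0, 16.0]
        # {1, 16} has the same geometric mean (4) as the whole crowd
        p = subgroup_pvalue(est, 2, 4.0, n_resamples=1000, seed=0)
        assert p == 1.0

    def test_matches_exhaustive_enumeration_small_crowds(self, rng):
        """Monte-Carlo p agrees with the all-subsets oracle for n <= 10."""
        for trial in range(6):
            n = int(rng.integers(4, 11))
            est = np.exp(rng.normal(3.0, 1.0, size=n))
            k = int(rng.integers(1, n))
            sub = rng.choice(est, size=k, replace=False)
            gm = geometric_mean(sub)
            exact = exhaustive_subgroup_pvalue(est, k, gm)
            R = 40_000
            mc = subgroup_pvalue(est, k, gm, n_resamples=R, seed=trial)
            tol = 3 * math.sqrt(max(exact * (1 - exact), 1e-4) / R)
            assert abs(mc - exact) <= tol

    def test_hand_enumerated_quartet(self):
        # crowd {1,2,4,8}, subgroup {4,8}: 2 of the 6 subsets lie at least
        # as far from WOC (in log2: distances {1,.5,0,0,.5,1}, obs = 1)
        exact = exhaustive_subgroup_pvalue([1, 2, 4, 8], 2, geometric_mean([4, 8]))
        assert exact == pytest.approx(1 / 3)
        mc = subgroup_pvalue([1, 2, 4, 8], 2, geometric_mean([4, 8]),
                             n_resamples=60_000, seed=1)
        assert mc == pytest.approx(1 / 3, abs=0.01)

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidInputError):
            subgroup_pvalue([1.0, 2.0], 3, 1.5, n_resamples=10, seed=0)


class TestSweep:
    def test_nested_subgroup_sizes(self):
        ws = np.array([0.1, 0.2, 0.6, 0.9])
        est = np.array([1.0, 2.0, 4.0, 8.0])
        pts = sweep_omega(ws, est, n_resamples=200, seed=0)
        assert [p.n_omega for p in pts] == [1, 2, 3, 4]
        assert [p.omega for p in pts] == [0.1, 0.2, 0.6, 0.9]
        # nesting: members accumulate
        for a, b in zip(pts, pts[1:]):
            assert set(a.member_ids) <= set(b.member_ids)

    def test_identical_weights_single_point(self):
        ws = np.full(5, 0.3)
        est = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pts = sweep_omega(ws, est, n_resamples=200, seed=0)
        assert len(pts) == 1 and pts[0].n_omega == 5 and pts[0].p == 1.0

    def test_negative_weights_enter_by_magnitude(self):
        ws = np.array([-0.15, 0.1, 0.9])
        est = np.array([2.0, 4.0, 8.0])
        pts = sweep_omega(ws, est, n_resamples=100, seed=0)
        assert [p.omega for p in pts] == pytest.approx([0.1, 0.15, 0.9])

    def test_low_weight_high_estimates_raise_gm_as_omega_drops(self):
        # subjects with low |ws| hold high estimates: gm decreases with omega
        ws = np.linspace(0.05, 0.95, 10)
        est = np.geomspace(1000.0, 1.0, 10)
        pts = sweep_omega(ws, est, n_resamples=100, seed=0)
        gms = [p.gm for p in pts]
        assert all(a > b for a, b in zip(gms, gms[1:]))


def _pt(omega, gm, p, n=5):
    return ResistSweepPoint(omega=omega, n_omega=n, gm=gm, p=p)


class TestResistAggregators:
    def test_single_significant_step_returns_its_gm(self):
        sweep = [_pt(0.2, 150.0, 0.01), _pt(0.4, 150.0, 0.01),
                 _pt(0.8, 90.0, 0.5)]
        assert resist1(sweep) == pytest.approx(150.0)
        assert resist2(sweep) == pytest.approx(150.0)

    def test_hand_integrated_two_steps(self):
        # widths 0.1 and 0.3, q = 0.04 / 0.01, gm = 100 / 200
        sweep = [_pt(0.1, 100.0, 0.01), _pt(0.2, 200.0, 0.04)]
        expected = (0.1 * 0.04 * 100 + 0.3 * 0.01 * 200) / (0.1 * 0.04 + 0.3 * 0.01)
        assert resist1(sweep) == pytest.approx(expected)  # 142.857...
        # resist2 weights the same steps by width only
        assert resist2(sweep) == pytest.approx((0.1 * 100 + 0.3 * 200) / 0.4)

    def test_equal_width_significant_steps_average_plainly(self):
        sweep = [_pt(0.1, 100.0, 0.01), _pt(0.3, 400.0, 0.02)]
        assert resist2(sweep) == pytest.approx(250.0)

    def test_no_significance_is_undefined(self):
        sweep = [_pt(0.1, 100.0, 0.3), _pt(0.4, 200.0, 0.9)]
        assert resist1(sweep) is None
        assert resist2(sweep) is None
        assert resist3(sweep) is None

    def test_integration_stops_at_omega_max(self):
        sweep = [_pt(0.4, 100.0, 0.01), _pt(0.7, 900.0, 0.001)]
        # only [0.4, 0.5) of the first step is inside the window
        assert resist1(sweep, omega_max=0.5) == pytest.approx(100.0)

    def test_resist3_picks_min_p_then_larger_subgroup(self):
        sweep = [_pt(0.1, 100.0, 0.01, n=2), _pt(0.2, 200.0, 0.001, n=3),
                 _pt(0.3, 300.0, 0.001, n=4)]
        gm, omega = resist3(sweep)
        assert (gm, omega) == (300.0, 0.3)

    def test_estimates_bounded_by_step_gms(self, rng):
        ws = rng.uniform(0, 1, size=20)
        est = np.exp(rng.normal(4, 1, size=20))
        res = resist_analysis(ws, est, n_resamples=2000, seed=3)
        sig = [p for p in res.sweep if p.significant and p.omega <= 0.5]
        if res.resist1 is not None:
            gms = [p.gm for p in sig]
            assert min(gms) <= res.resist1 <= max(gms)
            assert min(gms) <= res.resist2 <= max(gms)


class TestRecovery:
    def test_resistant_minority_recovers_truth(self):
        """A biased conformist majority drags WOC; resist1 stays near truth."""
        from resistwoc import (SyntheticConfig, biased_crowd_subpopulations,
                               generate_experiment, social_weights)
        truth = 100.0
        cfg = SyntheticConfig(n_subjects=48, truth=truth,
                              subpopulations=biased_crowd_subpopulations(),
                              condition="full", seed=5)
        table, _ = generate_experiment(cfg)
        e1 = table.estimates(1)
        recs = [r for r in social_weights(table) if r.defined]
        ws = np.array([r.ws for r in recs])
        est = e1.loc[[r.subject_id for r in recs]].to_numpy()
        res = resist_analysis(ws, est, n_resamples=5000, seed=6)
        woc = geometric_mean(est)
        assert res.resist1 is not None
        assert abs(np.log(res.resist1 / truth)) < abs(np.log(woc / truth))
        # WOC is dragged low by roughly the conformist share of the bias
        assert np.log(woc / truth) == pytest.approx(-0.75, abs=0.35)
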