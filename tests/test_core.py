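"""Unit and property tests for the log-domain update model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistwoc import (Condition, DegenerateDataError, ExperimentTable,
                       InsufficientDataError, InvalidInputError, PriorSummary,
                       SignalMode, SocialSignal,
                       fit_social_weight_from_variance, geometric_mean,
                       infer_social_weight, predict_posterior, predict_update,
                       prior_summary, social_signal, social_weights,
                       zscore_pool)


class TestGeometricMean:
    @pytest.mark.parametrize("values, expected", [
        ([1, 10, 100], 10.0),
        ([7.3], 7.3),
        ([2, 8], 4.0),
    ])
    def test_known_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [1.0, -2.0]])
    def test_rejects_empty_or_nonpositive(self, bad):
        with pytest.raises(InvalidInputError):
            geometric_mean(bad)


class TestSocialSignal:
    def test_geometric_vs_arithmetic(self):
        g = social_signal([1, 10, 100], SignalMode.GEOMETRIC)
        a = social_signal([1, 10, 100], SignalMode.ARITHMETIC)
        assert g.xs == pytest.approx(10.0)
        assert a.xs == pytest.approx(37.0)
        assert a.mu_s == pytest.approx(np.log(37.0))

    def test_constant_sample_either_mode(self):
        for mode in SignalMode:
            assert social_signal([5.0] * 7, mode).xs == pytest.approx(5.0)


class TestUpdateRule:
    def test_endpoint_weights(self):
        sig = SocialSignal(SignalMode.GEOMETRIC, 250.0)
        assert predict_update(17.0, 0.0, sig) == pytest.approx(17.0)
        assert predict_update(17.0, 1.0, sig) == pytest.approx(250.0)

    def test_hand_computed_interior_point(self):
        # log10 domain: 0.47*2 + 0.53*3 = 2.53
        sig = SocialSignal(SignalMode.GEOMETRIC, 1000.0)
        assert predict_update(100.0, 0.53, sig) == pytest.approx(10 ** 2.53, rel=1e-12)

    def test_rejects_nonpositive_x1(self):
        with pytest.raises(InvalidInputError):
            predict_update(0.0, 0.5, SocialSignal(SignalMode.GEOMETRIC, 10.0))

    @given(x1=st.floats(1e-3, 1e6), ws=st.floats(-1.0, 2.0),
           xs=st.floats(1e-3, 1e6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_raw_and_log_domain_agree(self, x1, ws, xs):
        """x2 = x1^(1-ws) * xs^ws equals the log-domain linear combination."""
        sig = SocialSignal(SignalMode.GEOMETRIC, xs)
        raw = x1 ** (1 - ws) * xs ** ws
        assert predict_update(x1, ws, sig) == pytest.approx(raw, rel=1e-12)

    @given(y1=st.floats(-5, 5), ws=st.floats(-1.0, 2.0), mu_s=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_inference_round_trip(self, y1, ws, mu_s):
        """Noise-free updates are exactly invertible where identifiable."""
        if abs(mu_s - y1) <= 1e-6:
            return
        sig = SocialSignal(SignalMode.GEOMETRIC, float(np.exp(mu_s)))
        x2 = predict_update(float(np.exp(y1)), ws, sig)
        rec = infer_social_weight(y1, float(np.log(x2)), mu_s)
        assert rec.defined
        assert rec.ws == pytest.approx(ws, abs=1e-9)


class TestSocialWeight:
    @pytest.mark.parametrize("y1, y2, mu_s, expected", [
        (0.0, 0.0, 1.0, 0.0),    # no change
        (0.0, 1.0, 1.0, 1.0),    # full adoption
        (0.0, -0.2, 1.0, -0.2),  # contrarian move
    ])
    def test_known_weights(self, y1, y2, mu_s, expected):
        rec = infer_social_weight(y1, y2, mu_s)
        assert rec.defined and rec.ws == pytest.approx(expected)
        assert rec.wp == pytest.approx(1.0 - expected)

    def test_coincident_estimate_is_undefined(self):
        rec = infer_social_weight(1.0, 3.0, 1.0)
        assert not rec.defined and np.isnan(rec.ws)

    def test_table_level_inference_uses_condition_signal(self, two_round_table):
        recs = social_weights(two_round_table)
        assert len(recs) == 4
        sig = social_signal(two_round_table.estimates(1), SignalMode.GEOMETRIC)
        a = recs[0]
        assert a.ws == pytest.approx((a.y2 - a.y1) / (sig.mu_s - a.y1))

    def test_no_information_condition_has_no_signal(self, two_round_table):
        two_round_table.condition = Condition.NONE
        with pytest.raises(InvalidInputError):
            social_weights(two_round_table)


class TestPriorSummary:
    def test_repeated_value(self):
        e = float(np.e)
        df = pd.DataFrame({"subject_id": ["a", "b"], "round": [1, 1],
                           "estimate": [e, e]})
        p = prior_summary(ExperimentTable(data=df))
        assert (p.mu_p, p.sigma_p, p.n) == pytest.approx((1.0, 0.0, 2))

    def test_two_point_sample_sd(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "round": [1, 1],
                           "estimate": [1.0, float(np.e) ** 2]})
        p = prior_summary(ExperimentTable(data=df))
        assert p.mu_p == pytest.approx(1.0)
        assert p.sigma_p == pytest.approx(np.sqrt(2.0))

    def test_single_subject_insufficient(self):
        df = pd.DataFrame({"subject_id": ["a"], "round": [1], "estimate": [2.0]})
        with pytest.raises(InsufficientDataError):
            prior_summary(ExperimentTable(data=df))


class TestPosteriorPrediction:
    def test_zero_weight_reproduces_prior(self):
        prior = PriorSummary(mu_p=1.3, sigma_p=0.7, n=10)
        post = predict_posterior(prior, 0.0, Condition.FULL)
        assert (post.mu_f, post.sigma_f) == (prior.mu_p, prior.sigma_p)

    def test_full_condition_sd_shrinkage(self):
        post = predict_posterior(PriorSummary(0.0, 1.0, 10), 0.53, Condition.FULL)
        assert post.mu_f == 0.0
        assert post.sigma_f == pytest.approx(np.sqrt(0.47))

    def test_aggregated_condition_mean_shift(self):
        post = predict_posterior(PriorSummary(0.0, 2.0, 10), 0.5,
                                 Condition.AGGREGATED)
        assert post.mu_f == pytest.approx(1.0)       # 0.5 * 4 / 2
        assert post.sigma_f == pytest.approx(np.sqrt(2.0))

    def test_posterior_sd_strictly_decreases_in_ws(self):
        prior = PriorSummary(0.0, 1.0, 10)
        sds = [predict_posterior(prior, w, Condition.FULL).sigma_f
               for w in np.linspace(0.0, 0.99, 25)]
        assert np.all(np.diff(sds) < 0)

    def test_degenerate_weight_rejected(self):
        with pytest.raises(DegenerateDataError):
            predict_posterior(PriorSummary(0.0, 1.0, 10), 1.0)


class TestZScorePooling:
    def _tables(self, rng, k=3, n=20):
        from resistwoc import SyntheticConfig, generate_experiment
        out = []
        for i in range(k):
            t, _ = generate_experiment(
                SyntheticConfig(n_subjects=n, seed=int(rng.integers(2 ** 31))),
                group_id=f"g{i}")
            out.append(t)
        return out

    def test_round1_pool_is_standard_per_experiment(self, rng):
        tables = self._tables(rng)
        pooled = zscore_pool(tables, round=1)
        n = tables[0].n_subjects
        for i in range(len(tables)):
            z = pooled.z[i * n:(i + 1) * n]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_identical_rounds_give_identical_pools(self, rng):
        t = self._tables(rng, k=1)[0]
        d = t.data.copy()
        d.loc[d["round"] == 2, "estimate"] = d.loc[d["round"] == 1, "estimate"].to_numpy()
        t2 = ExperimentTable(data=d, condition=t.condition)
        p1 = zscore_pool([t2], round=1)
        p2 = zscore_pool([t2], round=2)
        np.testing.assert_allclose(p1.z, p2.z)

    def test_variance_fit_inverts_sd(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 0.6856, size=200_000)
        assert fit_social_weight_from_variance(z) == pytest.approx(0.53, abs=0.01)

    def test_variance_fit_degenerate_and_negative(self):
        assert fit_social_weight_from_variance(np.zeros(5)) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            ws = fit_social_weight_from_variance(np.array([-2.0, 2.0, -2.0, 2.0]))
        assert ws < 0
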