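import numpy as np
import pytest

from deepdismisl.bag_data import InstanceFeatureBag
from deepdismisl.percentile_mil import (
    SCENARIO_PERCENTILES,
    AttentionParams,
    HeadParams,
    MILSurvivalModel,
    PercentileAggregator,
    PercentileScheme,
    ScorerParams,
    _attention_combine,
    load_checkpoint,
    predict_risk,
    predict_risk_attention,
    save_checkpoint,
    scenario_scheme,
    score_instances,
    select_percentile_instances,
)

# ---------------------------------------------------------------------------
# independent selection oracle: full sort + explicit nearest rank + shift
# ---------------------------------------------------------------------------


def oracle_select(scores, percentiles, k):
    s = sorted(scores)
    n = len(s)
    out = []
    for p in percentiles:
        c = int(np.floor(p / 100.0 * (n - 1) + 0.5))  # half away from zero
        half = (k - 1) // 2
        if n >= k:
            lo = c - half
            if lo < 0:
                lo = 0
            if lo + k - 1 > n - 1:
                lo = n - k
            win = list(range(lo, lo + k))
        else:
            win = [min(max(r, 0), n - 1) for r in range(c - half, c + half + 1)]
        out.extend(s[r] for r in win)
    return np.array(out)


class TestSchemes:
    def test_printed_scenario_lists(self):
        assert scenario_scheme(1).percentiles == (0, 100)
        assert scenario_scheme(4).percentiles == (0, 0.1, 1, 5, 95, 99, 99.9, 100)
        assert len(scenario_scheme(7).percentiles) == 13

    def test_scenario_widths(self):
        widths = [len(SCENARIO_PERCENTILES[s]) for s in range(1, 8)]
        assert widths == [2, 4, 6, 8, 10, 12, 13]

    def test_out_of_range_scenario(self):
        with pytest.raises(ValueError):
            scenario_scheme(8)

    @pytest.mark.parametrize(
        "percentiles,k",
        [((50, 10), 1), ((0, 101), 1), ((0, 100), 2), ((0, 100), 0), ((), 1)],
    )
    def test_invalid_schemes_rejected(self, percentiles, k):
        with pytest.raises(ValueError):
            PercentileScheme(percentiles, k)


class TestSelection:
    def test_min_median_max(self):
        scheme = PercentileScheme((0, 50, 100), 1)
        np.testing.assert_array_equal(
            select_percentile_instances([30, 10, 50, 20, 40], scheme), [10, 30, 50]
        )

    def test_boundary_window_shifts_inward(self):
        scheme = PercentileScheme((100,), 3)
        np.testing.assert_array_equal(
            select_percentile_instances([10, 20, 30, 40, 50], scheme), [30, 40, 50]
        )

    def test_nearest_rank_at_median_of_12000(self):
        # round(0.5 * 11999) = 6000 on the ascending sort
        scores = np.random.default_rng(0).permutation(12_000).astype(float)
        scheme = PercentileScheme((50,), 1)
        assert select_percentile_instances(scores, scheme)[0] == 6000.0

    def test_tiny_bag_pads_with_boundaries(self):
        scheme = PercentileScheme((0, 100), 5)
        out = select_percentile_instances([1.0, 2.0], scheme)
        assert out.shape == (10,)
        assert set(out) == {1.0, 2.0}

    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    @pytest.mark.parametrize("scenario", [1, 4, 7])
    def test_matches_oracle_small_n(self, scenario, k):
        rng = np.random.default_rng(k * 100 + scenario)
        scheme = scenario_scheme(scenario, k)
        for n in range(1, 30):
            scores = rng.normal(size=n)
            np.testing.assert_array_equal(
                select_percentile_instances(scores, scheme),
                oracle_select(scores, scheme.percentiles, k),
            )

    def test_constant_shift_moves_every_selected_value(self, rng):
        scheme = scenario_scheme(5, 3)
        scores = rng.normal(size=40)
        base = select_percentile_instances(scores, scheme)
        np.testing.assert_allclose(
            select_percentile_instances(scores + 2.5, scheme), base + 2.5
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_percentile_instances([], scenario_scheme(1))


class TestScorer:
    def test_zero_params_zero_scores(self, rng):
        bag = InstanceFeatureBag("b", rng.normal(size=(8, 3)))
        params = ScorerParams(np.zeros((3, 4)), np.zeros(4), np.zeros(4), 0.0)
        np.testing.assert_array_equal(score_instances(bag, params), np.zeros(8))

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(10, 5))
        params = ScorerParams.init(5, 6, seed=0)
        s = score_instances(InstanceFeatureBag("b", X), params)
        perm = rng.permutation(10)
        s2 = score_instances(InstanceFeatureBag("b", X[perm]), params)
        np.testing.assert_allclose(s2, s[perm], atol=1e-12)

    def test_hand_computed_one_feature_scorer(self):
        # layer1 w=1 b=0 (ReLU), layer2 w=2 b=1: x=1 -> 3, x=-1 -> 1
        bag = InstanceFeatureBag("b", np.array([[1.0], [-1.0]]))
        params = ScorerParams(np.array([[1.0]]), np.zeros(1), np.array([2.0]), 1.0)
        np.testing.assert_allclose(score_instances(bag, params), [3.0, 1.0])

    def test_width_mismatch_rejected(self, rng):
        bag = InstanceFeatureBag("b", rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            score_instances(bag, ScorerParams.init(5, 4, seed=0))


class TestPredictRisk:
    def _model_parts(self, d=4, scenario=2, k=3, seed=0):
        scheme = scenario_scheme(scenario, k)
        scorer = ScorerParams.init(d, 6, seed=seed)
        head = HeadParams.init(scheme.width, (8, 4), seed=seed + 1)
        return scheme, scorer, head

    def test_zero_head_returns_bias(self, rng):
        scheme, scorer, _ = self._model_parts()
        head = HeadParams(hidden=[], w_out=np.zeros(scheme.width), b_out=1.25)
        bag = InstanceFeatureBag("b", rng.normal(size=(20, 4)))
        assert predict_risk(bag, scorer, scheme, head) == 1.25

    def test_head_width_is_percentiles_times_k(self):
        scheme = scenario_scheme(7, 5)
        assert scheme.width == 65

    def test_permutation_invariance(self, rng):
        scheme, scorer, head = self._model_parts()
        X = rng.normal(size=(25, 4))
        r1 = predict_risk(InstanceFeatureBag("b", X), scorer, scheme, head)
        r2 = predict_risk(
            InstanceFeatureBag("b", X[rng.permutation(25)]), scorer, scheme, head
        )
        assert r2 == pytest.approx(r1, abs=1e-7)

    def test_extremes_invariant_to_duplication(self, rng):
        scheme = PercentileScheme((0, 100), 1)
        scorer = ScorerParams.init(4, 6, seed=2)
        head = HeadParams.init(2, (4,), seed=3)
        X = rng.normal(size=(11, 4))
        r1 = predict_risk(InstanceFeatureBag("b", X), scorer, scheme, head)
        r2 = predict_risk(
            InstanceFeatureBag("b", np.vstack([X, X])), scorer, scheme, head
        )
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_width_mismatch_rejected(self, rng):
        scheme, scorer, _ = self._model_parts()
        bad_head = HeadParams.init(scheme.width + 1, (4,), seed=0)
        bag = InstanceFeatureBag("b", rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            predict_risk(bag, scorer, scheme, bad_head)


class TestAttention:
    def test_weights_sum_to_one(self, rng):
        attn = AttentionParams.init(8, seed=1)
        v = rng.normal(size=(5, 4, 3))
        _, (_, _, w, _) = _attention_combine(v, attn)
        np.testing.assert_allclose(w.sum(axis=-1), np.ones((5, 4)))

    def test_combine_is_softmax_weighted_mean(self, rng):
        attn = AttentionParams.init(4, seed=2)
        v = rng.normal(size=(3,))
        y, _ = _attention_combine(v[None, :], attn)
        # independent recomputation of the weighted mean
        e = np.tanh(v[:, None] * attn.wa1 + attn.ba1) @ attn.wa2 + attn.ba2
        w = np.exp(e - e.max())
        w /= w.sum()
        assert y[0] == pytest.approx(float(w @ v), abs=1e-12)

    def test_given_weights_give_weighted_value(self):
        # window [1,2,3] with weights [0.5,0.25,0.25] must aggregate to 1.75
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.5, 0.25, 0.25])
        assert float(w @ v) == 1.75

    def test_k1_reduces_to_plain_prediction(self, rng):
        scheme = scenario_scheme(3, 1)
        scorer = ScorerParams.init(4, 6, seed=0)
        head = HeadParams.init(len(scheme.percentiles), (8,), seed=1)
        attn = AttentionParams.init(8, seed=2)
        bag = InstanceFeatureBag("b", rng.normal(size=(15, 4)))
        assert predict_risk_attention(
            bag, scorer, scheme, attn, head
        ) == pytest.approx(predict_risk(bag, scorer, scheme, head), abs=1e-12)


class TestModelGradients:
    @pytest.mark.parametrize("attention", [False, True])
    def test_backward_matches_finite_differences(self, attention):
        from deepdismisl.survival_stats import cox_loss, cox_loss_gradient

        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 12, 4))
        t = np.array([2.0, 1.0, 3.0])
        e = np.array([1, 0, 1])
        model = MILSurvivalModel(
            4,
            PercentileAggregator(scenario_scheme(2, 3)),
            scorer_hidden=5,
            head_hidden=(6, 4),
            attention=attention,
            seed=1,
        )
        params = model.get_params()
        O, cache = model.forward(X)
        grads = model.backward(cox_loss_gradient(O, t, e), cache)
        for key, p in params.items():
            flat = np.atleast_1d(p).ravel()
            gflat = np.atleast_1d(np.asarray(grads[key], dtype=float)).ravel()
            for i in range(flat.size):
                orig = flat[i]
                h = 1e-5
                for sign, store in ((1, "up"), (-1, "dn")):
                    flat[i] = orig + sign * h
                    model.set_params(params)
                    val = cox_loss(model.forward(X)[0], t, e)
                    if sign == 1:
                        up = val
                    else:
                        dn = val
                flat[i] = orig
                fd = (up - dn) / (2 * h)
                assert gflat[i] == pytest.approx(fd, rel=1e-4, abs=1e-7), key

    def test_batched_forward_matches_single_bag_path(self, rng):
        scheme = scenario_scheme(4, 3)
        model = MILSurvivalModel(
            5, PercentileAggregator(scheme), scorer_hidden=6, head_hidden=(8,), seed=3
        )
        X = rng.normal(size=(4, 18, 5)).astype(np.float32).astype(float)
        O = model.predict(X)
        for b in range(4):
            single = predict_risk(
                InstanceFeatureBag("b", X[b]), model.scorer, scheme, model.head
            )
            assert O[b] == pytest.approx(single, abs=1e-10)


class TestCheckpoint:
    def test_round_trip_identical_predictions(self, tmp_path, rng):
        model = MILSurvivalModel(
            4,
            PercentileAggregator(scenario_scheme(3, 3)),
            scorer_hidden=6,
            head_hidden=(8, 4),
            seed=5,
        )
        X = rng.normal(size=(3, 10, 4))
        path = save_checkpoint(model, str(tmp_path / "model.npz"))
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
        assert loaded.aggregator.scheme == model.aggregator.scheme
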