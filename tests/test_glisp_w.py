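"""MIL meta-model: attention contracts, permutation invariance, aggregation."""

import numpy as np
import pytest

from glisp.glisp_w import (
    GlispWConfig,
    GlispWModel,
    WTrainConfig,
    attention_pool,
    glisp_w_forward,
    predict_case,
    train_glisp_w,
)


@pytest.fixture()
def model():
    return GlispWModel(config=GlispWConfig(encoding_dim=16, hidden_dim=12,
                                           attn_dim=8, head_hidden=6, bag_size=8),
                       seed=2)


class TestAttentionPool:
    def test_identical_instances_weighted_uniformly(self, model, rng):
        h = np.tile(rng.standard_normal(12), (5, 1))
        pooled, a = attention_pool(h, model.params["V"], model.params["c"],
                                   model.params["w"])
        np.testing.assert_allclose(a, np.full(5, 0.2), atol=1e-12)
        np.testing.assert_allclose(pooled, h[0], atol=1e-12)

    def test_dominant_score_saturates(self):
        # engineered scorer: first coordinate is the score, logit gap >= 20
        V = np.zeros((2, 1))
        V[0, 0] = 1.0
        w = np.array([30.0])  # tanh in (-1,1): gap 30*(1 - (-1)) > 20
        h = np.array([[5.0, 0.0], [-5.0, 0.0], [-5.0, 0.0]])
        _, a = attention_pool(h, V, np.zeros(1), w)
        assert a[0] > 0.999

    def test_matches_softmax_oracle(self, model, rng):
        h = rng.standard_normal((5, 12))
        pooled, a = attention_pool(h, model.params["V"], model.params["c"],
                                   model.params["w"])
        scores = np.tanh(h @ model.params["V"] + model.params["c"]) @ model.params["w"]
        e = np.exp(scores)
        np.testing.assert_allclose(a, e / e.sum(), atol=1e-6)
        np.testing.assert_allclose(pooled, (e / e.sum()) @ h, atol=1e-6)

    def test_empty_bag_rejected(self, model):
        with pytest.raises(ValueError):
            attention_pool(np.empty((0, 12)), model.params["V"], model.params["c"],
                           model.params["w"])


class TestForward:
    def test_weights_nonnegative_and_sum_to_one(self, model, rng):
        for _ in range(10):
            _, a = model.forward_bag(rng.standard_normal((8, 16)))
            assert (a >= 0).all()
            assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_probability_in_unit_interval(self, model, rng):
        p, _ = model.forward_bag(rng.standard_normal((8, 16)) * 10)
        assert 0.0 <= p <= 1.0

    def test_permutation_invariance(self, model, rng):
        enc = rng.standard_normal((8, 16))
        p1, a1 = glisp_w_forward(enc, model)
        perm = rng.permutation(8)
        p2, a2 = glisp_w_forward(enc[perm], model)
        assert p1 == pytest.approx(p2, abs=1e-6)
        np.testing.assert_allclose(a1[perm], a2, atol=1e-6)

    def test_k1_reduces_to_mlp_chain(self, model, rng):
        enc = rng.standard_normal(16)
        p1, a1 = model.forward_bag(enc[None])
        assert a1[0] == pytest.approx(1.0)
        # explicit MLP2(MLP1(h)) with attention bypassed
        pr = self._mlp_chain(model, enc)
        assert p1 == pytest.approx(pr, abs=1e-9)

    @staticmethod
    def _mlp_chain(model, enc):
        p = model.params
        h = np.maximum(enc @ p["W1"] + p["b1"], 0)
        q = np.maximum(h @ p["W2"] + p["b2"], 0)
        return float(1 / (1 + np.exp(-(q @ p["w3"] + p["b3"])[0])))

    def test_constant_bag_collapses_to_single_instance(self, model, rng):
        enc = rng.standard_normal(16)
        p_bag, _ = model.forward_bag(np.tile(enc, (8, 1)))
        p_one, _ = model.forward_bag(enc[None])
        assert p_bag == pytest.approx(p_one, abs=1e-9)

    def test_wrong_encoding_dim_raises(self, model, rng):
        with pytest.raises(ValueError):
            model.forward_bag(rng.standard_normal((8, 7)))


def _toy_bags(rng, n_cases=24, n_patches=20, dim=16, signal=1.0):
    from glisp.labels import GeneLabelTable

    enc, cases, rows = {}, {}, []
    for i in range(n_cases):
        cid, sid = f"c{i:02d}", f"c{i:02d}_s0"
        y = i % 2
        e = rng.standard_normal((n_patches, dim))
        if y:
            e[: n_patches // 4] += signal  # witness instances
        enc[sid] = e
        cases[sid] = cid
        rows.append({"case_id": cid, "task": "idh", "status": y})
    import pandas as pd

    return enc, cases, GeneLabelTable(pd.DataFrame(rows))


class TestTraining:
    def test_reruns_with_same_seed_match(self, rng):
        enc, cases, labels = _toy_bags(rng)
        cfg = WTrainConfig(max_epochs=3, seed=4)
        mcfg = GlispWConfig(encoding_dim=16, bag_size=8)
        m1, _ = train_glisp_w(enc, cases, labels, "idh", config=cfg, model_config=mcfg)
        m2, _ = train_glisp_w(enc, cases, labels, "idh", config=cfg, model_config=mcfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k]), k

    def test_single_class_cohort_raises(self, rng):
        enc, cases, labels = _toy_bags(rng)
        tab = labels.table.copy()
        tab["status"] = 1
        from glisp.labels import GeneLabelTable

        with pytest.raises(ValueError):
            train_glisp_w(enc, cases, GeneLabelTable(tab), "idh",
                          config=WTrainConfig(max_epochs=1),
                          model_config=GlispWConfig(encoding_dim=16, bag_size=8))

    def test_learns_separable_bags(self, rng):
        enc, cases, labels = _toy_bags(rng, signal=3.0)
        model, history = train_glisp_w(
            enc, cases, labels, "idh",
            config=WTrainConfig(max_epochs=40, patience=40, seed=0),
            model_config=GlispWConfig(encoding_dim=16, bag_size=8))
        assert history["val_loss"][-1] < history["val_loss"][0]


class TestCaseAggregation:
    def test_single_slide_single_bag_equals_slide_probability(self, model, rng):
        enc = rng.standard_normal((8, 16))  # exactly bag-size patches: bag = all
        p_case = predict_case(model, [enc], n_draws=1, seed=0)
        p_slide, _ = model.forward_bag(enc)
        assert p_case == pytest.approx(p_slide, abs=1e-9)

    def test_mean_policy_over_two_slides(self, model, monkeypatch, rng):
        import glisp.glisp_w as gw

        probs = iter([0.2, 0.8])
        monkeypatch.setattr(gw, "predict_slide",
                            lambda *a, **k: next(probs))
        assert gw.predict_case(model, [rng.standard_normal((8, 16))] * 2) == \
            pytest.approx(0.5)

    def test_no_slides_raises(self, model):
        with pytest.raises(ValueError):
            predict_case(model, [])

    def test_more_draws_stabilize_not_shift(self, model, rng):
        enc = rng.standard_normal((40, 16))
        p8 = predict_case(model, [enc], n_draws=8, seed=1)
        p64 = predict_case(model, [enc], n_draws=64, seed=1)
        assert abs(p8 - p64) < 0.1
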