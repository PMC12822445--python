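"""Forward-pass contracts of the bag-level transformer."""

import numpy as np
import pytest

from cpmp.data import TileBag
from cpmp.model import (
    ModelConfig,
    embed_tile,
    forward_bag,
    forward_with_graph,
    init_params,
    load_checkpoint,
    positional_encoding,
    project_tiles,
    save_checkpoint,
)


def hand_forward(bag, params, config):
    """Straight-line NumPy re-implementation of the whole forward pass,
    written independently of the autodiff graph code."""
    p = {k: v.data for k, v in params.items()}
    D, nh = config.embed_dim, config.n_heads
    dh = D // nh
    n = bag.n_tiles

    def ln(x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        sd = np.sqrt(x.var(axis=-1, keepdims=True) + eps)
        return (x - mu) / sd * g + b

    def sm(x):
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    X = np.maximum(bag.features @ p["proj_W"] + p["proj_b"], 0.0)
    X = X + positional_encoding(bag.coords, D)
    S = np.vstack([X, p["cls_token"]])
    seq = n + 1
    k = min(config.n_agents, seq)
    sizes = np.full(k, seq // k)
    sizes[: seq % k] += 1
    P = np.zeros((k, seq))
    start = 0
    for j, s in enumerate(sizes):
        P[j, start : start + s] = 1.0 / s
        start += s

    Z = ln(S, p["ln1_g"], p["ln1_b"])
    Q, K, V = Z @ p["Wq"] + p["bq"], Z @ p["Wk"] + p["bk"], Z @ p["Wv"] + p["bv"]
    heads = []
    for h in range(nh):
        sl = slice(h * dh, (h + 1) * dh)
        Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
        A = P @ Qh
        attn1 = sm(A @ Kh.T / np.sqrt(dh))
        attn2 = sm(Qh @ A.T / np.sqrt(dh))
        heads.append(attn2 @ (attn1 @ Vh))
    S = S + np.hstack(heads) @ p["Wo"] + p["bo"]
    Z2 = ln(S, p["ln2_g"], p["ln2_b"])
    S = S + np.maximum(Z2 @ p["ff_W1"] + p["ff_b1"], 0) @ p["ff_W2"] + p["ff_b2"]
    cls = S[n]
    logit = ln(cls, p["head_ln_g"], p["head_ln_b"]) @ p["head_W"] + p["head_b"]
    return 1.0 / (1.0 + np.exp(-logit[0]))


class TestProjection:
    def test_zero_input_gives_relu_bias(self, small_params, small_config):
        out = project_tiles(np.zeros((3, small_config.input_dim)), small_params)
        expected = np.maximum(small_params["proj_b"].data, 0.0)
        assert np.allclose(out, np.tile(expected, (3, 1)))

    def test_output_nonnegative_and_matches_loop(self, rng, small_params):
        X = rng.standard_normal((3, 8))
        out = project_tiles(X, small_params)
        assert (out >= 0).all()
        W, b = small_params["proj_W"].data, small_params["proj_b"].data
        for i in range(3):
            for j in range(W.shape[1]):
                val = sum(X[i, t] * W[t, j] for t in range(8)) + b[j]
                assert abs(out[i, j] - max(val, 0.0)) < 1e-6

    def test_channel_mismatch(self, small_params):
        with pytest.raises(ValueError):
            project_tiles(np.zeros((2, 5)), small_params)


class TestPositionalEncoding:
    def test_origin_is_exact_sin0_cos1(self):
        pe = positional_encoding(np.array([[0, 0]]), 16)[0]
        assert np.allclose(pe[0::2], 0.0)
        assert np.allclose(pe[1::2], 1.0)

    def test_equal_coords_equal_rows(self):
        pe = positional_encoding(np.array([[3, 7], [3, 7]]), 32)
        assert np.array_equal(pe[0], pe[1])

    def test_column_one_matches_transcendentals(self):
        pe = positional_encoding(np.array([[1, 0]]), 8)[0]
        for i in range(2):
            f = 1.0 / 10000 ** (2 * i / 4)
            assert np.isclose(pe[2 * i], np.sin(f))
            assert np.isclose(pe[2 * i + 1], np.cos(f))
        assert np.allclose(pe[4::2], 0.0) and np.allclose(pe[5::2], 1.0)

    def test_bounds_and_bad_dim(self, rng):
        pe = positional_encoding(rng.integers(0, 100, (20, 2)), 64)
        assert (pe >= -1).all() and (pe <= 1).all()
        with pytest.raises(ValueError):
            positional_encoding(np.array([[0, 0]]), 6)


class TestForwardBag:
    def test_probability_in_open_unit_interval(self, small_cohort, small_params,
                                               small_config):
        for bag, _ in small_cohort:
            pred = forward_bag(bag, small_params, small_config)
            assert 0.0 < pred.risk_probability < 1.0
            assert len(pred.tile_scores_raw) == bag.n_tiles

    def test_matches_hand_forward(self, small_cohort, small_params, small_config):
        for bag, _ in small_cohort[:3]:
            pred = forward_bag(bag, small_params, small_config)
            assert abs(pred.risk_probability
                       - hand_forward(bag, small_params, small_config)) < 1e-6

    def test_hand_oracle_with_prescribed_constants(self):
        """3-tile bag, embed 8, one agent, all weights small constants."""
        config = ModelConfig(input_dim=4, embed_dim=8, n_heads=2,
                             ff_hidden_dim=8, n_agents=1)
        params = init_params(config, seed=0)
        for i, (k, v) in enumerate(sorted(params.items())):
            v.data[...] = 0.01 * (i + 1) * (1 + np.arange(v.data.size).reshape(
                v.data.shape) % 3)
        bag = TileBag(
            slide_id="s", patient_id="p",
            features=np.arange(12, dtype=float).reshape(3, 4) / 10,
            coords=np.array([[0, 0], [1, 0], [0, 1]]),
        )
        pred = forward_bag(bag, params, config)
        assert abs(pred.risk_probability - hand_forward(bag, params, config)) < 1e-6

    def test_permutation_invariance_fixed_agents(self, small_cohort, small_params,
                                                 small_config, rng):
        bag, _ = small_cohort[0]
        agents = rng.standard_normal((3, small_config.embed_dim))
        base = forward_bag(bag, small_params, small_config, agents=agents)
        perm = rng.permutation(bag.n_tiles)
        shuffled = TileBag(
            slide_id=bag.slide_id, patient_id=bag.patient_id,
            features=bag.features[perm], coords=bag.coords[perm],
            label_normalized=bag.label_normalized,
        )
        pred = forward_bag(shuffled, small_params, small_config, agents=agents)
        assert abs(pred.risk_probability - base.risk_probability) < 1e-5

    def test_pooled_agents_are_order_sensitive_but_bounded(
        self, small_cohort, small_params, small_config, rng
    ):
        """Segment-pooled agents depend on tile order (a documented property
        of query pooling); the induced prediction shift stays small."""
        bag, _ = small_cohort[0]
        base = forward_bag(bag, small_params, small_config)
        for _ in range(5):
            perm = rng.permutation(bag.n_tiles)
            shuffled = TileBag(
                slide_id=bag.slide_id, patient_id=bag.patient_id,
                features=bag.features[perm], coords=bag.coords[perm],
                label_normalized=bag.label_normalized,
            )
            pred = forward_bag(shuffled, small_params, small_config)
            assert abs(pred.risk_probability - base.risk_probability) < 0.2

    def test_empty_and_mismatched_bags_rejected(self, small_params, small_config):
        with pytest.raises(ValueError):
            TileBag(slide_id="s", patient_id="p",
                    features=np.zeros((0, 8)), coords=np.zeros((0, 2)))
        bad = TileBag(slide_id="s", patient_id="p",
                      features=np.zeros((2, 5)),
                      coords=np.array([[0, 0], [1, 0]]))
        with pytest.raises(ValueError):
            forward_bag(bad, small_params, small_config)


class TestEmbedTile:
    def test_singleton_consistency(self, small_cohort, small_params, small_config):
        bag, _ = small_cohort[0]
        single = TileBag(
            slide_id="t", patient_id="p",
            features=bag.features[:1], coords=bag.coords[:1],
        )
        via_forward = forward_bag(single, small_params, small_config).embedding_cls
        via_embed = embed_tile(bag.features[0], bag.coords[0],
                               small_params, small_config)
        assert np.allclose(via_embed, via_forward)

    def test_deterministic_and_correct_length(self, small_params, small_config, rng):
        f = rng.standard_normal(8)
        e1 = embed_tile(f, [2, 3], small_params, small_config)
        e2 = embed_tile(f, [2, 3], small_params, small_config)
        assert np.array_equal(e1, e2)
        assert e1.shape == (small_config.embed_dim,)

    def test_default_embedding_width_is_256(self):
        config = ModelConfig(input_dim=4)
        params = init_params(config, seed=0)
        assert embed_tile(np.zeros(4), [0, 0], params, config).shape == (256,)


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        """Backprop vs central differences on 10 random parameters, 5-tile bag."""
        config = ModelConfig(input_dim=6, embed_dim=16, n_heads=2,
                             ff_hidden_dim=12, n_agents=2)
        params = init_params(config, seed=3)
        bag = TileBag(
            slide_id="s", patient_id="p",
            features=rng.standard_normal((5, 6)),
            coords=np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1]]),
            label_normalized=0.8,
        )

        def loss_value():
            node, _ = forward_with_graph(bag, params, config)
            d = node - bag.label_normalized
            return (d * d).sum()

        loss = loss_value()
        loss.backward()
        names = list(params)
        for _ in range(10):
            name = names[rng.integers(len(names))]
            p = params[name]
            idx = tuple(int(rng.integers(s)) for s in p.data.shape)
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_value().data)
            p.data[idx] = orig - eps
            lm = float(loss_value().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = p.grad[idx]
            assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an), 1e-8)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_params, small_config, small_cohort):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, small_params, small_config, seed=99)
        params2, config2, seed = load_checkpoint(path)
        assert seed == 99
        assert config2 == small_config
        assert set(params2) == set(small_params)
        for k in small_params:
            assert np.array_equal(params2[k].data, small_params[k].data)
        bag, _ = small_cohort[0]
        p1 = forward_bag(bag, small_params, small_config).risk_probability
        p2 = forward_bag(bag, params2, config2).risk_probability
        assert p1 == p2

    def test_missing_meta_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, x=np.zeros(3))
        with pytest.raises(ValueError, match="__meta__"):
            load_checkpoint(path)
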