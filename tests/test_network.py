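import numpy as np
import pytest

from mvitoxnet import nn
from mvitoxnet.network import (
    ModelConfig,
    decode,
    encode_fingerprint,
    encode_sequence,
    forward,
    forward_backward,
    fuse,
    init_parameters,
    load_checkpoint,
    parameter_schema,
    save_checkpoint,
)

TINY = dict(
    vocab_sizes={"char": 6, "atom": 5, "bpe": 7},
    embed_dim=4,
    conv_channels=3,
    repr_dim=3,
    fc_hidden=5,
    fp_dim=9,
    max_lengths={"char": 7, "atom": 5, "bpe": 4},
)


@pytest.fixture
def tiny_setup():
    cfg = ModelConfig(**TINY)
    params = init_parameters(cfg, seed=1)
    rng = np.random.default_rng(0)
    feats = {
        "char": rng.integers(0, 6, (4, 7)),
        "atom": rng.integers(0, 5, (4, 5)),
        "bpe": rng.integers(0, 7, (4, 4)),
        "fp": rng.random((4, 9)),
    }
    return cfg, params, feats


class TestActivations:
    def test_swish_values(self):
        assert nn.swish(np.array(0.0)) == 0.0
        assert np.isclose(nn.swish(np.array(1.0)), 1.0 / (1.0 + np.exp(-1.0)))

    def test_swish_limits(self):
        assert np.isclose(nn.swish(np.array(-50.0)), 0.0, atol=1e-12)
        assert np.isclose(nn.swish(np.array(50.0)) / 50.0, 1.0)

    def test_softplus_values(self):
        assert np.isclose(nn.softplus(np.array(0.0)), np.log(2.0))
        x = np.linspace(-30, 30, 13)
        assert (nn.softplus(x) > 0).all()

    def test_softplus_overflow_safe(self):
        assert np.isclose(nn.softplus(np.array(50.0)), 50.0, atol=1e-6)
        assert np.isfinite(nn.softplus(np.array(1000.0)))


class TestFuse:
    def test_alpha_beta_zero_collapses_to_atom(self):
        r = np.array([1.0, 2.0])
        out = fuse(r, np.ones(2), np.ones(2), np.ones(2), alpha=0.0, beta=0.0)
        assert np.array_equal(out, r)

    def test_worked_elementwise_example(self):
        out = fuse(
            np.array([1.0, 0.0]),
            np.array([0.0, 1.0]),
            np.array([1.0, 1.0]),
            np.array([2.0, 2.0]),
            alpha=0.1,
            beta=0.1,
        )
        assert np.allclose(out, [1.3, 0.4])

    def test_zero_inputs_zero_output(self):
        z = np.zeros(3)
        assert np.array_equal(fuse(z, z, z, z, 0.7, 0.3), z)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(2), np.zeros(3), np.zeros(2), np.zeros(2), 0.1, 0.1)


class TestDecode:
    def test_zero_params_give_half(self, tiny_setup):
        cfg, params, _ = tiny_setup
        params["dec_W"][:] = 0.0
        params["dec_b"][:] = 0.0
        assert decode(np.ones(cfg.repr_dim), params) == 0.5

    def test_hand_computed_logit(self, tiny_setup):
        cfg, params, _ = tiny_setup
        params["dec_W"][:] = [1.0, -1.0, 0.0]
        params["dec_b"][:] = 0.5
        p = decode(np.array([2.0, 1.0, 0.0]), params)
        assert np.isclose(p, 1.0 / (1.0 + np.exp(-1.5)))

    def test_output_strictly_inside_unit_interval(self, tiny_setup):
        cfg, params, feats = tiny_setup
        probs = forward(feats, params, cfg)
        assert ((probs > 0.0) & (probs < 1.0)).all()


class TestFingerprintEncoder:
    def test_zero_parameters_give_zero_vector(self, tiny_setup):
        cfg, params, _ = tiny_setup
        for k in ("fp_W1", "fp_b1", "fp_W2", "fp_b2"):
            params[k][:] = 0.0
        assert np.array_equal(encode_fingerprint(np.ones(9), params), np.zeros(3))

    def test_hand_set_two_unit_toy(self):
        cfg = ModelConfig(
            vocab_sizes={"char": 3, "atom": 3, "bpe": 3},
            embed_dim=2, conv_channels=2, repr_dim=1, fc_hidden=2, fp_dim=2,
            max_lengths={"char": 3, "atom": 3, "bpe": 3},
        )
        params = init_parameters(cfg, seed=0)
        params["fp_W1"][:] = [[1.0, 0.0], [0.0, 1.0]]
        params["fp_b1"][:] = 0.0
        params["fp_W2"][:] = [[1.0], [1.0]]
        params["fp_b2"][:] = 0.25
        x = np.array([1.0, -2.0])
        expected = nn.swish(np.array(1.0)) + nn.swish(np.array(-2.0)) + 0.25
        assert np.isclose(encode_fingerprint(x, params)[0], expected)

    def test_deterministic(self, tiny_setup):
        cfg, params, feats = tiny_setup
        a = encode_fingerprint(feats["fp"][0], params)
        b = encode_fingerprint(feats["fp"][0], params)
        assert np.array_equal(a, b)


class TestSequenceEncoder:
    def test_all_pad_sequence_is_finite(self, tiny_setup):
        cfg, params, _ = tiny_setup
        out = encode_sequence(np.zeros(5, dtype=np.int64), params, "atom")
        assert np.isfinite(out).all()

    def test_pad_extension_invariance(self, tiny_setup):
        cfg, params, _ = tiny_setup
        short = np.array([2, 3, 2], dtype=np.int64)
        extended = np.array([2, 3, 2, 0, 0, 0], dtype=np.int64)
        a = encode_sequence(short, params, "atom")
        b = encode_sequence(extended, params, "atom")
        assert np.allclose(a, b, atol=1e-12)

    def test_hand_computed_toy_conv(self):
        cfg = ModelConfig(
            vocab_sizes={"char": 4, "atom": 4, "bpe": 4},
            embed_dim=1, conv_channels=1, repr_dim=1, fc_hidden=2, fp_dim=2,
            max_lengths={"char": 3, "atom": 3, "bpe": 3},
        )
        params = init_parameters(cfg, seed=0)
        # identity-ish embedding: token t -> scalar t
        params["emb_atom"][:] = np.arange(4)[:, None].astype(float)
        params["emb_atom"][0] = 0.0
        params["conv1_atom_W"][:] = np.array([[[0.0, 1.0, 0.0]]])  # identity kernel
        params["conv1_atom_b"][:] = 0.0
        params["conv2_atom_W"][:] = np.array([[[1.0, 1.0, 1.0]]])  # sum kernel
        params["conv2_atom_b"][:] = 0.0
        ids = np.array([2, 3, 2], dtype=np.int64)
        # conv1 -> softplus([2,3,2]); conv2 sums neighbours with zero ends
        h1 = nn.softplus(np.array([2.0, 3.0, 2.0]))
        h2 = nn.softplus(
            np.array([h1[0] + h1[1], h1[0] + h1[1] + h1[2], h1[1] + h1[2]])
        )
        expected = h2.max()
        assert np.isclose(encode_sequence(ids, params, "atom")[0], expected)

    def test_id_out_of_range_raises(self, tiny_setup):
        cfg, params, _ = tiny_setup
        with pytest.raises(ValueError):
            encode_sequence(np.array([99], dtype=np.int64), params, "atom")


class TestForward:
    def test_batch_of_one_equals_single_call(self, tiny_setup):
        cfg, params, feats = tiny_setup
        batch = forward(feats, params, cfg)
        for i in range(4):
            one = {k: v[i : i + 1] for k, v in feats.items()}
            assert np.allclose(forward(one, params, cfg)[0], batch[i], atol=1e-12)

    def test_batch_composition_independence(self, tiny_setup):
        cfg, params, feats = tiny_setup
        probs = forward(feats, params, cfg)
        perm = [2, 0, 3, 1]
        shuffled = {k: v[perm] for k, v in feats.items()}
        assert np.allclose(forward(shuffled, params, cfg), probs[perm], atol=1e-12)

    def test_ablation_alpha_beta_zero_ignores_auxiliary_inputs(self, tiny_setup):
        cfg, params, feats = tiny_setup
        cfg0 = ModelConfig(**{**TINY, "alpha": 0.0, "beta": 0.0})
        base = forward(feats, params, cfg0)
        rng = np.random.default_rng(5)
        perturbed = dict(feats)
        perturbed["fp"] = rng.random(feats["fp"].shape)
        perturbed["char"] = rng.integers(0, 6, feats["char"].shape)
        perturbed["bpe"] = rng.integers(0, 7, feats["bpe"].shape)
        assert np.allclose(forward(perturbed, params, cfg0), base, atol=1e-12)

    def test_parameter_schema_stability(self):
        cfg = ModelConfig(**TINY)
        a = init_parameters(cfg, seed=0)
        b = init_parameters(cfg, seed=99)
        assert set(a) == set(b) == set(parameter_schema(cfg))
        for k in a:
            assert a[k].shape == b[k].shape


class TestGradients:
    def test_gradients_finite_and_complete(self, tiny_setup):
        cfg, params, feats = tiny_setup
        y = np.array([1.0, 0.0, 1.0, 0.0])
        loss, grads = forward_backward(feats, y, params, cfg)
        assert np.isfinite(loss)
        assert set(grads) == set(params)
        for g in grads.values():
            assert np.isfinite(g).all()

    def test_gradients_match_finite_differences(self, tiny_setup):
        cfg, params, feats = tiny_setup
        y = np.array([1.0, 0.0, 1.0, 0.0])
        _, grads = forward_backward(feats, y, params, cfg)
        rng = np.random.default_rng(2)
        eps = 1e-6
        for name in ("conv1_atom_W", "emb_char", "fp_W1", "dec_W", "conv2_bpe_b"):
            p = params[name]
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                if name.startswith("emb_") and idx[0] == 0:
                    continue  # pad row is pinned, not trained
                old = p[idx]
                p[idx] = old + eps
                lp, _ = forward_backward(feats, y, params, cfg)
                p[idx] = old - eps
                lm, _ = forward_backward(feats, y, params, cfg)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert np.isclose(grads[name][idx], num, rtol=1e-4, atol=1e-7)


class TestCheckpointIO:
    def test_round_trip_bit_exact(self, tiny_setup, tmp_path):
        cfg, params, _ = tiny_setup
        path = tmp_path / "ck.npz"
        save_checkpoint(path, params, cfg, epoch=3, val_auprc=0.75)
        loaded, cfg2, epoch, auprc = load_checkpoint(path)
        assert epoch == 3 and auprc == 0.75
        assert cfg2.to_dict() == cfg.to_dict()
        assert set(loaded) == set(params)
        for k in params:
            assert np.array_equal(loaded[k], params[k])


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(**{**TINY, "kernel_size": 4})
    with pytest.raises(ValueError):
        ModelConfig(**{**TINY, "repr_dim": 0})
    with pytest.raises(ValueError):
        ModelConfig(vocab_sizes={"char": 5})
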