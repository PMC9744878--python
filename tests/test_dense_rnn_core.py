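"""Architecture contracts: recurrence oracles, normalization, dimensions,
parameter counts, determinism, and ablation-flag semantics."""

import numpy as np
import pytest

import progrnn as pg
from progrnn.autodiff import Var
from progrnn.dense_rnn_core import (
    CompositeBlock,
    DenseBlock,
    NumericError,
    _GATES,
)
from progrnn.exceptions import ConfigurationError, DimensionError, StateError


def make_cb(input_dim, config, seed=0):
    return CompositeBlock(input_dim, config, np.random.default_rng(seed), "cb")


# ---------------------------------------------------------------------------
# Independent step-by-step recurrence oracles
# ---------------------------------------------------------------------------


def vanilla_oracle(x, W, U, b):
    """Loop-unrolled tanh recurrence, one sequence at a time."""
    B, T, _ = x.shape
    C = b.shape[0]
    out = np.zeros((B, T, C))
    for i in range(B):
        h = np.zeros(C)
        for t in range(T):
            h = np.tanh(x[i, t] @ W + h @ U + b)
            out[i, t] = h
    return out


def gru_oracle(x, W, U, b):
    B, T, _ = x.shape
    C = b.shape[0] // 3
    out = np.zeros((B, T, C))
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for i in range(B):
        h = np.zeros(C)
        for t in range(T):
            z = sig(x[i, t] @ W[:, :C] + h @ U[:, :C] + b[:C])
            r = sig(x[i, t] @ W[:, C:2 * C] + h @ U[:, C:2 * C] + b[C:2 * C])
            cand = np.tanh(
                x[i, t] @ W[:, 2 * C:] + (r * h) @ U[:, 2 * C:] + b[2 * C:]
            )
            h = (1 - z) * h + z * cand
            out[i, t] = h
    return out


def lstm_oracle(x, W, U, b):
    B, T, _ = x.shape
    C = b.shape[0] // 4
    out = np.zeros((B, T, C))
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for i in range(B):
        h, c = np.zeros(C), np.zeros(C)
        for t in range(T):
            z = x[i, t] @ W + h @ U + b
            ig, f = sig(z[:C]), sig(z[C:2 * C])
            o, g = sig(z[2 * C:3 * C]), np.tanh(z[3 * C:])
            c = f * c + ig * g
            h = o * np.tanh(c)
            out[i, t] = h
    return out


ORACLES = {"vanilla": vanilla_oracle, "gru": gru_oracle, "lstm": lstm_oracle}


@pytest.mark.parametrize("cell", ["vanilla", "gru", "lstm"])
def test_recurrence_matches_unrolled_oracle(cell):
    """BN off: composite block output equals the hand recurrence."""
    rng = np.random.default_rng(3)
    cfg = pg.ModelConfig(cell_type=cell, cells_per_cb=5, cbs_per_db=1,
                         n_dbs=1, batch_norm=False, seed=3)
    blk = make_cb(4, cfg, seed=3)
    x = rng.normal(size=(6, 3, 4))
    got = pg.composite_block_forward(x, blk, mode="train")
    want = ORACLES[cell](x, blk.W.value, blk.U.value, blk.b.value)
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


def test_zero_weights_give_zero_fixed_point():
    cfg = pg.ModelConfig(cells_per_cb=3, cbs_per_db=1, n_dbs=1, seed=0)
    blk = make_cb(2, cfg)
    for v in (blk.W, blk.U, blk.b):
        v.value = np.zeros_like(v.value)
    blk.running_mean[:] = 0.0
    blk.running_var[:] = 1.0
    blk.batches_seen = 1
    out = pg.composite_block_forward(np.ones((2, 4, 2)), blk, mode="infer")
    np.testing.assert_allclose(out, 0.0)


def test_bn_normalizes_symmetric_pair():
    """Batch activations {1, -1} -> mean 0, var 1 -> ±1/sqrt(1+eps)."""
    eps = 1e-3
    cfg = pg.ModelConfig(cells_per_cb=1, cbs_per_db=1, n_dbs=1,
                         bn_epsilon=eps, seed=0)
    blk = make_cb(1, cfg)
    # identity-ish recurrence producing exactly {1, -1}: bypass the cell by
    # normalizing hand-made activations through the BN path
    hs = [Var(np.array([[1.0], [-1.0]]), requires_grad=False)]
    blk_forward = blk.forward

    def fake_recur(xs):
        return hs

    blk._recur = fake_recur
    out = blk_forward([Var(np.zeros((2, 1)), requires_grad=False)], "train")
    np.testing.assert_allclose(
        out[0].value, np.array([[1.0], [-1.0]]) / np.sqrt(1.0 + eps)
    )


def test_train_mode_bn_has_unit_batch_statistics():
    rng = np.random.default_rng(1)
    cfg = pg.ModelConfig(cells_per_cb=6, cbs_per_db=1, n_dbs=1, seed=1)
    blk = make_cb(3, cfg, seed=1)
    out = pg.composite_block_forward(rng.normal(size=(8, 4, 3)), blk, "train")
    flat = out.reshape(-1, 6)
    np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(flat.var(axis=0), 1.0, atol=2e-2)  # eps bias


def test_infer_before_train_raises():
    cfg = pg.ModelConfig(cells_per_cb=2, cbs_per_db=1, n_dbs=1, seed=0)
    blk = make_cb(2, cfg)
    with pytest.raises(StateError, match="uninitialized"):
        pg.composite_block_forward(np.zeros((1, 2, 2)), blk, "infer")


def test_bn_identity_configuration_equals_bn_off():
    """gamma = sqrt(var+eps), beta = mean makes BN the identity."""
    rng = np.random.default_rng(5)
    cfg_on = pg.ModelConfig(cells_per_cb=4, cbs_per_db=1, n_dbs=1, seed=5)
    cfg_off = pg.ModelConfig(cells_per_cb=4, cbs_per_db=1, n_dbs=1,
                             batch_norm=False, seed=5)
    on, off = make_cb(3, cfg_on, seed=5), make_cb(3, cfg_off, seed=5)
    x = rng.normal(size=(4, 3, 3))
    raw = pg.composite_block_forward(x, off, "train")
    mean = raw.reshape(-1, 4).mean(axis=0)
    var = raw.reshape(-1, 4).var(axis=0)
    on.running_mean, on.running_var = mean, var
    on.batches_seen = 1
    on.gamma.value = np.sqrt(var + cfg_on.bn_epsilon)
    on.beta.value = mean.copy()
    got = pg.composite_block_forward(x, on, "infer")
    np.testing.assert_allclose(got, raw, rtol=1e-10, atol=1e-12)


# ---------------------------------------------------------------------------
# Dense block dimensions and composition
# ---------------------------------------------------------------------------


def test_dense_concatenation_dimensions():
    cfg = pg.ModelConfig(cells_per_cb=4, cbs_per_db=3, n_dbs=1, seed=0)
    db = DenseBlock(10, cfg, np.random.default_rng(0), "db")
    assert [b.input_dim for b in db.blocks] == [10, 14, 18]
    assert db.output_dim == 22
    out = pg.dense_block_forward(np.zeros((2, 2, 10)), db, "train")
    assert out.shape == (2, 2, 22)


def test_single_block_dense_vs_chained_differ_only_by_passthrough():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(3, 2, 5))
    cfg_on = pg.ModelConfig(cells_per_cb=4, cbs_per_db=1, n_dbs=1,
                            batch_norm=False, seed=2)
    cfg_off = pg.ModelConfig(cells_per_cb=4, cbs_per_db=1, n_dbs=1,
                             batch_norm=False, dense_connections=False, seed=2)
    on = DenseBlock(5, cfg_on, np.random.default_rng(2), "db")
    off = DenseBlock(5, cfg_off, np.random.default_rng(2), "db")
    out_on = pg.dense_block_forward(x, on, "train")
    out_off = pg.dense_block_forward(x, off, "train")
    assert out_on.shape == (3, 2, 9) and out_off.shape == (3, 2, 4)
    np.testing.assert_allclose(out_on[..., :5], x)        # input passthrough
    np.testing.assert_allclose(out_on[..., 5:], out_off)  # same CB weights


def test_chained_block_equals_composite_composition():
    rng = np.random.default_rng(4)
    cfg = pg.ModelConfig(cells_per_cb=3, cbs_per_db=2, n_dbs=1,
                         dense_connections=False, batch_norm=False, seed=4)
    db = DenseBlock(4, cfg, np.random.default_rng(4), "db")
    x = rng.normal(size=(2, 3, 4))
    via_db = pg.dense_block_forward(x, db, "train")
    h1 = pg.composite_block_forward(x, db.blocks[0], "train")
    h2 = pg.composite_block_forward(h1, db.blocks[1], "train")
    np.testing.assert_allclose(via_db, h2, rtol=1e-12)


def test_inconsistent_state_dimension_names_block():
    cfg = pg.ModelConfig(cells_per_cb=3, cbs_per_db=2, n_dbs=1, seed=0)
    db = DenseBlock(4, cfg, np.random.default_rng(0), "db")
    db.blocks[1].input_dim = 99  # corrupt
    with pytest.raises(DimensionError, match="block 1"):
        pg.dense_block_forward(np.zeros((1, 2, 4)), db, "train")


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------


def test_minimal_architecture_equals_hand_recurrence():
    """D=1, K=1, dense off, BN off is a plain RNN + affine head."""
    rng = np.random.default_rng(6)
    cfg = pg.ModelConfig(cells_per_cb=4, cbs_per_db=1, n_dbs=1,
                         dense_connections=False, batch_norm=False, seed=6)
    model = pg.DenseRNNRegressor(3, cfg)
    x = rng.normal(size=(5, 4, 3))
    got = pg.model_forward(x, model, "train")
    blk = model.dbs[0].blocks[0]
    hs = vanilla_oracle(x, blk.W.value, blk.U.value, blk.b.value)
    want = hs[:, -1, :] @ model.head_W.value[:, 0] + model.head_b.value[0]
    np.testing.assert_allclose(got, want, rtol=1e-10)


def test_zero_weights_head_bias_passthrough():
    cfg = pg.ModelConfig(cells_per_cb=3, cbs_per_db=2, n_dbs=2,
                         batch_norm=False, seed=0)
    model = pg.DenseRNNRegressor(4, cfg)
    for v in model.parameters().values():
        v.value = np.zeros_like(v.value)
    model.head_b.value = np.array([7.5])
    for T in (1, 3, 5):
        out = pg.model_forward(np.zeros((2, T, 4)), model, "train")
        np.testing.assert_allclose(out, 7.5)


def test_reference_configuration_instantiates_and_runs():
    cfg = pg.ModelConfig()  # 256 vanilla cells, 4 CBs per DB, 3 DBs
    assert (cfg.cells_per_cb, cfg.cbs_per_db, cfg.n_dbs) == (256, 4, 3)
    model = pg.DenseRNNRegressor(8, cfg)
    out = pg.model_forward(np.random.default_rng(0).normal(size=(2, 2, 8)),
                           model, "train")
    assert out.shape == (2,) and np.isfinite(out).all()


def test_same_seed_identical_outputs():
    cfg = pg.ModelConfig(cells_per_cb=4, cbs_per_db=2, n_dbs=2, seed=11)
    x = np.random.default_rng(1).normal(size=(3, 2, 5))
    a = pg.model_forward(x, pg.DenseRNNRegressor(5, cfg), "train")
    b = pg.model_forward(x, pg.DenseRNNRegressor(5, cfg), "train")
    np.testing.assert_array_equal(a, b)


def test_inference_is_batch_composition_invariant():
    rng = np.random.default_rng(9)
    cfg = pg.ModelConfig(cells_per_cb=4, cbs_per_db=2, n_dbs=2, seed=9)
    model = pg.DenseRNNRegressor(5, cfg)
    warm = rng.normal(size=(6, 3, 5))
    pg.model_forward(warm, model, "train")  # initialize running stats
    x = rng.normal(size=(8, 3, 5))
    full = pg.model_forward(x, model, "infer")
    perm = rng.permutation(8)
    shuffled = pg.model_forward(x[perm], model, "infer")
    np.testing.assert_allclose(shuffled, full[perm], rtol=1e-12)
    one_by_one = np.concatenate(
        [pg.model_forward(x[i:i + 1], model, "infer") for i in range(8)]
    )
    np.testing.assert_allclose(one_by_one, full, rtol=1e-12)


def test_nonfinite_input_reports_location():
    cfg = pg.ModelConfig(cells_per_cb=2, cbs_per_db=1, n_dbs=1, seed=0)
    model = pg.DenseRNNRegressor(2, cfg)
    x = np.zeros((1, 2, 2))
    x[0, 1, 0] = np.nan
    with pytest.raises(NumericError, match="db0"):
        pg.model_forward(x, model, "train")


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        pg.ModelConfig(cell_type="elman").validate()
    with pytest.raises(ConfigurationError):
        pg.ModelConfig(bn_epsilon=0.0).validate()
    with pytest.raises(ConfigurationError):
        pg.ModelConfig(n_dbs=0).validate()


# ---------------------------------------------------------------------------
# Parameter counting
# ---------------------------------------------------------------------------


def test_smallest_case_by_hand():
    cfg = pg.ModelConfig(cell_type="vanilla", cells_per_cb=1, cbs_per_db=1,
                         n_dbs=1, dense_connections=False, batch_norm=False)
    # recurrent (1+1+1) = 3 plus head (1+1) = 2
    assert pg.count_parameters(cfg, 1) == 5


def test_bn_adds_two_gamma_beta_vectors_per_cb():
    base = dict(cells_per_cb=7, cbs_per_db=3, n_dbs=2)
    off = pg.ModelConfig(batch_norm=False, **base)
    on = pg.ModelConfig(batch_norm=True, **base)
    n_cbs = base["cbs_per_db"] * base["n_dbs"]
    assert (pg.count_parameters(on, 5) - pg.count_parameters(off, 5)
            == 2 * base["cells_per_cb"] * n_cbs)


def test_closed_form_matches_introspection_on_random_configs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        cfg = pg.ModelConfig(
            cell_type=str(rng.choice(["vanilla", "gru", "lstm"])),
            cells_per_cb=int(rng.integers(1, 6)),
            cbs_per_db=int(rng.integers(1, 4)),
            n_dbs=int(rng.integers(1, 4)),
            dense_connections=bool(rng.integers(2)),
            batch_norm=bool(rng.integers(2)),
            seed=int(rng.integers(100)),
        )
        dim = int(rng.integers(1, 9))
        model = pg.DenseRNNRegressor(dim, cfg)
        assert pg.count_parameters(cfg, dim) == model.num_parameters()


# ---------------------------------------------------------------------------
# Gradients and serialization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("cell", ["vanilla", "gru", "lstm"])
def test_model_gradients_match_finite_differences(cell):
    rng = np.random.default_rng(0)
    cfg = pg.ModelConfig(cell_type=cell, cells_per_cb=3, cbs_per_db=2,
                         n_dbs=2, seed=7)
    model = pg.DenseRNNRegressor(4, cfg)
    x = rng.normal(size=(4, 3, 4))
    y = rng.normal(size=4)

    def loss_value():
        pred = model.forward(x, "train")
        d = pred - Var(y[:, None], requires_grad=False)
        return (d * d).mean()

    loss = loss_value()
    model.zero_grad()
    loss.backward()
    eps = 1e-6
    for name, p in model.parameters().items():
        idx = np.unravel_index(int(rng.integers(p.value.size)), p.value.shape)
        g = p.grad[idx] if p.grad is not None else 0.0
        snap = model.get_state()
        orig = p.value[idx]
        p.value[idx] = orig + eps
        lp = loss_value().value
        model.set_state(snap)
        p.value[idx] = orig - eps
        lm = loss_value().value
        model.set_state(snap)
        num = (lp - lm) / (2 * eps)
        assert abs(num - g) <= 1e-4 * max(1.0, abs(num)), name


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    cfg = pg.ModelConfig(cell_type="gru", cells_per_cb=3, cbs_per_db=2,
                         n_dbs=2, seed=8)
    model = pg.DenseRNNRegressor(4, cfg)
    x = rng.normal(size=(5, 3, 4))
    pg.model_forward(x, model, "train")
    model.target_center, model.target_scale = 30.0, 12.0
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = pg.DenseRNNRegressor.load(path)
    assert loaded.config == cfg
    np.testing.assert_array_equal(loaded.predict(x), model.predict(x))
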