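"""Densely connected, batch-normalized recurrent architecture.

The network is organised in two levels. A *composite block* (CB) is a
recurrent layer (vanilla/GRU/LSTM cell, hidden width C) whose per-time-step
output activations are batch-normalized:

    H_t = BN_{gamma,beta}(h_t),   h_t = f(x_t, h_{t-1})

with BN(h) = beta + gamma * (h - E[h]) / sqrt(Var[h] + eps). Normalization
statistics are pooled over the mini-batch and over time steps; gamma/beta
are shared across time. In train mode the statistics come from the current
mini-batch and update the running estimates; in inference mode the frozen
running estimates are used, so predictions are independent of batch
composition.

A *dense block* (DB) stacks K CBs with dense connectivity: CB_j receives
the concatenation of the block input and all earlier CB outputs, and the
block returns the concatenation of its input with every CB output. Dense
blocks themselves are stacked under the same concatenation rule. The final
dense block's last-time-step output feeds a single affine unit producing
one real-valued severity score per sequence. (A literal flatten over time
steps would tie the head's size to the sequence length, which is
incompatible with training across variable visit counts; the last-step
readout is the variable-length-consistent reading.)

With ``dense_connections`` off the blocks are plainly chained; with
``batch_norm`` off each CB is a bare recurrent layer. Together the two
flags span the ablation grid the harness compares.

All computation runs on the package's numpy autodiff tape, so the same
forward code serves training (gradients) and inference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Var, concat
from .exceptions import (
    ConfigurationError,
    DimensionError,
    ProgrnnError,
    StateError,
)


class NumericError(ProgrnnError):
    """A non-finite value appeared inside the network."""


CELL_TYPES = ("vanilla", "gru", "lstm")
_GATES = {"vanilla": 1, "gru": 3, "lstm": 4}

BN_MOMENTUM = 0.1  # EMA weight of the current batch in the running stats


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs.

    Defaults are the reference configuration: 256 vanilla cells per
    composite block, 4 composite blocks per dense block, 3 dense blocks,
    with dense connections and batch normalization enabled.
    """

    cell_type: str = "vanilla"
    cells_per_cb: int = 256
    cbs_per_db: int = 4
    n_dbs: int = 3
    dense_connections: bool = True
    batch_norm: bool = True
    l2_coeff: float = 1e-4
    bn_epsilon: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"cell_type must be one of {CELL_TYPES}")
        if min(self.cells_per_cb, self.cbs_per_db, self.n_dbs) < 1:
            raise ConfigurationError("cells_per_cb, cbs_per_db, n_dbs must be >= 1")
        if self.bn_epsilon <= 0:
            raise ConfigurationError("bn_epsilon must be > 0")
        if self.l2_coeff < 0:
            raise ConfigurationError("l2_coeff must be >= 0")


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng, n):
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# Composite block
# ---------------------------------------------------------------------------


class CompositeBlock:
    """Recurrent layer + batch normalization of its output activations."""

    def __init__(self, input_dim: int, config: ModelConfig, rng, name: str):
        config.validate()
        self.name = name
        self.config = config
        self.input_dim = int(input_dim)
        C = config.cells_per_cb
        g = _GATES[config.cell_type]

        self.W = Var(np.concatenate(
            [_glorot(rng, input_dim, C) for _ in range(g)], axis=1))
        self.U = Var(np.concatenate(
            [_orthogonal(rng, C) for _ in range(g)], axis=1))
        bias = np.zeros(g * C)
        if config.cell_type == "lstm":
            bias[C:2 * C] = 1.0  # forget-gate bias
        self.b = Var(bias)

        self.gamma = Var(np.ones(C))
        self.beta = Var(np.zeros(C))
        self.running_mean = np.zeros(C)
        self.running_var = np.ones(C)
        self.batches_seen = 0

    # -- parameters -------------------------------------------------------

    def parameters(self) -> dict:
        p = {f"{self.name}.W": self.W, f"{self.name}.U": self.U,
             f"{self.name}.b": self.b}
        if self.config.batch_norm:
            p[f"{self.name}.gamma"] = self.gamma
            p[f"{self.name}.beta"] = self.beta
        return p

    def rnn_weight_vars(self) -> list:
        """Input and recurrent weight matrices — the L2-penalized set."""
        return [self.W, self.U]

    @property
    def output_dim(self) -> int:
        return self.config.cells_per_cb

    # -- forward ----------------------------------------------------------

    def _recur(self, xs: list) -> list:
        C = self.config.cells_per_cb
        B = xs[0].shape[0]
        h = Var(np.zeros((B, C)), requires_grad=False)
        cell = self.config.cell_type
        if cell == "lstm":
            c = Var(np.zeros((B, C)), requires_grad=False)
        hs = []
        for x in xs:
            if x.shape[1] != self.input_dim:
                raise DimensionError(
                    f"{self.name}: input dim {x.shape[1]} != {self.input_dim}"
                )
            z = x @ self.W + h @ self.U + self.b
            if cell == "vanilla":
                h = z.tanh()
            elif cell == "gru":
                # gate pre-activations are packed [update, reset, candidate];
                # the candidate needs the reset-gated state, so its recurrent
                # part is recomputed rather than sliced out of z.
                zu = Var(z.value[:, :C], parents=(z,),
                         vjps=(lambda g, C=C: _pad_cols(g, 0, 3 * C),))
                zr = Var(z.value[:, C:2 * C], parents=(z,),
                         vjps=(lambda g, C=C: _pad_cols(g, C, 3 * C),))
                update = zu.sigmoid()
                reset = zr.sigmoid()
                Wh = _col_slice(self.W, 2 * C, 3 * C)
                Uh = _col_slice(self.U, 2 * C, 3 * C)
                bh = _col_slice_vec(self.b, 2 * C, 3 * C)
                cand = (x @ Wh + (reset * h) @ Uh + bh).tanh()
                h = (1.0 - update) * h + update * cand
            else:  # lstm
                i = _col_slice(z, 0, C).sigmoid()
                f = _col_slice(z, C, 2 * C).sigmoid()
                o = _col_slice(z, 2 * C, 3 * C).sigmoid()
                gcell = _col_slice(z, 3 * C, 4 * C).tanh()
                c = f * c + i * gcell
                h = o * c.tanh()
            hs.append(h)
        return hs

    def forward(self, xs: list, mode: str) -> list:
        """Run the recurrence over a batch of same-length sequences.

        ``xs`` is a list over time steps of (B, input_dim) Vars; returns the
        list of (B, C) output Vars, full sequence.
        """
        _check_mode(mode)
        hs = self._recur(xs)
        if not self.config.batch_norm:
            return hs
        eps = self.config.bn_epsilon
        if mode == "train":
            hcat = concat(hs, axis=0)  # (B*T, C): stats pooled over batch+time
            m = hcat.mean(axis=0)
            d = hcat - m
            v = (d * d).mean(axis=0)
            self.running_mean = (
                (1 - BN_MOMENTUM) * self.running_mean + BN_MOMENTUM * m.value
            )
            self.running_var = (
                (1 - BN_MOMENTUM) * self.running_var + BN_MOMENTUM * v.value
            )
            self.batches_seen += 1
        else:
            if self.batches_seen == 0:
                raise StateError(
                    f"{self.name}: inference before any train-mode batch; "
                    "running statistics are uninitialized"
                )
            m = Var(self.running_mean, requires_grad=False)
            v = Var(self.running_var, requires_grad=False)
        denom = (v + eps).sqrt()
        return [self.beta + self.gamma * ((h - m) / denom) for h in hs]


def _pad_cols(g, start, total):
    out = np.zeros((g.shape[0], total))
    out[:, start:start + g.shape[1]] = g
    return out


def _col_slice(var: Var, a: int, b: int) -> Var:
    return Var(
        var.value[:, a:b],
        parents=(var,),
        vjps=(lambda g: _pad_cols(g, a, var.value.shape[1]),),
    )


def _col_slice_vec(var: Var, a: int, b: int) -> Var:
    def vjp(g):
        out = np.zeros(var.value.shape[0])
        out[a:b] = g.sum(axis=0) if g.ndim > 1 else g
        return out

    return Var(var.value[a:b], parents=(var,), vjps=(vjp,))


def _check_mode(mode):
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")


# ---------------------------------------------------------------------------
# Dense block
# ---------------------------------------------------------------------------


class DenseBlock:
    """K composite blocks with (optional) dense concatenation links."""

    def __init__(self, input_dim: int, config: ModelConfig, rng, name: str):
        self.name = name
        self.config = config
        self.input_dim = int(input_dim)
        C = config.cells_per_cb
        self.blocks = []
        for j in range(config.cbs_per_db):
            if config.dense_connections:
                dim = input_dim + j * C
            else:
                dim = input_dim if j == 0 else C
            self.blocks.append(
                CompositeBlock(dim, config, rng, name=f"{name}.cb{j}")
            )
        if config.dense_connections:
            self.output_dim = input_dim + config.cbs_per_db * C
        else:
            self.output_dim = C

    def parameters(self) -> dict:
        p = {}
        for blk in self.blocks:
            p.update(blk.parameters())
        return p

    def rnn_weight_vars(self) -> list:
        return [w for blk in self.blocks for w in blk.rnn_weight_vars()]

    def forward(self, xs: list, mode: str) -> list:
        _check_mode(mode)
        T = len(xs)
        if self.config.dense_connections:
            feats = [[x] for x in xs]  # per-time-step growing feature lists
            for j, blk in enumerate(self.blocks):
                inp = [f[0] if len(f) == 1 else concat(f, axis=1) for f in feats]
                try:
                    hs = blk.forward(inp, mode)
                except DimensionError as e:
                    raise DimensionError(f"block {j} of {self.name}: {e}") from e
                for t in range(T):
                    feats[t].append(hs[t])
            return [concat(f, axis=1) for f in feats]
        out = xs
        for j, blk in enumerate(self.blocks):
            try:
                out = blk.forward(out, mode)
            except DimensionError as e:
                raise DimensionError(f"block {j} of {self.name}: {e}") from e
        return out


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------


class DenseRNNRegressor:
    """Stack of dense blocks plus a single-unit affine regression head.

    The head reads the final dense block's output at the last time step and
    returns one real score per sequence. ``target_center``/``target_scale``
    hold the training-set standardization of the regression target; they
    are identity (0, 1) until :func:`progrnn.training.train` sets them, and
    :meth:`predict` always returns scores on the raw 0-272 scale.
    """

    def __init__(self, input_dim: int, config: ModelConfig):
        config.validate()
        self.config = config
        self.input_dim = int(input_dim)
        rng = np.random.default_rng(config.seed)

        self.dbs = []
        dims_in, dims_out = [], []
        for i in range(config.n_dbs):
            if config.dense_connections:
                dim = input_dim + sum(dims_out)
            else:
                dim = input_dim if i == 0 else dims_out[-1]
            db = DenseBlock(dim, config, rng, name=f"db{i}")
            self.dbs.append(db)
            dims_in.append(dim)
            dims_out.append(db.output_dim)
        self.head_dim = dims_out[-1]
        self.head_W = Var(_glorot(rng, self.head_dim, 1))
        self.head_b = Var(np.zeros(1))
        self.target_center = 0.0
        self.target_scale = 1.0

    # -- parameter access -------------------------------------------------

    def parameters(self) -> dict:
        p = {}
        for db in self.dbs:
            p.update(db.parameters())
        p["head.W"] = self.head_W
        p["head.b"] = self.head_b
        return p

    def rnn_weight_vars(self) -> list:
        return [w for db in self.dbs for w in db.rnn_weight_vars()]

    def num_parameters(self) -> int:
        return sum(v.value.size for v in self.parameters().values())

    def zero_grad(self) -> None:
        for v in self.parameters().values():
            v.zero_grad()

    # -- state snapshot ----------------------------------------------------

    def _composite_blocks(self):
        for db in self.dbs:
            yield from db.blocks

    def get_state(self) -> dict:
        state = {k: v.value.copy() for k, v in self.parameters().items()}
        for blk in self._composite_blocks():
            state[f"{blk.name}.running_mean"] = blk.running_mean.copy()
            state[f"{blk.name}.running_var"] = blk.running_var.copy()
            state[f"{blk.name}.batches_seen"] = np.array(blk.batches_seen)
        state["target_center"] = np.array(self.target_center)
        state["target_scale"] = np.array(self.target_scale)
        return state

    def set_state(self, state: dict) -> None:
        for k, v in self.parameters().items():
            v.value = np.asarray(state[k], dtype=np.float64).copy()
        for blk in self._composite_blocks():
            blk.running_mean = np.asarray(state[f"{blk.name}.running_mean"]).copy()
            blk.running_var = np.asarray(state[f"{blk.name}.running_var"]).copy()
            blk.batches_seen = int(state[f"{blk.name}.batches_seen"])
        self.target_center = float(state["target_center"])
        self.target_scale = float(state["target_scale"])

    def save(self, path) -> None:
        state = self.get_state()
        state["__config__"] = np.array(
            json.dumps(dataclasses.asdict(self.config))
        )
        state["__input_dim__"] = np.array(self.input_dim)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "DenseRNNRegressor":
        with np.load(path, allow_pickle=False) as npz:
            state = {k: npz[k] for k in npz.files}
        cfg = ModelConfig(**json.loads(str(state.pop("__config__"))))
        model = cls(int(state.pop("__input_dim__")), cfg)
        model.set_state(state)
        return model

    # -- forward -----------------------------------------------------------

    def forward(self, x_batch: np.ndarray, mode: str) -> Var:
        """Forward a (B, T, F) batch; returns a (B, 1) Var of scaled scores."""
        _check_mode(mode)
        x_batch = np.asarray(x_batch, dtype=np.float64)
        if x_batch.ndim != 3:
            raise DimensionError(
                f"expected (batch, time, features), got shape {x_batch.shape}"
            )
        if x_batch.shape[2] != self.input_dim:
            raise DimensionError(
                f"input feature dim {x_batch.shape[2]} != {self.input_dim}"
            )
        T = x_batch.shape[1]
        xs = [Var(x_batch[:, t, :], requires_grad=False) for t in range(T)]

        if self.config.dense_connections:
            outputs = []  # per-DB output sequences
            for i, db in enumerate(self.dbs):
                if outputs:
                    inp = [
                        concat([xs[t]] + [o[t] for o in outputs], axis=1)
                        for t in range(T)
                    ]
                else:
                    inp = xs
                out = db.forward(inp, mode)
                self._check_finite(out[-1], f"db{i}")
                outputs.append(out)
            last = outputs[-1][-1]
        else:
            seq = xs
            for i, db in enumerate(self.dbs):
                seq = db.forward(seq, mode)
                self._check_finite(seq[-1], f"db{i}")
            last = seq[-1]
        return last @ self.head_W + self.head_b

    @staticmethod
    def _check_finite(var: Var, where: str) -> None:
        if not np.isfinite(var.value).all():
            raise NumericError(f"non-finite activations at {where}, last step")

    def predict(self, x_batch: np.ndarray) -> np.ndarray:
        """Inference-mode predictions on the raw score scale, shape (B,)."""
        out = self.forward(x_batch, mode="infer").value[:, 0]
        return out * self.target_scale + self.target_center


# ---------------------------------------------------------------------------
# Functional wrappers and the parameter-count closed form
# ---------------------------------------------------------------------------


def composite_block_forward(x_seq: np.ndarray, block: CompositeBlock,
                            mode: str) -> np.ndarray:
    """Run one composite block on a (B, T, F) array; returns (B, T, C)."""
    x_seq = np.asarray(x_seq, dtype=np.float64)
    xs = [Var(x_seq[:, t, :], requires_grad=False) for t in range(x_seq.shape[1])]
    hs = block.forward(xs, mode)
    return np.stack([h.value for h in hs], axis=1)


def dense_block_forward(x_seq: np.ndarray, block: DenseBlock,
                        mode: str) -> np.ndarray:
    """Run one dense block on a (B, T, F) array; returns (B, T, out_dim)."""
    x_seq = np.asarray(x_seq, dtype=np.float64)
    xs = [Var(x_seq[:, t, :], requires_grad=False) for t in range(x_seq.shape[1])]
    hs = block.forward(xs, mode)
    return np.stack([h.value for h in hs], axis=1)


def model_forward(x_batch: np.ndarray, model: DenseRNNRegressor,
                  mode: str = "infer") -> np.ndarray:
    """Predicted scores for a batch of same-length sequences, shape (B,)."""
    out = model.forward(x_batch, mode).value[:, 0]
    return out * model.target_scale + model.target_center


def count_parameters(config: ModelConfig, input_dim: int) -> int:
    """Closed-form parameter total for a given config and input width.

    Per composite block with input width d: g*C*(d + C + 1) cell parameters
    (g = 1/3/4 gates for vanilla/GRU/LSTM) plus 2C when batch normalization
    is on; the head adds (final width + 1).
    """
    config.validate()
    C = config.cells_per_cb
    g = _GATES[config.cell_type]
    total = 0

    def db_params(d_in):
        nonlocal total
        for j in range(config.cbs_per_db):
            if config.dense_connections:
                d = d_in + j * C
            else:
                d = d_in if j == 0 else C
            total += g * C * (d + C + 1)
            if config.batch_norm:
                total += 2 * C
        return (d_in + config.cbs_per_db * C) if config.dense_connections else C

    dims_out = []
    for i in range(config.n_dbs):
        if config.dense_connections:
            d = input_dim + sum(dims_out)
        else:
            d = input_dim if i == 0 else dims_out[-1]
        dims_out.append(db_params(d))
    total += dims_out[-1] + 1  # affine head
    return total
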