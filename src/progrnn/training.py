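"""Optimization loop: MSE + L2 loss, Nadam, same-length mini-batching,
validation-driven learning-rate decay, early stopping, best-checkpoint
selection.

Variable-length histories are handled by grouping samples by history
length and batching only within a group, so every mini-batch is a
rectangular (B, T, F) array. The regression target is standardized with
the training-split mean/sd; the L2 penalty touches only the recurrent
layers' input/recurrent weight matrices (not biases, normalization
parameters, or the head).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Var
from .cohort_io import TrainingSample
from .dense_rnn_core import DenseRNNRegressor
from .exceptions import ConfigurationError, TrainingDivergedError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    max_epochs: int = 200
    initial_lr: float = 1e-2
    lr_factor: float = 0.2
    lr_patience_epochs: int = 10
    l2_coeff: float = 1e-4
    early_stop_patience: int = 30
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.lr_factor < 1.0):
            raise ConfigurationError("lr_factor must lie in (0, 1)")
        if self.lr_patience_epochs < 1 or self.early_stop_patience < 1:
            raise ConfigurationError("patience values must be >= 1")
        if self.initial_lr <= 0:
            raise ConfigurationError("initial_lr must be > 0")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigurationError("val_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")
        if self.l2_coeff < 0:
            raise ConfigurationError("l2_coeff must be >= 0")


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


def make_length_batches(samples, batch_size, seed_or_rng) -> list:
    """Group samples by history length, shuffle, and chunk into batches.

    Every sample appears in exactly one batch; batch order is shuffled
    across length groups so an epoch interleaves lengths.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    groups = defaultdict(list)
    for s in samples:
        groups[s.n].append(s)
    batches = []
    for n in sorted(groups):
        grp = list(groups[n])
        order = rng.permutation(len(grp))
        for start in range(0, len(grp), batch_size):
            batches.append([grp[i] for i in order[start:start + batch_size]])
    batch_order = rng.permutation(len(batches))
    return [batches[i] for i in batch_order]


def _stack(batch) -> tuple:
    x = np.stack([s.x_seq for s in batch])
    y = np.array([s.target for s in batch], dtype=np.float64)
    return x, y


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


def lr_step(current_lr: float, epochs_since_improvement: int,
            factor: float = 0.2, patience: int = 10) -> float:
    """Multiply the rate by ``factor`` at each full patience window without
    validation improvement; otherwise leave it unchanged."""
    if epochs_since_improvement < 0:
        raise ValueError("epochs_since_improvement must be >= 0")
    if current_lr <= 0:
        raise ValueError("current_lr must be > 0")
    if epochs_since_improvement > 0 and epochs_since_improvement % patience == 0:
        return current_lr * factor
    return current_lr


# ---------------------------------------------------------------------------
# Nadam
# ---------------------------------------------------------------------------


class Nadam:
    """Nesterov-accelerated Adam (Dozat 2016) over a named parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = (
                b1 * self.m[k] / (1 - b1 ** (self.t + 1))
                + (1 - b1) * g / (1 - b1 ** self.t)
            )
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Validation split
# ---------------------------------------------------------------------------


def subject_level_split(samples, val_fraction, rng) -> tuple:
    """Hold out whole subjects for validation, stratified by visit count.

    Subject-level (rather than sample-level) splitting prevents a subject's
    shorter windows from leaking into validation while its longer windows
    are trained on.
    """
    by_subject = defaultdict(list)
    for s in samples:
        by_subject[s.subject_id].append(s)
    strata = defaultdict(list)
    for sid, ss in by_subject.items():
        strata[max(x.n for x in ss)].append(sid)

    val_ids = set()
    for _, sids in sorted(strata.items()):
        sids = sorted(sids)
        order = rng.permutation(len(sids))
        k = int(round(val_fraction * len(sids)))
        val_ids.update(sids[i] for i in order[:k])
    if not val_ids and len(by_subject) >= 2:
        val_ids.add(sorted(by_subject)[int(rng.integers(len(by_subject)))])
    train = [s for s in samples if s.subject_id not in val_ids]
    val = [s for s in samples if s.subject_id in val_ids]
    return train, val


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _eval_mse(model, samples) -> float:
    """Inference-mode MSE on the standardized target scale."""
    if not samples:
        return np.nan
    groups = defaultdict(list)
    for s in samples:
        groups[s.n].append(s)
    sse, n = 0.0, 0
    for _, grp in sorted(groups.items()):
        x, y = _stack(grp)
        pred = model.forward(x, mode="infer").value[:, 0]
        y_scaled = (y - model.target_center) / model.target_scale
        sse += float(((pred - y_scaled) ** 2).sum())
        n += len(grp)
    return sse / n


def train(model: DenseRNNRegressor, samples, cfg: TrainConfig) -> list:
    """Minimize MSE + L2-on-recurrent-weights with Nadam.

    Returns the per-epoch loss history; the model is left at the parameter
    state with the best validation loss seen (never worse than the final
    epoch's state).
    """
    cfg.validate()
    if not samples:
        raise ConfigurationError("no training samples")
    rng = np.random.default_rng(cfg.seed)
    train_samples, val_samples = subject_level_split(samples, cfg.val_fraction, rng)
    if not train_samples:
        train_samples, val_samples = list(samples), []
    if not val_samples:
        logger.warning("no validation subjects; selecting on training loss")

    y_train = np.array([s.target for s in train_samples])
    model.target_center = float(y_train.mean())
    scale = float(y_train.std(ddof=1)) if len(y_train) > 1 else 1.0
    model.target_scale = scale if scale > 1e-12 else 1.0

    params = model.parameters()
    rnn_weights = model.rnn_weight_vars()
    opt = Nadam(params, lr=cfg.initial_lr)

    history: list = []
    best_val = np.inf
    best_state = model.get_state()
    since_improvement = 0
    lr = cfg.initial_lr

    for epoch in range(cfg.max_epochs):
        opt.lr = lr
        epoch_losses = []
        for batch in make_length_batches(train_samples, cfg.batch_size, rng):
            x, y = _stack(batch)
            y_scaled = (y - model.target_center) / model.target_scale
            pred = model.forward(x, mode="train")
            diff = pred - Var(y_scaled[:, None], requires_grad=False)
            loss = (diff * diff).mean()
            if cfg.l2_coeff > 0:
                reg = None
                for w in rnn_weights:
                    term = (w * w).sum()
                    reg = term if reg is None else reg + term
                loss = loss + cfg.l2_coeff * reg
            if not np.isfinite(loss.value):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.value))

        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_mse(model, val_samples) if val_samples else train_loss
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        history.append(EpochStats(epoch, train_loss, val_loss, lr))

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            since_improvement = 0
        else:
            since_improvement += 1
        lr = lr_step(lr, since_improvement, cfg.lr_factor, cfg.lr_patience_epochs)
        if since_improvement >= cfg.early_stop_patience:
            logger.info("early stop at epoch %d", epoch)
            break

    model.set_state(best_state)
    return history


def predict_samples(model: DenseRNNRegressor, samples,
                    batch_size: int = 256) -> np.ndarray:
    """Raw-scale predictions aligned with ``samples`` order."""
    preds = np.empty(len(samples))
    groups = defaultdict(list)
    for i, s in enumerate(samples):
        groups[s.n].append(i)
    for _, idx in sorted(groups.items()):
        for start in range(0, len(idx), batch_size):
            chunk = idx[start:start + batch_size]
            x = np.stack([samples[i].x_seq for i in chunk])
            preds[chunk] = model.predict(x)
    return preds
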