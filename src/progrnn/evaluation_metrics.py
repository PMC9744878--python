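"""Progression metrics: PIE, PIC, history-depth ablation, cross-validation.

Per prediction time point t (the index of the visit being predicted), the
root-mean-square error over subjects is RMSE_t; the Progression
Identification Error (PIE) is the unweighted mean of the RMSE_t over time
points. The Progression Identification Correlation (PIC) averages, over
the same time points, the Spearman rank correlation between predicted and
true scores. Both use full-history predictions only; truncated-history
records (from the ablation scheme) are excluded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .cohort_io import (
    SCORE_MAX,
    Cohort,
    TrainingSample,
    build_history_samples,
    fit_scaling,
)
from .dense_rnn_core import DenseRNNRegressor, ModelConfig
from .exceptions import EmptyInputError, IntegrityError, RangeError
from .training import TrainConfig, predict_samples, train

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Prediction records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionRecord:
    subject_id: str
    target_visit_index: int
    history_length: int
    y_true: float
    y_pred: float

    def __post_init__(self):
        if not (0 <= self.y_true <= SCORE_MAX):
            raise RangeError(f"y_true {self.y_true} outside [0, {SCORE_MAX}]")

    @property
    def full_history(self) -> bool:
        return self.history_length == self.target_visit_index


class PredictionSet:
    """A collection of prediction records, unique per
    (subject, target visit, history length)."""

    def __init__(self, records):
        self.records = list(records)
        keys = {
            (r.subject_id, r.target_visit_index, r.history_length)
            for r in self.records
        }
        if len(keys) != len(self.records):
            raise IntegrityError(
                "duplicate (subject, target visit, history length) record"
            )

    def __len__(self):
        return len(self.records)

    def full_history_records(self):
        return [r for r in self.records if r.full_history]


@dataclass
class MetricReport:
    rmse_per_timepoint: dict
    corr_per_timepoint: dict
    pie: float
    pic: Optional[float]
    n_per_timepoint: dict
    fold_mean_se: Optional[dict] = None

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# PIE / PIC
# ---------------------------------------------------------------------------


def _by_timepoint(records) -> dict:
    groups = defaultdict(list)
    for r in records:
        groups[r.target_visit_index].append(r)
    return groups


def compute_pie(preds: PredictionSet, pooled: bool = False) -> dict:
    """Per-time-point RMSE and their unweighted mean.

    ``pooled=True`` instead returns the single RMSE over all records
    (records weighted equally rather than time points).
    """
    records = preds.full_history_records()
    if not records:
        raise EmptyInputError("no full-history prediction records")
    groups = _by_timepoint(records)
    rmse = {
        t: float(np.sqrt(np.mean([(r.y_pred - r.y_true) ** 2 for r in rs])))
        for t, rs in sorted(groups.items())
    }
    if pooled:
        pie = float(
            np.sqrt(np.mean([(r.y_pred - r.y_true) ** 2 for r in records]))
        )
    else:
        pie = float(np.mean(list(rmse.values())))
    return {
        "rmse_per_timepoint": rmse,
        "pie": pie,
        "n_per_timepoint": {t: len(rs) for t, rs in sorted(groups.items())},
    }


def compute_pic(preds: PredictionSet) -> dict:
    """Per-time-point Spearman correlation and their unweighted mean.

    Time points with fewer than 3 records or constant true scores carry no
    rank information; they are excluded and logged.
    """
    records = preds.full_history_records()
    if not records:
        raise EmptyInputError("no full-history prediction records")
    corr = {}
    for t, rs in sorted(_by_timepoint(records).items()):
        y_true = np.array([r.y_true for r in rs])
        y_pred = np.array([r.y_pred for r in rs])
        if len(rs) < 3 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
            logger.info("PIC: excluding time point %d (n=%d)", t, len(rs))
            continue
        rho = stats.spearmanr(y_true, y_pred).statistic
        corr[t] = float(rho)
    if not corr:
        raise EmptyInputError("no time point eligible for rank correlation")
    return {"corr_per_timepoint": corr, "pic": float(np.mean(list(corr.values())))}


def make_report(preds: PredictionSet, pooled_pie: bool = False) -> MetricReport:
    pie_part = compute_pie(preds, pooled=pooled_pie)
    try:
        pic_part = compute_pic(preds)
    except EmptyInputError:
        pic_part = {"corr_per_timepoint": {}, "pic": None}
    return MetricReport(
        rmse_per_timepoint=pie_part["rmse_per_timepoint"],
        corr_per_timepoint=pic_part["corr_per_timepoint"],
        pie=pie_part["pie"],
        pic=pic_part["pic"],
        n_per_timepoint=pie_part["n_per_timepoint"],
    )


# ---------------------------------------------------------------------------
# Model evaluation helpers
# ---------------------------------------------------------------------------


def evaluate_model(model: DenseRNNRegressor, cohort: Cohort, subject_ids,
                   include_nontranscriptomic: bool = True) -> PredictionSet:
    """Full-history predictions for every target visit of the subjects."""
    wanted = set(subject_ids)
    samples = [
        s
        for s in build_history_samples(cohort, include_nontranscriptomic)
        if s.subject_id in wanted and s.n == s.target_visit_index
    ]
    if not samples:
        raise EmptyInputError("no evaluable history windows for these subjects")
    preds = predict_samples(model, samples)
    return PredictionSet(
        PredictionRecord(
            subject_id=s.subject_id,
            target_visit_index=s.target_visit_index,
            history_length=s.n,
            y_true=s.target,
            y_pred=float(p),
        )
        for s, p in zip(samples, preds)
    )


def history_ablation(model: DenseRNNRegressor, cohort: Cohort, subject_ids,
                     max_history: int,
                     include_nontranscriptomic: bool = True) -> dict:
    """Final-visit RMSE as a function of history depth.

    At depth k each subject's last visit is predicted from only its k most
    recent prior visits; subjects with fewer than k prior visits drop out
    at that depth. Returns ``{k: {"rmse": float|None, "n": int}}``.
    """
    if max_history < 1:
        raise ValueError("max_history must be >= 1")
    if cohort.scaling is None:
        raise EmptyInputError("cohort has no scaling state")
    ng = len(cohort.gene_columns)
    out = {}
    for k in range(1, max_history + 1):
        truths, samples = [], []
        for sid in subject_ids:
            visits = cohort.subjects[sid]
            n_visits = len(visits)
            if n_visits - 1 < k:
                continue
            window = visits[n_visits - 1 - k:n_visits - 1]
            steps = []
            for i, v in enumerate(window):
                nxt = (
                    window[i + 1].visit_month
                    if i + 1 < len(window)
                    else visits[-1].visit_month
                )
                feats = cohort.scaling.transform(v.features)
                if not include_nontranscriptomic:
                    feats = feats[:ng]
                y_scaled = (
                    v.score_total - cohort.scaling.target_center
                ) / cohort.scaling.target_scale
                steps.append(
                    np.concatenate(
                        [feats, [(nxt - v.visit_month) / 12.0, y_scaled]]
                    )
                )
            samples.append(
                TrainingSample(
                    x_seq=np.asarray(steps),
                    n=k,
                    target=float(visits[-1].score_total),
                    subject_id=sid,
                    target_visit_index=n_visits - 1,
                )
            )
            truths.append(float(visits[-1].score_total))
        if samples:
            preds = predict_samples(model, samples)
            rmse = float(np.sqrt(np.mean((preds - np.asarray(truths)) ** 2)))
        else:
            rmse = None
        out[k] = {"rmse": rmse, "n": len(samples)}
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def fold_mean_se(values) -> tuple:
    """Mean and standard error (sd/sqrt(n), sample sd) of fold-level values."""
    values = np.asarray(values, dtype=np.float64)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se


def assign_folds(cohort: Cohort, n_folds: int, seed: int) -> list:
    """Subject-level fold assignment over subjects with >= 2 visits.

    Returns ``[(train_ids, test_ids), ...]``; single-visit subjects join
    every training side (they contribute scaling rows but no windows).
    """
    eligible = sorted(s for s, v in cohort.subjects.items() if len(v) >= 2)
    if len(eligible) < n_folds:
        raise ValueError(
            f"need >= {n_folds} subjects with >= 2 visits, have {len(eligible)}"
        )
    ineligible = [s for s in cohort.subjects if len(cohort.subjects[s]) < 2]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    folds = []
    for test_idx in np.array_split(order, n_folds):
        test = sorted(eligible[i] for i in test_idx)
        train = sorted(set(eligible) - set(test)) + sorted(ineligible)
        folds.append((train, test))
    return folds


@dataclass
class CVResult:
    folds: list
    fold_reports: list
    pie_mean: float
    pie_se: float
    pic_mean: Optional[float]
    pic_se: Optional[float]

    @property
    def pie_values(self):
        return [r.pie for r in self.fold_reports]

    @property
    def pic_values(self):
        return [r.pic for r in self.fold_reports]


def crossvalidate(cohort: Cohort, model_cfg: ModelConfig, train_cfg: TrainConfig,
                  n_folds: int = 5, seed: int = 0,
                  include_nontranscriptomic: bool = True) -> CVResult:
    """Subject-level k-fold cross-validation of the recurrent model.

    Scaling, target standardization, and the model are fit per fold on the
    training subjects only; PIE/PIC are measured on the held-out subjects
    and aggregated as mean ± standard error across folds.
    """
    folds = assign_folds(cohort, n_folds, seed)
    reports = []
    for fold_i, (train_ids, test_ids) in enumerate(folds):
        cohort.scaling = fit_scaling(cohort, train_ids)
        samples = build_history_samples(cohort, include_nontranscriptomic)
        train_set = set(train_ids)
        fold_samples = [s for s in samples if s.subject_id in train_set]
        input_dim = fold_samples[0].x_seq.shape[1]
        model = DenseRNNRegressor(
            input_dim,
            dataclasses.replace(model_cfg, seed=model_cfg.seed + fold_i),
        )
        train(
            model,
            fold_samples,
            dataclasses.replace(train_cfg, seed=train_cfg.seed + 1000 * fold_i),
        )
        preds = evaluate_model(model, cohort, test_ids, include_nontranscriptomic)
        reports.append(make_report(preds))

    pie_mean, pie_se = fold_mean_se([r.pie for r in reports])
    pics = [r.pic for r in reports if r.pic is not None]
    pic_mean, pic_se = fold_mean_se(pics) if pics else (None, None)
    return CVResult(
        folds=folds,
        fold_reports=reports,
        pie_mean=pie_mean,
        pie_se=pie_se,
        pic_mean=pic_mean,
        pic_se=pic_se,
    )
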