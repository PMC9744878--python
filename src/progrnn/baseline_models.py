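"""Classical-regressor comparison arm.

The standard strategy for applying non-sequential learners to longitudinal
data is to collapse each subject's visit history into a single vector:
numerical columns by their mean, ordinal columns by their median (lower of
the two middles on even counts), and nominal columns by their mode (ties
broken by first occurrence). The aggregated vector — augmented with the
last observed score and the gap to the target visit, mirroring the score
and time inputs the recurrent model receives — feeds four regressors:
linear regression, support-vector regression, a decision tree, and a
random forest. Aggregation discards visit ordering by construction, which
is exactly the handicap the recurrent model is meant to expose.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .cohort_io import Cohort, fit_scaling
from .evaluation_metrics import (
    MetricReport,
    PredictionRecord,
    PredictionSet,
    fold_mean_se,
    make_report,
)
from .exceptions import ConfigurationError, IntegrityError
from .synthetic_cohort import synthetic_column_kinds

logger = logging.getLogger(__name__)

COLUMN_KIND_VALUES = ("numerical", "ordinal", "nominal")


@dataclass
class AggregatedSample:
    """One subject-window collapsed to a single vector per column."""

    subject_id: str
    features: np.ndarray  # one value per cohort column (genes then clinical)
    target: float
    target_visit_index: int
    history_length: int
    last_score: float
    delta_t_years: float


def _lower_median(values):
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _first_mode(values):
    counts = Counter(values)
    best = max(counts.values())
    for v in values:  # first occurrence wins ties
        if counts[v] == best:
            return v


def aggregate_history(visits, columns, column_kinds) -> np.ndarray:
    """Collapse a visit window column-wise by kind (mean/median/mode)."""
    if not visits:
        raise ConfigurationError("aggregate_history needs >= 1 visit")
    mat = np.stack([v.features for v in visits])
    out = np.empty(len(columns))
    for j, col in enumerate(columns):
        kind = column_kinds.get(col)
        if kind not in COLUMN_KIND_VALUES:
            raise ConfigurationError(
                f"column {col!r} has unknown kind {kind!r}; expected one of "
                f"{COLUMN_KIND_VALUES}"
            )
        vals = mat[:, j]
        if kind == "numerical":
            out[j] = vals.mean()
        elif kind == "ordinal":
            out[j] = _lower_median(vals.tolist())
        else:
            out[j] = _first_mode(vals.tolist())
    return out


def _make_samples(cohort: Cohort, subject_ids, column_kinds,
                  every_target: bool) -> list:
    """Aggregated samples; full history only (training) or one per target
    visit (evaluation)."""
    columns = cohort.gene_columns + cohort.clinical_columns
    samples = []
    for sid in subject_ids:
        visits = cohort.subjects[sid]
        if len(visits) < 2:
            continue
        targets = (
            range(1, len(visits)) if every_target else [len(visits) - 1]
        )
        for n in targets:
            window = visits[:n]
            samples.append(
                AggregatedSample(
                    subject_id=sid,
                    features=aggregate_history(window, columns, column_kinds),
                    target=float(visits[n].score_total),
                    target_visit_index=n,
                    history_length=n,
                    last_score=float(window[-1].score_total),
                    delta_t_years=(
                        visits[n].visit_month - window[-1].visit_month
                    ) / 12.0,
                )
            )
    return samples


def _design_matrix(samples, scaling) -> np.ndarray:
    rows = [
        np.concatenate(
            [
                scaling.transform(s.features),
                [
                    (s.last_score - scaling.target_center) / scaling.target_scale,
                    s.delta_t_years,
                ],
            ]
        )
        for s in samples
    ]
    return np.asarray(rows)


def default_baselines(seed: int) -> dict:
    return {
        "linear_regression": LinearRegression(),
        "svr": SVR(),
        "decision_tree": DecisionTreeRegressor(random_state=seed),
        "random_forest": RandomForestRegressor(random_state=seed),
    }


@dataclass
class BaselineResult:
    fold_reports: list
    pie_mean: float
    pie_se: float
    pic_mean: Optional[float]
    pic_se: Optional[float]
    hyperparameters: dict


def _validate_folds(cohort: Cohort, folds) -> None:
    seen = set()
    for train_ids, test_ids in folds:
        train_set, test_set = set(train_ids), set(test_ids)
        if not test_set or train_set & test_set:
            raise IntegrityError("folds must have disjoint, non-empty test sets")
        if seen & test_set:
            raise IntegrityError("a subject appears in two test folds")
        unknown = (train_set | test_set) - set(cohort.subjects)
        if unknown:
            raise IntegrityError(f"fold references unknown subjects {unknown}")
        seen |= test_set


def run_baselines(cohort: Cohort, folds, seed: int,
                  column_kinds: Optional[dict] = None) -> dict:
    """Fit and score the four aggregation baselines on shared folds.

    ``folds`` must be the same subject-level assignment used for the
    recurrent model's cross-validation (comparisons are only meaningful on
    identical splits); an inconsistent assignment raises. Column kinds
    default to the synthetic generator's naming convention.
    """
    _validate_folds(cohort, folds)
    if column_kinds is None:
        column_kinds = synthetic_column_kinds(cohort)

    results = {}
    for name, proto in default_baselines(seed).items():
        fold_reports = []
        for train_ids, test_ids in folds:
            scaling = fit_scaling(cohort, train_ids)
            train_samples = _make_samples(
                cohort, train_ids, column_kinds, every_target=False
            )
            test_samples = _make_samples(
                cohort, test_ids, column_kinds, every_target=True
            )
            model = type(proto)(**proto.get_params())
            model.fit(
                _design_matrix(train_samples, scaling),
                [s.target for s in train_samples],
            )
            preds = model.predict(_design_matrix(test_samples, scaling))
            records = PredictionSet(
                PredictionRecord(
                    subject_id=s.subject_id,
                    target_visit_index=s.target_visit_index,
                    history_length=s.history_length,
                    y_true=s.target,
                    y_pred=float(p),
                )
                for s, p in zip(test_samples, preds)
            )
            fold_reports.append(make_report(records))
        pie_mean, pie_se = fold_mean_se([r.pie for r in fold_reports])
        pics = [r.pic for r in fold_reports if r.pic is not None]
        pic_mean, pic_se = fold_mean_se(pics) if pics else (None, None)
        results[name] = BaselineResult(
            fold_reports=fold_reports,
            pie_mean=pie_mean,
            pie_se=pie_se,
            pic_mean=pic_mean,
            pic_se=pic_se,
            hyperparameters=proto.get_params(),
        )
    return results


def carry_forward_predictions(cohort: Cohort, subject_ids) -> PredictionSet:
    """Naive persistence baseline: predict the last observed score."""
    records = []
    for sid in subject_ids:
        visits = cohort.subjects[sid]
        for n in range(1, len(visits)):
            records.append(
                PredictionRecord(
                    subject_id=sid,
                    target_visit_index=n,
                    history_length=n,
                    y_true=float(visits[n].score_total),
                    y_pred=float(visits[n - 1].score_total),
                )
            )
    return PredictionSet(records)
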