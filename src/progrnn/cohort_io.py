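"""Cohort data model, table I/O, target assembly, scaling, and history windows.

The in-memory layout mirrors the long-format study tables: one expression
table (subject, visit, month, one column per gene, TPM-like values) and one
clinical table (subject, visit, month, non-transcriptomic features, four
per-part severity scores). A :class:`Cohort` holds the joined, time-ordered
visits per subject; :func:`build_history_samples` turns them into
variable-length history windows, each pairing the scaled feature sequence
with the next visit's total severity score.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    IntegrityError,
    RangeError,
    StateError,
)

logger = logging.getLogger(__name__)

SCORE_MAX = 272
N_SCORE_PARTS = 4
KEY_COLUMNS = ("subject_id", "visit_id", "visit_month")
PART_COLUMNS = ("score_part1", "score_part2", "score_part3", "score_part4")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VisitRecord:
    """One subject-visit: feature vector, month from baseline, severity."""

    subject_id: str
    visit_month: float
    features: np.ndarray  # genes then clinical, cohort-wide fixed order
    score_parts: tuple
    score_total: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.score_total != sum(self.score_parts):
            raise IntegrityError(
                f"score_total {self.score_total} != sum of parts "
                f"{sum(self.score_parts)} for subject {self.subject_id}"
            )


@dataclass
class ScalingState:
    """Per-column location/scale, learned from training subjects only.

    Gene columns are transformed as ``log2(x + 1)`` then centred/scaled;
    clinical columns are z-scored directly. Zero-variance columns get scale 1
    (pass-through). The target score's train-set mean/sd is carried along so
    models can standardize the regression target without touching test data.
    """

    gene_center: np.ndarray
    gene_scale: np.ndarray
    clinical_center: np.ndarray
    clinical_scale: np.ndarray
    target_center: float
    target_scale: float
    n_zero_variance: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_center)

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Scale one raw feature vector (genes then clinical)."""
        g = self.n_genes
        genes = (np.log2(features[:g] + 1.0) - self.gene_center) / self.gene_scale
        clin = (features[g:] - self.clinical_center) / self.clinical_scale
        return np.concatenate([genes, clin])

    def to_json(self, path) -> None:
        payload = {
            "gene_center": self.gene_center.tolist(),
            "gene_scale": self.gene_scale.tolist(),
            "clinical_center": self.clinical_center.tolist(),
            "clinical_scale": self.clinical_scale.tolist(),
            "target_center": self.target_center,
            "target_scale": self.target_scale,
            "n_zero_variance": self.n_zero_variance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ScalingState":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_center=np.asarray(d["gene_center"]),
            gene_scale=np.asarray(d["gene_scale"]),
            clinical_center=np.asarray(d["clinical_center"]),
            clinical_scale=np.asarray(d["clinical_scale"]),
            target_center=d["target_center"],
            target_scale=d["target_scale"],
            n_zero_variance=d["n_zero_variance"],
        )


@dataclass
class Cohort:
    """Time-ordered visits per subject plus column metadata.

    ``latent`` is populated by the synthetic generator only (per-subject
    noise-free severity trajectories, used by diagnostics and
    parameter-recovery tests); it is ``None`` for cohorts loaded from disk
    without a sidecar.
    """

    subjects: dict  # subject_id -> list[VisitRecord], time-ordered
    gene_columns: list
    clinical_columns: list
    scaling: Optional[ScalingState] = None
    latent: Optional[dict] = None  # subject_id -> list[float]

    @property
    def n_features(self) -> int:
        return len(self.gene_columns) + len(self.clinical_columns)

    def subject_ids(self) -> list:
        return list(self.subjects.keys())

    def validate(self) -> None:
        q = self.n_features
        for sid, visits in self.subjects.items():
            months = [v.visit_month for v in visits]
            if any(b <= a for a, b in zip(months, months[1:])):
                raise IntegrityError(
                    f"visit months not strictly increasing for subject {sid}"
                )
            for v in visits:
                if len(v.features) != q:
                    raise IntegrityError(
                        f"feature length {len(v.features)} != {q} for {sid}"
                    )


@dataclass
class TrainingSample:
    """One history window: scaled features ⊕ Δt (years) ⊕ normalized score.

    ``x_seq`` has shape ``(n, Q + 2)``; ``target`` is the raw next-visit
    total score; ``target_visit_index`` is the 0-based index of the target
    visit within the subject's visit list (equal to ``n`` when the full
    history is used).
    """

    x_seq: np.ndarray
    n: int
    target: float
    subject_id: str
    target_visit_index: int


# ---------------------------------------------------------------------------
# Target assembly
# ---------------------------------------------------------------------------


def assemble_target(parts) -> int:
    """Sum the four per-part severity scores into the 0-272 total."""
    parts = tuple(int(p) for p in parts)
    if len(parts) != N_SCORE_PARTS:
        raise RangeError(f"expected {N_SCORE_PARTS} score parts, got {len(parts)}")
    if any(p < 0 for p in parts):
        raise RangeError(f"negative score part in {parts}")
    total = sum(parts)
    if total > SCORE_MAX:
        raise RangeError(f"total score {total} exceeds {SCORE_MAX}")
    return total


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing key columns {missing}")
    if df[list(KEY_COLUMNS[:2])].duplicated().any():
        dup = df[df[list(KEY_COLUMNS[:2])].duplicated()].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate subject-visit row "
            f"({dup['subject_id']}, {dup['visit_id']})"
        )
    return df


def load_cohort(expression_path, clinical_path) -> Cohort:
    """Inner-join the expression and clinical tables into a Cohort.

    Visits present in only one table are dropped (count logged); subjects
    left with zero joined visits are dropped likewise. Missing values are
    rejected: the pipeline assumes complete cases.
    """
    expr = _read_table(expression_path)
    clin = _read_table(clinical_path)
    for name, df in (("expression", expr), ("clinical", clin)):
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise FormatError(f"{name} table contains missing values in {bad}")
    missing_parts = [c for c in PART_COLUMNS if c not in clin.columns]
    if missing_parts:
        raise FormatError(f"clinical table missing score columns {missing_parts}")

    gene_columns = [c for c in expr.columns if c not in KEY_COLUMNS]
    clinical_columns = [
        c for c in clin.columns if c not in KEY_COLUMNS and c not in PART_COLUMNS
    ]
    if gene_columns and (expr[gene_columns].to_numpy() < 0).any():
        raise FormatError("expression table contains negative abundances")

    merged = expr.merge(
        clin, on=["subject_id", "visit_id"], how="inner", suffixes=("", "_clin")
    )
    n_dropped = len(expr) + len(clin) - 2 * len(merged)
    if n_dropped:
        logger.info("dropped %d unmatched visit rows during join", n_dropped)
    if merged.empty:
        logger.warning("join produced an empty cohort")
        return Cohort(subjects={}, gene_columns=gene_columns,
                      clinical_columns=clinical_columns)

    month_col = "visit_month" if "visit_month" in merged.columns else None
    subjects: dict = {}
    for sid, grp in merged.groupby("subject_id", sort=True):
        grp = grp.sort_values(month_col)
        visits = []
        for _, row in grp.iterrows():
            parts = tuple(int(row[c]) for c in PART_COLUMNS)
            visits.append(
                VisitRecord(
                    subject_id=str(sid),
                    visit_month=float(row[month_col]),
                    features=np.concatenate(
                        [
                            row[gene_columns].to_numpy(dtype=np.float64),
                            row[clinical_columns].to_numpy(dtype=np.float64),
                        ]
                    ),
                    score_parts=parts,
                    score_total=assemble_target(parts),
                )
            )
        subjects[str(sid)] = visits

    cohort = Cohort(
        subjects=subjects,
        gene_columns=gene_columns,
        clinical_columns=clinical_columns,
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir, fmt: str = "tsv") -> dict:
    """Write the two long-format tables; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    ng = len(cohort.gene_columns)

    expr_rows, clin_rows = [], []
    for sid, visits in cohort.subjects.items():
        for i, v in enumerate(visits):
            key = {"subject_id": sid, "visit_id": f"V{i:02d}",
                   "visit_month": v.visit_month}
            expr_rows.append(
                {**key, **dict(zip(cohort.gene_columns, v.features[:ng]))}
            )
            clin_rows.append(
                {
                    **key,
                    **dict(zip(cohort.clinical_columns, v.features[ng:])),
                    **dict(zip(PART_COLUMNS, v.score_parts)),
                }
            )
    paths = {
        "expression": out_dir / f"expression.{fmt}",
        "clinical": out_dir / f"clinical.{fmt}",
    }
    pd.DataFrame(expr_rows).to_csv(paths["expression"], sep=sep, index=False)
    pd.DataFrame(clin_rows).to_csv(paths["clinical"], sep=sep, index=False)
    return paths


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def fit_scaling(cohort: Cohort, train_subject_ids) -> ScalingState:
    """Learn per-column location/scale from the training subjects only.

    Sample standard deviation (ddof=1) is used throughout; zero-variance
    columns get scale 1 so they pass through as exact zeros after centring.
    """
    train_ids = list(train_subject_ids)
    if not train_ids:
        raise ConfigurationError("train_subject_ids is empty")
    unknown = [s for s in train_ids if s not in cohort.subjects]
    if unknown:
        raise KeyError(f"unknown subject ids: {unknown[:5]}")

    rows = [v.features for s in train_ids for v in cohort.subjects[s]]
    scores = [v.score_total for s in train_ids for v in cohort.subjects[s]]
    mat = np.asarray(rows, dtype=np.float64)
    ng = len(cohort.gene_columns)

    def loc_scale(block):
        center = block.mean(axis=0)
        if block.shape[0] > 1:
            scale = block.std(axis=0, ddof=1)
        else:
            scale = np.zeros(block.shape[1])
        zero = scale < 1e-12
        scale = np.where(zero, 1.0, scale)
        return center, scale, int(zero.sum())

    gene_c, gene_s, nz_g = loc_scale(np.log2(mat[:, :ng] + 1.0))
    clin_c, clin_s, nz_c = loc_scale(mat[:, ng:])
    if nz_g + nz_c:
        logger.info("scaling: %d zero-variance columns pass through", nz_g + nz_c)

    t_center = float(np.mean(scores))
    t_scale = float(np.std(scores, ddof=1)) if len(scores) > 1 else 1.0
    if t_scale < 1e-12:
        t_scale = 1.0
    return ScalingState(
        gene_center=gene_c,
        gene_scale=gene_s,
        clinical_center=clin_c,
        clinical_scale=clin_s,
        target_center=t_center,
        target_scale=t_scale,
        n_zero_variance=nz_g + nz_c,
    )


# ---------------------------------------------------------------------------
# History windows
# ---------------------------------------------------------------------------


def build_history_samples(
    cohort: Cohort, include_nontranscriptomic: bool = True
) -> list:
    """Emit every history window targeting the immediately following visit.

    A subject with N >= 2 visits yields N-1 samples with history lengths
    1..N-1. Each step's augmented vector is the scaled features (clinical
    columns dropped when the flag is off), the gap to the following visit in
    years, and the observed score standardized by the train-split target
    mean/sd carried in the scaling state — so the score channel has the
    same O(1) spread as the z-scored feature columns. Subjects with a
    single visit yield nothing.
    """
    if cohort.scaling is None:
        raise StateError("cohort has no scaling state; call fit_scaling first")
    ng = len(cohort.gene_columns)
    samples = []
    for sid, visits in cohort.subjects.items():
        n_visits = len(visits)
        if n_visits < 2:
            continue
        scaled = [cohort.scaling.transform(v.features) for v in visits]
        if not include_nontranscriptomic:
            scaled = [s[:ng] for s in scaled]
        steps = []
        for i in range(n_visits - 1):
            dt_years = (visits[i + 1].visit_month - visits[i].visit_month) / 12.0
            if dt_years <= 0:
                raise IntegrityError(f"non-positive visit gap for subject {sid}")
            y_scaled = (
                visits[i].score_total - cohort.scaling.target_center
            ) / cohort.scaling.target_scale
            steps.append(np.concatenate([scaled[i], [dt_years, y_scaled]]))
            samples.append(
                TrainingSample(
                    x_seq=np.asarray(steps, dtype=np.float64),
                    n=i + 1,
                    target=float(visits[i + 1].score_total),
                    subject_id=sid,
                    target_visit_index=i + 1,
                )
            )
    return samples
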