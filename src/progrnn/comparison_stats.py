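"""Statistical comparison of cross-validated metrics, and the
instrument-noise floor of the severity score.

Two t-test routes are provided. ``ttest_from_folds`` is the paired test on
matched fold-level metric values (df = n_folds - 1). ``ttest_from_summary``
works from published mean ± standard-error summaries via the unpaired
two-sample statistic t = (m_a - m_b) / sqrt(se_a^2 + se_b^2); cross-model
comparisons reported only as summaries are reproducible this way.

The noise floor aggregates published per-part error variances of the
severity instrument as the sum of the per-part standard deviations,
sum_i sqrt(v_i) — the inferred reading of the printed total (a simple
upper-bound-style aggregate; the quadrature alternative sqrt(sum v_i) does
not match the published figure). A model whose RMSE sits below this floor
is operating within the instrument's own measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import RangeError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    df: int
    alpha: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self):
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significant flag inconsistent with p-value")


def _result(t, df, alpha, degenerate=False) -> TTestResult:
    if np.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(
        t_stat=float(t),
        p_value=p,
        df=df,
        alpha=alpha,
        significant=p < alpha,
        degenerate=degenerate,
    )


def ttest_from_folds(metrics_a, metrics_b,
                     alpha: float = DEFAULT_ALPHA) -> TTestResult:
    """Paired t-test across matched fold-level metric values.

    Zero variance of the differences is degenerate: t is 0 (identical
    vectors) or ±inf (constant non-zero shift), flagged accordingly.
    """
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("fold vectors must be equal-length 1-d with n >= 2")
    d = a - b
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd < 1e-300:
        mean = d.mean()
        if mean == 0:
            return TTestResult(0.0, 1.0, df, alpha, significant=False,
                               degenerate=True)
        return _result(np.sign(mean) * np.inf, df, alpha, degenerate=True)
    t = d.mean() / (sd / np.sqrt(len(d)))
    return _result(t, df, alpha)


def ttest_from_summary(mean_a: float, se_a: float, mean_b: float, se_b: float,
                       df: int, alpha: float = DEFAULT_ALPHA) -> TTestResult:
    """Two-sample t-statistic from published mean ± SE summaries."""
    if se_a < 0 or se_b < 0:
        raise RangeError("standard errors must be >= 0")
    if se_a == 0 and se_b == 0:
        raise ValueError("degenerate input: both standard errors are zero")
    t = (mean_a - mean_b) / np.sqrt(se_a**2 + se_b**2)
    return _result(t, df, alpha)


def noise_floor(part_error_variances) -> float:
    """Sum of per-part standard deviations, sum_i sqrt(v_i)."""
    v = np.asarray(part_error_variances, dtype=np.float64)
    if (v < 0).any():
        raise RangeError("error variances must be >= 0")
    return float(np.sqrt(v).sum())


def format_p(p: float) -> str:
    """Render a p-value to 4 decimals; very small values print as 0.000."""
    if p < 5e-5:
        return "0.000"
    return f"{p:.4f}"
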