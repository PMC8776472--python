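"""Scoring a fitted (imputed) dataset against the complete training set.

All three metrics operate on the normalised total score: the raw item total
divided by its maximum (``n_items * n_levels``, i.e. 80 for a 20-item
4-level scale), so a 20-item score lies in (0.25, 1].  Reported are

* RMSE of the per-subject normalised totals,
* the full width of the two-sided 95% Student confidence interval of the
  mean paired difference of normalised totals, and
* the Spearman rank correlation (midranks for ties) between the two
  normalised-total vectors.

For a multiply-imputed set the metric is computed per completion and
arithmetically averaged — pooling on the metric, not the data, so the
between-completion variability of the imputations is not smoothed away.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .cohort import ScaleDataset
from .imputers import ImputedSet

__all__ = [
    "EvaluationRecord",
    "ci_width_paired_t",
    "evaluate_fit",
    "normalized_total",
    "normalized_totals",
    "records_to_frame",
    "rmse_total",
    "spearman_total",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """One (mechanism, rate, method) cell's metrics for one replicate."""

    mechanism: str
    overall_rate: float
    method: str
    rmse: float
    ci_width: float
    scc: float
    n_subjects: int
    replicate_seed: int


def records_to_frame(records) -> pd.DataFrame:
    cols = [f.name for f in fields(EvaluationRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def _items_matrix(x) -> np.ndarray:
    if isinstance(x, ScaleDataset):
        return np.asarray(x.items, dtype=float)
    return np.asarray(x, dtype=float)


def _completions(fitted) -> list[np.ndarray]:
    if isinstance(fitted, ImputedSet):
        return [np.asarray(c, dtype=float) for c in fitted.completions]
    return [np.asarray(fitted, dtype=float)]


def normalized_total(items_row, n_levels: int = 4) -> float:
    """Total score of one subject rescaled to (1/n_levels, 1]."""
    row = np.asarray(items_row, dtype=float)
    if row.ndim != 1:
        raise ValidationError(f"expected a 1-d row of item scores, got ndim={row.ndim}")
    return float(row.sum() / (row.size * n_levels))


def normalized_totals(items, n_levels: int = 4) -> np.ndarray:
    """Per-subject normalised totals for a subjects-by-items matrix."""
    m = _items_matrix(items)
    if m.ndim != 2:
        raise ValidationError(f"expected a 2-d item matrix, got ndim={m.ndim}")
    return m.sum(axis=1) / (m.shape[1] * n_levels)


def _paired_totals(training, completion, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    t = _items_matrix(training)
    f = np.asarray(completion, dtype=float)
    if t.shape != f.shape:
        raise ValidationError(
            f"shape mismatch: training {t.shape} vs fitted {f.shape}"
        )
    return normalized_totals(t, n_levels), normalized_totals(f, n_levels)


def rmse_total(training, fitted, n_levels: int = 4) -> float:
    """Root-mean-square error of normalised totals (averaged over
    completions for a multiply-imputed set)."""
    vals = []
    for comp in _completions(fitted):
        tt, ft = _paired_totals(training, comp, n_levels)
        vals.append(float(np.sqrt(np.mean((ft - tt) ** 2))))
    return float(np.mean(vals))


def ci_width_paired_t(training, fitted, n_levels: int = 4) -> float:
    """Full width of the 95% Student CI for the mean paired difference of
    normalised totals: ``2 * t_{0.975, n-1} * sd(d) / sqrt(n)``."""
    vals = []
    for comp in _completions(fitted):
        tt, ft = _paired_totals(training, comp, n_levels)
        n = tt.size
        if n < 2:
            raise ValidationError("paired CI needs at least 2 subjects")
        d = ft - tt
        sd = float(np.std(d, ddof=1))
        tcrit = float(stats.t.ppf(0.975, n - 1))
        vals.append(2.0 * tcrit * sd / np.sqrt(n))
    return float(np.mean(vals))


def spearman_total(training, fitted, n_levels: int = 4) -> float:
    """Spearman rank correlation of normalised totals (midranks for ties)."""
    vals = []
    for comp in _completions(fitted):
        tt, ft = _paired_totals(training, comp, n_levels)
        if tt.size < 3:
            raise ValidationError("Spearman correlation needs at least 3 subjects")
        if np.ptp(tt) == 0 or np.ptp(ft) == 0:
            raise ValidationError(
                "Spearman correlation undefined: a total-score vector has zero variance"
            )
        if np.array_equal(tt, ft):
            vals.append(1.0)  # identical vectors: correlation is exactly 1
        else:
            vals.append(float(stats.spearmanr(tt, ft).statistic))
    return float(np.mean(vals))


def evaluate_fit(
    training,
    fitted,
    *,
    mechanism: str = "",
    overall_rate: float = float("nan"),
    replicate_seed: int = -1,
    n_levels: int = 4,
) -> EvaluationRecord:
    """All three metrics for one fitted set, as an EvaluationRecord."""
    method = fitted.method if isinstance(fitted, ImputedSet) else ""
    t = _items_matrix(training)
    return EvaluationRecord(
        mechanism=mechanism,
        overall_rate=float(overall_rate),
        method=method,
        rmse=rmse_total(training, fitted, n_levels),
        ci_width=ci_width_paired_t(training, fitted, n_levels),
        scc=spearman_total(training, fitted, n_levels),
        n_subjects=t.shape[0],
        replicate_seed=int(replicate_seed),
    )
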