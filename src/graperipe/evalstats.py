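"""Accuracy, confusion matrices and 2x2 contingency comparisons.

Two pipelines (e.g. full-spectrum vs CARS-selected) are compared per
stage with a 2x2 table of correct/incorrect prediction counts, tested
either with the Yates-continuity-corrected chi-squared statistic
(sum (|O-E| - 0.5)^2 / E on 1 df) or the two-sided Fisher exact test
(sum of hypergeometric probabilities of all margin-compatible tables no
more probable than the observed one).  The method is an explicit choice;
a helper flags tables whose expected counts fall below 5, the customary
small-count advisory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import STAGE_NAMES, stage_name

__all__ = [
    "accuracy",
    "confusion",
    "stage_contingency",
    "chi2_yates",
    "fisher_exact_two_sided",
    "small_expected_counts",
    "ContingencyResult",
    "compare_pipelines",
]


@dataclass
class ContingencyResult:
    """One stage's 2x2 comparison: counts, test used, statistic, p-value."""

    stage: str
    counts: np.ndarray
    method: str  # "chi2_yates" or "fisher"
    statistic: float
    p_value: float


def accuracy(true: np.ndarray, predicted: np.ndarray) -> float:
    """Percentage of matching labels: 100 * matches / n."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("empty label vectors")
    if true.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    return 100.0 * float((true == predicted).mean())


def confusion(true: np.ndarray, predicted: np.ndarray, k: int = 5) -> np.ndarray:
    """k x k count matrix, rows = true stage, columns = predicted stage."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if np.any((true < 0) | (true >= k)) or np.any((predicted < 0) | (predicted >= k)):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (true, predicted), 1)
    return cm


def confusion_frame(cm: np.ndarray) -> pd.DataFrame:
    names = list(STAGE_NAMES[: cm.shape[0]])
    return pd.DataFrame(cm, index=names, columns=names)


def stage_contingency(
    truth: np.ndarray,
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    stage: int,
) -> np.ndarray:
    """2x2 correct/incorrect counts for one true stage under two pipelines.

    Row 1 = pipeline A (correct, incorrect), row 2 = pipeline B.
    """
    truth = np.asarray(truth, dtype=int)
    preds_a = np.asarray(preds_a, dtype=int)
    preds_b = np.asarray(preds_b, dtype=int)
    if not (truth.shape == preds_a.shape == preds_b.shape):
        raise ValueError("label vectors must be aligned")
    mask = truth == stage
    if not mask.any():
        raise ValueError(f"stage {stage_name(stage)} absent from the truth labels")
    ca = int((preds_a[mask] == stage).sum())
    cb = int((preds_b[mask] == stage).sum())
    n = int(mask.sum())
    return np.array([[ca, n - ca], [cb, n - cb]])


def _check_2x2(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def small_expected_counts(table: np.ndarray, threshold: float = 5.0) -> bool:
    """True when any expected count under independence is below threshold."""
    t = _check_2x2(table).astype(float)
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return bool((expected < threshold).any())


def chi2_yates(table: np.ndarray, stage: str = "") -> ContingencyResult:
    """Pearson chi-squared with Yates continuity correction, df = 1."""
    t = _check_2x2(table).astype(float)
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a margin is zero")
    expected = np.outer(row, col) / n
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ContingencyResult(stage, t.astype(int), "chi2_yates", statistic, p)


def fisher_exact_two_sided(table: np.ndarray, stage: str = "") -> ContingencyResult:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    p = sum of P(table') over all tables with the observed margins whose
    probability does not exceed the observed table's (1e-12 relative
    tolerance on the comparison).
    """
    t = _check_2x2(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("Fisher test requires integer counts")
        t = np.round(t).astype(int)
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    # a = top-left cell; hypergeometric over draws of c1 from r1 | r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(int(t[0, 0]), n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    odds = np.inf
    if t[0, 1] * t[1, 0] > 0:
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return ContingencyResult(stage, t, "fisher", odds, min(p, 1.0))


def compare_pipelines(
    truth: np.ndarray,
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    methods: dict[int, str] | None = None,
) -> list[ContingencyResult]:
    """Per-stage 2x2 tests between two pipelines' predictions.

    ``methods`` maps stage index -> "chi2_yates" | "fisher"; stages not
    listed default to Fisher when any expected count is below 5, else the
    Yates chi-squared.
    """
    methods = methods or {}
    out = []
    for s in sorted(set(np.asarray(truth, dtype=int))):
        tab = stage_contingency(truth, preds_a, preds_b, s)
        method = methods.get(int(s))
        if method is None:
            method = "fisher" if small_expected_counts(tab) else "chi2_yates"
        fn = fisher_exact_two_sided if method == "fisher" else chi2_yates
        out.append(fn(tab, stage=stage_name(s)))
    return out


def contingency_table_report(results: list[ContingencyResult]) -> pd.DataFrame:
    """Text-table rendering of per-stage tests (published Table-3 layout)."""
    rows = []
    for r in results:
        rows.append(
            {
                "stage": r.stage,
                "A_correct": r.counts[0, 0],
                "A_incorrect": r.counts[0, 1],
                "B_correct": r.counts[1, 0],
                "B_incorrect": r.counts[1, 1],
                "method": r.method,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
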