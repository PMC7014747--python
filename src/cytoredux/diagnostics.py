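"""Diagnostic-test machinery: confusion metrics, ROC/AUC, Hanley-McNeil
variance and power, Youden cutoffs, and the association tests used in the
cohort analysis.

Conventions fixed package-wide:

* the positive class is **suboptimal cytoreduction** (label 1);
* the classification rule for a continuous marker is ``score >= cutoff ->
  positive`` (higher marker burden predicts residual disease);
* a metric whose denominator is zero is reported as ``nan`` (undefined),
  never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CohortError

_POSITIVE_LABELS = {1, True, "suboptimal"}
_NEGATIVE_LABELS = {0, False, "optimal"}


def as_binary(labels) -> np.ndarray:
    """Coerce outcome labels to {0,1} with 1 = suboptimal (positive)."""
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        key = lab.lower() if isinstance(lab, str) else lab
        if key in _POSITIVE_LABELS:
            out[i] = 1
        elif key in _NEGATIVE_LABELS:
            out[i] = 0
        else:
            raise ValueError(f"unrecognized outcome label {lab!r}")
    return out


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts; positive class = suboptimal cytoreduction."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy; nan = undefined."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def confusion_table(truth, predicted) -> ConfusionTable:
    """Cross-tabulate truth against prediction (positive = suboptimal)."""
    y = as_binary(truth)
    yhat = as_binary(predicted)
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} truth vs {len(yhat)} predicted")
    return ConfusionTable(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_metrics(table: ConfusionTable) -> DiagnosticMetrics:
    return DiagnosticMetrics(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=(table.tp + table.tn) / table.total,
    )


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and its area.

    ``points`` are (1-specificity, sensitivity) operating points over
    thresholds at every distinct score, bracketed by (0,0) and (1,1).
    ``auc`` is the midrank Mann-Whitney statistic
    (#{pos > neg pairs} + 0.5 * #ties) / (n_pos * n_neg), which equals the
    trapezoidal area under ``points``.
    """

    points: np.ndarray     # shape (m, 2): (fpr, tpr)
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.points[:, 1], self.points[:, 0]))


def _split_scores(scores, truth):
    s = np.asarray(scores, dtype=float)
    y = as_binary(truth)
    if len(s) != len(y):
        raise ValueError("scores and truth must have equal length")
    if y.sum() == 0 or y.sum() == len(y):
        raise CohortError("ROC requires both outcome classes")
    return s, y


def roc_auc(scores, truth) -> ROCResult:
    """Empirical ROC curve with midrank-tie-aware AUC (higher score =
    more likely suboptimal)."""
    s, y = _split_scores(scores, truth)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    points = np.column_stack(
        (np.r_[0.0, fps / n_neg], np.r_[0.0, tps / n_pos])
    )
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return ROCResult(points=points, thresholds=thresholds, auc=float(auc),
                     n_pos=n_pos, n_neg=n_neg)


def _hanley_variance(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auc_se_ci_hanley(auc: float, n_pos: int, n_neg: int, level: float = 0.95):
    """Hanley-McNeil standard error of an empirical AUC, with a symmetric
    normal confidence interval clipped to [0, 1].

    Returns ``(se, (lower, upper))``.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("Hanley-McNeil variance requires n_pos, n_neg >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    se = math.sqrt(max(_hanley_variance(auc, n_pos, n_neg), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return se, ci


def auc_power_hanley(auc_alt: float, n_pos: int, n_neg: int,
                     alpha: float = 0.05) -> float:
    """Power to distinguish an AUC of ``auc_alt`` from the null 0.5.

    Normal-approximation power with Hanley-McNeil standard errors under the
    null (SE0, at AUC 0.5) and the alternative (SE1, at ``auc_alt``), at
    two-sided ``alpha``:

        power = Phi((auc_alt - 0.5 - z_{1-alpha/2} * SE0) / SE1).
    """
    if not 0.5 < auc_alt <= 1.0:
        raise ValueError("auc_alt must be in (0.5, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    se0 = math.sqrt(_hanley_variance(0.5, n_pos, n_neg))
    se1 = math.sqrt(_hanley_variance(auc_alt, n_pos, n_neg))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if se1 == 0.0:
        return 1.0
    return float(stats.norm.cdf((auc_alt - 0.5 - z * se0) / se1))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_cutoff(scores, truth, criterion: str = "youden") -> CutoffResult:
    """Choose a dichotomizing cutoff for a continuous marker.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    scores plus -inf/+inf sentinels; the rule is ``score >= cutoff ->
    positive``.  ``criterion`` is ``"youden"`` (maximize J = sens + spec - 1)
    or ``"closest"`` (minimize distance to the (0,1) ROC corner).  Ties are
    broken toward the lowest cutoff.
    """
    if criterion not in {"youden", "closest"}:
        raise ValueError("criterion must be 'youden' or 'closest'")
    s, y = _split_scores(scores, truth)
    distinct = np.unique(s)
    candidates = np.r_[-np.inf, (distinct[:-1] + distinct[1:]) / 2.0, np.inf]

    best = None
    for c in candidates:
        positive = s >= c
        sens = float(positive[y == 1].mean())
        spec = float((~positive)[y == 0].mean())
        j = sens + spec - 1.0
        objective = j if criterion == "youden" else -math.hypot(1 - sens, 1 - spec)
        if best is None or objective > best[0] + 1e-12:
            best = (objective, c, j, sens, spec)
    _, cutoff, j, sens, spec = best
    return CutoffResult(cutoff=float(cutoff), youden_j=j,
                        sensitivity=sens, specificity=spec)


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on midranks).

    Returns ``nan`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_rho requires equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square on a 2xk contingency table, no continuity
    correction; df = k - 1."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2xk with k >= 2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive row and column margins")
    statistic, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(statistic), float(p)
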