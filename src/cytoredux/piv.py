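"""Predictive Index Value (PIV) model.

The PIV is an integer risk score for suboptimal cytoreduction: each of the
eight preoperative parameters (age, FIGO stage, histology, grade, CA125,
HE4, ECOG, ASA) is dichotomized against a cutoff, per-parameter diagnostic
tables are computed, parameters receive small integer point weights, and a
patient's score is the weighted sum of positive indicators.  Sweeping the
score threshold trades sensitivity against specificity.

Two weighting rules are provided:

* ``ppv_weighted`` (default) — every parameter is kept; weight 2 when its
  PPV >= 0.5, else 1 (maximum score 12);
* ``selected_only`` — only parameters whose PPV and NPV both clear 0.5 are
  kept, each at weight 2 (maximum score 8 with the reference diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort
from .diagnostics import (
    CutoffResult,
    DiagnosticMetrics,
    confusion_table,
    diagnostic_metrics,
    roc_auc,
    youden_cutoff,
    as_binary,
)
from .errors import CohortError

#: Canonical parameter order for indicator vectors and weight vectors.
PARAMETERS = (
    "age",
    "figo_stage",
    "histology",
    "grade",
    "ca125",
    "he4",
    "ecog",
    "asa",
)


@dataclass(frozen=True)
class CutoffSpec:
    """Dichotomization rules mapping a patient record to an 8-indicator vector.

    Boundary conventions: CA125/HE4/ASA use >=, age and ECOG use strict >.
    Defaults are the reference analysis cutoffs (age 68.5 years, CA125
    313.60 U/ml, HE4 777.10 pmol/L); histology's positive category is
    non-serous.
    """

    age_cutoff: float = 68.5          # age > cutoff -> positive
    figo_positive: str = "IV"
    histology_positive: str = "other"
    grade_positive: int = 3
    ca125_cutoff: float = 313.60      # ca125 >= cutoff -> positive
    he4_cutoff: float = 777.10        # he4 >= cutoff -> positive
    ecog_cutoff: int = 0              # ecog > cutoff -> positive
    asa_positive: str = "3plus"

    def describe(self) -> dict:
        return {
            "age": f"> {self.age_cutoff}",
            "figo_stage": f"= {self.figo_positive}",
            "histology": f"= {self.histology_positive}",
            "grade": f"= {self.grade_positive}",
            "ca125": f">= {self.ca125_cutoff}",
            "he4": f">= {self.he4_cutoff}",
            "ecog": f"> {self.ecog_cutoff}",
            "asa": f"= {self.asa_positive}",
        }


def binarize_record(record, spec: CutoffSpec) -> np.ndarray:
    """Indicator 8-vector for one patient, in :data:`PARAMETERS` order."""
    return np.array(
        [
            int(record.age > spec.age_cutoff),
            int(record.figo_stage == spec.figo_positive),
            int(record.histology == spec.histology_positive),
            int(record.grade == spec.grade_positive),
            int(record.ca125 >= spec.ca125_cutoff),
            int(record.he4 >= spec.he4_cutoff),
            int(record.ecog > spec.ecog_cutoff),
            int(record.asa == spec.asa_positive),
        ],
        dtype=int,
    )


def binarize_cohort(cohort: Cohort, spec: CutoffSpec) -> np.ndarray:
    return np.array([binarize_record(r, spec) for r in cohort])


@dataclass(frozen=True)
class ParameterDiagnostics:
    """Per-parameter diagnostic row: 2x2 metrics of the dichotomized
    parameter against the outcome, plus AUC of the underlying score."""

    parameter: str
    cutoff: str
    metrics: DiagnosticMetrics
    auc: float
    p_value: float
    point: int | None = None


@dataclass(frozen=True)
class WeightRule:
    mode: str = "ppv_weighted"        # or "selected_only"
    accuracy_min: float = 0.0
    ppv_min: float = 0.5
    npv_min: float = 0.5

    def __post_init__(self):
        if self.mode not in {"ppv_weighted", "selected_only"}:
            raise ValueError("mode must be 'ppv_weighted' or 'selected_only'")
        for name in ("accuracy_min", "ppv_min", "npv_min"):
            v = getattr(self, name)
            if not 0.0 <= v or v > 1.01:
                raise ValueError(f"{name} must be a proportion")


@dataclass(frozen=True)
class PIVModel:
    """Selected parameters with integer point weights."""

    weights: dict            # parameter -> positive integer weight
    cutoffs: CutoffSpec
    rule: WeightRule

    @property
    def max_score(self) -> int:
        return int(sum(self.weights.values()))

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(p, 0) for p in PARAMETERS], dtype=int)


def parameter_diagnostics(cohort: Cohort, spec: CutoffSpec) -> list[ParameterDiagnostics]:
    """Table of per-parameter diagnostic efficacy against the outcome.

    AUC uses the raw continuous value for age/CA125/HE4 and the binary
    indicator for the categorical parameters; the p-value is a two-sided
    normal test of AUC = 0.5 with the Hanley-McNeil standard error.
    """
    from scipy import stats as _st

    cohort.require_both_classes()
    y = cohort.outcomes
    indicators = binarize_cohort(cohort, spec)
    frame = cohort.to_frame()
    continuous = {"age", "ca125", "he4"}
    descriptions = spec.describe()

    rows = []
    for j, name in enumerate(PARAMETERS):
        ind = indicators[:, j]
        metrics = diagnostic_metrics(confusion_table(y, ind))
        score = frame[name].to_numpy(dtype=float) if name in continuous else ind
        roc = roc_auc(score, y)
        from .diagnostics import auc_se_ci_hanley

        se, _ = auc_se_ci_hanley(roc.auc, roc.n_pos, roc.n_neg)
        p = 2.0 * _st.norm.sf(abs(roc.auc - 0.5) / se) if se > 0 else 0.0
        rows.append(
            ParameterDiagnostics(
                parameter=name,
                cutoff=descriptions[name],
                metrics=metrics,
                auc=roc.auc,
                p_value=float(p),
            )
        )
    return rows


def build_piv_model(
    rows: list[ParameterDiagnostics],
    rule: WeightRule = WeightRule(),
    cutoffs: CutoffSpec = CutoffSpec(),
) -> PIVModel:
    """Assign point weights from per-parameter diagnostics.

    ``ppv_weighted``: every parameter passing ``accuracy_min`` is included,
    weight 2 iff PPV >= 0.5 else 1.  ``selected_only``: parameters passing
    ``accuracy_min``, ``ppv_min`` and ``npv_min`` are included at weight 2.
    Undefined (nan) metrics never pass a threshold.
    """
    if not rows:
        raise ValueError("no parameter diagnostics supplied")

    def _passes(value, threshold):
        return not np.isnan(value) and value >= threshold

    weights = {}
    for row in rows:
        m = row.metrics
        if not _passes(m.accuracy, rule.accuracy_min):
            continue
        if rule.mode == "ppv_weighted":
            weights[row.parameter] = 2 if _passes(m.ppv, 0.5) else 1
        else:
            if _passes(m.ppv, rule.ppv_min) and _passes(m.npv, rule.npv_min):
                weights[row.parameter] = 2
    if not weights:
        raise CohortError("no parameters selected by the weighting rule")
    return PIVModel(weights=weights, cutoffs=cutoffs, rule=rule)


def piv_scores(cohort: Cohort, spec: CutoffSpec, model: PIVModel):
    """Integer PIV per patient plus a score histogram by outcome.

    Returns ``(scores, histogram)`` where ``histogram`` is a DataFrame
    indexed by score 0..max_score with columns optimal/suboptimal/total.
    """
    indicators = binarize_cohort(cohort, spec)
    scores = indicators @ model.weight_vector()
    y = cohort.outcomes
    index = np.arange(model.max_score + 1)
    hist = pd.DataFrame(
        {
            "optimal": [int(((scores == s) & (y == 0)).sum()) for s in index],
            "suboptimal": [int(((scores == s) & (y == 1)).sum()) for s in index],
        },
        index=pd.Index(index, name="piv"),
    )
    hist["total"] = hist["optimal"] + hist["suboptimal"]
    return scores, hist


@dataclass(frozen=True)
class PIVThresholdRow:
    threshold: int
    metrics: DiagnosticMetrics
    n_flagged: int


def threshold_sweep(scores, truth, max_score: int | None = None) -> list[PIVThresholdRow]:
    """Diagnostic metrics of the rule ``PIV >= t`` for t = 1..max_score.

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold; this is verified as a post-condition.
    """
    scores = np.asarray(scores, dtype=int)
    y = as_binary(truth)
    if y.sum() == 0 or y.sum() == len(y):
        raise CohortError("threshold sweep requires both outcome classes")
    if max_score is None:
        max_score = int(scores.max())
    rows = []
    for t in range(1, max_score + 1):
        flagged = scores >= t
        rows.append(
            PIVThresholdRow(
                threshold=t,
                metrics=diagnostic_metrics(confusion_table(y, flagged.astype(int))),
                n_flagged=int(flagged.sum()),
            )
        )
    sens = [r.metrics.sensitivity for r in rows]
    spec = [r.metrics.specificity for r in rows]
    if any(b > a + 1e-12 for a, b in zip(sens, sens[1:])) or any(
        b < a - 1e-12 for a, b in zip(spec, spec[1:])
    ):
        raise AssertionError("threshold sweep monotonicity violated")
    return rows


class PIVClassifier(BaseEstimator, ClassifierMixin):
    """Points-based Predictive Index Value classifier (sklearn interface).

    ``fit`` expects ``X`` as a DataFrame with the cohort covariate columns
    (age, figo_stage, grade, histology, ca125, he4, ecog, asa) and ``y`` as
    outcome labels (``optimal``/``suboptimal`` or 0/1 with 1 = suboptimal).

    Parameters
    ----------
    rule_mode : {"ppv_weighted", "selected_only"}
        Point-weighting rule (see module docstring).
    cutoffs : CutoffSpec, "reference" or "auto"
        ``"reference"`` uses the fixed reference cutoffs; ``"auto"``
        re-derives the age/CA125/HE4 cutoffs from the training data by
        maximizing Youden's J.
    threshold : int
        Score threshold for ``predict`` (PIV >= threshold -> suboptimal).
    accuracy_min, ppv_min, npv_min : float
        Selection thresholds forwarded to :class:`WeightRule`.
    """

    def __init__(
        self,
        rule_mode: str = "ppv_weighted",
        cutoffs="reference",
        threshold: int = 6,
        accuracy_min: float = 0.0,
        ppv_min: float = 0.5,
        npv_min: float = 0.5,
    ):
        self.rule_mode = rule_mode
        self.cutoffs = cutoffs
        self.threshold = threshold
        self.accuracy_min = accuracy_min
        self.ppv_min = ppv_min
        self.npv_min = npv_min

    def _cohort(self, X, y=None) -> Cohort:
        from .cohort import PatientRecord

        frame = X.copy()
        if y is not None:
            frame = frame.assign(outcome=np.where(as_binary(y) == 1, "suboptimal", "optimal"))
        if "patient_id" not in frame.columns:
            frame = frame.assign(patient_id=[f"X{i:05d}" for i in range(len(frame))])
        records = tuple(PatientRecord.from_raw(row) for row in frame.to_dict("records"))
        return Cohort(records)

    def fit(self, X, y):
        cohort = X if isinstance(X, Cohort) else self._cohort(X, y)
        cohort.require_both_classes()
        outcome = cohort.outcomes

        if isinstance(self.cutoffs, CutoffSpec):
            spec = self.cutoffs
        elif self.cutoffs == "reference":
            spec = CutoffSpec()
        elif self.cutoffs == "auto":
            frame = cohort.to_frame()
            spec = CutoffSpec(
                age_cutoff=youden_cutoff(frame["age"], outcome).cutoff,
                ca125_cutoff=youden_cutoff(frame["ca125"], outcome).cutoff,
                he4_cutoff=youden_cutoff(frame["he4"], outcome).cutoff,
            )
        else:
            raise ValueError("cutoffs must be CutoffSpec, 'reference' or 'auto'")

        rule = WeightRule(
            mode=self.rule_mode,
            accuracy_min=self.accuracy_min,
            ppv_min=self.ppv_min,
            npv_min=self.npv_min,
        )
        rows = parameter_diagnostics(cohort, spec)
        model = build_piv_model(rows, rule, spec)
        rows = [replace(r, point=model.weights.get(r.parameter)) for r in rows]

        self.classes_ = np.array([0, 1])
        self.cutoff_spec_ = spec
        self.parameter_diagnostics_ = rows
        self.model_ = model
        self.weights_ = dict(model.weights)
        self.max_score_ = model.max_score
        return self

    def decision_function(self, X) -> np.ndarray:
        """Integer PIV score per patient."""
        cohort = X if isinstance(X, Cohort) else self._dummy_cohort(X)
        return binarize_cohort(cohort, self.cutoff_spec_) @ self.model_.weight_vector()

    def _dummy_cohort(self, X) -> Cohort:
        frame = X.copy()
        if "outcome" not in frame.columns:
            frame = frame.assign(outcome="optimal")  # placeholder; unused by scoring
        if "patient_id" not in frame.columns:
            frame = frame.assign(patient_id=[f"X{i:05d}" for i in range(len(frame))])
        from .cohort import PatientRecord

        return Cohort(tuple(PatientRecord.from_raw(r) for r in frame.to_dict("records")))

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold).astype(int)

    def sweep(self, X, y) -> list[PIVThresholdRow]:
        """Threshold sweep of the fitted score on (X, y)."""
        return threshold_sweep(self.decision_function(X), y, self.max_score_)
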