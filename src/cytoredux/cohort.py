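"""Patient-cohort data model, CSV I/O and group summaries.

The cohort is a table of preoperative covariates for advanced epithelial
ovarian cancer patients undergoing primary debulking surgery, together with
the binary surgical outcome: *optimal* cytoreduction (zero residual tumor)
versus *suboptimal*.  Throughout the package the positive class is
``suboptimal`` — the event every model tries to predict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortError, RowValidationError, SchemaError

#: Exact CSV column order for cohort files.
COLUMNS = (
    "patient_id",
    "age",
    "figo_stage",
    "grade",
    "histology",
    "ca125",
    "he4",
    "ecog",
    "asa",
    "outcome",
)

OUTCOMES = ("optimal", "suboptimal")
FIGO_STAGES = ("III", "IV")
HISTOLOGIES = ("serous", "other")
ASA_CLASSES = ("1", "2", "3plus")
GRADES = (1, 2, 3)
ECOG_LEVELS = (0, 1, 2)

CONTINUOUS_VARIABLES = ("age", "ca125", "he4")
CATEGORICAL_VARIABLES = ("figo_stage", "grade", "histology", "ecog", "asa")


def _normalize_figo(raw: str) -> str:
    v = str(raw).strip().upper()
    if v in {"III", "3"}:
        return "III"
    if v in {"IV", "4"}:
        return "IV"
    raise ValueError(f"invalid FIGO stage {raw!r} (advanced disease: III or IV)")


def _normalize_histology(raw: str) -> str:
    v = str(raw).strip().lower()
    if v == "serous":
        return "serous"
    if v in {"other", "others", "non-serous", "nonserous"}:
        return "other"
    raise ValueError(f"invalid histology {raw!r}")


def _normalize_asa(raw: str) -> str:
    v = str(raw).strip().lower().replace(" ", "")
    if v in {"1", "2"}:
        return v
    if v in {"3plus", "3+", ">=3", "≥3"}:
        return "3plus"
    try:
        if int(float(v)) >= 3:  # ASA >= 3 collapses to a single class
            return "3plus"
    except ValueError:
        pass
    raise ValueError(f"invalid ASA class {raw!r}")


def _normalize_outcome(raw: str) -> str:
    v = str(raw).strip().lower()
    if v in OUTCOMES:
        return v
    raise ValueError(f"invalid outcome {raw!r} (expected optimal/suboptimal)")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's preoperative covariates plus surgical outcome.

    Units: ``age`` in years, ``ca125`` in U/ml, ``he4`` in pmol/L.
    Validation enforces the complete-case design: every field is required
    and range-checked at construction.
    """

    patient_id: str
    age: float
    figo_stage: str
    grade: int
    histology: str
    ca125: float
    he4: float
    ecog: int
    asa: str
    outcome: str

    def __post_init__(self):
        checks = [
            ("age", 18.0 <= float(self.age) <= 100.0, "age must be in [18, 100]"),
            ("ca125", float(self.ca125) > 0, "ca125 must be > 0 (concentration)"),
            ("he4", float(self.he4) > 0, "he4 must be > 0 (concentration)"),
            ("figo_stage", self.figo_stage in FIGO_STAGES, "figo_stage must be III or IV"),
            ("grade", self.grade in GRADES, "grade must be 1, 2 or 3"),
            ("histology", self.histology in HISTOLOGIES, "histology must be serous/other"),
            ("ecog", self.ecog in ECOG_LEVELS, "ecog must be 0, 1 or 2"),
            ("asa", self.asa in ASA_CLASSES, "asa must be 1, 2 or 3plus"),
            ("outcome", self.outcome in OUTCOMES, "outcome must be optimal/suboptimal"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise RowValidationError(msg, field=name)

    @classmethod
    def from_raw(cls, raw: Mapping[str, object]) -> "PatientRecord":
        """Build a record from raw (string) cell values, normalizing case
        and collapsing ASA >= 3 into the ``3plus`` class."""

        def _field(name, convert):
            try:
                value = raw[name]
            except KeyError:
                raise SchemaError(f"missing required column '{name}'") from None
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise RowValidationError(f"missing value for '{name}'", field=name)
            try:
                return convert(value)
            except RowValidationError:
                raise
            except (ValueError, TypeError) as exc:
                raise RowValidationError(str(exc), field=name) from None

        return cls(
            patient_id=str(raw.get("patient_id", "")).strip(),
            age=_field("age", float),
            figo_stage=_field("figo_stage", _normalize_figo),
            grade=_field("grade", lambda v: int(float(v))),
            histology=_field("histology", _normalize_histology),
            ca125=_field("ca125", float),
            he4=_field("he4", float),
            ecog=_field("ecog", lambda v: int(float(v))),
            asa=_field("asa", _normalize_asa),
            outcome=_field("outcome", _normalize_outcome),
        )


@dataclass(frozen=True)
class Cohort:
    """Ordered, validated collection of :class:`PatientRecord`."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def outcomes(self) -> np.ndarray:
        """Binary outcome vector: 1 = suboptimal (positive class)."""
        return np.array([1 if r.outcome == "suboptimal" else 0 for r in self.records])

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "Cohort":
        recs = tuple(self.records[i] for i in indices)
        return Cohort(recs, provenance if provenance is not None else self.provenance)

    def with_provenance(self, provenance: str) -> "Cohort":
        return replace(self, provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in COLUMNS} for r in self.records],
            columns=list(COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for i, (_, row) in enumerate(frame.iterrows()):
            try:
                records.append(PatientRecord.from_raw(row.to_dict()))
            except RowValidationError as exc:
                raise RowValidationError(
                    f"row {i}: {exc} (field '{exc.field}')", row=i, field=exc.field
                ) from None
        return cls(tuple(records), provenance)

    def require_both_classes(self) -> None:
        present = {r.outcome for r in self.records}
        if set(OUTCOMES) - present:
            raise CohortError(
                "cannot compare groups: cohort lacks outcome class(es) "
                f"{sorted(set(OUTCOMES) - present)}"
            )


def read_cohort(path, provenance: str | None = None, **csv_options) -> Cohort:
    """Read a cohort CSV (UTF-8, comma-separated, header required).

    Categorical cells are normalized case-insensitively and ASA values >= 3
    are collapsed to ``3plus``.  Row order is preserved.
    """
    frame = pd.read_csv(path, dtype=str, **csv_options)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    cohort = Cohort.from_frame(frame[list(COLUMNS)], provenance or str(path))
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; ``read_cohort`` round-trips it field-for-field."""
    cohort.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ContinuousSummary:
    variable: str
    overall_mean: float
    overall_sd: float
    group_mean: dict
    group_sd: dict
    group_n: dict
    p_value: float


@dataclass(frozen=True)
class CategoricalSummary:
    variable: str
    levels: tuple
    overall_counts: dict
    group_counts: dict   # outcome -> {level: count}
    overall_pct: dict
    p_value: float
    min_expected: float


@dataclass(frozen=True)
class GroupSummary:
    """Outcome-stratified descriptive table with comparison p-values."""

    n: int
    group_n: dict
    optimal_rate: float
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)


def welch_t_from_moments(mean1, sd1, n1, mean2, sd2, n2, equal_var=False):
    """Two-sample t-test from summary statistics (Welch by default).

    Returns ``(t, p)``.  The Welch flavor is the package default because it is
    the appropriate test when group variances differ by factors of several,
    as serum-marker SDs here do.
    """
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(cohort: Cohort, t_flavor: str = "welch") -> GroupSummary:
    """Table-1-style summary: per-variable overall and per-outcome-group
    statistics with two-sample t (continuous) or Pearson chi-square
    (categorical) comparison p-values.

    Sample SD uses the n-1 denominator.  Chi-square is Pearson without
    continuity correction; a warning is emitted when any expected cell
    count falls below 5.
    """
    cohort.require_both_classes()
    if t_flavor not in {"welch", "student"}:
        raise ValueError("t_flavor must be 'welch' or 'student'")
    equal_var = t_flavor == "student"

    frame = cohort.to_frame()
    groups = {g: frame[frame["outcome"] == g] for g in OUTCOMES}
    group_n = {g: len(df) for g, df in groups.items()}

    continuous = {}
    for var in CONTINUOUS_VARIABLES:
        x = {g: df[var].to_numpy(dtype=float) for g, df in groups.items()}
        t, p = stats.ttest_ind(x["optimal"], x["suboptimal"], equal_var=equal_var)
        continuous[var] = ContinuousSummary(
            variable=var,
            overall_mean=float(frame[var].mean()),
            overall_sd=float(frame[var].std(ddof=1)),
            group_mean={g: float(v.mean()) for g, v in x.items()},
            group_sd={g: float(np.std(v, ddof=1)) for g, v in x.items()},
            group_n=group_n,
            p_value=float(p),
        )

    categorical = {}
    level_order = {
        "figo_stage": FIGO_STAGES,
        "grade": GRADES,
        "histology": HISTOLOGIES,
        "ecog": ECOG_LEVELS,
        "asa": ASA_CLASSES,
    }
    for var in CATEGORICAL_VARIABLES:
        levels = tuple(lv for lv in level_order[var] if (frame[var] == lv).any())
        table = np.array(
            [[int((groups[g][var] == lv).sum()) for lv in levels] for g in OUTCOMES]
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        min_expected = float(expected.min())
        if min_expected < 5:
            warnings.warn(
                f"chi-square for '{var}': smallest expected cell count is "
                f"{min_expected:.2f} (< 5); the asymptotic p-value is approximate",
                stacklevel=2,
            )
        if table.shape[1] < 2:
            p = float("nan")
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        overall_counts = {lv: int((frame[var] == lv).sum()) for lv in levels}
        categorical[var] = CategoricalSummary(
            variable=var,
            levels=levels,
            overall_counts=overall_counts,
            group_counts={
                g: {lv: int((groups[g][var] == lv).sum()) for lv in levels}
                for g in OUTCOMES
            },
            overall_pct={lv: overall_counts[lv] / len(frame) for lv in levels},
            p_value=float(p),
            min_expected=min_expected,
        )

    return GroupSummary(
        n=len(frame),
        group_n=group_n,
        optimal_rate=group_n["optimal"] / len(frame),
        continuous=continuous,
        categorical=categorical,
    )
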