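"""End-to-end orchestration: cohort acquisition -> group summary ->
marker cutoffs -> per-parameter diagnostics -> PIV build and threshold
sweep -> split-sample logistic fit and validation -> AUC power.

Every stage is deterministic given the run configuration: a single
top-level seed expands into named sub-seeds (generation, split) through a
fixed hash derivation, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    Cohort,
    GroupSummary,
    read_cohort,
    summarize_cohort,
)
from .diagnostics import auc_power_hanley, youden_cutoff
from .errors import PipelineStageError
from .logistic import (
    CovariateEncoding,
    LogisticFit,
    PublishedModel,
    ValidationResult,
    evaluate_validation,
    fit_logistic_irls,
    hosmer_lemeshow,
    published_model_probabilities,
    split_cohort,
)
from .piv import (
    CutoffSpec,
    PIVModel,
    ParameterDiagnostics,
    WeightRule,
    build_piv_model,
    parameter_diagnostics,
    piv_scores,
    threshold_sweep,
)
from .simulate import SyntheticConfig, generate_cohort, reference_config

logger = logging.getLogger("cytoredux")


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed derivation: sha256 of '<seed>:<label>', below 2^31."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``cohort_csv`` / ``synthetic`` supplies the cohort.
    ``cutoffs=None`` re-derives the CA125/HE4 cutoffs from the cohort by
    Youden's J (age and categorical rules keep their defaults); pass a
    :class:`CutoffSpec` to override.
    """

    cohort_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    cutoffs: CutoffSpec | None = None
    rule: WeightRule = field(default_factory=WeightRule)
    train_fraction: float = 43 / 83
    seed: int = 0
    piv_threshold: int = 6
    hl_groups: int = 10
    report_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.cohort_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of cohort_csv/synthetic must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "synthetic" in data and data["synthetic"] is not None:
            if data["synthetic"] == "reference":
                data["synthetic"] = reference_config()
            else:
                data["synthetic"] = SyntheticConfig.from_dict(data["synthetic"])
        if data.get("cutoffs"):
            data["cutoffs"] = CutoffSpec(**data["cutoffs"])
        if data.get("rule"):
            data["rule"] = WeightRule(**data["rule"])
        return cls(**data)


@dataclass
class ReportBundle:
    """Everything a full run computes, plus reproducibility metadata."""

    table1: GroupSummary
    cutoff_spec: CutoffSpec
    table2: list            # ParameterDiagnostics
    piv_model: PIVModel
    piv_scores: np.ndarray
    score_histogram: object  # DataFrame indexed by score
    table3: list            # PIVThresholdRow
    train_n: int
    validation_n: int
    logistic_fit: LogisticFit
    hl: object               # HLResult on training fit
    validation_refit: ValidationResult
    validation_published: ValidationResult
    power: float
    metadata: dict


def _stage(name):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the whole analysis; deterministic given config and seed."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)

    gen_seed = derive_seed(config.seed, "generate")
    split_seed = derive_seed(config.seed, "split")

    if config.cohort_csv is not None:
        cohort = _stage("load")(read_cohort, config.cohort_csv)
    else:
        cohort = _stage("simulate")(generate_cohort, config.synthetic, gen_seed)
    logger.info("cohort n=%d (%s)", len(cohort), cohort.provenance)

    table1 = _stage("summarize")(summarize_cohort, cohort)

    def _cutoffs():
        if config.cutoffs is not None:
            return config.cutoffs
        frame = cohort.to_frame()
        y = cohort.outcomes
        return CutoffSpec(
            ca125_cutoff=youden_cutoff(frame["ca125"], y).cutoff,
            he4_cutoff=youden_cutoff(frame["he4"], y).cutoff,
        )

    spec = _stage("cutoffs")(_cutoffs)
    logger.info("cutoffs: ca125 %.2f, he4 %.2f", spec.ca125_cutoff, spec.he4_cutoff)

    table2 = _stage("parameter_diagnostics")(parameter_diagnostics, cohort, spec)
    model = _stage("piv_build")(build_piv_model, table2, config.rule, spec)
    table2 = [dataclasses.replace(r, point=model.weights.get(r.parameter)) for r in table2]
    logger.info("piv weights: %s (max %d)", model.weights, model.max_score)

    def _scores_and_sweep():
        scores, hist = piv_scores(cohort, spec, model)
        return scores, hist, threshold_sweep(scores, cohort.outcomes, model.max_score)

    scores, hist, table3 = _stage("piv_sweep")(_scores_and_sweep)

    train, validation = _stage("split")(
        split_cohort, cohort, config.train_fraction, split_seed
    )
    logger.info("split: train %d / validation %d", len(train), len(validation))

    encoding = CovariateEncoding(
        ca125_cutoff=spec.ca125_cutoff, he4_cutoff=spec.he4_cutoff
    )

    def _fit():
        X, y = encoding.design(train)
        return fit_logistic_irls(X, y)

    fit = _stage("logistic_fit")(_fit)

    def _calibration():
        X, y = encoding.design(train)
        design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        from scipy.special import expit

        return hosmer_lemeshow(expit(design @ fit.coef), y, groups=config.hl_groups)

    hl = _stage("hosmer_lemeshow")(_calibration)

    def _validate():
        Xv, yv = encoding.design(validation)
        design = np.column_stack([np.ones(len(Xv)), Xv.to_numpy(dtype=float)])
        from scipy.special import expit

        refit = evaluate_validation(expit(design @ fit.coef), yv)
        published = evaluate_validation(
            published_model_probabilities(validation, PublishedModel(), encoding), yv
        )
        return refit, published

    refit_eval, published_eval = _stage("validate")(_validate)

    def _power():
        n_pos = int(validation.outcomes.sum())
        n_neg = len(validation) - n_pos
        if refit_eval.auc <= 0.5:
            return float("nan")
        return auc_power_hanley(refit_eval.auc, n_pos, n_neg)

    power = _stage("power")(_power)

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "generation_seed": gen_seed,
        "split_seed": split_seed,
        "cohort_n": len(cohort),
        "cohort_provenance": cohort.provenance,
        "train_n": len(train),
        "validation_n": len(validation),
        "rule_mode": config.rule.mode,
        "cutoffs": spec.describe(),
        "config_hash": (
            config.synthetic.config_hash() if config.synthetic else None
        ),
    }
    return ReportBundle(
        table1=table1,
        cutoff_spec=spec,
        table2=table2,
        piv_model=model,
        piv_scores=scores,
        score_histogram=hist,
        table3=table3,
        train_n=len(train),
        validation_n=len(validation),
        logistic_fit=fit,
        hl=hl,
        validation_refit=refit_eval,
        validation_published=published_eval,
        power=power,
        metadata=metadata,
    )


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.4f}"
    return str(x)


REPORT_FILES = (
    "table1.csv",
    "table2.csv",
    "table3.csv",
    "piv_model.json",
    "logistic.json",
    "power.json",
    "run_metadata.json",
)


def render_reports(bundle: ReportBundle, directory) -> None:
    """Write the report bundle as CSV/JSON files with stable ordering and
    fixed 4-decimal float formatting (re-rendering is byte-identical)."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)

    t1 = bundle.table1
    lines = ["Variable,Level,All,Optimal,Suboptimal,P"]
    for var, s in t1.continuous.items():
        lines.append(
            f"{var},mean_sd,"
            f"{_fmt(s.overall_mean)} ± {_fmt(s.overall_sd)},"
            f"{_fmt(s.group_mean['optimal'])} ± {_fmt(s.group_sd['optimal'])},"
            f"{_fmt(s.group_mean['suboptimal'])} ± {_fmt(s.group_sd['suboptimal'])},"
            f"{_fmt(s.p_value)}"
        )
    for var, s in t1.categorical.items():
        for lv in s.levels:
            lines.append(
                f"{var},{lv},{s.overall_counts[lv]},"
                f"{s.group_counts['optimal'][lv]},"
                f"{s.group_counts['suboptimal'][lv]},{_fmt(s.p_value)}"
            )
    lines.append(f"optimal_rate,,{_fmt(t1.optimal_rate)},,,")
    (out / "table1.csv").write_text("\n".join(lines) + "\n")

    lines = ["Parameter,Cutoff,Sensitivity,Specificity,PPV,NPV,Accuracy,AUC,P,Point"]
    for r in bundle.table2:
        m = r.metrics
        lines.append(
            f"{r.parameter},{r.cutoff},{_fmt(m.sensitivity)},{_fmt(m.specificity)},"
            f"{_fmt(m.ppv)},{_fmt(m.npv)},{_fmt(m.accuracy)},{_fmt(r.auc)},"
            f"{_fmt(r.p_value)},{_fmt(r.point)}"
        )
    (out / "table2.csv").write_text("\n".join(lines) + "\n")

    lines = ["PIV,Sensitivity,Specificity,PPV,NPV,Accuracy,N_flagged"]
    for r in bundle.table3:
        m = r.metrics
        lines.append(
            f">={r.threshold},{_fmt(m.sensitivity)},{_fmt(m.specificity)},"
            f"{_fmt(m.ppv)},{_fmt(m.npv)},{_fmt(m.accuracy)},{r.n_flagged}"
        )
    (out / "table3.csv").write_text("\n".join(lines) + "\n")

    piv_json = {
        "weights": {k: int(v) for k, v in sorted(bundle.piv_model.weights.items())},
        "max_score": bundle.piv_model.max_score,
        "cutoffs": bundle.cutoff_spec.describe(),
        "rule": dataclasses.asdict(bundle.piv_model.rule),
        "score_histogram": {
            str(idx): {
                "optimal": int(row["optimal"]),
                "suboptimal": int(row["suboptimal"]),
            }
            for idx, row in bundle.score_histogram.iterrows()
        },
    }
    (out / "piv_model.json").write_text(json.dumps(piv_json, indent=2, sort_keys=True))

    fit = bundle.logistic_fit
    logistic_json = {
        "terms": list(fit.terms),
        "coef": [round(float(c), 6) for c in fit.coef],
        "bse": [round(float(b), 6) for b in fit.bse],
        "odds_ratios": [round(float(o), 6) for o in fit.odds_ratios],
        "or_ci": [[round(float(a), 6), round(float(b), 6)] for a, b in fit.or_ci],
        "p_values": [round(float(p), 6) for p in fit.p_values],
        "n_train": bundle.train_n,
        "hosmer_lemeshow": {
            "statistic": round(bundle.hl.statistic, 6),
            "df": bundle.hl.df,
            "p": round(bundle.hl.p_value, 6),
        },
        "validation": {
            "refit": dataclasses.asdict(bundle.validation_refit),
            "published": dataclasses.asdict(bundle.validation_published),
        },
    }
    (out / "logistic.json").write_text(
        json.dumps(logistic_json, indent=2, sort_keys=True, default=float)
    )

    (out / "power.json").write_text(
        json.dumps(
            {
                "auc_alt": round(bundle.validation_refit.auc, 6),
                "power": None if np.isnan(bundle.power) else round(bundle.power, 6),
            },
            indent=2,
        )
    )
    (out / "run_metadata.json").write_text(
        json.dumps(bundle.metadata, indent=2, sort_keys=True)
    )
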