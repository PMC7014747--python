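import numpy as np
import pytest

from cytoredux import (
    Cohort,
    DiagnosticMetrics,
    ParameterDiagnostics,
    PatientRecord,
    generate_cohort,
    reference_config,
)
from cytoredux.piv import PARAMETERS

BENIGN = dict(
    age=50.0,
    figo_stage="III",
    grade=1,
    histology="serous",
    ca125=100.0,
    he4=100.0,
    ecog=0,
    asa="2",
    outcome="optimal",
)


def make_record(patient_id="P0", **overrides):
    fields = {**BENIGN, **overrides}
    return PatientRecord(patient_id=patient_id, **fields)


def make_cohort(spec_list, provenance="handmade"):
    """Build a cohort from a list of field-override dicts."""
    return Cohort(
        tuple(make_record(f"P{i}", **kw) for i, kw in enumerate(spec_list)),
        provenance,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic 300-patient cohort from the reference configuration."""
    return generate_cohort(reference_config(n=300), seed=20240201)


@pytest.fixture(scope="session")
def balanced_cohort_83():
    """83 records with exactly 52 optimal / 31 suboptimal, covariates drawn
    from the reference outcome-conditional distributions."""
    big = generate_cohort(reference_config(n=400), seed=7)
    opt = [r for r in big if r.outcome == "optimal"][:52]
    sub = [r for r in big if r.outcome == "suboptimal"][:31]
    return Cohort(tuple(opt + sub), "synthetic 52/31")


# Printed per-parameter diagnostic table (sens, spec, ppv, npv, acc, auc),
# in canonical parameter order, used to exercise the weighting rules.
PRINTED_TABLE2 = {
    "age": (0.16, 0.98, 0.83, 0.66, 0.67, 0.57),
    "figo_stage": (0.10, 0.89, 0.33, 0.62, 0.59, 0.49),
    "histology": (0.26, 0.87, 0.53, 0.66, 0.64, 0.56),
    "grade": (0.68, 0.35, 0.38, 0.64, 0.47, 0.51),
    "ca125": (0.81, 0.42, 0.45, 0.79, 0.57, 0.53),
    "he4": (0.48, 0.89, 0.71, 0.74, 0.73, 0.68),
    "ecog": (0.23, 0.87, 0.50, 0.65, 0.63, 0.55),
    "asa": (0.07, 0.94, 0.40, 0.63, 0.61, 0.50),
}


@pytest.fixture(scope="session")
def printed_table2_rows():
    rows = []
    for name in PARAMETERS:
        sens, spec, ppv, npv, acc, auc = PRINTED_TABLE2[name]
        rows.append(
            ParameterDiagnostics(
                parameter=name,
                cutoff="",
                metrics=DiagnosticMetrics(sens, spec, ppv, npv, acc),
                auc=auc,
                p_value=np.nan,
            )
        )
    return rows
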