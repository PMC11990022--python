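"""Diabetes screening, simplified cluster assignment and inflammation strata.

Screening follows fasting-sample criteria: diabetes if HbA1c exceeds 6.5 %
(strict) or fasting glucose is >= 7.0 mmol/L (126 mg/dL, closed bound).
Subjects on antidiabetic medication can be counted as diabetic even with
treated-to-target laboratory values (default on).

Diabetic subjects are sub-classified into the adult diabetes endotypes of
the ANDIS framework with a simplified, rule-based decision list driven by
beta-cell antibody status, age at diagnosis, BMI and insulin resistance:

    antibody positive            -> SAID  (severe autoimmune)
    age at diagnosis >= 65 y     -> MARD  (mild age-related)
    BMI >= 30 kg/m^2             -> MOD   (mild obesity-related)
    HOMA-IR >= 5.0               -> SIRD  (severe insulin-resistant)
    otherwise                    -> SIDD  (severe insulin-deficient)

The thresholds live in an editable rule table; the precedence order is
fixed (first matching rule wins).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .biomarkers import BiomarkerPanel
from .cohort import SubjectRecord

HAPTOGLOBIN_CUTOFF_MGDL = 209.8
CRP_CUTOFF_MGDL = 5.0

HBA1C_DIABETES_PCT = 6.5     # strict: "exceeded"
GLUCOSE_DIABETES_MMOLL = 7.0  # closed: ">="


class Cluster(str, Enum):
    MOD = "MOD"
    SIRD = "SIRD"
    SIDD = "SIDD"
    MARD = "MARD"
    SAID = "SAID"
    NONE = "none"


class Stratum(str, Enum):
    LOW = "low"
    HIGH = "high"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ClusterRules:
    """Editable thresholds of the simplified cluster decision list."""

    age_mard_years: float = 65.0
    bmi_mod_kg_m2: float = 30.0
    homa_ir_sird: float = 5.0


DEFAULT_CLUSTER_RULES = ClusterRules()


@dataclass(frozen=True)
class EndotypeLabel:
    """Per-subject endotype: diabetes status, cluster, inflammation strata,
    treatment status.  ``diabetes`` is None when neither HbA1c nor glucose
    is available and no medication forces the call."""

    diabetes: bool | None
    cluster: Cluster
    haptoglobin_stratum: Stratum
    crp_stratum: Stratum
    treated: bool


def screen_diabetes(record: SubjectRecord, medication_implies_diabetes: bool = True) -> bool | None:
    """Fasting-sample diabetes screen.

    True iff HbA1c > 6.5 % or fasting glucose >= 7.0 mmol/L; subjects on
    antidiabetic medication are counted as diabetic when
    ``medication_implies_diabetes`` (treated-to-target values otherwise
    escape the laboratory criteria).  Returns None (unknown) when both
    laboratory inputs are absent and medication does not decide.
    """
    if medication_implies_diabetes and record.antidiabetic_medications:
        return True
    hba1c = record.sample.hba1c
    glucose = record.sample.glucose
    if hba1c is None and glucose is None:
        return None
    if hba1c is not None and hba1c > HBA1C_DIABETES_PCT:
        return True
    if glucose is not None and glucose >= GLUCOSE_DIABETES_MMOLL:
        return True
    return False


def assign_cluster(
    record: SubjectRecord,
    panel: BiomarkerPanel | None = None,
    rules: ClusterRules = DEFAULT_CLUSTER_RULES,
    diabetes: bool | None = None,
    medication_implies_diabetes: bool = True,
) -> Cluster:
    """Simplified endotype cluster for one subject (``none`` if not diabetic).

    The decision list is evaluated in fixed order; see the module docstring.
    Age at diagnosis falls back to current age when undocumented.
    """
    if diabetes is None:
        diabetes = screen_diabetes(record, medication_implies_diabetes)
    if not diabetes:
        return Cluster.NONE
    if record.beta_cell_antibody_positive:
        return Cluster.SAID
    age_dx = record.age_at_diabetes_diagnosis
    if age_dx is None:
        age_dx = record.age
    if age_dx >= rules.age_mard_years:
        return Cluster.MARD
    if record.bmi >= rules.bmi_mod_kg_m2:
        return Cluster.MOD
    ir = panel.homa_ir if panel is not None else None
    if ir is not None and ir >= rules.homa_ir_sird:
        return Cluster.SIRD
    return Cluster.SIDD


def stratify_inflammation(record: SubjectRecord) -> tuple[Stratum, Stratum]:
    """Haptoglobin and CRP strata.

    Haptoglobin <= 209.8 mg/dL is low (the boundary belongs to the low
    stratum), > 209.8 high; CRP <= 5 mg/dL low, > 5 high; missing values
    map to ``unknown``.
    """
    if record.haptoglobin is None:
        hp = Stratum.UNKNOWN
    else:
        hp = Stratum.HIGH if record.haptoglobin > HAPTOGLOBIN_CUTOFF_MGDL else Stratum.LOW
    if record.crp is None:
        crp = Stratum.UNKNOWN
    else:
        crp = Stratum.HIGH if record.crp > CRP_CUTOFF_MGDL else Stratum.LOW
    return hp, crp


def treatment_status(record: SubjectRecord) -> bool:
    """True iff the subject takes any antidiabetic medication."""
    return len(record.antidiabetic_medications) > 0


def classify(
    record: SubjectRecord,
    panel: BiomarkerPanel | None = None,
    rules: ClusterRules = DEFAULT_CLUSTER_RULES,
    medication_implies_diabetes: bool = True,
) -> EndotypeLabel:
    """Full endotype label for one subject."""
    diabetes = screen_diabetes(record, medication_implies_diabetes)
    cluster = assign_cluster(record, panel, rules, diabetes, medication_implies_diabetes)
    hp, crp = stratify_inflammation(record)
    return EndotypeLabel(
        diabetes=diabetes,
        cluster=cluster,
        haptoglobin_stratum=hp,
        crp_stratum=crp,
        treated=treatment_status(record),
    )


def label_frame(cohort, panels_df=None, rules: ClusterRules = DEFAULT_CLUSTER_RULES,
                medication_implies_diabetes: bool = True):
    """Endotype labels for a whole cohort as DataFrame columns.

    ``panels_df`` is the output of :func:`glycendo.biomarkers.panel_frame`;
    when given, labels are appended to it, otherwise to the bare cohort frame.
    """
    from .biomarkers import compute_panel

    df = panels_df if panels_df is not None else cohort.to_dataframe()
    df = df.copy()
    labels = [
        classify(s, compute_panel(s.sample), rules, medication_implies_diabetes)
        for s in cohort
    ]
    df["diabetes"] = [lab.diabetes for lab in labels]
    df["cluster"] = [lab.cluster.value for lab in labels]
    df["hp_stratum"] = [lab.haptoglobin_stratum.value for lab in labels]
    df["crp_stratum"] = [lab.crp_stratum.value for lab in labels]
    df["treated"] = [lab.treated for lab in labels]
    return df
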