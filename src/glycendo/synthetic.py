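"""Seeded synthetic case-control cohorts of fasting metabolic data.

The generator emulates the joint structure of a hidradenitis suppurativa
(HS) cohort versus matched controls as summarised in published descriptive
tables: right-skewed fasting insulin (log-normal), near-normal fasting
glucose with a diabetic mixture tail, HbA1c as an affine function of
glucose plus noise, gamma-distributed haptoglobin spanning the
209.8 mg/dL inflammation cut-off, and diabetes prevalence of ~18 % in HS
versus ~4 % in controls with medication assignment conditional on
diabetes.  Default parameters are calibrated so that group medians and
interquartile ranges approximate the published values for glucose,
insulin, BMI and haptoglobin.

Disease-severity fields (Hurley stage, SAHS, lesion counts) are sampled
for the HS group only; controls receive zeros (Hurley absent), matching
how such tables report controls.

A single RNG stream (numpy default_rng) drives each cohort; the seed is
recorded in the cohort's provenance, and identical configurations with the
same seed regenerate the cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.stats import gamma as gamma_dist, norm

from .cohort import Cohort, FastingSample, SubjectRecord


@dataclass(frozen=True)
class GroupParams:
    """Distribution parameters for one study arm."""

    sex_female_prob: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    bmi_shift_dm: float          # BMI offset for diabetic subjects (kg/m^2)
    glucose_mean: float          # non-diabetic fasting glucose (mmol/L)
    glucose_sd: float
    glucose_mean_dm: float       # diabetic fasting glucose (mmol/L)
    glucose_sd_dm: float
    insulin_log_median: float    # log of the non-diabetic insulin median (pmol/L)
    insulin_log_sd: float
    insulin_log_shift_dm: float  # log-scale insulin offset for diabetics
    hba1c_present: bool          # whether HbA1c was measured in this arm
    hba1c_slope: float = 1.12    # HbA1c ≈ slope·glucose + intercept + noise
    hba1c_intercept: float = -0.23
    hba1c_sd: float = 0.25
    hapto_shape: float = 11.0    # gamma shape of haptoglobin (mg/dL)
    hapto_scale: float = 18.5
    hapto_shift_treated: float = 55.0  # haptoglobin offset under antidiabetic treatment
    crp_shape: float = 1.3       # gamma shape of CRP (mg/dL)
    crp_scale: float = 6.0
    crp_floor: float = 5.0       # assay reporting floor
    diabetes_prev: float = 0.18
    treated_given_dm: float = 0.70
    med_probs: dict = field(default_factory=dict)  # per-drug probability given treated
    antibody_prob: float = 0.01  # beta-cell antibody positivity given diabetes
    severity: bool = True        # sample HS severity fields

    def __post_init__(self) -> None:
        for name in ("age_sd", "bmi_sd", "glucose_sd", "glucose_sd_dm",
                     "insulin_log_sd", "hba1c_sd", "hapto_shape", "hapto_scale",
                     "crp_shape", "crp_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sex_female_prob", "diabetes_prev", "treated_given_dm", "antibody_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for drug, p in self.med_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"med_probs[{drug!r}] must be in [0, 1]")


HS_DEFAULTS = GroupParams(
    sex_female_prob=0.39,
    age_mean=42.5, age_sd=12.0,
    bmi_mean=31.5, bmi_sd=6.7, bmi_shift_dm=2.0,
    glucose_mean=5.05, glucose_sd=0.60,
    glucose_mean_dm=6.4, glucose_sd_dm=1.1,
    insulin_log_median=math.log(90.0), insulin_log_sd=0.92, insulin_log_shift_dm=0.51,
    hba1c_present=True,
    hapto_shape=11.0, hapto_scale=18.5, hapto_shift_treated=55.0,
    crp_shape=1.3, crp_scale=6.0,
    diabetes_prev=0.18, treated_given_dm=0.70,
    med_probs={"metformin": 0.80, "sitagliptin": 0.25, "vildagliptin": 0.05,
               "saxagliptin": 0.05, "glimepiride": 0.05, "empagliflozin": 0.05},
    antibody_prob=0.01,
    severity=True,
)

CONTROL_DEFAULTS = GroupParams(
    sex_female_prob=0.43,
    age_mean=40.0, age_sd=9.0,
    bmi_mean=27.0, bmi_sd=6.0, bmi_shift_dm=2.0,
    glucose_mean=4.95, glucose_sd=0.55,
    glucose_mean_dm=6.4, glucose_sd_dm=1.1,
    insulin_log_median=math.log(70.0), insulin_log_sd=0.72, insulin_log_shift_dm=0.55,
    hba1c_present=False,
    hapto_shape=11.0, hapto_scale=14.0, hapto_shift_treated=55.0,
    crp_shape=1.0, crp_scale=2.5,
    diabetes_prev=0.04, treated_given_dm=1.0,
    med_probs={"metformin": 1.0, "sitagliptin": 0.5},
    antibody_prob=0.01,
    severity=False,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort sizes, seed and per-arm distribution parameters."""

    n_hs: int = 95
    n_control: int = 49
    seed: int = 0
    hs: GroupParams = HS_DEFAULTS
    control: GroupParams = CONTROL_DEFAULTS
    #: Spearman rank correlation between fasting insulin and haptoglobin
    #: (unreported in the source tables; a weak positive default).
    insulin_haptoglobin_rho: float = 0.2

    def __post_init__(self) -> None:
        if self.n_hs < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not -1 < self.insulin_haptoglobin_rho < 1:
            raise ValueError("insulin_haptoglobin_rho must be in (-1, 1)")


def _sample_group(rng: np.random.Generator, n: int, group: str,
                  p: GroupParams, rho_spearman: float,
                  id_prefix: str) -> list[SubjectRecord]:
    if n == 0:
        return []
    sex = np.where(rng.random(n) < p.sex_female_prob, "female", "male")
    age = np.clip(rng.normal(p.age_mean, p.age_sd, n), 18.0, 85.0)
    diabetic = rng.random(n) < p.diabetes_prev
    bmi = np.clip(rng.normal(p.bmi_mean, p.bmi_sd, n) + p.bmi_shift_dm * diabetic, 16.0, 65.0)

    glucose = np.where(
        diabetic,
        np.clip(rng.normal(p.glucose_mean_dm, p.glucose_sd_dm, n), 4.8, 14.0),
        np.clip(rng.normal(p.glucose_mean, p.glucose_sd, n), 3.6, 6.9),
    )

    # Insulin and haptoglobin through a Gaussian copula so that a weak rank
    # correlation between hyperinsulinaemia and inflammation is preserved.
    rho_n = 2.0 * math.sin(math.pi * rho_spearman / 6.0)  # Spearman -> Pearson on normals
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho_n], [rho_n, 1.0]], size=n)
    log_ins = p.insulin_log_median + p.insulin_log_shift_dm * diabetic + p.insulin_log_sd * z[:, 0]
    insulin = np.clip(np.exp(log_ins), 1.0, 2900.0)
    hapto = gamma_dist.ppf(norm.cdf(z[:, 1]), p.hapto_shape, scale=p.hapto_scale)

    crp = np.maximum(rng.gamma(p.crp_shape, p.crp_scale, n), p.crp_floor)

    treated = diabetic & (rng.random(n) < p.treated_given_dm)
    hapto = hapto + p.hapto_shift_treated * treated

    if p.hba1c_present:
        hba1c = p.hba1c_slope * glucose + p.hba1c_intercept + rng.normal(0.0, p.hba1c_sd, n)
        hba1c = np.where(diabetic, np.clip(hba1c, 3.5, 15.0), np.clip(hba1c, 3.5, 6.5))
        # Untreated diabetics must be detectable from the fasting sample:
        # lift HbA1c over the screening bound where neither criterion fires.
        silent = diabetic & ~treated & (hba1c <= 6.5) & (glucose < 7.0)
        hba1c = np.where(silent, 6.6 + rng.exponential(0.3, n), hba1c)
    else:
        hba1c = np.full(n, np.nan)

    antibody = diabetic & (rng.random(n) < p.antibody_prob)
    age_dm_dx = np.clip(age - rng.uniform(0.0, 12.0, n), 20.0, None)

    drugs = sorted(p.med_probs)
    med_draws = {drug: rng.random(n) < p.med_probs[drug] for drug in drugs}

    if p.severity:
        hurley = rng.choice([1, 2, 3], size=n, p=[0.20, 0.45, 0.35])
        sahs = np.clip(np.rint(rng.normal(7.0, 2.8, n)), 0, 20).astype(int)
        exac = np.where(rng.random(n) < 0.60, 0, 1 + rng.poisson(1.5, n))
        regions = 1 + rng.poisson(2.6, n)
        fistulae = rng.negative_binomial(2.5, 2.5 / (2.5 + 5.3), n)
        nodules = rng.negative_binomial(2.2, 2.2 / (2.2 + 2.9), n)
        abscesses = np.where(rng.random(n) < 0.20, 1 + rng.poisson(1.0, n), 0)
    else:
        hurley = None
        sahs = exac = regions = fistulae = nodules = abscesses = np.zeros(n, dtype=int)

    records = []
    for i in range(n):
        meds = set()
        if treated[i]:
            meds = {drug for drug in drugs if med_draws[drug][i]}
            if not meds:
                meds = {"metformin"}
        records.append(SubjectRecord(
            subject_id=f"{id_prefix}{i + 1:05d}",
            group=group,
            sex=str(sex[i]),
            age=round(float(age[i]), 1),
            bmi=round(float(bmi[i]), 1),
            sample=FastingSample(
                glucose=round(float(glucose[i]), 3),
                insulin=round(float(insulin[i]), 2),
                hba1c=None if np.isnan(hba1c[i]) else round(float(hba1c[i]), 2),
            ),
            haptoglobin=round(float(hapto[i]), 1),
            crp=round(float(crp[i]), 2),
            beta_cell_antibody_positive=bool(antibody[i]) if diabetic[i] else None,
            age_at_diabetes_diagnosis=round(float(age_dm_dx[i]), 1) if diabetic[i] else None,
            antidiabetic_medications=frozenset(meds),
            hurley=None if hurley is None else int(hurley[i]),
            sahs=int(sahs[i]),
            exacerbations=int(exac[i]),
            affected_regions=int(regions[i]),
            fistulae=int(fistulae[i]),
            nodules=int(nodules[i]),
            abscesses=int(abscesses[i]),
        ))
    return records


def generate(config: SyntheticConfig = SyntheticConfig()) -> Cohort:
    """Generate a synthetic two-arm cohort.

    The same configuration (including seed) always regenerates the cohort
    exactly; the seed is recorded in the provenance note.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _sample_group(rng, config.n_hs, "HS", config.hs,
                             config.insulin_haptoglobin_rho, "HS")
    subjects += _sample_group(rng, config.n_control, "control", config.control,
                              config.insulin_haptoglobin_rho, "C")
    return Cohort(subjects, provenance=f"synthetic:seed={config.seed}")


def null_twin(config: SyntheticConfig = SyntheticConfig()) -> Cohort:
    """Null cohort: both arms drawn from the control distribution.

    Group labels and arm sizes are retained, so the comparison pipeline can
    be exercised under the null hypothesis of no group difference (type-I
    error studies).
    """
    null_cfg = replace(config, hs=replace(config.control, severity=config.control.severity))
    return replace_provenance(generate(null_cfg), f"synthetic-null:seed={config.seed}")


def replace_provenance(cohort: Cohort, note: str) -> Cohort:
    cohort.provenance = note
    return cohort


def save_config(config: SyntheticConfig, path) -> None:
    """Write a configuration as a flat ``section.key = value`` text file."""
    lines = []
    flat = asdict(config)
    for key in ("n_hs", "n_control", "seed", "insulin_haptoglobin_rho"):
        lines.append(f"{key} = {flat[key]}")
    for arm in ("hs", "control"):
        for key, val in flat[arm].items():
            if key == "med_probs":
                for drug, pr in sorted(val.items()):
                    lines.append(f"{arm}.med_probs.{drug} = {pr}")
            else:
                lines.append(f"{arm}.{key} = {val}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> SyntheticConfig:
    """Read a configuration written by :func:`save_config`."""
    top: dict = {}
    arms: dict[str, dict] = {"hs": {}, "control": {}}
    meds: dict[str, dict] = {"hs": {}, "control": {}}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            parts = key.split(".")
            value: object
            if raw in ("True", "False"):
                value = raw == "True"
            else:
                try:
                    value = int(raw)
                except ValueError:
                    value = float(raw)
            if len(parts) == 1:
                top[key] = value
            elif len(parts) == 2:
                arms[parts[0]][parts[1]] = value
            elif len(parts) == 3 and parts[1] == "med_probs":
                meds[parts[0]][parts[2]] = float(raw)
            else:
                raise ValueError(f"unrecognised config key {key!r}")
    for arm in ("hs", "control"):
        if meds[arm]:
            arms[arm]["med_probs"] = meds[arm]
    return SyntheticConfig(
        hs=GroupParams(**arms["hs"]),
        control=GroupParams(**arms["control"]),
        **top,
    )
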