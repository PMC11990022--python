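"""Calculated biomarkers of insulin-glucose homeostasis.

Seven fasting-based indices are computed from a :class:`~glycendo.cohort.FastingSample`:

* **HOMA-Beta, HOMA-IR, HOMA-IS** — the classic homeostasis-model-assessment
  indices.  With G in mmol/L and I in µIU/mL:
  HOMA-IR = G·I/22.5, HOMA-IS = 1/HOMA-IR, HOMA-Beta = 20·I/(G − 3.5).
* **QUICKI** — 1/(log10 G[mg/dL] + log10 I[µIU/mL]), a monotone decreasing
  transform of HOMA-IR (equivalently 1/log10(405·HOMA-IR)).
* **SPINA-GBeta, SPINA-GR, SPINA-DI** — structural parameters of the SPINA
  Carb feedback model of insulin-glucose homeostasis.  GBeta estimates the
  maximum secretory capacity of pancreatic beta cells (pmol/s); GR the
  insulin receptor gain, a measure of insulin sensitivity (mol/s); and the
  static disposition index DI = GBeta·GR the loop gain of the closed-loop
  system (dimensionless by convention, GBeta taken in pmol/s and GR in
  mol/s).

The SPINA parameters are the closed-form equilibrium solutions of the
structural model: at steady state insulin obeys

    alpha_i · GBeta · G/(d_beta + G) = beta_i · I

and glucose obeys

    alpha_g · P0 = beta_g · G · (1 + GE · GR · I/(d_r + I)),

giving

    GBeta = beta_i · I · (d_beta + G) / (alpha_i · G)
    GR    = (alpha_g · P0 − beta_g · G) · (d_r + I) / (beta_g · G · GE · I)

with G, I the fasting (equilibrium) concentrations in mol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .cohort import FastingSample
from .units import INSULIN_PMOLL_PER_UIUML, glucose_mmol_to_mgdl, insulin_pmol_to_uiu


class Flag(str, Enum):
    """Position of an index value relative to its reference range."""

    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class SpinaConstants:
    """Physiological constants of the SPINA Carb structural model.

    Defaults describe a standard adult at rest; all SI units.
    """

    p0: float = 150e-6      # mol/s — hepatic glucose production
    alpha_g: float = 0.11   # 1/L — reciprocal glucose distribution volume
    beta_g: float = 7.1e-4  # 1/s — glucose clearance exponent
    alpha_i: float = 0.2    # 1/L — reciprocal insulin distribution volume
    beta_i: float = 3.4e-3  # 1/s — insulin clearance exponent
    d_beta: float = 7e-3    # mol/L — half-saturation of glucose-stimulated secretion
    d_r: float = 1.6e-9     # mol/L — half-saturation of insulin at its receptor
    g_e: float = 50.0       # s/mol — insulin effector gain


DEFAULT_SPINA_CONSTANTS = SpinaConstants()


@dataclass(frozen=True)
class ReferenceRange:
    """Reference interval for one index, with the boundary semantics as
    printed: one-sided bounds ("<2.5", ">0.4") are strict; two-sided ranges
    are closed intervals."""

    index: str
    lower: float | None = None
    upper: float | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"reference range for {self.index}: lower must be < upper")

    def flag(self, value: float | None) -> Flag:
        if value is None or not math.isfinite(value):
            return Flag.NOT_EVALUABLE
        if self.lower is not None:
            if value < self.lower or (not self.lower_inclusive and value == self.lower):
                return Flag.BELOW
        if self.upper is not None:
            if value > self.upper or (not self.upper_inclusive and value == self.upper):
                return Flag.ABOVE
        return Flag.WITHIN


#: Reference ranges for a healthy, normal-BMI population.
DEFAULT_REFERENCE_RANGES: dict[str, ReferenceRange] = {
    "spina_gbeta": ReferenceRange("spina_gbeta", 0.64, 3.73, source="SPINA Carb validation cohorts"),
    "spina_gr": ReferenceRange("spina_gr", 1.41, 9.00, source="SPINA Carb validation cohorts"),
    "spina_di": ReferenceRange("spina_di", 4.01, 7.65, source="SPINA Carb validation cohorts"),
    "homa_ir": ReferenceRange("homa_ir", upper=2.5, upper_inclusive=False, source="HOMA literature"),
    "homa_is": ReferenceRange("homa_is", lower=0.4, lower_inclusive=False, source="HOMA literature"),
    "quicki": ReferenceRange("quicki", lower=0.4, lower_inclusive=False, source="QUICKI literature"),
}

INDEX_NAMES = ("homa_beta", "homa_ir", "homa_is", "quicki",
               "spina_gbeta", "spina_gr", "spina_di")


@dataclass(frozen=True)
class BiomarkerPanel:
    """The seven calculated indices for one subject, plus reference flags.

    An index that is undefined for the sample (degenerate denominator,
    zero insulin, ...) is None with flag ``not_evaluable``.
    """

    homa_beta: float | None
    homa_ir: float | None
    homa_is: float | None
    quicki: float | None
    spina_gbeta: float | None
    spina_gr: float | None
    spina_di: float | None
    flags: dict[str, Flag]

    def value(self, index: str) -> float | None:
        return getattr(self, index)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def homa_ir(sample: FastingSample, insulin_factor: float = INSULIN_PMOLL_PER_UIUML) -> float | None:
    """HOMA insulin-resistance index: G[mmol/L] · I[µIU/mL] / 22.5."""
    if sample.insulin <= 0 or sample.glucose <= 0:
        return None
    return sample.glucose * insulin_pmol_to_uiu(sample.insulin, insulin_factor) / 22.5


def homa_is(sample: FastingSample, insulin_factor: float = INSULIN_PMOLL_PER_UIUML) -> float | None:
    """HOMA insulin-sensitivity index, the reciprocal of HOMA-IR."""
    ir = homa_ir(sample, insulin_factor)
    return None if ir is None or ir <= 0 else 1.0 / ir


def homa_beta(sample: FastingSample, insulin_factor: float = INSULIN_PMOLL_PER_UIUML) -> float | None:
    """HOMA beta-cell function index: 20 · I[µIU/mL] / (G[mmol/L] − 3.5).

    Undefined for glucose <= 3.5 mmol/L.
    """
    if sample.glucose <= 3.5 or sample.insulin <= 0:
        return None
    return 20.0 * insulin_pmol_to_uiu(sample.insulin, insulin_factor) / (sample.glucose - 3.5)


def quicki(sample: FastingSample, insulin_factor: float = INSULIN_PMOLL_PER_UIUML) -> float | None:
    """QUICKI: 1 / (log10 G[mg/dL] + log10 I[µIU/mL]).

    Undefined when the conventional-unit product is <= 1 (log sum <= 0).
    """
    if sample.insulin <= 0 or sample.glucose <= 0:
        return None
    product = glucose_mmol_to_mgdl(sample.glucose) * insulin_pmol_to_uiu(sample.insulin, insulin_factor)
    if product <= 1.0:
        return None
    return 1.0 / math.log10(product)


def quicki_from_homa_ir(ir: float) -> float | None:
    """QUICKI via the algebraic identity 1/log10(405·HOMA-IR).

    405 = 18 (mg/dL per mmol/L) × 22.5; the identity is exact whatever the
    insulin unit conversion, because both indices use the same µIU/mL value.
    """
    if ir is None or 405.0 * ir <= 1.0:
        return None
    return 1.0 / math.log10(405.0 * ir)


def spina_parameters(
    sample: FastingSample,
    constants: SpinaConstants = DEFAULT_SPINA_CONSTANTS,
) -> tuple[float | None, float | None, float | None]:
    """SPINA-GBeta (pmol/s), SPINA-GR (mol/s) and SPINA-DI from one sample.

    Returns ``None`` entries when a denominator degenerates: GR (and hence
    DI) is undefined for insulin = 0, and for fasting glucose high enough
    that insulin-independent clearance alone exceeds glucose production
    (alpha_g·P0 <= beta_g·G, outside the model's domain).
    """
    c = constants
    g = sample.glucose * 1e-3   # mmol/L -> mol/L
    i = sample.insulin * 1e-12  # pmol/L -> mol/L
    if g <= 0:
        return None, None, None

    gbeta = c.beta_i * i * (c.d_beta + g) / (c.alpha_i * g) * 1e12  # pmol/s

    if i <= 0:
        return gbeta, None, None
    supply = c.alpha_g * c.p0 - c.beta_g * g
    if supply <= 0:
        return gbeta, None, None
    gr = supply * (c.d_r + i) / (c.beta_g * g * c.g_e * i)  # mol/s
    di = gbeta * gr
    return gbeta, gr, di


def compute_panel(
    sample: FastingSample,
    constants: SpinaConstants = DEFAULT_SPINA_CONSTANTS,
    ranges: dict[str, ReferenceRange] = DEFAULT_REFERENCE_RANGES,
    insulin_factor: float = INSULIN_PMOLL_PER_UIUML,
) -> BiomarkerPanel:
    """Compute all seven indices and flag them against the reference ranges."""
    gbeta, gr, di = spina_parameters(sample, constants)
    values = {
        "homa_beta": homa_beta(sample, insulin_factor),
        "homa_ir": homa_ir(sample, insulin_factor),
        "homa_is": homa_is(sample, insulin_factor),
        "quicki": quicki(sample, insulin_factor),
        "spina_gbeta": gbeta,
        "spina_gr": gr,
        "spina_di": di,
    }
    panel = BiomarkerPanel(flags={}, **values)
    return flag_against_reference(panel, ranges)


def flag_against_reference(
    panel: BiomarkerPanel,
    ranges: dict[str, ReferenceRange] = DEFAULT_REFERENCE_RANGES,
) -> BiomarkerPanel:
    """Label every index below/within/above its reference range.

    Indices without a published range (HOMA-Beta) and undefined values are
    flagged ``not_evaluable``.
    """
    flags: dict[str, Flag] = {}
    for name in INDEX_NAMES:
        rng = ranges.get(name)
        value = getattr(panel, name)
        flags[name] = rng.flag(value) if rng is not None else Flag.NOT_EVALUABLE
    return BiomarkerPanel(flags=flags, **panel.as_dict())


def panel_frame(cohort, constants: SpinaConstants = DEFAULT_SPINA_CONSTANTS,
                ranges: dict[str, ReferenceRange] = DEFAULT_REFERENCE_RANGES,
                insulin_factor: float = INSULIN_PMOLL_PER_UIUML):
    """Augment a cohort DataFrame with the seven indices and their flags."""
    import pandas as pd

    df = cohort.to_dataframe()
    panels = [compute_panel(s.sample, constants, ranges, insulin_factor) for s in cohort]
    for name in INDEX_NAMES:
        df[name] = [p.value(name) for p in panels]
        df[f"{name}_flag"] = [p.flags[name].value for p in panels]
    return df
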