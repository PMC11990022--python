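"""Unit conversions for fasting glucose and insulin.

Internal storage throughout the package is SI-style: glucose in mmol/L and
insulin in pmol/L.  Conventional units (mg/dL, µIU/mL) are converted at
ingest and, where an index formula is defined on conventional units (HOMA,
QUICKI), on the fly inside the formula.
"""

from __future__ import annotations

#: mg/dL per mmol/L of glucose (molar mass convention; 126 mg/dL ≡ 7.0 mmol/L).
GLUCOSE_MGDL_PER_MMOLL = 18.0

#: pmol/L per µIU/mL of insulin.  The conventional conversion factor; some
#: laboratories use 6.00.  Exposed as a parameter wherever it enters a formula.
INSULIN_PMOLL_PER_UIUML = 6.945

GLUCOSE_UNITS = ("mmol_L", "mg_dL")
INSULIN_UNITS = ("pmol_L", "uIU_mL")


def convert_glucose(value: float, from_unit: str = "mmol_L") -> float:
    """Convert a glucose concentration to mmol/L.

    Parameters
    ----------
    value:
        Non-negative concentration in ``from_unit``.
    from_unit:
        ``"mg_dL"`` or ``"mmol_L"``.
    """
    if value < 0:
        raise ValueError(f"glucose concentration must be >= 0, got {value}")
    if from_unit == "mmol_L":
        return float(value)
    if from_unit == "mg_dL":
        return float(value) / GLUCOSE_MGDL_PER_MMOLL
    raise ValueError(f"unknown glucose unit {from_unit!r}; expected one of {GLUCOSE_UNITS}")


def glucose_mmol_to_mgdl(value: float) -> float:
    """Inverse conversion, mmol/L -> mg/dL (used by QUICKI)."""
    return float(value) * GLUCOSE_MGDL_PER_MMOLL


def convert_insulin(
    value: float,
    from_unit: str = "pmol_L",
    factor: float = INSULIN_PMOLL_PER_UIUML,
) -> float:
    """Convert an insulin concentration to pmol/L.

    ``factor`` is the pmol/L per µIU/mL conversion constant.
    """
    if value < 0:
        raise ValueError(f"insulin concentration must be >= 0, got {value}")
    if from_unit == "pmol_L":
        return float(value)
    if from_unit == "uIU_mL":
        return float(value) * factor
    raise ValueError(f"unknown insulin unit {from_unit!r}; expected one of {INSULIN_UNITS}")


def insulin_pmol_to_uiu(value: float, factor: float = INSULIN_PMOLL_PER_UIUML) -> float:
    """Inverse conversion, pmol/L -> µIU/mL (used by HOMA and QUICKI)."""
    return float(value) / factor
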