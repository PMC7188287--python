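"""Creatinine-based GFR estimating equations.

Four equations commonly used to estimate glomerular filtration rate from
plasma creatinine (PCr), age and sex, all returning eGFR in
mL/min/1.73 m**2 with PCr in mg/dL:

* **CKD-EPI** (2009) -- sex-specific two-piece power law with knots at
  PCr 0.7 (female) / 0.9 (male) mg/dL and an age factor ``0.993**age``.
* **MDRD** (IDMS-traceable, coefficient 175) -- single power law in PCr
  and age with a 0.742 female multiplier.
* **LMR** (Lund-Malmo Revised) -- ``exp(X - 0.0158*age + 0.438*ln(age))``
  where ``X`` is a sex-specific piecewise function of PCr with knots at
  1.7 (female) / 2.0 (male) mg/dL.  The sub-knot linear term of the
  source publication is expressed per µmol/L of creatinine; here it is
  rescaled to per-mg/dL (x 88.4) so that a single creatinine unit is
  used throughout.
* **FAS** (Full Age Spectrum) -- ``107.3 * Q/PCr`` with the sex-specific
  healthy-median creatinine Q (0.9 male / 0.7 female mg/dL), decayed by
  ``0.988**(age-40)`` above age 40.

The 1.159 multiplier historically applied to Black patients in CKD-EPI
and MDRD is implemented but **off by default**, following the French
recommendation not to apply it in European populations; pass
``black_coefficient=True`` to enable it.

All equation functions accept scalar or array ``age``/``pcr`` (``sex``
is scalar per call) and are vectorised with numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

__all__ = [
    "Sex",
    "PatientRecord",
    "EGFRPanel",
    "UMOL_PER_MGDL",
    "BLACK_COEFFICIENT",
    "EQUATIONS",
    "convert_creatinine",
    "egfr_ckdepi",
    "egfr_mdrd",
    "egfr_lmr",
    "egfr_fas",
    "egfr_panel",
]

#: Table-footnote conversion factor: creatinine mg/dL -> umol/L.
UMOL_PER_MGDL = 88.4

#: Multiplier for Black patients in CKD-EPI and MDRD (disabled by default).
BLACK_COEFFICIENT = 1.159

ArrayLike = Union[float, np.ndarray]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


def _coerce_sex(sex) -> Sex:
    if isinstance(sex, Sex):
        return sex
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return Sex.MALE
    if s in ("f", "female"):
        return Sex.FEMALE
    raise ValueError(f"unknown sex: {sex!r}")


def _validate_age_pcr(age: ArrayLike, pcr: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    age = np.asarray(age, dtype=float)
    pcr = np.asarray(pcr, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(~np.isfinite(pcr)):
        raise ValueError("age and pcr must be finite")
    if np.any(pcr <= 0):
        raise ValueError("plasma creatinine must be strictly positive (mg/dL)")
    if np.any(age <= 0):
        raise ValueError("age must be strictly positive (years)")
    if np.any(age > 100):
        warnings.warn("age above 100 years; estimate extrapolates", stacklevel=3)
    return age, pcr


def _scalar_out(value: np.ndarray, *inputs) -> ArrayLike:
    if all(np.ndim(x) == 0 for x in inputs):
        return float(value)
    return value


def convert_creatinine(value: ArrayLike, from_unit: str) -> ArrayLike:
    """Convert creatinine between mg/dL and µmol/L (factor 88.4).

    Parameters
    ----------
    value : float or array
        Creatinine concentration, strictly positive.
    from_unit : {"mg_dL", "umol_L"}
        Unit of ``value``; the result is in the other unit.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("creatinine must be strictly positive and finite")
    unit = from_unit.strip().lower().replace("/", "_")
    if unit in ("mg_dl", "mgdl"):
        out = v * UMOL_PER_MGDL
    elif unit in ("umol_l", "umoll", "µmol_l"):
        out = v / UMOL_PER_MGDL
    else:
        raise ValueError(f"unknown creatinine unit: {from_unit!r}")
    return _scalar_out(out, value)


# ---------------------------------------------------------------------------
# CKD-EPI (2009)

_CKDEPI = {
    Sex.FEMALE: (0.7, 144.0, -0.329),
    Sex.MALE: (0.9, 141.0, -0.411),
}
_CKDEPI_HIGH_EXP = -1.209
_CKDEPI_AGE_BASE = 0.993


def egfr_ckdepi(age: ArrayLike, sex, pcr: ArrayLike, black_coefficient: bool = False) -> ArrayLike:
    """CKD-EPI 2009 creatinine equation, mL/min/1.73 m**2."""
    sex = _coerce_sex(sex)
    a, p = _validate_age_pcr(age, pcr)
    knot, base, low_exp = _CKDEPI[sex]
    ratio = p / knot
    exponent = np.where(p <= knot, low_exp, _CKDEPI_HIGH_EXP)
    out = base * ratio**exponent * _CKDEPI_AGE_BASE**a
    if black_coefficient:
        out = out * BLACK_COEFFICIENT
    return _scalar_out(out, age, pcr)


# ---------------------------------------------------------------------------
# MDRD (IDMS-traceable)


def egfr_mdrd(age: ArrayLike, sex, pcr: ArrayLike, black_coefficient: bool = False) -> ArrayLike:
    """IDMS-traceable MDRD study equation, mL/min/1.73 m**2."""
    sex = _coerce_sex(sex)
    a, p = _validate_age_pcr(age, pcr)
    out = 175.0 * p**-1.154 * a**-0.203
    if sex is Sex.FEMALE:
        out = out * 0.742
    if black_coefficient:
        out = out * BLACK_COEFFICIENT
    return _scalar_out(out, age, pcr)


# ---------------------------------------------------------------------------
# Lund-Malmo Revised

_LMR_KNOT = {Sex.FEMALE: 1.7, Sex.MALE: 2.0}  # mg/dL (150 / 180 umol/L)
_LMR_X0 = {Sex.FEMALE: 2.50, Sex.MALE: 2.56}
# Sub-knot slopes are per umol/L of creatinine in the source publication;
# rescaled here to per-mg/dL so the whole package works in mg/dL.
_LMR_SLOPE = {Sex.FEMALE: 0.0121 * UMOL_PER_MGDL, Sex.MALE: 0.00968 * UMOL_PER_MGDL}
_LMR_LOG_SLOPE = 0.926


def egfr_lmr(age: ArrayLike, sex, pcr: ArrayLike) -> ArrayLike:
    """Lund-Malmo Revised equation, mL/min/1.73 m**2."""
    sex = _coerce_sex(sex)
    a, p = _validate_age_pcr(age, pcr)
    knot, x0, slope = _LMR_KNOT[sex], _LMR_X0[sex], _LMR_SLOPE[sex]
    x = np.where(
        p < knot,
        x0 + slope * (knot - p),
        x0 - _LMR_LOG_SLOPE * np.log(p / knot),
    )
    out = np.exp(x - 0.0158 * a + 0.438 * np.log(a))
    return _scalar_out(out, age, pcr)


# ---------------------------------------------------------------------------
# Full Age Spectrum

_FAS_Q = {Sex.MALE: 0.9, Sex.FEMALE: 0.7}


def egfr_fas(age: ArrayLike, sex, pcr: ArrayLike) -> ArrayLike:
    """Full Age Spectrum equation, mL/min/1.73 m**2.

    ``107.3 * Q/PCr`` up to age 40, then decayed by ``0.988**(age-40)``;
    Q is 0.9 (male) / 0.7 (female) mg/dL.
    """
    sex = _coerce_sex(sex)
    a, p = _validate_age_pcr(age, pcr)
    base = 107.3 * _FAS_Q[sex] / p
    decay = np.where(a > 40.0, 0.988 ** (a - 40.0), 1.0)
    return _scalar_out(base * decay, age, pcr)


#: Equation registry keyed by the short names used throughout the package.
EQUATIONS = {
    "ckdepi": egfr_ckdepi,
    "mdrd": egfr_mdrd,
    "lmr": egfr_lmr,
    "fas": egfr_fas,
}


# ---------------------------------------------------------------------------
# Record / panel containers


@dataclass(frozen=True)
class PatientRecord:
    """One adult subject of a validation cohort.

    ``pcr`` is plasma creatinine in mg/dL; ``mgfr`` (optional) is the
    reference measured GFR in mL/min/1.73 m**2 with its measurement
    method; anthropometry is optional.
    """

    id: str
    age: float
    sex: Sex
    pcr: float
    mgfr: Optional[float] = None
    mgfr_method: str = "unknown"
    weight: Optional[float] = None
    height: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", _coerce_sex(self.sex))
        if not np.isfinite(self.age) or self.age < 18:
            raise ValueError(f"age must be >= 18 years, got {self.age}")
        if not np.isfinite(self.pcr) or self.pcr <= 0:
            raise ValueError(f"plasma creatinine must be > 0 mg/dL, got {self.pcr}")
        if self.mgfr is not None and (not np.isfinite(self.mgfr) or self.mgfr <= 0):
            raise ValueError(f"measured GFR must be > 0, got {self.mgfr}")
        if self.mgfr_method not in ("iohexol_plasma", "inulin_urinary", "unknown"):
            raise ValueError(f"unknown mGFR method: {self.mgfr_method!r}")


@dataclass(frozen=True)
class EGFRPanel:
    """The four equation estimates for one subject, mL/min/1.73 m**2."""

    ckdepi: float
    mdrd: float
    lmr: float
    fas: float

    def __post_init__(self):
        for name in ("ckdepi", "mdrd", "lmr", "fas"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} estimate must be positive and finite, got {v}")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("ckdepi", "mdrd", "lmr", "fas")}


def egfr_panel(record: PatientRecord, black_coefficient: bool = False) -> EGFRPanel:
    """Apply all four equations to one record."""
    return EGFRPanel(
        ckdepi=egfr_ckdepi(record.age, record.sex, record.pcr, black_coefficient),
        mdrd=egfr_mdrd(record.age, record.sex, record.pcr, black_coefficient),
        lmr=egfr_lmr(record.age, record.sex, record.pcr),
        fas=egfr_fas(record.age, record.sex, record.pcr),
    )
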