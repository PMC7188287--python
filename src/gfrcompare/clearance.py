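"""Reference (measured) GFR from raw clearance data.

Two reference techniques are supported:

* **Urinary inulin clearance** -- the classic UV/P formula averaged over
  three to four timed urine-collection periods under water diuresis.
* **Iohexol plasma clearance** -- single-bolus injection with late blood
  samples (nominally 120/180/240 min); a one-compartment slope-intercept
  fit of ``ln(conc)`` on time gives clearance ``dose * k / C0``, which is
  then corrected for the missed distribution phase with the
  Brochner-Mortensen quadratic.

Results are indexed to 1.73 m**2 body surface area via the DuBois
formula.  A Passing-Bablok regression is provided for cross-calibrating
the two techniques on paired measurements.

The Brochner-Mortensen and DuBois coefficients are the standard adult
values and are exposed as keyword arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UrinaryClearancePeriod",
    "PlasmaClearanceStudy",
    "ClearanceResult",
    "inulin_clearance",
    "iohexol_slope_clearance",
    "brochner_mortensen",
    "inverse_brochner_mortensen",
    "dubois_bsa",
    "index_to_bsa",
    "passing_bablok",
    "compute_plasma_mgfr",
    "BM_C1",
    "BM_C2",
]

# Standard adult Brochner-Mortensen coefficients.
BM_C1 = 0.990778
BM_C2 = -0.001218

# DuBois body-surface-area coefficients.
DUBOIS_COEF = 0.007184
DUBOIS_W_EXP = 0.425
DUBOIS_H_EXP = 0.725


@dataclass(frozen=True)
class UrinaryClearancePeriod:
    """One timed urine-collection period: U, V and mid-period plasma P."""

    urine_conc: float
    urine_flow: float  # mL/min
    plasma_conc: float  # same concentration units as urine_conc

    def __post_init__(self):
        for name in ("urine_conc", "urine_flow", "plasma_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class PlasmaClearanceStudy:
    """Single-bolus plasma-disappearance study.

    ``dose`` is the injected marker amount (mass); ``samples`` are
    (time min, concentration mass/volume) pairs with strictly increasing
    times; anthropometry is used for BSA indexing.
    """

    dose: float
    samples: tuple  # of (time_min, conc)
    weight: Optional[float] = None
    height: Optional[float] = None

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        samples = tuple((float(t), float(c)) for t, c in self.samples)
        if len(samples) < 2:
            raise ValueError("at least two plasma samples are required")
        times = np.array([t for t, _ in samples])
        concs = np.array([c for _, c in samples])
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(concs <= 0):
            raise ValueError("plasma concentrations must be strictly positive")
        object.__setattr__(self, "samples", samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.samples])


@dataclass(frozen=True)
class ClearanceResult:
    """Raw, corrected and BSA-indexed clearance for one study."""

    raw_clearance: float  # mL/min, one-compartment
    bm_corrected: float  # mL/min, total clearance
    bsa: Optional[float]  # m**2
    indexed: Optional[float]  # mL/min/1.73 m**2


def inulin_clearance(periods: Sequence[UrinaryClearancePeriod]) -> float:
    """Mean UV/P clearance over the collection periods, mL/min."""
    if not 2 <= len(periods) <= 6:
        raise ValueError("expected 2-6 urine collection periods")
    vals = [p.urine_conc * p.urine_flow / p.plasma_conc for p in periods]
    return float(np.mean(vals))


def iohexol_slope_clearance(study: PlasmaClearanceStudy) -> float:
    """One-compartment slope-intercept clearance from late plasma samples.

    Fits ``ln(conc) = ln(C0) - k*t`` by ordinary least squares; the
    clearance is ``dose * k / C0`` (equivalently dose/AUC with
    ``AUC = C0/k``).  Units follow the inputs: dose in mg and
    concentrations in mg/mL give mL/min.
    """
    t = study.times
    logc = np.log(study.concentrations)
    slope, intercept = np.polyfit(t, logc, 1)
    k = -slope
    if k <= 0:
        raise ValueError("fitted elimination slope is non-negative: degenerate kinetics")
    c0 = math.exp(intercept)
    return study.dose * k / c0


def brochner_mortensen(raw: float, c1: float = BM_C1, c2: float = BM_C2) -> float:
    """Correct a one-compartment clearance for the missed fast phase.

    ``corrected = c1*raw + c2*raw**2`` with the standard adult
    coefficients; always <= raw for raw > 0 over the physiological range.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw clearance must be non-negative")
    out = c1 * raw + c2 * raw**2
    return float(out) if np.ndim(out) == 0 else out


def inverse_brochner_mortensen(corrected: float, c1: float = BM_C1, c2: float = BM_C2) -> float:
    """Raw one-compartment clearance whose BM correction equals ``corrected``.

    Solves ``c2*r**2 + c1*r - corrected = 0`` for the physiological root
    (the branch below the parabola's apex).
    """
    if corrected < 0:
        raise ValueError("corrected clearance must be non-negative")
    disc = c1 * c1 + 4.0 * c2 * corrected
    if disc < 0:
        raise ValueError("corrected clearance outside the attainable range")
    # c2 < 0: the smaller-magnitude root is the physiological one.
    return (-c1 + math.sqrt(disc)) / (2.0 * c2)


def dubois_bsa(weight: float, height: float) -> float:
    """DuBois body surface area in m**2 from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be strictly positive")
    return DUBOIS_COEF * weight**DUBOIS_W_EXP * height**DUBOIS_H_EXP


def index_to_bsa(clearance: float, bsa: float) -> float:
    """Express a clearance per 1.73 m**2 of body surface area."""
    if bsa <= 0:
        raise ValueError("body surface area must be strictly positive")
    return clearance * 1.73 / bsa


def compute_plasma_mgfr(study: PlasmaClearanceStudy) -> ClearanceResult:
    """Full iohexol pipeline: slope clearance, BM correction, BSA indexing."""
    raw = iohexol_slope_clearance(study)
    corrected = brochner_mortensen(raw)
    if study.weight is not None and study.height is not None:
        bsa = dubois_bsa(study.weight, study.height)
        indexed = index_to_bsa(corrected, bsa)
    else:
        bsa = indexed = None
    return ClearanceResult(raw_clearance=raw, bm_corrected=corrected, bsa=bsa, indexed=indexed)


def passing_bablok(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Passing-Bablok method-comparison regression (original 1983 procedure).

    The slope is the shifted median of all pairwise slopes
    ``(y_j - y_i)/(x_j - x_i)``: slopes of exactly -1 are excluded,
    vertical slopes enter as signed infinity, and the median index is
    offset by K, the number of slopes below -1 (which makes the estimate
    invariant to swapping the axes up to inversion).  The intercept is
    ``median(y - slope*x)``.

    Returns ``(slope, intercept)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 pairs are required")
    if np.all(x == x[0]):
        raise ValueError("all x identical: slope undefined")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    slopes = []
    for a, b in zip(dx, dy):
        if a == 0.0 and b == 0.0:
            continue  # identical points carry no slope information
        if a == 0.0:
            slopes.append(math.inf if b > 0 else -math.inf)
            continue
        s = b / a
        if s == -1.0:
            continue  # excluded by the original procedure
        slopes.append(s)
    slopes = np.sort(np.asarray(slopes, dtype=float))
    nvalid = len(slopes)
    if nvalid == 0:
        raise ValueError("no informative pairwise slopes")
    k_off = int(np.sum(slopes < -1.0))
    if nvalid % 2 == 1:
        slope = slopes[(nvalid - 1) // 2 + k_off]
    else:
        lo = nvalid // 2 - 1 + k_off
        slope = 0.5 * (slopes[lo] + slopes[lo + 1])
    intercept = float(np.median(y - slope * x))
    return float(slope), intercept
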