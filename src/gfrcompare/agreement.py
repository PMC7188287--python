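"""Agreement and performance statistics for paired eGFR-mGFR samples.

One equation on one stratum is summarised by: signed bias (mean
eGFR - mGFR, positive = overestimation), precision (SD of the
differences), 2.5%/97.5% limits of agreement, P30 accuracy, log-scale
regression RMSE, the total deviation index (TDI), Lin's concordance
correlation coefficient (CCC, on the log scale by default, because the
spread of the differences grows with GFR level), and a Deming
errors-in-variables regression of eGFR on mGFR.

Conventions fixed here (all switchable):

* quantiles use linear interpolation of order statistics (numpy's
  default, the "type 7" rule);
* empirical limits of agreement are the 2.5th/97.5th percentiles of the
  differences; a parametric ``bias +/- 1.96*SD`` mode is available;
* the empirical TDI is the coverage-quantile of ``|ln(eGFR/mGFR)|``
  back-transformed to percent, so that under a multiplicative lognormal
  error model it estimates the same quantity as the parametric
  lognormal TDI ``100*(exp(z*sqrt(mu^2+sigma^2))-1)``; a plain
  relative-difference convention (quantile of ``|eGFR-mGFR|/mGFR``) is
  available via ``convention="relative"``;
* RMSE is the root mean squared residual of the OLS regression of
  log10(eGFR) on log10(mGFR) -- on the native scale the printed
  magnitudes of such validation studies (~0.13-0.18) would be
  impossible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import ndtri

__all__ = [
    "Stratum",
    "PairedSample",
    "AgreementReport",
    "BlandAltman",
    "bias",
    "precision_sd",
    "limits_of_agreement",
    "p30",
    "rmse_log",
    "tdi",
    "ccc",
    "ccc_band",
    "deming",
    "bland_altman_data",
    "compute_agreement",
]


class Stratum(str, Enum):
    ALL = "all"
    LT45 = "lt45"
    GE45 = "ge45"


@dataclass(frozen=True)
class PairedSample:
    """Paired eGFR/mGFR vectors for one equation on one stratum."""

    egfr: np.ndarray
    mgfr: np.ndarray
    stratum: Stratum = Stratum.ALL

    def __post_init__(self):
        e = np.asarray(self.egfr, dtype=float)
        m = np.asarray(self.mgfr, dtype=float)
        if e.shape != m.shape or e.ndim != 1:
            raise ValueError("egfr and mgfr must be one-dimensional and of equal length")
        if len(e) < 2:
            raise ValueError("at least two pairs are required")
        if np.any(e <= 0) or np.any(m <= 0):
            raise ValueError("eGFR and mGFR values must be strictly positive")
        object.__setattr__(self, "egfr", e)
        object.__setattr__(self, "mgfr", m)
        object.__setattr__(self, "stratum", Stratum(self.stratum))
        if self.stratum is Stratum.LT45 and np.any(m >= 45):
            raise ValueError("stratum lt45 requires every mGFR < 45")
        if self.stratum is Stratum.GE45 and np.any(m < 45):
            raise ValueError("stratum ge45 requires every mGFR >= 45")

    def __len__(self) -> int:
        return len(self.egfr)

    @property
    def differences(self) -> np.ndarray:
        return self.egfr - self.mgfr


@dataclass(frozen=True)
class AgreementReport:
    """Point estimates of every agreement statistic for one sample."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    p30: float
    rmse_log: float
    tdi: float
    ccc: float
    deming_slope: float
    deming_intercept: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def bias(sample: PairedSample) -> float:
    """Mean eGFR - mGFR difference; positive means overestimation."""
    return float(np.mean(sample.differences))


def precision_sd(sample: PairedSample) -> float:
    """Sample SD (n-1 denominator) of the eGFR - mGFR differences."""
    return float(np.std(sample.differences, ddof=1))


def limits_of_agreement(sample: PairedSample, mode: str = "empirical") -> tuple[float, float]:
    """2.5%/97.5% limits of agreement of the differences.

    ``empirical`` (default) uses the percentiles of the observed
    differences (n >= 10 required); ``parametric`` uses
    ``bias +/- 1.96*SD``.
    """
    d = sample.differences
    if mode == "empirical":
        if len(d) < 10:
            raise ValueError("empirical limits of agreement require n >= 10")
        lo, hi = np.quantile(d, [0.025, 0.975])
    elif mode == "parametric":
        b, s = float(np.mean(d)), float(np.std(d, ddof=1))
        lo, hi = b - 1.96 * s, b + 1.96 * s
    else:
        raise ValueError(f"unknown limits-of-agreement mode: {mode!r}")
    return float(lo), float(hi)


def p30(sample: PairedSample) -> float:
    """Percent of estimates within +/-30% of mGFR (boundary counts as within)."""
    within = np.abs(sample.differences) <= 0.30 * sample.mgfr
    return 100.0 * float(np.mean(within))


def rmse_log(sample: PairedSample) -> float:
    """Root mean squared residual of OLS log10(eGFR) on log10(mGFR)."""
    if len(sample) < 3:
        raise ValueError("rmse_log requires at least 3 pairs")
    x = np.log10(sample.mgfr)
    y = np.log10(sample.egfr)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(np.sqrt(np.mean(resid**2)))


def tdi(
    sample: PairedSample,
    coverage: float = 0.90,
    mode: str = "empirical",
    convention: str = "log_ratio",
) -> float:
    """Total deviation index in percent at the given coverage probability.

    A TDI of b means that ``coverage`` of the estimates deviate from the
    measurement by at most b percent.  ``empirical`` (default) takes the
    coverage-quantile of the observed deviations; ``parametric`` assumes
    a lognormal eGFR/mGFR ratio and returns
    ``100*(exp(z_{(1+coverage)/2} * sqrt(mu^2 + sigma^2)) - 1)`` from the
    mean and SD of ``ln(eGFR/mGFR)``.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    if mode == "parametric":
        lr = np.log(sample.egfr / sample.mgfr)
        mu = float(np.mean(lr))
        sd = float(np.std(lr, ddof=1))
        z = float(ndtri((1.0 + coverage) / 2.0))
        return 100.0 * (math.exp(z * math.sqrt(mu * mu + sd * sd)) - 1.0)
    if mode != "empirical":
        raise ValueError(f"unknown TDI mode: {mode!r}")
    if len(sample) < 10:
        raise ValueError("empirical TDI requires n >= 10")
    if convention == "log_ratio":
        q = float(np.quantile(np.abs(np.log(sample.egfr / sample.mgfr)), coverage))
        return 100.0 * (math.exp(q) - 1.0)
    if convention == "relative":
        rel = np.abs(sample.differences) / sample.mgfr
        return 100.0 * float(np.quantile(rel, coverage))
    raise ValueError(f"unknown TDI convention: {convention!r}")


def ccc(sample: PairedSample, log_transform: bool = True) -> float:
    """Lin's concordance correlation coefficient.

    ``rho_c = 2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)`` with sample
    (n-1) moments, computed on ln-transformed pairs by default.
    """
    if len(sample) < 3:
        raise ValueError("ccc requires at least 3 pairs")
    if log_transform:
        x, y = np.log(sample.mgfr), np.log(sample.egfr)
    else:
        x, y = sample.mgfr, sample.egfr
    sx2 = float(np.var(x, ddof=1))
    sy2 = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    dm = float(np.mean(x) - np.mean(y))
    denom = sx2 + sy2 + dm * dm
    if denom == 0.0:
        raise ValueError("concordance undefined: zero variance and equal means")
    return 2.0 * sxy / denom


def ccc_band(value: float) -> str:
    """Strength-of-agreement band for a CCC value.

    >0.990 almost perfect; 0.950-0.990 substantial; 0.900-0.949
    moderate; <0.900 poor (both band edges 0.950 and 0.990 belong to
    "substantial").
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("CCC must lie in [-1, 1]")
    if value > 0.990:
        return "almost_perfect"
    if value >= 0.950:
        return "substantial"
    if value >= 0.900:
        return "moderate"
    return "poor"


def deming(sample: PairedSample, variance_ratio: float = 1.0) -> tuple[float, float]:
    """Deming errors-in-variables regression of eGFR (y) on mGFR (x).

    ``variance_ratio`` is the ratio of the error variances
    (lambda = var_y_err / var_x_err); the default 1 is orthogonal
    regression.  Returns ``(slope, intercept)``.
    """
    if len(sample) < 3:
        raise ValueError("deming requires at least 3 pairs")
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    x, y = sample.mgfr, sample.egfr
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0.0:
        raise ValueError("Deming slope undefined: zero covariance")
    lam = variance_ratio
    diff = syy - lam * sxx
    slope = (diff + math.sqrt(diff * diff + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


@dataclass(frozen=True)
class BlandAltman:
    """Per-pair (mGFR, difference) rows plus the difference-trend line."""

    mgfr: np.ndarray
    difference: np.ndarray
    trend_slope: float
    trend_intercept: float


def bland_altman_data(sample: PairedSample) -> BlandAltman:
    """Data for a difference-versus-reference scatter with its trend line."""
    d = sample.differences
    m = sample.mgfr
    if np.ptp(m) == 0:
        slope, intercept = 0.0, float(np.mean(d))
    else:
        slope, intercept = np.polyfit(m, d, 1)
    return BlandAltman(
        mgfr=m.copy(),
        difference=d.copy(),
        trend_slope=float(slope),
        trend_intercept=float(intercept),
    )


def compute_agreement(
    sample: PairedSample,
    loa_mode: str = "empirical",
    tdi_coverage: float = 0.90,
    tdi_mode: str = "empirical",
    tdi_convention: str = "log_ratio",
    ccc_log: bool = True,
    deming_variance_ratio: float = 1.0,
) -> AgreementReport:
    """All agreement statistics for one sample as a single report."""
    lo, hi = limits_of_agreement(sample, mode=loa_mode)
    slope, intercept = deming(sample, variance_ratio=deming_variance_ratio)
    return AgreementReport(
        bias=bias(sample),
        sd=precision_sd(sample),
        loa_low=lo,
        loa_high=hi,
        p30=p30(sample),
        rmse_log=rmse_log(sample),
        tdi=tdi(sample, coverage=tdi_coverage, mode=tdi_mode, convention=tdi_convention),
        ccc=ccc(sample, log_transform=ccc_log),
        deming_slope=slope,
        deming_intercept=intercept,
        n=len(sample),
    )
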