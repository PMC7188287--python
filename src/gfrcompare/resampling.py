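"""Resampling inference and multiple-comparison control.

Provides the uncertainty machinery used by the comparison pipeline:

* **BCa bootstrap** confidence intervals (bias-corrected and
  accelerated): subjects are resampled with replacement, the bias
  correction ``z0`` comes from the fraction of bootstrap statistics
  below the observed one, and the acceleration ``a`` from the jackknife
  skewness; the percentile endpoints are then adjusted accordingly.
* **Cochran's Q** for comparing k paired proportions (the within-30%
  indicators of the equations) with **pairwise McNemar** follow-up
  (exact binomial for small discordance, chi-square otherwise).
* **Holm-Bonferroni** step-down control of the family-wise error rate.
* **Paired bootstrap comparison of two AUCs** on the same subjects.

Every operation is deterministic given its seed.  Pipeline runs derive
one stream per (statistic, equation, stratum) from a single root seed
so reports are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import binomtest, chi2

from .diagnostics import DiagnosticTask, auc

__all__ = [
    "BootstrapConfig",
    "IntervalEstimate",
    "AucComparison",
    "derive_seed",
    "bca_interval",
    "bca_from_replicates",
    "cochran_q",
    "mcnemar",
    "holm_bonferroni",
    "holm_adjusted_pvalues",
    "compare_auc_bootstrap",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, seed and interval coverage for bootstrap CIs."""

    replicates: int = 2000
    seed: int = 0
    coverage: float = 0.95

    def __post_init__(self):
        if self.replicates < 200:
            raise ValueError("at least 200 bootstrap replicates are required")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a confidence interval.

    ``pathological`` flags the rare BCa failure mode where the adjusted
    interval does not bracket the point estimate.
    """

    point: float
    low: float
    high: float
    pathological: bool = False


def derive_seed(root: int, *names: str) -> int:
    """Deterministic per-stream seed below 2**31 from a root seed and labels."""
    tag = zlib.crc32("/".join(names).encode()) & 0x7FFFFFFF
    return int(np.random.SeedSequence([int(root) & 0x7FFFFFFF, tag]).generate_state(1)[0] % (2**31))


def bca_from_replicates(
    theta_hat: float,
    theta_star: np.ndarray,
    theta_jack: np.ndarray,
    coverage: float = 0.95,
) -> IntervalEstimate:
    """BCa interval from precomputed bootstrap and jackknife statistics."""
    theta_star = np.asarray(theta_star, dtype=float)
    theta_star = theta_star[np.isfinite(theta_star)]
    b = len(theta_star)
    if b == 0:
        # e.g. a perfect test whose likelihood ratio is infinite in every
        # resample: no distribution to summarise, flag rather than crash
        warnings.warn("no finite bootstrap replicates: interval undefined")
        return IntervalEstimate(
            point=float(theta_hat), low=math.nan, high=math.nan, pathological=True
        )
    if np.ptp(theta_star) == 0.0:
        warnings.warn("degenerate bootstrap distribution: zero-width interval")
        v = float(theta_star[0])
        return IntervalEstimate(point=float(theta_hat), low=v, high=v)
    frac_below = np.sum(theta_star < theta_hat) / b
    frac_below = min(max(frac_below, 1.0 / (b + 1)), b / (b + 1.0))
    z0 = float(ndtri(frac_below))

    theta_jack = np.asarray(theta_jack, dtype=float)
    d = np.mean(theta_jack) - theta_jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - coverage
    lo_hi = []
    for z_alpha in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(theta_star, float(ndtr(adj)))))
    low, high = min(lo_hi), max(lo_hi)
    pathological = not (low <= theta_hat <= high)
    return IntervalEstimate(point=float(theta_hat), low=low, high=high, pathological=pathological)


def bca_interval(
    statistic: Callable,
    sample,
    config: BootstrapConfig,
    vectorized: bool = False,
) -> IntervalEstimate:
    """BCa bootstrap confidence interval for ``statistic(sample)``.

    ``sample`` is a 1-D data vector or a 2-D pair table whose rows are
    resampled with replacement.  With ``vectorized=True`` the statistic
    must accept a stacked array of resamples and reduce over the last
    axis (rows axis for 2-D samples are stacked on a new leading axis);
    this is much faster for simple statistics such as the mean.
    """
    data = np.asarray(sample, dtype=float)
    n = data.shape[0]
    if n < 10:
        raise ValueError("bootstrap requires n >= 10")
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.replicates, n))
    jack_idx = np.array([np.delete(np.arange(n), i) for i in range(n)])
    theta_hat = float(statistic(data))
    if vectorized:
        theta_star = np.asarray(statistic(data[idx]), dtype=float)
        theta_jack = np.asarray(statistic(data[jack_idx]), dtype=float)
    else:
        theta_star = np.array([statistic(data[row]) for row in idx], dtype=float)
        theta_jack = np.array([statistic(data[row]) for row in jack_idx], dtype=float)
    return bca_from_replicates(theta_hat, theta_star, theta_jack, coverage=config.coverage)


def cochran_q(indicator_table) -> tuple[float, float]:
    """Cochran's Q for a subjects x methods binary indicator table.

    Tests equality of the k paired proportions; Q is referred to a
    chi-square distribution on k-1 degrees of freedom.  Subjects with
    constant rows (all success or all failure) carry no information; if
    only such rows exist the statistic is undefined and (nan, nan) is
    returned with a warning.
    """
    t = np.asarray(indicator_table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("indicator table must be subjects x methods with >= 2 of each")
    if not np.all(np.isin(t, (0.0, 1.0))):
        raise ValueError("indicator table must be binary")
    n, k = t.shape
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    total = t.sum()
    denom = k * total - float(np.sum(row**2))
    if denom == 0.0:
        # every row constant: the methods never disagree, so there is no
        # evidence of a method effect (0/0 resolved as Q = 0)
        warnings.warn("Cochran Q carries no information: all subject rows are constant")
        return 0.0, 1.0
    q = (k - 1) * (k * float(np.sum(col**2)) - total**2) / denom
    p = float(chi2.sf(q, k - 1))
    return float(q), p


def mcnemar(b: int, c: int, method: str = "auto") -> float:
    """McNemar p-value from the discordant-pair counts ``b`` and ``c``.

    ``auto`` (default) uses the exact two-sided binomial test at
    p = 0.5 when b + c < 25 and the chi-square form
    ``(b-c)^2/(b+c)`` (no continuity correction) otherwise; ``exact``
    and ``chisq`` force either branch.  b + c = 0 returns p = 1 (no
    discordance, no evidence).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    total = b + c
    if total == 0:
        warnings.warn("no discordant pairs: McNemar p-value is 1")
        return 1.0
    if method == "auto":
        method = "exact" if total < 25 else "chisq"
    if method == "exact":
        return float(binomtest(int(b), int(total), 0.5).pvalue)
    if method == "chisq":
        stat = (b - c) ** 2 / total
        return float(chi2.sf(stat, 1))
    raise ValueError(f"unknown McNemar method: {method!r}")


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.005) -> np.ndarray:
    """Holm step-down rejection flags at family-wise error level alpha.

    Sorted p-values are compared with alpha/(m - i + 1); the procedure
    stops at the first failure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def holm_adjusted_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone running maximum)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adjusted[i] = running
    return adjusted


@dataclass(frozen=True)
class AucComparison:
    """Paired bootstrap comparison of two AUCs on the same subjects."""

    delta: float
    interval: IntervalEstimate
    p_value: float


def compare_auc_bootstrap(
    task_a: DiagnosticTask,
    task_b: DiagnosticTask,
    config: BootstrapConfig,
    max_redraws: int = 100,
) -> AucComparison:
    """Bootstrap the difference of two AUCs computed on the same subjects.

    Subjects are resampled jointly so the within-subject pairing of the
    two scores is preserved; resamples missing a class are redrawn (up
    to ``max_redraws`` times each, then dropped with a warning).  The
    two-sided p-value doubles the proportion of the bootstrap
    distribution of delta-AUC beyond zero; the interval is percentile.
    """
    if not np.array_equal(task_a.labels, task_b.labels):
        raise ValueError("both tasks must share the same subjects and labels")
    labels = task_a.labels
    n = len(labels)
    rng = np.random.default_rng(config.seed)
    observed = auc(task_a) - auc(task_b)
    deltas = np.empty(config.replicates)
    dropped = 0
    for r in range(config.replicates):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() == 0 and lab.max() == 1:
                break
        else:
            dropped += 1
            deltas[r] = np.nan
            continue
        ta = DiagnosticTask(lab, task_a.scores[idx], task_a.threshold)
        tb = DiagnosticTask(lab, task_b.scores[idx], task_b.threshold)
        deltas[r] = auc(ta) - auc(tb)
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate bootstrap replicates")
    deltas = deltas[np.isfinite(deltas)]
    alpha = 1.0 - config.coverage
    low, high = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    interval = IntervalEstimate(point=float(observed), low=float(low), high=float(high))
    p = 2.0 * min(float(np.mean(deltas <= 0.0)), float(np.mean(deltas >= 0.0)))
    return AucComparison(delta=float(observed), interval=interval, p_value=min(p, 1.0))
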