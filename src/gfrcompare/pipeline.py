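"""End-to-end comparison pipeline.

Reads (or accepts) a cohort, computes the four-equation eGFR panel,
stratifies on measured GFR at the clinical cutoff (default 45
mL/min/1.73 m**2), and produces:

* an agreement report per equation x {all, lt45, ge45} with BCa
  bootstrap confidence intervals on every statistic;
* a diagnostic report (AUC and 2x2 metrics at the cutoff) per equation
  with bootstrap CIs;
* a pairwise comparison table -- Cochran Q over the within-30%
  indicators, pairwise McNemar for P30, paired bootstrap for bias and
  AUC differences -- with Holm-adjusted significance per metric family;
* Bland-Altman scatter data per equation; and
* a run log with seed, versions and row-count accounting.

Reports are bit-reproducible for a given (input, seed, config): every
bootstrap stream is derived deterministically from the root seed and
the (statistic, equation, stratum) labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    PairedSample,
    Stratum,
    bland_altman_data,
    compute_agreement,
)
from .diagnostics import DiagnosticTask, auc, confusion_metrics
from .io import panel_frame, validate_cohort
from .resampling import (
    BootstrapConfig,
    bca_from_replicates,
    cochran_q,
    compare_auc_bootstrap,
    derive_seed,
    holm_adjusted_pvalues,
    holm_bonferroni,
    mcnemar,
)

__all__ = ["RunConfig", "ReportBundle", "run_comparison", "write_bundle"]

AGREEMENT_STATS = (
    "bias",
    "sd",
    "loa_low",
    "loa_high",
    "p30",
    "rmse_log",
    "tdi",
    "ccc",
    "deming_slope",
    "deming_intercept",
)
DIAGNOSTIC_STATS = ("auc", "sensitivity", "specificity", "ppv", "npv", "plr", "nlr")


@dataclass(frozen=True)
class RunConfig:
    """Everything a comparison run needs besides the data itself."""

    input: Union[str, Path, pd.DataFrame, None] = None
    outdir: Union[str, Path, None] = None
    cutoff: float = 45.0
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    alpha: float = 0.005
    equations: tuple = ("ckdepi", "mdrd", "lmr", "fas")
    fmt: str = "csv"
    loa_mode: str = "empirical"
    tdi_coverage: float = 0.90
    tdi_mode: str = "empirical"
    tdi_convention: str = "log_ratio"
    black_coefficient: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.fmt not in ("csv", "json"):
            raise ValueError("format must be csv or json")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        boot = raw.pop("bootstrap", {})
        raw.update(overrides)
        if "equations" in raw:
            raw["equations"] = tuple(raw["equations"])
        return cls(bootstrap=BootstrapConfig(**boot), **raw)


@dataclass
class ReportBundle:
    """All machine-readable outputs of one comparison run."""

    agreement: pd.DataFrame
    diagnostics: pd.DataFrame
    comparisons: pd.DataFrame
    bland_altman: dict
    exclusions: pd.DataFrame
    log: dict


def _agreement_battery(egfr: np.ndarray, mgfr: np.ndarray, config: RunConfig) -> np.ndarray:
    sample = PairedSample(egfr, mgfr)
    try:
        rep = compute_agreement(
            sample,
            loa_mode=config.loa_mode,
            tdi_coverage=config.tdi_coverage,
            tdi_mode=config.tdi_mode,
            tdi_convention=config.tdi_convention,
        )
    except ValueError:
        return np.full(len(AGREEMENT_STATS), np.nan)
    return np.array([getattr(rep, s) for s in AGREEMENT_STATS])


def _agreement_with_ci(
    egfr: np.ndarray, mgfr: np.ndarray, config: RunConfig, stream_seed: int
) -> dict:
    """Point estimates + BCa CIs from one shared bootstrap pass."""
    n = len(egfr)
    point = _agreement_battery(egfr, mgfr, config)
    rng = np.random.default_rng(stream_seed)
    b = config.bootstrap.replicates
    idx = rng.integers(0, n, size=(b, n))
    theta_star = np.array([_agreement_battery(egfr[row], mgfr[row], config) for row in idx])
    jack_rows = np.array([np.delete(np.arange(n), i) for i in range(n)])
    theta_jack = np.array([_agreement_battery(egfr[row], mgfr[row], config) for row in jack_rows])
    out = {"n": n}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s, stat in enumerate(AGREEMENT_STATS):
            est = bca_from_replicates(
                point[s], theta_star[:, s], theta_jack[:, s], coverage=config.bootstrap.coverage
            )
            out[stat] = est.point
            out[f"{stat}_low"] = est.low
            out[f"{stat}_high"] = est.high
            if est.pathological:
                out.setdefault("flags", []).append(f"bca_pathological:{stat}")
    return out


def _diagnostic_battery(task: DiagnosticTask) -> np.ndarray:
    rep = confusion_metrics(task)
    vals = [rep.auc if rep.auc is not None else np.nan]
    vals += [getattr(rep, s) for s in DIAGNOSTIC_STATS[1:]]
    return np.array(vals, dtype=float)


def _diagnostics_with_ci(task: DiagnosticTask, config: RunConfig, stream_seed: int) -> dict:
    n = len(task.labels)
    point = _diagnostic_battery(task)
    rng = np.random.default_rng(stream_seed)
    b = config.bootstrap.replicates
    theta_star = np.empty((b, len(DIAGNOSTIC_STATS)))
    for r in range(b):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            lab = task.labels[idx]
            if lab.min() == 0 and lab.max() == 1:
                break
        theta_star[r] = _diagnostic_battery(
            DiagnosticTask(lab, task.scores[idx], task.threshold)
        )
    jack_rows = [np.delete(np.arange(n), i) for i in range(n)]
    theta_jack = np.array(
        [
            _diagnostic_battery(DiagnosticTask(task.labels[row], task.scores[row], task.threshold))
            for row in jack_rows
        ]
    )
    out = {"n": n}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s, stat in enumerate(DIAGNOSTIC_STATS):
            est = bca_from_replicates(
                point[s], theta_star[:, s], theta_jack[:, s], coverage=config.bootstrap.coverage
            )
            out[stat] = est.point
            out[f"{stat}_low"] = est.low
            out[f"{stat}_high"] = est.high
    return out


def _paired_mean_diff_bootstrap(diffs: np.ndarray, cfg: BootstrapConfig) -> tuple[float, float]:
    """Bootstrap p-value and observed value for a paired mean difference."""
    rng = np.random.default_rng(cfg.seed)
    n = len(diffs)
    idx = rng.integers(0, n, size=(cfg.replicates, n))
    boot = diffs[idx].mean(axis=1)
    p = 2.0 * min(float(np.mean(boot <= 0.0)), float(np.mean(boot >= 0.0)))
    return float(np.mean(diffs)), min(p, 1.0)


def run_comparison(config: RunConfig, cohort: Optional[pd.DataFrame] = None) -> ReportBundle:
    """Run the full comparison; optionally write reports to ``config.outdir``."""
    source = cohort if cohort is not None else config.input
    if source is None:
        raise ValueError("no cohort provided (config.input or cohort argument)")
    valid, exclusions = validate_cohort(source, require_mgfr=True)
    if len(valid) < 10:
        raise ValueError(f"too few valid subjects ({len(valid)}) for a comparison run")
    panels = panel_frame(valid, black_coefficient=config.black_coefficient)
    mgfr = valid["mgfr"].to_numpy(dtype=float)
    root = config.bootstrap.seed

    strata_masks = {
        Stratum.ALL.value: np.ones(len(valid), dtype=bool),
        Stratum.LT45.value: mgfr < config.cutoff,
        Stratum.GE45.value: mgfr >= config.cutoff,
    }

    agreement_rows = []
    for eq in config.equations:
        scores = panels[eq].to_numpy(dtype=float)
        for stratum, mask in strata_masks.items():
            if mask.sum() < 10:
                warnings.warn(f"stratum {stratum} has fewer than 10 subjects; skipped")
                continue
            row = {"equation": eq, "stratum": stratum}
            stream = derive_seed(root, "agreement", eq, stratum)
            row.update(_agreement_with_ci(scores[mask], mgfr[mask], config, stream))
            row.pop("flags", None)
            agreement_rows.append(row)
    agreement = pd.DataFrame(agreement_rows)

    diag_rows = []
    tasks = {}
    both_classes = strata_masks[Stratum.LT45.value].any() and strata_masks[Stratum.GE45.value].any()
    for eq in config.equations:
        if not both_classes:
            warnings.warn("only one mGFR class present; diagnostic reports skipped")
            break
        task = DiagnosticTask.from_mgfr(panels[eq].to_numpy(dtype=float), mgfr, config.cutoff)
        tasks[eq] = task
        row = {"equation": eq}
        row.update(_diagnostics_with_ci(task, config, derive_seed(root, "diagnostics", eq)))
        diag_rows.append(row)
    diagnostics = pd.DataFrame(diag_rows)

    comparison_rows = []
    within30 = {
        eq: (np.abs(panels[eq].to_numpy(dtype=float) - mgfr) <= 0.30 * mgfr).astype(int)
        for eq in config.equations
    }
    if len(config.equations) >= 2:
        table = np.column_stack([within30[eq] for eq in config.equations])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q, q_p = cochran_q(table)
        comparison_rows.append(
            {"metric": "p30_cochran_q", "eq_a": "all", "eq_b": "all", "estimate": q, "p": q_p}
        )
    pairs = [
        (a, b)
        for i, a in enumerate(config.equations)
        for b in config.equations[i + 1 :]
    ]
    for family, rows in (("p30_mcnemar", []), ("bias_diff", []), ("auc_diff", [])):
        for a, b in pairs:
            if family == "p30_mcnemar":
                disc_b = int(np.sum((within30[a] == 1) & (within30[b] == 0)))
                disc_c = int(np.sum((within30[a] == 0) & (within30[b] == 1)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = mcnemar(disc_b, disc_c)
                est = (within30[a].mean() - within30[b].mean()) * 100.0
            elif family == "bias_diff":
                diffs = panels[a].to_numpy(dtype=float) - panels[b].to_numpy(dtype=float)
                cfg = replace(config.bootstrap, seed=derive_seed(root, "bias_diff", a, b))
                est, p = _paired_mean_diff_bootstrap(diffs, cfg)
            else:
                if not tasks:
                    continue
                cfg = replace(config.bootstrap, seed=derive_seed(root, "auc_diff", a, b))
                cmp_res = compare_auc_bootstrap(tasks[a], tasks[b], cfg)
                est, p = cmp_res.delta, cmp_res.p_value
            rows.append({"metric": family, "eq_a": a, "eq_b": b, "estimate": est, "p": p})
        if rows:
            pvals = np.array([r["p"] for r in rows])
            adj = holm_adjusted_pvalues(pvals)
            rej = holm_bonferroni(pvals, alpha=config.alpha)
            for r, pa, rj in zip(rows, adj, rej):
                r["p_holm"] = float(pa)
                r["reject"] = bool(rj)
            comparison_rows.extend(rows)
    comparisons = pd.DataFrame(comparison_rows)

    bland = {}
    for eq in config.equations:
        ba = bland_altman_data(PairedSample(panels[eq].to_numpy(dtype=float), mgfr))
        bland[eq] = pd.DataFrame(
            {
                "id": valid["id"].values,
                "mgfr": ba.mgfr,
                "difference": ba.difference,
                "trend_slope": ba.trend_slope,
                "trend_intercept": ba.trend_intercept,
            }
        )

    log = {
        "package_version": __version__,
        "seed": root,
        "replicates": config.bootstrap.replicates,
        "coverage": config.bootstrap.coverage,
        "alpha": config.alpha,
        "cutoff": config.cutoff,
        "equations": list(config.equations),
        "n_input": int(len(exclusions) + len(valid)),
        "n_valid": int(len(valid)),
        "exclusions_by_rule": exclusions["rule"].value_counts().to_dict() if len(exclusions) else {},
        "stratum_sizes": {k: int(m.sum()) for k, m in strata_masks.items()},
        "rng_streams": {
            f"agreement/{eq}/{st}": derive_seed(root, "agreement", eq, st)
            for eq in config.equations
            for st in strata_masks
        },
    }

    bundle = ReportBundle(
        agreement=agreement,
        diagnostics=diagnostics,
        comparisons=comparisons,
        bland_altman=bland,
        exclusions=exclusions,
        log=log,
    )
    if config.outdir is not None:
        write_bundle(bundle, config.outdir, fmt=config.fmt)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: Union[str, Path], fmt: str = "csv") -> None:
    """Write all reports to ``outdir`` as CSV (or JSON) plus the run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, name: str) -> None:
        if fmt == "csv":
            df.to_csv(out / f"{name}.csv", index=False)
        else:
            (out / f"{name}.json").write_text(df.to_json(orient="records", indent=2))

    _write(bundle.agreement, "agreement")
    _write(bundle.diagnostics, "diagnostics")
    _write(bundle.comparisons, "comparisons")
    _write(bundle.exclusions, "exclusions")
    for eq, df in bundle.bland_altman.items():
        _write(df, f"bland_altman_{eq}")
    (out / "run_log.json").write_text(json.dumps(bundle.log, indent=2, sort_keys=True))
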