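"""Simulation of labelled p-value datasets and benchmarking of correction methods.

Datasets are generated under the BBUM mixture itself.  For each simulated
experiment the total feature count is N ~ U(200, 1000), split into a signal and
a background half by Binomial(N, 0.5).  Within each half the component counts
cascade through binomials — primary ~ B(n, theta) (signal half only), outlier
~ B(n, theta') (background half only, when enabled), null ~ B(remaining,
lambda), secondary = remainder — and points are drawn from U(0,1), Beta(a,1),
Beta(a*r,1) and Beta(a*r',1) respectively.  Mixture parameters are drawn per
simulation from uniform priors: lambda, a ~ U(0.1, 0.9); log10 theta, log10 r
~ U(-1.5, -0.5); log10 theta' ~ U(-2.5, -1.5); log10 r' ~ U(-2, -1).
Simulations are redrawn until they contain at least three primary points (and,
with outliers enabled, at least one outlier).

The benchmark applies each correction method to each simulated dataset, scores
calls on the signal half against the component truth labels (positives =
primary), and aggregates mean FDR, CV of FDR and mean sensitivity with basic
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import bootstrap as _scipy_bootstrap

from .distribution import (
    LABEL_NULL,
    LABEL_OUTLIER,
    LABEL_PRIMARY,
    LABEL_SECONDARY,
    BBUMParams,
)
from .fitting import FitConfig, FittingError, PSplitDataset, fit_bbum
from .significance import bh_adjust, p_bbum_adjust, shi_adhoc_call
from .trimming import fit_with_trimming

__all__ = [
    "SimConfig",
    "ConfusionCounts",
    "BenchmarkResult",
    "METHODS",
    "draw_sim_params",
    "simulate_dataset",
    "inject_artificial_outliers",
    "evaluate_calls",
    "bootstrap_ci",
    "run_benchmark",
]

METHOD_SHI = "shi"
METHOD_ORIGINAL = "bbum_original"
METHOD_MODIFIED = "bbum_modified"
METHODS = (METHOD_SHI, METHOD_ORIGINAL, METHOD_MODIFIED)

ARTIFICIAL_OUTLIER_P = 1e-300


@dataclass
class SimConfig:
    """Priors and acceptance rules of the simulation scheme."""

    n_range: Tuple[int, int] = (200, 1000)
    split_prob: float = 0.5
    lambda_range: Tuple[float, float] = (0.1, 0.9)
    a_range: Tuple[float, float] = (0.1, 0.9)
    log10_theta_range: Tuple[float, float] = (-1.5, -0.5)
    log10_r_range: Tuple[float, float] = (-1.5, -0.5)
    outliers_enabled: bool = False
    log10_theta_out_range: Tuple[float, float] = (-2.5, -1.5)
    log10_r_out_range: Tuple[float, float] = (-2.0, -1.0)
    min_primary: int = 3
    min_outliers: int = 1
    max_redraws: int = 10000


def draw_sim_params(config: SimConfig, rng) -> Tuple[BBUMParams, float, float]:
    """Draw one simulation's mixture parameters (and outlier parameters
    theta', r') from the configured priors."""
    rng = np.random.default_rng(rng)
    la = rng.uniform(*config.lambda_range)
    a = rng.uniform(*config.a_range)
    theta = 10.0 ** rng.uniform(*config.log10_theta_range)
    r = 10.0 ** rng.uniform(*config.log10_r_range)
    theta_out = 10.0 ** rng.uniform(*config.log10_theta_out_range)
    r_out = 10.0 ** rng.uniform(*config.log10_r_out_range)
    return BBUMParams(lambda_=la, a=a, theta=theta, r=r), theta_out, r_out


def _beta_a1(rng, n: int, shape: float) -> np.ndarray:
    # Beta(shape, 1) by inverse CDF; may underflow to subnormal/0 for tiny shapes
    return rng.uniform(size=n) ** (1.0 / shape)


def _simulate_half(rng, n, params, theta_out, r_out, signal: bool):
    """Component counts and draws for one half of a dataset."""
    la, a, th, r = params.lambda_, params.a, params.theta, params.r
    n_primary = rng.binomial(n, th) if signal else 0
    n_outlier = 0 if signal or theta_out == 0.0 else rng.binomial(n, theta_out)
    n_primary = min(n_primary, n)
    n_outlier = min(n_outlier, n - n_primary)
    n_null = rng.binomial(n - n_primary - n_outlier, la)
    n_secondary = n - n_primary - n_outlier - n_null
    p = np.concatenate(
        [
            _beta_a1(rng, n_primary, a * r),
            _beta_a1(rng, n_outlier, a * r_out),
            rng.uniform(size=n_null),
            _beta_a1(rng, n_secondary, a),
        ]
    )
    labels = np.concatenate(
        [
            np.repeat(LABEL_PRIMARY, n_primary),
            np.repeat(LABEL_OUTLIER, n_outlier),
            np.repeat(LABEL_NULL, n_null),
            np.repeat(LABEL_SECONDARY, n_secondary),
        ]
    )
    perm = rng.permutation(n)
    return p[perm], labels[perm]


def simulate_dataset(
    config: SimConfig, rng
) -> Tuple[PSplitDataset, BBUMParams, float, float]:
    """One accepted simulated dataset with truth labels.

    Whole simulations (parameters included) are redrawn until the acceptance
    filters pass: at least ``min_primary`` primary points, and at least
    ``min_outliers`` outliers when outliers are enabled.
    """
    rng = np.random.default_rng(rng)
    for _ in range(config.max_redraws):
        params, theta_out, r_out = draw_sim_params(config, rng)
        if not config.outliers_enabled:
            theta_out = 0.0
        n_total = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        n_signal = int(rng.binomial(n_total, config.split_prob))
        n_background = n_total - n_signal
        sig_p, sig_lab = _simulate_half(
            rng, n_signal, params, theta_out, r_out, signal=True
        )
        bg_p, bg_lab = _simulate_half(
            rng, n_background, params, theta_out, r_out, signal=False
        )
        n_primary = int(np.sum(sig_lab == LABEL_PRIMARY))
        n_out = int(np.sum(bg_lab == LABEL_OUTLIER))
        if n_primary < config.min_primary:
            continue
        if config.outliers_enabled and n_out < config.min_outliers:
            continue
        data = PSplitDataset(
            signal_p=sig_p,
            background_p=bg_p,
            signal_labels=sig_lab,
            background_labels=bg_lab,
        )
        return data, params, theta_out, r_out
    raise RuntimeError("no simulation passed the acceptance filters")


def inject_artificial_outliers(data: PSplitDataset, k: int) -> PSplitDataset:
    """Append k extreme background points with raw p = 1e-300, labelled outlier."""
    if k < 1:
        raise ValueError("k must be at least 1")
    bg_p = np.concatenate([data.background_p, np.full(k, ARTIFICIAL_OUTLIER_P)])
    bg_lab = None
    if data.background_labels is not None:
        bg_lab = np.concatenate(
            [data.background_labels, np.repeat(LABEL_OUTLIER, k)]
        )
    bg_ids = None
    if data.background_ids is not None:
        bg_ids = np.concatenate(
            [data.background_ids, [f"artificial_outlier_{i}" for i in range(k)]]
        )
    return PSplitDataset(
        data.signal_p, bg_p, data.signal_ids, bg_ids, data.signal_labels, bg_lab
    )


@dataclass
class ConfusionCounts:
    """Confusion counts over the signal half (truth = primary component)."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def fdr(self) -> float:
        """FP / (FP + TP); 0 by convention when nothing is called."""
        called = self.FP + self.TP
        return self.FP / called if called > 0 else 0.0

    @property
    def sensitivity(self) -> float:
        pos = self.TP + self.FN
        return self.TP / pos if pos > 0 else 0.0


def evaluate_calls(calls, truth_labels) -> ConfusionCounts:
    """Score significance calls on the signal half against component labels."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth_labels) == LABEL_PRIMARY
    if len(calls) != len(truth):
        raise ValueError("calls and truth labels must have equal length")
    return ConfusionCounts(
        TP=int(np.sum(calls & truth)),
        FP=int(np.sum(calls & ~truth)),
        TN=int(np.sum(~calls & ~truth)),
        FN=int(np.sum(~calls & truth)),
    )


def bootstrap_ci(values, statistic, n_boot: int = 3000, seed=None):
    """Basic (empirical) bootstrap 95% CI of ``statistic`` over ``values``.

    Returns ``(low, high, half_width)`` where the half-width is the mean
    deviation of the two interval ends from the point estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    point = statistic(values)
    if values.size == 1 or np.ptp(values) == 0.0:
        return point, point, 0.0
    with warnings.catch_warnings():
        # resamples of all-zero FDR vectors make CV-type statistics degenerate
        warnings.simplefilter("ignore")
        res = _scipy_bootstrap(
            (values,),
            statistic,
            n_resamples=n_boot,
            method="basic",
            confidence_level=0.95,
            rng=np.random.default_rng(seed),
        )
    low, high = res.confidence_interval
    half = (abs(point - low) + abs(high - point)) / 2.0
    return float(low), float(high), float(half)


def _cv(x: np.ndarray) -> float:
    m = np.mean(x)
    return float(np.std(x, ddof=1) / m) if m != 0 else float("nan")


@dataclass
class BenchmarkResult:
    """Per-simulation scores and aggregate statistics of a benchmark run."""

    per_sim: pd.DataFrame  # one row per (simulation, method, alpha)
    summary: pd.DataFrame  # one row per (method, alpha)
    n_fit_failures: int = 0
    failures: list = field(default_factory=list)


def _bbum_calls(data, alpha, trim):
    """Fit (optionally with trimming) and call signal features at p_BBUM < alpha."""
    config = FitConfig(alpha_bbum=alpha)
    if trim:
        res = fit_with_trimming(data, config)
        fit = res.fit
        n_trimmed = res.n_trimmed
    else:
        fit = fit_bbum(data, config)
        n_trimmed = 0
    clamped = data.clamped()
    p_bbum = p_bbum_adjust(clamped.signal_p, fit.params)
    return p_bbum < alpha, n_trimmed


def _shi_calls(data):
    """Shi et al. extreme-value calls from BH adjustment over the combined set."""
    n_sig = data.n_signal
    combined = np.concatenate([data.signal_p, data.background_p])
    padj = bh_adjust(combined)
    _, calls = shi_adhoc_call(padj[:n_sig], padj[n_sig:])
    return calls


def run_benchmark(
    n_sims: int,
    methods: Sequence[str] = METHODS,
    alphas: Sequence[float] = (0.05,),
    outliers: bool = False,
    seed=None,
    n_boot: int = 3000,
    sim_config: Optional[SimConfig] = None,
) -> BenchmarkResult:
    """Simulate ``n_sims`` datasets and score each method at each alpha.

    The Shi comparator ignores ``alphas`` (its threshold is data-driven).
    BBUM methods are refit at each alpha because the upper bound of theta,
    1 - 2*alpha, depends on it.  Fit failures are recorded per simulation and
    excluded from aggregates rather than aborting the run.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    if sim_config is None:
        sim_config = SimConfig(outliers_enabled=outliers)
    master = np.random.SeedSequence(seed)
    sim_seeds, boot_seed = master.spawn(n_sims), master.spawn(1)[0]
    rows = []
    failures = []
    for i in range(n_sims):
        rng = np.random.default_rng(sim_seeds[i])
        data, params, theta_out, r_out = simulate_dataset(sim_config, rng)
        truth = data.signal_labels
        for method in methods:
            if method == METHOD_SHI:
                calls_by_alpha = {None: (_shi_calls(data), 0)}
            else:
                trim = method == METHOD_MODIFIED
                calls_by_alpha = {}
                for alpha in alphas:
                    try:
                        calls_by_alpha[alpha] = _bbum_calls(data, alpha, trim)
                    except FittingError as err:
                        failures.append((i, method, alpha, str(err)))
                        continue
            for alpha, (calls, n_trimmed) in calls_by_alpha.items():
                cc = evaluate_calls(calls, truth)
                rows.append(
                    {
                        "sim": i,
                        "method": method,
                        "alpha": np.nan if alpha is None else alpha,
                        "TP": cc.TP,
                        "FP": cc.FP,
                        "TN": cc.TN,
                        "FN": cc.FN,
                        "fdr": cc.fdr,
                        "sensitivity": cc.sensitivity,
                        "n_trimmed": n_trimmed,
                    }
                )
    per_sim = pd.DataFrame(rows)
    boot_rng = np.random.default_rng(boot_seed)
    summary_rows = []
    for (method, alpha), grp in per_sim.groupby(["method", "alpha"], dropna=False):
        fdr = grp["fdr"].to_numpy()
        sens = grp["sensitivity"].to_numpy()
        _, _, fdr_hw = bootstrap_ci(
            fdr, np.mean, n_boot=n_boot, seed=boot_rng.integers(2**31)
        )
        _, _, cv_hw = bootstrap_ci(
            fdr, _cv, n_boot=n_boot, seed=boot_rng.integers(2**31)
        )
        _, _, sens_hw = bootstrap_ci(
            sens, np.mean, n_boot=n_boot, seed=boot_rng.integers(2**31)
        )
        summary_rows.append(
            {
                "method": method,
                "alpha": alpha,
                "n_sims": len(grp),
                "mean_fdr": float(np.mean(fdr)),
                "mean_fdr_ci": fdr_hw,
                "cv_fdr": _cv(fdr),
                "cv_fdr_ci": cv_hw,
                "mean_sensitivity": float(np.mean(sens)),
                "mean_sensitivity_ci": sens_hw,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return BenchmarkResult(
        per_sim=per_sim,
        summary=summary,
        n_fit_failures=len(failures),
        failures=failures,
    )
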