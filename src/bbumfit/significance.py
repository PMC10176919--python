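"""Significance calling from a fitted BBUM model, plus comparator methods.

``p_bbum_adjust`` converts each raw signal-direction p value into the expected
false-discovery rate of calling everything at or below it,

    p_BBUM(p) = 1 - theta * p^(a*r) / F(p | lambda, a, theta, r),

mirroring how BH-adjusted p values report the expected FDR at each cutoff.
Features are then called significant at p_BBUM < alpha.  Two comparators are
provided: plain Benjamini-Hochberg adjustment, and the extreme-value rule of
Shi et al., which lowers the BH threshold through canonical values
(0.05, 0.01, 0.001, ...) until every background-direction feature is excluded.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .distribution import BBUMParams, bbum_cdf

__all__ = [
    "CATEGORIES",
    "p_bbum_adjust",
    "bh_adjust",
    "shi_adhoc_call",
    "classify_features",
]

CAT_BOTH = "both_significant"
CAT_BBUM_ONLY = "bbum_only"
CAT_PADJ_ONLY = "padj_only"
CAT_OUTLIER = "outlier_trimmed"
CAT_NONE = "not_significant"
CATEGORIES = (CAT_BOTH, CAT_BBUM_ONLY, CAT_PADJ_ONLY, CAT_OUTLIER, CAT_NONE)


def p_bbum_adjust(p, params: BBUMParams):
    """BBUM-FDR-adjusted p value: 1 - theta*p^(a*r) / F(p).

    The expected FDR among signal-direction features with raw p values at or
    below ``p``.  Monotone non-decreasing in p when r < 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p values must lie in (0, 1]")
    F = bbum_cdf(p, params)
    out = 1.0 - params.theta * p ** (params.a * params.r) / F
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def shi_adhoc_call(
    signal_padj, background_padj, canonical_start: float = 0.05
):
    """Extreme-value significance rule of Shi et al.

    The threshold is the most permissive member of the canonical sequence
    (0.05, 0.01, 0.001, 0.0001, ...) that lies strictly below every
    background-direction adjusted p value; when even the weakest background
    feature exceeds 0.05 the threshold stays at 0.05.  Signal features with
    adjusted p below the threshold are called.

    Returns
    -------
    threshold : float
    calls : ndarray of bool over the signal features
    """
    signal_padj = np.asarray(signal_padj, dtype=float)
    background_padj = np.asarray(background_padj, dtype=float)
    if background_padj.size == 0:
        threshold = canonical_start
    else:
        min_bg = float(np.min(background_padj))
        if min_bg > canonical_start:
            threshold = canonical_start
        elif min_bg <= 0.0:
            threshold = 0.0
        else:
            threshold = canonical_start
            k = 2  # canonical sequence continues 10^-2, 10^-3, ...
            while threshold >= min_bg:
                threshold = 10.0 ** (-k)
                k += 1
    calls = signal_padj < threshold
    return threshold, calls


def classify_features(
    direction: Sequence[str],
    raw_p,
    p_adj,
    p_bbum,
    trimmed,
    alpha_bbum: float = 0.05,
    alpha_bh: float = 0.05,
) -> pd.DataFrame:
    """Four-way classification of features by BBUM and BH significance.

    Parameters
    ----------
    direction : 'signal' or 'background' per feature.
    raw_p, p_adj : raw and BH-adjusted p values.
    p_bbum : BBUM-adjusted p values (NaN for background or trimmed features).
    trimmed : boolean flags for background features removed as outliers.

    Categories (mutually exclusive, in precedence order): ``outlier_trimmed``,
    then ``both_significant`` / ``bbum_only`` / ``padj_only``, then
    ``not_significant``.  Background features can only reach ``padj_only``
    since p_BBUM is undefined for them.
    """
    direction = np.asarray(direction)
    raw_p = np.asarray(raw_p, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    p_bbum = np.asarray(p_bbum, dtype=float)
    trimmed = np.asarray(trimmed, dtype=bool)
    n = len(direction)
    if not (len(raw_p) == len(p_adj) == len(p_bbum) == len(trimmed) == n):
        raise ValueError("all per-feature inputs must have equal length")
    bad = set(np.unique(direction)) - {"signal", "background"}
    if bad:
        raise ValueError(f"unknown directions: {bad}")
    is_signal = direction == "signal"
    if np.any(~np.isnan(p_bbum) & ~is_signal):
        raise ValueError("p_bbum must be NaN for background-direction features")

    bbum_sig = is_signal & ~trimmed & (p_bbum < alpha_bbum)
    bh_sig = p_adj < alpha_bh
    category = np.full(n, CAT_NONE, dtype=object)
    category[bh_sig] = CAT_PADJ_ONLY
    category[bbum_sig & ~bh_sig] = CAT_BBUM_ONLY
    category[bbum_sig & bh_sig] = CAT_BOTH
    category[trimmed] = CAT_OUTLIER
    return pd.DataFrame(
        {
            "direction": direction,
            "raw_p": raw_p,
            "p_adj": p_adj,
            "p_bbum": p_bbum,
            "trimmed": trimmed,
            "category": pd.Categorical(category, categories=list(CATEGORIES)),
        }
    )
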