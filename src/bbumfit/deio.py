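"""Reading DE results tables, direction partitioning, filtering, and the
end-to-end correction pipeline.

The expected input is the standard results table of a differential-expression
engine (one row per feature: id, log2 fold change, raw p value, optionally
BH-adjusted p and mean expression), as tab- or comma-delimited text.  Default
column names follow DESeq2 (``baseMean``, ``log2FoldChange``, ``pvalue``,
``padj``); other engines are handled through an explicit column mapping.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .fitting import FitConfig, PSplitDataset, clamp_underflow, fit_bbum
from .significance import bh_adjust, classify_features, p_bbum_adjust
from .trimming import fit_with_trimming

__all__ = [
    "DEFAULT_COLUMNS",
    "DETable",
    "RunConfig",
    "read_de_table",
    "write_table",
    "partition_by_direction",
    "filter_expression",
    "run_correction",
]

DEFAULT_COLUMNS = {
    "id": "id",
    "log2fc": "log2FoldChange",
    "p_raw": "pvalue",
    "p_adj": "padj",
    "base_mean": "baseMean",
}


@dataclass
class DETable:
    """Typed differential-expression results table.

    ``usable`` marks rows with a present, in-range raw p value and a nonzero
    fold change; only those rows enter fitting.
    """

    frame: pd.DataFrame  # columns: id, log2fc, p_raw, p_adj, base_mean

    def __post_init__(self) -> None:
        required = {"id", "log2fc", "p_raw"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DETable missing columns: {sorted(missing)}")

    @property
    def usable(self) -> pd.Series:
        p = self.frame["p_raw"]
        ok = p.notna() & (p >= 0.0) & (p <= 1.0)
        return ok & self.frame["log2fc"].notna()


@dataclass
class RunConfig:
    """End-to-end correction settings.

    ``signal_direction`` is the fold-change sign where primary effects can
    occur: ``"up"`` for degradation-pathway knockouts (substrates rise),
    ``"down"`` for miRNA transfections (targets fall).
    """

    signal_direction: str = "up"
    alpha_bbum: float = 0.05
    alpha_bh: float = 0.05
    trimming: bool = True
    min_count: int = 5
    count_filter_mode: str = "per_replicate"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.signal_direction not in ("up", "down"):
            raise ValueError("signal_direction must be 'up' or 'down'")
        if self.count_filter_mode not in ("per_replicate", "total"):
            raise ValueError("count_filter_mode must be 'per_replicate' or 'total'")


def _sniff_sep(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_de_table(
    path, columns: Optional[Dict[str, str]] = None, sep: Optional[str] = None
) -> DETable:
    """Read a delimited DE results table into a :class:`DETable`.

    ``columns`` maps the canonical field names (id, log2fc, p_raw, and
    optionally p_adj, base_mean) to the file's column names; unspecified
    fields fall back to the DESeq2 defaults.  If no id column exists the
    first column is used.
    """
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    if mapping["id"] not in raw.columns:
        mapping["id"] = raw.columns[0]
    missing = [
        mapping[k] for k in ("id", "log2fc", "p_raw") if mapping[k] not in raw.columns
    ]
    if missing:
        raise ValueError(
            f"required columns not found: {missing}; file has {list(raw.columns)}"
        )
    frame = pd.DataFrame(
        {
            "id": raw[mapping["id"]].astype(str),
            "log2fc": pd.to_numeric(raw[mapping["log2fc"]], errors="coerce"),
            "p_raw": pd.to_numeric(raw[mapping["p_raw"]], errors="coerce"),
        }
    )
    for opt in ("p_adj", "base_mean"):
        col = mapping.get(opt)
        frame[opt] = (
            pd.to_numeric(raw[col], errors="coerce")
            if col in raw.columns
            else np.nan
        )
    return DETable(frame)


def write_table(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a results table as delimited text (NA for missing values)."""
    frame.to_csv(path, sep=sep, index=False, na_rep="NA")


def partition_by_direction(table: DETable, config: RunConfig) -> PSplitDataset:
    """Split usable rows into signal/background halves by fold-change sign.

    Rows with log2fc exactly 0 carry no direction evidence and are excluded
    from both halves.
    """
    frame = table.frame[table.usable]
    sign = 1.0 if config.signal_direction == "up" else -1.0
    signal = frame[frame["log2fc"] * sign > 0]
    background = frame[frame["log2fc"] * sign < 0]
    if len(signal) == 0 or len(background) == 0:
        raise ValueError(
            "cannot partition: "
            f"{len(signal)} signal and {len(background)} background features"
        )
    return PSplitDataset(
        signal_p=signal["p_raw"].to_numpy(),
        background_p=background["p_raw"].to_numpy(),
        signal_ids=signal["id"].to_numpy(),
        background_ids=background["id"].to_numpy(),
    )


def filter_expression(
    counts: pd.DataFrame, min_count: int = 5, mode: str = "per_replicate"
) -> pd.Index:
    """Expression filter over a features x samples count table.

    ``per_replicate`` keeps features with at least ``min_count`` in every
    sample; ``total`` keeps features whose summed count reaches ``min_count``.
    """
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if mode == "per_replicate":
        keep = (values >= min_count).all(axis=1)
    elif mode == "total":
        keep = values.sum(axis=1) >= min_count
    else:
        raise ValueError("mode must be 'per_replicate' or 'total'")
    return counts.index[keep]


def run_correction(table: DETable, config: Optional[RunConfig] = None):
    """Full pipeline: clamp, partition, fit (with optional trimming), adjust,
    classify.

    Returns
    -------
    result : pandas.DataFrame
        The input rows annotated with ``direction``, ``p_adj`` (BH over the
        combined usable set when absent from input), ``p_bbum`` (signal
        direction, untrimmed rows only) and ``category``.
    fit : FitResult
        Diagnostics of the final fit.
    """
    if config is None:
        config = RunConfig()
    fit_config = FitConfig(alpha_bbum=config.alpha_bbum)
    data = partition_by_direction(table, config)
    clamped = data.clamped()

    trimmed_ids: set = set()
    if config.trimming:
        trimmed_result = fit_with_trimming(clamped, fit_config)
        fit = trimmed_result.fit
        if trimmed_result.trimmed_ids is not None:
            trimmed_ids = set(trimmed_result.trimmed_ids)
    else:
        fit = fit_bbum(clamped, fit_config)

    frame = table.frame.copy()
    usable = table.usable
    sign = 1.0 if config.signal_direction == "up" else -1.0
    direction = np.where(frame["log2fc"] * sign > 0, "signal", "background")
    frame["direction"] = direction
    frame.loc[~usable | (frame["log2fc"] == 0), "direction"] = "excluded"

    # BH over the combined usable set when the engine did not supply p_adj
    if frame["p_adj"].isna().all():
        padj = np.full(len(frame), np.nan)
        padj[usable.to_numpy()] = bh_adjust(frame.loc[usable, "p_raw"].to_numpy())
        frame["p_adj"] = padj

    frame["trimmed"] = frame["id"].isin(trimmed_ids) & (
        frame["direction"] == "background"
    )
    p_bbum = np.full(len(frame), np.nan)
    sig_mask = (frame["direction"] == "signal").to_numpy()
    if sig_mask.any():
        p_clamped = clamp_underflow(frame.loc[sig_mask, "p_raw"].to_numpy())
        p_bbum[sig_mask] = p_bbum_adjust(p_clamped, fit.params)
    frame["p_bbum"] = p_bbum

    scored = frame["direction"].isin(["signal", "background"])
    categories = np.full(len(frame), "not_significant", dtype=object)
    cls = classify_features(
        frame.loc[scored, "direction"],
        frame.loc[scored, "p_raw"],
        frame.loc[scored, "p_adj"],
        frame.loc[scored, "p_bbum"],
        frame.loc[scored, "trimmed"],
        alpha_bbum=config.alpha_bbum,
        alpha_bh=config.alpha_bh,
    )
    categories[scored.to_numpy()] = cls["category"].astype(str).to_numpy()
    frame["category"] = categories
    return frame, fit
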