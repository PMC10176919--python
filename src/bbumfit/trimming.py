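"""Outlier detection and trimming for background-direction p values.

Extreme background outliers (e.g. features knocked down by an orthogonal
mechanism) drag the secondary-effect beta component toward them and cause the
model to overcorrect genuine primary effects.  The trimming procedure first
fits with a wide bound on r, (0, 10): a fitted r > 1 would mean the primary
peak is *shallower* than the secondary peak, violating the model's assumption
and flagging unexpected strength in the background.  The smallest background
p values are then removed one at a time, refitting after each removal, until
the fitted r drops below 1 or a conservative cap — min(floor(5% of the
background), 10) points — is reached.  The reported fit is always re-done with
r bounded to (0, 1) on the trimmed data.  Fitting with this procedure enabled
is referred to as the *modified* BBUM method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .fitting import FitConfig, FitResult, PSplitDataset, fit_bbum

__all__ = ["TrimmedFitResult", "trim_cap", "fit_with_trimming"]

R_WIDE_UPPER = 10.0
TRIM_FRACTION = 0.05
TRIM_MAX = 10


@dataclass
class TrimmedFitResult:
    """Final fit (r bounded to (0,1)) plus the trimmed background points."""

    fit: FitResult
    trimmed_indices: np.ndarray  # positions within the background half
    trimmed_ids: Optional[np.ndarray]
    n_trimmed: int
    trim_cap: int
    preliminary_r: float


def trim_cap(n_background: int) -> int:
    """Maximum number of background points that may be trimmed:
    min(floor(0.05 * n_background), 10)."""
    return min(int(np.floor(TRIM_FRACTION * n_background)), TRIM_MAX)


def _without_smallest(data: PSplitDataset, k: int):
    """Dataset with the k smallest background p values removed (ties broken by
    input order), plus the removed positions."""
    if k == 0:
        return data, np.array([], dtype=int)
    order = np.argsort(data.background_p, kind="stable")
    removed = np.sort(order[:k])
    keep = np.ones(data.n_background, dtype=bool)
    keep[removed] = False
    trimmed = PSplitDataset(
        data.signal_p,
        data.background_p[keep],
        data.signal_ids,
        None if data.background_ids is None else data.background_ids[keep],
        data.signal_labels,
        None if data.background_labels is None else data.background_labels[keep],
    )
    return trimmed, removed


def fit_with_trimming(
    data: PSplitDataset, config: Optional[FitConfig] = None
) -> TrimmedFitResult:
    """Fit with automatic background-outlier trimming (the modified method).

    1. Preliminary fit with r bounded to (0, 10).
    2. If the fitted r < 1, nothing is trimmed.
    3. Otherwise remove the k smallest background p values for k = 1, 2, ...,
       refitting with the wide bound each time, until r < 1 or k reaches
       ``trim_cap(n_background)``.
    4. The reported fit is re-done with r bounded to (0, 1) on the final data.
    """
    if config is None:
        config = FitConfig()
    wide = replace(config, r_upper=R_WIDE_UPPER)
    narrow = replace(config, r_upper=1.0)

    prelim = fit_bbum(data, wide)
    cap = trim_cap(data.n_background)
    n_trimmed = 0
    if prelim.params.r >= 1.0 and data.n_background > 0:
        for k in range(1, cap + 1):
            n_trimmed = k
            candidate, _ = _without_smallest(data, k)
            refit = fit_bbum(candidate, wide)
            if refit.params.r < 1.0:
                break

    final_data, removed = _without_smallest(data, n_trimmed)
    final = fit_bbum(final_data, narrow)
    trimmed_ids = (
        data.background_ids[removed] if data.background_ids is not None else None
    )
    return TrimmedFitResult(
        fit=final,
        trimmed_indices=removed,
        trimmed_ids=trimmed_ids,
        n_trimmed=n_trimmed,
        trim_cap=cap,
        preliminary_r=prelim.params.r,
    )
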