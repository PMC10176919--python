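"""Scikit-learn style estimator wrapping the BBUM fit/adjust workflow."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .fitting import FitConfig, PSplitDataset, clamp_underflow, fit_bbum
from .significance import p_bbum_adjust
from .trimming import fit_with_trimming


class BBUMCorrector(TransformerMixin, BaseEstimator):
    """FDR correction of directional p values by the bi-beta-uniform mixture.

    ``fit`` estimates one shared mixture from the two directional halves of an
    experiment; ``transform`` maps raw signal-direction p values to
    BBUM-FDR-adjusted p values.

    Parameters
    ----------
    alpha : float, default 0.05
        Intended significance level; bounds theta above by ``1 - 2*alpha``.
    trim : bool, default True
        Enable automatic background-outlier trimming (the modified method).
    max_iter : int, default 200
        BFGS iteration cap per optimisation start.
    starts : array-like of shape (k, 4), optional
        Initial (lambda, a, theta, r) vectors; defaults to six fixed starts.

    Attributes
    ----------
    params_ : BBUMParams
        Fitted mixture parameters (final fit, r < 1).
    loglik_ : float
        Total log-likelihood at the optimum.
    start_index_ : int
        Index of the winning optimisation start.
    n_trimmed_ : int
        Background points removed as outliers (0 when ``trim=False``).
    trimmed_indices_ : ndarray
        Positions of trimmed points within the background half.

    Examples
    --------
    >>> corr = BBUMCorrector(trim=False)
    >>> corr.fit(p_values, direction_is_signal)  # doctest: +SKIP
    >>> p_bbum = corr.transform(p_values[direction_is_signal])  # doctest: +SKIP
    """

    def __init__(self, alpha: float = 0.05, trim: bool = True,
                 max_iter: int = 200, starts=None):
        self.alpha = alpha
        self.trim = trim
        self.max_iter = max_iter
        self.starts = starts

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha_bbum=self.alpha, max_iterations=self.max_iter, starts=self.starts
        )

    def fit(self, p, direction):
        """Fit the mixture to p values split by direction.

        Parameters
        ----------
        p : array-like of shape (n,)
            Raw p values in [0, 1] (zeros are clamped to the underflow floor).
        direction : array-like of bool, shape (n,)
            True for signal-direction features, False for background.
        """
        p = np.asarray(p, dtype=float)
        direction = np.asarray(direction, dtype=bool)
        if p.shape != direction.shape or p.ndim != 1:
            raise ValueError("p and direction must be 1-D arrays of equal length")
        data = PSplitDataset(
            clamp_underflow(p[direction]), clamp_underflow(p[~direction])
        )
        if self.trim:
            res = fit_with_trimming(data, self._config())
            fit = res.fit
            self.n_trimmed_ = res.n_trimmed
            self.trimmed_indices_ = res.trimmed_indices
        else:
            fit = fit_bbum(data, self._config())
            self.n_trimmed_ = 0
            self.trimmed_indices_ = np.array([], dtype=int)
        self.params_ = fit.params
        self.loglik_ = fit.loglik
        self.start_index_ = fit.start_index
        self.n_features_in_ = p.size
        return self

    def transform(self, p):
        """BBUM-FDR-adjusted p values for raw signal-direction p values."""
        if not hasattr(self, "params_"):
            raise RuntimeError("BBUMCorrector must be fitted before transform")
        p = clamp_underflow(np.asarray(p, dtype=float))
        return p_bbum_adjust(p, self.params_)

    def significant(self, p):
        """Boolean calls at p_BBUM < alpha for raw signal-direction p values."""
        return self.transform(p) < self.alpha
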