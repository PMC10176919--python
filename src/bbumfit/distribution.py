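"""Bi-beta-uniform mixture (BBUM) distribution: density, CDF and labelled sampling.

The BBUM distribution models the p values of a directional differential-expression
experiment as a three-component mixture::

    X ~ theta * Beta(a*r, 1) + (1-theta)(1-lambda) * Beta(a, 1) + (1-theta)*lambda * U(0, 1)

The steep ``Beta(a*r, 1)`` component carries the primary (direct) effects, the
shallower ``Beta(a, 1)`` component carries secondary (indirect) effects, and the
uniform component carries the null features.  The background half of an
experiment — features whose fold change points away from the direction where
primary effects can occur — is modelled by the same distribution with
``theta = 0`` and ``r = 1`` (no primary component).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BBUMParams",
    "LABEL_NULL",
    "LABEL_SECONDARY",
    "LABEL_PRIMARY",
    "LABEL_OUTLIER",
    "COMPONENT_LABELS",
    "bbum_pdf",
    "bbum_cdf",
    "bbum_sample",
]

# Component labels attached to sampled points (truth labels in simulations).
LABEL_NULL = "null"
LABEL_SECONDARY = "secondary"
LABEL_PRIMARY = "primary"
LABEL_OUTLIER = "outlier"
COMPONENT_LABELS = (LABEL_NULL, LABEL_SECONDARY, LABEL_PRIMARY, LABEL_OUTLIER)


@dataclass(frozen=True)
class BBUMParams:
    """Parameters of one BBUM distribution.

    Parameters
    ----------
    lambda_ : float
        Fraction of null density among the non-primary density, in (0, 1).
    a : float
        Shape of the secondary-effect beta component, in (0, 1).
    theta : float
        Mixing weight of the primary-effect component, in [0, 1).  ``theta = 0``
        gives the background-only restriction.
    r : float
        Ratio of the primary to the secondary shape, so the primary shape is
        ``a * r``.  Final fits constrain ``r`` to (0, 1); preliminary fits used
        for outlier detection allow ``r`` up to 10.
    """

    lambda_: float
    a: float
    theta: float
    r: float

    R_MAX_PRELIMINARY = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ < 1.0):
            raise ValueError(f"lambda_ must be in (0, 1), got {self.lambda_}")
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"a must be in (0, 1), got {self.a}")
        if not (0.0 <= self.theta < 1.0):
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if not (0.0 < self.r <= self.R_MAX_PRELIMINARY):
            raise ValueError(
                f"r must be in (0, {self.R_MAX_PRELIMINARY}], got {self.r}"
            )

    def background(self) -> "BBUMParams":
        """The background-only restriction (theta = 0, r = 1)."""
        return replace(self, theta=0.0, r=1.0)

    @property
    def weights(self) -> np.ndarray:
        """Mixing weights of (primary, secondary, null)."""
        return np.array(
            [
                self.theta,
                (1.0 - self.theta) * (1.0 - self.lambda_),
                (1.0 - self.theta) * self.lambda_,
            ]
        )


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p values must lie in (0, 1]")
    return p


def bbum_pdf(p, params: BBUMParams):
    """BBUM probability density at ``p``.

    f(p) = theta*a*r*p^(a*r - 1) + (1-theta)(1-lambda)*a*p^(a-1) + (1-theta)*lambda

    Monotonically non-increasing on (0, 1]; diverges as p -> 0+.
    """
    p = _check_p(p)
    la, a, th, r = params.lambda_, params.a, params.theta, params.r
    out = (
        th * a * r * p ** (a * r - 1.0)
        + (1.0 - th) * (1.0 - la) * a * p ** (a - 1.0)
        + (1.0 - th) * la
    )
    return out if out.ndim else float(out)


def bbum_cdf(p, params: BBUMParams):
    """BBUM cumulative distribution at ``p``.

    F(p) = theta*p^(a*r) + (1-theta)(1-lambda)*p^a + (1-theta)*lambda*p
    """
    p = _check_p(p)
    la, a, th, r = params.lambda_, params.a, params.theta, params.r
    out = (
        th * p ** (a * r)
        + (1.0 - th) * (1.0 - la) * p ** a
        + (1.0 - th) * la * p
    )
    return out if out.ndim else float(out)


def bbum_sample(
    n: int,
    params: BBUMParams,
    seed=None,
    background_only: bool = False,
):
    """Draw ``n`` labelled points from the BBUM mixture.

    Each point is drawn by first sampling its component (weights ``theta``,
    ``(1-theta)(1-lambda)``, ``(1-theta)*lambda``; ``theta`` is forced to 0 when
    ``background_only``), then sampling from that component via inverse-CDF
    (``Beta(alpha, 1)`` variates are ``U^(1/alpha)``).

    Returns
    -------
    p : ndarray of float
    labels : ndarray of str
        Component of each point (``"primary"``, ``"secondary"`` or ``"null"``).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    pars = params.background() if background_only else params
    weights = pars.weights
    comp = rng.choice(3, size=n, p=weights)
    u = rng.uniform(size=n)
    p = np.empty(n)
    shapes = np.array([pars.a * pars.r, pars.a, 1.0])
    p = u ** (1.0 / shapes[comp])
    labels = np.array([LABEL_PRIMARY, LABEL_SECONDARY, LABEL_NULL])[comp]
    return p, labels
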