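"""Menzerath-Altmann law fitting.

The Menzerath-Altmann law (MAL) relates the mean constituent size
``y`` (graphemes per syllable) to the construct size ``m`` (syllables
per word) through

    y(m) = alpha * m**beta * exp(-gamma * m),

with alpha > 0 and typically beta, gamma < 0.  When ``beta * gamma > 0``
the curve has an interior extremum at ``m* = beta / gamma``; beyond it
the law inverts: longer words carry *longer* syllables.  The memoryless
null curve ``a/m + b`` has no such extremum, which is what separates the
two models empirically.

Fitting is nonlinear least squares in linear space (Levenberg-
Marquardt), on the per-``m`` mean values of a length profile, unweighted
by default with an optional count weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import LengthProfile

__all__ = ["MALParams", "FitResult", "mal_curve", "fit_mal", "extremum"]


@dataclass(frozen=True)
class MALParams:
    """Parameters (alpha, beta, gamma) of the MAL curve."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (np.isfinite(self.beta) and np.isfinite(self.gamma)):
            raise ValueError("beta and gamma must be finite")


@dataclass(frozen=True)
class FitResult:
    """Fitted MAL parameters with goodness of fit.

    ``extremum_m`` is ``beta/gamma`` when ``beta * gamma > 0`` and
    ``None`` otherwise.  ``residuals`` are observed minus fitted values
    per bin, in profile order.
    """

    params: MALParams
    r_squared: float
    converged: bool
    residuals: tuple[float, ...]
    message: str = ""

    @property
    def extremum_m(self) -> float | None:
        return extremum(self.params)

    def to_dict(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "gamma": self.params.gamma,
            "r_squared": self.r_squared,
            "extremum_m": self.extremum_m,
            "converged": self.converged,
        }


def mal_curve(params: MALParams, m):
    """Evaluate ``alpha * m**beta * exp(-gamma m)`` (m >= 1, real allowed)."""
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 1):
        raise ValueError("MAL curve is defined for m >= 1")
    return params.alpha * m_arr**params.beta * np.exp(-params.gamma * m_arr)


def extremum(params: MALParams) -> float | None:
    """Interior extremum ``m* = beta/gamma``, present iff beta*gamma > 0.

    The derivative of the curve vanishes exactly there:
    d/dm log y = beta/m - gamma = 0.
    """
    if params.gamma == 0 or params.beta * params.gamma <= 0:
        return None
    return params.beta / params.gamma


# multi-start grid tried (in order) when the default start fails to converge
_RESTART_GRID = [
    (-0.2, -0.2),
    (-0.2, 0.05),
    (0.05, -0.2),
    (0.05, 0.05),
    (-0.05, 0.05),
]


def _solve(m, y, w, x0):
    def resid(theta):
        a, b, g = theta
        return (np.exp(a) * m**b * np.exp(-g * m) - y) * w

    return least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)


def fit_mal(
    profile: LengthProfile,
    init: MALParams | None = None,
    weights: str | None = None,
) -> FitResult:
    """Fit the MAL curve to a length profile by Levenberg-Marquardt.

    Parameters
    ----------
    profile
        Length profile with at least 4 bins (3 parameters + 1).
    init
        Starting parameters; default is alpha = mean y at the smallest
        m, beta = gamma = -0.05, with a small multi-start grid over
        (beta0, gamma0) as fallback on non-convergence.
    weights
        ``None`` (default, unweighted) or ``"counts"`` to weight each
        bin by the square root of its supporting token count.

    Notes
    -----
    alpha is optimized on a log scale to enforce positivity.  R^2 is
    ``1 - SS_res/SS_tot`` over exactly the fitted bins.  Non-convergence
    is reported through the ``converged`` flag, never an exception.
    """
    if len(profile) < 4:
        raise ValueError("need at least 4 bins to fit 3 parameters")
    if weights not in (None, "counts"):
        raise ValueError("weights must be None or 'counts'")
    m = np.asarray(profile.ms, dtype=float)
    y = np.asarray(profile.mean_y, dtype=float)
    w = (
        np.sqrt(np.asarray(profile.counts, dtype=float))
        if weights == "counts"
        else np.ones_like(y)
    )

    if init is None:
        starts = [(float(y[0]), -0.05, -0.05)]
        starts += [(float(y[0]), b0, g0) for b0, g0 in _RESTART_GRID]
    else:
        starts = [(init.alpha, init.beta, init.gamma)]

    best = None
    for a0, b0, g0 in starts:
        sol = _solve(m, y, w, np.array([np.log(max(a0, 1e-6)), b0, g0]))
        if (
            best is None
            or (sol.success and not best.success)
            or (sol.success == best.success and sol.cost < best.cost)
        ):
            best = sol
        if sol.success:
            break  # restarts are a fallback for non-convergence only

    la, beta, gamma = best.x
    params = MALParams(float(np.exp(la)), float(beta), float(gamma))
    fitted = mal_curve(params, m)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return FitResult(
        params=params,
        r_squared=r2,
        converged=bool(best.success),
        residuals=tuple(float(r) for r in (y - fitted)),
        message=best.message,
    )
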