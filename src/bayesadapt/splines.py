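"""M-spline and I-spline bases for baseline-hazard modelling.

An M-spline basis {M_l} is a set of nonnegative piecewise polynomials, each
integrating to one over the knot span; with simplex-constrained coefficients
psi the mixture M(t) = sum_l psi_l M_l(t) is a valid (normalized) hazard shape
and its antiderivative I(t) = sum_l psi_l I_l(t) the corresponding cumulative
hazard shape, with I(0)=0 and I(t)=1 beyond the upper boundary knot.

Both bases are evaluated analytically through B-splines:

    M_l(t) = k / (t_{l+k} - t_l) * B_{l,k}(t)          (order k = degree + 1)
    I_l(t) = sum_{j > l} B_{j,k+1}(t)                  (on knots extended once)

Evaluation outside the boundary knots is clamped: M is 0 there, I is 0 below
and 1 above the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineConfig", "mspline_basis", "ispline_basis", "default_knots"]


@dataclass(frozen=True)
class SplineConfig:
    """Knot layout and degree for an M-/I-spline basis.

    ``knots`` are the full boundary + interior breakpoints (strictly
    increasing; the first and last are the boundary knots).  The basis size is
    ``L = n_interior + degree + 1``.
    """

    knots: tuple[float, ...]
    degree: int = 3
    _t: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        knots = np.asarray(self.knots, dtype=float)
        if knots.size < 2 or np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be >= 2 strictly increasing values")
        order = self.degree + 1
        t = np.r_[np.repeat(knots[0], order), knots[1:-1], np.repeat(knots[-1], order)]
        object.__setattr__(self, "_t", t)

    @property
    def order(self) -> int:
        return self.degree + 1

    @property
    def size(self) -> int:
        """Number of basis functions L."""
        return len(self._t) - self.order

    @property
    def lower(self) -> float:
        return float(self.knots[0])

    @property
    def upper(self) -> float:
        return float(self.knots[-1])


def default_knots(
    event_times: np.ndarray, horizon: float, n_interior: int = 2
) -> SplineConfig:
    """Cubic basis with boundary knots at 0 and the horizon and interior knots
    at quantiles of the observed event times (terciles for ``n_interior=2``).

    Degenerate quantiles (ties, too few events) are dropped, so the basis can
    shrink when events are scarce.
    """
    qs = np.quantile(event_times, np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = [q for q in np.unique(qs) if 0.0 < q < horizon]
    return SplineConfig(knots=tuple([0.0, *interior, float(horizon)]), degree=3)


def mspline_basis(times: np.ndarray, config: SplineConfig) -> np.ndarray:
    """Evaluate the L M-spline basis functions at ``times`` (shape (n, L)).

    Values are clamped to 0 outside the knot span.
    """
    x = np.atleast_1d(np.asarray(times, dtype=float))
    t, k = config._t, config.order
    inside = (x >= config.lower) & (x <= config.upper)
    xc = np.clip(x, config.lower, config.upper)
    design = BSpline.design_matrix(xc, t, config.degree, extrapolate=False).toarray()
    # B-splines sum to one; rescale each to integrate to one.
    widths = t[k : k + config.size] - t[: config.size]
    out = design * (k / widths)
    out[~inside] = 0.0
    return out


def ispline_basis(times: np.ndarray, config: SplineConfig) -> np.ndarray:
    """Evaluate the L integrated (I-spline) basis functions at ``times``.

    Each I_l is nondecreasing with I_l(lower)=0 and I_l(t)=1 for t >= upper.
    Uses the identity that the running integral of an order-k B-spline is a
    tail sum of order-(k+1) B-splines on a once-extended knot vector.
    """
    x = np.atleast_1d(np.asarray(times, dtype=float))
    t = config._t
    t_ext = np.r_[t[0], t, t[-1]]
    xc = np.clip(x, config.lower, config.upper)
    design = BSpline.design_matrix(xc, t_ext, config.degree + 1, extrapolate=False).toarray()
    # I_l(x) = sum_{j >= l+1} B_{j, k+1}(x): reverse cumulative sum, dropping
    # the first order-(k+1) element.
    tail = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]
    out = tail[:, 1 : 1 + config.size]
    out[x >= config.upper] = 1.0
    out[x <= config.lower] = 0.0
    return out
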