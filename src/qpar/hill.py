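"""Hill dose-response algebra.

The single-chemical concentration-response relationship used throughout this
package is the two-parameter Hill sigmoid

    E(c) = 1 / (1 + (EC50 / c)^p) = c^p / (c^p + EC50^p),

with half-maximal concentration ``EC50 > 0`` and slope exponent ``p > 0``.
The maximal effect is fixed at 1, so effects are unitless fractions in
``[0, 1)``; percent readouts are converted at the I/O boundary.

The module provides the forward map (:func:`hill_effect`), its inverse
(:func:`ec_x`, the concentration eliciting a fractional effect ``x``), a
closed-form fit from two dose-response points (:func:`fit_two_point`) and a
least-squares fit from a full curve (:func:`fit_curve`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "HillParams",
    "DoseResponsePoint",
    "ECTable",
    "hill_effect",
    "ec_x",
    "fit_two_point",
    "fit_curve",
]

# Optimiser box for fit_curve, in log10 units.
_LOG_EC50_BOUNDS = (-8.0, 8.0)
_LOG_SLOPE_BOUNDS = (-2.0, 2.0)


@dataclass(frozen=True)
class HillParams:
    """Potency and slope of one chemical's Hill curve.

    Parameters
    ----------
    ec50
        Half-maximal effective concentration (e.g. μg/mL, or normalized
        abundance units in screening use). Strictly positive.
    p
        Hill slope exponent, dimensionless, strictly positive.
    """

    ec50: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and math.isfinite(self.ec50)):
            raise ValueError(f"ec50 must be a positive finite number, got {self.ec50}")
        if not (self.p > 0 and math.isfinite(self.p)):
            raise ValueError(f"slope p must be a positive finite number, got {self.p}")


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, effect) observation; effect is a fraction in [0, 1]."""

    concentration: float
    effect: float

    def __post_init__(self) -> None:
        if self.concentration < 0 or not math.isfinite(self.concentration):
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError(f"effect must lie in [0, 1], got {self.effect}")


# Effect levels at which standards are tabulated (EC5 ... EC50).
EC_LEVELS: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass(frozen=True)
class ECTable:
    """Per-standard table of EC_x concentrations at the six canonical levels.

    ``values`` maps effect level x (fraction) to the concentration (μg/mL)
    eliciting it. Concentrations must be strictly increasing in x.
    """

    name: str
    values: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = sorted(self.values)
        concs = [self.values[x] for x in levels]
        if any(c <= 0 for c in concs):
            raise ValueError(f"{self.name}: EC concentrations must be positive")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(
                f"{self.name}: EC concentrations must increase strictly with level"
            )

    def ec(self, x: float) -> float:
        """Concentration at effect level ``x`` (must be tabulated)."""
        try:
            return self.values[x]
        except KeyError:
            raise KeyError(f"{self.name}: no tabulated EC at level {x}") from None

    def fit(self, x1: float = 0.05, x2: float = 0.50) -> HillParams:
        """Hill parameters from two tabulated levels (defaults: EC5 and EC50)."""
        return fit_two_point(
            DoseResponsePoint(self.ec(x1), x1), DoseResponsePoint(self.ec(x2), x2)
        )


def hill_effect(c, params: HillParams):
    """Effect fraction elicited by concentration ``c``.

    Accepts a scalar or array of nonnegative concentrations; ``c = 0`` maps
    to effect 0 (the continuous limit). Strictly increasing in ``c``, with
    values in ``[0, 1)``.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be nonnegative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c_arr > 0, params.ec50 / np.where(c_arr > 0, c_arr, 1.0), np.inf)
        effect = 1.0 / (1.0 + ratio**params.p)
    effect = np.where(c_arr == 0, 0.0, effect)
    return float(effect) if np.isscalar(c) or c_arr.ndim == 0 else effect


def ec_x(params: HillParams, x) -> float:
    """Concentration eliciting effect fraction ``x`` (the inverse Hill map).

    ``EC_x = EC50 * (x / (1 - x))^(1/p)`` for ``x`` in the open interval
    (0, 1); exact inverse of :func:`hill_effect` on (0, ∞).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr <= 0) | (x_arr >= 1)):
        raise ValueError("effect level x must lie strictly between 0 and 1")
    out = params.ec50 * (x_arr / (1.0 - x_arr)) ** (1.0 / params.p)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def fit_two_point(p1: DoseResponsePoint, p2: DoseResponsePoint) -> HillParams:
    """Closed-form Hill fit through two dose-response points.

    The slope follows from the log-logit linearisation of the Hill curve,

        p = ln[(x1/(1-x1)) / (x2/(1-x2))] / ln(c1/c2),

    and the EC50 from inverting either point. The fit is exact: ``ec_x`` at
    x1 and x2 returns c1 and c2 to round-off.
    """
    for pt in (p1, p2):
        if pt.concentration <= 0:
            raise ValueError("two-point fit requires positive concentrations")
        if not (0.0 < pt.effect < 1.0):
            raise ValueError(
                "two-point fit requires effects strictly inside (0, 1); "
                f"got {pt.effect}"
            )
    if p1.concentration == p2.concentration or p1.effect == p2.effect:
        raise ValueError("degenerate fit: points must differ in both axes")
    p = (_logit(p1.effect) - _logit(p2.effect)) / math.log(
        p1.concentration / p2.concentration
    )
    if p <= 0:
        raise ValueError("degenerate fit: effect must increase with concentration")
    ec50 = p1.concentration * math.exp(-_logit(p1.effect) / p)
    return HillParams(ec50=ec50, p=p)


def _interior(points: list[DoseResponsePoint]) -> list[DoseResponsePoint]:
    return [pt for pt in points if 0.0 < pt.effect < 1.0 and pt.concentration > 0]


def fit_curve(
    points: list[DoseResponsePoint],
    seed: int = 0,
    n_starts: int = 8,
) -> HillParams:
    """Least-squares Hill fit to a full dose-response curve.

    Minimises the sum of squared effect residuals over (EC50, p) with a
    bounded derivative-free search (Nelder-Mead in log10 parameter space),
    multi-started from two-point closed-form fits of extreme point pairs
    plus seeded perturbations. With exactly two usable points this reduces
    to :func:`fit_two_point`.
    """
    if len(points) < 2:
        raise ValueError("need at least two dose-response points")
    interior = _interior(points)
    if len(interior) < 2:
        raise ValueError("degenerate fit: need >=2 points with effects inside (0,1)")
    if len({pt.concentration for pt in interior}) < 2:
        raise ValueError("degenerate fit: need >=2 distinct concentrations")
    if len(points) == 2:
        return fit_two_point(points[0], points[1])

    c = np.array([pt.concentration for pt in points])
    e = np.array([pt.effect for pt in points])
    mask = c > 0

    def loss(theta: np.ndarray) -> float:
        params = HillParams(10.0 ** theta[0], 10.0 ** theta[1])
        resid = hill_effect(c[mask], params) - e[mask]
        return float(resid @ resid) + float(np.sum(e[~mask] ** 2))

    # Closed-form starts from extreme interior pairs.
    by_conc = sorted(interior, key=lambda pt: pt.concentration)
    by_eff = sorted(interior, key=lambda pt: pt.effect)
    starts: list[np.ndarray] = []
    for a, b in ((by_conc[0], by_conc[-1]), (by_eff[0], by_eff[-1])):
        try:
            guess = fit_two_point(a, b)
        except ValueError:
            continue
        starts.append(np.array([math.log10(guess.ec50), math.log10(guess.p)]))
    if not starts:
        starts.append(np.array([math.log10(np.median(c[mask])), 0.0]))
    rng = np.random.default_rng(seed)
    base = starts[0]
    while len(starts) < n_starts:
        starts.append(base + rng.normal(scale=[0.5, 0.3]))

    bounds = [_LOG_EC50_BOUNDS, _LOG_SLOPE_BOUNDS]
    best_theta, best_loss = None, np.inf
    for theta0 in starts:
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            loss,
            theta0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-12, "fatol": 1e-16, "maxfev": 4000},
        )
        if res.fun < best_loss:
            best_loss, best_theta = res.fun, res.x
    assert best_theta is not None
    return HillParams(10.0 ** best_theta[0], 10.0 ** best_theta[1])
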