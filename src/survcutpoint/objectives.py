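"""ROC objective functions and their theoretical values under known marker laws.

Three classical criteria select a cut-point from a (SE, SP) curve:

* Youden: J(c) = SE(c) + SP(c) - 1, maximized; the vertical distance of
  the ROC curve from the chance line.
* Concordance probability: CZ(c) = SE(c) * SP(c), maximized; the area of
  the rectangle inscribed at the operating point.
* Closest-to-corner: ER(c) = sqrt((1-SE)^2 + (1-SP)^2), minimized; the
  Euclidean distance from (1-SP, SE) to the perfect point (0, 1).

When the marker is homoscedastic normal in diseased (mean mu, unit
variance) and disease-free (standard normal) subjects, all three reach
their optimum at the same c = mu/2. Under the gamma scenario — diseased
G(shape 2.5, scale beta) vs disease-free G(shape 1.5, scale 1) — the
three optima differ and are found numerically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .estimators import OperatingPoint
from .exceptions import EstimationError, InvalidInputError

__all__ = [
    "ObjectiveKind",
    "MarkerScenarioLaw",
    "youden",
    "concordance",
    "corner_distance",
    "theoretical_se_sp",
    "true_optimal_cutpoint",
]

# fixed shape parameters of the gamma scenario; only the diseased scale varies
GAMMA_DISEASED_SHAPE = 2.5
GAMMA_FREE_SHAPE = 1.5
GAMMA_FREE_SCALE = 1.0


class ObjectiveKind(enum.Enum):
    """One of the three cut-point selection criteria, with its direction."""

    YOUDEN = "youden"
    CONCORDANCE = "concordance"
    CORNER_DISTANCE = "corner_distance"

    @property
    def direction(self) -> str:
        return "minimize" if self is ObjectiveKind.CORNER_DISTANCE else "maximize"

    def evaluate(self, se, sp):
        """Vectorized objective value for arrays (or scalars) of SE and SP."""
        se = np.asarray(se, dtype=float)
        sp = np.asarray(sp, dtype=float)
        if self is ObjectiveKind.YOUDEN:
            return se + sp - 1.0
        if self is ObjectiveKind.CONCORDANCE:
            return se * sp
        return np.sqrt((1.0 - se) ** 2 + (1.0 - sp) ** 2)

    def better(self, a: float, b: float) -> bool:
        """True if objective value ``a`` is strictly better than ``b``."""
        return a < b if self.direction == "minimize" else a > b


def _as_point(point: OperatingPoint) -> OperatingPoint:
    if not isinstance(point, OperatingPoint):
        raise InvalidInputError("expected an OperatingPoint")
    return point


def youden(point: OperatingPoint) -> float:
    """J = SE + SP - 1, in [-1, 1]."""
    p = _as_point(point)
    return p.se + p.sp - 1.0


def concordance(point: OperatingPoint) -> float:
    """CZ = SE * SP, in [0, 1]."""
    p = _as_point(point)
    return p.se * p.sp


def corner_distance(point: OperatingPoint) -> float:
    """ER = Euclidean distance of (1-SP, SE) from the (0, 1) corner, in [0, sqrt(2)]."""
    p = _as_point(point)
    return math.hypot(1.0 - p.se, 1.0 - p.sp)


@dataclass(frozen=True)
class MarkerScenarioLaw:
    """Conditional marker distributions for diseased vs disease-free subjects.

    family "normal_homoscedastic": diseased ~ N(diseased_param, 1),
    disease-free ~ N(0, 1). family "gamma": diseased ~ G(2.5, scale
    diseased_param), disease-free ~ G(1.5, scale 1).
    """

    family: str
    diseased_param: float

    def __post_init__(self) -> None:
        if self.family not in ("normal_homoscedastic", "gamma"):
            raise InvalidInputError(f"unknown marker family {self.family!r}")
        if self.family == "gamma" and self.diseased_param <= 0:
            raise InvalidInputError("gamma scale must be positive")

    def diseased_dist(self):
        if self.family == "normal_homoscedastic":
            return stats.norm(loc=self.diseased_param, scale=1.0)
        return stats.gamma(a=GAMMA_DISEASED_SHAPE, scale=self.diseased_param)

    def disease_free_dist(self):
        if self.family == "normal_homoscedastic":
            return stats.norm(loc=0.0, scale=1.0)
        return stats.gamma(a=GAMMA_FREE_SHAPE, scale=GAMMA_FREE_SCALE)


def theoretical_se_sp(law: MarkerScenarioLaw, cutpoint: float) -> OperatingPoint:
    """Population (SE, SP) at a cut-point: upper tail of the diseased law,
    lower tail of the disease-free law."""
    se = float(law.diseased_dist().sf(cutpoint))
    sp = float(law.disease_free_dist().cdf(cutpoint))
    return OperatingPoint(se=se, sp=sp)


def _theoretical_objective(law: MarkerScenarioLaw, objective: ObjectiveKind):
    d, f = law.diseased_dist(), law.disease_free_dist()

    def value(c):
        return objective.evaluate(d.sf(c), f.cdf(c))

    return value


def true_optimal_cutpoint(
    law: MarkerScenarioLaw, objective: ObjectiveKind, *, xtol: float = 1e-8
) -> float:
    """Population-optimal cut-point for an objective under a marker law.

    Normal homoscedastic family: the three criteria share the closed-form
    optimum mu/2 (the crossing point of the two densities). Gamma family:
    grid scan plus bounded scalar refinement over (0, q_0.9999 of the
    wider law); the gamma objectives can have a shoulder near the origin,
    so the scan guards against landing in a secondary basin.
    """
    if not isinstance(objective, ObjectiveKind):
        raise InvalidInputError("objective must be an ObjectiveKind")
    if law.family == "normal_homoscedastic":
        return law.diseased_param / 2.0

    value = _theoretical_objective(law, objective)
    sign = -1.0 if objective.direction == "maximize" else 1.0
    hi = float(max(law.diseased_dist().ppf(0.9999), law.disease_free_dist().ppf(0.9999)))
    grid = np.linspace(1e-9, hi, 4001)
    best = int(np.argmin(sign * value(grid)))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda c: sign * float(value(c)), bounds=(lo_b, hi_b), method="bounded", options={"xatol": xtol}
    )
    if not res.success:
        raise EstimationError(f"cut-point optimization failed: {res.message}")
    return float(res.x)
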