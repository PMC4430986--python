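"""Empirical cut-point search, ROC reporting and the operating-point ellipse.

The optimizer evaluates the censoring-adjusted (SE, SP) at every
candidate cut-point — the sorted distinct observed marker values, the
maximum excluded so the test-positive group is never empty — and picks
the candidate optimizing the requested objective, smallest candidate on
ties. Because the classification rule is X <= c vs X > c, any cut-point
between consecutive order statistics is equivalent to the lower one, so
this grid is exhaustive.

The hot path (:func:`se_sp_curve`) computes all candidates at once:
subjects are sorted by marker, and prefix cumulative at-risk and death
counts over the distinct event times before tau yield the two
product-limit survival estimates of every split simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .estimators import OperatingPoint, SurvivalSample, se_sp_at_cutpoint
from .exceptions import (
    ConstantMarkerError,
    EstimationError,
    InvalidInputError,
    LogitBoundaryError,
    NoAdmissibleCutpointError,
    NoEventsBeforeHorizonError,
    NoSurvivorsAtHorizonError,
)
from .objectives import ObjectiveKind

__all__ = [
    "CutpointResult",
    "ROCCurve",
    "OperatingPointEllipse",
    "candidate_cutpoints",
    "se_sp_curve",
    "select_from_curve",
    "find_cutpoint",
    "empirical_roc",
    "operating_point_ellipse",
]


@dataclass(frozen=True)
class CutpointResult:
    """An estimated cut-point with its objective value and operating point."""

    cutpoint: float
    objective: ObjectiveKind
    objective_value: float
    operating_point: OperatingPoint
    n_candidates: int
    skipped_candidates: int


@dataclass(frozen=True)
class ROCCurve:
    """Empirical time-dependent ROC: (cut-point, FPF, TPF) per admissible candidate."""

    cutpoints: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray

    def __len__(self) -> int:
        return self.cutpoints.size


@dataclass(frozen=True)
class OperatingPointEllipse:
    """Joint confidence region for (FPF, TPF), elliptic on the logit scale."""

    center: tuple[float, float]  # (logit FPF, logit TPF)
    covariance: np.ndarray  # 2x2, of the logit pair
    confidence_level: float
    boundary: np.ndarray  # closed polyline of (fpf, tpf) rows
    n_effective: int  # bootstrap replicates behind the covariance

    def contains(self, fpf: float, tpf: float) -> bool:
        """Mahalanobis test on the logit scale at the chi-square(2) radius."""
        if not (0.0 < fpf < 1.0 and 0.0 < tpf < 1.0):
            return False
        d = np.array([logit(fpf) - self.center[0], logit(tpf) - self.center[1]])
        try:
            m2 = float(d @ np.linalg.solve(self.covariance, d))
        except np.linalg.LinAlgError:
            m2 = float(d @ np.linalg.pinv(self.covariance) @ d)
        return m2 <= stats.chi2.ppf(self.confidence_level, df=2)


def candidate_cutpoints(sample: SurvivalSample) -> np.ndarray:
    """Sorted distinct marker values, maximum excluded (X > c must be non-empty)."""
    distinct = np.unique(sample.marker)
    if distinct.size < 2:
        raise ConstantMarkerError("constant marker: no cut-point can split the sample")
    return distinct[:-1]


def se_sp_curve(sample: SurvivalSample, tau: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(candidates, SE, SP) at every candidate cut-point, NaN where inadmissible.

    Vectorized over candidates: equivalent to calling
    :func:`survcutpoint.estimators.se_sp_at_cutpoint` per candidate.
    """
    tau = float(tau)
    if tau <= 0:
        raise InvalidInputError(f"tau must be positive, got {tau}")
    candidates = candidate_cutpoints(sample)

    order = np.argsort(sample.marker, kind="stable")
    t = sample.time[order]
    e = sample.event[order].astype(bool)
    marker_sorted = sample.marker[order]
    n = sample.n

    event_times = np.unique(t[e & (t <= tau)])
    if event_times.size == 0:
        raise NoEventsBeforeHorizonError(f"no observed events by tau={tau}")

    # prefix (in marker order) at-risk and death counts at each event time
    at_risk = t[:, None] >= event_times[None, :]
    deaths = (t[:, None] == event_times[None, :]) & e[:, None]
    cum_risk = np.cumsum(at_risk, axis=0, dtype=np.int32)
    cum_death = np.cumsum(deaths, axis=0, dtype=np.int32)
    tot_risk = cum_risk[-1]
    tot_death = cum_death[-1]

    m = np.searchsorted(marker_sorted, candidates, side="right")  # sizes of X <= c
    r_lo = cum_risk[m - 1]
    d_lo = cum_death[m - 1]
    r_hi = tot_risk[None, :] - r_lo
    d_hi = tot_death[None, :] - d_lo

    def survival(d: np.ndarray, r: np.ndarray) -> np.ndarray:
        # where d > 0 the risk set is non-empty (r >= d), so the masked
        # division never sees r == 0
        terms = np.zeros(d.shape)
        np.divide(d, r, out=terms, where=d > 0)
        np.subtract(1.0, terms, out=terms)
        return np.prod(terms, axis=1)

    s_lo = survival(d_lo, r_lo)
    s_hi = survival(d_hi, r_hi)

    n_lo = m.astype(float)
    n_hi = n - n_lo
    exp_dis = (1.0 - s_lo) * n_lo + (1.0 - s_hi) * n_hi
    exp_free = s_lo * n_lo + s_hi * n_hi
    admissible = (exp_dis > 0.0) & (exp_free > 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(admissible, (1.0 - s_hi) * n_hi / exp_dis, np.nan)
        sp = np.where(admissible, s_lo * n_lo / exp_free, np.nan)
    if not admissible.any():
        if np.all(exp_free <= 0.0):
            raise NoSurvivorsAtHorizonError(f"estimated survival at tau={tau} is zero everywhere")
        raise NoAdmissibleCutpointError("every candidate cut-point is inadmissible")
    return candidates, se, sp


def select_from_curve(
    candidates: np.ndarray, se: np.ndarray, sp: np.ndarray, objective: ObjectiveKind
) -> CutpointResult:
    """Pick the objective's optimal candidate off a precomputed (SE, SP) curve.

    Ties — including numerical ties within a relative 1e-9 of the best
    value — are broken by the smallest candidate, so the result does not
    depend on rounding noise in the survival products.
    """
    if not isinstance(objective, ObjectiveKind):
        raise InvalidInputError("objective must be an ObjectiveKind")
    values = objective.evaluate(se, sp)
    skipped = int(np.isnan(values).sum())
    if objective.direction == "maximize":
        v_best = np.nanmax(values)
    else:
        v_best = np.nanmin(values)
    atol = 1e-9 * max(1.0, abs(float(v_best)))
    with np.errstate(invalid="ignore"):
        tied = np.abs(values - v_best) <= atol
    best = int(np.flatnonzero(tied)[0])
    return CutpointResult(
        cutpoint=float(candidates[best]),
        objective=objective,
        objective_value=float(values[best]),
        operating_point=OperatingPoint(se=float(se[best]), sp=float(sp[best])),
        n_candidates=int(candidates.size),
        skipped_candidates=skipped,
    )


def find_cutpoint(sample: SurvivalSample, tau: float, objective: ObjectiveKind) -> CutpointResult:
    """Optimize one objective over all candidate cut-points."""
    candidates, se, sp = se_sp_curve(sample, tau)
    return select_from_curve(candidates, se, sp, objective)


def empirical_roc(sample: SurvivalSample, tau: float) -> ROCCurve:
    """Empirical ROC over admissible candidates, in increasing cut-point order."""
    candidates, se, sp = se_sp_curve(sample, tau)
    keep = ~(np.isnan(se) | np.isnan(sp))
    return ROCCurve(cutpoints=candidates[keep], fpf=1.0 - sp[keep], tpf=se[keep])


def _weighted_group_survival(
    weights: np.ndarray, times: np.ndarray, events: np.ndarray, tau: float
) -> np.ndarray:
    """KM survival at tau for each row of multiplicity weights over one group."""
    event_times = np.unique(times[(events == 1) & (times <= tau)])
    if event_times.size == 0:
        return np.ones(weights.shape[0])
    at_risk = (times[:, None] >= event_times[None, :]).astype(float)
    deaths = ((times[:, None] == event_times[None, :]) & (events[:, None] == 1)).astype(float)
    r = weights @ at_risk
    d = weights @ deaths
    terms = 1.0 - np.where(d > 0, d / np.maximum(r, 1e-300), 0.0)
    return np.prod(terms, axis=1)


def operating_point_ellipse(
    sample: SurvivalSample,
    cutpoint: float,
    tau: float,
    level: float = 0.95,
    n_boot: int = 200,
    seed: int | None = None,
) -> OperatingPointEllipse:
    """Confidence ellipse for (FPF, TPF) at a fixed cut-point.

    The covariance of (logit FPF, logit TPF) is estimated by a
    nonparametric bootstrap at the fixed cut-point (the two estimators
    are correlated under censoring because censored subjects contribute
    to both); the boundary is the chi-square(2 df) contour on the logit
    scale mapped back through the inverse logit.
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"confidence level must be in (0, 1), got {level}")
    if n_boot < 2:
        raise InvalidInputError("n_boot must be at least 2")
    point = se_sp_at_cutpoint(sample, cutpoint, tau)
    fpf_hat, tpf_hat = 1.0 - point.sp, point.se
    if fpf_hat in (0.0, 1.0) or tpf_hat in (0.0, 1.0):
        raise LogitBoundaryError(f"logit undefined at boundary: FPF={fpf_hat}, TPF={tpf_hat}")

    rng = np.random.default_rng(seed)
    n = sample.n
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)

    low = sample.marker <= cutpoint
    w_lo, w_hi = weights[:, low], weights[:, ~low]
    n_lo_b, n_hi_b = w_lo.sum(axis=1), w_hi.sum(axis=1)
    s_lo = _weighted_group_survival(w_lo, sample.time[low], sample.event[low], tau)
    s_hi = _weighted_group_survival(w_hi, sample.time[~low], sample.event[~low], tau)

    exp_dis = (1.0 - s_lo) * n_lo_b + (1.0 - s_hi) * n_hi_b
    exp_free = s_lo * n_lo_b + s_hi * n_hi_b
    valid = (n_lo_b > 0) & (n_hi_b > 0) & (exp_dis > 0) & (exp_free > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b = (1.0 - s_hi) * n_hi_b / exp_dis
        sp_b = s_lo * n_lo_b / exp_free
    fpf_b, tpf_b = 1.0 - sp_b, se_b
    valid &= (fpf_b > 0) & (fpf_b < 1) & (tpf_b > 0) & (tpf_b < 1)
    if valid.sum() < 2:
        raise EstimationError("too few valid bootstrap replicates to estimate the covariance")

    logits = np.column_stack([logit(fpf_b[valid]), logit(tpf_b[valid])])
    cov = np.cov(logits, rowvar=False)

    center = (float(logit(fpf_hat)), float(logit(tpf_hat)))
    radius = np.sqrt(stats.chi2.ppf(level, df=2))
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval, 0.0, None)
    theta = np.linspace(0.0, 2.0 * np.pi, 181)
    circle = np.vstack([np.cos(theta), np.sin(theta)])
    pts = (eigvec @ (np.sqrt(eigval)[:, None] * circle)) * radius
    boundary = expit(pts.T + np.asarray(center))
    return OperatingPointEllipse(
        center=center,
        covariance=cov,
        confidence_level=level,
        boundary=boundary,
        n_effective=int(valid.sum()),
    )
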