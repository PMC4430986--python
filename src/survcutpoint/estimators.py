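"""Censoring-adjusted sensitivity and specificity at a fixed time horizon.

A continuous baseline biomarker X is dichotomized at a cut-point c
(test-positive means X > c). A subject is "diseased" if their event time
Z is at most the clinical horizon tau and "disease-free" otherwise.
Under right censoring the disease status of subjects censored before tau
is unknown, so the naive 2x2 proportions are not estimable. Instead, the
sample is split at c and the Kaplan-Meier survival at tau within each
marker group apportions every subject into expected diseased /
disease-free counts; sensitivity and specificity are simple proportions
of those expected counts:

    SE(c) = (1 - S_hi(tau)) n_hi / [(1 - S_lo(tau)) n_lo + (1 - S_hi(tau)) n_hi]
    SP(c) =       S_lo(tau) n_lo / [      S_lo(tau) n_lo +       S_hi(tau) n_hi]

where S_lo, S_hi are product-limit estimates in the groups X <= c and
X > c. With no censoring before tau the estimators reduce exactly to the
binary-outcome proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateCutpointError,
    EmptyStratumError,
    InvalidInputError,
    NoEventsBeforeHorizonError,
    NoSurvivorsAtHorizonError,
)

__all__ = [
    "SurvivalSample",
    "TauClassCounts",
    "ExpectedEventsMatrix",
    "OperatingPoint",
    "classify_by_tau",
    "km_survival_at",
    "expected_events_matrix",
    "se_sp_at_cutpoint",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored sample: marker X, observed time T = min(Z, C), event flag delta.

    Arrays are aligned per subject. ``event == 1`` means the event time was
    observed (T = Z); ``event == 0`` means the subject was censored at T.
    """

    marker: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        marker = np.asarray(self.marker, dtype=float)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if not (marker.shape == time.shape == event.shape) or marker.ndim != 1:
            raise InvalidInputError("marker, time and event must be equal-length 1-d arrays")
        if marker.size < 2:
            raise InvalidInputError("a survival sample needs at least two subjects")
        if not np.all(np.isfinite(marker)):
            raise InvalidInputError("marker values must be finite")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise InvalidInputError("times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise InvalidInputError("event indicators must be 0 or 1")
        object.__setattr__(self, "marker", marker)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))

    @property
    def n(self) -> int:
        return self.marker.size

    def subset(self, indices: np.ndarray) -> "SurvivalSample":
        """Row-select (with repetition allowed), e.g. for bootstrap resampling."""
        idx = np.asarray(indices)
        return SurvivalSample(self.marker[idx], self.time[idx], self.event[idx])


@dataclass(frozen=True)
class TauClassCounts:
    """Disease-status breakdown at the horizon (the three observable subgroups)."""

    n_disease_free: int  # T > tau, regardless of delta
    n_diseased: int  # T <= tau and delta = 1
    n_censored_by_tau: int  # T <= tau and delta = 0

    @property
    def total(self) -> int:
        return self.n_disease_free + self.n_diseased + self.n_censored_by_tau


@dataclass(frozen=True)
class OperatingPoint:
    """A (sensitivity, specificity) pair; both probabilities in [0, 1]."""

    se: float
    sp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.se <= 1.0 and 0.0 <= self.sp <= 1.0):
            raise InvalidInputError(f"SE/SP must lie in [0, 1], got ({self.se}, {self.sp})")


@dataclass(frozen=True)
class ExpectedEventsMatrix:
    """KM-weighted 2x2 table of expected diseased / disease-free counts at (c, tau)."""

    tau: float
    cutpoint: float
    n_low: int
    n_high: int
    s_low: float  # KM survival at tau in the X <= c group
    s_high: float  # KM survival at tau in the X > c group
    diseased_low: float = field(init=False)
    diseased_high: float = field(init=False)
    free_low: float = field(init=False)
    free_high: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseased_low", (1.0 - self.s_low) * self.n_low)
        object.__setattr__(self, "diseased_high", (1.0 - self.s_high) * self.n_high)
        object.__setattr__(self, "free_low", self.s_low * self.n_low)
        object.__setattr__(self, "free_high", self.s_high * self.n_high)

    @property
    def total_diseased(self) -> float:
        return self.diseased_low + self.diseased_high

    @property
    def total_disease_free(self) -> float:
        return self.free_low + self.free_high


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not np.isfinite(tau) or tau <= 0:
        raise InvalidInputError(f"tau must be a positive finite number, got {tau}")
    return tau


def classify_by_tau(sample: SurvivalSample, tau: float) -> TauClassCounts:
    """Count disease-free, diseased and censored-before-tau subjects."""
    tau = _check_tau(tau)
    free = sample.time > tau
    diseased = (sample.time <= tau) & (sample.event == 1)
    censored = (sample.time <= tau) & (sample.event == 0)
    return TauClassCounts(int(free.sum()), int(diseased.sum()), int(censored.sum()))


def km_survival_at(times, events, tau: float) -> float:
    """Kaplan-Meier product-limit survival probability evaluated at ``tau``.

    Right-continuous; if the largest observed time in the group is below
    ``tau`` the last computed value is carried forward. Censored subjects
    tied with events at the same time are kept in the risk set for that
    time (the standard convention).
    """
    tau = _check_tau(tau)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise EmptyStratumError("empty stratum: Kaplan-Meier undefined")
    if times.shape != events.shape:
        raise InvalidInputError("times and events must have matching shapes")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order].astype(bool)
    event_times = np.unique(t_sorted[e_sorted & (t_sorted <= tau)])
    if event_times.size == 0:
        return 1.0
    # risk set at t: subjects with T >= t; deaths at t: events with T == t
    at_risk = times.size - np.searchsorted(t_sorted, event_times, side="left")
    deaths = np.searchsorted(t_sorted[e_sorted], event_times, side="right") - np.searchsorted(
        t_sorted[e_sorted], event_times, side="left"
    )
    return float(np.prod(1.0 - deaths / at_risk))


def expected_events_matrix(sample: SurvivalSample, cutpoint: float, tau: float) -> ExpectedEventsMatrix:
    """KM-weighted expected 2x2 classification table at a cut-point."""
    tau = _check_tau(tau)
    cutpoint = float(cutpoint)
    low = sample.marker <= cutpoint
    n_low = int(low.sum())
    n_high = sample.n - n_low
    if n_low == 0 or n_high == 0:
        raise DegenerateCutpointError(
            f"cut-point {cutpoint} leaves an empty marker group (n_low={n_low}, n_high={n_high})"
        )
    s_low = km_survival_at(sample.time[low], sample.event[low], tau)
    s_high = km_survival_at(sample.time[~low], sample.event[~low], tau)
    return ExpectedEventsMatrix(tau=tau, cutpoint=cutpoint, n_low=n_low, n_high=n_high, s_low=s_low, s_high=s_high)


def se_sp_at_cutpoint(sample: SurvivalSample, cutpoint: float, tau: float) -> OperatingPoint:
    """Censoring-adjusted (SE, SP) at one cut-point, via the expected-events table."""
    m = expected_events_matrix(sample, cutpoint, tau)
    if m.total_diseased <= 0.0:
        raise NoEventsBeforeHorizonError(f"no expected events before tau={tau}: SE undefined")
    if m.total_disease_free <= 0.0:
        raise NoSurvivorsAtHorizonError(f"no expected survivors at tau={tau}: SP undefined")
    se = m.diseased_high / m.total_diseased
    sp = m.free_low / m.total_disease_free
    return OperatingPoint(se=float(se), sp=float(sp))
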