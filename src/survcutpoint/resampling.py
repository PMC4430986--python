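"""Bootstrap uncertainty for the estimated cut-point.

Nonparametric case resampling: draw ``n_boot`` samples of N records with
replacement, re-run the cut-point search on each, and summarize the
replicate distribution by its standard deviation and a percentile
confidence interval (nearest-order-statistic quantiles, no
interpolation). Replicates on which estimation fails — e.g. a resample
with no events before the horizon — are dropped and counted rather than
redrawn, so the resampling distribution is not biased toward easy
resamples; if more than half fail the result is refused as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cutfinder import find_cutpoint
from .estimators import SurvivalSample
from .exceptions import BootstrapUnstableError, EstimationError, InvalidInputError
from .objectives import ObjectiveKind

__all__ = ["BootstrapResult", "bootstrap_cutpoint"]

DEFAULT_N_BOOT = 200  # simulation-study default; prefer >= 999 on real data


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate summary: SD and percentile CI of the cut-point estimate."""

    sd_b: float
    ci_low: float
    ci_high: float
    n_requested: int
    n_effective: int
    level: float
    replicate_cutpoints: np.ndarray


def bootstrap_cutpoint(
    sample: SurvivalSample,
    tau: float,
    objective: ObjectiveKind,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap SD and percentile CI for the estimated cut-point.

    With the default ``level=0.95`` the interval is the 0.025 and 0.975
    empirical quantiles of the replicate cut-points. Fully reproducible
    for a fixed (sample, seed, n_boot).
    """
    if n_boot < 2:
        raise InvalidInputError("n_boot must be at least 2")
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"confidence level must be in (0, 1), got {level}")
    find_cutpoint(sample, tau, objective)  # the original estimate must exist

    rng = np.random.default_rng(seed)
    replicates = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, sample.n, size=sample.n)
        try:
            replicates.append(find_cutpoint(sample.subset(idx), tau, objective).cutpoint)
        except EstimationError:
            n_failed += 1
    if n_failed > n_boot // 2:
        raise BootstrapUnstableError(
            f"bootstrap unstable: {n_failed}/{n_boot} replicates failed to estimate"
        )
    reps = np.asarray(replicates)
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(reps, [alpha, 1.0 - alpha], method="inverted_cdf")
    sd = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
    return BootstrapResult(
        sd_b=sd,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_requested=n_boot,
        n_effective=int(reps.size),
        level=level,
        replicate_cutpoints=reps,
    )
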