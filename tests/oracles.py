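"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid every code path of the package under test: the
binary-outcome proportions are computed by direct counting, the
product-limit estimate by an explicit loop over distinct times, and the
cut-point search by a plain Python scan.
"""

import numpy as np

from survcutpoint import ObjectiveKind, SurvivalSample


def km_brute_force(times, events, tau: float) -> float:
    """Product-limit survival at tau via an explicit loop."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    surv = 1.0
    for t in sorted(set(times[(events == 1) & (times <= tau)])):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - deaths / at_risk
    return surv


def naive_se_sp(sample: SurvivalSample, cutpoint: float, tau: float):
    """Binary-outcome SE/SP; valid only when no subject is censored before tau."""
    diseased = sample.time <= tau  # all events observed by assumption
    positive = sample.marker > cutpoint
    se = (positive & diseased).sum() / diseased.sum()
    sp = (~positive & ~diseased).sum() / (~diseased).sum()
    return float(se), float(sp)


def brute_force_cutpoint(sample: SurvivalSample, tau: float, objective: ObjectiveKind) -> float:
    """Scan all candidates with the naive proportions; smallest candidate among
    optima tied within a relative 1e-9."""
    values = []
    for c in sorted(set(sample.marker))[:-1]:
        se, sp = naive_se_sp(sample, c, tau)
        if objective is ObjectiveKind.YOUDEN:
            v = se + sp - 1
        elif objective is ObjectiveKind.CONCORDANCE:
            v = se * sp
        else:
            v = -(((1 - se) ** 2 + (1 - sp) ** 2) ** 0.5)
        values.append((c, v))
    best = max(v for _, v in values)
    atol = 1e-9 * max(1.0, abs(best))
    return float(min(c for c, v in values if v >= best - atol))
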