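"""Trial-level efficacy statistics.

Response summaries (objective response rate, disease control rate),
CA19-9 decline classification, Kaplan-Meier survival with log-rank
comparison (delegating to lifelines), and an exact Simon two-stage
phase-II design calculator with binomial operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import binom

from .cellmap_io import RESPONSE_LEVELS


@dataclass(frozen=True)
class ResponseSummary:
    """Best-overall-response tallies with ORR and DCR percentages.

    ORR counts complete plus partial responses (CR + PR); DCR additionally
    counts stable disease (CR + PR + SD).  Percentages are reported to one
    decimal, as trial reports print them.
    """

    n: int
    counts: Mapping[str, int]
    orr_percent: float
    dcr_percent: float


def summarize_response(best_responses: Iterable[str]) -> ResponseSummary:
    values = list(best_responses)
    if not values:
        raise ValueError("no responses to summarize")
    bad = set(values) - set(RESPONSE_LEVELS)
    if bad:
        raise ValueError(f"unknown response levels: {sorted(bad)}")
    counts = {lvl: values.count(lvl) for lvl in RESPONSE_LEVELS}
    n = len(values)
    orr = 100.0 * (counts["CR"] + counts["PR"]) / n
    dcr = 100.0 * (counts["CR"] + counts["PR"] + counts["SD"]) / n
    return ResponseSummary(
        n=n, counts=counts,
        orr_percent=round(orr, 1), dcr_percent=round(dcr, 1),
    )


@dataclass(frozen=True)
class CA199Decline:
    """Counts of evaluable patients meeting per-threshold CA19-9 declines."""

    n_evaluable: int
    n_excluded: int
    counts: Mapping[float, int]        # threshold (%) -> patients meeting it
    percents: Mapping[float, float]    # threshold (%) -> 100*count/evaluable


def ca199_decline(
    records: pd.DataFrame,
    thresholds: Sequence[float] = (20.0, 90.0),
) -> CA199Decline:
    """Classify relative CA19-9 decline, ``100*(baseline-nadir)/baseline``.

    Patients lacking baseline or nadir, or with baseline 0, are
    non-evaluable and excluded (counted in ``n_excluded``).  Negative
    concentrations raise.
    """
    baseline = pd.to_numeric(records["ca199_baseline"], errors="raise")
    nadir = pd.to_numeric(records["ca199_nadir"], errors="raise")
    if (baseline.dropna() < 0).any() or (nadir.dropna() < 0).any():
        raise ValueError("negative CA19-9 concentration")
    evaluable = baseline.notna() & nadir.notna() & (baseline > 0)
    decline = 100.0 * (baseline[evaluable] - nadir[evaluable]) / baseline[evaluable]
    n_eval = int(evaluable.sum())
    counts = {float(t): int((decline >= t).sum()) for t in thresholds}
    percents = {
        t: round(100.0 * c / n_eval, 1) if n_eval else float("nan")
        for t, c in counts.items()
    }
    return CA199Decline(
        n_evaluable=n_eval,
        n_excluded=int(len(records) - n_eval),
        counts=counts,
        percents=percents,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood (log-log) confidence bands.

    ``median`` follows the standard convention — the smallest observed time
    with S(t) <= 0.5 — and is ``inf`` when never reached.
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: Tuple[float, float]
    landmark_survival: Dict[float, float]


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    landmarks: Sequence[float] = (),
    alpha: float = 0.05,
) -> SurvivalCurve:
    """Kaplan-Meier estimate via lifelines with landmark-rate lookups."""
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival time")
    e = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    ci = kmf.confidence_interval_survival_function_
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()

    def _first_crossing(values: np.ndarray) -> float:
        # smallest observed time with the step function <= 0.5
        hit = np.flatnonzero(values <= 0.5 + 1e-12)
        return float(timeline[hit[0]]) if len(hit) else float("inf")

    median = _first_crossing(surv)
    lo = _first_crossing(ci.iloc[:, 0].to_numpy())
    hi = _first_crossing(ci.iloc[:, 1].to_numpy())
    landmark = {
        float(lm): float(kmf.predict(lm)) for lm in landmarks
    }
    return SurvivalCurve(
        timeline=timeline,
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=kmf.event_table["at_risk"].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=median,
        median_ci=(lo, hi),
        landmark_survival=landmark,
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> Tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p.

    With no events in either group the statistic is 0 and p is 1.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


# ---------------------------------------------------------------------------
# Simon two-stage design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimonDesign:
    """A two-stage single-arm design with exact operating characteristics.

    Stage 1 enrols ``n1`` patients and stops for futility when successes
    are <= ``r1``; otherwise enrolment continues to ``n`` total and the
    null is rejected when total successes exceed ``r``.  ``pet0`` is the
    early-termination probability and ``en0`` the expected sample size,
    both under ``p0``.
    """

    p0: float
    p1: float
    alpha: float
    beta: float
    r1: int
    n1: int
    r: int
    n: int
    pet0: float
    en0: float
    attained_alpha: float
    attained_power: float
    criterion: str


def evaluate_two_stage(
    r1: int, n1: int, r: int, n: int, p: float
) -> Tuple[float, float, float]:
    """Exact (PET, P(reject), E[N]) of a two-stage design at true rate ``p``.

    PET = P(X1 <= r1); rejection requires passing stage 1 and total
    successes X1 + X2 > r; E[N] = n1 + (1 - PET) * (n - n1).
    """
    if not (0 <= r1 < n1 < n and r1 <= r <= n):
        raise ValueError(f"invalid design (r1={r1}, n1={n1}, r={r}, n={n})")
    n2 = n - n1
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = binom.pmf(x1, n1, p)
    # P(X2 > r - x1) with X2 ~ Bin(n2, p); sf(k) = P(X > k)
    reject = float((pmf1 * binom.sf(r - x1, n2, p)).sum())
    pet = float(binom.cdf(r1, n1, p))
    en = n1 + (1.0 - pet) * n2
    return pet, reject, en


def simon_two_stage(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    beta: float = 0.20,
    criterion: str = "optimal",
    n_max: int = 100,
) -> SimonDesign:
    """Exhaustive exact search for the Simon two-stage design.

    Feasible designs satisfy attained type-I error <= ``alpha`` (one-sided)
    and power >= ``1 - beta`` at ``p1``.  ``criterion`` "optimal" minimizes
    the expected sample size under the null (EN0); "minimax" minimizes the
    maximum sample size ``n`` (ties by EN0).  Raises when no design up to
    ``n_max`` is feasible.
    """
    if not 0 < p0 < p1 < 1:
        raise ValueError("need 0 < p0 < p1 < 1")
    if criterion not in ("optimal", "minimax"):
        raise ValueError("criterion must be 'optimal' or 'minimax'")
    power_target = 1.0 - beta

    best: Optional[SimonDesign] = None
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            x1 = np.arange(0, n1 + 1)
            pmf0 = binom.pmf(x1, n1, p0)
            pmf1 = binom.pmf(x1, n1, p1)
            cdf0 = binom.cdf(x1, n1, p0)
            r_grid = np.arange(0, n + 1)
            # A[x1, r] = pmf(x1) * P(X2 > r - x1)
            sf0 = binom.sf(r_grid[None, :] - x1[:, None], n2, p0)
            sf1 = binom.sf(r_grid[None, :] - x1[:, None], n2, p1)
            A0 = pmf0[:, None] * sf0
            A1 = pmf1[:, None] * sf1
            # suffix sums over x1 > r1
            S0 = A0[::-1].cumsum(axis=0)[::-1]
            S1 = A1[::-1].cumsum(axis=0)[::-1]
            for r1 in range(0, n1):
                # reject prob = sum_{x1 = r1+1..n1} A[x1, r]
                rej0 = S0[r1 + 1]
                rej1 = S1[r1 + 1]
                feas = np.flatnonzero(
                    (rej0 <= alpha + 1e-12) & (rej1 >= power_target - 1e-12)
                    & (r_grid >= r1)
                )
                if len(feas) == 0:
                    continue
                r = int(feas[0])  # smallest feasible r (max power, same EN0)
                pet0 = float(cdf0[r1])
                en0 = n1 + (1.0 - pet0) * n2
                cand = SimonDesign(
                    p0=p0, p1=p1, alpha=alpha, beta=beta,
                    r1=r1, n1=n1, r=r, n=n,
                    pet0=pet0, en0=float(en0),
                    attained_alpha=float(rej0[r]),
                    attained_power=float(rej1[r]),
                    criterion=criterion,
                )
                if best is None or _better(cand, best, criterion):
                    best = cand
    if best is None:
        raise ValueError(f"no feasible design with n <= {n_max}")
    return best


def _better(a: SimonDesign, b: SimonDesign, criterion: str) -> bool:
    if criterion == "optimal":
        return (a.en0, a.n, a.n1) < (b.en0, b.n, b.n1)
    return (a.n, a.en0, a.n1) < (b.n, b.en0, b.n1)
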