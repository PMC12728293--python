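"""Product-limit survival curves and log-rank comparisons.

Implements the Kaplan–Meier estimator with Greenwood variance, the k-group
log-rank test with its asymptotic chi-squared reference, a replicate-tank
pooling pre-check, and Bonferroni-corrected pairwise comparisons, directly
from the standard formulas.

Tie convention (test-pinned): deaths at the same time are aggregated into a
single d_i/n_i factor; an individual censored at the same time as a death is
still in the risk set for that death — censoring is processed after deaths.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "PairwiseLogRank",
    "km_estimate",
    "log_rank",
    "tank_pooling_check",
    "pairwise_logrank_bonferroni",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's observation time and outcome (1 death, 0 censored)."""

    individual: str
    tank: str
    treatment: str
    time: float  # d
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("observation time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate at the distinct death times."""

    times: np.ndarray  # distinct death times, ascending
    survival: np.ndarray  # S(t) just after each death time
    variance: np.ndarray  # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def ci_at(self, t: float, alpha: float = 0.05) -> tuple[float, float]:
        """Plain (linear) Greenwood confidence interval, clipped to [0, 1]."""
        idx = np.searchsorted(self.times, t, side="right")
        if idx == 0:
            return 1.0, 1.0
        s = float(self.survival[idx - 1])
        se = float(np.sqrt(self.variance[idx - 1]))
        z = _sps.norm.ppf(1 - alpha / 2)
        return max(0.0, s - z * se), min(1.0, s + z * se)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    groups: tuple[str, ...]
    observed: np.ndarray = field(default=None, repr=False)
    expected: np.ndarray = field(default=None, repr=False)


def _times_events(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    t = np.asarray([r.time for r in recs], float)
    e = np.asarray([r.event for r in recs], int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier estimate S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ) with Greenwood
    variance S(t)² Σ dᵢ / (nᵢ(nᵢ − dᵢ))."""
    if not records:
        raise ValueError("no survival records")
    t, e = _times_events(records)
    death_times = np.unique(t[e == 1])
    n = t.size
    surv, var_sum = [], []
    s, g = 1.0, 0.0
    n_risk, n_ev = [], []
    for dt in death_times:
        at_risk = int(np.sum(t >= dt))  # censored at dt still at risk
        d = int(np.sum((t == dt) & (e == 1)))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            g += d / (at_risk * (at_risk - d))
        else:
            g = np.inf  # S hits 0; variance degenerate
        surv.append(s)
        var_sum.append(g)
        n_risk.append(at_risk)
        n_ev.append(d)
    surv_arr = np.asarray(surv)
    gsum = np.asarray(var_sum)
    var = np.zeros_like(surv_arr)
    finite = np.isfinite(gsum)
    var[finite] = surv_arr[finite] ** 2 * gsum[finite]
    return KMCurve(
        times=death_times,
        survival=surv_arr,
        variance=var,
        n_at_risk=np.asarray(n_risk),
        n_events=np.asarray(n_ev),
        n_total=n,
    )


def log_rank(groups: dict[str, Sequence[SurvivalRecord]]) -> LogRankResult:
    """k-group log-rank test.

    At each distinct death time, the deaths expected in group g under the
    null are d · n_g/n; the statistic is (O−E)' V⁻¹ (O−E) over the first
    k−1 groups with the hypergeometric covariance

        V_gh = Σ_t d(n−d)/(n−1) · (δ_gh n_g/n − n_g n_h/n²).

    With no events the statistic is undefined; returns chi2 = 0, p = 1 with
    a warning.
    """
    codes = tuple(groups.keys())
    k = len(codes)
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    times = {c: _times_events(groups[c]) for c in codes}
    all_t = np.concatenate([times[c][0] for c in codes])
    all_e = np.concatenate([times[c][1] for c in codes])
    death_times = np.unique(all_t[all_e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for dt in death_times:
        n_g = np.array([np.sum(times[c][0] >= dt) for c in codes], float)
        d_g = np.array(
            [np.sum((times[c][0] == dt) & (times[c][1] == 1)) for c in codes],
            float,
        )
        n, d = n_g.sum(), d_g.sum()
        if n <= 1:
            continue
        observed += d_g
        expected += d * n_g / n
        c = d * (n - d) / (n - 1.0)
        V += c * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)
    if death_times.size == 0:
        warnings.warn("no events in any group; log-rank undefined", stacklevel=2)
        return LogRankResult(0.0, k - 1, 1.0, codes, observed, expected)
    diff = (observed - expected)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(_sps.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2, k - 1, p, codes, observed, expected)


def _by(records: Iterable[SurvivalRecord], attr: str) -> dict[str, list[SurvivalRecord]]:
    out: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        out.setdefault(getattr(r, attr), []).append(r)
    return out


@dataclass
class TankPoolingDecision:
    per_treatment_p: dict[str, float]
    min_p: float
    pooled: bool
    notes: list[str]


def tank_pooling_check(
    records: Sequence[SurvivalRecord], alpha: float = 0.05
) -> TankPoolingDecision:
    """Within-treatment replicate-tank log-rank pre-check.

    Pooling the replicate tanks of every treatment is approved iff the
    smallest within-treatment p-value exceeds ``alpha``.  A treatment with a
    single tank is trivially poolable (noted); a tank without records is an
    error.
    """
    notes: list[str] = []
    per_p: dict[str, float] = {}
    for code, recs in _by(records, "treatment").items():
        tanks = _by(recs, "tank")
        if any(len(v) == 0 for v in tanks.values()):
            raise ValueError(f"treatment {code}: empty tank")
        if len(tanks) < 2:
            notes.append(f"treatment {code}: single tank, trivially pooled")
            per_p[code] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_p[code] = log_rank(tanks).p
    min_p = min(per_p.values()) if per_p else 1.0
    return TankPoolingDecision(per_p, min_p, pooled=min_p > alpha, notes=notes)


@dataclass
class PairwiseLogRank:
    pair: tuple[str, str]
    chi2: float
    p_raw: float
    p_adjusted: float
    significant: bool


def pairwise_logrank_bonferroni(
    groups: dict[str, Sequence[SurvivalRecord]], alpha: float = 0.05
) -> list[PairwiseLogRank]:
    """All unordered pairwise log-rank tests with Bonferroni adjustment.

    p_adjusted = min(1, p_raw · number of pairs); significance is judged on
    the adjusted p at ``alpha``.
    """
    codes = list(groups.keys())
    pairs = list(itertools.combinations(codes, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = log_rank({a: groups[a], b: groups[b]})
        p_adj = min(1.0, res.p * m)
        results.append(
            PairwiseLogRank((a, b), res.chi2, res.p, p_adj, p_adj < alpha)
        )
    return results
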