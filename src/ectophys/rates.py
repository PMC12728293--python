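"""SMR, MMR, aerobic scope and Q10 estimation with animal-level QC.

SMR is the low quantile (default q = 0.2) of accepted, background-corrected
uptake measurements taken after the recovery/acclimation exclusion window —
15 h for normoxia, 24 h for hypoxia, where animals repay their oxygen debt
more slowly.  MMR is the larger of two candidates: a rolling-regression
estimate over the initial post-exhaustion sealed phase (steepest 3-min
slope), and the highest routine-cycle measurement driven by spontaneous
activity.  Aerobic scope is their difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trace import (
    BackgroundModel,
    MO2Record,
    Phase,
    RawTrace,
    slope_to_mo2,
)
from .water import WaterConditions

__all__ = [
    "SMREstimate",
    "MMREstimate",
    "MetabolicSummary",
    "Q10Result",
    "estimate_smr",
    "rolling_mmr",
    "routine_max_mo2",
    "select_mmr",
    "aerobic_scope",
    "q10",
    "qc_animal",
    "exclusion_window_for",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SMREstimate:
    value: float  # mg O2 h⁻¹
    q: float
    n_used: int
    exclusion_window_h: float
    r2_min: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("quantile q must lie in (0, 1)")


@dataclass(frozen=True)
class MMREstimate:
    value: float
    source: str  # post_chase_rolling | routine_max
    window_s: float = 180.0

    def __post_init__(self) -> None:
        if self.source not in ("post_chase_rolling", "routine_max"):
            raise ValueError(f"unknown MMR source {self.source!r}")
        if self.value <= 0:
            raise ValueError("MMR must be positive")
        if self.window_s < 60:
            raise ValueError("MMR regression window must be at least 60 s")


@dataclass
class MetabolicSummary:
    animal_id: str
    treatment: str
    wet_mass: float
    smr: SMREstimate
    mmr: MMREstimate
    aerobic_scope: float
    qc_flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags)


@dataclass(frozen=True)
class Q10Result:
    r1: float
    r2: float
    t1: float
    t2: float
    q10: float


def exclusion_window_for(oxygen_level_pct: float, override: float | None = None) -> float:
    """Acclimation/recovery window (h) to drop before the SMR quantile.

    Hypoxic animals (oxygen ≤ 50 %sat) repay their oxygen debt more slowly,
    so their window is 24 h instead of 15 h; pass ``override`` to force a
    specific value.
    """
    if override is not None:
        return override
    return 24.0 if oxygen_level_pct <= 50.0 else 15.0


def estimate_smr(
    records: list[MO2Record],
    q: float = 0.2,
    exclusion_window_h: float = 15.0,
    min_n: int = 10,
    r2_min: float = 0.90,
) -> SMREstimate:
    """Empirical q-quantile (linear interpolation) of post-window uptake."""
    values = np.asarray(
        [r.mo2 for r in records if r.time_h > exclusion_window_h], float
    )
    if values.size < min_n:
        raise ValueError(
            f"insufficient accepted slopes: {values.size} measurements after "
            f"the {exclusion_window_h}-h exclusion window (minimum {min_n})"
        )
    return SMREstimate(
        value=float(np.quantile(values, q)),
        q=q,
        n_used=int(values.size),
        exclusion_window_h=exclusion_window_h,
        r2_min=r2_min,
    )


def rolling_mmr(
    trace: RawTrace,
    long_phase: Phase,
    conditions: WaterConditions,
    volume_ml: float,
    mass_g: float,
    window_s: float = 180.0,
    step_s: float = 1.0,
    background: BackgroundModel | None = None,
) -> MMREstimate | None:
    """Steepest rolling-regression slope over the post-exhaustion phase.

    ``trace`` should already be smoothed and block-medianed; the block-median
    points inside the long phase are re-interpolated to a 1-s grid so the
    window can step by 1 s, then every window's OLS slope is computed in
    closed form from cumulative sums.  The most negative slope (earliest
    window on ties) is converted to uptake; background is subtracted at the
    phase midpoint.  Returns None (logged) when the phase is absent/short.
    """
    if long_phase is None:
        log.info("no post-exhaustion phase; rolling MMR candidate omitted")
        return None
    t, y = trace.phase_samples(long_phase)
    if t.size < 2 or long_phase.duration < window_s:
        log.info("post-exhaustion phase shorter than the regression window")
        return None
    grid = np.arange(t[0], t[-1] + 1e-9, step_s)
    yi = np.interp(grid, t, y)
    n_win = int(round(window_s / step_s))
    if n_win < 2 or grid.size < n_win:
        return None
    x = grid
    sx = _rolling_sum(x, n_win)
    sy = _rolling_sum(yi, n_win)
    sxx = _rolling_sum(x * x, n_win)
    sxy = _rolling_sum(x * yi, n_win)
    denom = n_win * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(denom > 0, (n_win * sxy - sx * sy) / denom, np.nan)
    i = int(np.nanargmin(slopes))  # steepest decline; argmin takes the first
    mo2 = slope_to_mo2(float(slopes[i]), conditions, volume_ml, mass_g)
    if background is not None:
        mid_h = 0.5 * (long_phase.start + long_phase.end) / 3600.0
        mo2 = max(0.0, mo2 - float(background.predict(mid_h)))
    if mo2 <= 0:
        log.info("rolling MMR candidate non-positive after correction; omitted")
        return None
    return MMREstimate(value=mo2, source="post_chase_rolling", window_s=window_s)


def _rolling_sum(a: np.ndarray, n: int) -> np.ndarray:
    c = np.cumsum(np.insert(a, 0, 0.0))
    return c[n:] - c[:-n]


def routine_max_mo2(records: list[MO2Record]) -> MMREstimate | None:
    """Highest accepted uptake over the regular intermittent-flow cycles."""
    cycle = [r for r in records if r.source_kind == "closed"]
    if not cycle:
        return None
    best = max(cycle, key=lambda r: r.mo2)
    if best.mo2 <= 0:
        return None
    return MMREstimate(value=best.mo2, source="routine_max")


def select_mmr(
    post_chase: MMREstimate | None, routine: MMREstimate | None
) -> MMREstimate:
    """The larger of the two MMR candidates; post-chase wins ties."""
    if post_chase is None and routine is None:
        raise ValueError("no MMR candidate available")
    if post_chase is None:
        return routine
    if routine is None or post_chase.value >= routine.value:
        return post_chase
    return routine


def aerobic_scope(mmr: MMREstimate, smr: SMREstimate) -> float:
    """AS = MMR − SMR.  May be negative when estimation failed; callers flag
    such animals via :func:`qc_animal` rather than silently clipping."""
    return mmr.value - smr.value


def q10(r1: float, r2: float, t1: float, t2: float) -> Q10Result:
    """Temperature coefficient Q10 = (R2/R1)^(10/(T2−T1)) for mean rates R1
    at T1 and R2 at T2 (°C), T2 > T1."""
    if t2 <= t1:
        raise ValueError("require t2 > t1")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    return Q10Result(r1, r2, t1, t2, (r2 / r1) ** (10.0 / (t2 - t1)))


def qc_animal(
    summary: MetabolicSummary,
    records: list[MO2Record] | None = None,
    cv_threshold: float = 0.25,
    exercise_ratio: float = 1.2,
    post_chase: MMREstimate | None = None,
    external_flags: set[str] | None = None,
) -> set[str]:
    """Animal-level exclusion flags, mirroring the trial's rules.

    - ``no_stable_low_mo2``: the post-exclusion uptake series never settles
      (coefficient of variation above ``cv_threshold``).
    - ``no_exercise_response``: the post-exhaustion candidate fails to exceed
      ``exercise_ratio`` × SMR.
    - external events (``moult``, ``death``) are passed through unchanged.

    Flags are added to ``summary.qc_flags`` and returned; flagged animals are
    excluded from cohort statistics downstream.
    """
    flags: set[str] = set(external_flags or ())
    if records is not None:
        vals = np.asarray(
            [r.mo2 for r in records if r.time_h > summary.smr.exclusion_window_h],
            float,
        )
        if vals.size >= 2 and vals.mean() > 0:
            if vals.std(ddof=1) / vals.mean() > cv_threshold:
                flags.add("no_stable_low_mo2")
    if post_chase is not None and post_chase.value < exercise_ratio * summary.smr.value:
        flags.add("no_exercise_response")
    if summary.aerobic_scope < 0:
        flags.add("negative_aerobic_scope")
    summary.qc_flags |= flags
    return summary.qc_flags
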