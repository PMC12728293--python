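"""Dissolved-oxygen trace containers and the slope-extraction chain.

An intermittent-flow respirometry run alternates sealed measurement phases
(DO declines as the animal respires) with flush phases (water renewal).  The
processing chain implemented here turns a raw 1-Hz %sat trace into accepted,
background-corrected oxygen-uptake measurements:

    smooth (running mean) -> 20-s block medians -> per-phase OLS slope over
    the last 480 s -> r² filter -> conversion to mg O2 h⁻¹ -> background
    correction from pre/post blank sessions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .water import WaterConditions, o2_solubility

__all__ = [
    "Phase",
    "TraceMeta",
    "RawTrace",
    "SlopeFit",
    "MO2Record",
    "BackgroundModel",
    "smooth_trace",
    "block_medians",
    "fit_phase_slope",
    "filter_slopes",
    "fit_background",
    "correct_mo2",
    "slope_to_mo2",
    "infer_phases",
]

log = logging.getLogger(__name__)

#: Tissue density (g mL⁻¹) used to convert animal wet mass to displaced volume.
TISSUE_DENSITY_G_PER_ML = 1.0

PHASE_KINDS = ("long_closed", "closed", "flush", "background")


@dataclass(frozen=True)
class Phase:
    kind: str
    start: float  # s
    end: float  # s

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.end > self.start:
            raise ValueError("phase end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Half-open membership [start, end) so phases tile the trace."""
        return (t >= self.start) & (t < self.end)


@dataclass
class TraceMeta:
    """Per-animal metadata carried alongside a DO trace."""

    animal_id: str = "unknown"
    treatment: str = ""
    mass_g: float = float("nan")
    volume_ml: float = float("nan")
    temperature_c: float = float("nan")
    salinity: float = float("nan")
    oxygen_level_pct: float = 100.0
    extra: dict = field(default_factory=dict)

    def conditions(self) -> WaterConditions:
        return WaterConditions(self.temperature_c, self.salinity)


@dataclass
class RawTrace:
    """A timestamped DO series (%air-saturation) with phase annotations."""

    time: np.ndarray  # s
    do: np.ndarray  # %sat
    phases: list[Phase]
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.do = np.asarray(self.do, dtype=float)
        if self.time.shape != self.do.shape or self.time.ndim != 1:
            raise ValueError("time and do must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("times must be strictly increasing")
        starts = [p.start for p in self.phases]
        if sorted(starts) != starts:
            raise ValueError("phases must be ordered")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("phases must not overlap")

    def __len__(self) -> int:
        return self.time.size

    def phase_samples(self, phase: Phase) -> tuple[np.ndarray, np.ndarray]:
        m = phase.contains(self.time)
        return self.time[m], self.do[m]

    def closed_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.kind in ("closed", "long_closed")]


@dataclass(frozen=True)
class SlopeFit:
    """An OLS line fitted to the DO decline inside one measurement window."""

    phase_kind: str
    window: tuple[float, float]  # s
    slope: float  # %sat s⁻¹
    intercept: float  # %sat
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a slope fit needs at least 2 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


@dataclass
class MO2Record:
    """One oxygen-uptake determination (mg O2 h⁻¹) at a point in time."""

    time_h: float  # hours since animal introduction (window midpoint)
    mo2: float
    source_kind: str = "closed"
    corrected: bool = False
    r2: float = float("nan")
    background: "BackgroundModel | None" = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mo2):
            raise ValueError("mo2 must be finite")


@dataclass(frozen=True)
class BackgroundModel:
    """Linear drift of blank-chamber (microbial) respiration over time."""

    intercept: float  # mg O2 h⁻¹
    slope: float  # mg O2 h⁻¹ per h
    n_sessions: int

    def predict(self, time_h: float | np.ndarray):
        """Predicted background uptake, floored at zero."""
        return np.maximum(0.0, self.intercept + self.slope * np.asarray(time_h, float))


# ---------------------------------------------------------------------------
# smoothing and block medians


def smooth_trace(trace: RawTrace, window: float = 15.0, *, strict: bool = False) -> RawTrace:
    """Centred running average of the DO series.

    The window is in seconds; edges use the available partial window so the
    series length is preserved.  Windows outside [15, 75] s warn (or raise
    with ``strict=True``) — narrower windows under-smooth 1-Hz optode noise,
    wider ones start eroding real curvature.
    """
    if not (15.0 <= window <= 75.0):
        msg = f"smoothing window {window} s outside the usual [15, 75] s range"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    dt = float(np.median(np.diff(trace.time))) if len(trace) > 1 else 1.0
    if window < dt:
        raise ValueError("smoothing window shorter than the sample interval")
    n = max(1, int(round(window / dt)))
    if n % 2 == 0:
        n += 1
    half = n // 2
    csum = np.cumsum(np.insert(trace.do, 0, 0.0))
    idx = np.arange(len(trace))
    lo = np.maximum(0, idx - half)
    hi = np.minimum(len(trace), idx + half + 1)
    sm = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(trace, time=trace.time.copy(), do=sm)


def block_medians(trace: RawTrace, block: float = 20.0) -> RawTrace:
    """Collapse the series to one median point per ``block`` seconds.

    Blocks are laid out from each phase's start and never span a phase
    boundary; each retained point sits at the block's time midpoint.  Empty
    blocks are skipped with a log entry.
    """
    dt = float(np.median(np.diff(trace.time))) if len(trace) > 1 else 1.0
    if block < dt:
        raise ValueError("block shorter than the sample interval")
    times: list[float] = []
    values: list[float] = []
    for phase in trace.phases:
        t, y = trace.phase_samples(phase)
        if t.size == 0:
            continue
        edges = np.arange(phase.start, phase.end + 1e-9, block)
        if edges[-1] < phase.end - 1e-9:
            edges = np.append(edges, phase.end)
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t >= lo) & (t < hi)
            if not m.any():
                log.debug("empty %g-s block at [%g, %g) skipped", block, lo, hi)
                continue
            times.append(0.5 * (lo + hi))
            values.append(float(np.median(y[m])))
    return replace(trace, time=np.asarray(times), do=np.asarray(values))


# ---------------------------------------------------------------------------
# slope fitting and filtering


def fit_phase_slope(
    trace: RawTrace,
    phase: Phase,
    measurement_window: float = 480.0,
    min_points: int = 10,
) -> SlopeFit | None:
    """OLS line over the last ``measurement_window`` seconds of a phase.

    Discarding the start of each sealed phase avoids the mixing transient
    that follows a flush.  r² is the squared Pearson correlation of DO vs
    time over the fitted window.  Returns None (logged) when fewer than
    ``min_points`` samples fall in the window.
    """
    if phase.kind not in ("closed", "long_closed", "background"):
        raise ValueError(f"cannot fit an uptake slope on a {phase.kind!r} phase")
    win_start = max(phase.start, phase.end - measurement_window)
    t, y = trace.phase_samples(phase)
    m = t >= win_start
    t, y = t[m], y[m]
    if t.size < min_points:
        log.info(
            "phase [%g, %g): only %d points in the measurement window "
            "(minimum %d); no fit",
            phase.start, phase.end, t.size, min_points,
        )
        return None
    res = _sps.linregress(t, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return SlopeFit(
        phase_kind=phase.kind,
        window=(float(t[0]), float(t[-1])),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(r2, 1.0),
        n_points=int(t.size),
    )


@dataclass
class FilterResult:
    accepted: list[SlopeFit]
    rejected: list[SlopeFit]

    @property
    def rejection_fraction(self) -> float:
        n = len(self.accepted) + len(self.rejected)
        return len(self.rejected) / n if n else 0.0


def filter_slopes(fits: Sequence[SlopeFit], r2_min: float = 0.90) -> FilterResult:
    """Keep fits with r² ≥ ``r2_min``.

    The threshold is deliberately per-animal configurable: with noisy traces
    a rigid global cutoff discards genuinely linear declines and biases the
    low quantile of uptake (hence SMR) upward.  Raises when every fit is
    rejected, advising a threshold review rather than silently returning an
    empty set.
    """
    if not fits:
        raise ValueError("no slope fits supplied")
    accepted = [f for f in fits if f.r2 >= r2_min]
    rejected = [f for f in fits if f.r2 < r2_min]
    if not accepted:
        raise ValueError(
            f"all {len(fits)} slopes rejected at r2_min={r2_min}; review the "
            "threshold for this animal (lowering it avoids underestimating SMR)"
        )
    return FilterResult(accepted=accepted, rejected=rejected)


# ---------------------------------------------------------------------------
# conversion and background correction


def slope_to_mo2(
    slope: float | SlopeFit,
    conditions: WaterConditions,
    volume_ml: float,
    mass_g: float,
) -> float:
    """Convert a DO decline (%sat s⁻¹) to oxygen uptake (mg O2 h⁻¹).

    mo2 = −slope · 3600 · C_sat/100 · V_eff, with the effective volume the
    chamber volume minus the animal's displacement (wet mass over tissue
    density ρ = 1.0 g mL⁻¹), in litres.
    """
    if isinstance(slope, SlopeFit):
        slope = slope.slope
    v_eff_l = (volume_ml - mass_g / TISSUE_DENSITY_G_PER_ML) / 1000.0
    if v_eff_l <= 0:
        raise ValueError("animal larger than chamber: effective volume <= 0")
    return -slope * 3600.0 * (o2_solubility(conditions) / 100.0) * v_eff_l


def fit_background(sessions: Sequence[tuple[float, float]]) -> BackgroundModel:
    """Linear regression of blank-chamber uptake vs time.

    ``sessions`` are (time h, mo2 mg O2 h⁻¹) pairs, typically one measured
    before the animal is introduced and one after removal; microbial growth
    makes the blank drift upward over a multi-day run.  A single session
    yields a constant model with a warning.
    """
    if len(sessions) == 0:
        raise ValueError("at least one background session is required")
    t = np.asarray([s[0] for s in sessions], float)
    y = np.asarray([s[1] for s in sessions], float)
    if len(sessions) == 1:
        warnings.warn(
            "single background session: assuming constant background",
            stacklevel=2,
        )
        return BackgroundModel(intercept=float(y[0]), slope=0.0, n_sessions=1)
    if np.unique(t).size < 2:
        raise ValueError("background sessions must span distinct times")
    slope, intercept = np.polyfit(t, y, 1)
    return BackgroundModel(float(intercept), float(slope), len(sessions))


def correct_mo2(records: Iterable[MO2Record], model: BackgroundModel) -> list[MO2Record]:
    """Subtract the predicted background from each record, floored at zero."""
    out = []
    for r in records:
        corrected = max(0.0, r.mo2 - float(model.predict(r.time_h)))
        out.append(
            MO2Record(
                time_h=r.time_h,
                mo2=corrected,
                source_kind=r.source_kind,
                corrected=True,
                r2=r.r2,
                background=model,
            )
        )
    return out


# ---------------------------------------------------------------------------
# phase inference for unlabelled traces


def infer_phases(
    trace: RawTrace,
    rate_threshold: float = 0.01,
    smooth_s: float = 30.0,
    min_phase_s: float = 40.0,
    long_factor: float = 1.5,
) -> list[Phase]:
    """Reconstruct the flush/closed schedule from DO upturns.

    A flush is detected wherever the smoothed DO derivative exceeds
    ``rate_threshold`` %sat s⁻¹ (flushing drives DO rapidly back toward the
    inflow level, respiration only lowers it).  The leading closed segment is
    labelled ``long_closed`` when it is ``long_factor`` times longer than the
    median closed segment.  Labelled input should always take precedence over
    this heuristic.
    """
    if len(trace) < 3:
        raise ValueError("trace too short to infer phases")
    dt = float(np.median(np.diff(trace.time)))
    sm = smooth_trace(trace, smooth_s).do  # partial windows: no edge artefacts
    deriv = np.gradient(sm, trace.time)
    is_flush = deriv > rate_threshold
    # segment boundaries where the flush flag flips
    flips = np.flatnonzero(np.diff(is_flush.astype(int))) + 1
    bounds = np.concatenate(([0], flips, [len(trace)]))
    segments: list[tuple[bool, float, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        start = trace.time[a]
        end = trace.time[b - 1] + dt
        flag = bool(is_flush[a])
        if segments and (end - start) < min_phase_s:
            # glue runt segments onto the previous one
            prev = segments.pop()
            segments.append((prev[0], prev[1], end))
            continue
        if not segments and (end - start) < min_phase_s:
            segments.append((None, start, end))  # defer to the next segment
            continue
        if segments and segments[-1][0] is None:
            head = segments.pop()
            segments.append((flag, head[1], end))
            continue
        segments.append((flag, start, end))
    # merge consecutive same-kind runs left by runt gluing
    merged: list[tuple[bool, float, float]] = []
    for flag, start, end in segments:
        if merged and merged[-1][0] == flag:
            merged[-1] = (flag, merged[-1][1], end)
        else:
            merged.append((flag, start, end))
    segments = merged
    closed_durs = [e - s for f, s, e in segments if not f]
    median_closed = float(np.median(closed_durs)) if closed_durs else 0.0
    phases: list[Phase] = []
    first_closed = True
    for flag, start, end in segments:
        if flag:
            phases.append(Phase("flush", start, end))
        else:
            kind = "closed"
            if first_closed and median_closed and (end - start) > long_factor * median_closed:
                kind = "long_closed"
            first_closed = False
            phases.append(Phase(kind, start, end))
    return phases
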