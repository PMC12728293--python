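"""Synthetic respirometry traces, survival cohorts and enzyme panels.

Every downstream stage of the pipeline is tested against data generated
here, where the ground truth is known exactly.  The trace generator encodes
the measurement model of intermittent-flow respirometry: inside a sealed
phase the chamber's dissolved oxygen obeys

    d(DO)/dt = -100 · (U_animal(t) + U_bg(t)) / (C_sat · V_eff · 3600)

with DO in %air-saturation, uptakes in mg O2 h⁻¹, C_sat the air-saturated
O2 concentration (mg L⁻¹) and V_eff the water volume (L) net of the animal.
The animal's instantaneous uptake is standard metabolism plus a decaying
acclimation elevation, an exponentially decaying post-exercise excess
(EPOC, repaying the oxygen debt from the pre-trial exhaustive chase), and
spontaneous-activity bursts:

    U_animal(t) = SMR·(1 + a·e^(-t/τ_a)) + A·e^(-t/τ_EPOC) + bursts(t)

where A = MMR − SMR·(1 + a) so that U_animal(0) = MMR exactly.  During a
flush the chamber relaxes first-order toward the inflow DO.  Sensor noise is
Gaussian, optionally AR(1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .enzymes import EnzymePanel
from .survival import SurvivalRecord
from .trace import Phase, RawTrace, TraceMeta
from .water import WaterConditions, o2_solubility

__all__ = [
    "TraceSimConfig",
    "TraceGroundTruth",
    "SurvivalSimConfig",
    "EnzymeSimConfig",
    "simulate_do_trace",
    "simulate_background_trace",
    "simulate_survival_cohort",
    "simulate_enzyme_panel",
]

_TISSUE_DENSITY = 1.0  # g mL^-1


@dataclass
class TraceSimConfig:
    """Generator settings for one animal's respirometry run.

    Defaults describe the study conditions this package targets: a ≈300-mL
    chamber, 1-Hz optode sampling, a ~2-h initial sealed phase after the
    exhaustion chase, then 300-s flush / 660-s sealed cycles for ~2 days.
    """

    respirometer_volume: float = 300.0  # mL
    animal_mass: float = 8.4  # g wet
    temperature: float = 2.0  # °C
    salinity: float = 33.0
    true_smr: float = 0.38  # mg O2 h⁻¹
    true_mmr: float = 1.66  # mg O2 h⁻¹
    epoc_tau: float = 1.5  # h
    acclimation_elevation: float = 0.2  # fraction of SMR at t=0
    acclimation_duration: float = 15.0  # h; decay constant is duration/5
    burst_rate: float = 0.5  # events h⁻¹
    burst_magnitude_max: float = 0.5  # fraction of (MMR − SMR)
    background_intercept: float = 0.01  # mg O2 h⁻¹
    background_slope: float = 0.0008  # mg O2 h⁻¹ per h
    noise_sd: float = 0.3  # %sat
    ar1_coef: float = 0.0
    sample_interval: float = 1.0  # s
    long_closed_duration: float = 7200.0  # s
    flush_duration: float = 300.0  # s
    closed_duration: float = 660.0  # s
    total_duration: float = 50.0  # h
    flush_time_constant: float = 26.0  # s ≈ V / (3.5 L min⁻¹ shared over 5)
    inflow_do: float = 100.0  # %sat
    forced_bursts: Sequence[tuple[float, float, float]] = ()  # (start s, dur s, frac)
    animal_id: str = "sim"
    treatment: str = ""
    seed: int = 0

    def validate(self) -> None:
        if not (self.true_mmr > self.true_smr > 0):
            raise ValueError("require true_mmr > true_smr > 0")
        for name in (
            "respirometer_volume", "animal_mass", "epoc_tau",
            "acclimation_duration", "sample_interval", "long_closed_duration",
            "flush_duration", "closed_duration", "total_duration",
            "flush_time_constant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.inflow_do <= 100):
            raise ValueError("inflow_do must lie in (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.respirometer_volume <= self.animal_mass / _TISSUE_DENSITY:
            raise ValueError("animal larger than chamber")

    @property
    def effective_volume_l(self) -> float:
        return (self.respirometer_volume - self.animal_mass / _TISSUE_DENSITY) / 1000.0

    def conditions(self) -> WaterConditions:
        return WaterConditions(self.temperature, self.salinity)

    def meta(self) -> TraceMeta:
        return TraceMeta(
            animal_id=self.animal_id,
            treatment=self.treatment,
            mass_g=self.animal_mass,
            volume_ml=self.respirometer_volume,
            temperature_c=self.temperature,
            salinity=self.salinity,
            oxygen_level_pct=self.inflow_do,
        )


@dataclass
class TraceGroundTruth:
    """What the generator actually put into a trace."""

    smr: float
    mmr: float
    background_model: tuple[float, float]  # (intercept, slope per h)
    uptake: Callable[[np.ndarray], np.ndarray]  # animal uptake, mg O2 h⁻¹ vs s
    phase_mean_uptake: list[tuple[Phase, float]] = field(default_factory=list)


def _build_schedule(cfg: TraceSimConfig) -> list[Phase]:
    total_s = cfg.total_duration * 3600.0
    phases: list[Phase] = [Phase("long_closed", 0.0, min(cfg.long_closed_duration, total_s))]
    t = phases[0].end
    while t < total_s - 1e-9:
        f_end = min(t + cfg.flush_duration, total_s)
        phases.append(Phase("flush", t, f_end))
        t = f_end
        if t >= total_s - 1e-9:
            break
        c_end = min(t + cfg.closed_duration, total_s)
        phases.append(Phase("closed", t, c_end))
        t = c_end
    return phases


def _burst_train(cfg: TraceSimConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rectangular activity pulses: (start s, duration s, magnitude mg O2 h⁻¹)."""
    span = cfg.true_mmr - cfg.true_smr
    bursts = [(s, d, frac * span) for s, d, frac in cfg.forced_bursts]
    if cfg.burst_rate > 0:
        n = rng.poisson(cfg.burst_rate * cfg.total_duration)
        starts = rng.uniform(0.0, cfg.total_duration * 3600.0, n)
        durs = rng.uniform(30.0, 120.0, n)
        mags = rng.uniform(0.0, cfg.burst_magnitude_max * span, n)
        bursts.extend(zip(starts, durs, mags))
    return sorted(bursts)


def _uptake_fn(cfg: TraceSimConfig, bursts: list[tuple[float, float, float]]) -> Callable:
    tau_acc_s = (cfg.acclimation_duration / 5.0) * 3600.0
    tau_epoc_s = cfg.epoc_tau * 3600.0
    amp = cfg.true_mmr - cfg.true_smr * (1.0 + cfg.acclimation_elevation)

    def uptake(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        u = cfg.true_smr * (1.0 + cfg.acclimation_elevation * np.exp(-t / tau_acc_s))
        u = u + amp * np.exp(-t / tau_epoc_s)
        for s, d, m in bursts:
            u = u + m * ((t >= s) & (t < s + d))
        # spontaneous activity cannot push aerobic uptake past MMR
        return np.minimum(u, cfg.true_mmr)

    return uptake


def simulate_do_trace(cfg: TraceSimConfig) -> tuple[RawTrace, TraceGroundTruth]:
    """Generate one full intermittent-flow DO trace and its ground truth.

    Sealed phases integrate the mass-balance ODE (uptake does not depend on
    DO, so the integral is a cumulative trapezoid); flush phases relax
    exponentially toward the inflow DO.  Identical seeds give bit-identical
    traces.  Raises when the noiseless DO would reach zero inside a sealed
    phase — such a configuration cannot be measured, only reconfigured.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    phases = _build_schedule(cfg)
    bursts = _burst_train(cfg, rng)
    uptake = _uptake_fn(cfg, bursts)
    csat = o2_solubility(cfg.conditions())
    veff = cfg.effective_volume_l

    def u_bg(t_s: np.ndarray) -> np.ndarray:
        return cfg.background_intercept + cfg.background_slope * np.asarray(t_s, float) / 3600.0

    total_s = cfg.total_duration * 3600.0
    time = np.arange(0.0, total_s, cfg.sample_interval)
    do = np.empty_like(time)
    do_level = cfg.inflow_do
    phase_means: list[tuple[Phase, float]] = []
    for phase in phases:
        m = phase.contains(time)
        t = time[m]
        if t.size == 0:
            continue
        if phase.kind == "flush":
            do[m] = cfg.inflow_do + (do_level - cfg.inflow_do) * np.exp(
                -(t - phase.start) / cfg.flush_time_constant
            )
            do_level = cfg.inflow_do + (do_level - cfg.inflow_do) * math.exp(
                -(phase.end - phase.start) / cfg.flush_time_constant
            )
        else:
            u = uptake(t) + u_bg(t)
            # mg consumed since phase start (trapezoid over seconds -> hours)
            consumed = np.concatenate(
                ([0.0], np.cumsum(0.5 * (u[1:] + u[:-1]) * np.diff(t)))
            ) / 3600.0
            seg = do_level - 100.0 * consumed / (csat * veff)
            # extend to the phase end for the handoff to the next flush
            end_consumed = consumed[-1] + float(u[-1]) * (phase.end - t[-1]) / 3600.0
            if seg.min() <= 0.0 or do_level - 100.0 * end_consumed / (csat * veff) <= 0.0:
                raise ValueError(
                    "trace depletion; shorten closed phase or reduce uptake"
                )
            do[m] = seg
            do_level = do_level - 100.0 * end_consumed / (csat * veff)
            phase_means.append((phase, float(np.mean(uptake(t)))))
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd, time.size)
        if cfg.ar1_coef > 0:
            phi = cfg.ar1_coef
            innov = eps * math.sqrt(1.0 - phi * phi)
            ar = np.empty_like(eps)
            ar[0] = eps[0]
            for i in range(1, eps.size):
                ar[i] = phi * ar[i - 1] + innov[i]
            eps = ar
        do = do + eps
    truth = TraceGroundTruth(
        smr=cfg.true_smr,
        mmr=cfg.true_mmr,
        background_model=(cfg.background_intercept, cfg.background_slope),
        uptake=uptake,
        phase_mean_uptake=phase_means,
    )
    return RawTrace(time=time, do=do, phases=phases, meta=cfg.meta()), truth


def simulate_background_trace(
    cfg: TraceSimConfig, at_time: float, duration: float = 900.0
) -> RawTrace:
    """A blank-chamber sealed trace with only background respiration.

    ``at_time`` (h) positions the session on the background drift line,
    emulating the pre-introduction and post-removal blank measurements.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    csat = o2_solubility(cfg.conditions())
    veff = cfg.respirometer_volume / 1000.0  # no animal in the chamber
    u = cfg.background_intercept + cfg.background_slope * at_time
    time = np.arange(0.0, duration, cfg.sample_interval)
    do = cfg.inflow_do - 100.0 * (u * time / 3600.0) / (csat * veff)
    if do.min() <= 0.0:
        raise ValueError("trace depletion; shorten closed phase or reduce uptake")
    if cfg.noise_sd > 0:
        do = do + rng.normal(0.0, cfg.noise_sd, time.size)
    meta = cfg.meta()
    meta.animal_id = f"{cfg.animal_id}-blank"
    meta.mass_g = 0.0
    return RawTrace(
        time=time, do=do, phases=[Phase("background", 0.0, duration)], meta=meta
    )


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass
class SurvivalSimConfig:
    """Per-treatment Weibull hazards with the trial's censoring scheme.

    ``treatments`` maps a code to (shape, scale days); shape 1 is an
    exponential hazard, scale ``inf`` means no mortality.  On ``censor_day``
    a fixed number of survivors per tank leaves for respirometry and is
    right-censored; everyone alive at ``follow_up`` is censored there.
    """

    treatments: Sequence[tuple[str, float, float]]
    n_per_tank: int = 70
    tanks_per_treatment: int = 2
    censor_day: float = 28.0
    censored_per_tank: int = 5
    follow_up: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.censored_per_tank > self.n_per_tank:
            raise ValueError("censored_per_tank must not exceed n_per_tank")
        if self.censor_day > self.follow_up:
            raise ValueError("censor_day must not exceed follow_up")
        for code, shape, scale in self.treatments:
            if shape <= 0 or scale <= 0:
                raise ValueError(f"treatment {code}: shape and scale must be positive")


def simulate_survival_cohort(cfg: SurvivalSimConfig) -> list[SurvivalRecord]:
    """Draw one cohort of individual death/censoring records."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[SurvivalRecord] = []
    for code, shape, scale in cfg.treatments:
        for tank_i in range(cfg.tanks_per_treatment):
            tank = f"{code}-t{tank_i + 1}"
            if math.isinf(scale):
                t_death = np.full(cfg.n_per_tank, np.inf)
            else:
                t_death = scale * rng.weibull(shape, cfg.n_per_tank)
            alive_at_censor = np.flatnonzero(t_death > cfg.censor_day)
            if alive_at_censor.size < cfg.censored_per_tank:
                warnings.warn(
                    f"tank {tank}: only {alive_at_censor.size} survivors at "
                    f"day {cfg.censor_day}; censoring all of them",
                    stacklevel=2,
                )
                removed = alive_at_censor
            else:
                removed = rng.choice(
                    alive_at_censor, size=cfg.censored_per_tank, replace=False
                )
            removed_set = set(removed.tolist())
            for i in range(cfg.n_per_tank):
                ind = f"{tank}-{i:03d}"
                if i in removed_set:
                    records.append(SurvivalRecord(ind, tank, code, cfg.censor_day, 0))
                elif t_death[i] <= cfg.follow_up:
                    records.append(
                        SurvivalRecord(ind, tank, code, float(t_death[i]), 1)
                    )
                else:
                    records.append(SurvivalRecord(ind, tank, code, cfg.follow_up, 0))
    return records


# ---------------------------------------------------------------------------
# enzyme panels


@dataclass
class EnzymeSimConfig:
    """Duplicate-assayed enzyme activities with treatment structure.

    ``treatment_means`` maps a treatment code to {enzyme: (mean, sd)} of the
    specific activity (U g⁻¹ protein).  Total activity (U g⁻¹ wet) is the
    specific activity times a per-animal protein fraction, which builds in
    the strong total-vs-specific correlation seen in real panels.  Each
    activity is assayed in duplicate as value·(1 + ε), ε ~ N(0, duplicate_cv).
    """

    treatment_means: dict[str, dict[str, tuple[float, float]]]
    duplicate_cv: float = 0.03
    n_per_treatment: int = 9
    protein_fraction: float = 0.18  # g protein per g wet tissue
    protein_fraction_cv: float = 0.02  # small vs between-animal activity spread
    # so measured total and specific activities stay correlated (r >= 0.8)
    seed: int = 0

    def validate(self) -> None:
        if self.duplicate_cv < 0:
            raise ValueError("duplicate_cv must be non-negative")
        if self.n_per_treatment < 1:
            raise ValueError("n_per_treatment must be at least 1")
        for code, enz in self.treatment_means.items():
            for name, (mean, sd) in enz.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"{code}/{name}: mean must be > 0, sd >= 0")


def simulate_enzyme_panel(cfg: EnzymeSimConfig) -> list[EnzymePanel]:
    """Draw duplicate-measured panels for every animal in every treatment."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panels: list[EnzymePanel] = []
    for code, enz_means in cfg.treatment_means.items():
        for i in range(cfg.n_per_treatment):
            protein = cfg.protein_fraction * max(
                0.05, 1.0 + rng.normal(0.0, cfg.protein_fraction_cv)
            )
            specific: dict[str, tuple[float, float]] = {}
            total: dict[str, tuple[float, float]] = {}
            for name, (mean, sd) in enz_means.items():
                true = max(1e-6, rng.normal(mean, sd))
                eps = rng.normal(0.0, cfg.duplicate_cv, 2)
                pair = tuple(max(0.0, true * (1.0 + e)) for e in eps)
                specific[name] = pair  # U g^-1 protein
                eps_t = rng.normal(0.0, cfg.duplicate_cv, 2)
                total[name] = tuple(
                    max(0.0, true * protein * (1.0 + e)) for e in eps_t
                )
            panels.append(
                EnzymePanel(
                    animal_id=f"{code}-{i:03d}",
                    treatment=code,
                    specific=specific,
                    total=total,
                )
            )
    return panels
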