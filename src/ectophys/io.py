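"""Readers/writers for trace files and run configuration.

Respirometry traces have no established interchange format, so this package
uses a minimal CSV dialect: '#'-prefixed ``key=value`` metadata header lines
followed by columns ``time_s, do_percent_sat[, phase]``.  When the phase
column is absent the flush/closed schedule is inferred from DO upturns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trace import Phase, RawTrace, TraceMeta, infer_phases

__all__ = ["read_trace_file", "write_trace_file", "RunConfig"]

_META_FIELDS = {
    "animal_id": str,
    "treatment": str,
    "mass_g": float,
    "volume_ml": float,
    "temperature_c": float,
    "salinity": float,
    "oxygen_level_pct": float,
}


def write_trace_file(trace: RawTrace, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for name in _META_FIELDS:
        lines.append(f"# {name}={getattr(trace.meta, name)}")
    lines.append("time_s,do_percent_sat,phase")
    kinds = np.empty(len(trace), dtype=object)
    kinds[:] = ""
    for p in trace.phases:
        kinds[p.contains(trace.time)] = p.kind
    for t, d, k in zip(trace.time, trace.do, kinds):
        lines.append(f"{t:.3f},{d:.6f},{k}")
    path.write_text("\n".join(lines) + "\n")


def _phases_from_labels(time: np.ndarray, labels: list[str], dt: float) -> list[Phase]:
    phases: list[Phase] = []
    start_i = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start_i]:
            kind = labels[start_i]
            if kind:
                end = time[i - 1] + dt if i == len(labels) else time[i]
                phases.append(Phase(kind, float(time[start_i]), float(end)))
            start_i = i
    return phases


def read_trace_file(path: str | Path) -> RawTrace:
    """Parse a trace file; malformed rows are reported with line numbers."""
    path = Path(path)
    meta_kwargs: dict = {}
    times: list[float] = []
    dos: list[float] = []
    labels: list[str] = []
    header_cols: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _META_FIELDS:
                    meta_kwargs[key] = _META_FIELDS[key](val.strip())
                continue
            if header_cols is None:
                header_cols = [c.strip() for c in line.split(",")]
                required = {"time_s", "do_percent_sat"}
                if not required <= set(header_cols):
                    raise ValueError(
                        f"{path}:{lineno}: missing required columns "
                        f"{sorted(required - set(header_cols))}"
                    )
                continue
            parts = [c.strip() for c in line.split(",")]
            row = dict(zip(header_cols, parts))
            try:
                times.append(float(row["time_s"]))
                dos.append(float(row["do_percent_sat"]))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed data row {line!r}") from exc
            labels.append(row.get("phase", ""))
    if header_cols is None or not times:
        raise ValueError(f"{path}: no data rows found")
    missing_meta = [k for k in ("mass_g", "volume_ml", "temperature_c", "salinity")
                    if k not in meta_kwargs]
    if missing_meta:
        raise ValueError(f"{path}: missing metadata {missing_meta}")
    time = np.asarray(times)
    if time.size >= 2 and not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0])
        raise ValueError(f"{path}: non-monotone time around sample {bad + 1}")
    dt = float(np.median(np.diff(time))) if time.size > 1 else 1.0
    meta = TraceMeta(**meta_kwargs)
    if any(labels):
        phases = _phases_from_labels(time, labels, dt)
        return RawTrace(time=time, do=np.asarray(dos), phases=phases, meta=meta)
    trace = RawTrace(
        time=time,
        do=np.asarray(dos),
        phases=[Phase("closed", float(time[0]), float(time[-1]) + dt)],
        meta=meta,
    )
    trace.phases = infer_phases(trace)
    return trace


@dataclass
class RunConfig:
    """Parameters for the full simulation -> processing -> statistics run."""

    seed: int = 0
    n_per_treatment: int = 9
    smoothing_window_s: float | str = 15.0  # seconds, or "auto"
    block_s: float = 20.0
    r2_min: float = 0.90
    r2_min_overrides: dict[str, float] = field(default_factory=dict)  # animal -> r2
    measurement_window_s: float = 480.0
    smr_quantile: float = 0.2
    exclusion_normoxia_h: float = 15.0
    exclusion_hypoxia_h: float = 24.0
    mmr_window_s: float = 180.0
    trace_duration_h: float = 50.0
    noise_sd: float = 0.3
    alpha: float = 0.05
    outdir: str = "ectophys_results"

    def validate(self) -> None:
        if not (0 < self.smr_quantile < 1):
            raise ValueError("smr_quantile must lie in (0, 1)")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must lie in [0, 1]")
        if self.mmr_window_s < 60:
            raise ValueError("mmr_window_s must be at least 60 s")
        if self.n_per_treatment < 2:
            raise ValueError("n_per_treatment must be at least 2")
        if isinstance(self.smoothing_window_s, str) and self.smoothing_window_s != "auto":
            raise ValueError("smoothing_window_s must be a number or 'auto'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
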