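"""Trace files and run configuration.

Traces are stored as two-column whitespace-delimited text (time_s, da_uM)
with an optional commented JSON metadata header; the reader tolerates a
missing header. Run configurations are YAML documents validated against a
pydantic schema before any computation; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import constants
from .stimulus import BurstProtocol, make_repeated_burst, make_single_burst
from .trace import Trace

__all__ = ["read_trace", "write_trace", "RunConfig", "load_config", "protocol_from_config"]

_META_PREFIX = "# meta: "


def write_trace(trace: Trace, path) -> None:
    """Write a trace with its metadata header."""
    path = Path(path)
    lines = []
    if trace.meta:
        lines.append(_META_PREFIX + json.dumps(trace.meta, sort_keys=True))
    lines.append("# time_s\tda_uM")
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{t:.6f}\t{v:.9g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    """Read a trace file; malformed rows and non-uniform grids are errors."""
    path = Path(path)
    meta = {}
    times = []
    values = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith(_META_PREFIX):
                meta = json.loads(line[len(_META_PREFIX):])
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        times.append(t)
        values.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than two samples")
    try:
        return Trace(times=np.array(times), values=np.array(values), meta=meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration schema


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    kind: Literal["single", "repeated", "custom"] = "single"
    t0: float = 5.0
    current: float = constants.STIM_CURRENT
    interstimulus: float = 5.0
    spacing_convention: Literal["offset_to_onset", "onset_to_onset"] = "offset_to_onset"
    onsets: Optional[list[float]] = None  # custom only
    np_pulses: int = constants.PULSES_PER_BURST
    frequency: float = constants.BURST_FREQUENCY
    onset_shift: float = 0.0


class GeometryConfig(_Strict):
    r_l: float = constants.CYLINDER_RADIUS
    r_d: float = constants.DEAD_SPACE_RADIUS
    d: float = constants.DIFFUSION_COEFF
    dr: float = constants.SOLVER_DR
    site_spacing: float = constants.SITE_SPACING
    site_positions: Optional[list[float]] = None


class SolverConfig(_Strict):
    dt: float = constants.SOLVER_DT
    scheme: Literal["cn", "euler"] = "cn"


class PriorEntryConfig(_Strict):
    mean: float
    sd: float
    lower: float
    upper: Optional[float] = None


class PriorConfig(_Strict):
    free: dict[str, PriorEntryConfig] = Field(default_factory=dict)
    fixed: dict[str, float] = Field(default_factory=dict)
    km: Optional[float] = None  # defaults to 0.2 uM with a logged notice


class RunConfig(_Strict):
    """One simulate/fit/recover run, fully specified."""

    model: Literal["sur", "stur", "stdr"] = "sur"
    preset: Optional[str] = "WT-sweep1-S"
    protocol: Optional[ProtocolConfig] = None
    params: dict[str, float] = Field(default_factory=dict)  # theta overrides
    prior: Optional[PriorConfig] = None
    free: list[str] = Field(default_factory=lambda: ["da_p", "v_m"])
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    seed: int = 0
    noise_sd: float = 0.0
    t_end: Optional[float] = None
    fs: float = constants.FSCV_SAMPLING_RATE
    bypass_electrode: bool = False
    max_iter: int = 500
    n_replicates: int = 10

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def protocol_from_config(cfg: ProtocolConfig) -> BurstProtocol:
    if cfg.kind == "single":
        proto = make_single_burst(cfg.t0, cfg.current)
    elif cfg.kind == "repeated":
        proto = make_repeated_burst(
            cfg.t0, cfg.current, cfg.interstimulus, cfg.spacing_convention
        )
    else:
        if not cfg.onsets:
            raise ValueError("custom protocol requires explicit onsets")
        proto = BurstProtocol(
            onsets=tuple(cfg.onsets),
            np_pulses=cfg.np_pulses,
            frequency=cfg.frequency,
            current=cfg.current,
        )
    if cfg.onset_shift:
        proto = proto.with_shift(cfg.onset_shift)
    return proto
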