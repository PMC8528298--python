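"""Run configuration: YAML-serialisable description of one simulation.

A :class:`RunConfig` fully determines a run (geometry, parameter set,
ChR2 block, protocols, numerics, recorders), so every experiment is
expressible as one config file and two runs from the same config are
bitwise identical (there is no hidden randomness; protocol evaluation is
pure).  Defaults carry provenance tags so a resolved config records whether
each value came from the study's printed numerics, the external ChR2
parameterisation, or package plumbing.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .chr2 import ChR2Params
from .ionic_models import IonicParams, make_caf_params, make_healthy_params
from .protocols import LightProtocol, Region, StimProtocol

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError",
           "DEFAULT_PROVENANCE"]

# provenance of the main defaults: paper = printed in the study,
# ref36 = external ChR2 parameterisation, artifact = package plumbing
DEFAULT_PROVENANCE = {
    "numerics.dt": "paper", "numerics.dx": "paper", "numerics.D": "paper",
    "chr2.g_ChR2": "paper", "chr2.G_d1": "paper", "chr2.G_d2": "paper",
    "chr2.G_r": "paper", "chr2.eps1": "paper", "chr2.eps2": "paper",
    "chr2.wavelength": "paper", "chr2.S_cell": "paper",
    "chr2.gamma": "ref36", "chr2.E_ChR2": "ref36", "chr2.tau_ChR2": "ref36",
    "chr2.w_loss": "ref36",
    "chr2.irradiance_unit_scale": "artifact",
    "stim.amplitude": "artifact", "stim.duration": "artifact",
    "recorders": "artifact",
}

GEOMETRIES = ("cell", "cable", "sheet", "hybrid")
PARAM_SETS = {"healthy": make_healthy_params, "caf": make_caf_params}


class ConfigError(ValueError):
    """Schema violation; the message lists the offending keys."""


@dataclass
class Numerics:
    dt: float = 0.02       # ms
    dx: float = 0.022      # cm
    D: float = 0.0023      # cm^2/ms
    duration: float = 1000.0  # ms


@dataclass
class GeometrySpec:
    kind: str = "cell"
    nx: int = 1
    ny: int = 1
    strip_nx: int = 1536   # hybrid only
    strip_ny: int = 30


@dataclass
class RecorderSpec:
    trace_sites: list = field(default_factory=list)
    trace_every: float = 1.0    # ms; 0 = every step
    frame_every: float = 10.0   # ms; 0 = off


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    params: str = "healthy"
    param_overrides: dict = field(default_factory=dict)
    chr2: dict = field(default_factory=dict)
    numerics: Numerics = field(default_factory=Numerics)
    light: Optional[dict] = None
    pace: Optional[dict] = None
    recorders: RecorderSpec = field(default_factory=RecorderSpec)
    out: Optional[str] = None
    provenance: dict = field(default_factory=lambda: dict(DEFAULT_PROVENANCE))

    def ionic_params(self) -> IonicParams:
        if self.params not in PARAM_SETS:
            raise ConfigError(f"unknown parameter set: {self.params!r}")
        return PARAM_SETS[self.params](**self.param_overrides)

    def chr2_params(self) -> ChR2Params:
        return ChR2Params(**self.chr2)

    def light_protocol(self) -> Optional[LightProtocol]:
        if not self.light:
            return None
        d = dict(self.light)
        region = _region_from(d.pop("region", None))
        mode = d.pop("mode", "constant")
        key_map = {"ee": "E_e", "freq_hz": "frequency", "pw_ms": "pulse_width"}
        kw = {key_map.get(k, k): v for k, v in d.items()}
        return LightProtocol(mode=mode, region=region, **kw)

    def stim_protocol(self) -> Optional[StimProtocol]:
        if not self.pace:
            return None
        d = dict(self.pace)
        region = _region_from(d.pop("region", "left-edge"))
        return StimProtocol(region=region, **d)

    def validate(self) -> "RunConfig":
        bad = []
        g, n = self.geometry, self.numerics
        if g.kind not in GEOMETRIES:
            bad.append(f"geometry.kind={g.kind!r}")
        if n.dt <= 0 or n.dx <= 0 or n.D < 0:
            bad.append("numerics (dt, dx must be > 0; D >= 0)")
        elif g.kind != "cell" and n.D * n.dt / n.dx ** 2 > 0.25 + 1e-12:
            bad.append(f"numerics: D*dt/dx^2 = {n.D * n.dt / n.dx ** 2:.3f} "
                       "violates the stability bound 1/4")
        if self.params not in PARAM_SETS:
            bad.append(f"params={self.params!r}")
        try:
            self.ionic_params()
        except (TypeError, ValueError) as e:
            bad.append(f"param_overrides: {e}")
        try:
            self.chr2_params()
        except (TypeError, ValueError) as e:
            bad.append(f"chr2: {e}")
        try:
            self.light_protocol()
        except (TypeError, ValueError) as e:
            bad.append(f"light: {e}")
        try:
            self.stim_protocol()
        except (TypeError, ValueError) as e:
            bad.append(f"pace: {e}")
        if bad:
            raise ConfigError("invalid config keys: " + "; ".join(bad))
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = GeometrySpec(**d["geometry"])
        if "numerics" in d and isinstance(d["numerics"], dict):
            d["numerics"] = Numerics(**d["numerics"])
        if "recorders" in d and isinstance(d["recorders"], dict):
            rs = dict(d["recorders"])
            rs["trace_sites"] = [tuple(s) for s in rs.get("trace_sites", [])]
            d["recorders"] = RecorderSpec(**rs)
        cfg = cls(**d)
        return cfg.validate()


def _region_from(spec) -> Region:
    if spec is None:
        return Region()
    if spec == "left-edge":
        return Region(x1=4)
    if spec == "lower-half":
        return Region()  # resolved against the domain at run time by callers
    if isinstance(spec, dict):
        return Region(**spec)
    raise ConfigError(f"unknown region spec: {spec!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise ConfigError."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
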