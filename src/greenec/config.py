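"""Run configuration: one plain-text (YAML) file drives a reproducible run."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import EnsembleGenConfig, StationGenConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All knobs of the pipeline, with the analysis defaults.

    ``delta_co2_1980_2015`` (ppm) is the CO2 increase over the inversion
    record used by the NPP scaling; ``co2_pi`` the pre-industrial 284 ppm
    reference; the GPP:NPP factor is 0.5 with 10% relative uncertainty.
    """

    seed: int = 0
    band: tuple[float, float] = (60.0, 90.0)
    obs_window: tuple[int, int] = (1982, 2016)
    model_window: tuple[int, int] = (1971, 2005)
    mk_alpha: float = 0.1
    bootstrap_m_min: int = 100
    bootstrap_tol: float = 0.01
    bootstrap_m_max: int = 10_000
    x_points: int = 2001
    y_points: int = 2001
    span_sd: float = 5.0
    co2_pi: float = 284.0
    npp_factor: float = 0.5
    npp_factor_rel_sd: float = 0.10
    delta_co2_1980_2015: float = 56.8
    run_drawdown: bool = True
    drawdown_min_years: int = 30
    ensemble: EnsembleGenConfig = field(default_factory=EnsembleGenConfig)
    station: StationGenConfig = field(default_factory=StationGenConfig)

    def __post_init__(self) -> None:
        for name in ("mk_alpha", "bootstrap_tol", "co2_pi", "npp_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")
        # generators follow the run seed unless overridden in the file
        self.ensemble = dataclasses.replace(self.ensemble, seed=self.seed)
        self.station = dataclasses.replace(self.station, seed=self.seed + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["obs_window"] = list(self.obs_window)
        d["model_window"] = list(self.model_window)
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file with keyword overrides.

    Nested ``ensemble:`` and ``station:`` blocks map onto the generator
    configs; every other key maps onto a RunConfig field.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    ens = data.pop("ensemble", {})
    sta = data.pop("station", {})
    for key in ("band", "obs_window", "model_window"):
        if key in data:
            data[key] = tuple(data[key])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if ens:
        cfg.ensemble = dataclasses.replace(cfg.ensemble, **ens)
    if sta:
        cfg.station = dataclasses.replace(cfg.station, **sta)
    return cfg
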