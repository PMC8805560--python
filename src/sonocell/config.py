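"""Run configuration: one flat, serializable record covering every stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .membrane import ParameterError

__all__ = ["RunConfig", "PRESETS"]


@dataclass
class RunConfig:
    """Flat parameter set for the coupled pipeline (SI units unless noted).

    Stimulus defaults follow the measurement protocol: 6.72 MHz carrier,
    1 MPa amplitude, 50 ms burst.  ``t_pre``/``t_post`` pad the simulated
    window around the burst; spike latency is measured from burst onset.
    """

    # membrane / fluid
    d: float = 10.0e-6
    gamma: float = 1.0e-3
    rho: float = 1000.0
    eta: float = 1.0e-3
    # stimulus
    P0: float = 1.0e6
    f: float = 6.72e6
    t_pre: float = 1.0e-3
    t_dur: float = 50.0e-3
    t_post: float = 5.0e-3
    # membrane solver
    n_modes: int = 101
    geometry_factor: str = "pi_over_d"
    cutoff: float = 1.0e5          # slow-time low-pass cutoff [Hz]
    dt_slow: float = 1.0e-6        # slow-time sampling [s]
    nx: int = 401
    # coupling
    L: float = 5.0e-9
    eps_r: float = 2.0
    Cm0: float = 1.0
    savgol_window: int = 7
    # neuron
    rtol: float = 1.0e-6
    atol: float = 1.0e-8
    spike_threshold: float = 0.0
    refractory_ms: float = 2.0
    # bookkeeping
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.dt_slow <= 0 or self.cutoff <= 0:
            raise ParameterError("dt_slow and cutoff must be positive")
        if self.cutoff >= 0.5 / self.dt_slow:
            raise ParameterError(
                "cutoff must be below the slow-grid Nyquist frequency "
                f"({0.5 / self.dt_slow:g} Hz)"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


#: named stimulus presets: (P0 [Pa], t_dur [s])
PRESETS = {
    "short-low": {"P0": 0.5e6, "t_dur": 5.0e-3},
    "short-high": {"P0": 1.0e6, "t_dur": 5.0e-3},
    "long-low": {"P0": 0.5e6, "t_dur": 50.0e-3},
    "long-high": {"P0": 1.0e6, "t_dur": 50.0e-3},
}
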