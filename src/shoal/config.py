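"""Simulation configuration: model parameters, units, and TOML round-trip.

Units throughout: length in body lengths L (30 mm), time in units of
T = L / v_f = 0.3 s where v_f = 100 mm/s is the typical cruising speed,
so the dimensionless cruise speed is v0 = 1.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: physical size of one body length, millimetres
BODY_LENGTH_MM = 30.0
#: physical duration of one simulation time unit, seconds
TIME_UNIT_S = 0.3

__all__ = ["SimulationConfig", "load_config", "dump_config",
           "BODY_LENGTH_MM", "TIME_UNIT_S"]


@dataclass
class SimulationConfig:
    """All parameters of the shoal model.

    The interaction defaults are the shipped reference parameter set: a
    strong, short-ranged spring-like attraction with built-in repulsion,
    a weak alignment torque, moderate dipolar hydrodynamic coupling, and
    a 60-degree blind zone behind each fish.  With these values a group
    of three switches intermittently between schooling, milling and
    swarming.  They are a tunable model choice, not measured fish
    parameters.
    """

    n_fish: int = 3
    v0: float = 1.0                 # cruise speed, L/T
    d_phi: float = 0.015            # rotational diffusion coefficient, rad^2/T
    arena_radius: float = 66.7      # tank radius R, L
    dt: float = 0.05                # integrator step, T
    n_steps: int = 100_000          # recorded steps after burn-in
    burn_in: int = 10_000           # discarded initial steps
    seed: int = 0
    stride: int = 1                 # record every stride-th step

    # wall avoidance: magnitude k_w * exp(-(R - |r|)/lambda_w), inward
    wall_strength: float = 4.0
    wall_decay: float = 2.0

    # attraction-repulsion spring: k_att*(r - r_eq) toward the neighbour,
    # zero beyond r_cut, magnitude capped at f_max
    k_att: float = 3.0
    k_rep: float = 8.0
    r_eq: float = 1.0
    r_cut: float = 30.0
    f_max: float = 3.0

    # alignment torque: k_al * sin(phi_j - phi_i) * exp(-r/r_al)
    k_al: float = 0.12
    r_al: float = 3.0

    # hydrodynamic dipole strength (advection + core vorticity)
    s_h: float = 0.9
    hyd_core: float = 1.5           # regularisation radius of the dipole, L

    # perception: neighbour influences att/al only within this half-angle
    # of the heading (150 deg = 60 deg blind zone behind)
    fov_half_angle_deg: float = 150.0

    # speed model
    speed_model: str = "fixed"      # "fixed" | "variable"
    tau_v: float = 2.0              # speed relaxation time, T
    v_floor: float = 0.05           # lower clip for variable speed, L/T

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.arena_radius > 0:
            raise ValueError("arena_radius must be positive")
        if not 0 < self.fov_half_angle_deg <= 180:
            raise ValueError("fov_half_angle_deg must be in (0, 180]")
        for name in ("v0", "d_phi", "wall_strength", "wall_decay", "k_att", "k_rep",
                     "r_eq", "r_cut", "f_max", "k_al", "r_al", "s_h",
                     "tau_v", "v_floor", "stride"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.speed_model not in ("fixed", "variable"):
            raise ValueError("speed_model must be 'fixed' or 'variable'")

    @property
    def frame_interval_s(self) -> float:
        """Seconds between recorded frames."""
        return self.dt * self.stride * TIME_UNIT_S

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def log(self) -> None:
        """Log every parameter at run start, for reproducibility."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def dump_config(config: SimulationConfig, path) -> None:
    """Write a flat TOML file with one key per configuration field."""
    lines = [
        f"# shoal simulation config; units: L = {BODY_LENGTH_MM} mm, "
        f"T = {TIME_UNIT_S} s"
    ]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {_format_value(getattr(config, f.name))}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path, **overrides) -> SimulationConfig:
    """Read a flat TOML config, applying keyword overrides on top."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    data.update(overrides)
    return SimulationConfig(**data)
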