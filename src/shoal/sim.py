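"""Agent-based shoal model: overdamped heading dynamics in a circular arena.

Each fish i moves at speed v_i (constant v0 by default) along its heading
phi_i and can only turn:

    dx_i/dt   = v_i cos(phi_i) + u_x(r_i)
    dy_i/dt   = v_i sin(phi_i) + u_y(r_i)
    dphi_i/dt = (1/v_i) (F_wall + F_att) . e_phi
                + sum_j k_al sin(phi_j - phi_i) exp(-r_ij / r_al)
                + omega(r_i)/2 + eta_i

where e_phi = (-sin phi_i, cos phi_i) is the turning direction, eta_i is
zero-mean Gaussian white noise with <eta_i(t) eta_j(t')> =
2 D_phi delta_ij delta(t - t'), and u, omega are the flow and vorticity
of the summed hydrodynamic dipoles of the other fish.  Forces:

* wall:       k_w exp(-(R - |r_i|)/lambda_w), pointing inward — a soft
              repulsive boundary at radius R;
* attraction: a spring k_att (r_ij - r_eq) toward each visible
              neighbour within r_cut, magnitude capped at f_max; the
              sign change at r_eq builds in short-range repulsion;
* alignment:  a weak torque toward each visible neighbour's heading;
* perception: neighbours influence the attraction and alignment
              channels only inside a field of view of half-angle
              theta_fov about the heading (hydrodynamics is felt
              regardless — flow does not require vision);
* hydrodynamics: each fish sources a 2D potential dipole of strength
              s_h v_j along its heading, regularised inside a core of
              radius ``hyd_core``; others are advected by the summed
              flow and turned by half its (core-only) vorticity.

Integration is Euler-Maruyama with synchronous updates.  Units: length
in body lengths L, time in T = 0.3 s, so v0 = 1 and D_phi = 0.015.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import SimulationConfig
from .trajectory import TrajectoryDataset

logger = logging.getLogger(__name__)

__all__ = ["SimState", "wall_force", "pair_interactions", "step",
           "variable_speed_step", "simulate", "initial_state"]

# indices into the packed parameter vector handed to the numba kernels
_P_V0, _P_DPHI, _P_R, _P_DT, _P_KW, _P_LAMW, _P_KATT, _P_REQ, _P_RCUT, \
    _P_FMAX, _P_KAL, _P_RAL, _P_SH, _P_EPSH, _P_COSFOV, _P_VAR, _P_TAUV, \
    _P_VFLOOR, _P_KREP = range(19)


def _pack(config: SimulationConfig) -> np.ndarray:
    p = np.empty(19)
    p[_P_KREP] = config.k_rep
    p[_P_V0] = config.v0
    p[_P_DPHI] = config.d_phi
    p[_P_R] = config.arena_radius
    p[_P_DT] = config.dt
    p[_P_KW] = config.wall_strength
    p[_P_LAMW] = config.wall_decay
    p[_P_KATT] = config.k_att
    p[_P_REQ] = config.r_eq
    p[_P_RCUT] = config.r_cut
    p[_P_FMAX] = config.f_max
    p[_P_KAL] = config.k_al
    p[_P_RAL] = config.r_al
    p[_P_SH] = config.s_h
    p[_P_EPSH] = config.hyd_core
    p[_P_COSFOV] = math.cos(math.radians(config.fov_half_angle_deg))
    p[_P_VAR] = 1.0 if config.speed_model == "variable" else 0.0
    p[_P_TAUV] = config.tau_v
    p[_P_VFLOOR] = config.v_floor
    return p


@dataclass
class SimState:
    """Instantaneous simulation state."""

    positions: np.ndarray   # (N, 2), body lengths
    headings: np.ndarray    # (N,), radians in (-pi, pi]
    speeds: np.ndarray      # (N,), L/T
    step_count: int = 0

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.headings.copy(),
                        self.speeds.copy(), self.step_count)


@njit(cache=True)
def _wall(x, y, p):
    """Soft exponential wall: magnitude k_w exp(-(R-|r|)/lam), inward."""
    rho = math.sqrt(x * x + y * y)
    mag = p[_P_KW] * math.exp(-(p[_P_R] - rho) / p[_P_LAMW])
    if rho < 1e-12:
        return 0.0, 0.0
    return -mag * x / rho, -mag * y / rho


@njit(cache=True)
def _interactions(pos, phi, spd, p, f_att, torque, flow, omega):
    """Fill per-fish attraction forces, alignment torques, dipolar flow
    and core vorticity.  Channels are kept separate for inspection."""
    n = pos.shape[0]
    for i in range(n):
        f_att[i, 0] = 0.0
        f_att[i, 1] = 0.0
        torque[i] = 0.0
        flow[i, 0] = 0.0
        flow[i, 1] = 0.0
        omega[i] = 0.0
    if (p[_P_KATT] == 0.0 and p[_P_KREP] == 0.0 and p[_P_KAL] == 0.0
            and p[_P_SH] == 0.0):
        return
    eps_h = p[_P_EPSH]
    for i in range(n):
        hx = math.cos(phi[i])
        hy = math.sin(phi[i])
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            r = math.sqrt(dx * dx + dy * dy)
            if r < 1e-12:
                # coincident fish: deterministic tiny separation
                if i < j:
                    dx, dy = 1e-6, 0.0
                else:
                    dx, dy = -1e-6, 0.0
                r = 1e-6
            ex = dx / r
            ey = dy / r
            visible = (hx * ex + hy * ey) >= p[_P_COSFOV]
            if visible:
                if r <= p[_P_RCUT]:
                    k = p[_P_KATT] if r >= p[_P_REQ] else p[_P_KREP]
                    mag = k * (r - p[_P_REQ])
                    if mag > p[_P_FMAX]:
                        mag = p[_P_FMAX]
                    elif mag < -p[_P_FMAX]:
                        mag = -p[_P_FMAX]
                    f_att[i, 0] += mag * ex
                    f_att[i, 1] += mag * ey
                torque[i] += (p[_P_KAL] * math.sin(phi[j] - phi[i])
                              * math.exp(-r / p[_P_RAL]))
            # hydrodynamics: flow at i sourced by j (not vision-gated)
            if p[_P_SH] > 0.0:
                px = math.cos(phi[j])
                py = math.sin(phi[j])
                # d points from source j to fish i
                ddx = -dx
                ddy = -dy
                dhx = ddx / r
                dhy = ddy / r
                rr = r if r > eps_h else eps_h
                pref = p[_P_SH] * spd[j] / (rr * rr)
                dp = dhx * px + dhy * py
                flow[i, 0] += pref * (2.0 * dp * dhx - px)
                flow[i, 1] += pref * (2.0 * dp * dhy - py)
                if r < eps_h:
                    # curl is zero outside the regularised core
                    cr = px * dhy - py * dhx   # sin(alpha - psi_j)
                    rc = r if r > 0.1 else 0.1
                    omega[i] += 2.0 * p[_P_SH] * spd[j] * cr / (eps_h * eps_h * rc)


@njit(cache=True)
def _step_inplace(pos, phi, spd, p, xi, f_att, torque, flow, omega):
    """One synchronous Euler-Maruyama step; returns False on blow-up."""
    n = pos.shape[0]
    _interactions(pos, phi, spd, p, f_att, torque, flow, omega)
    dt = p[_P_DT]
    amp = math.sqrt(2.0 * p[_P_DPHI] * dt)
    variable = p[_P_VAR] > 0.5
    ok = True
    for i in range(n):
        fwx, fwy = _wall(pos[i, 0], pos[i, 1], p)
        fx = fwx + f_att[i, 0]
        fy = fwy + f_att[i, 1]
        ephix = -math.sin(phi[i])
        ephiy = math.cos(phi[i])
        dphi = (dt * ((fx * ephix + fy * ephiy) / spd[i]
                      + torque[i] + 0.5 * omega[i])
                + amp * xi[i])
        new_phi = phi[i] + dphi
        # wrap to (-pi, pi]
        new_phi = new_phi - 2.0 * math.pi * math.floor(
            (new_phi + math.pi) / (2.0 * math.pi))
        if variable:
            ehx = math.cos(phi[i])
            ehy = math.sin(phi[i])
            v = spd[i] + dt * ((p[_P_V0] - spd[i]) / p[_P_TAUV]
                               + fx * ehx + fy * ehy)
            if v < p[_P_VFLOOR]:
                v = p[_P_VFLOOR]
            spd[i] = v
        phi[i] = new_phi
        pos[i, 0] += dt * (spd[i] * math.cos(new_phi) + flow[i, 0])
        pos[i, 1] += dt * (spd[i] * math.sin(new_phi) + flow[i, 1])
        if not (math.isfinite(pos[i, 0]) and math.isfinite(pos[i, 1])
                and math.isfinite(phi[i]) and math.isfinite(spd[i])):
            ok = False
    return ok


@njit(cache=True)
def _run(pos, phi, spd, p, noise, out, burn_in, stride):
    """Advance through all noise rows, recording every stride-th
    post-burn-in step into ``out``.  Returns the index of the first bad
    step, or -1 on success."""
    n = pos.shape[0]
    f_att = np.empty((n, 2))
    torque = np.empty(n)
    flow = np.empty((n, 2))
    omega = np.empty(n)
    rec = 0
    for t in range(noise.shape[0]):
        ok = _step_inplace(pos, phi, spd, p, noise[t], f_att, torque,
                           flow, omega)
        if not ok:
            return t
        if t >= burn_in and (t - burn_in) % stride == 0:
            if rec < out.shape[0]:
                out[rec, :, 0] = pos[:, 0]
                out[rec, :, 1] = pos[:, 1]
                rec += 1
    return -1


def wall_force(position, config: SimulationConfig) -> np.ndarray:
    """Wall-avoidance force at a point: k_w exp(-(R - |r|)/lambda_w)
    directed from the wall toward the arena centre."""
    x, y = float(position[0]), float(position[1])
    return np.array(_wall(x, y, _pack(config)))


def pair_interactions(state: SimState, config: SimulationConfig) -> dict:
    """Per-fish interaction channels for the current state.

    Returns a dict with ``attraction`` (N, 2) forces, ``alignment``
    (N,) heading torques, ``flow`` (N, 2) hydrodynamic advection
    velocities and ``vorticity`` (N,) local flow vorticities.
    """
    n = state.positions.shape[0]
    f_att = np.empty((n, 2))
    torque = np.empty(n)
    flow = np.empty((n, 2))
    omega = np.empty(n)
    _interactions(np.ascontiguousarray(state.positions, dtype=float),
                  np.asarray(state.headings, dtype=float),
                  np.asarray(state.speeds, dtype=float),
                  _pack(config), f_att, torque, flow, omega)
    return {"attraction": f_att, "alignment": torque, "flow": flow,
            "vorticity": omega}


def step(state: SimState, config: SimulationConfig,
         noise: np.ndarray | None = None,
         rng: np.random.Generator | None = None) -> SimState:
    """Advance the state by one Euler-Maruyama step.

    ``noise`` supplies the per-fish standard-normal heading increments;
    if omitted they are drawn from ``rng`` (or zeros if that is also
    omitted, giving the deterministic drift update).
    """
    new = state.copy()
    n = new.positions.shape[0]
    if noise is None:
        noise = rng.standard_normal(n) if rng is not None else np.zeros(n)
    noise = np.asarray(noise, dtype=float)
    f_att = np.empty((n, 2))
    torque = np.empty(n)
    flow = np.empty((n, 2))
    omega = np.empty(n)
    ok = _step_inplace(new.positions, new.headings, new.speeds,
                       _pack(config), noise, f_att, torque, flow, omega)
    if not ok:
        raise RuntimeError(
            f"non-finite state after step {state.step_count + 1}")
    new.step_count += 1
    return new


def variable_speed_step(state: SimState, config: SimulationConfig,
                        noise: np.ndarray | None = None,
                        rng: np.random.Generator | None = None) -> SimState:
    """One step of the variable-speed model: the speed relaxes toward
    v0 with time constant tau_v and responds to the force component
    along the heading; requires ``config.speed_model == "variable"``.
    """
    if config.speed_model != "variable":
        raise ValueError("config.speed_model must be 'variable'")
    return step(state, config, noise=noise, rng=rng)


def initial_state(config: SimulationConfig,
                  rng: np.random.Generator) -> SimState:
    """Random start: fish clustered in a small disc at the arena centre
    with uniform random headings, at cruise speed."""
    n = config.n_fish
    r0 = max(2.0, 1.2 * math.sqrt(n))
    r = r0 * np.sqrt(rng.uniform(size=n))
    a = rng.uniform(-np.pi, np.pi, size=n)
    pos = np.stack([r * np.cos(a), r * np.sin(a)], axis=1)
    phi = rng.uniform(-np.pi, np.pi, size=n)
    spd = np.full(n, config.v0)
    return SimState(pos, phi, spd)


def simulate(config: SimulationConfig,
             initial: SimState | None = None) -> TrajectoryDataset:
    """Run the model and return the recorded 2D trajectory.

    ``config.n_steps`` frames are recorded every ``config.stride`` steps
    after ``config.burn_in`` discarded steps.  The same seed and config
    always reproduce the identical trajectory.
    """
    config.log()
    rng = np.random.default_rng(config.seed)
    state = initial.copy() if initial is not None else initial_state(config, rng)
    total = config.burn_in + config.n_steps * config.stride
    noise = rng.standard_normal((total, config.n_fish))
    out = np.empty((config.n_steps, config.n_fish, 2))
    p = _pack(config)
    bad = _run(state.positions, state.headings, state.speeds, p, noise,
               out, config.burn_in, config.stride)
    if bad >= 0:
        raise RuntimeError(f"non-finite state at step {bad}")
    logger.info("simulate: N=%d recorded %d frames (dt=%g, stride=%d)",
                config.n_fish, config.n_steps, config.dt, config.stride)
    return TrajectoryDataset(
        out, np.arange(config.n_steps), np.arange(config.n_fish),
        frame_interval=config.frame_interval_s,
    )
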