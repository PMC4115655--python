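"""Synthetic session generator.

Emulates a rat performing a pellet-chasing task in an open-field arena
(96 cm circle or 60 x 60 cm square), tracked by two head-mounted LEDs, together
with spike trains of the unit classes the analysis pipeline targets:
von Mises head-direction cells (with optional CW/CCW preferred-direction
offset), Gaussian place cells, theta and theta-cycle-skipping cells (a theta
oscillation plus a half-frequency component that attenuates alternate cycles),
and homogeneous Poisson units.

The trajectory is a mean-reverting (Ornstein-Uhlenbeck) angular-velocity and
speed process integrated with specular reflection at the arena wall: a smooth,
space-filling random walk whose 20-minute sessions cover the arena and all
72 directional bins, so the pipeline's inclusion rules pass as they would for
a well-behaved recording session.

All spike trains are inhomogeneous Poisson processes generated by thinning;
given the same inputs and seed, outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as _signal

from .errors import InvalidArgumentError
from .session import ArenaSpec, GroundTruth, SpikeTrain, Trajectory

# Rig geometry: two LEDs on the head stage, front and back, along the head axis.
LED_SEPARATION_CM = 6.0

# Foraging-walk parameters (a brisk pellet-chasing rat).
_MEAN_SPEED = 20.0        # cm/s
_SPEED_SD = 8.0           # cm/s, stationary SD of the OU speed process
_SPEED_TAU = 1.0          # s, speed correlation time
_OMEGA_SD = 160.0         # deg/s, stationary SD of the OU angular velocity
_OMEGA_TAU = 0.5          # s, angular-velocity correlation time
_WALL_MARGIN = 1.0        # cm kept between LED midpoint and the wall


def _ou_series(n: int, dt: float, mean: float, sd: float, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path via its exact AR(1) recursion."""
    if n == 0:
        return np.empty(0)
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    x0 = rng.normal(0.0, sd)
    noise = rng.normal(0.0, innov_sd, size=n - 1)
    devs = _signal.lfilter([1.0], [1.0, -a], np.concatenate(([x0], noise)))
    return mean + devs


def simulate_trajectory(arena: ArenaSpec, duration_s: float, sample_rate: float = 50.0,
                        seed: int = 0) -> Trajectory:
    """Simulate a foraging trajectory in the given arena.

    Parameters
    ----------
    arena
        Arena geometry; the walk reflects off its wall.
    duration_s
        Session length in seconds. ``duration_s=0`` yields a single-sample
        trajectory (the documented degenerate convention).
    sample_rate
        Tracker rate in Hz (default 50).
    seed
        Seed for the random generator; identical calls are bit-reproducible.
    """
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be positive")
    if duration_s < 0:
        raise InvalidArgumentError("duration_s must be >= 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    n = int(round(duration_s * sample_rate)) + 1
    t = np.arange(n) * dt

    speed = np.clip(_ou_series(n, dt, _MEAN_SPEED, _SPEED_SD, _SPEED_TAU, rng), 1.0, None)
    omega = _ou_series(n, dt, 0.0, _OMEGA_SD, _OMEGA_TAU, rng)  # deg/s, math (CCW+) sense
    dphi = np.deg2rad(omega) * dt

    half = arena.half_extent_cm - _WALL_MARGIN
    circle = arena.shape == "circle"

    xs = np.empty(n)
    ys = np.empty(n)
    phis = np.empty(n)
    # Start at a uniform random point well inside the wall, random heading.
    while True:
        x, y = rng.uniform(-half, half, size=2)
        if not circle or math.hypot(x, y) < 0.8 * half:
            break
    phi = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(n):
        xs[k], ys[k], phis[k] = x, y, phi
        if k == n - 1:
            break
        phi += dphi[k]
        step = speed[k] * dt
        nx = x + step * math.cos(phi)
        ny = y + step * math.sin(phi)
        if circle:
            r = math.hypot(nx, ny)
            if r > half:
                ux, uy = nx / r, ny / r
                over = r - half
                nx -= 2.0 * over * ux
                ny -= 2.0 * over * uy
                # reflect velocity about the tangent
                vx, vy = math.cos(phi), math.sin(phi)
                dot = vx * ux + vy * uy
                phi = math.atan2(vy - 2.0 * dot * uy, vx - 2.0 * dot * ux)
                if math.hypot(nx, ny) > half:  # very large step: clamp inside
                    s = 0.999 * half / math.hypot(nx, ny)
                    nx *= s
                    ny *= s
        else:
            if nx > half:
                nx = 2.0 * half - nx
                phi = math.pi - phi
            elif nx < -half:
                nx = -2.0 * half - nx
                phi = math.pi - phi
            if ny > half:
                ny = 2.0 * half - ny
                phi = -phi
            elif ny < -half:
                ny = -2.0 * half - ny
                phi = -phi
            nx = min(max(nx, -half), half)
            ny = min(max(ny, -half), half)
        x, y = nx, ny
    head = np.column_stack([np.cos(phis), np.sin(phis)]) * (LED_SEPARATION_CM / 2.0)
    mid = np.column_stack([xs, ys])
    return Trajectory(timestamps=t, led_front=mid + head, led_back=mid - head,
                      arena=arena, sample_rate=sample_rate)


def _thin(rate_at, lam_max: float, duration_s: float,
          rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [0, duration] by thinning.

    ``rate_at`` maps an array of times to intensities (must be <= lam_max).
    """
    if lam_max <= 0 or duration_s <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    if n_cand == 0:
        return cand
    accept = rng.uniform(0.0, 1.0, size=n_cand) * lam_max < rate_at(cand)
    return cand[accept]


def _nearest_sample(times: np.ndarray, traj: Trajectory) -> np.ndarray:
    idx = np.rint(np.asarray(times) * traj.sample_rate).astype(int)
    return np.clip(idx, 0, traj.n_samples - 1)


def generate_hd_spike_train(traj: Trajectory, truth: GroundTruth, seed: int = 0,
                            unit_id: str = "hd0") -> SpikeTrain:
    """Head-direction cell: lambda(t) = b + peak exp(kappa (cos(theta - theta_p) - 1)).

    With a nonzero ``cw_ccw_offset_deg`` the preferred direction shifts by
    +offset/2 during clockwise head turns and -offset/2 during
    counter-clockwise turns (sign taken from the smoothed angular velocity in
    the package's CW-positive convention), giving a ground-truth separation
    angle equal to the full offset.
    """
    if truth.cell_kind != "hd":
        raise InvalidArgumentError("truth.cell_kind must be 'hd'")
    from . import tracking  # late import; tracking depends only on session

    hd = tracking.head_direction_from_leds(traj)
    av = tracking.angular_velocity(hd)
    theta = hd.theta_deg
    pref = truth.preferred_direction_deg + np.where(
        av.omega_deg_per_s >= 0.0, 0.5, -0.5) * truth.cw_ccw_offset_deg
    lam_samples = truth.baseline_hz + truth.peak_rate_hz * np.exp(
        truth.kappa * (np.cos(np.deg2rad(theta - pref)) - 1.0))

    def rate_at(ts):
        return lam_samples[_nearest_sample(ts, traj)]

    rng = np.random.default_rng(seed)
    spikes = _thin(rate_at, truth.baseline_hz + truth.peak_rate_hz, traj.duration_s, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=spikes, session_duration=traj.duration_s)


def generate_place_spike_train(traj: Trajectory, truth: GroundTruth, seed: int = 0,
                               unit_id: str = "pl0") -> SpikeTrain:
    """Place cell: lambda(t) = b + peak exp(-|x(t) - c|^2 / (2 sigma^2))."""
    if truth.cell_kind != "place":
        raise InvalidArgumentError("truth.cell_kind must be 'place'")
    pos = traj.midpoints
    d2 = np.sum((pos - np.asarray(truth.field_center_xy)) ** 2, axis=1)
    lam_samples = truth.baseline_hz + truth.peak_rate_hz * np.exp(
        -d2 / (2.0 * truth.field_sigma_cm ** 2))

    def rate_at(ts):
        return lam_samples[_nearest_sample(ts, traj)]

    rng = np.random.default_rng(seed)
    spikes = _thin(rate_at, truth.baseline_hz + truth.peak_rate_hz, traj.duration_s, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=spikes, session_duration=traj.duration_s)


def generate_theta_skipping_train(duration_s: float, truth: GroundTruth, seed: int = 0,
                                  unit_id: str = "ts0") -> SpikeTrain:
    """Theta / theta-cycle-skipping cell.

    lambda(t) = r0 [1 + m1 cos(2 pi f t) + m2 cos(pi f t)] with r0 =
    ``truth.baseline_hz``, f = ``truth.f_theta_hz`` (default 8.67 Hz, the
    high-theta regime), m1 = ``depth_theta`` and m2 = ``depth_skip``. The
    half-frequency cosine attenuates every second theta cycle, producing the
    alternating low/high autocorrelogram peaks at lags 1/f and 2/f.
    """
    if truth.cell_kind not in ("theta", "theta_skipping", "poisson"):
        raise InvalidArgumentError("truth.cell_kind must be theta, theta_skipping or poisson")
    if duration_s < 0:
        raise InvalidArgumentError("duration_s must be >= 0")
    r0 = truth.baseline_hz
    m1, m2 = truth.depth_theta, truth.depth_skip
    if truth.cell_kind == "poisson":
        m1 = m2 = 0.0
    two_pi_f = 2.0 * math.pi * truth.f_theta_hz

    def rate_at(ts):
        lam = r0 * (1.0 + m1 * np.cos(two_pi_f * ts) + m2 * np.cos(0.5 * two_pi_f * ts))
        return np.clip(lam, 0.0, None)  # clipped at 0 if depths ever sum past 1

    rng = np.random.default_rng(seed)
    spikes = _thin(rate_at, r0 * (1.0 + m1 + m2), duration_s, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=spikes, session_duration=duration_s)


def write_session(directory, traj: Trajectory, trains, truths=None, seed=None):
    """Write a session as delimited text; see :mod:`hdtheta.io`."""
    from . import io as _io

    return _io.write_session(directory, traj, trains, truths=truths, seed=seed)
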