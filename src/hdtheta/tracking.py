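"""Head direction, angular velocity and occupancy from two-LED tracking.

Sign convention (important): head direction is the mathematical bearing of the
front-minus-back LED vector, counter-clockwise positive, in [0, 360). Angular
velocity is reported CLOCKWISE-POSITIVE, i.e. the negated time derivative of
the mathematical bearing, so that "+120 deg/s" selects clockwise head turns.
Screen-coordinate pipelines often invert this; all thresholds in this package
assume the CW-positive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidArgumentError
from .session import ArenaSpec, Trajectory
from ._circular import wrap_deg

DEFAULT_DIR_BIN_DEG = 5.0
DEFAULT_SPATIAL_BIN_CM = 2.5


@dataclass
class HeadDirectionSeries:
    """Per-sample head direction in degrees, [0, 360); NaN where the LEDs coincided."""

    timestamps: np.ndarray
    theta_deg: np.ndarray
    sample_rate: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.theta_deg)


@dataclass
class AngularVelocitySeries:
    """Signed angular head velocity, degrees/second, positive = clockwise."""

    timestamps: np.ndarray
    omega_deg_per_s: np.ndarray


@dataclass
class DirectionalOccupancy:
    """Dwell time and visit counts per directional bin (default 72 x 5 deg)."""

    bin_edges_deg: np.ndarray     # n_bins + 1 edges, 0..360
    dwell_s: np.ndarray
    visits: np.ndarray

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    @property
    def n_bins(self) -> int:
        return self.dwell_s.size

    @property
    def all_sampled(self) -> bool:
        return bool(np.all(self.dwell_s > 0))


@dataclass
class OccupancyMap:
    """2-D dwell-time map over the arena bounding box.

    ``dwell_s[i, j]`` is time spent in x-bin i, y-bin j; ``in_arena`` flags
    bins whose centre lies inside the arena wall.
    """

    x_edges_cm: np.ndarray
    y_edges_cm: np.ndarray
    dwell_s: np.ndarray
    in_arena: np.ndarray
    bin_cm: float
    arena: ArenaSpec

    @property
    def coverage_fraction(self) -> float:
        """Fraction of in-arena bins with nonzero dwell."""
        n_in = int(np.sum(self.in_arena))
        if n_in == 0:
            return 0.0
        return float(np.sum((self.dwell_s > 0) & self.in_arena)) / n_in


@dataclass
class InclusionResult:
    """Session-level inclusion decision.

    The session enters analysis only if the animal visited at least 90% of
    the in-arena spatial bins and dwelt in every directional bin.
    """

    coverage_fraction: float
    spatial_ok: bool
    directional_ok: bool

    @property
    def passed(self) -> bool:
        return self.spatial_ok and self.directional_ok


def head_direction_from_leds(traj: Trajectory) -> HeadDirectionSeries:
    """Head direction per tracker sample from the LED pair.

    theta = atan2(front - back), CCW-positive, wrapped to [0, 360). Samples
    where the LEDs coincide become NaN; a trajectory with no valid sample is
    rejected.
    """
    d = traj.led_front - traj.led_back
    coincident = (d[:, 0] == 0) & (d[:, 1] == 0)
    theta = wrap_deg(np.rad2deg(np.arctan2(d[:, 1], d[:, 0])))
    theta[coincident] = np.nan
    if np.all(coincident):
        raise InvalidArgumentError("all LED pairs coincide; no head direction available")
    return HeadDirectionSeries(timestamps=traj.timestamps, theta_deg=theta,
                               sample_rate=traj.sample_rate)


def angular_velocity(hd: HeadDirectionSeries,
                     smooth_window_samples: int = 5) -> AngularVelocitySeries:
    """Angular head velocity from the head-direction series.

    Unwraps the heading, takes a central finite difference, applies a boxcar
    of ``smooth_window_samples`` (1 disables smoothing), and negates so that
    positive values mean clockwise rotation.
    """
    if smooth_window_samples < 1:
        raise InvalidArgumentError("smooth_window_samples must be >= 1")
    if hd.theta_deg.size < 2:
        raise InvalidArgumentError("need at least 2 samples for angular velocity")
    theta = hd.theta_deg.copy()
    bad = ~np.isfinite(theta)
    if bad.any():  # interpolate through NaN gaps before differencing
        idx = np.arange(theta.size)
        theta[bad] = np.interp(idx[bad], idx[~bad], theta[~bad])
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(theta)))
    dmath = np.gradient(unwrapped, hd.timestamps)
    omega = -dmath  # CW-positive
    w = smooth_window_samples
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.pad(omega, pad, mode="edge")
        omega = np.convolve(padded, kernel, mode="same")[pad:pad + omega.size]
    return AngularVelocitySeries(timestamps=hd.timestamps, omega_deg_per_s=omega)


def _direction_bin_index(theta_deg: np.ndarray, bin_deg: float) -> np.ndarray:
    return np.floor(wrap_deg(theta_deg) / bin_deg).astype(int)


def directional_occupancy(hd: HeadDirectionSeries,
                          bin_deg: float = DEFAULT_DIR_BIN_DEG) -> DirectionalOccupancy:
    """Dwell and visit counts per directional bin.

    Dwell per bin is (samples in bin) / sample_rate; a visit is an entry into
    a bin (the first valid sample counts as one entry).
    """
    n_bins_f = 360.0 / bin_deg
    if bin_deg <= 0 or abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise InvalidArgumentError("bin_deg must evenly divide 360")
    n_bins = int(round(n_bins_f))
    valid = hd.valid
    theta = hd.theta_deg[valid]
    idx = _direction_bin_index(theta, bin_deg)
    dt = 1.0 / hd.sample_rate
    dwell = np.bincount(idx, minlength=n_bins).astype(float) * dt
    visits = np.zeros(n_bins, dtype=int)
    if idx.size:
        entries = idx[np.concatenate(([True], np.diff(idx) != 0))]
        visits = np.bincount(entries, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_deg
    return DirectionalOccupancy(bin_edges_deg=edges, dwell_s=dwell, visits=visits)


def _arena_grid(arena: ArenaSpec, bin_cm: float):
    half = arena.half_extent_cm
    n = int(np.ceil(2.0 * half / bin_cm))
    edges = -half + np.arange(n + 1) * bin_cm
    cx = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(cx, cx, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    in_arena = arena.contains(centers).reshape(n, n)
    return edges, in_arena


def spatial_occupancy(traj: Trajectory, bin_cm: float = DEFAULT_SPATIAL_BIN_CM) -> OccupancyMap:
    """Dwell-time map over the arena, accumulated at LED midpoints."""
    if bin_cm <= 0:
        raise InvalidArgumentError("bin_cm must be positive")
    edges, in_arena = _arena_grid(traj.arena, bin_cm)
    pos = traj.midpoints
    dt = 1.0 / traj.sample_rate
    h, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[edges, edges])
    return OccupancyMap(x_edges_cm=edges, y_edges_cm=edges, dwell_s=h * dt,
                        in_arena=in_arena, bin_cm=bin_cm, arena=traj.arena)


def joint_occupancy(traj: Trajectory, hd: HeadDirectionSeries,
                    bin_cm: float = DEFAULT_SPATIAL_BIN_CM,
                    bin_deg: float = DEFAULT_DIR_BIN_DEG):
    """Joint dwell t(x, y, theta): seconds spent in each position x heading cell.

    Returns ``(dwell, x_edges, dir_edges)`` where ``dwell`` has shape
    (nx, ny, n_dir). This is the substrate of the distributive-hypothesis
    prediction of apparent directional tuning from a spatial rate map.
    """
    if bin_cm <= 0:
        raise InvalidArgumentError("bin_cm must be positive")
    edges, _ = _arena_grid(traj.arena, bin_cm)
    n_dir = int(round(360.0 / bin_deg))
    dir_edges = np.arange(n_dir + 1) * bin_deg
    valid = hd.valid
    pos = traj.midpoints[valid]
    theta = wrap_deg(hd.theta_deg[valid])
    sample = np.column_stack([pos, np.minimum(theta, 360.0 - 1e-9)])
    dwell, _ = np.histogramdd(sample, bins=[edges, edges, dir_edges])
    return dwell / traj.sample_rate, edges, dir_edges


def session_inclusion(occ: OccupancyMap, docc: DirectionalOccupancy,
                      coverage_threshold: float = 0.9) -> InclusionResult:
    """Apply the exploration and directional-sampling inclusion rules."""
    cov = occ.coverage_fraction
    return InclusionResult(coverage_fraction=cov,
                           spatial_ok=cov >= coverage_threshold,
                           directional_ok=docc.all_sampled)
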