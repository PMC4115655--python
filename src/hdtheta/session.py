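"""Core session containers: arena geometry, tracking, spike trains, ground truth.

An arena is centred on the origin. Positions are in centimetres, times in
seconds. A trajectory carries the two head-mounted LED coordinates per tracker
sample; the animal's position is taken as the LED midpoint and its head
direction as the front-minus-back LED bearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidArgumentError

CIRCLE = "circle"
SQUARE = "square"


@dataclass(frozen=True)
class ArenaSpec:
    """Open-field arena geometry.

    ``circle`` uses ``diameter_cm`` (default 96 cm), ``square`` uses
    ``side_cm`` (default 60 cm). Both are centred on (0, 0).
    """

    shape: str = CIRCLE
    diameter_cm: float = 96.0
    side_cm: float = 60.0

    def __post_init__(self):
        if self.shape not in (CIRCLE, SQUARE):
            raise InvalidArgumentError(f"unknown arena shape {self.shape!r}")
        if self.diameter_cm <= 0 or self.side_cm <= 0:
            raise InvalidArgumentError("arena dimensions must be positive")

    @property
    def half_extent_cm(self) -> float:
        """Half-width of the bounding box."""
        return self.diameter_cm / 2.0 if self.shape == CIRCLE else self.side_cm / 2.0

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (n, 2) points lie inside the arena."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.shape == CIRCLE:
            return np.hypot(xy[:, 0], xy[:, 1]) <= self.diameter_cm / 2.0 + 1e-9
        h = self.side_cm / 2.0
        return (np.abs(xy[:, 0]) <= h + 1e-9) & (np.abs(xy[:, 1]) <= h + 1e-9)


@dataclass
class Trajectory:
    """Two-LED tracking time series on a uniform clock.

    ``led_front``/``led_back`` are (n, 2) arrays of cm coordinates; the head
    points from back to front. Midpoints are guaranteed inside the arena;
    the LEDs themselves may poke slightly past the wall.
    """

    timestamps: np.ndarray
    led_front: np.ndarray
    led_back: np.ndarray
    arena: ArenaSpec
    sample_rate: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.led_front = np.asarray(self.led_front, dtype=float)
        self.led_back = np.asarray(self.led_back, dtype=float)
        n = self.timestamps.size
        if self.led_front.shape != (n, 2) or self.led_back.shape != (n, 2):
            raise InvalidArgumentError("LED arrays must be (n, 2) matching timestamps")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        """(n - 1) / sample_rate for a uniform clock."""
        return (self.n_samples - 1) / self.sample_rate if self.n_samples else 0.0

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.led_front + self.led_back)


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit within one session."""

    unit_id: str
    spike_times: np.ndarray
    session_duration: float

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise InvalidArgumentError("spike_times must be one-dimensional")
        if np.any(~np.isfinite(self.spike_times)):
            raise InvalidArgumentError("spike_times must be finite")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.session_duration + 1e-9
        ):
            raise InvalidArgumentError("spike times must lie within [0, session_duration]")
        if np.any(np.diff(self.spike_times) < 0):
            raise InvalidArgumentError("spike_times must be sorted ascending")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of one synthetic unit.

    ``cell_kind`` selects the intensity model:

    - ``hd``: von Mises directional tuning, optionally with a clockwise /
      counter-clockwise preferred-direction offset (``cw_ccw_offset_deg`` is
      the full CW-minus-CCW separation).
    - ``place``: isotropic Gaussian place field.
    - ``theta`` / ``theta_skipping``: rate r0 [1 + m1 cos(2 pi f t)
      + m2 cos(pi f t)]; the half-frequency term produces alternate-cycle
      skipping. r0 is ``baseline_hz``.
    - ``poisson``: homogeneous at ``baseline_hz``.
    """

    cell_kind: str
    preferred_direction_deg: float = 90.0
    kappa: float = 4.0
    peak_rate_hz: float = 30.0
    baseline_hz: float = 0.5
    cw_ccw_offset_deg: float = 0.0
    field_center_xy: Tuple[float, float] = (0.0, 0.0)
    field_sigma_cm: float = 8.0
    f_theta_hz: float = 8.67
    depth_theta: float = 0.6
    depth_skip: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.cell_kind not in ("hd", "place", "theta", "theta_skipping", "poisson"):
            raise InvalidArgumentError(f"unknown cell_kind {self.cell_kind!r}")
        if self.kappa < 0:
            raise InvalidArgumentError("kappa must be >= 0")
        if self.peak_rate_hz < 0 or self.baseline_hz < 0:
            raise InvalidArgumentError("rates must be >= 0")
        if not (0.0 <= self.preferred_direction_deg < 360.0):
            raise InvalidArgumentError("preferred_direction_deg must lie in [0, 360)")
        if self.depth_theta < 0 or self.depth_skip < 0:
            raise InvalidArgumentError("modulation depths must be >= 0")
        if self.depth_theta + self.depth_skip > 1.0 + 1e-12:
            raise InvalidArgumentError("depth_theta + depth_skip must be <= 1 (non-negative intensity)")
        if self.field_sigma_cm <= 0:
            raise InvalidArgumentError("field_sigma_cm must be positive")

    # Convenience constructors with field-realistic defaults per kind.
    @classmethod
    def hd_cell(cls, preferred_direction_deg=90.0, kappa=4.0, peak_rate_hz=30.0,
                baseline_hz=0.5, cw_ccw_offset_deg=0.0, seed=0) -> "GroundTruth":
        return cls(cell_kind="hd", preferred_direction_deg=preferred_direction_deg,
                   kappa=kappa, peak_rate_hz=peak_rate_hz, baseline_hz=baseline_hz,
                   cw_ccw_offset_deg=cw_ccw_offset_deg, seed=seed)

    @classmethod
    def place_cell(cls, field_center_xy=(0.0, 0.0), field_sigma_cm=8.0,
                   peak_rate_hz=20.0, baseline_hz=0.1, seed=0) -> "GroundTruth":
        return cls(cell_kind="place", field_center_xy=tuple(field_center_xy),
                   field_sigma_cm=field_sigma_cm, peak_rate_hz=peak_rate_hz,
                   baseline_hz=baseline_hz, seed=seed)

    @classmethod
    def theta_skipping_cell(cls, rate_hz=5.0, depth_theta=0.6, depth_skip=0.4,
                            f_theta_hz=8.67, seed=0) -> "GroundTruth":
        return cls(cell_kind="theta_skipping", baseline_hz=rate_hz,
                   depth_theta=depth_theta, depth_skip=depth_skip,
                   f_theta_hz=f_theta_hz, seed=seed)

    @classmethod
    def theta_cell(cls, rate_hz=5.0, depth_theta=0.6, f_theta_hz=8.67, seed=0) -> "GroundTruth":
        return cls(cell_kind="theta", baseline_hz=rate_hz, depth_theta=depth_theta,
                   depth_skip=0.0, f_theta_hz=f_theta_hz, seed=seed)

    @classmethod
    def poisson_cell(cls, rate_hz=0.5, seed=0) -> "GroundTruth":
        return cls(cell_kind="poisson", baseline_hz=rate_hz, peak_rate_hz=0.0, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)
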