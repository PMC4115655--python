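"""Unit-category assignment and cross-day unit matching.

The taxonomy mirrors the population breakdown of a midline-thalamus recording
study: head-direction, theta-cycle-skipping, other theta-modulated, fast
firing, weakly-theta-modulated, other spatially-tuned, and unidentified
low-firing units. The numeric thresholds separating the non-HD categories are
documented conventions of this package (the source taxonomy reports the
categories but no rules); all live in :class:`SessionConfig` and are
configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields as _dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError, MissingMetricError
from .hd import HDMetrics
from .skipping import SkippingFit, SkippingIndices
from .spatial import SpatialMetrics


class UnitCategory(str, enum.Enum):
    HD = "hd"
    THETA_SKIPPING = "theta_skipping"
    THETA_MODULATED = "theta_modulated"
    FAST_FIRING = "fast_firing"
    WEAKLY_THETA_MODULATED = "weakly_theta_modulated"
    SPATIALLY_TUNED = "spatially_tuned"
    UNIDENTIFIED_LOW_FIRING = "unidentified_low_firing"


@dataclass
class SkippingSummary:
    """Temporal-modulation inputs to classification."""

    is_skipping: bool
    theta_depth: float          # a1 / (a1 + b) from the autocorrelogram fit
    converged: bool = True


@dataclass(frozen=True)
class SessionConfig:
    """All tunable analysis thresholds and bin sizes.

    Serialises to/from a plain ``key = value`` text block; round-trips
    byte-identically.
    """

    spatial_bin_cm: float = 2.5
    direction_bin_deg: float = 5.0
    cw_ccw_threshold_deg_per_s: float = 120.0
    coverage_threshold: float = 0.9
    rayleigh_r_threshold: float = 0.4       # HD-cell criterion (convention)
    rayleigh_p_threshold: float = 0.01
    min_hd_spikes: int = 100
    jump_factor_threshold: float = 0.2
    theta_depth_modulated: float = 0.3
    theta_depth_weak: float = 0.1
    fast_firing_hz: float = 10.0
    spatial_info_threshold: float = 0.5     # bits/spike for "spatially tuned"
    match_max_distance: float = 1.0
    seed: int = 0

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in _dc_fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SessionConfig":
        kw = {}
        types = {f.name: f.type for f in _dc_fields(cls)}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InvalidArgumentError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise InvalidArgumentError(f"unknown config key: {key!r}")
            kw[key] = int(val) if types[key] == "int" else float(val)
        return cls(**kw)


def classify_unit(hd_metrics: Optional[HDMetrics],
                  spatial: Optional[SpatialMetrics],
                  skipping: Optional[SkippingSummary],
                  avg_rate_hz: Optional[float],
                  config: SessionConfig = SessionConfig()) -> UnitCategory:
    """Assign exactly one category to a unit from its computed metrics.

    Precedence: hd > theta_skipping > spatially_tuned > theta_modulated >
    fast_firing > weakly_theta_modulated > unidentified_low_firing. A missing
    (None) metric raises :class:`MissingMetricError` naming it.
    """
    for name, value in (("hd_metrics", hd_metrics), ("spatial", spatial),
                        ("skipping", skipping), ("avg_rate_hz", avg_rate_hz)):
        if value is None:
            raise MissingMetricError(name)
    if (hd_metrics.rayleigh_r >= config.rayleigh_r_threshold
            and hd_metrics.rayleigh_p < config.rayleigh_p_threshold
            and hd_metrics.n_spikes >= config.min_hd_spikes):
        return UnitCategory.HD
    if skipping.is_skipping:
        return UnitCategory.THETA_SKIPPING
    if (spatial.fields
            and spatial.information_bits_per_spike >= config.spatial_info_threshold):
        return UnitCategory.SPATIALLY_TUNED
    if skipping.converged and skipping.theta_depth >= config.theta_depth_modulated:
        return UnitCategory.THETA_MODULATED
    if avg_rate_hz > config.fast_firing_hz:
        return UnitCategory.FAST_FIRING
    if skipping.converged and skipping.theta_depth >= config.theta_depth_weak:
        return UnitCategory.WEAKLY_THETA_MODULATED
    return UnitCategory.UNIDENTIFIED_LOW_FIRING


def category_percentages(counts: Dict[str, int], total: int,
                         decimals: int = 1) -> Dict[str, float]:
    """Percentages of a population breakdown, rounded to the printed precision."""
    if total <= 0:
        raise InvalidArgumentError("total must be positive")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


@dataclass(frozen=True)
class UnitWaveformStats:
    """Waveform features used to match units across recording days."""

    amplitude: float
    height: float
    duration_ms: float

    def __post_init__(self):
        vals = (self.amplitude, self.height, self.duration_ms)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InvalidArgumentError("waveform stats must be positive and finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.amplitude, self.height, self.duration_ms])


def match_units_across_days(day_a: Sequence[UnitWaveformStats],
                            day_b: Sequence[UnitWaveformStats],
                            max_distance: float = 1.0
                            ) -> List[Tuple[Optional[int], Optional[int], Optional[float]]]:
    """Greedy one-to-one matching on z-scored (amplitude, height, duration).

    Features are z-scored over the pooled population; the matching repeatedly
    links the globally closest remaining pair whose normalised Euclidean
    distance (divided by sqrt(3)) stays within ``max_distance``. Returns
    triples (index_a, index_b, distance); unmatched units appear with a None
    partner.
    """
    if not day_a or not day_b:
        raise InvalidArgumentError("both day lists must be non-empty")
    fa = np.array([u.as_array() for u in day_a])
    fb = np.array([u.as_array() for u in day_b])
    pooled = np.vstack([fa, fb])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    za = (fa - mu) / sd
    zb = (fb - mu) / sd
    dist = np.sqrt(((za[:, None, :] - zb[None, :, :]) ** 2).sum(axis=2)) / np.sqrt(3.0)
    pairs = []
    free_a = set(range(len(day_a)))
    free_b = set(range(len(day_b)))
    order = np.argsort(dist, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > max_distance:
            break
        if i in free_a and j in free_b:
            pairs.append((int(i), int(j), float(dist[i, j])))
            free_a.discard(int(i))
            free_b.discard(int(j))
    for i in sorted(free_a):
        pairs.append((i, None, None))
    for j in sorted(free_b):
        pairs.append((None, j, None))
    return pairs
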