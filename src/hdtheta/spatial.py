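"""Rate maps and spatial firing statistics.

Implements the measures used to verify that head-direction units are not
place-modulated: Skaggs spatial information (bits/spike), place-field
detection (side-sharing connected components of pixels above 20% of the peak
rate, minimum nine pixels), spatial selectivity (peak/mean rate), and average
firing frequency. A "pixel" is one occupancy bin; metric maps default to 5 cm
pixels (coverage assessment uses the finer 2.5 cm grid). No smoothing is
applied by default; an optional boxcar is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as _ndimage

from .errors import InvalidArgumentError, UndefinedMetricError
from .session import SpikeTrain, Trajectory
from .tracking import OccupancyMap

FIELD_RATE_FRACTION = 0.2   # pixels above this fraction of the peak may join a field
FIELD_MIN_PIXELS = 9        # minimum side-sharing pixels for a place field
FIELD_MIN_CONTRAST = 2.0    # field mean rate must exceed this multiple of the map mean
#: Pixel size for metric maps (information, selectivity, fields). Coarser than
#: the 2.5 cm occupancy grid so a 20-min session leaves ~4 s dwell per pixel;
#: at finer pixels the unsmoothed rate estimates are sampling-noise dominated.
DEFAULT_METRIC_BIN_CM = 5.0
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class RateMap:
    """Per-pixel firing rate (Hz). NaN marks unvisited or out-of-arena pixels."""

    rate_hz: np.ndarray
    spike_count: np.ndarray
    bin_cm: float
    in_arena: np.ndarray
    x_edges_cm: np.ndarray
    y_edges_cm: np.ndarray

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.rate_hz) & self.in_arena

    @property
    def peak_rate_hz(self) -> float:
        v = self.rate_hz[self.visited]
        return float(np.max(v)) if v.size else 0.0


@dataclass
class PlaceField:
    """One detected place field: a set of side-sharing supra-threshold pixels."""

    member_pixels: List[Tuple[int, int]]
    peak_pixel: Tuple[int, int]
    threshold_rate_hz: float

    @property
    def size_pixels(self) -> int:
        return len(self.member_pixels)

    def contains(self, pixel: Tuple[int, int]) -> bool:
        return tuple(pixel) in set(map(tuple, self.member_pixels))


@dataclass
class SpatialMetrics:
    information_bits_per_spike: float
    selectivity: float
    average_rate_hz: float
    fields: List[PlaceField] = field(default_factory=list)


def rate_map(spikes: SpikeTrain, traj: Trajectory, occ: OccupancyMap,
             smooth_window_bins: int = 1) -> RateMap:
    """Per-pixel rate = spike count / dwell, at LED-midpoint spike positions.

    ``smooth_window_bins > 1`` applies a boxcar to both spike counts and dwell
    before dividing (off by default).
    """
    if traj.duration_s <= 0:
        raise InvalidArgumentError("zero-duration session has no rate map")
    idx = np.clip(np.rint(spikes.spike_times * traj.sample_rate).astype(int),
                  0, traj.n_samples - 1)
    pos = traj.midpoints[idx]
    counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1],
                                  bins=[occ.x_edges_cm, occ.y_edges_cm])
    dwell = occ.dwell_s.astype(float)
    if smooth_window_bins > 1:
        k = np.ones((smooth_window_bins, smooth_window_bins))
        counts = _ndimage.convolve(counts, k, mode="constant")
        dwell = _ndimage.convolve(dwell, k, mode="constant")
    # rate defined wherever there is dwell (even border bins whose centre
    # falls outside the wall); the arena mask scopes the metrics instead
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dwell > 0, counts / np.maximum(dwell, 1e-300), np.nan)
    return RateMap(rate_hz=rate, spike_count=counts, bin_cm=occ.bin_cm,
                   in_arena=occ.in_arena, x_edges_cm=occ.x_edges_cm,
                   y_edges_cm=occ.y_edges_cm)


def spatial_information(rmap: RateMap, occ: OccupancyMap) -> float:
    """Skaggs spatial information, bits per spike.

    I = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar), with
    p_i the dwell fraction of visited pixel i and lambda_bar the dwell-weighted
    mean rate. Pixels with zero rate contribute zero. Undefined (raises) for a
    silent unit.
    """
    visited = rmap.visited
    dwell = occ.dwell_s[visited]
    lam = rmap.rate_hz[visited]
    total = dwell.sum()
    if total <= 0:
        raise UndefinedMetricError("no dwell time; information undefined")
    p = dwell / total
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        raise UndefinedMetricError("mean rate is zero; information undefined")
    pos = lam > 0
    ratio = lam[pos] / lam_bar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def detect_place_fields(rmap: RateMap,
                        rate_fraction: float = FIELD_RATE_FRACTION,
                        min_pixels: int = FIELD_MIN_PIXELS,
                        min_contrast: float = FIELD_MIN_CONTRAST) -> List[PlaceField]:
    """Detect place fields as side-sharing components above 20% of peak rate.

    Diagonal contact does not connect pixels. Components smaller than
    ``min_pixels`` (default nine) are discarded, as are components whose mean
    rate is below ``min_contrast`` times the map's mean visited-pixel rate:
    a field is a region of *elevated* firing, and without the contrast
    requirement any uniformly firing unit would qualify (its whole map sits
    above 20% of a peak close to the mean). ``min_contrast=0`` restores the
    plain threshold rule. An all-zero map yields no fields.
    """
    peak = rmap.peak_rate_hz
    if peak <= 0:
        return []
    threshold = rate_fraction * peak
    map_mean = float(np.mean(rmap.rate_hz[rmap.visited]))
    supra = np.where(rmap.visited, rmap.rate_hz > threshold, False)
    labels, n = _ndimage.label(supra, structure=_FOUR_CONN)
    fields = []
    for lab in range(1, n + 1):
        members = np.argwhere(labels == lab)
        if members.shape[0] < min_pixels:
            continue
        rates = rmap.rate_hz[members[:, 0], members[:, 1]]
        if np.mean(rates) < min_contrast * map_mean:
            continue
        peak_px = tuple(int(v) for v in members[int(np.argmax(rates))])
        fields.append(PlaceField(member_pixels=[tuple(int(v) for v in m) for m in members],
                                 peak_pixel=peak_px, threshold_rate_hz=threshold))
    fields.sort(key=lambda f: -f.size_pixels)
    return fields


def selectivity(rmap: RateMap, occ: OccupancyMap) -> float:
    """Spatial selectivity: maximal pixel rate / overall mean rate (>= 1)."""
    visited = rmap.visited
    dwell = occ.dwell_s[visited]
    lam = rmap.rate_hz[visited]
    if dwell.sum() <= 0:
        raise UndefinedMetricError("no dwell time; selectivity undefined")
    mean = float(np.sum(dwell * lam) / dwell.sum())
    if mean <= 0:
        raise UndefinedMetricError("mean rate is zero; selectivity undefined")
    return float(np.max(lam) / mean)


def average_frequency(spikes: SpikeTrain, duration_s: Optional[float] = None) -> float:
    """Average firing frequency: total spikes / total recording time (Hz)."""
    dur = spikes.session_duration if duration_s is None else duration_s
    if dur is None or dur <= 0:
        raise InvalidArgumentError("duration must be positive")
    return spikes.n_spikes / dur


def spatial_metrics(spikes: SpikeTrain, traj: Trajectory,
                    occ: Optional[OccupancyMap] = None,
                    bin_cm: float = DEFAULT_METRIC_BIN_CM) -> SpatialMetrics:
    """Convenience: rate map plus all spatial statistics for one unit.

    When ``occ`` is omitted, occupancy is computed at the metric pixel size
    (default 5 cm; the finer 2.5 cm grid serves coverage assessment, not rate
    estimation).
    """
    if occ is None:
        from .tracking import spatial_occupancy
        occ = spatial_occupancy(traj, bin_cm)
    rmap = rate_map(spikes, traj, occ)
    avg = average_frequency(spikes, traj.duration_s)
    if spikes.n_spikes == 0:
        return SpatialMetrics(information_bits_per_spike=0.0, selectivity=1.0,
                              average_rate_hz=0.0, fields=[])
    return SpatialMetrics(information_bits_per_spike=spatial_information(rmap, occ),
                          selectivity=selectivity(rmap, occ),
                          average_rate_hz=avg,
                          fields=detect_place_fields(rmap))
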