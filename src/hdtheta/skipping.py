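"""Spike-train autocorrelograms and the theta-cycle-skipping model fit.

The autocorrelogram (all ordered spike pairs, lags -1000..+1000 ms, 1 ms bins,
zero-lag self-pairs excluded) of a theta-cycle-skipping unit shows alternating
low and high peaks at lags 1/f and 2/f. The non-normalised counts are fitted
with a superposition of two decaying cosines plus exponential terms:

    y(x) = [a1 cos(w1 x) + a2 cos(w2 x)] exp(-|x| / tau1)
           + b + c1 exp(-|x| / tau2) - c2 exp(-|x| / tau3)

where the cosine arguments take the lag in seconds with angular frequencies in
rad/s (w1 in [12 pi, 24 pi] <=> 6-12 Hz theta; w2 in [6 pi, 12 pi] <=> 3-6 Hz,
the alternate-cycle component) while the exponentials take the lag in
milliseconds with time constants tau1 in [0, 5000], tau2 in [0, 100] and
tau3 in [0, 10] ms (slow envelope decay, the Poisson-ISI exponential, and the
refractory dip respectively). Amplitudes a1, a2, b, c1, c2 are bounded by
[0, N] with N the autocorrelogram peak.

Derived indices:

- jump factor a2 / (a1 + a2): relative contribution of the low-frequency
  cosine to the high peaks (> 0.5 means it dominates);
- frequency ratio w1 / w2 (close to 2 verifies the superposition model);
- theta-skipping index TS = (P2 - P1) / max(P1, P2) on the first two local
  maxima of the fitted curve after the centre peak; positive when alternate
  cycles are skipped, always in [-1, +1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import optimize as _optimize
from scipy import signal as _signal

from .errors import (InvalidArgumentError, NotConvergedError,
                     UndefinedMetricError)
from .session import SpikeTrain

OMEGA1_BOUNDS = (12.0 * math.pi, 24.0 * math.pi)   # rad/s, 6-12 Hz
OMEGA2_BOUNDS = (6.0 * math.pi, 12.0 * math.pi)    # rad/s, 3-6 Hz
TAU1_BOUNDS_MS = (1e-2, 5000.0)
TAU2_BOUNDS_MS = (1e-2, 100.0)
TAU3_BOUNDS_MS = (1e-2, 10.0)
REFRACTORY_MS = 2.0
REFRACTORY_MAX_FRACTION = 0.005   # "clean" refractory period criterion


@dataclass
class ISIHistogram:
    """Histogram of successive inter-spike intervals."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    refractory_fraction: float

    @property
    def refractory_clean(self) -> bool:
        return self.refractory_fraction < REFRACTORY_MAX_FRACTION


@dataclass
class Autocorrelogram:
    """All-pairs spike autocorrelogram, symmetric in lag."""

    lags_ms: np.ndarray    # bin centres, -max_lag..+max_lag
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.lags_ms.size

    @property
    def peak(self) -> float:
        """N: the peak of the autocorrelation signal."""
        return float(np.max(self.counts)) if self.counts.size else 0.0


@dataclass
class SkippingFit:
    """Fitted model parameters. Amplitudes in count units, taus in ms, omegas in rad/s."""

    a1: float
    a2: float
    b: float
    c1: float
    c2: float
    omega1: float
    omega2: float
    tau1: float
    tau2: float
    tau3: float
    residual_norm: float
    converged: bool
    n_peak: float   # the [0, N] amplitude bound used

    def params(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.b, self.c1, self.c2,
                         self.omega1, self.omega2, self.tau1, self.tau2, self.tau3])

    @property
    def f_high_hz(self) -> float:
        return self.omega1 / (2.0 * math.pi)

    @property
    def f_low_hz(self) -> float:
        return self.omega2 / (2.0 * math.pi)

    def predict(self, lags_ms: np.ndarray) -> np.ndarray:
        return model_curve(self.params(), lags_ms)

    def predict_envelope(self, lags_ms: np.ndarray) -> np.ndarray:
        """Rhythmic part of the fit: the two cosines times their decay, plus b.

        Excludes the centre-peak transients (c1, c2), whose rebound can
        otherwise masquerade as an early oscillation peak.
        """
        x_s = np.asarray(lags_ms, dtype=float) / 1000.0
        ax = np.abs(np.asarray(lags_ms, dtype=float))
        return ((self.a1 * np.cos(self.omega1 * x_s)
                 + self.a2 * np.cos(self.omega2 * x_s)) * np.exp(-ax / self.tau1)
                + self.b)


@dataclass
class SkippingIndices:
    jump_factor: float
    frequency_ratio: float
    ts_index: Optional[float]
    f_high_hz: float
    f_low_hz: float


def isi_histogram(spikes: SpikeTrain, bin_ms: float = 1.0,
                  max_ms: float = 500.0) -> ISIHistogram:
    """Successive inter-spike-interval histogram and refractory fraction.

    ``refractory_fraction`` is the fraction of intervals shorter than 2 ms;
    a well-isolated unit keeps it essentially at zero.
    """
    if spikes.n_spikes < 2:
        raise InvalidArgumentError("need at least 2 spikes for an ISI histogram")
    isi_ms = np.diff(spikes.spike_times) * 1000.0
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(np.clip(isi_ms, 0, max_ms - 1e-9), bins=edges)
    refr = float(np.mean(isi_ms < REFRACTORY_MS))
    return ISIHistogram(bin_edges_ms=edges, counts=counts, refractory_fraction=refr)


def autocorrelogram(spikes: SpikeTrain, max_lag_ms: float = 1000.0,
                    bin_ms: float = 1.0) -> Autocorrelogram:
    """All-ordered-pairs autocorrelogram on +-max_lag with 1 ms bins.

    Bin centres sit at integer multiples of ``bin_ms``; the zero-lag bin
    excludes self-pairs. Symmetric by construction: each unordered pair at
    lag L contributes one count at +L and one at -L.
    """
    if max_lag_ms <= 0 or bin_ms <= 0:
        raise InvalidArgumentError("max_lag_ms and bin_ms must be positive")
    if spikes.n_spikes < 2:
        raise InvalidArgumentError("need at least 2 spikes for an autocorrelogram")
    t = spikes.spike_times
    n_half = int(round(max_lag_ms / bin_ms))
    lags = np.arange(-n_half, n_half + 1) * bin_ms
    counts = np.zeros(2 * n_half + 1)
    edge_s = (max_lag_ms + 0.5 * bin_ms) / 1000.0
    # positive lags: for each spike, pairs with later spikes within the window
    hi = np.searchsorted(t, t + edge_s, side="left")
    pos_lags_ms = np.concatenate(
        [t[i + 1:hi[i]] - t[i] for i in range(t.size)]) * 1000.0 if t.size else np.empty(0)
    half_counts = np.zeros(n_half + 1)
    if pos_lags_ms.size:
        idx = np.rint(pos_lags_ms / bin_ms).astype(int)
        idx = idx[idx <= n_half]
        half_counts = np.bincount(idx, minlength=n_half + 1).astype(float)
    counts[n_half:] = half_counts
    counts[:n_half] = half_counts[:0:-1]
    counts[n_half] = 2.0 * half_counts[0]  # |lag| < bin/2 pairs, both orders
    return Autocorrelogram(lags_ms=lags, counts=counts)


def model_curve(params: np.ndarray, lags_ms: np.ndarray) -> np.ndarray:
    """Evaluate the two-cosine skipping model at the given lags (ms)."""
    a1, a2, b, c1, c2, w1, w2, t1, t2, t3 = params
    x_s = np.asarray(lags_ms, dtype=float) / 1000.0
    ax = np.abs(np.asarray(lags_ms, dtype=float))
    return ((a1 * np.cos(w1 * x_s) + a2 * np.cos(w2 * x_s)) * np.exp(-ax / t1)
            + b + c1 * np.exp(-ax / t2) - c2 * np.exp(-ax / t3))


def _initial_params(lags: np.ndarray, counts: np.ndarray, n_peak: float):
    """Signal-statistics initialisation for the non-frequency parameters."""
    tail = counts[lags >= 800.0]
    b0 = float(np.mean(tail)) if tail.size else float(np.mean(counts))
    near = counts[(lags >= 3.0) & (lags <= 30.0)]
    c10 = float(np.clip(np.mean(near) - b0 if near.size else 0.0, 0.0, n_peak))
    centre = counts[lags <= 2.0]
    c20 = float(np.clip(b0 + c10 - (np.mean(centre) if centre.size else b0),
                        0.0, n_peak))
    first_peak = counts[(lags >= 80.0) & (lags <= 150.0)]
    a_tot = float(np.clip((np.max(first_peak) if first_peak.size else b0) - b0,
                          1e-3, n_peak))
    b0 = float(np.clip(b0, 0.0, n_peak))
    return a_tot, b0, c10, c20


def fit_skipping_model(acorr: Autocorrelogram, n_freq_starts: int = 5) -> SkippingFit:
    """Bounded least-squares fit of the two-cosine model to the autocorrelogram.

    Runs a multi-start over an ``n_freq_starts x n_freq_starts`` grid of
    (omega1, omega2) initial values spanning their bounds; remaining parameters
    are initialised from signal statistics (tail mean for b, centre mass for
    c1/c2, first-peak excess for a1 + a2). The model is even in lag and the
    autocorrelogram symmetric, so the residual is evaluated on the
    non-negative lags only — the optimum is unchanged. The best residual wins;
    all parameters respect the printed bounds on exit.
    """
    if acorr.peak <= 0:
        raise InvalidArgumentError("autocorrelogram has no counts to fit")
    pos = acorr.lags_ms >= 0
    lags = acorr.lags_ms[pos]
    counts = acorr.counts[pos].astype(float)
    n_peak = acorr.peak
    lower = np.array([0.0, 0.0, 0.0, 0.0, 0.0,
                      OMEGA1_BOUNDS[0], OMEGA2_BOUNDS[0],
                      TAU1_BOUNDS_MS[0], TAU2_BOUNDS_MS[0], TAU3_BOUNDS_MS[0]])
    upper = np.array([n_peak, n_peak, n_peak, n_peak, n_peak,
                      OMEGA1_BOUNDS[1], OMEGA2_BOUNDS[1],
                      TAU1_BOUNDS_MS[1], TAU2_BOUNDS_MS[1], TAU3_BOUNDS_MS[1]])
    a_tot, b0, c10, c20 = _initial_params(lags, counts, n_peak)
    x_s = lags / 1000.0

    def residual(p):
        return model_curve(p, lags) - counts

    w1_grid = np.linspace(*OMEGA1_BOUNDS, n_freq_starts + 2)[1:-1]
    w2_grid = np.linspace(*OMEGA2_BOUNDS, n_freq_starts + 2)[1:-1]
    best = None
    any_ok = False
    for w1_0 in w1_grid:
        for w2_0 in w2_grid:
            p0 = np.clip(np.array([a_tot / 2, a_tot / 2, b0, c10, c20,
                                   w1_0, w2_0, 300.0, 30.0, 2.0]),
                         lower, upper)
            try:
                res = _optimize.least_squares(residual, p0, bounds=(lower, upper),
                                              method="trf", xtol=1e-10, ftol=1e-10)
            except Exception:
                continue
            any_ok = any_ok or res.success
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise NotConvergedError("no start of the skipping-model fit converged")
    p = np.clip(best.x, lower, upper)
    fit = SkippingFit(a1=p[0], a2=p[1], b=p[2], c1=p[3], c2=p[4],
                      omega1=p[5], omega2=p[6], tau1=p[7], tau2=p[8], tau3=p[9],
                      residual_norm=float(np.sqrt(2.0 * best.cost)),
                      converged=bool(any_ok), n_peak=n_peak)
    if not any_ok:
        raise NotConvergedError("skipping-model fit did not converge", best_fit=fit)
    return fit


def jump_factor(fit: SkippingFit) -> float:
    """a2 / (a1 + a2): relative contribution of the low-frequency cosine."""
    s = fit.a1 + fit.a2
    if s <= 0:
        raise UndefinedMetricError("a1 + a2 = 0; jump factor undefined")
    return fit.a2 / s


def frequency_ratio(fit: SkippingFit) -> float:
    """omega1 / omega2; close to 2 verifies the superposition model."""
    if fit.omega2 <= 0:
        raise UndefinedMetricError("omega2 = 0; frequency ratio undefined")
    return fit.omega1 / fit.omega2


def _curve_peaks(y: np.ndarray) -> np.ndarray:
    peaks, _ = _signal.find_peaks(y)
    return peaks


def theta_skipping_index(fit: SkippingFit, acorr: Autocorrelogram,
                         use_fitted: bool = True) -> float:
    """TS = (P2 - P1) / max(P1, P2) on the first two post-centre maxima.

    P1 and P2 are the heights of the first and second local maxima, after the
    centre peak and within +1000 ms, of the fitted rhythmic envelope — the
    cosine terms times their decay plus the baseline b, with the centre-peak
    transient exponentials excluded so their rebound cannot pose as an early
    peak. With ``use_fitted=False`` the raw counts are used instead, searching
    lags >= 40 ms (clear of the centre peak: the slowest admissible theta puts
    the first oscillation peak at 83 ms). Positive TS means the second peak
    exceeds the first — alternate theta cycles are skipped. Always in [-1, 1].
    """
    if not fit.converged:
        raise UndefinedMetricError("fit did not converge; TS undefined")
    if use_fitted:
        lags = np.arange(0.0, 1000.0 + 1.0, 1.0)
        y = fit.predict_envelope(lags)
        min_lag = 0.0
    else:
        pos = acorr.lags_ms >= 0
        lags = acorr.lags_ms[pos]
        y = acorr.counts[pos].astype(float)
        min_lag = 40.0
    peaks = _curve_peaks(y)
    peaks = peaks[lags[peaks] > min_lag]
    if peaks.size < 2:
        raise UndefinedMetricError("fewer than two post-centre maxima; TS undefined")
    p1, p2 = float(y[peaks[0]]), float(y[peaks[1]])
    denom = max(p1, p2)
    if denom <= 0:
        raise UndefinedMetricError("non-positive peak heights; TS undefined")
    return (p2 - p1) / denom


def skipping_indices(fit: SkippingFit, acorr: Autocorrelogram) -> SkippingIndices:
    """Assemble the derived indices; TS is None when undefined."""
    try:
        ts = theta_skipping_index(fit, acorr)
    except UndefinedMetricError:
        ts = None
    return SkippingIndices(jump_factor=jump_factor(fit) if fit.a1 + fit.a2 > 0 else 0.0,
                           frequency_ratio=frequency_ratio(fit),
                           ts_index=ts, f_high_hz=fit.f_high_hz, f_low_hz=fit.f_low_hz)


def oscillation_noise_floor(acorr: Autocorrelogram, n_sigma: float = 3.0) -> float:
    """Amplitude below which a fitted cosine is indistinguishable from noise.

    Estimated from the flat tail (|lag| >= 800 ms): a pure-noise cosine fitted
    to n bins of standard deviation s has amplitude ~ s sqrt(2/n).
    """
    tail = acorr.counts[np.abs(acorr.lags_ms) >= 800.0]
    if tail.size == 0:
        return 0.0
    n = acorr.n_bins
    return n_sigma * float(np.std(tail)) * math.sqrt(2.0 / n)


def theta_modulation_depth(fit: SkippingFit) -> float:
    """Relative depth of the theta cosine against the flat baseline: a1/(a1+b)."""
    if fit.a1 + fit.b <= 0:
        return 0.0
    return fit.a1 / (fit.a1 + fit.b)


def classify_theta_skipping(fit: SkippingFit, indices: SkippingIndices,
                            acorr: Autocorrelogram,
                            jump_threshold: float = 0.2) -> bool:
    """Decide whether a unit is a theta-cycle-skipping cell.

    True iff the fit converged, TS > 0, the jump factor reaches
    ``jump_threshold`` (a documented convention; the taxonomy itself states no
    numeric rule), and the summed cosine amplitude clears the tail-noise floor.
    """
    if not fit.converged or indices.ts_index is None:
        return False
    if fit.a1 + fit.a2 <= oscillation_noise_floor(acorr):
        return False
    return indices.ts_index > 0 and indices.jump_factor >= jump_threshold
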