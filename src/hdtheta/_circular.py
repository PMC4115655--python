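"""Circular-statistics helpers (degrees throughout).

All public angle-valued quantities in the package live in [0, 360) and all
signed angular differences in (-180, 180].
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError


def wrap_deg(theta):
    """Wrap angles to [0, 360)."""
    return np.mod(theta, 360.0)


def circ_diff_deg(a, b):
    """Signed circular difference a - b, wrapped to (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circ_mean_deg(theta_deg, weights=None):
    """Weighted circular mean direction in [0, 360).

    Raises if the resultant vector is (numerically) zero, in which case the
    mean direction is undefined.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    if th.size == 0:
        raise InvalidArgumentError("circular mean of empty input")
    w = np.ones_like(th) if weights is None else np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(th))
    s = np.sum(w * np.sin(th))
    if np.hypot(c, s) < 1e-12 * max(np.sum(np.abs(w)), 1.0):
        raise UndefinedDirectionError("resultant vector length ~ 0; mean direction undefined")
    return float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0))


class UndefinedDirectionError(InvalidArgumentError):
    """Resultant vector is zero; no mean direction exists."""


def rayleigh_test(theta_deg):
    """Rayleigh test of circular uniformity.

    Returns ``(mean_direction_deg, r, p)`` where ``r`` is the mean resultant
    length |sum e^{i theta}| / n and ``p`` follows the standard approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n r.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    n = th.size
    if n == 0:
        raise InvalidArgumentError("Rayleigh test needs at least one heading")
    c = np.sum(np.cos(th))
    s = np.sum(np.sin(th))
    big_r = float(np.hypot(c, s))
    r = big_r / n
    mean_dir = float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)) if big_r > 0 else 0.0
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)) - (1.0 + 2.0 * n)))
    return mean_dir, float(r), min(p, 1.0)
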