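"""Cardiac pulse modulation of spike amplitude.

Per-spike scaled projection weights (alpha') are windowed -0.1 s before to
0.9 s after each EKG R-wave, averaged across cardiac cycles into a binned
profile, baselined by the pre-R mean, and fit with the impulse-response form
``A * t**n * exp(-m*t)`` by trust-region-reflective nonlinear least squares.
A unit whose firing amplitude tracks the pulse yields a high R^2; an
unmodulated unit fits near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import CardiacFit, Recording
from .errors import DegenerateInputError, InvalidParameterError
from .synth import impulse_response

logger = logging.getLogger(__name__)

CARDIAC_WINDOW = (-0.1, 0.9)   # seconds around each R-wave
DEFAULT_BINS = 50
MIN_RR_S = 0.3                 # refractory separation between R-waves
ADAPT_FRACTION = 0.6           # of the rolling maximum
ADAPT_WINDOW_S = 2.0


def detect_r_waves(ekg: Recording) -> np.ndarray:
    """R-wave times (seconds) by adaptive-threshold peak picking.

    Threshold is 0.6 x the rolling 2 s maximum of the trace, peaks at least
    300 ms apart; scale-invariant, so amplifier gain does not matter.  A flat
    EKG returns an empty array with a warning.
    """
    x = ekg.samples
    if x.size == 0 or not np.any(x):
        logger.warning("flat EKG trace; no R-waves detected")
        return np.empty(0)
    w = max(1, int(round(ADAPT_WINDOW_S * ekg.rate)))
    roll = maximum_filter1d(x, size=w, mode="nearest")
    thr = ADAPT_FRACTION * np.maximum(roll, 1e-12 * np.max(np.abs(x)))
    peaks, _ = find_peaks(x, distance=max(1, int(MIN_RR_S * ekg.rate)))
    peaks = peaks[x[peaks] >= thr[peaks]]
    return peaks / ekg.rate


@dataclass
class CardiacProfile:
    """Binned alpha'-versus-cardiac-phase profile, baselined."""

    bin_centers: np.ndarray
    values: np.ndarray       # baselined mean alpha' per bin (nan = empty)
    counts: np.ndarray
    baseline: float
    n_spikes: int
    n_cycles: int
    n_dropped: int


def cardiac_profile(spike_times_s: np.ndarray, alpha_scaled: np.ndarray,
                    r_times_s: np.ndarray,
                    window: tuple[float, float] = CARDIAC_WINDOW,
                    n_bins: int = DEFAULT_BINS) -> CardiacProfile:
    """Average alpha' across cardiac cycles, relative to the R-wave.

    Each spike is assigned to the most recent R-wave whose window contains
    it; spikes outside every window are dropped and tallied.  The profile is
    baselined by the mean alpha' over the pre-R interval [window[0], 0).
    """
    t = np.asarray(spike_times_s, dtype=float)
    a = np.asarray(alpha_scaled, dtype=float)
    r = np.sort(np.asarray(r_times_s, dtype=float))
    if r.size == 0:
        raise InvalidParameterError("need at least one R-wave")
    lo, hi = window
    # most recent R whose window could contain the spike
    idx = np.searchsorted(r, t - lo, side="right") - 1
    rel = np.where(idx >= 0, t - r[np.clip(idx, 0, None)], np.inf)
    keep = (rel >= lo) & (rel < hi)
    n_dropped = int(np.sum(~keep))
    rel, a_k = rel[keep], a[keep]
    if rel.size == 0:
        raise DegenerateInputError("no spikes fall inside any cardiac window")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=a_k, minlength=n_bins)
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                      where=counts > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pre = (centers < 0) & (counts > 0)
    baseline = float(np.mean(means[pre])) if pre.any() else 0.0
    n_cycles = int(np.unique(idx[keep]).size)
    return CardiacProfile(centers, means - baseline, counts, baseline,
                          int(rel.size), n_cycles, n_dropped)


def _model(t, A, n, m):
    return impulse_response(t, A, n, m)


def fit_impulse_response(profile: CardiacProfile) -> CardiacFit:
    """Fit ``A * t**n * exp(-m*t)`` to the baselined post-R profile.

    Trust-region-reflective least squares from a small multi-start grid of
    (n, m) initials; parameters are unbounded in sign (an unmodulated unit
    can fit a negative decay).  R^2 is computed on the binned points used in
    the fit; total non-convergence returns a failure result, not an
    exception.
    """
    mask = (profile.bin_centers > 0) & np.isfinite(profile.values)
    t = profile.bin_centers[mask]
    y = profile.values[mask]
    if t.size < 5:
        raise InvalidParameterError("need >= 5 post-R bins with data")
    scale = float(np.max(np.abs(y))) or 1.0
    best, best_sse = None, np.inf
    for n0 in (0.5, 1.0, 2.0, 4.0):
        for m0 in (1.0, 5.0, 10.0, 20.0):
            f0 = (n0 / m0) ** n0 * np.exp(-n0)
            A0 = scale / f0 if f0 > 0 else scale
            try:
                popt, _ = curve_fit(_model, t, y, p0=[A0, n0, m0],
                                    method="trf", maxfev=1000)
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _model(t, *popt)) ** 2))
            if np.isfinite(sse) and sse < best_sse:
                best, best_sse = popt, sse
    common = dict(baseline=profile.baseline,
                  bin_centers=profile.bin_centers, profile=profile.values,
                  bin_counts=profile.counts, n_spikes=profile.n_spikes,
                  n_cycles=profile.n_cycles, n_dropped=profile.n_dropped)
    if best is None:
        return CardiacFit(np.nan, np.nan, np.nan, np.nan, success=False,
                          message="no start converged", **common)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else np.nan
    return CardiacFit(float(best[0]), float(best[1]), float(best[2]), r2,
                      success=True, **common)
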