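"""Spike detection and template-match sorting.

Pipeline stage conventions: the trace is zero-phase band-pass filtered
(300 Hz - 9 kHz), a negative threshold is set at -4 robust standard
deviations of the filtered trace, each downward crossing is aligned to the
largest-magnitude sample within 0.6 ms, and a 2 ms waveform (0.5 ms pre /
1.5 ms post alignment) is extracted.  Sorting assigns each waveform to the
template with the minimum normalized sum-of-squares difference, provided it
is within the fit tolerance; clusters are QC'd by the 2 ms refractory-
violation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import (Recording, SortResult, SpikeEvent, frame_samples,
                   post_samples, pre_samples)
from .errors import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

ALIGN_SEARCH_S = 0.6e-3   # alignment search window after a crossing
COLLAPSE_S = 0.5e-3       # crossings closer than this merge into one event
QC_REFRACTORY_PCT = 2.0   # flag units above this violation rate


def bandpass_filter(rec: Recording, low: float = 300.0,
                    high: float = 9000.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if not 0 < low < high:
        raise InvalidParameterError("need 0 < low < high")
    if high >= rec.rate / 2:
        raise InvalidParameterError("high cutoff must be below Nyquist")
    sos = butter(order, [low, high], btype="bandpass", fs=rec.rate,
                 output="sos")
    return rec.replace_samples(sosfiltfilt(sos, rec.samples))


def estimate_threshold(filtered: Recording,
                       multiplier: float = -4.0) -> float:
    """Detection threshold: ``multiplier`` x robust noise scale.

    The noise scale is ``median(|x|) / 0.6745``, the standard robust
    estimator of the background SD in the presence of spikes.
    """
    x = filtered.samples
    if x.size == 0 or not np.any(x):
        raise DegenerateInputError("cannot estimate threshold of a null trace")
    sigma = float(np.median(np.abs(x))) / 0.6745
    return multiplier * sigma


def detect_waveforms(filtered: Recording,
                     threshold: float) -> list[SpikeEvent]:
    """Detect negative-going threshold crossings and extract 2 ms waveforms.

    Each crossing is aligned to the largest-magnitude sample within 0.6 ms
    after it; crossings closer than 0.5 ms are collapsed to the larger
    extremum; events whose extraction frame does not fit inside the trace
    are discarded.  For positive-going detection, negate the trace.
    """
    if threshold >= 0:
        raise InvalidParameterError("threshold must be negative")
    x = filtered.samples
    rate = filtered.rate
    p, q = pre_samples(rate), post_samples(rate)
    w_align = max(1, int(round(ALIGN_SEARCH_S * rate)))
    w_collapse = int(round(COLLAPSE_S * rate))

    crossings = np.flatnonzero((x[1:] < threshold)
                               & (x[:-1] >= threshold)) + 1
    events: list[SpikeEvent] = []
    used: set[int] = set()
    i = 0
    while i < len(crossings):
        group = [crossings[i]]
        while (i + 1 < len(crossings)
               and crossings[i + 1] - group[-1] < w_collapse):
            i += 1
            group.append(crossings[i])
        i += 1
        best_align, best_mag = -1, -np.inf
        for c in group:
            seg = x[c:c + w_align]
            if seg.size == 0:
                continue
            a = c + int(np.argmax(np.abs(seg)))
            if np.abs(x[a]) > best_mag:
                best_align, best_mag = a, float(np.abs(x[a]))
        if best_align < p or best_align + q > x.size or best_align in used:
            continue
        used.add(best_align)
        events.append(SpikeEvent(time=best_align,
                                 waveform=x[best_align - p:best_align + q]
                                 .copy()))
    return events


@dataclass
class TemplateSelection:
    """Initial templates from PCA scores + k-means in 2-D score space."""

    templates: np.ndarray
    labels: np.ndarray
    degenerate: bool = False


def pca_template_selection(waveforms: np.ndarray, n_units: int,
                           seed: int = 0) -> TemplateSelection:
    """Seed templates: project onto the first two PCs, k-means, group means.

    A degenerate partition (an empty group, or groups whose mean waveforms
    coincide) is flagged; empty groups fall back to the grand mean.
    """
    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2 or W.shape[0] < n_units or n_units < 1:
        raise InvalidParameterError("need at least n_units waveforms")
    n_comp = min(2, W.shape[0], W.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(W)
    km = KMeans(n_clusters=n_units, n_init=10, random_state=seed)
    with np.errstate(all="ignore"):
        labels = km.fit_predict(scores)
    grand = W.mean(axis=0)
    templates = np.empty((n_units, W.shape[1]))
    degenerate = False
    for u in range(n_units):
        mask = labels == u
        if not mask.any():
            templates[u] = grand
            degenerate = True
        else:
            templates[u] = W[mask].mean(axis=0)
    for a in range(n_units):
        for b in range(a + 1, n_units):
            if np.allclose(templates[a], templates[b]):
                degenerate = True
    if degenerate:
        logger.warning("degenerate template partition (empty or identical "
                       "groups)")
    return TemplateSelection(templates, labels, degenerate)


def _normalized_ss(waveform: np.ndarray, templates: np.ndarray,
                   full_scale: float) -> np.ndarray:
    return np.mean((templates - waveform[None, :]) ** 2,
                   axis=1) / full_scale ** 2


def template_match_sort(events: list[SpikeEvent], templates: np.ndarray,
                        fit_tolerance: float = 0.25, rate: float = 44000.0,
                        full_scale: float | None = None,
                        refine_passes: int = 1,
                        threshold: float = np.nan) -> SortResult:
    """Assign each event to its minimum sum-of-squares template.

    The sum-of-squares distance is normalized: mean per-sample squared error
    divided by the squared full-scale value (default: the largest absolute
    template sample), so assignments are invariant to a common rescaling of
    trace and templates.  An event is assigned iff its minimum distance is
    within ``fit_tolerance``; exact ties go to the lower-indexed template and
    are logged.  ``refine_passes`` re-estimates templates from assignments
    and re-assigns.
    """
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    if templates.shape[0] < 1:
        raise InvalidParameterError("need at least one template")
    if not fit_tolerance > 0:
        raise InvalidParameterError("fit_tolerance must be positive")
    notes: list[str] = []
    if not events:
        return SortResult([], templates, fit_tolerance, rate,
                          threshold=threshold)
    fs = full_scale if full_scale is not None else float(
        np.max(np.abs(templates)))
    if fs <= 0:
        raise DegenerateInputError("templates are identically zero")

    cur = templates
    for _ in range(refine_passes + 1):
        n_ties = 0
        for e in events:
            ss = _normalized_ss(e.waveform, cur, fs)
            j = int(np.argmin(ss))
            if np.sum(ss == ss[j]) > 1:
                n_ties += 1
            e.unit_id = j if ss[j] <= fit_tolerance else None
        if n_ties:
            notes.append(f"{n_ties} sum-of-squares ties resolved to the "
                         "lower-indexed template")
            logger.info(notes[-1])
        new = cur.copy()
        for u in range(cur.shape[0]):
            w = [e.waveform for e in events if e.unit_id == u]
            if w:
                new[u] = np.mean(w, axis=0)
        if np.allclose(new, cur):
            break
        cur = new

    result = SortResult(events, cur, fit_tolerance, rate,
                        threshold=threshold, notes=notes)
    for u in range(cur.shape[0]):
        times = result.unit_spike_times(u)
        rv = refractory_violation_rate(times)
        result.refractory_rates[u] = rv
        result.qc_flags[u] = rv > QC_REFRACTORY_PCT
    return result


def refractory_violation_rate(spike_times_s: np.ndarray,
                              isi_threshold: float = 0.002) -> float:
    """Percent of spikes whose ISI to the previous spike is below threshold.

    ``100 * (# ISIs < isi_threshold) / (# spikes)``; fewer than 2 spikes
    yields 0.  Input must be sorted ascending.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise InvalidParameterError("spike times must be sorted ascending")
    if t.size < 2:
        return 0.0
    return 100.0 * float(np.sum(np.diff(t) < isi_threshold)) / t.size
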