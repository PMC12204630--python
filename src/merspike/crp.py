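"""Canonical-response parameterization (CRP) of sorted spike units.

The method discovers a unit's significant spike window empirically instead
of assuming a fixed waveform duration.  Individual spikes are projected onto
the unit's mean waveform with a semi-normalized dot product

    p_k(w) = <v_k[w], m_{-k}[w]> / ||v_k[w]||

where ``m_{-k}`` is the leave-one-out mean waveform and ``w`` a candidate
window.  Sweeping the window end forward from the alignment extremum, the
maximum of the mean profile S(w) marks the spike end time tau_R; sweeping the
window start backward from tau_R marks the spike start time tau_i.  The
unit-norm mean waveform over [tau_i, tau_R] is the canonical shape C(t);
each spike k then carries a projection weight

    alpha_k = <v_k, C>,      alpha'_k = alpha_k / sqrt(T)

(T = window sample count) so that the whole trace decomposes as
``V(t) = sum_k alpha_k C_{n(k)}(t' + tau_k) + Vo(t)`` with Vo the residual
local field potential.  Subtracting one parameterized unit and re-sorting
with the same threshold resolves overlapping spikes hidden inside larger
spikes' windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (Recording, SortResult, SpikeEvent, SpikeUnit,
                   post_samples, pre_samples)
from .errors import (DegenerateInputError, InsufficientSpikesError,
                     InvalidParameterError, NumericalError)

logger = logging.getLogger(__name__)

MIN_SPIKES = 5          # projection profiles need at least this many spikes
MIN_WINDOW_SAMPLES = 4
PLATEAU_RTOL = 1e-9     # ties within this relative tolerance of the maximum
SNR_CAP = 1e12          # sentinel when the residual energy is exactly zero


@dataclass
class ProjectionProfile:
    """Semi-normalized projection magnitude versus candidate window.

    ``offsets`` are window end offsets (forward) or start offsets (reverse)
    in samples relative to the alignment extremum; ``magnitudes`` the mean
    profile S(w) over spikes.
    """

    offsets: np.ndarray
    magnitudes: np.ndarray
    direction: str

    def argmax_offset(self) -> int:
        """Offset of the profile maximum; plateau ties break to the
        shortest window (earliest forward offset / latest reverse offset)."""
        m = self.magnitudes
        if not np.all(np.isfinite(m)):
            raise NumericalError("non-finite projection profile")
        top = m.max()
        tol = abs(top) * PLATEAU_RTOL
        near = np.flatnonzero(m >= top - tol)
        return int(self.offsets[near[0]])


def _profile_over_windows(W: np.ndarray, windows: list[slice]) -> np.ndarray:
    """Mean semi-normalized leave-one-out projection for each window."""
    n = W.shape[0]
    out = np.empty(len(windows))
    for i, sl in enumerate(windows):
        M = W[:, sl]
        s = M.sum(axis=0)
        # <v_k, m_{-k}> = (v_k . s - ||v_k||^2) / (n - 1)
        num = (M @ s - np.einsum("ij,ij->i", M, M)) / (n - 1)
        den = np.linalg.norm(M, axis=1)
        p = np.divide(num, den, out=np.zeros(n), where=den > 0)
        out[i] = p.mean()
    return out


def projection_profile(waveforms: np.ndarray, rate: float,
                       direction: str = "forward",
                       anchor: int | None = None) -> ProjectionProfile:
    """Temporal profile of projection magnitude for one unit's spikes.

    Forward: windows ``[0, e)`` for end offsets e = 1 .. +1.5 ms.  Reverse:
    windows ``[s, anchor)`` for start offsets s = -1 down to -0.5 ms, with
    ``anchor`` the end offset found by the forward pass (windows shorter than
    4 samples are not offered).
    """
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if W.shape[0] < MIN_SPIKES:
        raise InsufficientSpikesError(
            f"projection profile needs >= {MIN_SPIKES} spikes")
    p = pre_samples(rate)
    q = post_samples(rate)
    if W.shape[1] != p + q:
        raise InvalidParameterError("waveforms must span the 2 ms frame")
    if direction == "forward":
        offsets = np.arange(1, q + 1)
        windows = [slice(p, p + e) for e in offsets]
    elif direction == "reverse":
        if anchor is None or not 0 < anchor <= q:
            raise InvalidParameterError("reverse profile needs a valid anchor")
        s_hi = min(-1, anchor - MIN_WINDOW_SAMPLES)
        offsets = np.arange(s_hi, -p - 1, -1)
        windows = [slice(p + s, p + anchor) for s in offsets]
    else:
        raise InvalidParameterError("direction must be forward or reverse")
    mags = _profile_over_windows(W, windows)
    return ProjectionProfile(offsets, mags, direction)


def discover_spike_window(waveforms: np.ndarray,
                          rate: float) -> tuple[float, float]:
    """Empirical spike window ``(tau_i, tau_R)`` in seconds.

    tau_R is the forward-profile maximum; tau_i the reverse-profile maximum
    anchored at tau_R.  Deterministic: identical input yields an identical
    window.
    """
    fwd = projection_profile(waveforms, rate, "forward")
    end = fwd.argmax_offset()
    rev = projection_profile(waveforms, rate, "reverse", anchor=end)
    start = rev.argmax_offset()
    return start / rate, end / rate


def build_unit(unit_id: int, waveforms: np.ndarray, rate: float,
               spike_times: np.ndarray | None = None) -> SpikeUnit:
    """Construct a :class:`SpikeUnit` with its discovered window and C(t).

    With fewer than 5 spikes the window falls back to the full 2 ms frame
    and the unit is flagged (``window_fallback``).
    """
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    p, q = pre_samples(rate), post_samples(rate)
    fallback = False
    try:
        tau_i, tau_R = discover_spike_window(W, rate)
        start, end = int(round(tau_i * rate)), int(round(tau_R * rate))
    except InsufficientSpikesError:
        start, end = -p, q
        fallback = True
        logger.warning("unit %s: <%d spikes, window falls back to the full "
                       "frame", unit_id, MIN_SPIKES)
    mean_wf = W.mean(axis=0)
    seg = mean_wf[p + start:p + end]
    nrm = np.linalg.norm(seg)
    if nrm == 0:
        raise DegenerateInputError("mean waveform is zero over the window")
    return SpikeUnit(unit_id=unit_id, mean_waveform=mean_wf,
                     canonical_shape=seg / nrm, window_start=start,
                     window_end=end, rate=rate,
                     spike_times=(np.empty(0, int) if spike_times is None
                                  else np.asarray(spike_times)),
                     window_fallback=fallback)


def parameterize_spikes(events: list[SpikeEvent],
                        unit: SpikeUnit) -> list[SpikeEvent]:
    """Fill each event's projection weights alpha and alpha' (= alpha/sqrt T).

    alpha_k is the plain inner product of the spike's windowed waveform with
    the unit-norm canonical shape, so it is on the voltage scale; alpha'_k
    approximates the spike's rms voltage deflection over the window.
    """
    sl = unit.window_slice()
    C = unit.canonical_shape
    sqT = np.sqrt(unit.n_window_samples)
    for e in events:
        a = float(e.waveform[sl] @ C)
        e.alpha = a
        e.alpha_scaled = a / sqT
    return events


def spike_metrics(event: SpikeEvent, unit: SpikeUnit) -> SpikeEvent:
    """Per-spike residual metrics over the unit's spike window.

    lfp_energy = Vo'Vo with Vo = v - alpha*C; snr = alpha / Vo'Vo as printed
    in the source convention (capped at 1e12 when Vo'Vo = 0), plus the
    scale-consistent variant snr_rms = alpha' / rms(Vo); explained variance
    = 1 - Vo'Vo / v'v.
    """
    sl = unit.window_slice()
    v = event.waveform[sl]
    vv = float(v @ v)
    if vv == 0:
        raise DegenerateInputError("zero-energy waveform window")
    if not np.isfinite(event.alpha):
        parameterize_spikes([event], unit)
    vo = v - event.alpha * unit.canonical_shape
    ee = float(vo @ vo)
    event.lfp_energy = ee
    event.snr = event.alpha / ee if ee > 0 else np.sign(event.alpha) * SNR_CAP
    rms = np.sqrt(ee / unit.n_window_samples)
    event.snr_rms = (event.alpha_scaled / rms if rms > 0
                     else np.sign(event.alpha) * SNR_CAP)
    event.explained_variance = 1.0 - ee / vv
    return event


def unit_metrics(events: list[SpikeEvent], unit: SpikeUnit,
                 duration_s: float | None = None) -> dict:
    """Summary metrics for a unit: means of the per-spike quantities, the
    window duration, firing rate and ISI statistics."""
    ev = [e for e in events if np.isfinite(e.alpha)]
    t = np.sort([e.time for e in ev]) / unit.rate
    isi = np.diff(t)
    out = {
        "unit_id": unit.unit_id,
        "n_spikes": len(ev),
        "mean_alpha": float(np.mean([e.alpha for e in ev])) if ev else np.nan,
        "mean_alpha_scaled": (float(np.mean([e.alpha_scaled for e in ev]))
                              if ev else np.nan),
        "mean_lfp_energy": (float(np.mean([e.lfp_energy for e in ev]))
                            if ev else np.nan),
        "mean_snr": float(np.mean([e.snr for e in ev])) if ev else np.nan,
        "mean_explained_variance": (
            float(np.mean([e.explained_variance for e in ev]))
            if ev else np.nan),
        "window_ms": 1e3 * (unit.tau_R - unit.tau_i),
        "mean_isi_s": float(isi.mean()) if isi.size else np.nan,
    }
    if duration_s:
        out["firing_rate_hz"] = len(ev) / duration_s
    return out


def subtract_unit(trace: Recording, unit: SpikeUnit,
                  events: list[SpikeEvent]) -> Recording:
    """Subtract ``alpha_k * C`` at every spike of one unit.

    Samples outside all spike windows are untouched.  A window that runs past
    a trace edge is subtracted partially, with a warning.
    """
    out = trace.samples.copy()
    C = unit.canonical_shape
    T = unit.n_window_samples
    n = out.size
    for e in events:
        if not np.isfinite(e.alpha):
            raise InvalidParameterError("events must be parameterized first")
        lo = e.time + unit.window_start
        hi = lo + T
        clo, chi = max(lo, 0), min(hi, n)
        if clo >= chi:
            continue
        if clo != lo or chi != hi:
            warnings.warn("spike window clipped at trace edge; partial "
                          "subtraction", stacklevel=2)
        out[clo:chi] -= e.alpha * C[clo - lo:chi - lo]
    return trace.replace_samples(out)


def _unit_amplitude(template: np.ndarray) -> float:
    return float(np.max(np.abs(template)))


def serial_sort(filtered: Recording, sort: SortResult, threshold: float,
                dedupe_s: float = 0.5e-3) -> SortResult:
    """Resolve overlapping spikes by serial subtraction and re-sorting.

    Units are processed largest-amplitude-first.  Each unit is windowed,
    parameterized, and subtracted from the working trace; detection is re-run
    with the SAME threshold and new events are template-matched against the
    not-yet-subtracted units.  Events that duplicate an existing spike of the
    same unit (within ``dedupe_s``) are discarded; genuinely new events are
    flagged ``recovered``.  Spikes exactly coincident at the alignment
    extremum cannot be resolved; an expected count of such complete overlaps
    is reported in the result notes.  Refractory rates are recomputed after
    every pass.
    """
    from .detect import (detect_waveforms, refractory_violation_rate,
                         template_match_sort)

    n_units = sort.templates.shape[0]
    if n_units < 2:
        out = SortResult(sort.events, sort.templates, sort.fit_tolerance,
                         sort.rate, threshold=threshold,
                         refractory_rates=dict(sort.refractory_rates),
                         qc_flags=dict(sort.qc_flags),
                         notes=sort.notes + ["serial sort skipped: "
                                             "fewer than 2 units"])
        return out

    order = sorted(range(n_units),
                   key=lambda u: -_unit_amplitude(sort.templates[u]))
    work = filtered
    events = list(sort.events)
    fs = float(np.max(np.abs(sort.templates)))
    notes = list(sort.notes)

    for pos, u in enumerate(order):
        u_events = [e for e in events if e.unit_id == u]
        if not u_events:
            continue
        unit = build_unit(u, np.array([e.waveform for e in u_events]),
                          work.rate,
                          np.array([e.time for e in u_events]))
        parameterize_spikes(u_events, unit)
        work = subtract_unit(work, unit, u_events)
        remaining = [v for v in order[pos + 1:]]
        if not remaining:
            break
        redetected = detect_waveforms(work, threshold)
        if not redetected:
            continue
        sub = template_match_sort(redetected,
                                  sort.templates[remaining],
                                  sort.fit_tolerance, rate=work.rate,
                                  full_scale=fs, refine_passes=0,
                                  threshold=threshold)
        tol = int(round(dedupe_s * work.rate))
        tol_any = max(1, tol // 2)
        all_times = np.array([k.time for k in events], dtype=int)
        for e in sub.events:
            if e.unit_id is None:
                continue
            v = remaining[e.unit_id]
            known = np.array([k.time for k in events if k.unit_id == v],
                             dtype=int)
            if known.size and np.min(np.abs(known - e.time)) < tol:
                continue
            # an event this close to ANY known spike is a subtraction
            # remnant (window-edge residual), not a hidden spike
            if all_times.size and np.min(np.abs(all_times - e.time)) < tol_any:
                continue
            e.unit_id = v
            e.recovered = True
            events.append(e)

    n_rec = sum(e.recovered for e in events)
    notes.append(f"serial sort recovered {n_rec} overlapping spikes")
    # expected complete-peak coincidences (unresolvable): rate-based estimate
    dur = filtered.duration
    rates = [len([e for e in events if e.unit_id == u]) / dur
             for u in range(n_units)]
    delta = 1.0 / filtered.rate
    exp_unres = sum(2 * delta * rates[a] * rates[b] * dur
                    for a in range(n_units) for b in range(a + 1, n_units))
    notes.append(f"expected unresolved complete-peak overlaps: "
                 f"{exp_unres:.2f}")

    out = SortResult(events, sort.templates, sort.fit_tolerance, sort.rate,
                     threshold=threshold, notes=notes)
    for u in range(n_units):
        rv = refractory_violation_rate(out.unit_spike_times(u))
        out.refractory_rates[u] = rv
        out.qc_flags[u] = rv > 2.0
    return out


def residual_lfp(raw: Recording, units: list[SpikeUnit],
                 events: list[SpikeEvent]) -> Recording:
    """Residual LFP: subtract every parameterized spike from the RAW trace.

    ``Vo(t) = V(t) - sum_k alpha_k C_{n(k)}(t' + tau_k)``; projection weights
    come from the filtered trace, subtraction happens on the unfiltered one,
    so Vo keeps the low-frequency content the band-pass would discard.
    """
    by_id = {u.unit_id: u for u in units}
    out = raw
    for uid, unit in by_id.items():
        if unit.rate != raw.rate:
            raise InvalidParameterError("unit/trace rate mismatch")
        ev = [e for e in events if e.unit_id == uid]
        if ev:
            out = subtract_unit(out, unit, ev)
    return out
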