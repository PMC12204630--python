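"""Synthetic microelectrode (MER) and EKG signal generation with ground truth.

Emulates the statistics of intraoperative deep-brain recordings: biphasic /
triphasic extracellular spike templates of varying width, Poisson firing with
an absolute refractory period, lognormal per-spike amplitude jitter, optional
cardiac pulse modulation of spike amplitude, and background noise made of a
1/f^beta process, a white floor, and optional line / narrow-band components.

Everything is deterministic given the config seed, and every inserted spike
is listed in the returned :class:`GroundTruth`, so downstream detection,
sorting, windowing, overlap resolution and modulation fitting can all be
scored against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Recording, frame_samples, pre_samples
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

_SUPPORT_EPS = 1e-3  # template support = where |s| exceeds this x peak


@dataclass
class SpikeTemplate:
    """An extracellular spike template on the 2 ms extraction frame.

    ``samples`` covers the full frame; the alignment extremum (largest
    absolute sample) sits at the frame's time-zero index and has magnitude 1.
    ``support_start`` / ``support_end`` bound the non-zero region, in seconds
    relative to the extremum.
    """

    shape_id: int
    samples: np.ndarray
    support_start: float
    support_end: float
    polarity: str
    rate: float

    @property
    def peak_index(self) -> int:
        return pre_samples(self.rate)


@dataclass
class NoiseConfig:
    """Background noise model: 1/f^beta + white floor + optional tones."""

    pink_rms: float = 0.15
    pink_exponent: float = 1.0
    white_rms: float = 0.08
    line_freq: float | None = None
    line_amp: float = 0.0
    osc_freq: float | None = None
    osc_amp: float = 0.0


@dataclass
class CardiacConfig:
    """Cardiac pulse modulation of spike amplitude.

    The modulated unit's per-spike amplitude is
    ``baseline + A * t**n * exp(-m*t)`` evaluated at t = time since the last
    R-wave.  ``A`` defaults to ``None`` meaning "50% peak modulation of the
    unit's baseline amplitude" (resolved at simulation time).
    """

    heart_rate_bpm: float = 70.0
    rr_jitter: float = 0.03
    A: float | None = None
    n: float = 2.0
    m: float = 10.0
    modulated_units: tuple[int, ...] = (0,)


@dataclass
class SimulationConfig:
    """Stated world of a synthetic MER session."""

    duration: float = 30.0
    rate: float = 44000.0
    templates: list[SpikeTemplate] = field(default_factory=list)
    firing_rates: list[float] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)
    amp_jitter: float = 0.1        # lognormal sigma, multiplicative
    refractory: float = 0.002      # absolute dead time, seconds
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    overlap_frac: float = 0.0      # fraction of unit>0 spikes forced to
    # land 0.3-1.0 ms after a unit-0 spike
    cardiac: CardiacConfig | None = None
    seed: int = 0
    depth_mm: float | None = None
    site_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidParameterError("duration must be positive")
        if self.rate <= 2 * 9000:
            raise InvalidParameterError(
                "rate must exceed twice the 9 kHz analysis band")
        n = len(self.templates)
        if not self.firing_rates:
            self.firing_rates = [20.0] * n
        if not self.amplitudes:
            self.amplitudes = [1.0] * n
        if len(self.firing_rates) != n or len(self.amplitudes) != n:
            raise InvalidParameterError(
                "firing_rates/amplitudes must match templates")


@dataclass
class GroundTruth:
    """Every inserted spike, plus R-wave times when cardiac modulation is on.

    ``times`` are alignment-extremum sample indices; ``amplitudes`` the true
    multiplicative scale of each inserted template; ``overlapped`` marks
    spikes deliberately placed inside another unit's spike window.
    """

    unit_ids: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray
    overlapped: np.ndarray
    templates: list[SpikeTemplate]
    rate: float
    r_wave_times: np.ndarray | None = None
    n_dropped: int = 0

    def times_of(self, unit_id: int) -> np.ndarray:
        return self.times[self.unit_ids == unit_id]

    def to_frame(self) -> pd.DataFrame:
        """Per-spike table with times in seconds."""
        return pd.DataFrame({
            "unit_id": self.unit_ids,
            "time_s": self.times / self.rate,
            "amplitude": self.amplitudes,
            "overlapped": self.overlapped,
        })


def impulse_response(t, A, n, m):
    """``A * t**n * exp(-m*t)`` for t > 0, zero elsewhere."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    # log-space evaluation keeps extreme (n, m) trials finite during fitting
    with np.errstate(over="ignore", invalid="ignore"):
        val = np.exp(np.clip(n * np.log(t[pos]) - m * t[pos], -700, 700))
    out[pos] = A * val
    return out


# ---------------------------------------------------------------------------
# templates


def _template_samples(rate, sigma1, sigma2_ratio, delta_ratio,
                      lead_frac, sign):
    """Main lobe at t=0, trailing rebound, optional leading hump.

    The positive lobes exactly balance the main lobe's area (zero net area):
    real extracellular spikes carry almost no energy below the 300 Hz
    analysis band, so the band-pass leaves their shape and trough depth
    intact.  ``lead_frac`` moves part of the balancing area into a hump
    before the trough, giving triphasic shapes.
    """
    L = frame_samples(rate)
    p = pre_samples(rate)
    t = (np.arange(L) - p) / rate
    delta = delta_ratio * sigma1
    sigma2 = sigma2_ratio * sigma1
    sigma0 = 0.8 * sigma1
    s = -np.exp(-0.5 * (t / sigma1) ** 2)
    if lead_frac > 0:
        s += (lead_frac * sigma1 / sigma0) * np.exp(
            -0.5 * ((t + 1.6 * sigma1) / sigma0) ** 2)
    s += ((1.0 - lead_frac) * sigma1 / sigma2) * np.exp(
        -0.5 * ((t - delta) / sigma2) ** 2)
    s *= sign
    # overlapping lobes can pull the extremum a sample off t=0: recenter
    shift = p - int(np.argmax(np.abs(s)))
    if shift:
        s = np.roll(s, shift)
        if shift > 0:
            s[:shift] = 0.0
        else:
            s[shift:] = 0.0
    s /= np.abs(s[p])
    # hard-zero outside support so superposition bookkeeping is exact
    keep = np.abs(s) > _SUPPORT_EPS
    if keep.any():
        i0, i1 = np.flatnonzero(keep)[[0, -1]]
        s[:i0] = 0.0
        s[i1 + 1:] = 0.0
    return s, t


def make_templates(n_shapes: int, rate: float = 44000.0,
                   seed: int = 0) -> list[SpikeTemplate]:
    """Generate ``n_shapes`` mutually dissimilar spike templates.

    Widths span ~0.3-1.2 ms; polarity and biphasic/triphasic structure vary
    across shapes.  Any pair of distinct templates has shape similarity
    (centered, unit-norm dot product) below 0.95; shapes are re-drawn with
    jittered widths until that holds.
    """
    if n_shapes < 1:
        raise InvalidParameterError("n_shapes must be >= 1")
    from .cluster import waveform_similarity

    rng = np.random.default_rng(seed)
    templates: list[SpikeTemplate] = []
    # deterministic width ladder with a small random jitter per shape
    widths = np.linspace(0.05e-3, 0.16e-3, max(n_shapes, 2))
    for i in range(n_shapes):
        for attempt in range(50):
            sigma1 = widths[i] * float(np.exp(rng.normal(0, 0.08)))
            sigma2_ratio = float(rng.uniform(1.6, 2.4))
            delta_ratio = float(rng.uniform(2.0, 3.0))
            lead = float(rng.uniform(0.3, 0.5)) if i % 3 == 2 else 0.0
            sign = 1.0 if i % 4 != 3 else -1.0
            s, t = _template_samples(rate, sigma1, sigma2_ratio,
                                     delta_ratio, lead, sign)
            p = pre_samples(rate)
            # the main lobe, not the rebound, must be the global extremum
            if (int(np.argmax(np.abs(s))) != p
                    or np.sign(s[p]) != -np.sign(sign)):
                continue
            ok = all(abs(waveform_similarity(s, tpl.samples)) < 0.95
                     for tpl in templates)
            if ok:
                break
        else:  # pragma: no cover - ladder spacing makes this unreachable
            raise RuntimeError("could not draw a dissimilar template")
        nz = np.flatnonzero(s != 0.0)
        polarity = "negative-leading" if sign > 0 else "positive-leading"
        templates.append(SpikeTemplate(
            shape_id=i, samples=s,
            support_start=float(t[nz[0]]), support_end=float(t[nz[-1]]),
            polarity=polarity, rate=rate))
    return templates


# ---------------------------------------------------------------------------
# point process and noise


def poisson_refractory_train(rng, duration, rate_hz, refractory):
    """Spike times (s) of a Poisson process with absolute dead time.

    ISIs are ``refractory + Exp(1/lam)`` with ``lam = r / (1 - r*refractory)``
    so the mean ISI is exactly ``1/r``.
    """
    if rate_hz <= 0:
        return np.empty(0)
    if rate_hz * refractory >= 1:
        raise InvalidParameterError("firing rate incompatible with refractory")
    lam = rate_hz / (1.0 - rate_hz * refractory)
    times = []
    t = rng.exponential(1.0 / lam)
    while t < duration:
        times.append(t)
        t += refractory + rng.exponential(1.0 / lam)
    return np.asarray(times)


def synth_noise(rng, n, rate, cfg: NoiseConfig):
    """Realize the background-noise model as an n-sample trace."""
    out = np.zeros(n)
    if cfg.pink_rms > 0:
        coef = rng.normal(size=n // 2 + 1) + 1j * rng.normal(size=n // 2 + 1)
        f = np.fft.rfftfreq(n, d=1.0 / rate)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-cfg.pink_exponent / 2.0)
        pink = np.fft.irfft(coef * scale, n=n)
        sd = pink.std()
        if sd > 0:
            out += pink * (cfg.pink_rms / sd)
    if cfg.white_rms > 0:
        out += rng.normal(0.0, cfg.white_rms, size=n)
    t = np.arange(n) / rate
    if cfg.line_freq and cfg.line_amp:
        out += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t
                                     + rng.uniform(0, 2 * np.pi))
    if cfg.osc_freq and cfg.osc_amp:
        out += cfg.osc_amp * np.sin(2 * np.pi * cfg.osc_freq * t
                                    + rng.uniform(0, 2 * np.pi))
    return out


# ---------------------------------------------------------------------------
# cardiac helpers


def _r_wave_times(rng, duration, bpm, rr_jitter):
    rr = 60.0 / bpm
    times = []
    t = rng.uniform(0, rr)
    while t < duration:
        times.append(t)
        t += rr * float(np.exp(rng.normal(0.0, rr_jitter)))
    return np.asarray(times)


def _resolve_cardiac_A(cfg: CardiacConfig, baseline: float) -> float:
    if cfg.A is not None:
        return cfg.A
    peak = (cfg.n / cfg.m) ** cfg.n * np.exp(-cfg.n) if cfg.m > 0 else None
    if peak is None or peak <= 0:
        raise InvalidParameterError(
            "default modulation depth needs m > 0; pass A explicitly")
    return 0.5 * baseline / peak


def _check_cardiac_amplitudes(baseline, A, n, m, t_max):
    tt = np.linspace(1e-6, max(t_max, 1e-3), 512)
    amp = baseline + impulse_response(tt, A, n, m)
    if np.any(amp <= 0):
        raise InvalidParameterError(
            "cardiac modulation drives spike amplitude non-positive")


def simulate_pulse_modulated_train(duration, firing_rate, baseline,
                                   cardiac: CardiacConfig, amp_noise=0.1,
                                   refractory=0.002, seed=0):
    """Spike times, true amplitudes and R-wave times, without a voltage trace.

    Light-weight path for studying cardiac modulation of spike amplitude:
    amplitude_k = (baseline + A*t^n*exp(-m t)) * lognormal(amp_noise), with
    t the time since the most recent R-wave (pre-R spikes sit at baseline).
    """
    rng = np.random.default_rng(seed)
    r_times = _r_wave_times(rng, duration, cardiac.heart_rate_bpm,
                            cardiac.rr_jitter)
    A = _resolve_cardiac_A(cardiac, baseline)
    _check_cardiac_amplitudes(baseline, A, cardiac.n, cardiac.m,
                              90.0 / cardiac.heart_rate_bpm)
    spikes = poisson_refractory_train(rng, duration, firing_rate, refractory)
    idx = np.searchsorted(r_times, spikes, side="right") - 1
    tsince = np.where(idx >= 0, spikes - r_times[np.clip(idx, 0, None)],
                      np.inf)
    amps = baseline + np.where(np.isfinite(tsince),
                               impulse_response(tsince, A, cardiac.n,
                                                cardiac.m), 0.0)
    if amp_noise > 0:
        amps = amps * np.exp(rng.normal(0.0, amp_noise, size=amps.size))
    return spikes, amps, r_times


# ---------------------------------------------------------------------------
# main simulators


def _unit_spike_times(rng, config, unit, unit0_times):
    times = poisson_refractory_train(
        rng, config.duration, config.firing_rates[unit], config.refractory)
    overlapped = np.zeros(times.size, dtype=bool)
    if unit > 0 and config.overlap_frac > 0 and unit0_times.size and times.size:
        n_ov = int(round(config.overlap_frac * times.size))
        if n_ov:
            pick = rng.choice(times.size, size=n_ov, replace=False)
            host = rng.choice(unit0_times, size=n_ov)
            times = times.copy()
            times[pick] = host + rng.uniform(0.3e-3, 1.0e-3, size=n_ov)
            overlapped[pick] = True
            order = np.argsort(times)
            times, overlapped = times[order], overlapped[order]
            keep = np.ones(times.size, dtype=bool)
            last = -np.inf
            for i, t in enumerate(times):
                if t - last < config.refractory:
                    keep[i] = False
                else:
                    last = t
            times, overlapped = times[keep], overlapped[keep]
    return times, overlapped


def simulate_recording(config: SimulationConfig):
    """Simulate one MER site: returns ``(Recording, GroundTruth)``.

    The trace is the exact superposition of amplitude-scaled templates at
    the ground-truth times plus one realization of the noise model.  Spikes
    whose template support would cross a trace edge are dropped (and logged),
    never truncated.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.rate))
    L = frame_samples(config.rate)
    p = pre_samples(config.rate)

    r_times = None
    cardiac = config.cardiac
    if cardiac is not None:
        r_times = _r_wave_times(rng, config.duration,
                                cardiac.heart_rate_bpm, cardiac.rr_jitter)

    unit_ids, times, amps, over = [], [], [], []
    dropped = 0
    unit0_times = np.empty(0)
    trace = synth_noise(rng, n, config.rate, config.noise)

    for u, tpl in enumerate(config.templates):
        t_u, ov_u = _unit_spike_times(rng, config, u, unit0_times)
        if u == 0:
            unit0_times = t_u
        base = config.amplitudes[u]
        if cardiac is not None and u in cardiac.modulated_units:
            A = _resolve_cardiac_A(cardiac, base)
            _check_cardiac_amplitudes(base, A, cardiac.n, cardiac.m,
                                      90.0 / cardiac.heart_rate_bpm)
            idx = np.searchsorted(r_times, t_u, side="right") - 1
            tsince = np.where(idx >= 0, t_u - r_times[np.clip(idx, 0, None)],
                              np.inf)
            a_u = base + np.where(np.isfinite(tsince),
                                  impulse_response(tsince, A, cardiac.n,
                                                   cardiac.m), 0.0)
        else:
            a_u = np.full(t_u.size, base)
        if config.amp_jitter > 0:
            a_u = a_u * np.exp(rng.normal(0.0, config.amp_jitter,
                                          size=a_u.size))
        for t, a, ov in zip(t_u, a_u, ov_u):
            k = int(round(t * config.rate))
            start = k - p
            if start < 0 or start + L > n:
                dropped += 1
                logger.info("dropped edge spike of unit %d at %.4fs", u, t)
                continue
            trace[start:start + L] += a * tpl.samples
            unit_ids.append(u)
            times.append(k)
            amps.append(a)
            over.append(ov)

    order = np.argsort(times) if times else slice(None)
    gt = GroundTruth(
        unit_ids=np.asarray(unit_ids, dtype=int)[order],
        times=np.asarray(times, dtype=int)[order],
        amplitudes=np.asarray(amps, dtype=float)[order],
        overlapped=np.asarray(over, dtype=bool)[order],
        templates=list(config.templates), rate=config.rate,
        r_wave_times=(None if r_times is None
                      else np.asarray(r_times * config.rate, dtype=int)),
        n_dropped=dropped)
    rec = Recording(trace, config.rate, "MER", config.depth_mm,
                    config.site_id)
    return rec, gt


def simulate_cardiac_session(config: SimulationConfig):
    """Simulate a site with cardiac modulation plus a matching EKG channel.

    Returns ``(mer, ekg, ground_truth)``.  The EKG carries an R-wave-like
    positive deflection (12 ms Gaussian) at every ground-truth cardiac time.
    """
    if config.cardiac is None:
        raise InvalidParameterError("cardiac config required")
    if config.cardiac.heart_rate_bpm <= 0:
        raise InvalidParameterError("heart rate must be positive")
    mer, gt = simulate_recording(config)
    n = mer.samples.size
    rng = np.random.default_rng(np.random.default_rng(config.seed)
                                .integers(2 ** 31 - 1) + 1)
    ekg = rng.normal(0.0, 0.02, size=n)
    t = np.arange(n) / config.rate
    for rk in gt.r_wave_times:
        tr = rk / config.rate
        lo = max(0, int((tr - 0.05) * config.rate))
        hi = min(n, int((tr + 0.05) * config.rate))
        ekg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tr) / 0.012) ** 2)
    ekg_rec = Recording(ekg, config.rate, "EKG", config.depth_mm,
                        config.site_id)
    return mer, ekg_rec, gt


def reconstruct_truth(gt: GroundTruth, n_samples: int) -> np.ndarray:
    """Noise-free superposition of ground-truth spikes (oracle helper)."""
    p = pre_samples(gt.rate)
    L = frame_samples(gt.rate)
    out = np.zeros(n_samples)
    for u, k, a in zip(gt.unit_ids, gt.times, gt.amplitudes):
        out[k - p:k - p + L] += a * gt.templates[u].samples
    return out
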