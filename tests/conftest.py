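import numpy as np
import pytest

import merspike as m
from merspike.core import frame_samples, pre_samples

RATE = 44000.0


@pytest.fixture(scope="session")
def rate():
    return RATE


@pytest.fixture(scope="session")
def templates():
    """Two dissimilar negative-leading templates used across tests."""
    return m.make_templates(2, RATE, seed=1)


@pytest.fixture(scope="session")
def three_templates():
    return m.make_templates(3, RATE, seed=2)


def make_waveforms(template, n_spikes, amp_mean=1.0, amp_jitter=0.1,
                   noise_sd=0.05, seed=0):
    """Spike waveform matrix: jittered template + white noise (oracle-simple
    construction used where a full trace is unnecessary)."""
    rng = np.random.default_rng(seed)
    amps = amp_mean * np.exp(rng.normal(0, amp_jitter, n_spikes))
    L = template.samples.size
    W = amps[:, None] * template.samples[None, :]
    W = W + rng.normal(0, noise_sd, (n_spikes, L))
    return W, amps


def make_unit(mean_waveform, window_start, window_end, rate=RATE,
              unit_id=0, spike_times=None):
    """Construct a SpikeUnit directly from a mean waveform and window."""
    p = pre_samples(rate)
    seg = np.asarray(mean_waveform, dtype=float)[p + window_start:
                                                 p + window_end]
    return m.SpikeUnit(unit_id=unit_id,
                       mean_waveform=np.asarray(mean_waveform, dtype=float),
                       canonical_shape=seg / np.linalg.norm(seg),
                       window_start=window_start, window_end=window_end,
                       rate=rate,
                       spike_times=(np.empty(0, int) if spike_times is None
                                    else np.asarray(spike_times)))


def acceptance_sim(seed, overlap_frac=0.0, duration=30.0):
    """The clean two-unit world used by the recovery-style checks:
    SNR ~25-35 (in-band), 10% amplitude jitter, 15/12 Hz firing."""
    tpls = m.make_templates(2, RATE, seed=1)
    cfg = m.SimulationConfig(
        duration=duration, templates=tpls, firing_rates=[15.0, 12.0],
        amplitudes=[1.0, 0.8],
        noise=m.NoiseConfig(pink_rms=0.05, white_rms=0.02),
        overlap_frac=overlap_frac, seed=seed)
    return m.simulate_recording(cfg)


def sort_recording(rec, n_units=2, seed=0):
    """filter -> threshold -> detect -> PCA templates -> template match."""
    f = m.bandpass_filter(rec)
    thr = m.estimate_threshold(f)
    ev = m.detect_waveforms(f, thr)
    sel = m.pca_template_selection(np.stack([e.waveform for e in ev]),
                                   n_units, seed=seed)
    sort = m.template_match_sort(ev, sel.templates, rate=rec.rate,
                                 threshold=thr)
    return f, thr, sort


def map_units_to_truth(sort, gt):
    """Sorted-unit index -> ground-truth template index, by shape match."""
    return {u: int(np.argmax([m.waveform_similarity(sort.templates[u],
                                                    t.samples)
                              for t in gt.templates]))
            for u in range(sort.templates.shape[0])}


def match_tolerance_samples(rate=RATE, tol_s=0.2e-3):
    return int(round(tol_s * rate))
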