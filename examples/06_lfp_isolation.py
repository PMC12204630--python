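"""Isolate the spike-removed local field potential and compare spectra.

Subtracting every parameterized spike (alpha_k * C) from the RAW trace
leaves the residual LFP Vo(t).  Spike shapes contaminate the PSD above
~150 Hz, so removal lowers 200-300 Hz band power; a paired t-test across
sites quantifies the reduction.
"""

import numpy as np

import merspike as m

templates = m.make_templates(2, rate=44000.0, seed=1)
raw_bp, residual_bp = [], []
for site in range(6):
    config = m.SimulationConfig(
        duration=8.0, templates=templates, firing_rates=[25.0, 20.0],
        amplitudes=[1.0, 0.8],
        noise=m.NoiseConfig(pink_rms=0.05, white_rms=0.02), seed=100 + site)
    recording, _ = m.simulate_recording(config)
    result = m.analyze_recording(recording, m.RunConfig(n_units=2, seed=0))
    raw_bp.append(result.band_powers["raw"])
    residual_bp.append(result.band_powers["residual"])
    print(f"site {site}: 200-300 Hz power raw {raw_bp[-1]:.3e} -> "
          f"residual {residual_bp[-1]:.3e}")

test = m.paired_band_power_test(np.array(raw_bp), np.array(residual_bp))
print(f"paired t-test: t({test.df}) = {test.t_stat:.2f}, "
      f"p = {test.p_value:.4f}, reduction {test.percent_reduction:.1f}%")
# Band power falls at every site (spike removal never ADDS power); the
# paired test shows the reduction is systematic across sites.
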