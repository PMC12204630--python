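"""Quantify cardiac pulse modulation of spike amplitude.

Per-spike alpha' values are windowed -0.1 to +0.9 s around each EKG R-wave,
averaged across cardiac cycles, baselined by the pre-R mean, and fit with
the impulse-response form A * t^n * exp(-m t).  A pulse-modulated unit
yields a high R^2; an unmodulated unit does not.
"""

import numpy as np

import merspike as m

cardiac = m.CardiacConfig(heart_rate_bpm=70.0, n=2.0, m=10.0)
spikes, amplitudes, r_times = m.simulate_pulse_modulated_train(
    duration=60.0, firing_rate=20.0, baseline=1.0, cardiac=cardiac,
    amp_noise=0.1, seed=0)

profile = m.cardiac_profile(spikes, amplitudes, r_times)
fit = m.fit_impulse_response(profile)
print(f"modulated unit : A={fit.A:.1f}  n={fit.n:.2f}  m={fit.m:.2f}  "
      f"R^2={fit.r_squared:.2f}  (truth n=2.00, m=10.00)")

rng = np.random.default_rng(1)
flat = np.exp(rng.normal(0.0, 0.1, spikes.size))     # no cardiac tuning
fit0 = m.fit_impulse_response(m.cardiac_profile(spikes, flat, r_times))
print(f"unmodulated    : A={fit0.A:.2g}  n={fit0.n:.2f}  m={fit0.m:.2f}  "
      f"R^2={fit0.r_squared:.2f}")
print(f"cycles averaged: {profile.n_cycles}, spikes used: {profile.n_spikes}")
# R^2 separates pulse-modulated firing from flat firing; the recovered
# (n, m) match the generating impulse-response parameters.
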