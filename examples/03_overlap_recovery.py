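"""Resolve overlapping spikes by serial subtraction and re-sorting.

10% of the second unit's spikes are deliberately placed 0.3-1.0 ms after a
first-unit spike, hiding them inside the larger spike's window.  Subtracting
the parameterized first unit and re-detecting with the SAME threshold
recovers them.
"""

import numpy as np

import merspike as m

templates = m.make_templates(2, rate=44000.0, seed=1)
config = m.SimulationConfig(
    duration=30.0, templates=templates, firing_rates=[15.0, 12.0],
    amplitudes=[1.0, 0.8], noise=m.NoiseConfig(pink_rms=0.05, white_rms=0.02),
    overlap_frac=0.10, seed=3)
recording, truth = m.simulate_recording(config)

filtered = m.bandpass_filter(recording)
threshold = m.estimate_threshold(filtered)
events = m.detect_waveforms(filtered, threshold)
selection = m.pca_template_selection(
    np.stack([e.waveform for e in events]), n_units=2, seed=0)
first_pass = m.template_match_sort(events, selection.templates,
                                   rate=recording.rate, threshold=threshold)
second_pass = m.serial_sort(filtered, first_pass, threshold)

n_hidden = int(truth.overlapped.sum())
gained = len(second_pass.events) - len(first_pass.events)
print(f"hidden overlapping spikes injected : {n_hidden}")
print(f"events first pass / after serial   : {len(first_pass.events)} / "
      f"{len(second_pass.events)} (+{100 * gained / len(first_pass.events):.1f}%)")
for note in second_pass.notes:
    if "recovered" in note or "unresolved" in note:
        print("note:", note)
# The spike-count gain comes from overlaps that single-pass sorting cannot
# see; exactly peak-coincident spikes remain unresolvable in principle.
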