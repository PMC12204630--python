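# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `merspike`, and what the synthetic validation does and
does not establish.

## Signal model and conventions

A recording site is a single-channel voltage trace `V(t)` sampled at 44 kHz
(default). All analysis of spikes happens on the zero-phase band-passed
trace (4th-order Butterworth, 300 Hz – 9 kHz, applied forward–backward so
waveform shape is not phase-distorted). Sample indexing is 0-based; windows
are half-open `[start, end)`; every public table serializes times in
seconds.

Each detected spike is extracted into a fixed 2 ms frame: 0.5 ms before and
1.5 ms after the **alignment extremum**, the largest-magnitude sample within
0.6 ms after the threshold crossing. The sorted-unit model is

    V(t) = Σ_k α_k · C_{n(k)}(t′ + τ_k) + Vo(t)

with `C_n` the unit-norm canonical shape of unit `n` over its spike window
`[τ_i, τ_R]`, `α_k` the spike's projection weight, and `Vo` the residual
LFP ("LFP" here is the encompassing non-spiking component: narrow-band
oscillations plus 1/f broadband).

## Detection and sorting

- **Threshold**: `multiplier × median(|x|)/0.6745` (default multiplier −4).
  The robust scale estimator is used because the raw SD of a spike-laden
  trace overestimates the background; this is our explicit reading of the
  "−4 standard deviations" convention, which device software computes from
  an internal histogram whose formula is not public.
- **Crossing hygiene**: crossings closer than 0.5 ms collapse into one
  event (the larger extremum wins); events whose 2 ms frame does not fit in
  the trace are discarded.
- **Template seeding**: waveforms are projected onto their first two
  principal components and k-means-partitioned (fixed seed, 10 restarts);
  group means are the initial templates. Degenerate partitions (empty or
  coincident groups) are flagged, not silently accepted.
- **Template matching**: an event is assigned to the template minimizing
  the normalized sum-of-squares distance — mean per-sample squared error
  divided by the squared full scale (largest absolute template sample) —
  provided the minimum is within the **fit tolerance** (default 0.25).
  Exact ties go to the lower-indexed template and are logged. One
  refinement pass re-estimates templates from assignments by default.
- **Why 0.25**: the tolerance only *gates* assignment (the argmin decides
  the unit), so it has almost no effect on accuracy; but serial overlap
  resolution requires host+hidden composites — which carry roughly
  0.1 FS² of extra mean-square error — to remain assigned to the host unit
  so the host is parameterized and subtracted. Tolerances near 0.05 reject
  composites and overlaps are never resolved. The device-native tolerance
  ("5 in units of 0.01% of the maximum A/D value") does not translate
  unambiguously to a normalized metric; ours is defined above and
  configurable.
- **QC**: refractory violation rate = 100 × (# ISIs < 2 ms)/(# spikes);
  units above 2% are flagged. Refinement is left to the caller (the
  original workflow's refinement was manual).

## Spike-window discovery (canonical response parameterization)

For one unit with spike waveforms `v_k` on the 2 ms frame, the projection
profile over a candidate window `w` is

    p_k(w) = ⟨v_k[w], m₋k[w]⟩ / ‖v_k[w]‖ ,     S̄(w) = mean_k p_k(w)

with `m₋k` the leave-one-out mean waveform. Forward sweep: windows `[0, e)`
for e = 1 … +1.5 ms; the argmax of `S̄` is the spike end `τ_R`. Reverse
sweep anchored at `τ_R`: windows `[s, τ_R)` for s = −1 … −0.5 ms; the
argmax is the spike start `τ_i`. Windows shorter than 4 samples are not
offered, and the window always contains the alignment extremum
(τ_i < 0 ≤ τ_R).

Choices that matter:

- **Normalization by the projecting spike's own norm** (`‖v_k[w]‖`): as the
  window grows past the true support, the numerator stops growing while the
  denominator keeps accumulating noise, so the profile peaks at the
  support boundary. Normalizing by the near-zero mean-waveform tail instead
  would plateau. (The semi-normalized dot product is stated abstractly in
  the source method; this operationalization is ours.)
- **Plateau tie-break**: the earliest offset within relative tolerance
  1e-9 of the profile maximum — with noise-free identical waveforms the
  profile is a non-decreasing `‖template[w]‖`, and the tie-break selects
  the support end rather than the frame edge.
- **Polarity**: a global sign flip of all waveforms flips both `v_k` and
  `m₋k`, so the profile — and the discovered window — is *invariant* under
  polarity inversion.
- **Fallback**: units with fewer than 5 spikes cannot support a
  leave-one-out profile; the window falls back to the full frame and the
  unit is flagged (`window_fallback`).

`C(t)` is the unit-L2-norm mean waveform over `[τ_i, τ_R]`, so
`α_k = ⟨v_k, C⟩` is a plain inner product on the voltage scale and
`α′_k = α_k/√T` equals the rms deflection of a perfectly shaped spike.
Per-spike residual metrics over the window (`Vo = v_k − α_k C`):
`lfp_energy = VoᵀVo`; `snr = α_k/VoᵀVo` as printed in the source convention
(dimensionally a voltage over a voltage², so a scale-consistent variant
`α′_k / rms(Vo)` is also emitted as `snr_rms`); `explained_variance =
1 − VoᵀVo/vᵀv` (capped sentinel 1e12 for `snr` when `VoᵀVo = 0`).

## Serial overlap resolution

Units are processed largest-amplitude-first. Each is windowed,
parameterized and subtracted from the working (filtered) trace; detection
re-runs with the *same* threshold, and new events are template-matched
against the not-yet-subtracted units. Two hygiene rules:

- new events within 0.5 ms of an existing event *of the same unit* are
  duplicates (re-detections) and dropped;
- new events within 0.25 ms of *any* known event are subtraction remnants —
  the canonical shape is subtracted only over `[τ_i, τ_R]`, so a spike's
  sub-threshold leading edge outside the window can re-cross threshold at
  the host's own position — and are dropped. Genuine hidden overlaps sit
  ≥ 0.3 ms from their host and are unaffected.

Spikes exactly coincident at the alignment extremum are unresolvable in
principle; the result notes report a rate-based expectation of such
complete overlaps (Σ_{i<j} 2·Δ·r_i·r_j·T, Δ = one sample), since they
cannot be counted from data. Refractory rates are recomputed after every
pass — recovered spikes could belong to another unit, so quality metrics
must be reassessed.

LFP isolation (`residual_lfp`) subtracts `α_k C` from the **raw** trace
(weights estimated on the filtered trace): re-sorting operates on the
filtered trace, LFP isolation on the unfiltered one. Residual low-frequency
spike remnants and amplifier phase response are acknowledged
approximations.

## Shape similarity and clustering

Similarity of two units = dot product of their mean waveforms over the
union window `[min(τ_i), max(τ_R)]` after centering to zero mean *and*
scaling to unit L2 norm. Centering alone cannot bound the score; the unit
norm makes the stated range [−1, 1] an actual invariant (Cauchy–Schwarz)
and removes amplitude, which mostly reflects electrode-to-cell distance.
Distances are `d = 1 − max(s, 0)` — negative similarities clamp to zero
*before* the subtraction, so an anti-similar pair is maximally distant
(d = 1), not super-distant (d = 2). The upper clamp at 1 only absorbs float
rounding.

Average-linkage (UPGMA) agglomeration builds the tree; the cluster count is
the elbow (kneedle: maximum perpendicular distance to the chord) of the
mean intra-cluster distance versus k, with manual override supported. A
conventional baseline — 2-D PCA of (optionally unit-normalized) mean
waveforms, k-means, Hungarian one-to-one label matching — quantifies
agreement with the shape-based labels as a percentage.

## Cardiac modulation

R-waves are detected by adaptive-threshold peak picking (0.6 × rolling 2 s
maximum, ≥ 300 ms separation) — scale-invariant, sufficient for clean EKG;
full QRS delineation is out of scope. Each spike joins the most recent
R-wave whose window [−0.1, +0.9] s contains it; `α′` is averaged in 50 bins
and baselined by the pre-R mean. The fit `A·tⁿ·e^(−mt)` runs on post-R bins
by trust-region-reflective least squares from a 4×4 multi-start grid
(n ∈ {0.5, 1, 2, 4}, m ∈ {1, 5, 10, 20}); parameters are unbounded in sign
(an unmodulated unit legitimately fits a negative decay). R² is computed on
the binned points used in the fit; total non-convergence yields a failure
result, not an exception. The model is evaluated in log space so extreme
trial parameters stay finite.

## Synthetic data: the stated world

The generator emulates what the downstream stages need to be tested
against, not a biophysical neuron:

- **Templates**: biphasic/triphasic difference-of-Gaussian shapes, main
  trough at t = 0, total widths ~0.3–1.2 ms, varying rebound delay/width,
  optional leading hump, alternating polarity. Lobes are area-balanced
  (zero net area) because real extracellular spikes carry almost no energy
  below the 300 Hz analysis band — without this the band-pass inverts or
  guts the trough and threshold detection breaks. Distinct templates are
  re-drawn until pairwise |similarity| < 0.95.
- **Firing**: Poisson with a 2 ms absolute refractory period
  (ISI = dead time + Exp(λ), λ chosen so the mean rate is exact).
- **Amplitudes**: lognormal multiplicative jitter, σ = 0.1.
- **Noise**: 1/f^β synthesized in the frequency domain (β = 1 default) plus
  a white floor; optional 50/60 Hz line and narrow-band oscillation.
  Defaults (pink 0.15, white 0.08 for a unit-amplitude spike) put detection
  in a plausible SNR regime; the recovery-style validations use a cleaner
  well-isolated-unit regime (pink 0.05, white 0.02, in-band σ ≈ 0.027).
  That choice follows from an identifiability analysis: band-limited noise
  projects onto the canonical shape with ~2× the white σ, so with 10%
  amplitude jitter the ceiling on Pearson r(α, true amplitude) at in-band
  SNR 8 is ≈ 0.85 *for any estimator*; r ≥ 0.95 requires SNR ≳ 20.
- **Overlaps**: an optional fraction of a later unit's spikes is placed
  0.3–1.0 ms after a first-unit spike (ground truth flags them).
- **Cardiac**: R-wave times at a configurable heart rate with lognormal RR
  jitter; the modulated unit's amplitude is
  `baseline + A·tⁿ·e^(−mt)` at t = time since the last R-wave (default
  depth: 50% of baseline at the mode); the EKG channel carries a 12 ms
  Gaussian deflection per R-wave. Configurations driving amplitudes
  non-positive are rejected.

Everything is deterministic given the seed; spikes whose support would
cross a trace edge are dropped and logged, never truncated.

**What a green test does not establish**: the generator has no electrode
drift, no multi-channel geometry, no bursting/adaptation structure, no
biophysical waveform variability beyond amplitude scaling, and its noise is
stationary. Validation therefore establishes correctness of the estimators
under the stated model, not performance on arbitrary clinical recordings.

## Numerical details

- Identities such as `V = ΣαC + Vo` hold to float rounding (~1 ulp per
  subtract/add round trip), not bit-exactly, wherever windows overlap or
  operation order differs; tests assert at 1e-12 of signal peak.
- The leave-one-out mean is computed algebraically
  (`(n·m − v_k)/(n−1)`), not by re-averaging, for O(nL) profiles.
- `snr` sentinel 1e12 when the residual is exactly zero; degenerate inputs
  (all-zero traces, constant waveforms, zero-energy windows) raise typed
  errors rather than propagating NaNs.
- Welch PSD: 1 s Hann segments, 50% overlap, density scaling (integral ≈
  variance); band power is the *mean* density over 200–300 Hz so values are
  comparable across bands of different width. Zero-variance paired
  differences flag the t-test degenerate instead of emitting infinities.

## Known limitations

- Serial resolution cannot recover spikes coincident at the peak, and its
  hygiene radius (0.25 ms) makes overlaps closer than that unrecoverable by
  construction.
- The windowed subtraction leaves each spike's sub-window tails in the
  residual LFP; with an amplifier whose phase response is not flat, the
  reconstructed residual may distort high-frequency content.
- The elbow criterion is a heuristic; for flat intra-distance curves the
  manual override is the intended path.
- `snr = α/VoᵀVo` is reported for continuity with the source convention
  despite its units; prefer `snr_rms` for scale-consistent comparisons.
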