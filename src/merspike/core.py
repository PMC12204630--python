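"""Shared containers and the 2 ms extraction-frame conventions.

Every detected spike is extracted into a fixed frame of 0.5 ms before and
1.5 ms after the alignment extremum (the largest-magnitude sample after the
threshold crossing).  Sample indexing is 0-based; windows are half-open
``[start, end)``.  Times inside containers are sample indices; public tables
serialize seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: extraction frame before / after the alignment extremum, seconds
PRE_S = 0.5e-3
POST_S = 1.5e-3


def pre_samples(rate: float) -> int:
    """Samples before the alignment extremum in the extraction frame."""
    return int(round(PRE_S * rate))


def post_samples(rate: float) -> int:
    """Samples at/after the alignment extremum in the extraction frame."""
    return frame_samples(rate) - pre_samples(rate)


def frame_samples(rate: float) -> int:
    """Total extraction-frame length, ``round(0.002 * rate)`` samples."""
    return int(round((PRE_S + POST_S) * rate))


@dataclass
class Recording:
    """A single-channel voltage trace with acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (float).
    rate : float
        Sampling rate in Hz.
    channel_role : {"MER", "EKG"}
        Microelectrode or electrocardiogram channel.
    depth_mm : float or None
        Electrode depth relative to the surgical target (negative = past
        target), when known.
    site_id : str
        Identifier of the recording site.
    """

    samples: np.ndarray
    rate: float
    channel_role: str = "MER"
    depth_mm: float | None = None
    site_id: str = "site0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.rate > 0:
            raise InvalidParameterError("rate must be positive")
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.rate

    def replace_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with new samples, metadata preserved."""
        return Recording(samples, self.rate, self.channel_role,
                         self.depth_mm, self.site_id)


@dataclass
class SpikeEvent:
    """One detected action potential.

    ``time`` is the sample index of the alignment extremum in the source
    trace; ``waveform`` is the 2 ms extraction (0.5 ms pre / 1.5 ms post).
    Projection fields are filled by :mod:`merspike.crp`.
    """

    time: int
    waveform: np.ndarray
    unit_id: int | None = None
    alpha: float = math.nan
    alpha_scaled: float = math.nan
    lfp_energy: float = math.nan
    snr: float = math.nan
    snr_rms: float = math.nan
    explained_variance: float = math.nan
    recovered: bool = False


@dataclass
class SpikeUnit:
    """A sorted unit with its empirically discovered spike window.

    ``window_start`` / ``window_end`` are sample offsets relative to the
    alignment extremum (half-open; start < 0 <= end), so ``tau_i`` and
    ``tau_R`` are in seconds.  ``canonical_shape`` is the unit-L2-norm mean
    waveform restricted to the window.
    """

    unit_id: int
    mean_waveform: np.ndarray
    canonical_shape: np.ndarray
    window_start: int
    window_end: int
    rate: float
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    window_fallback: bool = False

    def __post_init__(self) -> None:
        if self.window_start >= 0 or self.window_end <= 0:
            raise InvalidParameterError(
                "spike window must contain the alignment extremum "
                "(window_start < 0 <= window_end)")
        if self.n_window_samples < 4:
            raise InvalidParameterError("spike window shorter than 4 samples")
        nrm = float(np.linalg.norm(self.canonical_shape))
        if not math.isclose(nrm, 1.0, rel_tol=1e-9):
            raise InvalidParameterError("canonical shape must have unit norm")

    @property
    def tau_i(self) -> float:
        return self.window_start / self.rate

    @property
    def tau_R(self) -> float:
        return self.window_end / self.rate

    @property
    def n_window_samples(self) -> int:
        return self.window_end - self.window_start

    def window_slice(self, rate: float | None = None) -> slice:
        """Slice of the extraction frame covered by the spike window."""
        p = pre_samples(rate or self.rate)
        return slice(p + self.window_start, p + self.window_end)


@dataclass
class SortResult:
    """Outcome of template-match sorting for one recording site."""

    events: list[SpikeEvent]
    templates: np.ndarray
    fit_tolerance: float
    rate: float
    threshold: float = math.nan
    refractory_rates: dict[int, float] = field(default_factory=dict)
    qc_flags: dict[int, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def events_of(self, unit_id: int | None) -> list[SpikeEvent]:
        return [e for e in self.events if e.unit_id == unit_id]

    def unit_spike_times(self, unit_id: int) -> np.ndarray:
        """Sorted spike times (seconds) of one unit."""
        t = np.array(sorted(e.time for e in self.events
                            if e.unit_id == unit_id), dtype=float)
        return t / self.rate


@dataclass
class SimilarityMatrix:
    """Pairwise shape-similarity scores between sorted units."""

    unit_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise InvalidParameterError("similarity matrix shape mismatch")


@dataclass
class ClusterResult:
    """Agglomerative clustering of unit shapes."""

    linkage: np.ndarray
    k: int
    labels: np.ndarray
    mean_shapes: dict[int, np.ndarray]
    sizes: dict[int, int]
    intra_curve: np.ndarray | None = None


@dataclass
class CardiacFit:
    """Impulse-response fit of a cardiac-phase amplitude profile.

    The model is ``A * t**n * exp(-m*t)`` with t measured in seconds from
    the R-wave; the fit runs on the baselined profile at t > 0.
    """

    A: float
    n: float
    m: float
    r_squared: float
    baseline: float
    bin_centers: np.ndarray
    profile: np.ndarray
    bin_counts: np.ndarray
    n_spikes: int
    n_cycles: int
    n_dropped: int = 0
    success: bool = True
    message: str = ""


@dataclass
class BandPowerResult:
    """Paired raw-vs-residual band-power comparison across sites."""

    band: tuple[float, float]
    raw: np.ndarray
    residual: np.ndarray
    t_stat: float
    df: int
    p_value: float
    percent_reduction: float
    degenerate: bool = False
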