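"""Shape similarity, hierarchical clustering and depth profiling of units.

Two sorted units are compared over the union of their spike windows
(earliest tau_i to latest tau_R), each mean waveform is centered to zero
mean and scaled to unit L2 norm, and the similarity is the dot product of
the two normalized shapes: 1 for identical shapes, -1 for identical
inverted shapes, 0 for complete dissimilarity, independent of raw amplitude.
Distances are ``1 - max(s, 0)`` (negative similarities clamp to 0 first, so
an anti-similar pair is maximally distant, not super-distant), clustered by
average-linkage agglomeration with an elbow (kneedle) choice of k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import ClusterResult, SimilarityMatrix, SpikeUnit, pre_samples
from .errors import DegenerateInputError, InvalidParameterError


def normalize_shape(waveform: np.ndarray,
                    window: slice | None = None) -> np.ndarray:
    """Center a waveform to zero mean and scale to unit L2 norm.

    Centering alone cannot bound a dot product to [-1, 1]; the unit-norm
    scaling makes the similarity a cosine and amplitude-invariant.
    """
    w = np.asarray(waveform, dtype=float)
    if window is not None:
        w = w[window]
    if w.size < 4:
        raise InvalidParameterError("window shorter than 4 samples")
    w = w - w.mean()
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise DegenerateInputError("constant waveform has no shape")
    return w / nrm


def waveform_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Similarity of two raw waveforms over a common window."""
    return float(normalize_shape(a) @ normalize_shape(b))


def similarity(unit_a: SpikeUnit, unit_b: SpikeUnit) -> float:
    """Shape similarity of two units over the union of their spike windows.

    The comparison window runs from the earliest tau_i to the latest tau_R;
    both mean waveforms (aligned at their extremum) are sampled over it.
    """
    if unit_a.rate != unit_b.rate:
        raise InvalidParameterError("units must share a sampling rate")
    p = pre_samples(unit_a.rate)
    start = min(unit_a.window_start, unit_b.window_start)
    end = max(unit_a.window_end, unit_b.window_end)
    sl = slice(p + start, p + end)
    return float(normalize_shape(unit_a.mean_waveform, sl)
                 @ normalize_shape(unit_b.mean_waveform, sl))


def similarity_matrix(units: list[SpikeUnit]) -> SimilarityMatrix:
    """All-pairs similarity; symmetric with a unit diagonal."""
    n = len(units)
    if n < 2:
        raise InvalidParameterError("need at least 2 units")
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = similarity(units[i], units[j])
    return SimilarityMatrix([u.unit_id for u in units], s)


def distance_matrix(sim: SimilarityMatrix) -> np.ndarray:
    """Distance ``1 - max(s, 0)``: clamp negatives to 0, then subtract.

    The upper clamp only absorbs float rounding (|s| can exceed 1 by an
    ulp), keeping distances inside [0, 1].
    """
    d = 1.0 - np.clip(sim.values, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(distances: np.ndarray) -> np.ndarray:
    """Average-linkage agglomerative merge tree (scipy linkage matrix)."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidParameterError("distances must be square")
    return linkage(squareform(d, checks=False), method="average")


def intra_cluster_distance_curve(Z: np.ndarray, distances: np.ndarray,
                                 k_max: int = 10) -> np.ndarray:
    """Mean within-cluster pairwise distance as a function of k.

    For each k the tree is cut and the mean is taken over all within-cluster
    pairs (0 when no pair exists).
    """
    n = distances.shape[0]
    ks = range(1, min(k_max, n) + 1)
    out = np.empty(len(list(ks)))
    for i, k in enumerate(range(1, min(k_max, n) + 1)):
        labels = fcluster(Z, t=k, criterion="maxclust")
        vals = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size > 1:
                sub = distances[np.ix_(idx, idx)]
                vals.extend(sub[np.triu_indices(idx.size, 1)])
        out[i] = float(np.mean(vals)) if vals else 0.0
    return out


def select_k_elbow(Z: np.ndarray, distances: np.ndarray,
                   k_max: int = 10) -> int:
    """Elbow choice of cluster count (kneedle criterion).

    Returns the k whose point on the intra-cluster-distance curve lies
    farthest (perpendicular) from the chord joining the curve endpoints.
    With fewer than 3 units, returns n.
    """
    n = distances.shape[0]
    if n < 3:
        return n
    curve = intra_cluster_distance_curve(Z, distances, k_max)
    ks = np.arange(1, curve.size + 1, dtype=float)
    if curve[0] == curve[-1]:
        return 1
    p0 = np.array([ks[0], curve[0]])
    p1 = np.array([ks[-1], curve[-1]])
    chord = p1 - p0
    chord = chord / np.linalg.norm(chord)
    rel = np.stack([ks, curve], axis=1) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(ks[int(np.argmax(dist))])


def cluster_shapes(units: list[SpikeUnit], Z: np.ndarray, k: int,
                   distances: np.ndarray | None = None) -> ClusterResult:
    """Cut the tree at k clusters and average normalized shapes per cluster."""
    n = len(units)
    if not 1 <= k <= n:
        raise InvalidParameterError("k must be in [1, n]")
    labels = fcluster(Z, t=k, criterion="maxclust")
    shapes = np.stack([normalize_shape(u.mean_waveform) for u in units])
    mean_shapes, sizes = {}, {}
    for c in np.unique(labels):
        mask = labels == c
        sizes[int(c)] = int(mask.sum())
        mean_shapes[int(c)] = shapes[mask].mean(axis=0)
    curve = (intra_cluster_distance_curve(Z, distances)
             if distances is not None else None)
    return ClusterResult(Z, k, labels, mean_shapes, sizes, curve)


def depth_profile(result: ClusterResult, units: list[SpikeUnit],
                  depths_mm: list[float | None],
                  duration_s: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit depth table and per-cluster firing statistics.

    Returns ``(per_unit, per_cluster)``: per-unit rows carry depth, cluster
    label, firing rate (n_spikes / duration) and mean ISI (null for units
    with < 2 spikes); per-cluster rows carry mean +/- SEM of both.
    """
    rows = []
    for u, lab, d in zip(units, result.labels, depths_mm):
        t = np.sort(np.asarray(u.spike_times, dtype=float)) / u.rate
        isi = np.diff(t)
        rows.append({
            "unit_id": u.unit_id,
            "depth_mm": d,
            "cluster": int(lab),
            "firing_rate_hz": t.size / duration_s,
            "mean_isi_s": float(isi.mean()) if isi.size else None,
        })
    per_unit = pd.DataFrame(rows)
    ordered = per_unit[per_unit.depth_mm.notna()]
    per_unit = pd.concat([ordered.sort_values("depth_mm"),
                          per_unit[per_unit.depth_mm.isna()]],
                         ignore_index=True)
    g = per_unit.groupby("cluster")
    per_cluster = g.agg(
        n_units=("unit_id", "size"),
        firing_rate_mean=("firing_rate_hz", "mean"),
        firing_rate_sem=("firing_rate_hz", "sem"),
        isi_mean=("mean_isi_s", "mean"),
        isi_sem=("mean_isi_s", "sem"),
    ).reset_index()
    return per_unit, per_cluster


def hungarian_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Percent agreement after optimal one-to-one label matching."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((ua.size, ub.size))
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            cont[i, j] = np.sum((a == ca) & (b == cb))
    ri, cj = linear_sum_assignment(-cont)
    return 100.0 * cont[ri, cj].sum() / a.size


def compare_pca_kmeans(units: list[SpikeUnit], hier_labels: np.ndarray,
                       k: int, normalize: bool = True,
                       seed: int = 0) -> tuple[np.ndarray, float]:
    """Conventional PCA + k-means clustering and its overlap with the
    shape-based hierarchical labels.

    Mean waveforms (optionally normalized to remove amplitude as a confound)
    are projected on two principal components and k-means clustered; the
    Hungarian method matches labels one-to-one and the percent agreement is
    returned.
    """
    n = len(units)
    if k > n:
        raise InvalidParameterError("k cannot exceed the number of units")
    if normalize:
        X = np.stack([normalize_shape(u.mean_waveform) for u in units])
    else:
        X = np.stack([u.mean_waveform for u in units])
    scores = PCA(n_components=min(2, n, X.shape[1])).fit_transform(X)
    labels = KMeans(n_clusters=k, n_init=10,
                    random_state=seed).fit_predict(scores)
    return labels, hungarian_overlap(labels, hier_labels)
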