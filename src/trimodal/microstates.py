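"""EEG microstate segmentation.

The resting EEG is reduced to a sequence of four quasi-stable scalp
topographies: band-pass and average-reference the data, take the
topographies at the local maxima of the global field power (GFP), cluster
them with the modified atomize-and-agglomerate hierarchical clustering
(AAHC), sort the four cluster maps against canonical templates A-D, and
back-fit a per-sample label sequence.  Polarity is ignored throughout,
as is conventional for resting-state microstates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .types import EEGRecording, MicrostateSet, ValidationError

UNASSIGNED = -1


@dataclass
class GfpSeries:
    """Global field power: per-sample spatial SD across channels (non-negative)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class MicrostateSegmentation:
    """Maps plus a per-sample label sequence and its explained variance."""

    maps: MicrostateSet
    labels: np.ndarray
    gev: float
    stats: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValidationError(f"gev must lie in [0, 1], got {self.gev}")
        assigned = self.labels[self.labels != UNASSIGNED]
        if assigned.size and assigned.max() >= self.maps.n_maps:
            raise ValidationError("label index exceeds map count")


def prepare_eeg(
    rec: EEGRecording,
    band: tuple[float, float] = (2.0, 20.0),
    fs_out: float = 125.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase band-pass, resample, and re-reference to the average.

    Defaults follow the standard microstate pipeline: 2-20 Hz and
    125 Hz output rate.  The average reference is applied last so each
    output sample has exactly zero channel mean.
    """
    low, high = band
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValidationError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    if fs_out <= 0 or fs_out > rec.fs:
        raise ValidationError("fs_out must be positive and not exceed fs")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    if fs_out != rec.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=fs_out, ch_names=list(rec.ch_names),
                        positions=rec.positions)


def gfp(rec: EEGRecording) -> GfpSeries:
    """Per-sample spatial standard deviation across channels."""
    if rec.n_channels < 2:
        raise ValidationError("GFP requires at least 2 channels")
    return GfpSeries(values=rec.data.std(axis=0, ddof=0), fs=rec.fs)


def find_gfp_peaks(g: GfpSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Indices of strict local GFP maxima, at least ``min_separation_ms`` apart.

    When two maxima fall closer than the separation, the larger is kept.
    """
    if g.n_samples < 3:
        raise ValidationError("GFP series too short for peak detection")
    distance = max(1, int(round(min_separation_ms / 1000.0 * g.fs)))
    peaks, _ = sps.find_peaks(g.values, distance=distance)
    return peaks


def _zero_mean_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def _unit_rows(x: np.ndarray, eps: float = 1e-30) -> np.ndarray:
    n = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.maximum(n, eps)


def _principal_map(members: np.ndarray) -> np.ndarray:
    """First principal direction of a set of maps (rows), unit norm.

    Sign fixed so the largest-magnitude channel is positive (determinism).
    """
    cov = members.T @ members
    w, v = np.linalg.eigh(cov)
    c = v[:, -1]
    j = int(np.argmax(np.abs(c)))
    if c[j] < 0:
        c = -c
    return c


def aahc_cluster(peak_maps: np.ndarray, k_target: int = 4) -> MicrostateSet:
    """Modified atomize-and-agglomerate hierarchical clustering.

    Every GFP-peak topography starts as its own cluster.  At each step
    the cluster contributing least to the global explained variance
    (GEV) is atomized: its members are reassigned, one by one, to the
    cluster whose centroid they correlate with best in absolute value
    (polarity-invariant).  Centroids are the first principal direction
    of their member maps.  Stops when ``k_target`` clusters remain.

    GEV is computed with GFP-squared weights: each peak map contributes
    its squared GFP times the squared spatial correlation with its
    cluster centroid, normalised by the total squared GFP.
    """
    x = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    n_maps, n_ch = x.shape
    if k_target < 1:
        raise ValidationError("k_target must be at least 1")
    if n_maps < k_target:
        raise ValidationError(
            f"cannot form {k_target} clusters from {n_maps} maps"
        )
    x = _zero_mean_rows(x)
    gfp_w = x.std(axis=1, ddof=0)
    xn = _unit_rows(x)
    w2 = gfp_w**2
    total_w2 = float(w2.sum())
    if total_w2 <= 0:
        raise ValidationError("all peak maps are flat")

    assign = np.arange(n_maps)
    centroids: dict[int, np.ndarray] = {i: xn[i].copy() for i in range(n_maps)}
    # cos_i = correlation of map i with its cluster centroid
    cos = np.ones(n_maps)

    def recompute(cid: int) -> None:
        members = np.flatnonzero(assign == cid)
        centroids[cid] = _principal_map(x[members])
        cos[members] = xn[members] @ centroids[cid]

    while len(centroids) > k_target:
        ids = np.fromiter(centroids.keys(), dtype=int)
        contrib = np.zeros(ids.size)
        id_pos = {cid: i for i, cid in enumerate(ids)}
        np.add.at(contrib, [id_pos[c] for c in assign], w2 * cos**2)
        worst = ids[int(np.argmin(contrib))]
        members = np.flatnonzero(assign == worst)
        del centroids[worst]
        remaining = np.fromiter(centroids.keys(), dtype=int)
        cmat = np.stack([centroids[c] for c in remaining])
        sim = np.abs(xn[members] @ cmat.T)
        assign[members] = remaining[np.argmax(sim, axis=1)]
        for cid in np.unique(assign[members]):
            recompute(cid)

    order = sorted(centroids.keys())
    maps = np.stack([centroids[c] for c in order])
    gev = float(np.sum(w2 * cos**2) / total_w2)
    return MicrostateSet(maps=maps, gev=min(gev, 1.0))


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise spatial correlation between map rows of ``a`` and ``b``."""
    an = _unit_rows(_zero_mean_rows(np.atleast_2d(a)))
    bn = _unit_rows(_zero_mean_rows(np.atleast_2d(b)))
    return an @ bn.T


def sort_to_templates(maps: MicrostateSet, templates: MicrostateSet) -> MicrostateSet:
    """Relabel maps A-D by optimal assignment against template maps.

    The one-to-one assignment maximises the total absolute spatial
    correlation over all permutations; each assigned map is flipped to
    correlate positively with its template.
    """
    if maps.n_channels != templates.n_channels:
        raise ValidationError(
            f"channel mismatch: {maps.n_channels} vs {templates.n_channels}"
        )
    if maps.n_maps != templates.n_maps:
        raise ValidationError("map count mismatch with templates")
    c = spatial_correlation(maps.maps, templates.maps)
    rows, cols = linear_sum_assignment(-np.abs(c))
    order = rows[np.argsort(cols)]  # map index assigned to template j
    out = maps.maps[order].copy()
    for j, i in enumerate(order):
        if c[i, j] < 0:
            out[j] = -out[j]
    return MicrostateSet(maps=out, labels=list(templates.labels), gev=maps.gev)


def backfit(
    rec: EEGRecording,
    maps: MicrostateSet,
    peaks_only: bool = False,
    min_separation_ms: float = 10.0,
) -> tuple[np.ndarray, dict]:
    """Label every sample with its best-matching map (polarity-invariant).

    With ``peaks_only`` the competition runs at GFP peaks and labels are
    extended to all samples by nearest-peak interpolation.  Zero-variance
    samples stay unassigned and are excluded from the statistics.

    Returns the label sequence and per-state statistics (coverage over
    assigned samples, mean dwell duration in ms, sample count).
    """
    data = _zero_mean_rows(rec.data.T)  # samples x channels
    norms = np.linalg.norm(data, axis=1)
    valid = norms > 1e-12
    mapsn = _unit_rows(_zero_mean_rows(maps.maps))
    labels = np.full(rec.n_samples, UNASSIGNED, dtype=int)

    if peaks_only:
        g = gfp(rec)
        peaks = find_gfp_peaks(g, min_separation_ms)
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(g.values))])
        corr = np.abs((data[peaks] / norms[peaks, None]) @ mapsn.T)
        peak_labels = np.argmax(corr, axis=1)
        nearest = np.searchsorted(peaks, np.arange(rec.n_samples))
        nearest = np.clip(nearest, 0, peaks.size - 1)
        left = np.clip(nearest - 1, 0, peaks.size - 1)
        use_left = np.abs(peaks[left] - np.arange(rec.n_samples)) <= np.abs(
            peaks[nearest] - np.arange(rec.n_samples)
        )
        choice = np.where(use_left, left, nearest)
        labels = peak_labels[choice]
        labels = np.where(valid, labels, UNASSIGNED)
    else:
        corr = np.abs((data[valid] / norms[valid, None]) @ mapsn.T)
        labels[valid] = np.argmax(corr, axis=1)

    stats = _label_stats(labels, maps, rec.fs)
    return labels, stats


def _label_stats(labels: np.ndarray, maps: MicrostateSet, fs: float) -> dict:
    assigned = labels[labels != UNASSIGNED]
    n_assigned = assigned.size
    stats: dict = {}
    # dwell runs over the assigned subsequence
    durations: dict[int, list[int]] = {k: [] for k in range(maps.n_maps)}
    run_label, run_len = None, 0
    for lab in labels:
        if lab == UNASSIGNED:
            continue
        if lab == run_label:
            run_len += 1
        else:
            if run_label is not None:
                durations[run_label].append(run_len)
            run_label, run_len = lab, 1
    if run_label is not None:
        durations[run_label].append(run_len)
    for k, name in enumerate(maps.labels):
        count = int((assigned == k).sum())
        stats[name] = {
            "coverage": count / n_assigned if n_assigned else 0.0,
            "mean_duration_ms": (
                1000.0 * float(np.mean(durations[k])) / fs if durations[k] else 0.0
            ),
            "n_samples": count,
        }
    stats["n_assigned"] = n_assigned
    return stats


def extract_state_epochs(
    rec: EEGRecording, labels: np.ndarray, state: int | str,
    maps: MicrostateSet | None = None,
) -> EEGRecording:
    """Concatenate all samples carrying one microstate label, in order."""
    labels = np.asarray(labels)
    if labels.size != rec.n_samples:
        raise ValidationError("label sequence length does not match recording")
    if isinstance(state, str):
        if maps is None or state not in maps.labels:
            raise ValidationError(f"unknown state label {state!r}")
        state = maps.labels.index(state)
    sel = labels == state
    if not sel.any():
        warnings.warn(f"state {state} absent from the label sequence",
                      stacklevel=2)
    return EEGRecording(data=rec.data[:, sel], fs=rec.fs,
                        ch_names=list(rec.ch_names), positions=rec.positions)


def segment(
    rec: EEGRecording,
    templates: MicrostateSet,
    k: int = 4,
    min_separation_ms: float = 10.0,
    peaks_only: bool = False,
) -> MicrostateSegmentation:
    """Full segmentation: GFP peaks -> AAHC -> template sorting -> backfit."""
    g = gfp(rec)
    peaks = find_gfp_peaks(g, min_separation_ms)
    if peaks.size < k:
        raise ValidationError(f"only {peaks.size} GFP peaks for k={k}")
    clustered = aahc_cluster(rec.data[:, peaks].T, k_target=k)
    sorted_maps = sort_to_templates(clustered, templates)
    labels, stats = backfit(rec, sorted_maps, peaks_only=peaks_only,
                            min_separation_ms=min_separation_ms)
    return MicrostateSegmentation(maps=sorted_maps, labels=labels,
                                  gev=clustered.gev, stats=stats)
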