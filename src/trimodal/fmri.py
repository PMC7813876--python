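"""Voxel-wise resting-state fMRI measures: ReHo, degree centrality, fALFF.

ReHo is Kendall's coefficient of concordance (KCC) of a voxel's time
series with its neighbours (27-voxel cubic neighbourhood by default,
shrunk to the in-mask subset at mask edges).  Degree centrality counts
in-mask voxels whose Pearson correlation with the seed exceeds a
positive threshold (0.25 by default).  fALFF is the in-band
(0.01-0.1 Hz) amplitude divided by the total amplitude over all
positive frequencies, computed on detrended full-band data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from scipy.stats import rankdata

from .types import BoldSeries, ValidationError, Volume

log = logging.getLogger(__name__)

_FOOTPRINTS = {}


def _footprint(neighbourhood: int) -> np.ndarray:
    if neighbourhood not in _FOOTPRINTS:
        if neighbourhood == 27:
            fp = np.ones((3, 3, 3), bool)
        elif neighbourhood == 19:
            fp = np.ones((3, 3, 3), bool)
            for c in [(0, 0, 0), (0, 0, 2), (0, 2, 0), (0, 2, 2),
                      (2, 0, 0), (2, 0, 2), (2, 2, 0), (2, 2, 2)]:
                fp[c] = False
        elif neighbourhood == 7:
            fp = np.zeros((3, 3, 3), bool)
            fp[1, 1, :] = fp[1, :, 1] = fp[:, 1, 1] = True
        else:
            raise ValidationError(
                f"neighbourhood must be 7, 19 or 27, got {neighbourhood}"
            )
        _FOOTPRINTS[neighbourhood] = fp
    return _FOOTPRINTS[neighbourhood]


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 motion columns, WM and CSF means, trends.

    The constant, linear and quadratic trend columns are generated from
    the series length when the design matrix is built.
    """

    motion: np.ndarray
    wm_mean: np.ndarray
    csf_mean: np.ndarray

    _NAMES = ["motion1", "motion2", "motion3", "motion4", "motion5", "motion6",
              "wm", "csf", "const", "linear", "quadratic"]

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, float))
        if self.motion.shape[1] != 6:
            raise ValidationError("motion must have 6 columns")
        self.wm_mean = np.asarray(self.wm_mean, float).ravel()
        self.csf_mean = np.asarray(self.csf_mean, float).ravel()
        t = self.motion.shape[0]
        if self.wm_mean.size != t or self.csf_mean.size != t:
            raise ValidationError("nuisance columns have unequal lengths")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    def design(self) -> tuple[np.ndarray, list[str]]:
        t = self.n_timepoints
        lin = np.linspace(-1.0, 1.0, t)
        x = np.column_stack([self.motion, self.wm_mean, self.csf_mean,
                             np.ones(t), lin, lin**2])
        return x, list(self._NAMES)

def detrend_design(t: int) -> tuple[np.ndarray, list[str]]:
    """Constant + linear + quadratic trend design for ``t`` timepoints."""
    lin = np.linspace(-1.0, 1.0, t)
    return np.column_stack([np.ones(t), lin, lin**2]), ["const", "linear", "quadratic"]


def _regress_out(y: np.ndarray, x: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        tol = max(np.abs(r).max() * max(x.shape) * np.finfo(float).eps, 1e-12)
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) <= tol)]
        raise ValidationError(
            f"rank-deficient nuisance design; dependent columns: {', '.join(bad or names)}"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def nuisance_regress(
    b: BoldSeries, n: NuisanceSet | tuple[np.ndarray, list[str]]
) -> BoldSeries:
    """Remove the nuisance design from every voxel by least squares."""
    x, names = n.design() if isinstance(n, NuisanceSet) else n
    if x.shape[0] != b.n_volumes:
        raise ValidationError(
            f"nuisance columns have {x.shape[0]} rows for {b.n_volumes} volumes"
        )
    mask = b.mask_array()
    out = b.data.copy()
    y = b.data[mask].T  # t x voxels
    out[mask] = _regress_out(y, x, names).T
    return BoldSeries(data=out, tr_s=b.tr_s, mask=b.mask)


def bandpass(b: BoldSeries, low: float = 0.01, high: float = 0.08,
             order: int = 4) -> BoldSeries:
    """Zero-phase Butterworth band-pass of every voxel time series."""
    fs = 1.0 / b.tr_s
    nyq = fs / 2.0
    if not (0 <= low < high <= nyq):
        raise ValidationError(
            f"band ({low}, {high}) Hz exceeds the Nyquist range [0, {nyq:.4f}]"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, b.data, axis=-1)
    return BoldSeries(data=data, tr_s=b.tr_s, mask=b.mask)


def _tie_correction(series: np.ndarray) -> np.ndarray:
    """Per-voxel Kendall tie term sum(t^3 - t) over tied groups.

    ``series``: voxels x timepoints.
    """
    s = np.sort(series, axis=1)
    t = s.shape[1]
    out = np.zeros(s.shape[0])
    for i in range(s.shape[0]):
        _, counts = np.unique(s[i], return_counts=True)
        tied = counts[counts > 1]
        if tied.size:
            out[i] = float(np.sum(tied.astype(float) ** 3 - tied))
    return out


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series (rows) over n points.

    Midranks are used for ties and the standard tie correction is
    subtracted from the denominator.
    """
    x = np.atleast_2d(np.asarray(series, float))
    k, n = x.shape
    if n < 3:
        raise ValidationError("Kendall's W needs at least 3 timepoints")
    ranks = rankdata(x, axis=1)
    r = ranks.sum(axis=0)
    s = float(((r - r.mean()) ** 2).sum())
    tie = float(_tie_correction(x).sum())
    denom = k**2 * (n**3 - n) - k * tie
    if denom <= 0:
        return 0.0
    return 12.0 * s / denom


def reho(b: BoldSeries, neighbourhood: int = 27) -> Volume:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    Neighbourhoods that extend beyond the analysis mask shrink to their
    in-mask subset (the effective K is reduced accordingly).
    """
    n = b.n_volumes
    if n < 3:
        raise ValidationError("ReHo needs at least 3 timepoints")
    fp = _footprint(neighbourhood).astype(float)
    mask = b.mask_array()
    shape = b.grid_shape

    ranks = np.zeros(shape + (n,))
    ranks[mask] = rankdata(b.data[mask], axis=1)
    ties = np.zeros(shape)
    ties[mask] = _tie_correction(b.data[mask])

    kernel4 = fp[..., None]
    maskf = mask.astype(float)
    k_eff = ndimage.correlate(maskf, fp, mode="constant")
    rank_sums = ndimage.correlate(ranks * maskf[..., None], kernel4, mode="constant")
    sum_sq = (rank_sums**2).sum(axis=-1)
    # each in-mask rank series sums to n(n+1)/2 over time
    s = sum_sq - n * (k_eff * (n + 1) / 2.0) ** 2
    tie_sums = ndimage.correlate(ties, fp, mode="constant")
    denom = k_eff**2 * (n**3 - n) - k_eff * tie_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, 0.0)
    w = np.clip(np.where(mask, w, 0.0), 0.0, 1.0)
    return Volume(data=w)


def degree_centrality(
    b: BoldSeries,
    r_threshold: float = 0.25,
    weighted: bool = False,
    chunk: int = 512,
) -> Volume:
    """Binary (or weighted) degree: in-mask voxels correlating above threshold.

    Only positive correlations strictly greater than ``r_threshold``
    count; self-connections are excluded.  Zero-variance voxels are
    treated as uncorrelated with everything (and logged).
    """
    mask = b.mask_array()
    series = b.data[mask]
    n_vox = series.shape[0]
    if n_vox < 2:
        raise ValidationError("degree centrality needs at least 2 in-mask voxels")
    z = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    flat = norms <= 1e-12
    if flat.any():
        log.warning("%d zero-variance voxels treated as correlation 0", flat.sum())
    norms[flat] = np.inf
    z = z / norms[:, None]

    deg = np.zeros(n_vox)
    for start in range(0, n_vox, chunk):
        stop = min(start + chunk, n_vox)
        c = z[start:stop] @ z.T
        above = c > r_threshold
        for i in range(start, stop):
            above[i - start, i] = False  # exclude self
        if weighted:
            deg[start:stop] = np.where(above, c, 0.0).sum(axis=1)
        else:
            deg[start:stop] = above.sum(axis=1)

    out = np.zeros(b.grid_shape)
    out[mask] = deg
    return Volume(data=out)


def falff(b: BoldSeries, band: tuple[float, float] = (0.01, 0.1)) -> Volume:
    """Fractional amplitude of low-frequency fluctuations.

    Per voxel: the sum of amplitude-spectrum values (square root of the
    periodogram) inside the band divided by the sum over all positive
    frequencies.  Input should be full-band and already detrended (the
    nuisance design includes trend columns); only the voxel mean is
    removed here.  All-zero voxels yield 0 (logged).
    """
    low, high = band
    nyq = 0.5 / b.tr_s
    if not (0 <= low < high):
        raise ValidationError("band must satisfy 0 <= low < high")
    mask = b.mask_array()
    series = b.data[mask]
    series = series - series.mean(axis=1, keepdims=True)
    n = b.n_volumes
    amp = np.abs(np.fft.rfft(series, axis=1))
    freqs = np.fft.rfftfreq(n, d=b.tr_s)
    positive = freqs > 0
    inband = positive & (freqs >= low) & (freqs <= high)
    total = amp[:, positive].sum(axis=1)
    flat = total <= 1e-300
    if flat.any():
        log.warning("%d all-zero voxels assigned fALFF 0", flat.sum())
    total[flat] = np.inf
    ratio = amp[:, inband].sum(axis=1) / total
    out = np.zeros(b.grid_shape)
    out[mask] = ratio
    return Volume(data=out)
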