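"""Intermodal statistics.

Parametric maps from the three modalities are put on a common scale by
voxel-wise Z standardisation over an analysis mask, restricted to grey
matter, and compared region by region with Pearson correlations whose
family-wise error rate is controlled by a max-statistic permutation
test.  Group comparisons of regional values use a stepdown (Holm)
Dunn's rank test, and one-sample Kolmogorov-Smirnov tests check the
normality of extracted voxel values.

Caveat on the permutation scheme: the null is built by permuting the
voxel order of one map, which assumes exchangeable voxels.  Spatially
autocorrelated maps violate this and inflate false positives; a block
permutation mode is available to blunt that effect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special as ssp
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .types import StatResult, ValidationError, Volume


@dataclass
class ZMap:
    """A Z-standardised parametric map (in-mask mean 0, SD 1)."""

    volume: Volume
    mask: Volume
    source_quantity: str = ""

    def in_mask(self) -> np.ndarray:
        return self.volume.data[self.mask.data.astype(bool)]


@dataclass
class CorrelationFamily:
    """A family of regional correlations with max-statistic adjusted p."""

    pair_names: list = field(default_factory=list)
    r_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_adjusted: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_voxels: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_permutations: int = 0
    alpha: float = 0.05
    seed: int | None = None

    def significant(self) -> np.ndarray:
        return self.p_adjusted <= self.alpha


def z_standardize(v: Volume, mask: Volume, source_quantity: str = "") -> ZMap:
    """Standardise in-mask voxels to mean 0, SD 1 (population SD).

    Out-of-mask voxels are set to zero.
    """
    v.require_same_grid(mask, "map and mask")
    m = mask.data.astype(bool)
    vals = v.data[m]
    if vals.size < 2:
        raise ValidationError("mask must contain at least 2 voxels")
    sd = vals.std(ddof=0)
    if sd <= 0:
        raise ValidationError("zero variance inside the standardisation mask")
    out = np.zeros(v.shape)
    out[m] = (vals - vals.mean()) / sd
    vol = Volume(data=out, voxel_size_mm=v.voxel_size_mm, offset_mm=v.offset_mm)
    return ZMap(volume=vol, mask=mask, source_quantity=source_quantity)


def gm_correct(region: Volume, gm_prob: Volume, threshold: float = 0.5) -> Volume:
    """Restrict a region mask to voxels with GM probability strictly above
    ``threshold``."""
    region.require_same_grid(gm_prob, "region and GM probability map")
    if not (0 <= threshold < 1):
        raise ValidationError("threshold must lie in [0, 1)")
    out = region.data.astype(bool) & (gm_prob.data > threshold)
    return Volume(data=out, voxel_size_mm=region.voxel_size_mm,
                  offset_mm=region.offset_mm)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xz = x - x.mean()
    yz = y - y.mean()
    return float(xz @ yz / (np.linalg.norm(xz) * np.linalg.norm(yz)))


def _permutations(rng: np.random.Generator, n_perm: int, n: int,
                  block: int = 1) -> np.ndarray:
    """n_perm random voxel orderings; ``block > 1`` permutes contiguous blocks."""
    if block <= 1:
        return np.argsort(rng.random((n_perm, n)), axis=1)
    n_blocks = int(np.ceil(n / block))
    order = np.argsort(rng.random((n_perm, n_blocks)), axis=1)
    flat = (order[..., None] * block + np.arange(block)[None, None, :]).reshape(
        n_perm, -1
    )
    return flat[flat < n].reshape(n_perm, n)  # drop padding past the last block


def correlate_fwer(
    x_maps: list,
    y_maps: list,
    regions: list,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    block: int = 1,
    chunk: int = 20_000,
) -> CorrelationFamily:
    """Regional Pearson correlations with max-statistic permutation FWER.

    Pair ``i`` correlates the in-region voxels of ``x_maps[i]`` and
    ``y_maps[i]`` over ``regions[i]``.  The null permutes the voxel
    order of the y map; for each permutation the maximum |r| across the
    family is recorded, and the adjusted p-value of each pair is
    ``(1 + #{max >= |r_obs|}) / (n_perm + 1)``.  Per-pair unadjusted
    permutation p-values use the pair's own null.  Deterministic given
    ``seed``.  Regions with fewer than 3 voxels are skipped.
    """
    if not (len(x_maps) == len(y_maps) == len(regions)):
        raise ValidationError("x_maps, y_maps and regions must have equal length")
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)

    names, xs, ys, nvox = [], [], [], []
    for i, (xm, ym, reg) in enumerate(zip(x_maps, y_maps, regions)):
        xv = xm.volume if isinstance(xm, ZMap) else xm
        yv = ym.volume if isinstance(ym, ZMap) else ym
        xv.require_same_grid(yv, f"pair {i} maps")
        xv.require_same_grid(reg, f"pair {i} map and region")
        m = reg.data.astype(bool)
        if m.sum() < 3:
            warnings.warn(f"pair {i} skipped: region has {m.sum()} voxels",
                          stacklevel=2)
            continue
        x, y = xv.data[m], yv.data[m]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"pair {i} skipped: constant map in region", stacklevel=2)
            continue
        names.append(i)
        xs.append(x)
        ys.append(y)
        nvox.append(int(m.sum()))

    n_pairs = len(names)
    if n_pairs == 0:
        return CorrelationFamily(n_permutations=n_perm, alpha=alpha, seed=seed)

    r_obs = np.array([_pearson(x, y) for x, y in zip(xs, ys)])
    exceed_single = np.zeros(n_pairs)
    max_stats = np.full(n_perm, -np.inf)
    done = 0
    while done < n_perm:
        m_chunk = min(chunk, n_perm - done)
        abs_chunk = np.empty((m_chunk, n_pairs))
        for j, (x, y) in enumerate(zip(xs, ys)):
            n = x.size
            xz = (x - x.mean()) / (x.std() * np.sqrt(n))
            yz = (y - y.mean()) / (y.std() * np.sqrt(n))
            idx = _permutations(rng, m_chunk, n, block=block)
            abs_chunk[:, j] = np.abs(yz[idx] @ xz)
        exceed_single += (abs_chunk >= np.abs(r_obs)[None, :] - 1e-15).sum(axis=0)
        max_stats[done:done + m_chunk] = abs_chunk.max(axis=1)
        done += m_chunk

    p_single = (1.0 + exceed_single) / (n_perm + 1.0)
    exceed_max = (max_stats[:, None] >= np.abs(r_obs)[None, :] - 1e-15).sum(axis=0)
    p_adj = (1.0 + exceed_max) / (n_perm + 1.0)
    return CorrelationFamily(
        pair_names=names,
        r_values=r_obs,
        p_values=p_single,
        p_adjusted=p_adj,
        n_voxels=np.array(nvox),
        n_permutations=n_perm,
        alpha=alpha,
        seed=seed,
    )


def dunn_zstats(groups: list) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Dunn z statistics from a joint midrank ranking.

    Returns the k x k antisymmetric z matrix and the mean ranks.
    The variance term applies the standard tie correction
    ``sum(t^3 - t) / (12 (N - 1))``.
    """
    arrs = [np.asarray(g, float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValidationError("need at least 2 groups")
    for g in arrs:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 observations")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = sst.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    mean_ranks = np.asarray(mean_ranks)

    _, counts = np.unique(pooled, return_counts=True)
    tied = counts[counts > 1].astype(float)
    tie_term = float(np.sum(tied**3 - tied)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(arrs)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            se = np.sqrt(base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            z[i, j] = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
    return z, mean_ranks


def dunn_stepdown(groups: list, alpha: float = 0.05,
                  labels: list[str] | None = None) -> list[StatResult]:
    """Stepdown Dunn's test for nonparametric pairwise comparisons.

    Pairwise z statistics are computed from the joint ranking; two-sided
    normal p-values are adjusted by the Holm stepdown procedure over the
    ``k (k - 1) / 2`` comparisons.
    """
    z, _ = dunn_zstats(groups)
    k = z.shape[0]
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    zs = np.array([z[i, j] for i, j in pairs])
    p = 2.0 * sst.norm.sf(np.abs(zs))
    reject, p_holm, _, _ = multipletests(p, alpha=alpha, method="holm")
    return [
        StatResult(effect=float(zs[m]), p=float(p[m]), p_adjusted=float(p_holm[m]),
                   method="dunn-holm", significant=bool(reject[m]),
                   label=f"{labels[i]} vs {labels[j]}")
        for m, (i, j) in enumerate(pairs)
    ]


def ks_normality(sample, alpha: float = 0.05) -> StatResult:
    """One-sample KS test of normality against the sample's own mean/SD.

    D is the supremum distance between the empirical CDF and the fitted
    normal CDF; the p-value comes from the asymptotic Kolmogorov
    distribution.  (With estimated parameters this p-value is known to
    be conservative toward non-rejection; it is reported as such.)
    """
    x = np.asarray(sample, float).ravel()
    if x.size < 5:
        raise ValidationError("KS normality test needs at least 5 observations")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValidationError("zero-variance sample")
    z = (x - x.mean()) / sd
    d = float(sst.kstest(z, "norm").statistic)
    p = float(ssp.kolmogorov(np.sqrt(x.size) * d))
    return StatResult(effect=d, p=p, p_adjusted=p, method="ks-normal",
                      significant=p <= alpha, label="ks_normality")
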