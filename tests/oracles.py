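"""Independent brute-force reference implementations.

Each oracle here is written directly from the textbook definition of
its statistic, with loops instead of vectorisation, and is kept fully
independent of the package's implementation paths.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def gfp_oracle(data: np.ndarray) -> np.ndarray:
    """Spatial SD per sample: loop over samples, explicit formula."""
    n_ch, n_s = data.shape
    out = np.empty(n_s)
    for t in range(n_s):
        col = data[:, t]
        m = sum(col) / n_ch
        out[t] = math.sqrt(sum((v - m) ** 2 for v in col) / n_ch)
    return out


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kendall_w_oracle(series: np.ndarray) -> float:
    """Kendall's W from explicit rank sums with midranks and tie correction."""
    series = np.atleast_2d(series)
    k, n = series.shape
    ranks = [ _midranks(list(row)) for row in series ]
    rank_sums = [sum(ranks[j][t] for j in range(k)) for t in range(n)]
    mean_r = sum(rank_sums) / n
    s = sum((r - mean_r) ** 2 for r in rank_sums)
    tie = 0.0
    for row in series:
        seen = {}
        for v in row:
            seen[v] = seen.get(v, 0) + 1
        tie += sum(c**3 - c for c in seen.values())
    denom = k**2 * (n**3 - n) - k * tie
    return 12.0 * s / denom if denom > 0 else 0.0


def dc_oracle(series: np.ndarray, threshold: float) -> np.ndarray:
    """O(N^2) pairwise Pearson degree count, positive threshold only."""
    n = series.shape[0]
    deg = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = series[i], series[j]
            sxi, sxj = xi.std(), xj.std()
            if sxi == 0 or sxj == 0:
                continue
            r = float(np.mean((xi - xi.mean()) * (xj - xj.mean())) / (sxi * sxj))
            if r > threshold:
                deg[i] += 1
    return deg


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p: textbook step-up with monotonisation."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def dunn_z_oracle(groups: list) -> np.ndarray:
    """Pairwise Dunn z from explicit pooled midranks."""
    pooled = [v for g in groups for v in g]
    ranks = _midranks(pooled)
    n_total = len(pooled)
    mean_ranks, start = [], 0
    for g in groups:
        mean_ranks.append(sum(ranks[start:start + len(g)]) / len(g))
        start += len(g)
    seen = {}
    for v in pooled:
        seen[v] = seen.get(v, 0) + 1
    tie = sum(c**3 - c for c in seen.values()) / (12.0 * (n_total - 1))
    base = n_total * (n_total + 1) / 12.0 - tie
    k = len(groups)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                se = math.sqrt(base * (1 / len(groups[i]) + 1 / len(groups[j])))
                z[i, j] = (mean_ranks[i] - mean_ranks[j]) / se
    return z


def ks_d_oracle(sample: np.ndarray) -> float:
    """Sup distance between the empirical CDF and the fitted normal CDF."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    z = (x - mu) / sd
    cdf = 0.5 * (1.0 + np.array([math.erf(v / math.sqrt(2)) for v in z]))
    d = 0.0
    for i in range(n):
        d = max(d, (i + 1) / n - cdf[i], cdf[i] - i / n)
    return d


def local_maxima_oracle(values: np.ndarray) -> list[int]:
    """Indices of strict interior local maxima, exhaustive scan."""
    out = []
    for i in range(1, len(values) - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            out.append(i)
    return out


def best_assignment_oracle(corr: np.ndarray):
    """Exhaustive search over all permutations maximising total |corr|."""
    k = corr.shape[0]
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(k)):
        total = sum(abs(corr[perm[j], j]) for j in range(k))
        if total > best:
            best, best_perm = total, perm
    return np.array(best_perm), best


def hat_matrix_residual_oracle(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual via the explicit projection matrix I - X (X'X)^-1 X'."""
    h = x @ np.linalg.inv(x.T @ x) @ x.T
    return (np.eye(x.shape[0]) - h) @ y
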