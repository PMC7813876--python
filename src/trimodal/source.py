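"""Distributed EEG source imaging and per-microstate network identification.

The inverse solution is the standardized minimum-norm estimate (sLORETA):
a Tikhonov-regularised minimum-norm current estimate standardised per
source by the corresponding diagonal element of the model resolution
matrix.  For scalar (fixed-orientation) sources this standardisation has
zero localisation error on noiseless point sources.

Microstate generators are then localised with the TESS approach: each
source time series is regressed on a microstate indicator together with
the global field power, the state coefficient's p-values are controlled
for false discovery rate (Benjamini-Hochberg), and significant betas are
Z-scored into a network map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .microstates import GfpSeries
from .types import EEGRecording, Leadfield, ValidationError


@dataclass
class InverseSolution:
    """Standardized source activity (sources x samples) on a source grid."""

    source_activity: np.ndarray
    source_coords: np.ndarray
    regularization: float
    fs: float = 1.0

    def __post_init__(self) -> None:
        self.source_activity = np.atleast_2d(
            np.asarray(self.source_activity, dtype=float)
        )
        self.source_coords = np.atleast_2d(np.asarray(self.source_coords, float))
        if self.source_coords.shape[0] != self.source_activity.shape[0]:
            raise ValidationError("source coordinate count does not match activity")

    @property
    def n_sources(self) -> int:
        return self.source_activity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.source_activity.shape[1]


@dataclass
class TessNetwork:
    """Per-source GLM result for one microstate regressor."""

    betas: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    z_map: np.ndarray
    mask: np.ndarray
    q_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.z_map[~self.mask] != 0):
            raise ValidationError("z_map must be zero outside the mask")


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def slo_inverse(
    rec: EEGRecording,
    leadfield: Leadfield,
    alpha: float | None = None,
) -> InverseSolution:
    """sLORETA inverse: standardized minimum-norm source activity.

    Parameters
    ----------
    alpha : float or None
        Tikhonov regularisation.  ``None`` picks a scale-free default,
        1e-4 times the mean diagonal of the model sensor covariance
        ``L @ L.T``; 0 uses the pseudo-inverse alone.
    """
    if rec.n_channels != leadfield.n_channels:
        raise ValidationError(
            f"recording has {rec.n_channels} channels, "
            f"leadfield {leadfield.n_channels}"
        )
    n_ch = rec.n_channels
    h = _centering(n_ch)
    k = h @ leadfield.gain  # average-referenced leadfield
    data = rec.data - rec.data.mean(axis=0, keepdims=True)

    c0 = k @ k.T
    if alpha is None:
        alpha = 1e-4 * float(np.trace(c0)) / n_ch
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    c = c0 + alpha * h
    cinv = np.linalg.pinv(c, hermitian=True)
    t = k.T @ cinv
    resolution = t @ k
    diag = np.diag(resolution).copy()
    bad = diag <= 1e-15 * diag.max()
    diag[bad] = np.inf  # sources the leadfield cannot see map to zero
    activity = (t @ data) / np.sqrt(diag)[:, None]
    return InverseSolution(
        source_activity=activity,
        source_coords=leadfield.source_coords,
        regularization=float(alpha),
        fs=rec.fs,
    )


def standardized_power(sol: InverseSolution) -> np.ndarray:
    """Time-summed standardized power per source."""
    return (sol.source_activity**2).sum(axis=1)


def state_indicators(labels: np.ndarray, n_states: int) -> np.ndarray:
    """Binary state time courses (n_states x n_samples) from a label sequence."""
    labels = np.asarray(labels, dtype=int)
    return np.stack([(labels == k).astype(float) for k in range(n_states)])


def tess_glm(
    sol: InverseSolution,
    state_timecourses: np.ndarray,
    gfp: GfpSeries | np.ndarray,
    q: float = 0.01,
) -> list[TessNetwork]:
    """Per-state GLM of every source time series with BH-FDR control.

    For each state the design is [state indicator, GFP, intercept]; the
    state coefficient's two-sided t p-values are adjusted across sources
    by Benjamini-Hochberg, significant betas are Z-scored (mean/SD over
    the significant set), and the network mask keeps q <= threshold.
    """
    if not (0 < q < 1):
        raise ValidationError("q must lie in (0, 1)")
    g = gfp.values if isinstance(gfp, GfpSeries) else np.asarray(gfp, float)
    states = np.atleast_2d(np.asarray(state_timecourses, dtype=float))
    n = sol.n_samples
    if states.shape[1] != n or g.size != n:
        raise ValidationError("regressors are not aligned to the solution samples")

    y = sol.source_activity.T  # samples x sources
    networks = []
    for k in range(states.shape[0]):
        x = np.column_stack([states[k], g, np.ones(n)])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            offending = _dependent_columns(x, ["state", "gfp", "intercept"])
            raise ValidationError(
                f"collinear regressors for state {k}: {', '.join(offending)}"
            )
        xtx_inv = np.linalg.inv(x.T @ x)
        beta_all = xtx_inv @ x.T @ y
        resid = y - x @ beta_all
        dof = n - x.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
        beta = beta_all[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
        pval = 2.0 * sst.t.sf(np.abs(tval), dof)
        _, qval, _, _ = multipletests(pval, method="fdr_bh")
        mask = qval <= q
        z = np.zeros_like(beta)
        if mask.sum() >= 2 and beta[mask].std() > 0:
            z[mask] = (beta[mask] - beta[mask].mean()) / beta[mask].std()
        networks.append(
            TessNetwork(betas=beta, p_values=pval, q_values=qval, z_map=z,
                        mask=mask, q_threshold=q)
        )
    return networks


def _dependent_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in a rank deficiency, flagged from the QR diagonal."""
    _, r = np.linalg.qr(x)
    tol = np.abs(r).max() * max(x.shape) * np.finfo(float).eps
    small = np.abs(np.diag(r)) <= max(tol, 1e-12)
    # QR without pivoting flags the later of each dependent pair
    return [names[i] for i in np.flatnonzero(small)] or list(names)


def group_mask(z_maps: list[np.ndarray], min_fraction: float = 0.5) -> np.ndarray:
    """Sources with z > 0 in at least ``min_fraction`` of subjects (inclusive)."""
    if not z_maps:
        raise ValidationError("empty subject list")
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must lie in (0, 1]")
    stack = np.stack([np.asarray(z, float) for z in z_maps])
    frac = (stack > 0).mean(axis=0)
    return frac >= min_fraction - 1e-12
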