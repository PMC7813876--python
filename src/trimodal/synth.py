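"""Synthetic trimodal inputs with known ground truth.

Every generator here is a pure function of its seed, producing the
smallest dataset on which a downstream measure can demonstrably recover
a planted effect: four canonical microstate topographies driving a
Markov-switching EEG, a BOLD grid with locally homogeneous blocks, hub
voxels and band-limited oscillators, dynamic PET frames with target and
reference concentrations, and a toy atlas with RSN-like regions, a
grey-matter probability map and a distance-based leadfield.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    BoldSeries,
    EEGRecording,
    Leadfield,
    MicrostateSet,
    ValidationError,
    Volume,
)

MICROSTATE_LABELS = ("A", "B", "C", "D")

# Pole centres on the unit scalp disc (+x right, +y anterior) for the
# four canonical classes: A right-frontal/left-posterior, B left-frontal/
# right-posterior, C midline frontal-occipital, D midline frontal.
_POLES = {
    "A": [((0.55, 0.55), +1.0), ((-0.55, -0.55), -1.0)],
    "B": [((-0.55, 0.55), +1.0), ((0.55, -0.55), -1.0)],
    "C": [((0.0, 0.70), +1.0), ((0.0, -0.70), -1.0)],
    "D": [((0.0, 0.45), +1.0)],
}
_POLE_SIGMA = 0.45


@dataclass
class MicrostateGroundTruth:
    """Generating model for synthetic microstate EEG."""

    templates: np.ndarray  # K x channels, zero-mean unit-norm rows
    state_sequence: np.ndarray  # per-sample label, may be empty pre-simulation
    transition_matrix: np.ndarray  # row-stochastic, at fs_ref
    mean_duration_ms: float
    fs_ref: float = 125.0

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.mean_duration_ms <= 0:
            raise ValidationError("mean_duration_ms must be positive")

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]

    def transition_for_fs(self, fs: float) -> np.ndarray:
        """Per-sample transition matrix giving the stated mean dwell at fs."""
        k = self.n_states
        p_leave = min(1.0, 1.0 / (fs * self.mean_duration_ms / 1000.0))
        t = np.full((k, k), p_leave / (k - 1))
        np.fill_diagonal(t, 1.0 - p_leave)
        return t


@dataclass
class BoldGroundTruth:
    """Planted BOLD structure: homogeneity blocks, hubs, in-band voxels."""

    homo_blocks: list = field(default_factory=list)  # list of (m, 3) index arrays
    hub_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    inband_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    tr_s: float = 2.2
    hub_partner_fraction: float = 0.3

    def __post_init__(self) -> None:
        self.homo_blocks = [np.atleast_2d(np.asarray(b, int)) for b in self.homo_blocks]
        self.hub_voxels = np.atleast_2d(np.asarray(self.hub_voxels, int)).reshape(-1, 3)
        self.inband_voxels = np.atleast_2d(
            np.asarray(self.inband_voxels, int)
        ).reshape(-1, 3)
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")

    def validate_grid(self, shape: tuple[int, int, int]) -> None:
        for name, sets in (
            ("homo_blocks", self.homo_blocks),
            ("hub_voxels", [self.hub_voxels]),
            ("inband_voxels", [self.inband_voxels]),
        ):
            for idx in sets:
                if idx.size == 0:
                    continue
                if (idx < 0).any() or (idx >= np.asarray(shape)).any():
                    raise ValidationError(f"{name} contains indices outside {shape}")


@dataclass
class PetGroundTruth:
    """Target/reference concentrations driving synthetic dynamic PET."""

    target_mask: np.ndarray
    reference_mask: np.ndarray
    c_t: np.ndarray  # kBq/ml per frame
    c_ref: np.ndarray
    injected_MBq: float = 200.0
    weight_kg: float = 80.0

    def __post_init__(self) -> None:
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        self.reference_mask = np.asarray(self.reference_mask, dtype=bool)
        self.c_t = np.atleast_1d(np.asarray(self.c_t, dtype=float))
        self.c_ref = np.atleast_1d(np.asarray(self.c_ref, dtype=float))
        if not self.target_mask.any() or not self.reference_mask.any():
            raise ValidationError("target and reference masks must be non-empty")
        if (self.target_mask & self.reference_mask).any():
            raise ValidationError("target and reference masks overlap")
        if (self.c_t < 0).any() or (self.c_ref < 0).any():
            raise ValidationError("concentrations must be non-negative")
        if self.injected_MBq <= 0 or self.weight_kg <= 0:
            raise ValidationError("injected_MBq and weight_kg must be positive")


def disc_layout(n_channels: int) -> np.ndarray:
    """Deterministic electrode positions on the unit scalp disc.

    One centre electrode plus concentric rings, mimicking the coverage
    of a standard cap without reproducing any specific montage.
    """
    if n_channels < 1:
        raise ValidationError("need at least one channel")
    pos = [(0.0, 0.0)]
    remaining = n_channels - 1
    n_rings = max(1, int(np.ceil(remaining / 8)))
    per_ring = [remaining // n_rings + (1 if i < remaining % n_rings else 0)
                for i in range(n_rings)]
    for ring, count in enumerate(per_ring):
        r = (ring + 1) / n_rings * 0.9
        for j in range(count):
            th = 2 * np.pi * j / count + (np.pi / count if ring % 2 else 0.0)
            # angle 0 at the nasion (anterior), clockwise toward the right
            pos.append((r * np.sin(th), r * np.cos(th)))
    return np.asarray(pos[:n_channels], dtype=float)


def _pole_map(positions: np.ndarray, poles) -> np.ndarray:
    v = np.zeros(positions.shape[0])
    for (cx, cy), sign in poles:
        d2 = (positions[:, 0] - cx) ** 2 + (positions[:, 1] - cy) ** 2
        v += sign * np.exp(-d2 / (2 * _POLE_SIGMA**2))
    return v


def make_templates(
    n_channels: int = 32,
    layout: np.ndarray | None = None,
    mean_duration_ms: float = 100.0,
) -> tuple[MicrostateSet, MicrostateGroundTruth]:
    """Build the four canonical microstate topographies on a scalp layout.

    Gaussian poles are placed at the canonical locations of classes A-D,
    each map is average-referenced, and the set is symmetrically
    (Loewdin) orthonormalised.  Symmetric orthonormalisation treats the
    four maps on an equal footing, so mirroring the layout left-right
    exactly swaps maps A and B.

    Returns the maps as a :class:`MicrostateSet` together with the
    generating ground truth (templates, dwell model).
    """
    if n_channels < 8:
        raise ValidationError(
            f"at least 8 channels required for 4 separable maps, got {n_channels}"
        )
    positions = disc_layout(n_channels) if layout is None else np.asarray(layout, float)
    if positions.shape[0] != n_channels:
        raise ValidationError("layout size does not match n_channels")

    raw = np.column_stack(
        [_pole_map(positions, _POLES[lbl]) for lbl in MICROSTATE_LABELS]
    )
    raw -= raw.mean(axis=0, keepdims=True)  # average reference per map
    # Loewdin: the closest matrix with orthonormal columns; preserves the
    # zero channel mean (columns stay in the span of the raw maps).
    u, _, vt = np.linalg.svd(raw, full_matrices=False)
    maps = (u @ vt).T  # K x channels, orthonormal rows

    truth = MicrostateGroundTruth(
        templates=maps,
        state_sequence=np.empty(0, dtype=int),
        transition_matrix=np.eye(4),  # placeholder, rebuilt below
        mean_duration_ms=mean_duration_ms,
    )
    truth.transition_matrix = truth.transition_for_fs(truth.fs_ref)
    mset = MicrostateSet(maps=maps.copy(), labels=list(MICROSTATE_LABELS))
    return mset, truth


def simulate_eeg(
    truth: MicrostateGroundTruth,
    duration_s: float,
    fs: float = 125.0,
    snr: float = 4.0,
    seed: int = 0,
) -> tuple[EEGRecording, np.ndarray]:
    """Markov-switching microstate EEG with sensor noise.

    Each sample is the active template scaled by a half-wave sine
    amplitude envelope over its dwell period (GFP peaks mid-state), plus
    i.i.d. Gaussian sensor noise scaled so that total signal power over
    total noise power equals ``snr``.  ``snr=inf`` gives noiseless data.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValidationError("duration_s and fs must be positive")
    if snr < 0:
        raise ValidationError("snr must be non-negative")
    t = np.asarray(truth.transition_matrix, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or (t < 0).any() or not np.allclose(
        t.sum(axis=1), 1.0, atol=1e-9
    ):
        raise ValidationError("transition matrix must be row-stochastic")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    k = truth.n_states
    trans = truth.transition_for_fs(fs)
    cum = np.cumsum(trans, axis=1)

    states = np.empty(n, dtype=int)
    states[0] = rng.integers(k)
    u = rng.random(n - 1)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1])

    # half-wave sine envelope over each dwell run
    amp = np.empty(n)
    start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[start]:
            length = i - start
            amp[start:i] = np.sin(np.pi * (np.arange(length) + 0.5) / length)
            start = i

    n_ch = truth.templates.shape[1]
    signal = truth.templates[states].T * amp[None, :]
    if np.isinf(snr):
        data = signal
    else:
        sig_power = float(np.mean(amp**2))  # rows are unit norm
        noise_sd = np.sqrt(sig_power / (n_ch * snr)) if snr > 0 else np.inf
        if snr == 0:
            raise ValidationError("snr must be positive or inf")
        data = signal + noise_sd * rng.standard_normal(signal.shape)

    rec = EEGRecording(
        data=data, fs=fs, positions=disc_layout(n_ch)
    )
    return rec, states


def _bandlimited_signal(rng: np.random.Generator, n: int, tr_s: float,
                        low: float = 0.01, high: float = 0.08) -> np.ndarray:
    """Unit-variance sum of sinusoids confined to [low, high] Hz."""
    t = np.arange(n) * tr_s
    freqs = rng.uniform(low, high, size=8)
    phases = rng.uniform(0, 2 * np.pi, size=8)
    s = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
               axis=0)
    return (s - s.mean()) / s.std()


def default_bold_truth(shape: tuple[int, int, int], tr_s: float = 2.2) -> BoldGroundTruth:
    """Disjoint planted structure for a grid of at least 10 voxels per axis."""
    if min(shape) < 10:
        raise ValidationError("grid too small for the default planted structure")
    gx = np.arange(1, 4)
    block = np.array(np.meshgrid(gx, gx, gx, indexing="ij")).reshape(3, -1).T
    hub = np.array([[shape[0] - 3, 2, 2]])
    inb = np.array([[2, shape[1] - 3, shape[2] - 3],
                    [3, shape[1] - 3, shape[2] - 3]])
    return BoldGroundTruth(homo_blocks=[block], hub_voxels=hub,
                           inband_voxels=inb, tr_s=tr_s)


def simulate_bold(
    shape: tuple[int, int, int],
    n_vols: int,
    truth: BoldGroundTruth,
    seed: int = 0,
) -> BoldSeries:
    """White-noise BOLD grid with planted ReHo / hub / band-limited structure.

    Homogeneity blocks share one band-limited latent signal plus weak
    independent noise; the hub voxel shares a latent with a random
    fraction of background voxels strongly enough that the pairwise
    correlation exceeds 0.25 in expectation; in-band voxels carry a
    large sinusoid inside 0.01-0.1 Hz.  Everything else is white noise.
    """
    if n_vols < 32:
        raise ValidationError(f"n_vols must be at least 32, got {n_vols}")
    truth.validate_grid(shape)
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape + (n_vols,))

    for block in truth.homo_blocks:
        if block.size == 0:
            continue
        latent = _bandlimited_signal(rng, n_vols, truth.tr_s)
        ix = tuple(block.T)
        data[ix] = 1.5 * latent[None, :] + 0.7 * data[ix]

    if truth.hub_voxels.size:
        hub_sig = _bandlimited_signal(rng, n_vols, truth.tr_s)
        special = {tuple(v) for v in truth.hub_voxels}
        special |= {tuple(v) for v in truth.inband_voxels}
        for b in truth.homo_blocks:
            special |= {tuple(v) for v in b}
        all_idx = [v for v in np.ndindex(shape) if v not in special]
        n_partner = int(truth.hub_partner_fraction * len(all_idx))
        partners = rng.choice(len(all_idx), size=n_partner, replace=False)
        for p in partners:
            data[all_idx[p]] += 0.45 * hub_sig
        for v in truth.hub_voxels:
            data[tuple(v)] = 1.5 * hub_sig + 0.5 * data[tuple(v)]

    for v in truth.inband_voxels:
        f = rng.uniform(0.02, 0.07)
        ph = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_vols) * truth.tr_s
        data[tuple(v)] = 4.0 * np.sin(2 * np.pi * f * t + ph) + 0.3 * data[tuple(v)]

    return BoldSeries(data=data, tr_s=truth.tr_s)


def default_pet_truth(shape: tuple[int, int, int], n_frames: int = 3) -> PetGroundTruth:
    """Target box with rising uptake against a flat reference region."""
    target = np.zeros(shape, dtype=bool)
    reference = np.zeros(shape, dtype=bool)
    target[1:4, 1:4, 1:4] = True
    reference[-4:-1, -4:-1, -4:-1] = True
    c_ref = np.full(n_frames, 5.0)
    c_t = 5.0 * (1.5 + 0.2 * np.arange(n_frames))
    return PetGroundTruth(target_mask=target, reference_mask=reference,
                          c_t=c_t, c_ref=c_ref)


def simulate_pet(
    shape: tuple[int, int, int],
    truth: PetGroundTruth,
    n_frames: int | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    frame_duration_min: float = 2.0,
):
    """Dynamic PET frames: c_t in the target, c_ref elsewhere, plus noise.

    The background is filled with the reference concentration so that a
    reference-region binding-potential map is zero outside the target.
    Returns a :class:`~trimodal.pet.PetFrameSet`.
    """
    from .pet import PetFrameSet  # local import avoids a cycle

    if truth.target_mask.shape != tuple(shape):
        raise ValidationError("ground-truth masks do not match the grid shape")
    if n_frames is None:
        n_frames = len(truth.c_t)
    if n_frames < 1:
        raise ValidationError("n_frames must be at least 1")
    if len(truth.c_t) < n_frames or len(truth.c_ref) < n_frames:
        raise ValidationError("fewer concentration samples than frames")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        vol = np.full(shape, truth.c_ref[f], dtype=float)
        vol[truth.target_mask] = truth.c_t[f]
        if noise_sd > 0:
            vol = vol + noise_sd * rng.standard_normal(shape)
        frames.append(Volume(data=vol))
    return PetFrameSet(
        frames=frames,
        durations_min=np.full(n_frames, frame_duration_min),
        injected_MBq=truth.injected_MBq,
        weight_kg=truth.weight_kg,
    )


def make_atlas(
    shape: tuple[int, int, int],
    seed: int = 0,
    n_channels: int = 32,
    max_sources: int = 200,
) -> dict:
    """RSN-like region masks, a GM probability map, and a toy leadfield.

    Four disjoint box regions stand in for the default-mode, salience,
    executive-control and sensorimotor networks.  GM probability is high
    inside the regions and noisy elsewhere.  The leadfield places scalp
    channels on a hemisphere above the grid and couples them to a
    subsampled cortical source grid with an inverse-square falloff.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 8:
        raise ValidationError("grid too small for 5 disjoint regions")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    h = max(2, min(shape) // 4)

    def box(x0, y0, z0):
        m = np.zeros(shape, dtype=bool)
        m[x0:x0 + h, y0:y0 + h, z0:z0 + h] = True
        return m

    masks = {
        "DMN": box(1, 1, 1),
        "SN": box(nx - h - 1, 1, 1),
        "ECN": box(1, ny - h - 1, 1),
        "SMN": box(nx - h - 1, ny - h - 1, nz - h - 1),
    }
    union = np.zeros(shape, dtype=bool)
    for m in masks.values():
        union |= m

    gm = 0.30 + 0.18 * rng.random(shape)
    gm[union] = 0.72 + 0.20 * rng.random(union.sum())
    gm = np.clip(gm, 0.0, 1.0)

    # leadfield: sources at GM-likely voxel centres, channels on a dome
    src_idx = np.argwhere(gm > 0.5)
    if len(src_idx) > max_sources:
        stride = int(np.ceil(len(src_idx) / max_sources))
        src_idx = src_idx[::stride]
    src_xyz = src_idx.astype(float) + 0.5
    disc = disc_layout(n_channels)
    radius = max(nx, ny) * 0.75
    centre = np.array([nx / 2, ny / 2, 0.0])
    ch_xyz = np.column_stack([
        centre[0] + disc[:, 0] * radius,
        centre[1] + disc[:, 1] * radius,
        nz + 2.0 + (1.0 - np.hypot(disc[:, 0], disc[:, 1]) ** 2) * 0.3 * radius,
    ])
    d2 = ((ch_xyz[:, None, :] - src_xyz[None, :, :]) ** 2).sum(axis=2)
    gain = 1.0 / (d2 + 4.0)

    return {
        "masks": {k: Volume(data=v) for k, v in masks.items()},
        "gm_prob": Volume(data=gm),
        "leadfield": Leadfield(gain=gain, source_coords=src_xyz),
    }
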