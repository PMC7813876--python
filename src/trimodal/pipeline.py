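"""End-to-end demo pipeline: simulate -> segment -> localise -> quantify ->
correlate, with a reproducibility manifest.

The pipeline is deterministic given the config's seed: every stage seed
is derived from it, all outputs are written as text-stable formats
(uncompressed NIfTI, JSON with sorted keys, TSV with fixed float
format), and the manifest records parameters, seeds, package versions
and a SHA-256 checksum of every output file.
"""
from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fmri import bandpass, degree_centrality, detrend_design, falff, nuisance_regress, reho
from .io import run_length_encode, write_bold, write_eeg, write_json, write_leadfield, write_volume
from .microstates import gfp, prepare_eeg, segment
from .pet import compute_bpnd, compute_suv, frame_average, gaussian_smooth
from .source import group_mask, slo_inverse, state_indicators, tess_glm
from .stats import correlate_fwer, dunn_stepdown, gm_correct, ks_normality, z_standardize
from .synth import (
    default_bold_truth,
    default_pet_truth,
    make_atlas,
    make_templates,
    simulate_bold,
    simulate_eeg,
    simulate_pet,
)
from .types import BoldSeries, ConfigError, Volume

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 7,
    "eeg": {"n_channels": 32, "duration_s": 40.0, "fs": 125.0, "snr": 4.0,
            "band": [2.0, 20.0]},
    "microstates": {"k": 4, "min_separation_ms": 10.0, "peaks_only": False},
    "tess": {"q": 0.01, "min_fraction": 0.5},
    "bold": {"shape": [12, 12, 12], "n_vols": 120, "tr_s": 2.2},
    "bandpass": {"low": 0.01, "high": 0.08},
    "fmri": {"falff_band": [0.01, 0.1], "dc_threshold": 0.25, "neighbourhood": 27},
    "pet": {"n_frames": 3, "noise_sd": 0.2, "smooth_fwhm_mm": 2.5},
    "atlas": {"gm_threshold": 0.5},
    "stats": {"n_perm": 2000, "alpha": 0.05, "smooth_fwhm_mm": 3.0},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unspecified values from the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Range-check every stage parameter; errors name ``stage.param``."""
    def require(cond: bool, name: str, msg: str) -> None:
        if not cond:
            raise ConfigError(f"{name}: {msg}")

    require(isinstance(cfg.get("seed"), int) and cfg["seed"] >= 0,
            "seed", "must be a non-negative integer")
    eeg = cfg["eeg"]
    require(eeg["n_channels"] >= 8, "eeg.n_channels", "must be at least 8")
    require(eeg["duration_s"] > 0, "eeg.duration_s", "must be positive")
    require(eeg["fs"] > 0, "eeg.fs", "must be positive")
    require(eeg["snr"] > 0, "eeg.snr", "must be positive")
    lo, hi = eeg["band"]
    require(0 < lo < hi < eeg["fs"] / 2, "eeg.band",
            f"({lo}, {hi}) must lie inside (0, Nyquist)")
    require(cfg["microstates"]["k"] >= 1, "microstates.k", "must be at least 1")
    require(0 < cfg["tess"]["q"] < 1, "tess.q", "must lie in (0, 1)")
    require(0 < cfg["tess"]["min_fraction"] <= 1, "tess.min_fraction",
            "must lie in (0, 1]")
    bold = cfg["bold"]
    require(bold["n_vols"] >= 32, "bold.n_vols", "must be at least 32")
    require(bold["tr_s"] > 0, "bold.tr_s", "must be positive")
    require(min(bold["shape"]) >= 10, "bold.shape", "needs at least 10 voxels per axis")
    nyq = 0.5 / bold["tr_s"]
    bp = cfg["bandpass"]
    require(bp["low"] >= 0, "bandpass.low", "must be non-negative")
    require(bp["low"] < bp["high"], "bandpass.low", "must be below bandpass.high")
    require(bp["high"] <= nyq, "bandpass.high",
            f"{bp['high']} Hz exceeds the Nyquist frequency {nyq:.4f} Hz")
    require(cfg["fmri"]["dc_threshold"] > 0, "fmri.dc_threshold", "must be positive")
    require(cfg["fmri"]["neighbourhood"] in (7, 19, 27), "fmri.neighbourhood",
            "must be 7, 19 or 27")
    require(cfg["pet"]["n_frames"] >= 1, "pet.n_frames", "must be at least 1")
    require(cfg["pet"]["smooth_fwhm_mm"] >= 0, "pet.smooth_fwhm_mm",
            "must be non-negative")
    require(cfg["stats"]["n_perm"] >= 100, "stats.n_perm", "must be at least 100")
    require(0 < cfg["stats"]["alpha"] < 1, "stats.alpha", "must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the full demo pipeline and write a manifest.

    Returns a dict with the in-memory results and the manifest path.
    """
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    written: list[Path] = []
    t0 = time.time()

    def stage(name: str):
        log.info("[%s] %.1fs", name, time.time() - t0)

    # --- synthetic inputs -------------------------------------------------
    stage("simulate")
    eeg_cfg = cfg["eeg"]
    templates, ms_truth = make_templates(eeg_cfg["n_channels"])
    rec, true_states = simulate_eeg(ms_truth, eeg_cfg["duration_s"],
                                    eeg_cfg["fs"], eeg_cfg["snr"], seed)
    shape = tuple(cfg["bold"]["shape"])
    atlas = make_atlas(shape, seed=seed + 1, n_channels=eeg_cfg["n_channels"])
    bold_truth = default_bold_truth(shape, cfg["bold"]["tr_s"])
    bold = simulate_bold(shape, cfg["bold"]["n_vols"], bold_truth, seed=seed + 2)
    pet_truth = default_pet_truth(shape, cfg["pet"]["n_frames"])
    pet_frames = simulate_pet(shape, pet_truth, cfg["pet"]["n_frames"],
                              seed=seed + 3, noise_sd=cfg["pet"]["noise_sd"])
    written.append(write_eeg(rec, out / "eeg.tsv"))
    written.append(write_bold(bold.data, bold.tr_s, out / "bold.nii"))
    written.append(write_leadfield(atlas["leadfield"], out / "leadfield.tsv"))

    # --- microstates ------------------------------------------------------
    stage("microstates")
    ms_cfg = cfg["microstates"]
    prep = prepare_eeg(rec, tuple(eeg_cfg["band"]), fs_out=eeg_cfg["fs"])
    seg = segment(prep, templates, k=ms_cfg["k"],
                  min_separation_ms=ms_cfg["min_separation_ms"],
                  peaks_only=ms_cfg["peaks_only"])
    written.append(write_json(
        {
            "maps": seg.maps.maps,
            "labels_rle": run_length_encode(seg.labels),
            "gev": seg.gev,
            "stats": seg.stats,
        },
        out / "segmentation.json",
    ))

    # --- source networks --------------------------------------------------
    stage("tess")
    inv = slo_inverse(prep, atlas["leadfield"])
    g = gfp(prep)
    present = [k for k in range(seg.maps.n_maps) if (seg.labels == k).any()]
    indicators = state_indicators(seg.labels, seg.maps.n_maps)[present]
    networks = tess_glm(inv, indicators, g, q=cfg["tess"]["q"])
    net_masks = {}
    for k, net in zip(present, networks):
        name = seg.maps.labels[k]
        net_masks[name] = group_mask([net.z_map], cfg["tess"]["min_fraction"])
    written.append(write_json(
        {seg.maps.labels[k]: {"n_significant": int(net.mask.sum()),
                              "z_map": net.z_map}
         for k, net in zip(present, networks)},
        out / "tess_networks.json",
    ))

    # --- PET quantification ----------------------------------------------
    stage("pet")
    avg = frame_average(pet_frames)
    avg_s = gaussian_smooth(avg, cfg["pet"]["smooth_fwhm_mm"])
    suv = compute_suv(avg_s, pet_frames.injected_MBq, pet_frames.weight_kg)
    bpnd = compute_bpnd(avg_s, Volume(data=pet_truth.reference_mask))
    written.append(write_volume(suv.volume, out / "suv.nii"))
    written.append(write_volume(bpnd.volume, out / "bpnd.nii"))

    # --- fMRI measures ----------------------------------------------------
    stage("fmri")
    detr = nuisance_regress(bold, detrend_design(bold.n_volumes))
    bp = bandpass(detr, cfg["bandpass"]["low"], cfg["bandpass"]["high"])
    reho_map = reho(bp, cfg["fmri"]["neighbourhood"])
    dc_map = degree_centrality(bp, cfg["fmri"]["dc_threshold"])
    falff_map = falff(detr, tuple(cfg["fmri"]["falff_band"]))
    for name, vol in [("reho", reho_map), ("dc", dc_map), ("falff", falff_map)]:
        written.append(write_volume(vol, out / f"{name}.nii"))

    # --- intermodal statistics -------------------------------------------
    stage("stats")
    gm_thr = cfg["atlas"]["gm_threshold"]
    whole = Volume(data=np.ones(shape, dtype=bool))
    gm_mask = gm_correct(whole, atlas["gm_prob"], gm_thr)
    z_maps = {}
    for name, vol in [("suv", suv.volume), ("bpnd", bpnd.volume),
                      ("reho", reho_map), ("dc", dc_map), ("falff", falff_map)]:
        zm = z_standardize(vol, gm_mask, source_quantity=name)
        zm.volume = gaussian_smooth(zm.volume, cfg["stats"]["smooth_fwhm_mm"])
        z_maps[name] = zm

    dmn_gm = gm_correct(atlas["masks"]["DMN"], atlas["gm_prob"], gm_thr)
    pairs_x = [z_maps["suv"], z_maps["suv"], z_maps["bpnd"], z_maps["suv"]]
    pairs_y = [z_maps["bpnd"], z_maps["reho"], z_maps["dc"], z_maps["falff"]]
    pair_regions = [dmn_gm, gm_mask, gm_mask, gm_mask]
    family = correlate_fwer(pairs_x, pairs_y, pair_regions,
                            n_perm=cfg["stats"]["n_perm"],
                            alpha=cfg["stats"]["alpha"], seed=seed + 4)

    region_groups, region_labels = [], []
    for name, m in atlas["masks"].items():
        mg = gm_correct(m, atlas["gm_prob"], gm_thr)
        vals = suv.volume.data[mg.data]
        if vals.size >= 2:
            region_groups.append(vals)
            region_labels.append(name)
    dunn = dunn_stepdown(region_groups, alpha=cfg["stats"]["alpha"],
                         labels=region_labels)
    ks = ks_normality(suv.volume.data[gm_mask.data])

    written.append(write_json(
        {
            "correlations": {
                "pairs": [["suv-bpnd", "suv-reho", "bpnd-dc", "suv-falff"][i]
                          for i in family.pair_names],
                "r": family.r_values,
                "p": family.p_values,
                "p_adjusted": family.p_adjusted,
                "n_voxels": family.n_voxels,
                "n_permutations": family.n_permutations,
                "seed": seed + 4,
            },
            "dunn": [
                {"pair": s.label, "z": s.effect, "p": s.p,
                 "p_adjusted": s.p_adjusted, "significant": s.significant}
                for s in dunn
            ],
            "ks_normality": {"D": ks.effect, "p": ks.p,
                             "reject_normality": ks.significant},
        },
        out / "stats.json",
    ))

    # --- manifest ---------------------------------------------------------
    stage("manifest")
    manifest = {
        "package": "trimodal",
        "version": __version__,
        "numpy": np.__version__,
        "config": cfg,
        "derived_seeds": {
            "eeg": seed, "atlas": seed + 1, "bold": seed + 2,
            "pet": seed + 3, "permutations": seed + 4,
        },
        "checksums": {p.name: _sha256(p) for p in sorted(written)},
    }
    manifest_path = write_json(manifest, out / "manifest.json")

    return {
        "segmentation": seg,
        "true_states": true_states,
        "networks": dict(zip([seg.maps.labels[k] for k in present], networks)),
        "network_masks": net_masks,
        "suv": suv,
        "bpnd": bpnd,
        "reho": reho_map,
        "dc": dc_map,
        "falff": falff_map,
        "correlations": family,
        "dunn": dunn,
        "ks": ks,
        "manifest_path": manifest_path,
        "manifest": manifest,
    }
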