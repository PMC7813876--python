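"""Readers and writers for the formats the pipeline touches.

Volumes and BOLD series are NIfTI-1 (uncompressed ``.nii`` so written
bytes are reproducible).  EEG is either a TSV sample matrix with a JSON
sidecar (sampling rate, labels, positions) or EDF: reading goes through
mne, writing uses a minimal 16-bit EDF writer implemented here.
Leadfields are a TSV gain matrix plus a JSON coordinate sidecar.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import EEGRecording, FormatError, Leadfield, ValidationError, Volume

_BOOL_TAG = "dtype=bool"


# ---------------------------------------------------------------- volumes

def write_volume(v: Volume, path: str | Path) -> Path:
    path = Path(path)
    data = v.data
    if data.dtype == bool:
        img = nib.Nifti1Image(data.astype(np.uint8), v.affine)
        img.header["descrip"] = _BOOL_TAG.encode()
    else:
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), v.affine)
    img.header.set_zooms(v.voxel_size_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, file has {data.ndim} dimensions "
            f"(shape {data.shape})"
        )
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="ignore")
    if _BOOL_TAG in descrip:
        data = data.astype(bool)
    zooms = img.header.get_zooms()[:3]
    offset = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data=data, voxel_size_mm=tuple(float(z) for z in zooms),
                  offset_mm=offset)


def write_bold(data4d: np.ndarray, tr_s: float, path: str | Path,
               voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float64), aff)
    img.header.set_zooms(tuple(voxel_size_mm) + (tr_s,))
    nib.save(img, str(path))
    return path


def read_bold(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D series, file has {data.ndim} dimensions"
        )
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return data, tr


# -------------------------------------------------------------------- EEG

def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """Write EEG as EDF (``.edf``) or TSV matrix + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "fs": rec.fs,
        "ch_names": list(rec.ch_names),
        "unit": "uV",
    }
    if rec.positions is not None:
        sidecar["positions"] = rec.positions.tolist()
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return path


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    positions = np.asarray(sidecar["positions"]) if "positions" in sidecar else None

    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads EEG in volts
        return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                            ch_names=list(raw.ch_names), positions=positions)

    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for matrix EEG: {sidecar_path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ch_names = sidecar.get("ch_names", list(df.columns))
    if len(ch_names) != df.shape[1]:
        raise FormatError(
            f"sidecar lists {len(ch_names)} channels, matrix has {df.shape[1]}"
        )
    return EEGRecording(data=df.to_numpy().T, fs=float(sidecar["fs"]),
                        ch_names=ch_names, positions=positions)


def _ascii_field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole signal.

    16-bit samples with per-channel physical scaling; fixed start
    date/time so identical recordings produce identical files.
    """
    data = rec.data
    n_ch, n_samp = data.shape
    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins < 1e-9
    pmaxs[flat] = pmins[flat] + 1.0
    dmin, dmax = -32768, 32767

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field("X X X X", 80),
        _ascii_field("Startdate 01-JAN-2000 X X X", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(str(256 * (1 + n_ch)), 8),
        _ascii_field("", 44),
        _ascii_field("1", 8),  # one data record
        _ascii_field(f"{n_samp / rec.fs:.6g}", 8),
        _ascii_field(str(n_ch), 4),
    ])
    fields = [
        [_ascii_field(name, 16) for name in rec.ch_names],
        [_ascii_field("", 80)] * n_ch,
        [_ascii_field("uV", 8)] * n_ch,
        [_ascii_field(f"{v:.6g}", 8) for v in pmins],
        [_ascii_field(f"{v:.6g}", 8) for v in pmaxs],
        [_ascii_field(str(dmin), 8)] * n_ch,
        [_ascii_field(str(dmax), 8)] * n_ch,
        [_ascii_field("", 80)] * n_ch,
        [_ascii_field(str(n_samp), 8)] * n_ch,
        [_ascii_field("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # EDF stores the header's printed physical range, so digitise
        # against the same rounded values the reader will see
        pmins_r = np.array([float(f"{v:.6g}") for v in pmins])
        pmaxs_r = np.array([float(f"{v:.6g}") for v in pmaxs])
        scale = (dmax - dmin) / (pmaxs_r - pmins_r)
        for c in range(n_ch):
            dig = np.round((data[c] - pmins_r[c]) * scale[c] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())


def edf_quantization_step(rec: EEGRecording) -> np.ndarray:
    """Per-channel quantisation step of the EDF encoding of ``rec``."""
    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    flat = pmaxs - pmins < 1e-9
    pmaxs[flat] = pmins[flat] + 1.0
    pmins = np.array([float(f"{v:.6g}") for v in pmins])
    pmaxs = np.array([float(f"{v:.6g}") for v in pmaxs])
    return (pmaxs - pmins) / (32767 - (-32768))


# -------------------------------------------------------------- leadfield

def write_leadfield(lf: Leadfield, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, lf.gain, delimiter="\t", fmt="%.12g")
    path.with_suffix(".json").write_text(
        json.dumps({"source_coords": lf.source_coords.tolist()}, sort_keys=True)
    )
    return path


def read_leadfield(path: str | Path) -> Leadfield:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON coordinate sidecar: {sidecar}")
    gain = np.loadtxt(path, delimiter="\t", ndmin=2)
    coords = np.asarray(json.loads(sidecar.read_text())["source_coords"])
    return Leadfield(gain=gain, source_coords=coords)


# ------------------------------------------------------------ misc tables

def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))
    return path


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def run_length_encode(labels: np.ndarray) -> list[list[int]]:
    """[value, count] pairs for a label sequence (compact JSON form)."""
    labels = np.asarray(labels)
    out = []
    if labels.size == 0:
        return out
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    for s, e in zip(starts, ends):
        out.append([int(labels[s]), int(e - s)])
    return out


def run_length_decode(pairs: list[list[int]]) -> np.ndarray:
    if not pairs:
        return np.empty(0, dtype=int)
    return np.concatenate([np.full(c, v, dtype=int) for v, c in pairs])
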