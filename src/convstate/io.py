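"""File formats: BIDS-style events TSV, trial tables, NIfTI volumes and
masks, results JSON, and run manifests.

Events use the BIDS events dialect (columns onset, duration, trial_type,
run; onsets in seconds from run start); the trial identity and interval
are packed into trial_type as ``<trial_id>/<interval>`` and unpacked on
read, so write -> read round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_trial_table",
    "read_trial_table",
    "read_nifti",
    "write_nifti",
    "bold_matrix_from_nifti",
    "mask_indices_from_nifti",
    "write_results_json",
    "sha256_file",
    "write_manifest",
]

_FLOAT_FMT = "%.10g"


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "onset": events["onset"],
            "duration": events["duration"],
            "trial_type": events["trial_id"].astype(str) + "/" + events["interval"].astype(str),
            "run": events["run"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV, validating each row.

    Malformed rows (negative/zero duration, negative onset, missing
    fields) raise with the 1-based data line number named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ("onset", "duration", "trial_type", "run")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if pd.isna(row["onset"]) or row["onset"] < 0:
            raise ValueError(f"{path}: line {line}: invalid onset {row['onset']!r}")
        if pd.isna(row["duration"]) or row["duration"] <= 0:
            raise ValueError(f"{path}: line {line}: invalid duration {row['duration']!r}")
        if not isinstance(row["trial_type"], str) or "/" not in row["trial_type"]:
            raise ValueError(
                f"{path}: line {line}: trial_type must be '<trial_id>/<interval>', "
                f"got {row['trial_type']!r}"
            )
    parts = df["trial_type"].str.rsplit("/", n=1, expand=True)
    out = pd.DataFrame(
        {
            "onset": df["onset"].astype(float),
            "duration": df["duration"].astype(float),
            "trial_id": parts[0],
            "interval": parts[1],
            "run": df["run"].astype(int),
        }
    )
    return out.sort_values("onset", kind="stable").reset_index(drop=True)


def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def write_nifti(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    return path


def bold_matrix_from_nifti(
    bold_path: str | Path, mask: np.ndarray | None = None
) -> np.ndarray:
    """Flatten a 4-D BOLD NIfTI into (timepoints x voxels), optionally
    restricted to a boolean mask over the spatial grid."""
    data, _ = read_nifti(bold_path)
    if data.ndim != 4:
        raise ValueError(f"{bold_path}: expected 4-D BOLD, got shape {data.shape}")
    flat = data.reshape(-1, data.shape[3]).T  # time x voxels
    if mask is not None:
        mask = np.asarray(mask).reshape(-1).astype(bool)
        if mask.size != flat.shape[1]:
            raise ValueError("mask size does not match the spatial grid")
        flat = flat[:, mask]
    return np.asarray(flat, dtype=float)


def mask_indices_from_nifti(path: str | Path) -> np.ndarray:
    """Voxel indices (into the flattened grid) of a binary ROI mask."""
    data, _ = read_nifti(path)
    flat = np.asarray(data).reshape(-1)
    idx = np.flatnonzero(flat > 0)
    if idx.size == 0:
        raise ValueError(f"{path}: empty ROI mask")
    return idx


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results_json(results: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path, config_dict: dict, seed: int, files: list[str | Path]
) -> Path:
    """Manifest tying every output file to the config, seed and package
    version via content checksums.  Deliberately timestamp-free so rerun
    manifests are byte-identical."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "package": "convstate",
        "version": __version__,
        "seed": seed,
        "config": _jsonify(config_dict),
        "files": {
            str(Path(f).relative_to(outdir)): sha256_file(f) for f in sorted(map(str, files))
        },
    }
    return write_results_json(manifest, outdir / "manifest.json")
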