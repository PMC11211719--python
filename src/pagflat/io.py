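"""Readers/writers for the pipeline's on-disk formats.

BOLD volumes and masks are NIfTI-1 (via nibabel); events, motion,
physiological traces, coordinates and rank tables are tab-separated
tables with BIDS-like columns; ground truth and mask provenance travel
as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray,
               provenance: dict | None = None) -> Path:
    path = write_nifti(path, mask.astype(np.uint8), affine)
    if provenance is not None:
        sidecar = path.with_suffix("").with_suffix(".json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=str))
    return path


def write_tsv(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_physio_tsv(path: str | Path, samples: np.ndarray,
                     fs_hz: float = 1000.0) -> Path:
    t = np.arange(len(samples)) / fs_hz
    return write_tsv(path, pd.DataFrame({"time": t, "value": samples}))


def read_physio_tsv(path: str | Path) -> tuple[np.ndarray, float]:
    df = read_tsv(path)
    dt = float(np.median(np.diff(df["time"])))
    return df["value"].to_numpy(), 1.0 / dt


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
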