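"""File formats: NIfTI volumes, CSV tables, HDF5 curve banks, JSON sidecars.

Every artifact written by the pipeline carries a JSON sidecar recording
the configuration hash and seeds, so reruns are attributable and
deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .cnn import CurvePair
from .curves import ConcentrationCurve
from .errors import InputError
from .phantom import CTPStudy

__all__ = [
    "config_to_dict",
    "config_hash",
    "save_sidecar",
    "load_sidecar",
    "save_study",
    "load_study",
    "save_map",
    "load_map",
    "save_mask",
    "volumes_to_csv",
    "volumes_from_csv",
    "save_pairs",
    "load_pairs",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_to_dict(config) -> dict:
    """Dataclass (possibly nested) to a plain JSON-serializable dict."""
    return _jsonable(config)


def config_hash(config) -> str:
    """Short stable hash of a configuration object."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def load_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_study(study: CTPStudy, prefix, extra: dict | None = None) -> None:
    """Write a study as <prefix>.nii.gz + masks + <prefix>.json sidecar."""
    prefix = Path(prefix)
    aff = _affine(study.spacing)
    nib.save(nib.Nifti1Image(study.volume.astype(np.float32), aff), f"{prefix}.nii.gz")
    nib.save(
        nib.Nifti1Image(study.brain_mask.astype(np.uint8), aff),
        f"{prefix}_brain_mask.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(study.artery_mask.astype(np.uint8), aff),
        f"{prefix}_artery_mask.nii.gz",
    )
    sidecar = {
        "times_s": study.times,
        "spacing_mm": study.spacing,
        "midline_axis": study.midline_axis,
    }
    sidecar.update(extra or {})
    save_sidecar(f"{prefix}.json", sidecar)


def load_study(prefix) -> CTPStudy:
    prefix = Path(prefix)
    img = nib.load(f"{prefix}.nii.gz")
    meta = load_sidecar(f"{prefix}.json")
    brain = nib.load(f"{prefix}_brain_mask.nii.gz").get_fdata().astype(bool)
    artery = nib.load(f"{prefix}_artery_mask.nii.gz").get_fdata().astype(bool)
    return CTPStudy(
        volume=np.asarray(img.dataobj, dtype=float),
        times=np.asarray(meta["times_s"], dtype=float),
        spacing=tuple(meta["spacing_mm"]),
        brain_mask=brain,
        artery_mask=artery,
        midline_axis=int(meta.get("midline_axis", 0)),
    )


def save_map(arr: np.ndarray, spacing, path) -> None:
    nib.save(nib.Nifti1Image(arr.astype(np.float32), _affine(spacing)), str(path))


def load_map(path) -> np.ndarray:
    return nib.load(str(path)).get_fdata().astype(float)


def save_mask(mask: np.ndarray, spacing, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), str(path))


def volumes_to_csv(volumes_ml: dict[str, float], path) -> None:
    """One row per threshold label, volumes to 1 decimal mL."""
    df = pd.DataFrame(
        {"threshold": list(volumes_ml), "volume_mL": [round(v, 1) for v in volumes_ml.values()]}
    )
    df.to_csv(path, index=False)


def volumes_from_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["threshold"], df["volume_mL"].astype(float)))


def save_pairs(pairs: list[CurvePair], path, manifest: dict | None = None) -> None:
    """HDF5 curve bank: groups inputs/labels plus a JSON manifest attribute."""
    if not pairs:
        raise InputError("no pairs to save")
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=np.stack([p.input_values for p in pairs]))
        f.create_dataset("labels", data=np.stack([p.label_values for p in pairs]))
        f.create_dataset("times", data=pairs[0].times)
        f.create_dataset("normalization", data=np.array([p.normalization for p in pairs]))
        f.attrs["manifest"] = json.dumps(_jsonable(manifest or {}), sort_keys=True)


def load_pairs(path) -> tuple[list[CurvePair], dict]:
    with h5py.File(path, "r") as f:
        x = f["inputs"][...]
        y = f["labels"][...]
        t = f["times"][...]
        norm = f["normalization"][...]
        manifest = json.loads(f.attrs["manifest"])
    pairs = [
        CurvePair(input_values=x[i], label_values=y[i], times=t, normalization=float(norm[i]))
        for i in range(x.shape[0])
    ]
    return pairs, manifest
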