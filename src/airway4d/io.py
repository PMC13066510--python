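"""NIfTI readers/writers, landmark sidecars, and dataset manifests.

Label volumes are uint8 NIfTI-1 with values validated against {0, 1, 2};
probability maps are float32 with the three class channels in the fourth
dimension; the affine encodes the voxel spacing.  Landmarks are JSON
sidecars ``{participant, position, landmarks: {name: z_mm}}``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import LabelVolume, ProbabilityMap, VolumeValidationError


def _affine(spacing_mm) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return (float(z[0]), float(z[1]), float(z[2]))


def write_label_volume(path: str | Path, volume: LabelVolume) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), _affine(volume.spacing_mm))
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Load and validate a label volume; unexpected values raise."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    try:
        return LabelVolume(data.astype(np.uint8, casting="unsafe")
                           if data.dtype != np.uint8 else data,
                           _spacing_from(img))
    except VolumeValidationError as exc:
        raise VolumeValidationError(f"{path}: {exc}") from exc


def write_intensity_volume(path: str | Path, intensity: np.ndarray,
                           spacing_mm) -> None:
    nib.save(nib.Nifti1Image(np.asarray(intensity, dtype=np.float32),
                             _affine(spacing_mm)), str(path))


def read_intensity_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), _spacing_from(img)


def write_probability_map(path: str | Path, pm: ProbabilityMap) -> None:
    nib.save(nib.Nifti1Image(pm.probs.astype(np.float32), _affine(pm.spacing_mm)),
             str(path))


def read_probability_map(path: str | Path) -> ProbabilityMap:
    img = nib.load(str(path))
    return ProbabilityMap(np.asarray(img.dataobj, dtype=np.float32), _spacing_from(img))


def write_landmarks(path: str | Path, participant: str, position: str,
                    landmarks: dict[str, float]) -> None:
    Path(path).write_text(json.dumps(
        {"participant": participant, "position": position,
         "landmarks": {k: float(v) for k, v in landmarks.items()}},
        indent=1, sort_keys=True))


def read_landmarks(path: str | Path) -> dict[str, float]:
    payload = json.loads(Path(path).read_text())
    return {k: float(v) for k, v in payload["landmarks"].items()}


def read_manifest(dataset_root: str | Path) -> dict:
    root = Path(dataset_root)
    manifest = json.loads((root / "manifest.json").read_text())
    missing = [e["label"] for e in manifest["images"]
               if not (root / e["label"]).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files, e.g. {missing[:3]}")
    return manifest


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping (re-serialization invariant)."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
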