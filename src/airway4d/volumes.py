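"""Core in-memory containers for segmentation volumes.

A :class:`LabelVolume` is a 3-D integer grid over the airway ROI with three
classes (0 = background, 1 = upper airway, 2 = epiglottic airway) and an
anisotropic voxel spacing.  A :class:`ProbabilityMap` carries the per-voxel
3-class simplex emitted by a segmentation backend.  Axis 2 of every grid is
the superior->inferior direction; all physical coordinates are millimetres
measured from the superior grid face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_LABELS = (0, 1, 2)
LABEL_BACKGROUND, LABEL_AIRWAY, LABEL_EPIGLOTTIC = VALID_LABELS

#: channel order of every probability map
PROB_CHANNELS = ("background", "upper_airway", "epiglottic_airway")

SIMPLEX_ATOL = 1e-6


class VolumeValidationError(ValueError):
    """Raised when a grid violates the label or simplex contract."""


@dataclass(frozen=True)
class LabelVolume:
    """3-D class grid with voxel spacing in millimetres.

    Parameters
    ----------
    voxels
        Integer array of shape (nx, ny, nz) with values in {0, 1, 2}.
    spacing_mm
        Voxel edge lengths (dx, dy, dz) in mm; axis 2 is superior->inferior.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 2.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise VolumeValidationError(f"label grid must be 3-D, got shape {vox.shape}")
        bad = np.setdiff1d(np.unique(vox), VALID_LABELS)
        if bad.size:
            raise VolumeValidationError(f"unexpected label values {bad.tolist()}; allowed {VALID_LABELS}")
        if any(s <= 0 for s in self.spacing_mm):
            raise VolumeValidationError(f"voxel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def in_plane_area_mm2(self) -> float:
        dx, dy, _ = self.spacing_mm
        return dx * dy

    def slice_z_mm(self, z_index: int) -> float:
        """Physical z coordinate (mm) of a slice centre."""
        return (z_index + 0.5) * self.spacing_mm[2]

    def z_index(self, z_mm: float) -> int:
        """Slice index whose centre is nearest to ``z_mm`` (clipped to grid)."""
        k = int(round(z_mm / self.spacing_mm[2] - 0.5))
        return int(np.clip(k, 0, self.shape[2] - 1))


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel 3-class probabilities, channels last.

    ``probs`` has shape (nx, ny, nz, 3) with channels ordered
    (background, upper airway, epiglottic airway).  Every voxel must lie on
    the probability simplex to within ``SIMPLEX_ATOL``.
    """

    probs: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 2.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float32)
        if p.ndim != 4 or p.shape[-1] != 3:
            raise VolumeValidationError(f"probability map must have shape (nx,ny,nz,3), got {p.shape}")
        validate_simplex(p)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]

    def argmax_labels(self) -> LabelVolume:
        """Hard segmentation: assign each voxel its most probable class."""
        return LabelVolume(np.argmax(self.probs, axis=-1).astype(np.uint8), self.spacing_mm)


def validate_simplex(p: np.ndarray, atol: float = SIMPLEX_ATOL) -> None:
    """Check channels-last probabilities: nonnegative and summing to one."""
    p = np.asarray(p)
    if np.min(p) < -atol:
        raise VolumeValidationError(f"negative probability {np.min(p)}")
    sums = p.sum(axis=-1)
    err = float(np.max(np.abs(sums - 1.0)))
    if err > atol:
        raise VolumeValidationError(f"probabilities deviate from simplex by {err:g} (> {atol:g})")


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """One-hot encode a label grid, channels last, float32."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    for c in range(n_classes):
        out[..., c] = labels == c
    return out
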