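"""Shared helpers: desk-scale cohort configurations and phantom builders."""

from __future__ import annotations

import numpy as np

from airway4d.cohort import DEFAULT_EFFECTS, CohortConfig
from airway4d.volumes import LabelVolume


def tiny_config(seed: int = 0, **overrides) -> CohortConfig:
    """A 10-participant, 2-frame cohort on a small grid for fast campaigns."""
    effects = {m: dict(t) for m, t in DEFAULT_EFFECTS.items()}
    effects["total_length_cm"].update(intercept=4.0, male=0.5, symptomatic=0.4,
                                      open=0.3, participant_sd=0.25,
                                      position_sd=0.08)
    kwargs = dict(
        n_participants=10, n_frames_per_position=2,
        grid_shape=(32, 32, 48), sex_counts=(5, 5), n_osa_excluded=0,
        symptomatic_fraction=0.5, effect_table=effects, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def cylinder_volume(radius_mm: float = 8.0, shape=(64, 64, 40),
                    spacing=(1.25, 1.25, 2.0), label: int = 1,
                    radius_by_slice=None) -> LabelVolume:
    """Analytic cylinder phantom along the slice axis (voxel-centre sampling).

    ``radius_by_slice`` (mm per slice) overrides the constant radius to build
    notched tubes.
    """
    nx, ny, nz = shape
    dx, dy, dz = spacing
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    dist2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    r = np.full(nz, radius_mm, dtype=float) if radius_by_slice is None \
        else np.asarray(radius_by_slice, dtype=float)
    vox = (dist2[:, :, None] <= (r ** 2)[None, None, :]).astype(np.uint8) * label
    return LabelVolume(vox, spacing)
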