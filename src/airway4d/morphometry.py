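"""Frame-wise airway morphometry and 20-frame temporal summaries.

All measurements are taken on axial grid slices of a label volume:

* CSA of a slice = (number of airway voxels) x in-plane voxel area;
* level-specific CSA (retropalatal / retroglossal) = minimum slice CSA
  within the landmark window;
* lengths are slice-axis distances between landmark planes (the pharynx is
  near-vertical, so no centerline is traced);
* volume = airway voxel count x voxel volume;
* temporal variability = coefficient of variation (CV = SD/mean, sample SD)
  of a metric over the frames of one breathing series.

"Total airway" is labels {1, 2}; "epiglottic airway" is label {2} alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np

from .volumes import LabelVolume

TOTAL_LABELS = frozenset({1, 2})
EPIGLOTTIC_LABELS = frozenset({2})

#: metric column names shared by the per-frame and summary tables
FRAME_METRIC_NAMES = ("total_length_cm", "epiglottic_length_cm",
                      "total_volume_cm3", "epiglottic_volume_cm3",
                      "mean_csa_cm2", "retropalatal_csa_cm2", "retroglossal_csa_cm2")


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class LandmarkWindows:
    """Axial landmark planes and level windows, in mm from the superior face."""

    retropalatal: tuple[float, float]
    retroglossal: tuple[float, float]
    soft_palate_z_mm: float
    epiglottic_tip_z_mm: float | None = None
    epiglottic_base_z_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("retropalatal", "retroglossal"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise MorphometryError(f"{name} window must satisfy start < end, got ({lo}, {hi})")

    @classmethod
    def from_landmarks(cls, landmarks: Mapping[str, float]) -> "LandmarkWindows":
        """Build windows from a landmark sidecar.

        Retropalatal space = soft palate..velum tip; retroglossal space =
        velum tip..epiglottic tip.
        """
        return cls(
            retropalatal=(landmarks["soft_palate_sup"], landmarks["velum_tip"]),
            retroglossal=(landmarks["velum_tip"], landmarks["epiglottic_tip"]),
            soft_palate_z_mm=landmarks["soft_palate_sup"],
            epiglottic_tip_z_mm=landmarks.get("epiglottic_tip"),
            epiglottic_base_z_mm=landmarks.get("epiglottic_base"),
        )


@dataclass(frozen=True)
class FrameMetrics:
    """All seven morphometric measurements of a single frame."""

    total_length_cm: float
    epiglottic_length_cm: float
    total_volume_cm3: float
    epiglottic_volume_cm3: float
    mean_csa_cm2: float
    retropalatal_csa_cm2: float
    retroglossal_csa_cm2: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "flags"}


def slice_csa(volume: LabelVolume, z_index: int,
              labels: frozenset[int] | set[int] = TOTAL_LABELS) -> float:
    """Cross-sectional area (cm^2) of the given label set on one axial slice."""
    if not 0 <= z_index < volume.shape[2]:
        raise MorphometryError(f"slice index {z_index} out of range [0, {volume.shape[2]})")
    sl = volume.voxels[:, :, z_index]
    count = int(np.isin(sl, list(labels)).sum())
    return count * volume.in_plane_area_mm2 / 100.0


def _slice_counts(volume: LabelVolume, labels) -> np.ndarray:
    """Airway voxel count per axial slice (vectorized over z)."""
    lab = frozenset(labels)
    if lab == TOTAL_LABELS:
        return np.count_nonzero(volume.voxels, axis=(0, 1))
    if lab == EPIGLOTTIC_LABELS:
        return np.count_nonzero(volume.voxels == 2, axis=(0, 1))
    return np.isin(volume.voxels, list(labels)).sum(axis=(0, 1))


def _window_indices(volume: LabelVolume, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    z_mm = (np.arange(volume.shape[2]) + 0.5) * volume.spacing_mm[2]
    return np.flatnonzero((z_mm >= lo) & (z_mm <= hi))


def min_csa_window(volume: LabelVolume, window: tuple[float, float],
                   labels: frozenset[int] | set[int] = TOTAL_LABELS
                   ) -> tuple[float, bool]:
    """Minimum slice CSA (cm^2) within a z window.

    Returns ``(csa, zero_slice_flag)``; slices inside the window without any
    airway voxel count as area 0 and raise the flag.
    """
    idx = _window_indices(volume, window)
    if idx.size == 0:
        raise MorphometryError(f"window {window} contains no slice centres")
    counts = _slice_counts(volume, labels)[idx]
    area = counts.min() * volume.in_plane_area_mm2 / 100.0
    return float(area), bool(counts.min() == 0)


def lengths(volume: LabelVolume, landmarks: LandmarkWindows | None
            ) -> tuple[float, float]:
    """(total, epiglottic) airway lengths in cm.

    Total length = soft palate to epiglottic base along the slice axis;
    epiglottic length = epiglottic tip to base.  When tip/base landmarks are
    missing, the axial extent of label 2 is used as a fallback; a missing
    soft-palate landmark cannot be recovered.
    """
    lm = landmarks
    ep_extent = None
    if lm is None or lm.epiglottic_tip_z_mm is None or lm.epiglottic_base_z_mm is None:
        z2 = np.flatnonzero(_slice_counts(volume, EPIGLOTTIC_LABELS) > 0)
        dz = volume.spacing_mm[2]
        ep_extent = ((z2[0] + 0.5) * dz, (z2[-1] + 0.5) * dz) if z2.size else (0.0, 0.0)
    if lm is None or lm.soft_palate_z_mm is None:
        raise MorphometryError("soft palate landmark is required for total airway length")
    base = lm.epiglottic_base_z_mm if lm.epiglottic_base_z_mm is not None else ep_extent[1]
    tip = lm.epiglottic_tip_z_mm if lm.epiglottic_tip_z_mm is not None else ep_extent[0]
    total = abs(base - lm.soft_palate_z_mm) / 10.0
    epiglottic = abs(base - tip) / 10.0
    return float(total), float(epiglottic)


def volumes(volume: LabelVolume) -> tuple[float, float]:
    """(total, epiglottic) airway volumes in cm^3 from voxel counts."""
    vv = volume.voxel_volume_mm3 / 1000.0
    counts = np.bincount(volume.voxels.ravel(), minlength=3)
    total = float((counts[1] + counts[2]) * vv)
    epiglottic = float(counts[2] * vv)
    return total, epiglottic


def frame_metrics(volume: LabelVolume, landmarks: LandmarkWindows) -> FrameMetrics:
    """Assemble all seven per-frame metrics.

    Mean CSA averages slice CSAs between the soft palate and the epiglottic
    base over slices containing at least one airway voxel.
    """
    flags: list[str] = []
    total_len, ep_len = lengths(volume, landmarks)
    counts_total = _slice_counts(volume, TOTAL_LABELS)
    counts_ep = _slice_counts(volume, EPIGLOTTIC_LABELS)
    vv = volume.voxel_volume_mm3 / 1000.0
    total_vol = float(counts_total.sum() * vv)
    ep_vol = float(counts_ep.sum() * vv)

    def _window_min(window: tuple[float, float]) -> tuple[float, bool]:
        idx = _window_indices(volume, window)
        if idx.size == 0:
            raise MorphometryError(f"window {window} contains no slice centres")
        m = counts_total[idx].min()
        return float(m * volume.in_plane_area_mm2 / 100.0), bool(m == 0)

    rp, rp_zero = _window_min(landmarks.retropalatal)
    rg, rg_zero = _window_min(landmarks.retroglossal)
    if rp_zero:
        flags.append("retropalatal_zero_slice")
    if rg_zero:
        flags.append("retroglossal_zero_slice")

    base = landmarks.epiglottic_base_z_mm
    if base is None:
        z2 = np.flatnonzero(counts_ep > 0)
        base = (z2[-1] + 0.5) * volume.spacing_mm[2] if z2.size else landmarks.soft_palate_z_mm
    span = _window_indices(volume, (landmarks.soft_palate_z_mm, base))
    counts = counts_total[span] if span.size else np.array([])
    counts = counts[counts > 0]
    if counts.size:
        mean_csa = float(counts.mean() * volume.in_plane_area_mm2 / 100.0)
    else:
        mean_csa = 0.0
        flags.append("no_airway_in_span")
    return FrameMetrics(
        total_length_cm=total_len, epiglottic_length_cm=ep_len,
        total_volume_cm3=total_vol, epiglottic_volume_cm3=ep_vol,
        mean_csa_cm2=mean_csa, retropalatal_csa_cm2=rp, retroglossal_csa_cm2=rg,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class SeriesSummary:
    """Per-metric mean and coefficient of variation over one breathing series."""

    mean: dict[str, float]
    cv: dict[str, float]
    n_frames: int
    flags: tuple[str, ...] = ()


def series_summary(frames: Sequence[FrameMetrics]) -> SeriesSummary:
    """Summarize a series of frames: mean and CV (sample SD / mean) per metric.

    A metric whose mean is zero has an undefined CV, reported as NaN with a
    flag.
    """
    if len(frames) < 2:
        raise MorphometryError("series summaries require at least two frames")
    means: dict[str, float] = {}
    cvs: dict[str, float] = {}
    flags: list[str] = []
    for name in FRAME_METRIC_NAMES:
        values = np.array([getattr(f, name) for f in frames], dtype=float)
        mu = float(values.mean())
        means[name] = mu
        if mu == 0.0:
            cvs[name] = math.nan
            flags.append(f"cv_undefined:{name}")
        else:
            cvs[name] = float(values.std(ddof=1) / mu)
    return SeriesSummary(mean=means, cv=cvs, n_frames=len(frames), flags=tuple(flags))


# --------------------------------------------------------------------------
# cohort-level driver
# --------------------------------------------------------------------------

def cohort_metrics_table(cohort, participants: Sequence[str] | None = None):
    """Per-participant/position summary table for a synthetic cohort.

    One row per (participant, position) with ``<metric>`` mean columns and
    ``<metric>_cv`` columns, plus the demographics needed downstream.
    Frames are rasterized lazily and never kept in memory.
    """
    import pandas as pd

    rows = []
    ids = participants if participants is not None else cohort.participant_ids
    for pid in ids:
        profile = cohort.profile(pid)
        for position in cohort.config.positions:
            lm = LandmarkWindows.from_landmarks(cohort.landmarks(pid, position))
            per_frame = [frame_metrics(label, lm)
                         for label, _ in cohort.frames(pid, position, with_intensity=False)]
            summary = series_summary(per_frame)
            row = {"participant": pid, "position": position,
                   "sex": profile.sex, "symptomatic": profile.symptomatic,
                   "osa_excluded": profile.osa_excluded,
                   "age": profile.age, "bmi": profile.bmi,
                   "height": profile.height, "weight": profile.weight,
                   "neck_circumference": profile.neck_circumference,
                   "delta_d": profile.delta_d, "n_frames": summary.n_frames}
            row.update(summary.mean)
            row.update({f"{k}_cv": v for k, v in summary.cv.items()})
            rows.append(row)
    return pd.DataFrame(rows)
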