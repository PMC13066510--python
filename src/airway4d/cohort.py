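"""Synthetic 4D upper-airway cohort generator.

Emulates a dynamic-MRI study cohort at desk scale: per-participant
demographics with the sex/symptom category structure of the study
population, a tubular airway phantom per participant and mouth position
(closed / open) whose landmark span, level-specific cross-sectional areas
and volume carry planted group effects, sinusoidal respiratory modulation
of the lumen radius that produces controllable frame-to-frame variability,
and label/intensity/probability volumes on the acquisition grid
(1.25 x 1.25 x 2.0 mm voxels, 20 frames per position).

The planted effect magnitudes are the cohort-level differences the
downstream statistics are expected to recover: mouth opening lengthens the
airway and narrows the retropalatal level, male participants have larger
airways, symptomatic participants have longer airways and a narrower, more
variable retropalatal level.  Respiratory amplitudes are set by inverting
the closed-form relation CV ~ 2a * sqrt(n/(2(n-1))) between a relative
radius amplitude ``a`` and the coefficient of variation of a sinusoidally
modulated cross-section sampled over n frames.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from ._rng import substream
from .volumes import LabelVolume, ProbabilityMap, one_hot

POSITIONS = ("closed", "open")
LANDMARK_NAMES = ("hard_palate", "soft_palate_sup", "velum_tip",
                  "epiglottic_tip", "epiglottic_base")

SNORE_LEVELS = ("never", "occasionally", "consistently")


class ConfigurationError(ValueError):
    """Invalid or infeasible cohort configuration."""


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be rasterized onto the requested grid."""


# --------------------------------------------------------------------------
# planted cohort structure (study defaults)
# --------------------------------------------------------------------------

#: additive effect models, natural units.  Keys per metric:
#: intercept, male, symptomatic, open, open_symptomatic (optional),
#: participant_sd (between-participant), position_sd (within-participant,
#: per mouth position), floor (hard lower clamp).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "total_length_cm": {
        "intercept": 6.59, "male": 1.36, "symptomatic": 0.92, "open": 0.51,
        "participant_sd": 0.50, "position_sd": 0.15,
    },
    "epiglottic_length_cm": {
        "intercept": 1.12, "male": 0.35, "symptomatic": 0.12, "open": 0.01,
        "participant_sd": 0.12, "position_sd": 0.04, "floor": 0.4,
    },
    "retropalatal_csa_cm2": {
        "intercept": 1.89, "male": 0.20, "symptomatic": -0.28, "open": -0.29,
        "open_symptomatic": -0.15,
        "participant_sd": 0.45, "position_sd": 0.12, "floor": 0.35,
    },
    "retroglossal_csa_cm2": {
        "intercept": 3.38, "male": 0.74, "symptomatic": 0.0, "open": -0.06,
        "participant_sd": 0.55, "position_sd": 0.15, "floor": 1.0,
    },
    # multiplicative scale on the non-landmark area control points; drives
    # mean CSA and total volume (male airways are larger throughout)
    "area_scale": {
        "intercept": 1.0, "male": 0.17, "symptomatic": 0.0, "open": 0.0,
        "participant_sd": 0.12, "position_sd": 0.03, "floor": 0.5,
    },
}

#: relative radius amplitudes a per (region, position); derived from the
#: target CVs via a = CV / (2 * sqrt(20/(2*19))) = CV / 1.4504
DEFAULT_AMPLITUDES: dict[tuple[str, str], float] = {
    ("global", "closed"): 0.0207, ("global", "open"): 0.0276,
    ("retropalatal", "closed"): 0.0414, ("retropalatal", "open"): 0.0827,
    ("retroglossal", "closed"): 0.0276, ("retroglossal", "open"): 0.0483,
    ("epiglottic", "closed"): 0.0414, ("epiglottic", "open"): 0.0552,
}

#: respiratory phase lag per region (radians): the luminal wave propagates
#: cranio-caudally, so regional fluctuations are not in phase and partially
#: cancel in whole-airway volume and mean-CSA variability, as observed
#: in vivo (regional CVs exceed the whole-airway CV)
REGION_PHASE_LAG: dict[str, float] = {
    "global": 0.0, "retropalatal": 0.0,
    "retroglossal": np.pi / 3.0, "epiglottic": 2.0 * np.pi / 3.0,
}

#: ventral chord offset of the epiglottic sub-label, as a fraction of the
#: local lumen radius: label 2 covers the lumen ventral to
#: y < centre + 0.3 r, ~69% of the local cross-section
EPIGLOTTIC_VENTRAL_OFFSET = 0.3

#: relative area retained at the ROI edges (the lumen tapers over the 1 cm
#: margins above the hard palate and below the epiglottic base)
_EDGE_TAPER = 0.15

#: per-sex (male, female) category counts of the analyzed cohort:
#: snore and gasp frequencies, (never, occasionally, consistently)
DEFAULT_SNORE_BY_SEX = {"male": (13, 5, 10), "female": (38, 11, 7)}
DEFAULT_GASP_BY_SEX = {"male": (20, 5, 3), "female": (54, 1, 1)}

#: per-sex truncated-normal parameters: (mean, sd, lo, hi)
DEFAULT_CONTINUOUS = {
    "age": {"male": (39.18, 17.52, 18.0, 80.0), "female": (42.32, 14.02, 18.0, 80.0)},
    "weight": {"male": (70.36, 9.98, 40.0, 130.0), "female": (59.29, 10.63, 35.0, 120.0)},
    "height": {"male": (172.38, 4.89, 150.0, 200.0), "female": (158.81, 5.86, 140.0, 185.0)},
    "neck_circumference": {"male": (36.79, 3.13, 28.0, 50.0), "female": (32.93, 2.79, 25.0, 45.0)},
    "sacs": {"male": (5.46, 7.30, 0.0, 40.0), "female": (1.18, 1.89, 0.0, 40.0)},
}
DEFAULT_DELTA_D = (16.77, 3.73, 5.0, 30.0)  # mouth-opening extent, mm


def zeroed_effects() -> dict[str, dict[str, float]]:
    """Effect table with every group effect and noise term set to zero."""
    out = {}
    for metric, terms in DEFAULT_EFFECTS.items():
        z = {k: 0.0 for k in terms}
        z["intercept"] = terms["intercept"]
        if "floor" in terms:
            z["floor"] = terms["floor"]
        out[metric] = z
    return out


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    The defaults reproduce the study conditions: 90 participants (6 of whom
    are flagged as OSA-excluded and dropped from the statistical cohort),
    20 frames per mouth position, the acquisition voxel grid, the analyzed
    cohort's 28/56 male/female split and its snore/gasp category tables,
    and the planted morphometric effect structure.
    """

    n_participants: int = 90
    n_frames_per_position: int = 20
    positions: tuple[str, str] = POSITIONS
    grid_shape: tuple[int, int, int] = (64, 64, 72)
    voxel_spacing_mm: tuple[float, float, float] = (1.25, 1.25, 2.0)
    sex_counts: tuple[int, int] = (28, 56)          # analyzed (male, female)
    n_osa_excluded: int = 6
    symptomatic_fraction: float | None = None       # None -> category tables
    snore_counts_by_sex: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SNORE_BY_SEX))
    gasp_counts_by_sex: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GASP_BY_SEX))
    effect_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(t) for m, t in DEFAULT_EFFECTS.items()})
    respiratory_amplitude: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    respiratory_period_frames: float = 4.0          # ~4 s at ~1 volume/s
    label_noise: float = 0.1
    intensity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_frames_per_position <= 0:
            raise ConfigurationError("participant and frame counts must be positive")
        if self.n_osa_excluded < 0 or self.n_osa_excluded >= self.n_participants:
            raise ConfigurationError("n_osa_excluded must be in [0, n_participants)")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError("grid shape must be positive")
        if self.label_noise < 0 or self.intensity_noise < 0:
            raise ConfigurationError("noise levels must be nonnegative")
        for key, a in self.respiratory_amplitude.items():
            if not 0.0 <= a <= 0.5:
                raise ConfigurationError(f"amplitude {key} = {a} outside [0, 0.5]")
        for metric, terms in self.effect_table.items():
            for name in ("participant_sd", "position_sd"):
                if terms.get(name, 0.0) < 0:
                    raise ConfigurationError(f"{metric}.{name} must be nonnegative")
        if self.symptomatic_fraction is not None and not 0.0 <= self.symptomatic_fraction <= 1.0:
            raise ConfigurationError("symptomatic_fraction must lie in [0, 1]")

    @property
    def n_analyzed(self) -> int:
        return self.n_participants - self.n_osa_excluded

    @property
    def n_frames_total(self) -> int:
        return self.n_participants * len(self.positions) * self.n_frames_per_position

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["respiratory_amplitude"] = {f"{r}|{p}": a for (r, p), a in self.respiratory_amplitude.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "respiratory_amplitude" in d:
            amp = {}
            for key, a in dict(d["respiratory_amplitude"]).items():
                region, pos = key.split("|") if isinstance(key, str) else key
                amp[(region, pos)] = float(a)
            d["respiratory_amplitude"] = amp
        for name in ("positions", "grid_shape", "voxel_spacing_mm", "sex_counts"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class ParticipantProfile:
    """Demographics and study covariates of one participant."""

    participant_id: str
    age: float
    sex: str                       # "male" | "female"
    weight: float                  # kg
    height: float                  # cm
    bmi: float                     # kg/m^2, derived
    neck_circumference: float      # cm
    sacs: float
    snore: str                     # never | occasionally | consistently
    gasp: str
    symptomatic: bool
    delta_d: float                 # mouth-opening extent, mm
    osa_excluded: bool = False

    def __post_init__(self) -> None:
        expected = self.snore != "never" or self.gasp != "never"
        if self.symptomatic != expected:
            raise ConfigurationError(
                f"{self.participant_id}: symptomatic flag inconsistent with snore/gasp")
        if self.delta_d < 0:
            raise ConfigurationError("delta_d must be nonnegative")


@dataclass
class AirwayGeometry:
    """Analytic airway phantom for one participant and mouth position.

    The lumen is a tube of circular cross-section along the
    superior->inferior axis.  ``area_control_points`` give the baseline
    cross-sectional area (cm^2) at normalized stations s in [0, 1] between
    the soft palate (s=0) and the epiglottic base (s=1); the profile is
    PCHIP-interpolated, which keeps the retropalatal notch value an exact
    local minimum.  The labeled extent runs from 1 cm above the hard palate
    to 1 cm below the epiglottic base.
    """

    participant_id: str
    position: str
    landmark_z_mm: dict[str, float]
    area_control_points: tuple[tuple[float, float], ...]
    respiratory_phase_offset: float
    amplitude_by_region: dict[str, float]
    planted: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        zs = [self.landmark_z_mm[k] for k in LANDMARK_NAMES]
        if any(b < a for a, b in zip(zs, zs[1:])):
            raise GenerationError(f"landmarks out of superior->inferior order: {self.landmark_z_mm}")
        areas = [a for _, a in self.area_control_points]
        if min(areas) <= 0:
            raise GenerationError("cross-sectional area profile must be positive")
        self._interp = PchipInterpolator(*zip(*self.area_control_points))

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Superior and inferior limits of the labeled airway (ROI rule)."""
        return (self.landmark_z_mm["hard_palate"] - 10.0,
                self.landmark_z_mm["epiglottic_base"] + 10.0)

    def _station(self, z_mm: np.ndarray) -> np.ndarray:
        z0 = self.landmark_z_mm["soft_palate_sup"]
        z1 = self.landmark_z_mm["epiglottic_base"]
        return np.clip((np.asarray(z_mm, float) - z0) / (z1 - z0), 0.0, 1.0)

    def area_cm2(self, z_mm: np.ndarray) -> np.ndarray:
        """Baseline lumen area (cm^2) at physical depth z; 0 outside the ROI.

        Within the 1 cm ROI margins above the hard palate and below the
        epiglottic base the area tapers linearly toward a small edge value,
        emulating the cropped continuation of the airway.
        """
        z_mm = np.asarray(z_mm, float)
        area = np.maximum(self._interp(self._station(z_mm)), 1e-6)
        lo, hi = self.extent_mm
        z0 = self.landmark_z_mm["soft_palate_sup"]
        z1 = self.landmark_z_mm["epiglottic_base"]
        outside = np.where(z_mm < z0, z0 - z_mm, np.maximum(z_mm - z1, 0.0))
        margin_sup, margin_inf = z0 - lo, hi - z1
        margin = np.where(z_mm < z0, margin_sup, margin_inf)
        taper = 1.0 - (1.0 - _EDGE_TAPER) * np.clip(outside / margin, 0.0, 1.0)
        return np.where((z_mm >= lo) & (z_mm <= hi), area * taper, 0.0)

    def radius_mm(self, z_mm: np.ndarray) -> np.ndarray:
        return 10.0 * np.sqrt(self.area_cm2(z_mm) / np.pi)

    def _region_windows(self) -> tuple[tuple[str, float, float], ...]:
        lm = self.landmark_z_mm
        return (
            ("retropalatal", lm["soft_palate_sup"], lm["velum_tip"]),
            ("retroglossal", lm["velum_tip"], lm["epiglottic_tip"]),
            ("epiglottic", lm["epiglottic_tip"], lm["epiglottic_base"]),
        )

    def amplitude_at(self, z_mm: np.ndarray) -> np.ndarray:
        """Relative radius modulation amplitude, region-piecewise in z."""
        z = np.asarray(z_mm, float)
        a = np.full(z.shape, self.amplitude_by_region.get("global", 0.0))
        for region, lo, hi in self._region_windows():
            if region in self.amplitude_by_region:
                a = np.where((z >= lo) & (z < hi), self.amplitude_by_region[region], a)
        return a

    def phase_lag_at(self, z_mm: np.ndarray) -> np.ndarray:
        """Respiratory phase lag (radians), region-piecewise in z.

        The cranio-caudal lag de-phases the regional fluctuations so that
        whole-airway volume and mean-CSA vary less, relatively, than any
        single level does.
        """
        z = np.asarray(z_mm, float)
        lag = np.full(z.shape, REGION_PHASE_LAG["global"])
        for region, lo, hi in self._region_windows():
            lag = np.where((z >= lo) & (z < hi), REGION_PHASE_LAG[region], lag)
        return lag


# --------------------------------------------------------------------------
# demographics
# --------------------------------------------------------------------------

def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``weights``."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _truncnorm_rvs(rng: np.random.Generator, mean: float, sd: float,
                   lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _categories_for_sex(n: int, sex: str, config: CohortConfig,
                        rng: np.random.Generator) -> list[tuple[str, str]]:
    """(snore, gasp) per participant of one sex, honoring the planted tables.

    Gasping participants are drawn from within the snoring ("ever") set so
    that symptomatic status (snore or gasp present) equals snore != never,
    mirroring the analyzed cohort's category structure.
    """
    if config.symptomatic_fraction is None:
        snore_counts = _largest_remainder(n, config.snore_counts_by_sex[sex])
        gasp_counts = _largest_remainder(n, config.gasp_counts_by_sex[sex])
    else:
        n_sym = int(round(config.symptomatic_fraction * n))
        occ = n_sym // 2
        snore_counts = [n - n_sym, occ, n_sym - occ]
        n_gasp = int(round(0.3 * n_sym))
        g_occ = (n_gasp + 1) // 2
        gasp_counts = [n - n_gasp, g_occ, n_gasp - g_occ]
    n_ever = snore_counts[1] + snore_counts[2]
    n_gasp_ever = gasp_counts[1] + gasp_counts[2]
    if n_gasp_ever > n_ever:  # cannot keep gasp within the snoring set
        overflow = n_gasp_ever - n_ever
        take = min(overflow, gasp_counts[2])
        gasp_counts = [gasp_counts[0] + overflow, gasp_counts[1] - (overflow - take),
                       gasp_counts[2] - take]
        n_gasp_ever = n_ever
    snore = (["never"] * snore_counts[0] + ["occasionally"] * snore_counts[1]
             + ["consistently"] * snore_counts[2])
    gasp = ["never"] * n
    ever_idx = list(range(snore_counts[0], n))
    rng.shuffle(ever_idx)
    for j, idx in enumerate(ever_idx[:n_gasp_ever]):
        gasp[idx] = "occasionally" if j < gasp_counts[1] else "consistently"
    pairs = list(zip(snore, gasp))
    rng.shuffle(pairs)
    return pairs


def sample_demographics(config: CohortConfig, seed: int | None = None) -> list[ParticipantProfile]:
    """Draw the full cohort's demographics.

    Category counts (sex, snore, gasp) are planted exactly via
    largest-remainder scaling of the configured tables; continuous
    covariates are independent truncated normals per sex; BMI is derived
    from weight and height.  ``n_osa_excluded`` participants are flagged
    for exclusion from downstream statistics.
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "demographics")
    n, n_exc = config.n_participants, config.n_osa_excluded
    n_analyzed = config.n_analyzed

    m, f = config.sex_counts
    if m + f != n_analyzed:
        male_analyzed, female_analyzed = _largest_remainder(n_analyzed, (m, f))
    else:
        male_analyzed, female_analyzed = m, f
    male_exc, female_exc = _largest_remainder(n_exc, (m, f))

    profiles: list[ParticipantProfile] = []
    pid = 0
    for sex, n_a, n_e in (("male", male_analyzed, male_exc),
                          ("female", female_analyzed, female_exc)):
        n_sex = n_a + n_e
        cats = _categories_for_sex(n_a, sex, config, rng) + \
            _categories_for_sex(n_e, sex, config, rng)
        cont = {name: _truncnorm_rvs(rng, *DEFAULT_CONTINUOUS[name][sex], size=n_sex)
                for name in DEFAULT_CONTINUOUS}
        dd = _truncnorm_rvs(rng, *DEFAULT_DELTA_D, size=n_sex)
        for i in range(n_sex):
            snore, gasp = cats[i]
            weight = float(cont["weight"][i])
            height = float(cont["height"][i])
            profiles.append(ParticipantProfile(
                participant_id=f"P{pid:03d}",
                age=float(cont["age"][i]), sex=sex,
                weight=weight, height=height,
                bmi=weight / (height / 100.0) ** 2,
                neck_circumference=float(cont["neck_circumference"][i]),
                sacs=float(cont["sacs"][i]),
                snore=snore, gasp=gasp,
                symptomatic=(snore != "never" or gasp != "never"),
                delta_d=float(dd[i]),
                osa_excluded=i >= n_a,
            ))
            pid += 1
    # interleave so excluded participants are not a contiguous block
    order = rng.permutation(len(profiles))
    profiles = [profiles[i] for i in order]
    for new_id, p in enumerate(profiles):
        p.participant_id = f"P{new_id:03d}"
    return profiles


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

_HARD_PALATE_Z_MM = 12.0
_SOFT_PALATE_OFFSET_MM = 2.0
_VELUM_FRACTION = 0.35   # velum tip station along the soft-palate..base span
_RP_STATION = 0.18       # retropalatal notch station


def _planted_value(terms: Mapping[str, float], male: bool, symptomatic: bool,
                   is_open: bool, eps_participant: float, eps_position: float) -> float:
    v = terms["intercept"]
    v += terms.get("male", 0.0) * male
    v += terms.get("symptomatic", 0.0) * symptomatic
    v += terms.get("open", 0.0) * is_open
    v += terms.get("open_symptomatic", 0.0) * (is_open and symptomatic)
    v += terms.get("participant_sd", 0.0) * eps_participant
    v += terms.get("position_sd", 0.0) * eps_position
    return max(v, terms.get("floor", 1e-3))


def build_geometry(profile: ParticipantProfile, position: str,
                   config: CohortConfig) -> AirwayGeometry:
    """Construct the airway phantom for one participant and mouth position.

    Participant-level random effects are drawn from a substream keyed by the
    participant only (shared across positions, giving within-participant
    correlation); position-level noise and the respiratory phase come from a
    (participant, position) substream.
    """
    if position not in config.positions:
        raise ConfigurationError(f"unknown position {position!r}")
    is_open = position == "open"
    metrics = list(config.effect_table)
    rng_p = substream(config.seed, "geometry", profile.participant_id)
    eps_p = {m: float(rng_p.standard_normal()) for m in metrics}
    rng_pos = substream(config.seed, "geometry", profile.participant_id, position)
    eps_pos = {m: float(rng_pos.standard_normal()) for m in metrics}
    phase = float(rng_pos.uniform(0.0, 2.0 * np.pi))

    # clip latent noise to +-3 SD so phantoms stay on the grid
    for d in (eps_p, eps_pos):
        for m in d:
            d[m] = float(np.clip(d[m], -3.0, 3.0))

    val = {m: _planted_value(config.effect_table[m], profile.sex == "male",
                             profile.symptomatic, is_open, eps_p[m], eps_pos[m])
           for m in metrics}

    l_tot = val["total_length_cm"]
    l_ep = min(val["epiglottic_length_cm"], 0.6 * l_tot)
    soft_palate = _HARD_PALATE_Z_MM + _SOFT_PALATE_OFFSET_MM
    base = soft_palate + 10.0 * l_tot
    landmarks = {
        "hard_palate": _HARD_PALATE_Z_MM,
        "soft_palate_sup": soft_palate,
        "velum_tip": soft_palate + _VELUM_FRACTION * 10.0 * l_tot,
        "epiglottic_tip": base - 10.0 * l_ep,
        "epiglottic_base": base,
    }
    k = val["area_scale"]
    a_rp, a_rg = val["retropalatal_csa_cm2"], val["retroglossal_csa_cm2"]
    # retroglossal plateau is flat (equal PCHIP knots), so the window minimum
    # equals the planted value; the retropalatal notch is the [0, 0.35] dip
    control = (
        (0.0, 2.4 * k),
        (_RP_STATION, a_rp),
        (0.35, a_rg),
        (0.55, a_rg),
        (0.85, a_rg),
        (1.0, 2.7 * k),
    )
    amplitudes = {region: config.respiratory_amplitude.get((region, position), 0.0)
                  for region in ("global", "retropalatal", "retroglossal", "epiglottic")}
    return AirwayGeometry(
        participant_id=profile.participant_id, position=position,
        landmark_z_mm=landmarks, area_control_points=control,
        respiratory_phase_offset=phase, amplitude_by_region=amplitudes,
        planted={m: val[m] for m in metrics},
    )


def rasterize_frame(geometry: AirwayGeometry, frame_index: int,
                    config: CohortConfig, with_intensity: bool = True
                    ) -> tuple[LabelVolume, np.ndarray | None]:
    """Discretize one respiratory frame onto the voxel grid.

    Returns the label volume (0 background, 1 upper airway, 2 epiglottic
    airway = the ventral portion of the lumen between epiglottic tip and
    base, out to a chord at 0.3 of the local radius) and a float32 intensity
    grid (dark lumen, bright tissue, additive Gaussian noise), or ``None``
    in place of the intensity when ``with_intensity`` is false (label-only
    analyses skip the per-voxel noise draw).
    """
    if not 0 <= frame_index < config.n_frames_per_position:
        raise GenerationError(f"frame index {frame_index} outside [0, {config.n_frames_per_position})")
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.voxel_spacing_mm
    lo, hi = geometry.extent_mm
    if hi > nz * dz or lo < 0:
        raise GenerationError(
            f"{geometry.participant_id}/{geometry.position}: airway extent "
            f"[{lo:.1f}, {hi:.1f}] mm exceeds grid depth {nz * dz:.1f} mm")

    z_mm = (np.arange(nz) + 0.5) * dz
    phase = 2.0 * np.pi * frame_index / config.respiratory_period_frames \
        + geometry.respiratory_phase_offset
    modulation = 1.0 + geometry.amplitude_at(z_mm) * np.sin(phase - geometry.phase_lag_at(z_mm))
    r_mm = geometry.radius_mm(z_mm) * modulation

    x_mm = (np.arange(nx) + 0.5) * dx
    y_mm = (np.arange(ny) + 0.5) * dy
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    max_r = float(r_mm.max())
    if max_r > min(cx, cy):
        raise GenerationError(
            f"{geometry.participant_id}/{geometry.position}: lumen radius "
            f"{max_r:.1f} mm exceeds in-plane half-extent {min(cx, cy):.1f} mm")
    dist2 = (x_mm[:, None] - cx) ** 2 + (y_mm[None, :] - cy) ** 2   # (nx, ny)

    lumen = dist2[:, :, None] <= (r_mm ** 2)[None, None, :]
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[lumen] = 1
    tip = geometry.landmark_z_mm["epiglottic_tip"]
    bas = geometry.landmark_z_mm["epiglottic_base"]
    chord = cy + EPIGLOTTIC_VENTRAL_OFFSET * r_mm          # per-slice cut
    epiglottic = lumen & ((z_mm >= tip) & (z_mm <= bas))[None, None, :] \
        & (y_mm[None, :, None] < chord[None, None, :])
    labels[epiglottic] = 2

    if not with_intensity:
        return LabelVolume(labels, config.voxel_spacing_mm), None
    rng = substream(config.seed, "intensity", geometry.participant_id,
                    geometry.position, frame_index)
    intensity = np.where(lumen, 0.25, 0.80).astype(np.float32)
    if config.intensity_noise > 0:
        intensity = intensity + rng.normal(0.0, config.intensity_noise,
                                           size=intensity.shape).astype(np.float32)
    return LabelVolume(labels, config.voxel_spacing_mm), intensity


def soften_labels(label: LabelVolume, noise_level: float,
                  seed: int = 0) -> ProbabilityMap:
    """Turn a hard segmentation into a probability map with tunable entropy.

    Each voxel's one-hot vector is mixed toward the uniform simplex with
    weight 1 - exp(-noise_level); a seeded Dirichlet(40, 40, 40) jitter
    keeps the map non-degenerate.  Mean voxel entropy is strictly
    increasing in ``noise_level``: 0 gives a one-hot map, the large-noise
    limit approaches the uniform distribution (entropy ln 3).
    """
    if noise_level < 0:
        raise ConfigurationError("noise_level must be nonnegative")
    oh = one_hot(label.voxels)
    lam = 1.0 - np.exp(-noise_level)
    if lam == 0.0:
        return ProbabilityMap(oh, label.spacing_mm)
    rng = np.random.default_rng(seed)
    jitter = rng.gamma(40.0, size=oh.shape).astype(np.float32)
    jitter /= jitter.sum(axis=-1, keepdims=True)
    probs = (1.0 - lam) * oh + lam * jitter
    probs /= probs.sum(axis=-1, keepdims=True)
    return ProbabilityMap(probs, label.spacing_mm)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

class SyntheticCohort:
    """Lazy in-memory view of a generated cohort.

    Demographics are sampled eagerly; geometries and frames are built on
    demand so that count/bookkeeping queries and per-participant analyses
    never pay for the full 4D rasterization.
    """

    def __init__(self, config: CohortConfig):
        self.config = config
        self.profiles = sample_demographics(config)
        self._geometries: dict[tuple[str, str], AirwayGeometry] = {}

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.profiles]

    @property
    def analyzed_profiles(self) -> list[ParticipantProfile]:
        return [p for p in self.profiles if not p.osa_excluded]

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def geometry(self, participant_id: str, position: str) -> AirwayGeometry:
        key = (participant_id, position)
        if key not in self._geometries:
            self._geometries[key] = build_geometry(self.profile(participant_id),
                                                   position, self.config)
        return self._geometries[key]

    def frame(self, participant_id: str, position: str, frame_index: int,
              with_intensity: bool = True) -> tuple[LabelVolume, np.ndarray | None]:
        return rasterize_frame(self.geometry(participant_id, position),
                               frame_index, self.config, with_intensity)

    def frames(self, participant_id: str, position: str,
               with_intensity: bool = True
               ) -> Iterator[tuple[LabelVolume, np.ndarray | None]]:
        geo = self.geometry(participant_id, position)
        for i in range(self.config.n_frames_per_position):
            yield rasterize_frame(geo, i, self.config, with_intensity)

    def landmarks(self, participant_id: str, position: str) -> dict[str, float]:
        return dict(self.geometry(participant_id, position).landmark_z_mm)

    def probability_map(self, participant_id: str, position: str,
                        frame_index: int) -> ProbabilityMap:
        label, _ = self.frame(participant_id, position, frame_index)
        frame_seed = substream(self.config.seed, "probseed", participant_id,
                               position, frame_index).integers(2 ** 31)
        return soften_labels(label, self.config.label_noise, int(frame_seed))

    def demographics_frame(self):
        import pandas as pd
        return pd.DataFrame([dataclasses.asdict(p) for p in self.profiles])


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    write_intensity: bool = True,
                    write_probabilities: bool = False) -> Path:
    """Write a full synthetic dataset to disk and return the manifest path.

    Layout: ``labels/<pid>_<position>_f<frame>.nii.gz`` (+ matching
    ``intensity/`` and optional ``probability/`` trees), one landmark JSON
    sidecar per participant/position, ``demographics.csv``, and
    ``manifest.json`` recording the config, seeds and every file.
    """
    from . import io as a4io

    out = Path(out_dir)
    try:
        (out / "labels").mkdir(parents=True, exist_ok=True)
        (out / "landmarks").mkdir(exist_ok=True)
        if write_intensity:
            (out / "intensity").mkdir(exist_ok=True)
        if write_probabilities:
            (out / "probability").mkdir(exist_ok=True)
    except OSError as exc:
        raise GenerationError(f"cannot create output tree under {out}: {exc}") from exc

    cohort = SyntheticCohort(config)
    entries = []
    for pid in cohort.participant_ids:
        for position in config.positions:
            lm_path = out / "landmarks" / f"{pid}_{position}.json"
            a4io.write_landmarks(lm_path, pid, position, cohort.landmarks(pid, position))
            for k in range(config.n_frames_per_position):
                label, intensity = cohort.frame(pid, position, k)
                stem = f"{pid}_{position}_f{k:02d}.nii.gz"
                label_path = out / "labels" / stem
                a4io.write_label_volume(label_path, label)
                entry = {"participant": pid, "position": position, "frame": k,
                         "label": str(label_path.relative_to(out)),
                         "landmarks": str(lm_path.relative_to(out))}
                if write_intensity:
                    ipath = out / "intensity" / stem
                    a4io.write_intensity_volume(ipath, intensity, config.voxel_spacing_mm)
                    entry["intensity"] = str(ipath.relative_to(out))
                if write_probabilities:
                    ppath = out / "probability" / stem
                    a4io.write_probability_map(ppath, cohort.probability_map(pid, position, k))
                    entry["probability"] = str(ppath.relative_to(out))
                entries.append(entry)
    cohort.demographics_frame().to_csv(out / "demographics.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_images": len(entries),
        "demographics": "demographics.csv",
        "images": entries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
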