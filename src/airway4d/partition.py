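"""Dataset fingerprints and the balanced five-group split with role assignment.

Participants are divided into five groups whose intensity fingerprints do
not differ significantly (Kruskal-Wallis p > 0.05 on the per-participant
median intensity).  Group 1 is split into an initial training set and a
fixed validation set; Groups 2-4 enter the active-learning candidate pool
wave by wave; Group 5 is the hold-out test set and is never touched before
the final evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._rng import substream

ROLES = ("initial_train", "fixed_validation", "pool_wave2", "pool_wave3",
         "pool_wave4", "holdout_test")


class PartitionError(RuntimeError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """Median shape and intensity distribution summary of one participant."""

    median_shape: tuple[int, int, int]
    intensity_median: float
    intensity_p10: float
    intensity_p90: float

    def __post_init__(self) -> None:
        if not self.intensity_p10 <= self.intensity_median <= self.intensity_p90:
            raise PartitionError("fingerprint percentiles out of order")


@dataclass
class PartitionPlan:
    """Group membership, role assignment, and the balance diagnostic."""

    group_of: dict[str, int]
    roles: dict[str, str] = field(default_factory=dict)
    balance_p: float = float("nan")
    n_attempts: int = 0

    def members(self, group: int) -> list[str]:
        return sorted(pid for pid, g in self.group_of.items() if g == group)

    def role_members(self, role: str) -> list[str]:
        return sorted(pid for pid, r in self.roles.items() if r == role)

    def image_counts(self, n_frames_per_position: int = 20,
                     n_positions: int = 2) -> dict[str, int]:
        """Images per role (= participants x positions x frames), plus the
        total and the non-hold-out pool size."""
        per = n_frames_per_position * n_positions
        counts = {role: len(self.role_members(role)) * per for role in ROLES}
        counts["total"] = len(self.group_of) * per
        counts["non_holdout"] = counts["total"] - counts["holdout_test"]
        return counts


def compute_fingerprint(volumes: Sequence[np.ndarray]) -> Fingerprint:
    """Fingerprint a participant from one or more intensity volumes.

    The shape is the element-wise median of the volume shapes; intensity
    statistics are taken over foreground-candidate voxels (above the volume
    mean, which separates bright tissue from the dark lumen and any padding).
    """
    if len(volumes) == 0:
        raise PartitionError("cannot fingerprint an empty volume list")
    shapes = np.array([v.shape for v in volumes])
    median_shape = tuple(int(s) for s in np.median(shapes, axis=0))
    fg = []
    for v in volumes:
        v = np.asarray(v, dtype=float)
        candidates = v[v > v.mean()]
        fg.append(candidates if candidates.size else v.ravel())
    allv = np.concatenate(fg)
    p10, med, p90 = np.percentile(allv, [10, 50, 90])
    return Fingerprint(median_shape, float(med), float(p10), float(p90))


def partition_cohort(fingerprints: Mapping[str, Fingerprint], n_groups: int = 5,
                     seed: int = 0, max_attempts: int = 100,
                     balance_alpha: float = 0.05) -> PartitionPlan:
    """Split participants into equal groups balanced on intensity median.

    Stratified randomization: participants are sorted by median intensity,
    shuffled within deciles, and dealt round-robin; the split is accepted
    when a Kruskal-Wallis test across groups gives p > ``balance_alpha``,
    re-randomizing up to ``max_attempts`` times.
    """
    ids = sorted(fingerprints)
    n = len(ids)
    if n < n_groups:
        raise PartitionError(f"need at least {n_groups} participants, got {n}")
    scalar = np.array([fingerprints[pid].intensity_median for pid in ids])
    order = np.argsort(scalar, kind="stable")
    rng = substream(seed, "partition")

    last_p = float("nan")
    for attempt in range(1, max_attempts + 1):
        shuffled = order.copy()
        # shuffle within deciles of the sorted order, then deal round-robin
        for block in np.array_split(np.arange(n), 10):
            if block.size > 1:
                shuffled[block] = shuffled[rng.permutation(block)]
        group_of = {ids[shuffled[i]]: (i % n_groups) + 1 for i in range(n)}
        samples = [scalar[[ids.index(pid) for pid in ids if group_of[pid] == g]]
                   for g in range(1, n_groups + 1)]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(scalar) == 0:
            last_p = 1.0  # identical fingerprints: any split is balanced
        else:
            last_p = float(stats.kruskal(*samples).pvalue)
        if last_p > balance_alpha:
            return PartitionPlan(group_of=group_of, balance_p=last_p,
                                 n_attempts=attempt)
    raise PartitionError(
        f"no balanced split after {max_attempts} attempts "
        f"(last Kruskal-Wallis p = {last_p:.4f}); fingerprints may be multimodal")


def assign_roles(plan: PartitionPlan, seed: int = 0, n_initial_train: int = 14,
                 n_fixed_validation: int = 4) -> PartitionPlan:
    """Assign active-learning roles on top of the group split.

    Group 1 is divided uniformly at random into the initial training set and
    the fixed validation set; Groups 2-4 become pool waves; Group 5 is the
    hold-out test set.
    """
    n_groups = max(plan.group_of.values())
    if n_groups != 5:
        raise PartitionError(f"role assignment expects 5 groups, plan has {n_groups}")
    group1 = plan.members(1)
    need = n_initial_train + n_fixed_validation
    if len(group1) < need:
        raise PartitionError(
            f"Group 1 has {len(group1)} participants; "
            f"{n_initial_train}+{n_fixed_validation} required")
    rng = substream(seed, "roles")
    perm = rng.permutation(len(group1))
    roles = {}
    for i, idx in enumerate(perm):
        if i < n_initial_train:
            roles[group1[idx]] = "initial_train"
        elif i < need:
            roles[group1[idx]] = "fixed_validation"
        else:  # group-1 surplus beyond the protocol sizes stays in the pool
            roles[group1[idx]] = "pool_wave2"
    for g, role in ((2, "pool_wave2"), (3, "pool_wave3"), (4, "pool_wave4"),
                    (5, "holdout_test")):
        for pid in plan.members(g):
            roles[pid] = role
    return PartitionPlan(group_of=dict(plan.group_of), roles=roles,
                         balance_p=plan.balance_p, n_attempts=plan.n_attempts)


def cohort_fingerprints(cohort, frames_per_position: int = 1) -> dict[str, Fingerprint]:
    """Fingerprint every participant from a few representative frames."""
    out = {}
    for pid in cohort.participant_ids:
        vols = []
        for position in cohort.config.positions:
            for k in range(frames_per_position):
                _, intensity = cohort.frame(pid, position, k)
                vols.append(intensity)
        out[pid] = compute_fingerprint(vols)
    return out
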