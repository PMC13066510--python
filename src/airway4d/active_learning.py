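"""Entropy-driven active-learning campaign bookkeeping.

Uncertainty of a segmentation is the median over voxels of the 3-class
entropy -sum(p log p) (natural log, maximum ln 3).  Each generation the
candidate pool is expanded by one wave, every pool image is re-scored with
the current model, and any image whose score exceeds the pool mean by more
than one sample SD is selected: unseen images are labeled and added to the
training multiset, previously trained images gain one extra copy
(re-selection of persistent hard examples).  The fixed validation set and
the hold-out test set never enter the pool or the training multiset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

from .volumes import LabelVolume, ProbabilityMap, validate_simplex

MAX_ENTROPY = float(np.log(3.0))

ImageId = str


class ActiveLearningError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# uncertainty
# --------------------------------------------------------------------------

def voxel_entropy(p: np.ndarray) -> np.ndarray | float:
    """Shannon entropy (nats) of channel-last probability triples.

    ``0 * log 0`` is taken as 0.  Accepts a single triple or any array whose
    last axis holds the three class probabilities.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ActiveLearningError(f"expected 3 class probabilities, got shape {p.shape}")
    validate_simplex(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    h = np.clip(h, 0.0, MAX_ENTROPY)
    return float(h) if h.ndim == 0 else h


@dataclass(frozen=True)
class UncertaintyRecord:
    """Representative uncertainty of one image: the median voxel entropy."""

    image_id: ImageId
    score: float
    generation: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= MAX_ENTROPY + 1e-12:
            raise ActiveLearningError(f"score {self.score} outside [0, ln 3]")


def image_score(pm: ProbabilityMap, image_id: ImageId = "",
                generation: int = 0, mask: np.ndarray | None = None) -> UncertaintyRecord:
    """Median voxel entropy of a probability map.

    By default the median runs over *all* voxels including background; a
    boolean ``mask`` restricts it to a body region when provided.
    """
    h = voxel_entropy(pm.probs)
    if mask is not None:
        h = h[np.asarray(mask, bool)]
    if h.size == 0:
        raise ActiveLearningError("cannot score an empty probability map")
    return UncertaintyRecord(image_id=image_id, score=float(np.median(h)),
                             generation=generation)


def selection_threshold(scores: Sequence[float]) -> float:
    """High-entropy cutoff: pool mean plus one sample SD (selection uses >)."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ActiveLearningError("threshold needs at least two scores")
    return float(scores.mean() + scores.std(ddof=1))


# --------------------------------------------------------------------------
# Dice
# --------------------------------------------------------------------------

def dice(a: LabelVolume, b: LabelVolume, classes: Sequence[int] = (1, 2),
         mode: str = "mean") -> dict:
    """Dice overlap between two label volumes.

    Per class c: 2|A_c & B_c| / (|A_c| + |B_c|).  ``mode="mean"`` averages
    over the classes present in the reference ``a``; ``mode="union"`` pools
    all foreground classes into one mask first.
    """
    if a.shape != b.shape:
        raise ActiveLearningError(f"shape mismatch {a.shape} vs {b.shape}")
    per_class: dict[int, float] = {}
    for c in classes:
        am, bm = a.voxels == c, b.voxels == c
        denom = int(am.sum()) + int(bm.sum())
        if denom:
            per_class[c] = 2.0 * int((am & bm).sum()) / denom
    if mode == "union":
        am = np.isin(a.voxels, list(classes))
        bm = np.isin(b.voxels, list(classes))
        denom = int(am.sum()) + int(bm.sum())
        overall = 2.0 * int((am & bm).sum()) / denom if denom else float("nan")
    elif mode == "mean":
        present = [c for c in classes if (a.voxels == c).any()]
        overall = float(np.mean([per_class[c] for c in present])) if present else float("nan")
    else:
        raise ActiveLearningError(f"unknown dice mode {mode!r}")
    return {"per_class": per_class, "mean": overall}


# --------------------------------------------------------------------------
# campaign state
# --------------------------------------------------------------------------

class SegmenterBackend(Protocol):
    """Contract every segmentation backend must satisfy.

    ``fit`` consumes a training multiset of (intensity volume, label volume,
    multiplicity) triples and must be deterministic given its seed;
    ``predict_probabilities`` returns a simplex-valid probability map.
    """

    def fit(self, samples: Sequence[tuple[np.ndarray, LabelVolume, int]]) -> None: ...

    def predict_probabilities(self, image: np.ndarray) -> ProbabilityMap: ...


@dataclass
class TrainingMultiset:
    """Training collection in which persistent hard examples accrue copies."""

    counts: Counter = field(default_factory=Counter)

    def add(self, image_id: ImageId, copies: int = 1) -> None:
        if copies <= 0:
            raise ActiveLearningError("copies must be positive")
        self.counts[image_id] += copies

    def __contains__(self, image_id: ImageId) -> bool:
        return image_id in self.counts

    @property
    def unique_count(self) -> int:
        return len(self.counts)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return self.counts.items()


@dataclass
class GenerationLog:
    generation: int
    threshold: float
    n_new: int
    n_reselected: int
    training_total: int
    training_unique: int
    val_dice_mean: float
    val_entropy_median: float
    pool_entropy_median: float = float("nan")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CampaignState:
    """Bookkeeping for one active-learning campaign."""

    training: TrainingMultiset
    candidate_pool: set[ImageId]
    validation_ids: frozenset[ImageId]
    holdout_ids: frozenset[ImageId]
    generation: int = 1
    selection_log: list[GenerationLog] = field(default_factory=list)

    def check_isolation(self) -> None:
        """Validation/hold-out images must never be trained on or pooled."""
        protected = self.validation_ids | self.holdout_ids
        leaked = (set(self.training.counts) | self.candidate_pool) & protected
        if leaked:
            raise ActiveLearningError(
                f"validation/hold-out leakage at generation {self.generation}: {sorted(leaked)[:5]}")


@dataclass
class CampaignData:
    """Data access used by the campaign driver.

    ``get_image``/``get_label`` fetch intensity and reference label volumes
    by image id; ``labeler`` is the annotation callback invoked exactly once
    per newly selected image (here it returns the synthetic truth; in the
    original protocol it is the manual annotation step).
    """

    get_image: Callable[[ImageId], np.ndarray]
    get_label: Callable[[ImageId], LabelVolume]
    labeler: Callable[[ImageId], LabelVolume] | None = None

    def label_for_training(self, image_id: ImageId) -> LabelVolume:
        fn = self.labeler if self.labeler is not None else self.get_label
        return fn(image_id)


def _evaluate_validation(state: CampaignState, backend: SegmenterBackend,
                         data: CampaignData) -> tuple[float, float]:
    dices, entropies = [], []
    for vid in sorted(state.validation_ids):
        pm = backend.predict_probabilities(data.get_image(vid))
        entropies.append(image_score(pm, vid).score)
        dices.append(dice(data.get_label(vid), pm.argmax_labels())["mean"])
    return float(np.mean(dices)), float(np.median(entropies))


def _pool_entropy_median(state: CampaignState, backend: SegmenterBackend,
                         data: CampaignData) -> float:
    """Median image score over the candidate pool under the current model."""
    scores = [image_score(backend.predict_probabilities(data.get_image(iid)), iid,
                          generation=state.generation).score
              for iid in sorted(state.candidate_pool)]
    return float(np.median(scores)) if scores else float("nan")


def _fit(backend: SegmenterBackend, state: CampaignState, data: CampaignData) -> None:
    samples = [(data.get_image(iid), data.get_label(iid), mult)
               for iid, mult in sorted(state.training.items())]
    try:
        backend.fit(samples)
    except Exception as exc:
        raise ActiveLearningError(
            f"backend fit failed at generation {state.generation}: {exc}") from exc


def start_campaign(initial_train: Iterable[ImageId], validation: Iterable[ImageId],
                   holdout: Iterable[ImageId], backend: SegmenterBackend,
                   data: CampaignData) -> CampaignState:
    """Generation 1: fit on the fully labeled initial training set."""
    training = TrainingMultiset()
    for iid in initial_train:
        training.add(iid)
    if training.unique_count == 0:
        raise ActiveLearningError("initial training set is empty")
    state = CampaignState(training=training,
                          candidate_pool=set(training.counts),
                          validation_ids=frozenset(validation),
                          holdout_ids=frozenset(holdout))
    state.check_isolation()
    _fit(backend, state, data)
    val_dice, val_entropy = _evaluate_validation(state, backend, data)
    state.selection_log.append(GenerationLog(
        generation=1, threshold=float("nan"), n_new=0, n_reselected=0,
        training_total=state.training.total_count,
        training_unique=state.training.unique_count,
        val_dice_mean=val_dice, val_entropy_median=val_entropy,
        pool_entropy_median=_pool_entropy_median(state, backend, data)))
    return state


def run_generation(state: CampaignState, backend: SegmenterBackend,
                   new_wave: Iterable[ImageId], data: CampaignData,
                   max_generation: int = 4) -> CampaignState:
    """Advance the campaign by one generation.

    The pool is expanded by ``new_wave``; every pool image (including those
    already trained on) is re-scored with the current model; images above
    mean + 1 SD are selected -- new ones are labeled and added, previously
    trained ones gain one extra copy; the backend is refit on the augmented
    multiset and validation metrics are recorded.
    """
    if state.generation >= max_generation:
        raise ActiveLearningError(
            f"campaign already at final generation {max_generation}")
    state.candidate_pool |= set(new_wave)
    state.check_isolation()
    pool = sorted(state.candidate_pool)
    try:
        records = [image_score(backend.predict_probabilities(data.get_image(iid)), iid,
                               generation=state.generation + 1)
                   for iid in pool]
    except ActiveLearningError:
        raise
    except Exception as exc:
        raise ActiveLearningError(
            f"scoring failed at generation {state.generation + 1}: {exc}") from exc
    threshold = selection_threshold([r.score for r in records])
    selected = [r.image_id for r in records if r.score > threshold]
    n_new = n_reselected = 0
    for iid in selected:
        if iid in state.training:
            state.training.add(iid)      # one extra copy per qualifying generation
            n_reselected += 1
        else:
            data.label_for_training(iid)  # annotation event
            state.training.add(iid)
            n_new += 1
    state.generation += 1
    state.check_isolation()
    _fit(backend, state, data)
    val_dice, val_entropy = _evaluate_validation(state, backend, data)
    state.selection_log.append(GenerationLog(
        generation=state.generation, threshold=threshold,
        n_new=n_new, n_reselected=n_reselected,
        training_total=state.training.total_count,
        training_unique=state.training.unique_count,
        val_dice_mean=val_dice, val_entropy_median=val_entropy,
        pool_entropy_median=_pool_entropy_median(state, backend, data)))
    return state


def run_campaign(waves: dict[int, list[ImageId]], initial_train: list[ImageId],
                 validation: list[ImageId], holdout: list[ImageId],
                 backend: SegmenterBackend, data: CampaignData,
                 n_generations: int = 4) -> CampaignState:
    """Run the full campaign: generation 1 plus one pool wave per generation.

    ``waves`` maps generation number (2..n) to the image ids introduced at
    that generation.
    """
    state = start_campaign(initial_train, validation, holdout, backend, data)
    for g in range(2, n_generations + 1):
        state = run_generation(state, backend, waves.get(g, []), data,
                               max_generation=n_generations)
    return state
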