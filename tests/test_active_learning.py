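"""Entropy scoring, threshold selection, campaign bookkeeping, Dice, backend."""

import math

import numpy as np
import pytest

from airway4d.active_learning import (MAX_ENTROPY, ActiveLearningError,
                                      CampaignData, TrainingMultiset,
                                      UncertaintyRecord, dice, image_score,
                                      run_campaign, run_generation,
                                      selection_threshold, start_campaign,
                                      voxel_entropy)
from airway4d.backend import AtlasIntensityBackend, reference_backend
from airway4d.cohort import SyntheticCohort
from airway4d.volumes import LabelVolume, ProbabilityMap
from conftest import tiny_config


class TestVoxelEntropy:
    def test_one_hot_zero(self):
        assert voxel_entropy((1.0, 0.0, 0.0)) == 0.0

    def test_uniform_maximum(self):
        assert voxel_entropy((1 / 3, 1 / 3, 1 / 3)) == pytest.approx(math.log(3))
        assert MAX_ENTROPY == pytest.approx(math.log(3))

    def test_two_outcome_uniform(self):
        assert voxel_entropy((0.5, 0.5, 0.0)) == pytest.approx(math.log(2))

    def test_vectorized_over_grid(self):
        p = np.full((2, 2, 2, 3), 1 / 3)
        h = voxel_entropy(p)
        assert h.shape == (2, 2, 2)
        assert np.allclose(h, math.log(3))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(Exception):
            voxel_entropy((0.9, 0.3, 0.3))      # not normalized
        with pytest.raises(Exception):
            voxel_entropy((-0.1, 0.6, 0.5))     # negative
        with pytest.raises(ActiveLearningError):
            voxel_entropy((0.5, 0.5))           # wrong arity


class TestImageScore:
    def test_majority_one_hot_median_zero(self):
        # > 50% one-hot voxels, rest uniform -> median 0
        probs = np.zeros((3, 3, 3, 3), dtype=np.float32)
        probs[..., 0] = 1.0
        probs.reshape(-1, 3)[:13] = 1 / 3
        rec = image_score(ProbabilityMap(probs), "img")
        assert rec.score == 0.0

    def test_uniform_map_scores_ln3(self):
        probs = np.full((2, 2, 2, 3), 1 / 3, dtype=np.float32)
        assert image_score(ProbabilityMap(probs)).score == pytest.approx(math.log(3))

    def test_mask_restriction(self):
        probs = np.zeros((2, 2, 2, 3), dtype=np.float32)
        probs[..., 0] = 1.0
        probs[0, 0, 0] = [1 / 3, 1 / 3, 1 / 3]
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        assert image_score(ProbabilityMap(probs), mask=mask).score == pytest.approx(math.log(3))

    def test_score_bounds_enforced(self):
        with pytest.raises(ActiveLearningError):
            UncertaintyRecord("x", score=1.2)


class TestSelectionThreshold:
    def test_hand_computed_oracle(self):
        scores = [1, 2, 3, 4, 10]
        thr = selection_threshold(scores)
        assert thr == pytest.approx(4 + math.sqrt(12.5))
        assert [s for s in scores if s > thr] == [10]

    def test_closed_form_case(self):
        thr = selection_threshold([0, 0, 3])
        assert thr == pytest.approx(1 + math.sqrt(3))
        assert [s for s in [0, 0, 3] if s > thr] == [3]

    def test_all_equal_selects_nothing(self):
        thr = selection_threshold([0.4] * 6)
        assert thr == pytest.approx(0.4)
        assert not [s for s in [0.4] * 6 if s > thr]

    def test_needs_two_scores(self):
        with pytest.raises(ActiveLearningError):
            selection_threshold([1.0])


class TestDice:
    def _vol(self, arr):
        return LabelVolume(np.asarray(arr, dtype=np.uint8).reshape(1, 1, -1))

    def test_identical_is_one(self):
        v = self._vol([0, 1, 1, 2, 2, 0])
        out = dice(v, v)
        assert out["per_class"] == {1: 1.0, 2: 1.0}
        assert out["mean"] == 1.0

    def test_disjoint_is_zero(self):
        a = self._vol([1, 1, 0, 0])
        b = self._vol([0, 0, 1, 1])
        assert dice(a, b)["mean"] == 0.0

    def test_half_overlap(self):
        a = self._vol([1, 1, 1, 1, 0, 0])
        b = self._vol([1, 1, 0, 0, 1, 1])
        assert dice(a, b)["per_class"][1] == pytest.approx(0.5)

    def test_mean_over_reference_classes_only(self):
        a = self._vol([1, 1, 0, 0])         # no class 2 in reference
        b = self._vol([1, 0, 2, 0])
        out = dice(a, b)
        assert out["mean"] == pytest.approx(2 * 1 / (2 + 1))

    def test_union_mode(self):
        a = self._vol([1, 2, 0, 0])
        b = self._vol([2, 1, 0, 0])
        out = dice(a, b, mode="union")
        assert out["mean"] == 1.0           # pooled foreground identical

    def test_shape_mismatch(self):
        with pytest.raises(ActiveLearningError, match="shape"):
            dice(self._vol([0, 1]), self._vol([0, 1, 2]))


# --------------------------------------------------------------------------
# campaign bookkeeping with a score-controlled fake backend
# --------------------------------------------------------------------------

LOW = (0.98, 0.01, 0.01)
HIGH = (0.4, 0.3, 0.3)


class FakeBackend:
    """Backend whose per-image entropy is dictated by the image's content."""

    def __init__(self, triples):
        self.triples = triples
        self.fit_calls = []

    def fit(self, samples):
        self.fit_calls.append([(float(img.flat[0]), mult) for img, _, mult in samples])

    def predict_probabilities(self, image):
        triple = self.triples[round(float(image.flat[0]), 3)]
        probs = np.broadcast_to(np.asarray(triple, np.float32),
                                image.shape + (3,)).copy()
        return ProbabilityMap(probs)


def _fake_setup():
    values = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4, "V": 0.5, "H": 0.6, "E": 0.7}
    triples = {v: (HIGH if iid == "D" else LOW) for iid, v in values.items()}
    backend = FakeBackend(triples)
    labeled = []

    def get_image(iid):
        return np.full((2, 2, 2), values[iid])

    def get_label(iid):
        return LabelVolume(np.zeros((2, 2, 2), np.uint8))

    def labeler(iid):
        labeled.append(iid)
        return get_label(iid)

    data = CampaignData(get_image=get_image, get_label=get_label, labeler=labeler)
    return backend, data, labeled


class TestCampaign:
    def test_selection_reselection_and_identity(self):
        backend, data, labeled = _fake_setup()
        state = start_campaign(["A"], ["V"], ["H"], backend, data)
        state = run_generation(state, backend, ["B", "C", "D"], data)
        assert state.training.counts == {"A": 1, "D": 1}
        assert labeled == ["D"]             # annotation exactly once per new image
        state = run_generation(state, backend, [], data)
        assert state.training.counts == {"A": 1, "D": 2}
        state = run_generation(state, backend, ["E"], data)
        assert state.training.counts == {"A": 1, "D": 3}
        assert labeled == ["D"]

        logs = state.selection_log
        assert [g.generation for g in logs] == [1, 2, 3, 4]
        assert [g.n_new for g in logs] == [0, 1, 0, 0]
        assert [g.n_reselected for g in logs] == [0, 0, 1, 1]
        # two-column identity: total = unique + cumulative re-selections
        cum = 0
        for g in logs:
            cum += g.n_reselected
            assert g.training_total == g.training_unique + cum
        assert math.isnan(logs[0].threshold)
        assert all(g.threshold > 0 for g in logs[1:])

    def test_pool_grows_monotonically(self):
        backend, data, _ = _fake_setup()
        state = start_campaign(["A"], ["V"], ["H"], backend, data)
        before = set(state.candidate_pool)
        state = run_generation(state, backend, ["B"], data)
        assert before <= state.candidate_pool

    def test_validation_leak_raises(self):
        backend, data, _ = _fake_setup()
        state = start_campaign(["A"], ["V"], ["H"], backend, data)
        with pytest.raises(ActiveLearningError, match="leakage"):
            run_generation(state, backend, ["V", "B"], data)

    def test_holdout_leak_raises(self):
        backend, data, _ = _fake_setup()
        with pytest.raises(ActiveLearningError, match="leakage"):
            start_campaign(["A", "H"], ["V"], ["H"], backend, data)

    def test_final_generation_guard(self):
        backend, data, _ = _fake_setup()
        state = run_campaign({2: ["B"], 3: ["C"], 4: ["D"]}, ["A"], ["V"], ["H"],
                             backend, data)
        assert state.generation == 4
        with pytest.raises(ActiveLearningError, match="final generation"):
            run_generation(state, backend, ["E"], data)

    def test_empty_initial_training_rejected(self):
        backend, data, _ = _fake_setup()
        with pytest.raises(ActiveLearningError, match="empty"):
            start_campaign([], ["V"], ["H"], backend, data)

    def test_multiset_contract(self):
        ms = TrainingMultiset()
        ms.add("a")
        ms.add("a")
        ms.add("b")
        assert ms.total_count == 3 and ms.unique_count == 2
        with pytest.raises(ActiveLearningError):
            ms.add("c", copies=0)


# --------------------------------------------------------------------------
# reference backend contract
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def noiseless_frame():
    cfg = tiny_config(seed=6, intensity_noise=0.0)
    cohort = SyntheticCohort(cfg)
    pid = cohort.participant_ids[0]
    label, intensity = cohort.frame(pid, "closed", 0)
    return label, intensity


class TestReferenceBackend:
    def test_deterministic(self, noiseless_frame):
        label, intensity = noiseless_frame
        maps = []
        for _ in range(2):
            b = reference_backend(seed=0)
            b.fit([(intensity, label, 1)])
            maps.append(b.predict_probabilities(intensity).probs)
        assert np.array_equal(maps[0], maps[1])

    def test_recovers_training_distribution(self, noiseless_frame):
        label, intensity = noiseless_frame
        b = reference_backend(seed=0)
        b.fit([(intensity, label, 1)])
        pred = b.predict_probabilities(intensity).argmax_labels()
        assert dice(label, pred)["mean"] > 0.95

    def test_entropy_decreases_with_training_mass(self, noiseless_frame):
        label, intensity = noiseless_frame
        scores = []
        for mult in (1, 5, 25):
            b = reference_backend(seed=0)
            b.fit([(intensity, label, mult)])
            scores.append(image_score(b.predict_probabilities(intensity)).score)
        assert scores[0] > scores[1] > scores[2]

    def test_fit_errors(self, noiseless_frame):
        label, intensity = noiseless_frame
        b = AtlasIntensityBackend()
        with pytest.raises(ActiveLearningError, match="empty"):
            b.fit([])
        with pytest.raises(ActiveLearningError, match="fit before"):
            b.predict_probabilities(intensity)
        b.fit([(intensity, label, 1)])
        with pytest.raises(ActiveLearningError, match="shape"):
            b.predict_probabilities(np.zeros((2, 2, 2)))
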