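"""Voting rules, cascade routing, training harness and evaluation metrics."""

import numpy as np
import pytest

from adcascade import nn
from adcascade.cascade import (
    NEEDS_EEG,
    SubjectRecord,
    TrainConfig,
    classify_subject,
    evaluate,
    split_subjects,
    train_stage,
    vote_stage1,
    vote_stage2,
)


def scores_with_votes(n, k, spread=0.4):
    """n two-class score rows of which exactly k vote for class 1."""
    scores = np.full((n, 2), 0.5)
    scores[:k, 1] += spread
    scores[:k, 0] -= spread
    scores[k:, 0] += spread
    scores[k:, 1] -= spread
    return scores


class StubModel:
    """Reads the vote off the first element of each clip/epoch (in [0, 1])."""

    def predict_proba(self, X):
        p = np.clip(np.asarray(X)[:, 0, 0, 0].astype(float), 0.0, 1.0)
        return np.stack([1.0 - p, p], axis=1)


def make_subject(label, clip_votes, epoch_votes=None, sid="s"):
    clips = np.zeros((len(clip_votes), 3, 4, 2), dtype=np.float32)
    clips[:, 0, 0, 0] = clip_votes
    epochs = None
    if epoch_votes is not None:
        epochs = np.zeros((len(epoch_votes), 3, 4, 2), dtype=np.float32)
        epochs[:, 0, 0, 0] = epoch_votes
    return SubjectRecord(subject_id=sid, label=label, gait_clips=clips, eeg_epochs=epochs)


class TestVoting:
    def test_12_of_20_clips_is_patient(self):
        frac, decision = vote_stage1(scores_with_votes(20, 12))
        assert frac == pytest.approx(0.60)
        assert decision == "PATIENT"

    def test_exactly_half_is_hc(self):
        frac, decision = vote_stage1(scores_with_votes(20, 10))
        assert frac == pytest.approx(0.50)
        assert decision == "HC"

    def test_zero_patient_votes_is_hc(self):
        assert vote_stage1(scores_with_votes(13, 0))[1] == "HC"

    def test_empty_clip_set_rejected(self):
        with pytest.raises(ValueError):
            vote_stage1(np.zeros((0, 2)))

    def test_80_of_120_epochs_is_ad(self):
        frac, decision = vote_stage2(scores_with_votes(120, 80))
        assert frac == pytest.approx(80 / 120)
        assert decision == "AD"

    def test_unanimous_mci(self):
        assert vote_stage2(scores_with_votes(120, 0))[1] == "MCI"

    def test_tie_broken_by_summed_scores(self):
        scores = scores_with_votes(120, 60)
        scores[0, 1] += 0.05  # nudge total AD confidence up without a new vote
        assert vote_stage2(scores)[1] == "AD"
        scores[0, 1] -= 0.10
        assert vote_stage2(scores)[1] == "MCI"

    def test_voting_invariant_to_ordering(self, rng):
        scores = rng.random((31, 2))
        perm = rng.permutation(31)
        assert vote_stage1(scores) == vote_stage1(scores[perm])
        assert vote_stage2(scores) == vote_stage2(scores[perm])

    def test_flipping_one_vote_to_patient_is_monotone(self, rng):
        for n in range(1, 12):
            for k in range(n):
                before = vote_stage1(scores_with_votes(n, k))[1]
                after = vote_stage1(scores_with_votes(n, k + 1))[1]
                assert not (before == "PATIENT" and after == "HC")


class TestCascadeRouting:
    def test_all_hc_clips_skips_stage2(self):
        subject = make_subject("HC", clip_votes=[0.1] * 9)
        pred = classify_subject(subject, StubModel(), StubModel())
        assert pred.final == "HC"
        assert pred.stage2_ad_fraction is None

    def test_patient_then_ad(self):
        subject = make_subject("AD", clip_votes=[0.9] * 6 + [0.1] * 4,
                               epoch_votes=[0.9] * 7 + [0.1] * 3)
        pred = classify_subject(subject, StubModel(), StubModel())
        assert pred.stage1_patient_fraction == pytest.approx(0.6)
        assert pred.stage2_ad_fraction == pytest.approx(0.7)
        assert pred.final == "AD"

    def test_patient_without_eeg_is_needs_eeg(self):
        subject = make_subject("MCI", clip_votes=[0.9] * 6 + [0.1] * 4)
        pred = classify_subject(subject, StubModel(), StubModel())
        assert pred.final == NEEDS_EEG

    def test_final_hc_iff_stage1_hc(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 15))
            votes = rng.random(n).round()
            subject = make_subject("MCI", clip_votes=votes, epoch_votes=[0.9] * 4)
            pred = classify_subject(subject, StubModel(), StubModel())
            if votes.mean() > 0.5:
                assert pred.final in ("MCI", "AD")
            else:
                assert pred.final == "HC"


class ToyModel:
    """Minimal trainable model: flatten → affine; exercises the harness."""

    class _Cfg:
        num_classes = 2

    config = _Cfg()

    def __init__(self, in_dim, seed=0):
        self.flatten = nn.Flatten()
        self.fc = nn.Linear(in_dim, 2, np.random.default_rng(seed))

    def params(self):
        return self.fc.params()

    def forward(self, x, train=False):
        return self.fc.forward(self.flatten.forward(x))

    def backward(self, g):
        self.flatten.backward(self.fc.backward(g))

    def predict_proba(self, X):
        return nn.softmax(self.forward(np.asarray(X, dtype=np.float32)))


class TestTraining:
    def _toy_data(self, rng, n=64):
        X = rng.standard_normal((n, 3, 2, 2)).astype(np.float32)
        y = (X[:, 0, 0, 0] > 0).astype(int)
        X[:, 0, 0, 0] += 2.0 * (2 * y - 1)  # make it linearly separable
        return X, y

    def test_single_epoch_history_length(self, rng):
        X, y = self._toy_data(rng)
        history = train_stage(ToyModel(12), X, y, TrainConfig.gait(epochs=1, seed=0))
        assert len(history) == 1
        assert set(history[0]) == {"epoch", "loss", "accuracy"}

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = self._toy_data(rng, n=128)
        history = train_stage(
            ToyModel(12), X, y,
            TrainConfig.gait(learning_rate=0.01, epochs=10, batch_size=32, seed=0),
        )
        assert history[-1]["loss"] < history[0]["loss"]
        assert history[-1]["accuracy"] > 0.9

    def test_identical_seeds_identical_final_loss(self, rng):
        X, y = self._toy_data(rng)
        h1 = train_stage(ToyModel(12, seed=5), X, y, TrainConfig.eeg(epochs=3, seed=9))
        h2 = train_stage(ToyModel(12, seed=5), X, y, TrainConfig.eeg(epochs=3, seed=9))
        assert h1 == h2

    def test_label_outside_class_set_rejected(self, rng):
        X, _ = self._toy_data(rng, n=8)
        with pytest.raises(ValueError, match="class range"):
            train_stage(ToyModel(12), X, np.array([0, 1, 2, 0, 1, 0, 1, 0]),
                        TrainConfig.gait(epochs=1))

    def test_default_configs_match_training_protocol(self):
        gait = TrainConfig.gait()
        eeg = TrainConfig.eeg()
        assert (gait.learning_rate, gait.epochs, gait.batch_size) == (0.05, 50, 64)
        assert (eeg.learning_rate, eeg.epochs, eeg.batch_size) == (0.005, 70, 64)


class TestSplitAndEvaluate:
    def _cohort(self):
        subjects = []
        for i in range(8):
            subjects.append(make_subject("HC", [0.1] * 5, sid=f"hc{i}"))
        for i in range(8):
            subjects.append(make_subject("MCI", [0.9] * 5, [0.1] * 4, sid=f"mci{i}"))
        for i in range(4):
            subjects.append(make_subject("AD", [0.9] * 5, [0.9] * 4, sid=f"ad{i}"))
        return subjects

    def test_subject_split_is_stratified_disjoint_exhaustive(self):
        subjects = self._cohort()
        train, test = split_subjects(subjects, 0.75, seed=0)
        assert len(train) + len(test) == len(subjects)
        assert {s.subject_id for s in train} & {s.subject_id for s in test} == set()
        assert sum(s.label == "HC" for s in train) == 6
        assert sum(s.label == "AD" for s in train) == 3

    def test_perfect_predictor_scores_one_everywhere(self):
        metrics = evaluate(self._cohort(), StubModel(), StubModel())
        for key in ("clip_accuracy", "epoch_accuracy", "stage1_subject_accuracy",
                    "stage2_subject_accuracy", "threeway_subject_accuracy"):
            assert metrics[key] == 1.0
        assert metrics["needs_eeg"] == 0

    def test_all_hc_predictions_on_balanced_set_score_one_third(self):
        subjects = []
        for i, label in enumerate(["HC", "MCI", "AD"] * 2):
            subjects.append(make_subject(label, [0.1] * 5, [0.5] * 2, sid=f"s{i}"))
        metrics = evaluate(subjects, StubModel(), StubModel())
        assert metrics["threeway_subject_accuracy"] == pytest.approx(1 / 3)

    def test_threeway_accuracy_equals_confusion_trace(self):
        metrics = evaluate(self._cohort(), StubModel(), StubModel())
        conf = metrics["confusion"]
        assert metrics["threeway_subject_accuracy"] == pytest.approx(
            np.trace(conf) / conf.sum()
        )

    def test_needs_eeg_counted_not_silently_hc(self):
        subjects = [make_subject("MCI", [0.9] * 5, sid="m0")]
        metrics = evaluate(subjects, StubModel(), StubModel())
        assert metrics["needs_eeg"] == 1
        assert metrics["confusion"].sum() == 0
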