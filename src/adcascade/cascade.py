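"""Two-stage subject-level decision logic, training and evaluation.

Stage 1 votes over a subject's gait clips: if *strictly more than half* of
the clips are classified as patient, the subject proceeds to stage 2,
otherwise the final label is HC.  Stage 2 votes the same way over the
subject's EEG epochs to decide MCI vs AD.  A patient-voted subject without
EEG yields an explicit needs-EEG outcome rather than a silent fallback.

Class index conventions: stage 1 scores are (HC, PATIENT); stage 2 scores
are (MCI, AD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn

logger = logging.getLogger(__name__)

LABELS = ("HC", "MCI", "AD")
NEEDS_EEG = "NEEDS_EEG"

STAGE1_CLASSES = ("HC", "PATIENT")
STAGE2_CLASSES = ("MCI", "AD")


@dataclass
class SubjectRecord:
    """Preprocessed per-subject data entering the cascade.

    ``gait_clips`` is (N_g, 3, T, V); ``eeg_epochs`` is (N_e, 3, C, 2T) or
    None — healthy controls carry no EEG.
    """

    subject_id: str
    label: str
    gait_clips: np.ndarray
    eeg_epochs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.gait_clips is None or len(self.gait_clips) == 0:
            raise ValueError(f"subject {self.subject_id!r} has no gait clips")


@dataclass(frozen=True)
class CascadePrediction:
    """Vote fractions and the final label for one subject."""

    stage1_patient_fraction: float
    stage2_ad_fraction: float | None
    final: str  # HC / MCI / AD / NEEDS_EEG


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one stage (SGD with momentum)."""

    stage: str  # "gait" | "eeg"
    learning_rate: float
    epochs: int
    batch_size: int = 64
    momentum: float = 0.9
    seed: int = 0
    class_weights: tuple[float, ...] | None = None

    @classmethod
    def gait(cls, **overrides) -> "TrainConfig":
        base = dict(stage="gait", learning_rate=0.05, epochs=50, batch_size=64)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def eeg(cls, **overrides) -> "TrainConfig":
        base = dict(stage="eeg", learning_rate=0.005, epochs=70, batch_size=64)
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------


def vote_stage1(clip_scores: np.ndarray) -> tuple[float, str]:
    """Majority vote over clips: PATIENT iff strictly more than half vote patient."""
    scores = np.asarray(clip_scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] == 0 or scores.shape[1] != 2:
        raise ValueError(f"clip scores must be (N >= 1, 2), got {scores.shape}")
    patient_votes = int((scores.argmax(axis=1) == 1).sum())
    fraction = patient_votes / scores.shape[0]
    return fraction, ("PATIENT" if fraction > 0.5 else "HC")


def vote_stage2(epoch_scores: np.ndarray) -> tuple[float, str]:
    """Majority vote over epochs: MCI vs AD.

    An exact tie (possible only for even epoch counts) is broken by the
    higher summed softmax score, which is deterministic and uses the
    available confidence without a label bias.
    """
    scores = np.asarray(epoch_scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] == 0 or scores.shape[1] != 2:
        raise ValueError(f"epoch scores must be (N >= 1, 2), got {scores.shape}")
    ad_votes = int((scores.argmax(axis=1) == 1).sum())
    n = scores.shape[0]
    fraction = ad_votes / n
    if ad_votes * 2 > n:
        return fraction, "AD"
    if ad_votes * 2 < n:
        return fraction, "MCI"
    sums = scores.sum(axis=0)
    return fraction, ("AD" if sums[1] > sums[0] else "MCI")


def classify_subject(subject: SubjectRecord, stage1_model, stage2_model) -> CascadePrediction:
    """Run the cascade for one subject.

    EEG is consulted only when stage 1 votes PATIENT; a PATIENT vote with no
    EEG available produces the explicit ``NEEDS_EEG`` outcome.
    """
    clip_scores = stage1_model.predict_proba(np.ascontiguousarray(subject.gait_clips))
    frac1, decision1 = vote_stage1(clip_scores)
    if decision1 == "HC":
        return CascadePrediction(frac1, None, "HC")
    if subject.eeg_epochs is None or len(subject.eeg_epochs) == 0:
        return CascadePrediction(frac1, None, NEEDS_EEG)
    epoch_scores = stage2_model.predict_proba(subject.eeg_epochs)
    frac2, decision2 = vote_stage2(epoch_scores)
    return CascadePrediction(frac1, frac2, decision2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_stage(
    model,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> list[dict]:
    """Minimize cross-entropy with minibatch SGD; returns per-epoch history.

    Seed-reproducible on a single worker: the shuffling stream is derived
    from ``config.seed`` and the model's dropout stream from its own seed.
    """
    y = np.asarray(y)
    n_classes = model.config.num_classes
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(
            f"labels outside the stage's class range [0, {n_classes}): "
            f"found {sorted(set(np.unique(y)))}"
        )
    weights = (
        np.asarray(config.class_weights, dtype=np.float64)
        if config.class_weights is not None
        else None
    )
    opt = nn.SGD(model.params(), lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(config.seed)
    n = len(X)
    history: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = np.ascontiguousarray(X[idx])
            yb = y[idx]
            opt.zero_grad()
            logits = model.forward(xb, train=True)
            loss, probs, grad = nn.softmax_cross_entropy(logits, yb, weights)
            model.backward(grad)
            opt.step()
            total_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
        history.append(
            {"epoch": epoch, "loss": total_loss / n, "accuracy": correct / n}
        )
        logger.info(
            "%s epoch %d/%d: loss %.4f, accuracy %.3f",
            config.stage, epoch + 1, config.epochs,
            history[-1]["loss"], history[-1]["accuracy"],
        )
    return history


def split_subjects(
    subjects: Sequence[SubjectRecord],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Subject-wise stratified random split (per-label proportions preserved)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[SubjectRecord] = []
    test: list[SubjectRecord] = []
    for label in LABELS:
        group = [s for s in subjects if s.label == label]
        if not group:
            continue
        perm = rng.permutation(len(group))
        n_train = int(train_fraction * len(group) + 0.5)
        for j, k in enumerate(perm):
            (train if j < n_train else test).append(group[k])
    return train, test


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(subjects: Sequence[SubjectRecord], stage1_model, stage2_model) -> dict:
    """Clip/epoch-level and subject-level metrics plus the 3×3 confusion matrix.

    ``stage2_subject_accuracy`` measures stage 2 in isolation (majority vote
    over every true patient's epochs), independent of whether stage 1 routed
    the subject there.  ``confusion`` rows are true labels, columns predicted
    labels, in HC/MCI/AD order; needs-EEG outcomes are counted separately and
    excluded from the matrix.
    """
    clip_correct = clip_total = 0
    epoch_correct = epoch_total = 0
    stage1_correct = 0
    stage2_correct = stage2_total = 0
    threeway_correct = 0
    needs_eeg = 0
    confusion = np.zeros((3, 3), dtype=int)
    label_to_idx = {l: i for i, l in enumerate(LABELS)}
    predictions: dict[str, CascadePrediction] = {}

    for subject in subjects:
        binary_truth = 0 if subject.label == "HC" else 1
        clip_scores = stage1_model.predict_proba(np.ascontiguousarray(subject.gait_clips))
        clip_correct += int((clip_scores.argmax(axis=1) == binary_truth).sum())
        clip_total += len(clip_scores)
        frac1, decision1 = vote_stage1(clip_scores)
        stage1_correct += int((decision1 == "PATIENT") == bool(binary_truth))

        if subject.label in STAGE2_CLASSES and subject.eeg_epochs is not None:
            truth2 = STAGE2_CLASSES.index(subject.label)
            epoch_scores = stage2_model.predict_proba(subject.eeg_epochs)
            epoch_correct += int((epoch_scores.argmax(axis=1) == truth2).sum())
            epoch_total += len(epoch_scores)
            _, decision2 = vote_stage2(epoch_scores)
            stage2_correct += int(decision2 == subject.label)
            stage2_total += 1

        pred = classify_subject(subject, stage1_model, stage2_model)
        predictions[subject.subject_id] = pred
        if pred.final == NEEDS_EEG:
            needs_eeg += 1
        else:
            confusion[label_to_idx[subject.label], label_to_idx[pred.final]] += 1
            threeway_correct += int(pred.final == subject.label)

    n = len(subjects)
    return {
        "n_subjects": n,
        "clip_accuracy": clip_correct / clip_total if clip_total else float("nan"),
        "epoch_accuracy": epoch_correct / epoch_total if epoch_total else float("nan"),
        "stage1_subject_accuracy": stage1_correct / n if n else float("nan"),
        "stage2_subject_accuracy": (
            stage2_correct / stage2_total if stage2_total else float("nan")
        ),
        "n_stage2_subjects": stage2_total,
        "threeway_subject_accuracy": threeway_correct / n if n else float("nan"),
        "needs_eeg": needs_eeg,
        "confusion": confusion,
        "predictions": predictions,
    }
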