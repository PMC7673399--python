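"""Run configuration, dataset readers and the end-to-end pipeline.

``run_pipeline`` executes simulate → preprocess → train stage 1 → train
stage 2 → cascade evaluation, writing metrics, confusion matrix, training
logs and model checkpoints to the output directory, fully reproducible from
the configuration and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import eeg as eeg_mod
from . import gait as gait_mod
from .astgcn import AstGcn, AstGcnConfig
from .cascade import SubjectRecord, TrainConfig, evaluate, split_subjects, train_stage
from .graph import keypoint_graph, kinect_v2_graph, partition_adjacency
from .simulate import EEGSimParams, GaitSimParams, SimulatedSubject, generate_cohort
from .stcnn import StCnn, StCnnConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs; YAML-serializable."""

    out_dir: str = "run"
    seed: int = 0
    # cohort
    n_hc: int = 35
    n_mci: int = 35
    n_ad: int = 17
    effect: float = 1.0
    gait_frames: int = 300
    gait_frame_rate: float = 30.0
    eeg_duration_s: float = 60.0
    eeg_sampling_rate: float = 5000.0
    # gait preprocessing
    rotation_deg: float = -27.0
    clip_window: int = 60
    clip_stride: int = 3
    use_keypoints: bool = True
    # EEG preprocessing
    eeg_target_rate: float = 250.0
    eeg_window: int = 256
    epochs_per_subject: int = 120
    eeg_split: str = "subject"  # "subject" | "epoch"
    # models
    gait_model: str = "default"  # "default" | "small"
    attention: str = ""  # empty = the preset's default placement
    # training
    train_fraction: float = 0.75
    gait_lr: float = 0.05
    gait_epochs: int = 50
    gait_batch: int = 64
    eeg_lr: float = 0.005
    eeg_epochs: int = 70
    eeg_batch: int = 64

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dataset reading
# ---------------------------------------------------------------------------


def read_skeleton_dataset(root: str | Path) -> tuple[list[gait_mod.SkeletonRecord], pd.DataFrame | None]:
    """Read every skeleton CSV / JSON-lines file under ``root``.

    Malformed files are skipped with a per-file warning; only front-view
    records are returned.  A ``manifest.tsv`` beside the data is read when
    present.
    """
    root = Path(root)
    records = []
    files = sorted(list(root.glob("*.csv")) + list(root.glob("*.jsonl")))
    if not files:
        logger.warning("no skeleton files found under %s", root)
    for path in files:
        try:
            if path.suffix == ".csv":
                rec = gait_mod.read_skeleton_csv(path)
            else:
                rec = gait_mod.read_skeleton_jsonl(path)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        if rec.view != "front":
            continue
        records.append(rec)
    manifest_path = root.parent / "manifest.tsv"
    manifest = gait_mod.read_manifest(manifest_path) if manifest_path.exists() else None
    return records, manifest


# ---------------------------------------------------------------------------
# preprocessing raw simulated subjects into cascade inputs
# ---------------------------------------------------------------------------


def preprocess_gait_record(
    record: gait_mod.SkeletonRecord,
    config: RunConfig,
    label: str | None = None,
) -> list[gait_mod.GaitClip]:
    rec = gait_mod.rotate_record(record, config.rotation_deg)
    rec = gait_mod.center_record(rec, root_index=0)
    clips = gait_mod.extract_clips(rec, config.clip_window, config.clip_stride, label=label)
    if config.use_keypoints:
        subset = gait_mod.JointSubset()
        clips = [gait_mod.select_joints(c, subset) for c in clips]
    return clips


def preprocess_eeg_records(
    open_record: eeg_mod.EEGRecord,
    closed_record: eeg_mod.EEGRecord,
    config: RunConfig,
    label: str | None = None,
) -> list[eeg_mod.EEGEpoch]:
    prepared = []
    for rec in (open_record, closed_record):
        rec = eeg_mod.rereference_common_average(rec)
        rec = eeg_mod.downsample(rec, config.eeg_target_rate)
        prepared.append(rec)
    return eeg_mod.extract_epochs(
        prepared[0], prepared[1],
        window=config.eeg_window,
        epochs_per_subject=config.epochs_per_subject,
        label=label,
    )


def build_subject_records(
    cohort: list[SimulatedSubject], config: RunConfig, release_raw: bool = False
) -> list[SubjectRecord]:
    """Preprocess every simulated subject into cascade-ready arrays.

    ``release_raw=True`` drops each subject's raw records once processed,
    which keeps peak memory near one subject's worth of raw EEG.
    """
    out = []
    for subj in cohort:
        clips = preprocess_gait_record(subj.gait, config, label=subj.group)
        epochs = None
        if subj.has_eeg:
            epoch_list = preprocess_eeg_records(subj.eeg_open, subj.eeg_closed, config, label=subj.group)
            epochs = eeg_mod.epochs_to_array(epoch_list)
        if release_raw:
            subj.eeg_open = None
            subj.eeg_closed = None
        out.append(
            SubjectRecord(
                subject_id=subj.subject_id,
                label=subj.group,
                gait_clips=gait_mod.clips_to_array(clips),
                eeg_epochs=epochs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the end-to-end pipeline
# ---------------------------------------------------------------------------


def _sim_params(config: RunConfig) -> tuple[GaitSimParams, EEGSimParams]:
    gait_params = GaitSimParams(
        frame_rate=config.gait_frame_rate,
        frames_per_record=config.gait_frames,
        subjects_per_group={"HC": config.n_hc, "MCI": config.n_mci, "AD": config.n_ad},
        seed=config.seed,
    ).scaled(config.effect)
    eeg_params = EEGSimParams(
        sampling_rate=config.eeg_sampling_rate,
        duration_s=config.eeg_duration_s,
        subjects_per_group={"MCI": config.n_mci, "AD": config.n_ad},
        seed=config.seed + 1,
    ).scaled(config.effect)
    return gait_params, eeg_params


def _gait_model_config(config: RunConfig) -> AstGcnConfig:
    if config.gait_model == "small":
        cfg = AstGcnConfig.small()
    elif config.gait_model == "default":
        cfg = AstGcnConfig()
    else:
        raise ValueError(f"unknown gait model preset {config.gait_model!r}")
    if config.attention:
        cfg = dataclasses.replace(cfg, attention=config.attention)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, preprocess, train both stages, evaluate the cascade.

    Returns the metrics dict; writes metrics.json, confusion.csv, manifest,
    per-stage training histories and model checkpoints under ``out_dir``.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    timer = time.time()
    stage = "simulate"
    try:
        gait_params, eeg_params = _sim_params(config)
        cohort, manifest = generate_cohort(gait_params, eeg_params)
        gait_mod.write_manifest(manifest, out / "manifest.tsv")
        logger.info("simulate: %.1fs", time.time() - timer)

        stage = "preprocess"
        timer = time.time()
        subjects = build_subject_records(cohort, config, release_raw=True)
        del cohort
        logger.info("preprocess: %.1fs", time.time() - timer)

        stage = "train-gait"
        timer = time.time()
        graph = keypoint_graph() if config.use_keypoints else kinect_v2_graph()
        adjacency = partition_adjacency(graph)
        train_subjects, test_subjects = split_subjects(
            subjects, config.train_fraction, seed=config.seed
        )
        X1 = np.concatenate([s.gait_clips for s in train_subjects])
        y1 = np.concatenate([
            np.full(len(s.gait_clips), 0 if s.label == "HC" else 1) for s in train_subjects
        ])
        stage1 = AstGcn(_gait_model_config(config), adjacency, seed=config.seed)
        gait_history = train_stage(
            stage1, X1, y1,
            TrainConfig.gait(
                learning_rate=config.gait_lr, epochs=config.gait_epochs,
                batch_size=config.gait_batch, seed=config.seed,
            ),
        )

        logger.info("train-gait: %.1fs", time.time() - timer)

        stage = "train-eeg"
        timer = time.time()
        if config.eeg_split == "subject":
            eeg_train = [s for s in train_subjects if s.eeg_epochs is not None]
            X2 = np.concatenate([s.eeg_epochs for s in eeg_train])
            y2 = np.concatenate([
                np.full(len(s.eeg_epochs), cascade_mod.STAGE2_CLASSES.index(s.label))
                for s in eeg_train
            ])
        elif config.eeg_split == "epoch":
            # protocol-style pooled split: every patient's epochs, 75% at random
            pool = [s for s in subjects if s.eeg_epochs is not None]
            # concatenate single planes, then broadcast back to 3 depth copies
            planes = np.concatenate([s.eeg_epochs[:, 0] for s in pool])
            Xall = np.broadcast_to(planes[:, None], (len(planes), 3) + planes.shape[1:])
            yall = np.concatenate([
                np.full(len(s.eeg_epochs), cascade_mod.STAGE2_CLASSES.index(s.label))
                for s in pool
            ])
            perm = np.random.default_rng(config.seed + 2).permutation(len(Xall))
            n_train = int(round(config.train_fraction * len(Xall)))
            X2, y2 = Xall[perm[:n_train]], yall[perm[:n_train]]
        else:
            raise ValueError(f"unknown eeg split {config.eeg_split!r}")
        stcnn_cfg = StCnnConfig(time_points=2 * config.eeg_window)
        stage2 = StCnn(stcnn_cfg, seed=config.seed)
        eeg_history = train_stage(
            stage2, X2, y2,
            TrainConfig.eeg(
                learning_rate=config.eeg_lr, epochs=config.eeg_epochs,
                batch_size=config.eeg_batch, seed=config.seed,
            ),
        )

        logger.info("train-eeg: %.1fs", time.time() - timer)

        stage = "evaluate"
        metrics = evaluate(test_subjects, stage1, stage2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage1.save(out / "stage1_astgcn.npz")
    stage2.save(out / "stage2_stcnn.npz")
    _write_history(gait_history, out / "gait_history.jsonl")
    _write_history(eeg_history, out / "eeg_history.jsonl")
    np.savetxt(out / "confusion.csv", metrics["confusion"], fmt="%d", delimiter=",",
               header=",".join(cascade_mod.LABELS), comments="")
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in metrics.items()
        if k != "predictions"
    }
    serializable["predictions"] = {
        sid: dataclasses.asdict(pred) for sid, pred in metrics["predictions"].items()
    }
    serializable["test_subjects"] = [s.subject_id for s in test_subjects]
    with open(out / "metrics.json", "w") as fh:
        json.dump(serializable, fh, indent=2)
    return metrics


def _write_history(history: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for row in history:
            fh.write(json.dumps(row) + "\n")


# ---------------------------------------------------------------------------
# on-disk stores for the step-by-step CLI
# ---------------------------------------------------------------------------


def save_record_h5(record: eeg_mod.EEGRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=record.data, compression="gzip")
        f.create_dataset("channel_labels", data=list(record.channel_labels),
                         dtype=h5py.string_dtype())
        f.attrs["subject_id"] = record.subject_id
        f.attrs["condition"] = record.condition
        f.attrs["sampling_rate"] = record.sampling_rate


def load_record_h5(path: str | Path) -> eeg_mod.EEGRecord:
    with h5py.File(path, "r") as f:
        return eeg_mod.EEGRecord(
            subject_id=str(f.attrs["subject_id"]),
            condition=str(f.attrs["condition"]),
            channel_labels=tuple(
                s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][...]
            ),
            sampling_rate=float(f.attrs["sampling_rate"]),
            data=f["data"][...],
        )


def save_clips_h5(subjects: list[SubjectRecord], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype()
        f.create_dataset(
            "clips",
            data=np.concatenate([s.gait_clips for s in subjects]).astype(np.float32),
            compression="gzip",
        )
        sids, labels = [], []
        for s in subjects:
            sids += [s.subject_id] * len(s.gait_clips)
            labels += [s.label] * len(s.gait_clips)
        f.create_dataset("subject_id", data=sids, dtype=str_dt)
        f.create_dataset("label", data=labels, dtype=str_dt)


def load_clips_h5(path: str | Path) -> list[SubjectRecord]:
    with h5py.File(path, "r") as f:
        clips = f["clips"][...]
        sids = [s.decode() if isinstance(s, bytes) else s for s in f["subject_id"][...]]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["label"][...]]
    subjects = []
    order = list(dict.fromkeys(sids))
    arr_sids = np.array(sids)
    for sid in order:
        mask = arr_sids == sid
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=labels[int(np.nonzero(mask)[0][0])],
                gait_clips=clips[mask],
            )
        )
    return subjects
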