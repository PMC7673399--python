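"""EEG data model and preprocessing.

Resting EEG is recorded from 64 electrodes (62 scalp channels plus the Ref
and Gnd electrodes) at 5,000 Hz for two conditions, eyes open and eyes
closed.  Preprocessing: drop Ref/Gnd and re-reference every remaining channel
to the common average, downsample to 250 Hz with an anti-alias FIR filter,
cut non-overlapping one-second (256-sample) windows, concatenate the i-th
eyes-open window with the i-th eyes-closed window along time, and replicate
the resulting C × 2T matrix across three depth planes for the convolutional
classifier.  Artifact removal is assumed to have happened upstream; this
module validates amplitude ranges only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import scipy.signal

logger = logging.getLogger(__name__)

CONDITIONS = ("eyes_open", "eyes_closed")

#: 64 labels of the extended 10-20 montage: 62 scalp electrodes + Ref + Gnd.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT7", "FC3", "FC4", "FT8", "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "Ref", "Gnd",
)

REFERENCE_LABELS = ("Ref", "Gnd")


@dataclass(frozen=True)
class EEGRecord:
    """A multichannel recording: ``data`` is (channels, samples) in microvolts."""

    subject_id: str
    condition: str
    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(f"data must be (channels, samples), got {data.shape}")
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels but {data.shape[0]} data channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])


@dataclass(frozen=True)
class EEGEpoch:
    """One classifier input: ``data`` is (3, C, 2T), three identical planes."""

    data: np.ndarray
    subject_id: str
    label: str | None = None

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_times(self) -> int:
        return int(self.data.shape[2])


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def rereference_common_average(
    record: EEGRecord,
    reference_labels: tuple[str, ...] = REFERENCE_LABELS,
) -> EEGRecord:
    """Drop the Ref/Gnd channels and subtract the mean of the rest per sample.

    If the reference channels are already gone, the data is only re-averaged,
    which makes the operation idempotent.
    """
    labels = list(record.channel_labels)
    present = [l for l in reference_labels if l in labels]
    if record.n_channels == 64 and not present:
        raise ValueError(
            f"none of the reference labels {reference_labels} found in a 64-channel record"
        )
    keep = [i for i, l in enumerate(labels) if l not in reference_labels]
    data = record.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return replace(
        record,
        data=data,
        channel_labels=tuple(labels[i] for i in keep),
    )


def downsample(record: EEGRecord, target_rate: float = 250.0) -> EEGRecord:
    """Anti-alias filter and decimate to ``target_rate`` (integer factor only).

    Decimation is staged in factors ≤ 10 (5,000 → 250 Hz runs as 5 × 4) with
    zero-phase FIR filtering, so band power below the new Nyquist frequency
    is preserved without phase distortion.
    """
    factor = record.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {record.sampling_rate} not an integer multiple of {target_rate}"
        )
    q = int(round(factor))
    if q == 1:
        return record
    data = record.data
    for stage in _decimation_stages(q):
        data = scipy.signal.decimate(data, stage, ftype="fir", zero_phase=True, axis=1)
    return replace(record, data=data, sampling_rate=float(target_rate))


def _decimation_stages(q: int) -> list[int]:
    stages = []
    while q > 10:
        for p in (10, 8, 7, 5, 4, 3, 2):
            if q % p == 0:
                stages.append(p)
                q //= p
                break
        else:
            raise ValueError(f"cannot factor decimation ratio {q}")
    stages.append(q)
    return stages


def extract_epochs(
    open_record: EEGRecord,
    closed_record: EEGRecord,
    window: int = 256,
    epochs_per_subject: int = 120,
    label: str | None = None,
    selection: str = "first",
    seed: int | None = None,
) -> list[EEGEpoch]:
    """Cut index-aligned eyes-open / eyes-closed windows into (3, C, 2·window) epochs.

    The i-th non-overlapping window of the eyes-open record is concatenated
    along time with the i-th window of the eyes-closed record, then the
    C × 2·window matrix is replicated across three depth planes.  Exactly
    ``epochs_per_subject`` epochs are emitted; ``selection='first'`` takes
    the first pairs in temporal order, ``selection='random'`` a seeded draw.
    """
    if open_record.condition != "eyes_open" or closed_record.condition != "eyes_closed":
        raise ValueError("records must be (eyes_open, eyes_closed), in that order")
    if open_record.channel_labels != closed_record.channel_labels:
        raise ValueError("channel order differs between the two conditions")
    if abs(open_record.sampling_rate - closed_record.sampling_rate) > 1e-9:
        raise ValueError("sampling rates differ between the two conditions")
    available = min(open_record.n_samples, closed_record.n_samples) // window
    if available < epochs_per_subject:
        raise ValueError(
            f"subject {open_record.subject_id!r}: only {available} non-overlapping "
            f"window pairs available, {epochs_per_subject} requested"
        )
    if selection == "first":
        picks = np.arange(epochs_per_subject)
    elif selection == "random":
        rng = np.random.default_rng(seed)
        picks = np.sort(rng.choice(available, size=epochs_per_subject, replace=False))
    else:
        raise ValueError(f"unknown selection {selection!r}")
    epochs = []
    for i in picks:
        sl = slice(i * window, (i + 1) * window)
        plane = np.concatenate([open_record.data[:, sl], closed_record.data[:, sl]], axis=1)
        plane = np.ascontiguousarray(plane, dtype=np.float32)
        # three identical depth planes, stored once (stride-0 broadcast view)
        data = np.broadcast_to(plane[None], (3,) + plane.shape)
        epochs.append(EEGEpoch(data=data, subject_id=open_record.subject_id, label=label))
    return epochs


def split_epochs(
    epochs: list[EEGEpoch],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[EEGEpoch], list[EEGEpoch]]:
    """Uniform random epoch-wise partition; train size = round(fraction · N).

    Epoch-wise splitting lets epochs of one subject land on both sides,
    leaking subject identity across the split; prefer a subject-wise split
    when estimating generalization to new patients.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    n = len(epochs)
    if n == 0:
        raise ValueError("no epochs to split")
    n_train = int(round(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [e for i, e in enumerate(epochs) if i in train_idx]
    test = [e for i, e in enumerate(epochs) if i not in train_idx]
    return train, test


def epochs_to_array(epochs: list[EEGEpoch]) -> np.ndarray:
    """Stack epochs into a (N, 3, C, 2T) float32 array.

    The identical depth planes are represented by a stride-0 broadcast view
    (read-only), so the stack costs one plane of memory per epoch; indexing
    a batch out of it materializes that batch only.
    """
    if len(epochs) == 0:
        raise ValueError("no epochs to stack")
    planes = np.stack([np.asarray(e.data[0], dtype=np.float32) for e in epochs])
    return np.broadcast_to(planes[:, None], (len(epochs), 3) + planes.shape[1:])


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------


def save_epochs_h5(epochs: list[EEGEpoch], path: str | Path) -> None:
    """HDF5 epoch store; only one depth plane is stored (they are copies)."""
    with h5py.File(path, "w") as f:
        planes = np.stack([np.asarray(e.data[0], dtype=np.float32) for e in epochs])
        f.create_dataset("plane", data=planes, compression="gzip")
        str_dt = h5py.string_dtype()
        f.create_dataset("subject_id", data=[e.subject_id for e in epochs], dtype=str_dt)
        f.create_dataset(
            "label", data=[e.label if e.label is not None else "" for e in epochs], dtype=str_dt
        )
        f.attrs["depth_planes"] = 3


def load_epochs_h5(path: str | Path) -> list[EEGEpoch]:
    with h5py.File(path, "r") as f:
        planes = f["plane"][...]
        subjects = [s.decode() if isinstance(s, bytes) else s for s in f["subject_id"][...]]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["label"][...]]
        depth = int(f.attrs.get("depth_planes", 3))
    out = []
    for plane, sid, lab in zip(planes, subjects, labels):
        data = np.broadcast_to(plane[None], (depth,) + plane.shape)
        out.append(EEGEpoch(data=data, subject_id=sid, label=lab or None))
    return out


def read_eeg_edf(path: str | Path, subject_id: str, condition: str) -> EEGRecord:
    """Read an EDF(+) recording into an :class:`EEGRecord` (microvolts)."""
    import mne  # heavy import; only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecord(
        subject_id=subject_id,
        condition=condition,
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
    )


def validate_amplitude(record: EEGRecord, max_abs_uv: float = 500.0) -> bool:
    """Flag gross outliers (|amplitude| beyond ``max_abs_uv`` microvolts)."""
    peak = float(np.abs(record.data).max()) if record.n_samples else 0.0
    if peak > max_abs_uv:
        logger.warning(
            "record %s/%s peaks at %.1f uV (> %.0f uV); check artifact removal",
            record.subject_id, record.condition, peak, max_abs_uv,
        )
        return False
    return True
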