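"""Synthetic gait and EEG cohorts with configurable group effect sizes.

The generators emulate the statistical structure the cascade relies on,
so every stage is testable without clinical data:

* **Gait** — a 25-joint walking skeleton: the pelvis translates at the
  sampled walking speed, legs and arms follow sinusoidal flexion
  trajectories at the sampled cadence (left/right in antiphase), and the
  camera tilt is applied so the preprocessing rotation has something to
  undo.  Patient groups walk slower, with shorter stride, lower cadence and
  a markedly reduced *right*-arm swing, which makes the lower-body +
  right-upper-limb joint subset the most informative one.

* **EEG** — 64 labeled channels (62 scalp + flat Ref/Gnd): band-limited
  oscillator sources (theta/alpha/beta) mixed across channels with
  subject-specific random weights, on top of 1/f background noise.  The AD
  group shows EEG slowing relative to MCI: more theta, less alpha.  The
  alpha rhythm is boosted with eyes closed, as in resting recordings.

``cadence_hz`` is the gait-cycle rate (full left + right stride cycles per
second, ≈ 1 Hz for healthy adults); each ankle completes one lift per cycle,
so the dominant frequency of an ankle trajectory equals the sampled cadence.

Every generator is a pure function of its seed; the ``effect`` scale
interpolates patient-group means toward the reference group (0 = identical
groups, 1 = the default separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .eeg import CHANNELS_64, EEGRecord
from .gait import SkeletonRecord, rotation_matrix_x

# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

#: Standing-pose template, meters, world frame (x lateral, y up, z walking
#: direction).  Index layout follows the Kinect V2 scheme in :mod:`.gait`.
TEMPLATE_JOINTS = np.array([
    (0.00, 1.00, 0.00),   # 0  SpineBase
    (0.00, 1.20, 0.00),   # 1  SpineMid
    (0.00, 1.45, 0.00),   # 2  Neck
    (0.00, 1.60, 0.00),   # 3  Head
    (-0.18, 1.40, 0.00),  # 4  ShoulderLeft
    (-0.21, 1.12, 0.00),  # 5  ElbowLeft
    (-0.23, 0.88, 0.00),  # 6  WristLeft
    (-0.24, 0.80, 0.00),  # 7  HandLeft
    (0.18, 1.40, 0.00),   # 8  ShoulderRight
    (0.21, 1.12, 0.00),   # 9  ElbowRight
    (0.23, 0.88, 0.00),   # 10 WristRight
    (0.24, 0.80, 0.00),   # 11 HandRight
    (-0.09, 0.95, 0.00),  # 12 HipLeft
    (-0.10, 0.50, 0.00),  # 13 KneeLeft
    (-0.10, 0.08, 0.00),  # 14 AnkleLeft
    (-0.10, 0.02, 0.12),  # 15 FootLeft
    (0.09, 0.95, 0.00),   # 16 HipRight
    (0.10, 0.50, 0.00),   # 17 KneeRight
    (0.10, 0.08, 0.00),   # 18 AnkleRight
    (0.10, 0.02, 0.12),   # 19 FootRight
    (0.00, 1.40, 0.00),   # 20 SpineShoulder
    (-0.24, 0.72, 0.00),  # 21 HandTipLeft
    (-0.21, 0.78, 0.00),  # 22 ThumbLeft
    (0.24, 0.72, 0.00),   # 23 HandTipRight
    (0.21, 0.78, 0.00),   # 24 ThumbRight
])

_LEFT_LEG = {12: 0.25, 13: 0.60, 14: 1.00, 15: 1.00}
_RIGHT_LEG = {16: 0.25, 17: 0.60, 18: 1.00, 19: 1.00}
_LEFT_ARM = {4: 0.10, 5: 0.50, 6: 1.00, 7: 1.00, 21: 1.00, 22: 1.00}
_RIGHT_ARM = {8: 0.10, 9: 0.50, 10: 1.00, 11: 1.00, 23: 1.00, 24: 1.00}


@dataclass(frozen=True)
class GaitGroupParams:
    """Per-group walking kinematics: (mean, sd) pairs, meters and Hz."""

    cadence_hz: tuple[float, float]
    stride_m: tuple[float, float]       # peak-to-peak sagittal swing amplitude
    speed_mps: tuple[float, float]
    arm_swing_m: tuple[float, float]    # right-arm swing amplitude
    joint_noise_m: float


def _default_gait_groups() -> dict[str, GaitGroupParams]:
    return {
        "HC": GaitGroupParams((1.00, 0.06), (0.32, 0.03), (1.15, 0.08), (0.20, 0.03), 0.008),
        "MCI": GaitGroupParams((0.82, 0.05), (0.22, 0.03), (0.85, 0.07), (0.08, 0.02), 0.010),
        "AD": GaitGroupParams((0.70, 0.05), (0.16, 0.03), (0.65, 0.07), (0.05, 0.015), 0.012),
    }


@dataclass(frozen=True)
class GaitSimParams:
    groups: Mapping[str, GaitGroupParams] = field(default_factory=_default_gait_groups)
    frame_rate: float = 30.0
    frames_per_record: int = 300
    subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 35, "MCI": 35, "AD": 17}
    )
    camera_tilt_deg: float = 27.0
    left_arm_swing_m: float = 0.18
    seed: int = 0

    def scaled(self, effect: float) -> "GaitSimParams":
        """Interpolate patient-group means toward HC (effect 0 = no group differences)."""
        hc = self.groups["HC"]
        groups = {"HC": hc}
        for name, g in self.groups.items():
            if name == "HC":
                continue
            groups[name] = GaitGroupParams(
                cadence_hz=(_lerp(hc.cadence_hz[0], g.cadence_hz[0], effect), g.cadence_hz[1]),
                stride_m=(_lerp(hc.stride_m[0], g.stride_m[0], effect), g.stride_m[1]),
                speed_mps=(_lerp(hc.speed_mps[0], g.speed_mps[0], effect), g.speed_mps[1]),
                arm_swing_m=(_lerp(hc.arm_swing_m[0], g.arm_swing_m[0], effect), g.arm_swing_m[1]),
                joint_noise_m=g.joint_noise_m,
            )
        return replace(self, groups=groups)


def _lerp(a: float, b: float, w: float) -> float:
    return a + w * (b - a)


def _sample(rng: np.random.Generator, mean_sd: tuple[float, float]) -> float:
    return max(mean_sd[0] + mean_sd[1] * rng.standard_normal(), 0.0)


def generate_gait_record(
    params: GaitSimParams,
    group: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> SkeletonRecord:
    """Simulate one front-view walking pass for a subject of ``group``."""
    g = params.groups[group]
    rng = np.random.default_rng(subject_seed)
    cadence = _sample(rng, g.cadence_hz)
    stride = _sample(rng, g.stride_m)
    speed = _sample(rng, g.speed_mps)
    right_arm = _sample(rng, g.arm_swing_m)
    left_arm = params.left_arm_swing_m if g.arm_swing_m[0] > 0 else 0.0

    T = params.frames_per_record
    t = np.arange(T) / params.frame_rate
    phase = 2.0 * np.pi * cadence * t
    data = np.tile(TEMPLATE_JOINTS, (T, 1, 1))

    # forward progression of the whole body
    data[:, :, 2] += (speed * t)[:, None]

    half = 0.5 * stride
    lift = 0.15 * stride
    swing_l, swing_r = np.sin(phase), np.sin(phase + np.pi)
    lift_l = 0.5 * (1.0 - np.cos(phase))
    lift_r = 0.5 * (1.0 - np.cos(phase + np.pi))
    for j, w in _LEFT_LEG.items():
        data[:, j, 2] += w * half * swing_l
        if w == 1.0:
            data[:, j, 1] += lift * lift_l
    for j, w in _RIGHT_LEG.items():
        data[:, j, 2] += w * half * swing_r
        if w == 1.0:
            data[:, j, 1] += lift * lift_r
    # arms swing in antiphase with the ipsilateral leg
    for j, w in _LEFT_ARM.items():
        data[:, j, 2] += w * 0.5 * left_arm * swing_r
    for j, w in _RIGHT_ARM.items():
        data[:, j, 2] += w * 0.5 * right_arm * swing_l

    if g.joint_noise_m > 0:
        data += g.joint_noise_m * rng.standard_normal(data.shape)

    # camera tilt: the preprocessing rotation by -tilt undoes this exactly
    tilt = rotation_matrix_x(params.camera_tilt_deg)
    data = data @ tilt.T

    sid = subject_id if subject_id is not None else f"{group}-{subject_seed}"
    return SkeletonRecord(subject_id=sid, data=data, view="front")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}


@dataclass(frozen=True)
class EEGGroupParams:
    """Per-group band amplitudes, microvolts RMS per channel: (mean, sd)."""

    theta_uv: tuple[float, float]
    alpha_uv: tuple[float, float]
    beta_uv: tuple[float, float]

    def amplitude(self, band: str) -> tuple[float, float]:
        return getattr(self, f"{band}_uv")


def _default_eeg_groups() -> dict[str, EEGGroupParams]:
    # AD shows EEG slowing relative to MCI: theta up, alpha down
    return {
        "MCI": EEGGroupParams((4.0, 0.8), (10.0, 1.5), (3.0, 0.8)),
        "AD": EEGGroupParams((7.5, 0.8), (5.5, 1.5), (2.5, 0.8)),
    }


@dataclass(frozen=True)
class EEGSimParams:
    groups: Mapping[str, EEGGroupParams] = field(default_factory=_default_eeg_groups)
    sampling_rate: float = 5000.0
    duration_s: float = 60.0            # paper-scale geometry (480 s) by flag
    background_exponent: float = 1.0    # 1/f^exponent power spectrum
    background_uv: float = 3.0
    alpha_closed_boost: float = 1.8
    n_sources_per_band: int = 4
    channel_mixing_seed: int = 1234
    subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MCI": 35, "AD": 17}
    )
    seed: int = 0

    def scaled(self, effect: float) -> "EEGSimParams":
        """Interpolate AD means toward MCI (effect 0 = no group differences)."""
        ref = self.groups["MCI"]
        groups = {"MCI": ref}
        for name, g in self.groups.items():
            if name == "MCI":
                continue
            groups[name] = EEGGroupParams(
                theta_uv=(_lerp(ref.theta_uv[0], g.theta_uv[0], effect), g.theta_uv[1]),
                alpha_uv=(_lerp(ref.alpha_uv[0], g.alpha_uv[0], effect), g.alpha_uv[1]),
                beta_uv=(_lerp(ref.beta_uv[0], g.beta_uv[0], effect), g.beta_uv[1]),
            )
        return replace(self, groups=groups)


def generate_eeg_record(
    params: EEGSimParams,
    group: str,
    condition: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> EEGRecord:
    """Simulate one resting recording (62 scalp channels + flat Ref/Gnd)."""
    g = params.groups[group]
    fs = params.sampling_rate
    n = int(round(params.duration_s * fs))
    n_scalp = len(CHANNELS_64) - 2

    # subject traits (band amplitudes) are shared across conditions
    traits_rng = np.random.default_rng([subject_seed, 101])
    amps = {band: _sample(traits_rng, g.amplitude(band)) for band in BANDS}
    if condition == "eyes_closed":
        amps["alpha"] *= params.alpha_closed_boost

    mix_rng = np.random.default_rng([params.channel_mixing_seed, subject_seed])
    cond_idx = 0 if condition == "eyes_open" else 1
    noise_rng = np.random.default_rng([subject_seed, 17, cond_idx])

    data = np.zeros((n_scalp, n))
    k = params.n_sources_per_band
    for band, (f_lo, f_hi) in BANDS.items():
        weights = mix_rng.standard_normal((n_scalp, k)) / np.sqrt(k)
        if amps[band] <= 0 or n < 64:
            continue
        sos = scipy.signal.butter(4, (f_lo, f_hi), btype="bandpass", fs=fs, output="sos")
        sources = scipy.signal.sosfiltfilt(sos, noise_rng.standard_normal((k, n)), axis=1)
        sources /= sources.std(axis=1, keepdims=True)
        data += amps[band] * (weights @ sources)

    if params.background_uv > 0:
        data += params.background_uv * _one_over_f_noise(
            noise_rng, n_scalp, n, fs, params.background_exponent
        )

    full = np.zeros((len(CHANNELS_64), n))
    full[:n_scalp] = data  # Ref and Gnd rows stay flat
    sid = subject_id if subject_id is not None else f"{group}-{subject_seed}"
    return EEGRecord(
        subject_id=sid,
        condition=condition,
        channel_labels=CHANNELS_64,
        sampling_rate=fs,
        data=full,
    )


def _one_over_f_noise(
    rng: np.random.Generator, channels: int, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum per channel."""
    white = rng.standard_normal((channels, n))
    spec = scipy.fft.rfft(white, axis=1)
    freqs = scipy.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = scipy.fft.irfft(spec * shaping[None, :], n=n, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSubject:
    """Raw simulated data for one subject (before any preprocessing)."""

    subject_id: str
    group: str
    gait: SkeletonRecord
    eeg_open: EEGRecord | None = None
    eeg_closed: EEGRecord | None = None

    @property
    def has_eeg(self) -> bool:
        return self.eeg_open is not None and self.eeg_closed is not None


def generate_cohort(
    gait_params: GaitSimParams,
    eeg_params: EEGSimParams,
) -> tuple[list[SimulatedSubject], pd.DataFrame]:
    """Generate the full cohort and its manifest.

    Mirrors the study design: healthy controls carry gait data only, MCI and
    AD subjects carry gait plus both-condition EEG.  Reproducible
    byte-for-byte from the parameter seeds.
    """
    subjects: list[SimulatedSubject] = []
    rows = []
    idx = 0
    for group in ("HC", "MCI", "AD"):
        n = int(gait_params.subjects_per_group.get(group, 0))
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            gait_seed = _subject_seed(gait_params.seed, idx)
            record = generate_gait_record(gait_params, group, gait_seed, subject_id=sid)
            subj = SimulatedSubject(subject_id=sid, group=group, gait=record)
            if group in ("MCI", "AD"):
                eeg_seed = _subject_seed(eeg_params.seed, idx)
                subj.eeg_open = generate_eeg_record(
                    eeg_params, group, "eyes_open", eeg_seed, subject_id=sid
                )
                subj.eeg_closed = generate_eeg_record(
                    eeg_params, group, "eyes_closed", eeg_seed, subject_id=sid
                )
            subjects.append(subj)
            rows.append({"subject_id": sid, "label": group, "has_eeg": subj.has_eeg})
            idx += 1
    manifest = pd.DataFrame(rows)
    return subjects, manifest


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))
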