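# Methods

## The classification problem

Three-way staging of Alzheimer's disease — cognitively healthy controls
(HC), mild cognitive impairment (MCI), and AD — from two complementary
signals:

* **Gait**, recorded as Kinect V2 skeleton sequences (25 joints × 3-D camera
  coordinates per frame).  Gait separates healthy controls from patients
  well, but MCI and AD walk too similarly to separate reliably.
* **Resting EEG** (64 electrodes, two conditions: eyes open / eyes closed),
  which distinguishes MCI from AD through spectral slowing, but is costly to
  collect — so it is collected for patients only.

The cascade exploits this asymmetry.  Stage 1 classifies each gait *clip* as
HC vs patient with a graph-convolutional network; a subject whose clips vote
majority-patient proceeds to stage 2, where a convolutional network
classifies each EEG *epoch* as MCI vs AD and a second majority vote fixes the
final label.  Subjects voted HC at stage 1 never need EEG at all.

## Stage 1: attention-based spatial-temporal graph convolution

Clips are D × T × V arrays (D = 3 coordinates, T = 60 frames, V joints) cut
from each record by a sliding window (stride 3) after two normalizations:
rotation about the x-axis by −27° (undoing the ceiling-camera tilt) and
re-centering every frame on the spine base.  Records shorter than the window
are dropped rather than padded — padding would fabricate gait frames.

The skeleton graph uses the natural bone connections.  Each node's
neighborhood (including itself, via the self-connection I) is split by the
spatial-configuration rule into root / centripetal / centrifugal subsets
according to hop distance to the spine base; each subset k gets its own
channel map W_k and the spatial operation per frame is

    f_out = Σ_k Λ^(−1/2) ((A + I) ⊙ M_k)_k Λ^(−1/2) f_in W_k ,

with Λ the degree matrix of the full A + I (shared across subsets) and M_k a
learnable per-edge importance mask initialized to ones.  Distances are
computed on the template skeleton, so the partition is static — a
requirement for fixed convolution operators, and consistent with all frames
being re-centered on the spine base.  A tie in distance is assigned
centripetally, which keeps the rule deterministic.

Each block follows the graph convolution with batch normalization, a
rectifier, a temporal convolution (kernel 9 along frames, per joint) and a
residual connection (1 × 1 projection when shapes differ; the first block
carries no residual).  The default backbone is the reference ten-block plan
(channels 64×4, 128×3, 256×3; temporal stride 2 at blocks 5 and 8; dropout
0.5 from block 5).  A narrow five-block preset (16, 16, 32, 32, 64) is
provided for desk-scale experiments and used by the test suite.

**Hourglass attention.**  A gating branch downsamples time twice with
stride-4 convolutions (T → T/4 → T/16), upsamples back with nearest-neighbor
repetition (parameter-free and shape-exact; lengths that are not multiples
of 16 are handled by crop-after-upsample), applies a 1 × 1 convolution and a
sigmoid, and rescales the trunk by (1 + g) with g ∈ (0, 1) — attention can
emphasize joints and instants but never erase them.  One module after block
9 is the default placement; `none`, `after-3`, `after-6`, `after-9` and
`all` are configurable.  Internal widths of the branch (kernel 5, channel
count preserved) are this package's choice.

## Stage 2: spatial-temporal CNN on raw EEG epochs

Preprocessing: drop the Ref/Gnd electrodes and re-reference the remaining 62
channels to their common average; downsample 5,000 → 250 Hz with zero-phase
FIR anti-alias filtering (staged 5 × 4); cut 120 non-overlapping 256-sample
(~1 s) windows per condition; concatenate the i-th eyes-open window with the
i-th eyes-closed window along time (index-aligned pairing); replicate the
62 × 512 matrix across three depth planes.  Which 120 of the available
windows: the first, in temporal order (a seeded random selection is
available).  Artifact removal is assumed done upstream; the reader only
flags gross amplitude outliers.  Epochs are stored single-plane and
broadcast to three planes at load, which is bit-identical and three times
smaller.

The network alternates spatial (kernel K_s along electrodes) and temporal
(kernel K_t = 33 along samples, where the stride lives) convolutions:

| module | channels | K_s | K_t | stride |
|--------|----------|-----|-----|--------|
| 1      | 3 → 4    | 1   | 33  | 1      |
| 2      | 4 → 4    | 15  | 33  | 4      |
| 3      | 4 → 16   | 62  | 33  | 1      |
| 4      | 16 → 8   | 1   | 33  | 4      |

Module 3's full-extent spatial kernel collapses the electrode axis (valid
convolution); all other convolutions are same-padded, and the stride applies
to the temporal axis only — the only reading under which a 3 × 62 × 512
epoch flattens to the designed 256-dimensional feature (8 × 1 × 32).  Batch
normalization of the input planes and per-module batch statistics with an
exponential-linear nonlinearity follow the EEG-decoding lineage this
architecture descends from.

## Cascade voting and training

Stage 1 votes PATIENT iff *strictly more than half* of the clips have
patient as the argmax class; otherwise the subject is final-labeled HC and
EEG is never consulted.  Stage 2 likewise takes the epoch majority; an exact
tie (possible only with an even epoch count) is broken by the larger summed
softmax score — deterministic, confidence-weighted and label-unbiased.  A
patient-voted subject without EEG yields an explicit needs-EEG outcome, not
a silent fallback.

Both stages minimize unweighted cross-entropy with momentum SGD
(momentum 0.9, constant learning rate): gait lr 0.05, 50 epochs, batch 64;
EEG lr 0.005, 70 epochs, batch 64.  A class-weight option exists for the
imbalanced cohort but is off by default.  The gait split is subject-wise
(75% of subjects, stratified); the EEG default in this package is also
subject-wise, because the protocol-style pooled *epoch-wise* split (75% of
epochs) leaks subject identity between train and test.  The epoch-wise mode
is provided (`eeg_split: epoch`) for protocol fidelity.

## Numerical core

No deep-learning framework is used: the layers (convolutions, batch
normalization, nonlinearities, dropout, pooling, affine heads) are
implemented directly on numpy arrays with hand-written backpropagation,
verified against central-difference gradients in the test suite.  Long 1-D
convolutions (the 33-tap temporal and 15-tap spatial EEG filters) are
evaluated in the frequency domain — cross-correlation via real FFTs with a
transform length covering input + kernel − 1 samples so the circular wrap
lands on zero padding — and checked against the direct tap-loop path to
float32 precision.  Training is deterministic on one worker given the
configuration seed: shuffling, initialization and dropout all derive from
it.

## Synthetic cohort

The generators provide the statistical structure the cascade assumes, with
one `effect` knob scaling every between-group difference (1 = default
separation, 0 = identical groups):

* **Gait**: a 25-joint template walks with pelvis translation at the sampled
  speed and sinusoidal limb trajectories at the sampled cadence (defined as
  gait cycles/s; each ankle lifts once per cycle, so the ankle trajectory's
  dominant frequency equals the cadence).  Group defaults (HC/MCI/AD):
  cadence 1.00/0.82/0.70 Hz, stride amplitude 0.32/0.22/0.16 m, speed
  1.15/0.85/0.65 m/s, right-arm swing 0.20/0.08/0.05 m, with subject-level
  standard deviations of roughly 0.05–0.08 in each unit.  The reduced
  right-arm swing in patients makes the lower-body + right-upper-limb joint
  subset the informative one, mirroring the clinical observation that the
  left hemisphere (controlling the right side) is affected earlier in
  right-handed patients.  The camera tilt (+27°) is applied so preprocessing
  has something to undo.
* **EEG**: per band (theta 4–8, alpha 8–12, beta 13–30 Hz), band-limited
  oscillator sources are mixed across the 62 scalp channels with
  subject-specific random weights on top of 1/f background noise; Ref/Gnd
  are flat.  AD shows slowing relative to MCI: theta 7.5 vs 4.0 µV, alpha
  5.5 vs 10.0 µV (σ ≈ 0.8–1.5 µV between subjects); alpha is boosted ×1.8
  with eyes closed.  These defaults put the between-subject group separation
  near d ≈ 3, which is what a ≥ 90% subject-level voting accuracy
  mathematically requires — with, say, d ≈ 0.8 the groups overlap so much
  that even a Bayes-optimal epoch classifier would misassign roughly a
  quarter of subjects, no matter the model.  Band amplitudes are subject
  traits: the same draw feeds both conditions of a subject.

What the simulator does *not* emulate: artifacts (ocular, myogenic, line
noise), non-stationarity within a recording, skeleton tracking dropouts and
occlusions, turn-arounds in the walking path, electrode-position variation,
and any within-group clinical heterogeneity beyond Gaussian parameter
spread.  Passing tests therefore demonstrate that the pipeline recovers the
group structure it was told to expect at realistic effect sizes — not that
it would survive clinical data.

## Scale of the shipped experiments

The test suite and the acceptance script run the cascade at desk scale, as
the package's own configuration choices: a 30/30/15-subject cohort,
81-frame gait records (8 clips each), 7 s of EEG per condition (6 epochs per
subject), the narrow gait backbone, 10 gait / 15 EEG training epochs, EEG
batch 16.  The null control uses a 20/10/10 cohort at `effect: 0` with even
shorter training, and checks that subject-level accuracies stay inside the
95% binomial interval around chance (0.5 for each balanced stage).  The
full-scale geometry (8-minute EEG, 300-frame walks, 120 epochs/subject,
paper-sized backbone) is reachable through `RunConfig` flags.

## Known limitations

* The backbone depth/widths of the gait network and the hourglass module's
  internal widths are design choices; reported parameter counts are this
  implementation's own and are not claimed to match any published count.
* The epoch-wise EEG split mode reproduces a protocol that leaks subject
  identity; the subject-wise default is the honest estimate and is what the
  shipped experiments use.
* Majority voting needs an odd number of votes to be tie-free; the tie rule
  only matters for even counts and is documented above.
* EDF input is supported via `mne` when installed; EDF export is not
  provided (epoch stores are HDF5).
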