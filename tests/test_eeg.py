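"""EEG preprocessing: re-referencing, downsampling, epoching, splitting, storage."""

import numpy as np
import pytest

from adcascade.eeg import (
    CHANNELS_64,
    EEGRecord,
    downsample,
    epochs_to_array,
    extract_epochs,
    load_epochs_h5,
    rereference_common_average,
    save_epochs_h5,
    split_epochs,
)


def make_record(data, condition="eyes_open", rate=250.0, labels=None, sid="s1"):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = CHANNELS_64[: data.shape[0]]
    return EEGRecord(
        subject_id=sid, condition=condition, channel_labels=labels,
        sampling_rate=rate, data=data,
    )


def random_record(rng, n_channels=64, n_samples=1000, **kw):
    labels = CHANNELS_64[: n_channels - 2] + ("Ref", "Gnd") if n_channels == 64 else None
    return make_record(rng.standard_normal((n_channels, n_samples)), labels=labels, **kw)


class TestRereference:
    def test_64_to_62_channels(self, rng):
        out = rereference_common_average(random_record(rng))
        assert out.n_channels == 62
        assert "Ref" not in out.channel_labels and "Gnd" not in out.channel_labels

    def test_constant_channels_become_zero(self):
        rec = make_record(np.full((64, 100), 7.0), labels=CHANNELS_64)
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_per_sample_mean_is_zero(self, rng):
        out = rereference_common_average(random_record(rng))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)

    def test_idempotent_once_references_gone(self, rng):
        once = rereference_common_average(random_record(rng))
        twice = rereference_common_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_missing_reference_labels_rejected(self, rng):
        labels = tuple(f"ch{i}" for i in range(64))
        rec = make_record(rng.standard_normal((64, 10)), labels=labels)
        with pytest.raises(ValueError, match="reference labels"):
            rereference_common_average(rec)


class TestDownsample:
    def test_5000_to_250_sample_count(self, rng):
        rec = random_record(rng, n_samples=5000, rate=5000.0)
        out = downsample(rec, 250.0)
        assert out.n_samples == 250
        assert out.sampling_rate == 250.0

    def test_dc_signal_unchanged(self):
        rec = make_record(np.full((4, 5000), 3.5), rate=5000.0,
                          labels=("a", "b", "c", "d"))
        out = downsample(rec, 250.0)
        # FIR edge transients affect only the record boundaries
        np.testing.assert_allclose(out.data[:, 20:-20], 3.5, atol=1e-6)

    def test_10hz_sinusoid_amplitude_preserved_within_1pct(self):
        t = np.arange(50000) / 5000.0
        rec = make_record(np.sin(2 * np.pi * 10.0 * t)[None, :], rate=5000.0, labels=("a",))
        out = downsample(rec, 250.0)
        # oracle: least-squares sine fit at the known frequency
        td = np.arange(out.n_samples) / 250.0
        design = np.stack([np.sin(2 * np.pi * 10 * td), np.cos(2 * np.pi * 10 * td)], axis=1)
        coef, *_ = np.linalg.lstsq(design, out.data[0], rcond=None)
        amplitude = float(np.hypot(*coef))
        assert abs(amplitude - 1.0) < 0.01

    def test_non_integer_factor_rejected(self, rng):
        rec = random_record(rng, rate=300.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(rec, 250.0)


class TestEpochExtraction:
    def _pair(self, rng, n_samples, n_channels=62):
        kw = dict(n_channels=n_channels, n_samples=n_samples, rate=250.0)
        return (
            random_record(rng, condition="eyes_open", **kw),
            random_record(rng, condition="eyes_closed", **kw),
        )

    def test_8min_records_yield_468_windows_120_epochs(self, rng):
        op, cl = self._pair(rng, n_samples=120000)
        assert op.n_samples // 256 == 468
        epochs = extract_epochs(op, cl, epochs_per_subject=120)
        assert len(epochs) == 120

    def test_epoch_shape_is_3x62x512(self, rng):
        op, cl = self._pair(rng, n_samples=2048)
        epochs = extract_epochs(op, cl, epochs_per_subject=4)
        assert epochs[0].data.shape == (3, 62, 512)

    def test_depth_planes_identical(self, rng):
        op, cl = self._pair(rng, n_samples=1024)
        e = extract_epochs(op, cl, epochs_per_subject=2)[0]
        np.testing.assert_array_equal(e.data[0], e.data[1])
        np.testing.assert_array_equal(e.data[0], e.data[2])

    def test_windows_are_index_aligned_and_nonoverlapping(self, rng):
        op, cl = self._pair(rng, n_samples=1024)
        epochs = extract_epochs(op, cl, epochs_per_subject=3)
        for i, e in enumerate(epochs):
            sl = slice(i * 256, (i + 1) * 256)
            np.testing.assert_allclose(e.data[0, :, :256], op.data[:, sl], atol=1e-6)
            np.testing.assert_allclose(e.data[0, :, 256:], cl.data[:, sl], atol=1e-6)

    def test_insufficient_samples_error_states_achievable_count(self, rng):
        op, cl = self._pair(rng, n_samples=1000)
        with pytest.raises(ValueError, match="only 3"):
            extract_epochs(op, cl, epochs_per_subject=10)

    def test_available_windows_match_bruteforce(self, rng):
        for n in (256, 300, 511, 512, 513, 1000):
            op, cl = self._pair(rng, n_samples=n)
            brute = sum(1 for s in range(0, n, 256) if s + 256 <= n)
            if brute == 0:
                with pytest.raises(ValueError):
                    extract_epochs(op, cl, epochs_per_subject=1)
            else:
                assert len(extract_epochs(op, cl, epochs_per_subject=brute)) == brute

    def test_mismatched_conditions_rejected(self, rng):
        op, cl = self._pair(rng, n_samples=512)
        with pytest.raises(ValueError, match="eyes_open"):
            extract_epochs(cl, op, epochs_per_subject=1)


class TestSplit:
    def _epochs(self, rng, n):
        op, cl = (
            random_record(rng, n_channels=4, n_samples=n * 16, condition=c, rate=250.0)
            for c in ("eyes_open", "eyes_closed")
        )
        return extract_epochs(op, cl, window=16, epochs_per_subject=n)

    def test_75_25_split_sizes(self, rng):
        epochs = self._epochs(rng, 100)
        train, test = split_epochs(epochs, 0.75, seed=0)
        assert len(train) == 75 and len(test) == 25

    def test_split_is_disjoint_and_exhaustive(self, rng):
        epochs = self._epochs(rng, 40)
        train, test = split_epochs(epochs, 0.75, seed=3)
        ids = {id(e) for e in epochs}
        assert {id(e) for e in train} | {id(e) for e in test} == ids
        assert {id(e) for e in train} & {id(e) for e in test} == set()

    def test_same_seed_reproduces_partition(self, rng):
        epochs = self._epochs(rng, 30)
        t1, _ = split_epochs(epochs, 0.75, seed=7)
        t2, _ = split_epochs(epochs, 0.75, seed=7)
        assert [id(e) for e in t1] == [id(e) for e in t2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no epochs"):
            split_epochs([], 0.75, seed=0)


class TestStorage:
    def test_h5_roundtrip_replicates_planes(self, rng, tmp_path):
        op, cl = (
            random_record(rng, n_channels=4, n_samples=64, condition=c, rate=250.0)
            for c in ("eyes_open", "eyes_closed")
        )
        epochs = extract_epochs(op, cl, window=32, epochs_per_subject=2, label="MCI")
        path = tmp_path / "epochs.h5"
        save_epochs_h5(epochs, path)
        back = load_epochs_h5(path)
        assert len(back) == 2
        assert back[0].label == "MCI"
        np.testing.assert_allclose(
            epochs_to_array(back), epochs_to_array(epochs), atol=1e-7
        )

    def test_epochs_to_array_shape(self, rng, tmp_path):
        op, cl = (
            random_record(rng, n_channels=4, n_samples=64, condition=c, rate=250.0)
            for c in ("eyes_open", "eyes_closed")
        )
        epochs = extract_epochs(op, cl, window=32, epochs_per_subject=2)
        arr = epochs_to_array(epochs)
        assert arr.shape == (2, 3, 4, 64)
        assert arr.dtype == np.float32
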