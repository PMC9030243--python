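import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from emgdenoise import (
    SimulationSpec,
    contaminate,
    generate_clean_eeg,
    generate_emg,
    make_training_set,
    simulate_record,
)
from emgdenoise.signal import ConfigurationError
from emgdenoise.simulate import burst_mask


class TestSimulationSpec:
    def test_defaults_valid(self):
        spec = SimulationSpec()
        assert spec.n_samples == 2500

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"freq_range": (30.0, 0.1)},
            {"freq_range": (0.0, 30.0)},
            {"freq_range": (0.1, 130.0)},
            {"emg_band": (45.0, 5.0)},
            {"emg_band": (5.0, 200.0)},
            {"fs": -1.0},
            {"burst_windows": ((0.0, 11.0),)},
            {"burst_windows": ((-0.5, 1.0),)},
            {"burst_windows": ((0.0, 3.0), (2.0, 4.0))},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationSpec(**kwargs)


class TestGenerateCleanEEG:
    def test_zero_sinusoids_gives_zero_signal(self):
        spec = SimulationSpec(n_sinusoids=0, seed=1)
        sig = generate_clean_eeg(spec)
        assert sig.n_samples == 2500
        assert np.all(sig.data == 0.0)

    def test_length_10s_at_250hz(self):
        sig = generate_clean_eeg(SimulationSpec(seed=2))
        assert sig.n_samples == 2500
        assert sig.fs == 250.0

    def test_spectral_containment(self):
        sig = generate_clean_eeg(SimulationSpec(seed=3))
        f, p = periodogram(sig.data, fs=sig.fs)
        assert p[f > 35.0].sum() / p.sum() < 0.01

    def test_deterministic(self):
        a = generate_clean_eeg(SimulationSpec(seed=4))
        b = generate_clean_eeg(SimulationSpec(seed=4))
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a = generate_clean_eeg(SimulationSpec(seed=5))
        b = generate_clean_eeg(SimulationSpec(seed=6))
        assert not np.array_equal(a.data, b.data)

    def test_amplitude_scales_linearly(self):
        a = generate_clean_eeg(SimulationSpec(seed=5, amplitude=1.0))
        b = generate_clean_eeg(SimulationSpec(seed=5, amplitude=0.25))
        np.testing.assert_allclose(b.data, 0.25 * a.data, rtol=1e-12)


class TestGenerateEMG:
    def test_zero_gain_gives_zero(self):
        sig = generate_emg(SimulationSpec(artifact_gain=0.0, seed=1))
        assert np.all(sig.data == 0.0)

    def test_band_limited(self):
        sig = generate_emg(SimulationSpec(seed=2))
        f, p = periodogram(sig.data, fs=sig.fs)
        outside = (f < 4.0) | (f > 46.0)
        assert p[outside].sum() / p.sum() < 0.05

    def test_deterministic(self):
        a = generate_emg(SimulationSpec(seed=3))
        b = generate_emg(SimulationSpec(seed=3))
        np.testing.assert_array_equal(a.data, b.data)

    def test_rms_ratio_matches_gain(self):
        spec = SimulationSpec(seed=4, artifact_gain=2.0)
        clean = generate_clean_eeg(spec)
        emg = generate_emg(spec)
        ratio = np.sqrt(np.mean(emg.data**2) / np.mean(clean.data**2))
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_independent_of_clean_stream(self):
        # same spec: EMG noise is drawn from its own substream, so the EMG
        # waveform shape is unchanged when only n_sinusoids changes the clean
        a = generate_emg(SimulationSpec(seed=5))
        b = generate_emg(SimulationSpec(seed=5, n_sinusoids=5))
        corr = np.corrcoef(a.data, b.data)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)


class TestContaminate:
    def test_no_windows_is_identity(self, default_spec):
        clean = generate_clean_eeg(default_spec)
        emg = generate_emg(default_spec)
        rec = contaminate(clean, emg, [])
        np.testing.assert_array_equal(rec.corrupted.data, clean.data)
        assert not rec.burst_mask.any()

    def test_default_windows_mask_count(self):
        # half-open windows: (1.3 + 2.2 + 0.9) s * 250 Hz = 1100 samples
        mask = burst_mask(SimulationSpec().burst_windows, 2500, 250.0)
        assert mask.sum() == 1100

    def test_additivity_on_and_off_mask(self, record):
        # bit-exact: corrupted is constructed as clean + masked emg
        np.testing.assert_array_equal(
            record.corrupted.data, record.clean.data + record.emg.data
        )
        assert np.all(record.emg.data[~record.burst_mask] == 0.0)
        np.testing.assert_array_equal(
            record.corrupted.data[~record.burst_mask],
            record.clean.data[~record.burst_mask],
        )

    def test_window_outside_record_raises(self, default_spec):
        clean = generate_clean_eeg(default_spec)
        emg = generate_emg(default_spec)
        with pytest.raises(IndexError):
            contaminate(clean, emg, [(9.5, 10.5)])

    def test_length_mismatch_raises(self, default_spec):
        clean = generate_clean_eeg(default_spec)
        emg = generate_emg(
            dataclasses.replace(default_spec, duration_s=5.0, burst_windows=())
        )
        with pytest.raises(ValueError):
            contaminate(clean, emg, [])


class TestSimulateRecord:
    def test_reproducible(self, default_spec, record):
        again = simulate_record(default_spec)
        np.testing.assert_array_equal(again.corrupted.data, record.corrupted.data)
        np.testing.assert_array_equal(again.clean.data, record.clean.data)

    def test_shared_length_and_fs(self, record):
        n = record.clean.n_samples
        assert record.emg.n_samples == n == record.corrupted.n_samples
        assert record.clean.fs == record.emg.fs == record.corrupted.fs


class TestMakeTrainingSet:
    def test_balanced_labels(self):
        epochs, labels = make_training_set(5, SimulationSpec(seed=1))
        assert len(epochs) == 10
        assert (labels == "NC-EEG").sum() == 5
        assert (labels == "C-EEG").sum() == 5

    def test_minimal_set(self):
        epochs, labels = make_training_set(1, SimulationSpec(seed=1))
        assert len(epochs) == 2
        assert set(labels) == {"NC-EEG", "C-EEG"}

    def test_epochs_have_distinct_seeds(self):
        epochs, _ = make_training_set(3, SimulationSpec(seed=1))
        data = [e.data for e in epochs]
        for i in range(len(data)):
            for j in range(i + 1, len(data)):
                assert not np.array_equal(data[i], data[j])

    def test_n_per_class_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            make_training_set(0, SimulationSpec(seed=1))
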