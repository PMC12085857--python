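"""Haar-subband, statistical features and feature-vector assembly."""

import numpy as np
import pytest

from ecgmi.records import SynthConfig
from ecgmi.staticfeat import (EPS, AssembleConfig, BlockLayout, FeatureError,
                              assemble, haar_features, information_gain,
                              kurtosis, log_energy_entropy, relative_amplitude,
                              relative_energy, segment_channels, signal_mean,
                              signal_variance)
from ecgmi.synth import generate_record


class TestHaar:
    def test_constant_signal_hits_floor(self):
        out = haar_features(np.full(64, 2.5))
        assert np.allclose(out, np.log(EPS))

    def test_subband_energies_partition_total_energy(self):
        import pywt
        rng = np.random.default_rng(1)
        x = rng.standard_normal(256)
        coeffs = pywt.wavedec(x, "haar", level=4, mode="periodization")
        total = sum(float(np.sum(c ** 2)) for c in coeffs)
        assert total == pytest.approx(float(np.sum(x ** 2)), abs=1e-9)

    def test_alternating_signal_concentrates_in_level_one(self):
        x = np.tile([1.0, -1.0], 64)
        out = haar_features(x)
        rel = np.exp(out) - EPS
        assert rel[0] > 0.99

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            haar_features(np.ones(8))


class TestMoments:
    def test_small_example_population_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert signal_mean(x) == pytest.approx(2.0)
        assert signal_variance(x) == pytest.approx(2.0 / 3.0)

    def test_constant(self):
        assert signal_mean(np.full(10, 4.2)) == pytest.approx(4.2)
        assert signal_variance(np.full(10, 4.2)) == pytest.approx(0.0, abs=1e-20)

    def test_affine_map(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        a, b = 2.5, -1.0
        assert signal_mean(a * x + b) == pytest.approx(a * signal_mean(x) + b)
        assert signal_variance(a * x + b) == pytest.approx(a ** 2 * signal_variance(x))


class TestRelativeAmplitude:
    def test_identical_channels_all_zero(self):
        ch = np.tile(np.sin(np.linspace(0, 5, 100)), (4, 1))
        assert np.allclose(relative_amplitude(ch), 0.0)

    def test_three_to_one_ratio(self):
        ch = np.array([[3.0, -3.0, 1.0], [1.0, 0.5, -1.0]])
        out = relative_amplitude(ch, n_pairs=1)
        assert out[0] == pytest.approx(0.5)  # (3-1)/(3+1)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ch = rng.standard_normal((rng.integers(2, 14), 64))
            out = relative_amplitude(ch)
            assert np.all(np.abs(out) <= 1.0)

    def test_zero_pair_defined_as_zero(self):
        ch = np.zeros((2, 10))
        assert np.allclose(relative_amplitude(ch), 0.0)

    def test_single_lead_segments_give_12_pseudochannels(self):
        ch = segment_channels(np.arange(125.0), 12)
        assert ch.shape == (12, 10)


class TestRelativeEnergy:
    def test_normalised_to_unit_sum(self):
        rng = np.random.default_rng(0)
        out = relative_energy(rng.standard_normal(4096))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.shape == (100,)

    def test_sinusoid_lands_in_expected_band(self):
        fs, n = 1000.0, 10_000
        t = np.arange(n) / fs
        # band j covers ((j*5), (j+1)*5] Hz for 100 bands to 500 Hz
        x = np.sin(2 * np.pi * 87.0 * t)
        out = relative_energy(x)
        assert np.argmax(out) == 17

    def test_white_noise_nearly_uniform(self):
        rng = np.random.default_rng(11)
        out = relative_energy(rng.standard_normal(1_000_000))
        assert np.max(np.abs(out - 0.01)) < 0.002

    def test_all_zero_fallback_uniform(self):
        out = relative_energy(np.zeros(1000))
        assert np.allclose(out, 0.01)


class TestEntropy:
    def test_unit_magnitude_signal_near_zero(self):
        x = np.array([1.0, -1.0] * 50)
        assert log_energy_entropy(x) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_hits_floor(self):
        assert log_energy_entropy(np.zeros(100)) == pytest.approx(np.log(EPS))

    def test_gaussian_below_constant_magnitude_at_equal_rms(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(10_000)
        c = np.sign(rng.standard_normal(10_000))
        assert log_energy_entropy(g) < log_energy_entropy(c)


class TestKurtosis:
    def test_standard_normal_near_three(self):
        rng = np.random.default_rng(0)
        assert kurtosis(rng.standard_normal(1_000_000)) == pytest.approx(3.0, abs=0.1)

    def test_two_point_signal_exactly_one(self):
        assert kurtosis(np.array([1.0, -1.0] * 10)) == pytest.approx(1.0)

    def test_outlier_increases_kurtosis(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        x_out = np.append(x, 50.0)
        assert kurtosis(x_out) > kurtosis(x)

    def test_zero_variance_defined_as_zero(self):
        assert kurtosis(np.full(10, 2.0)) == 0.0


class TestInformationGain:
    def test_uniform_histogram_zero(self):
        x = np.repeat(np.arange(10), 5) + 0.5  # 5 samples per bin exactly
        assert information_gain(x, bins=10) == pytest.approx(0.0, abs=1e-9)

    def test_constant_signal_max_gain(self):
        assert information_gain(np.full(100, 1.5), bins=10) == pytest.approx(np.log2(10))

    def test_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.standard_normal(rng.integers(10, 500))
            g = information_gain(x)
            assert 0.0 <= g <= np.log2(10) + 1e-12


class TestAssemble:
    def test_default_layout_lengths(self, clean_record):
        fv = assemble(clean_record)
        assert fv.layout.lengths() == (5, 30, 4, 1, 1, 50, 100, 1, 1, 1)
        assert fv.values.shape == (194,)

    def test_layout_partitions_exactly(self, clean_record):
        fv = assemble(clean_record)
        fv.layout.validate_partition()
        off = 0
        for name, o, ln in fv.layout.blocks:
            assert o == off
            off += ln
        assert off == fv.values.size

    def test_identical_records_identical_vectors(self, clean_record):
        a = assemble(clean_record)
        b = assemble(clean_record)
        assert np.array_equal(a.values, b.values)

    def test_zeroing_secondary_lead_changes_only_a6(self):
        rec = generate_record(SynthConfig(duration_s=10, heart_rate_bpm=60,
                                          n_leads=2, seed=1))
        # rename leads so the primary-lead choice is lead 0 in both cases
        rec.lead_names = ["I", "V1"]
        zeroed = rec.with_samples(np.vstack([rec.samples[0], np.zeros(rec.n_samples)]))
        zeroed.lead_names = ["I", "V1"]
        a = assemble(rec)
        b = assemble(zeroed)
        for name in ("A1", "A2", "A3", "A4", "A5", "A7", "A8", "A9", "A10"):
            assert np.array_equal(a.block(name), b.block(name)), name
        assert not np.array_equal(a.block("A6"), b.block("A6"))

    def test_block_error_names_block(self):
        short = generate_record(SynthConfig(duration_s=2.5, heart_rate_bpm=30, seed=0))
        with pytest.raises(FeatureError, match="A1"):
            assemble(short)

    def test_column_name_roundtrip(self):
        layout = AssembleConfig().layout()
        rebuilt = BlockLayout.from_column_names(layout.column_names())
        assert rebuilt.lengths() == layout.lengths()
        assert [b[0] for b in rebuilt.blocks] == [b[0] for b in layout.blocks]
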