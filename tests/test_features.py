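import numpy as np
import pytest

import oracles
from ieegfuse.emd import emd, fuzzy_entropy
from ieegfuse.features import (
    FEATURE_NAMES,
    FeatureConfig,
    emd_fuzzy_features,
    extract_feature_sequence,
    extract_feature_vector,
    frequency_domain_features,
    higuchi_fd,
    katz_fd,
    kraskov_entropy,
    permutation_entropy,
    petrosian_fd,
    renyi_entropy,
    sample_entropy,
    shannon_entropy,
    svd_entropy,
    time_domain_features,
)
from ieegfuse.preprocess import PreprocessConfig, SubbandSet
from ieegfuse.synthetic import SynthConfig, generate_segment
from ieegfuse.types import Segment


def _ar1(n, phi=0.9, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.standard_normal()
    return x


class TestTimeDomain:
    def test_population_moments_on_tiny_input(self):
        f = time_domain_features(np.array([1.0, 2.0, 3.0, 2.0]))
        assert f["mean"] == pytest.approx(2.0)
        assert f["variance"] == pytest.approx(np.mean(([1, 2, 3, 2] - np.mean([1, 2, 3, 2])) ** 2))

    def test_zero_crossings_count_sign_changes(self):
        f = time_domain_features(np.array([1.0, -1.0, 1.0, -1.0]))
        assert f["zero_crossings"] == 3

    def test_gaussian_kurtosis_and_hurst(self):
        """White noise: excess kurtosis near 0, R/S Hurst near 0.5 (20 seeds)."""
        kurts, hursts = [], []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(4096)
            f = time_domain_features(x)
            kurts.append(f["kurtosis"])
            hursts.append(f["hurst"])
        assert abs(np.mean(kurts)) < 0.2
        assert abs(np.mean(hursts) - 0.5) < 0.1

    def test_constant_input_sentinels_are_finite(self):
        f = time_domain_features(np.full(64, 3.14))
        assert np.isfinite(list(f.values())).all()
        assert f["variance"] == 0.0


class TestFrequencyDomain:
    def test_high_band_tone_dominates_spr(self):
        t = np.arange(2048) / 512.0
        f = frequency_domain_features(np.sin(2 * np.pi * 100 * t), 512.0)
        assert f["spr"] > 10

    def test_white_noise_spectral_entropy_near_one(self, rng):
        f = frequency_domain_features(rng.standard_normal(8192), 512.0)
        assert f["spectral_entropy"] > 0.9

    def test_centroid_recovers_tone_frequency(self):
        fs = 512.0
        t = np.arange(4096) / fs
        f = frequency_domain_features(np.sin(2 * np.pi * 30 * t), fs)
        assert f["spectral_centroid"] == pytest.approx(30.0, abs=1.0)

    def test_low_rate_signal_warns_and_zeroes_spr(self):
        with pytest.warns(UserWarning, match="SPR"):
            f = frequency_domain_features(np.random.default_rng(0).standard_normal(512), 100.0)
        assert f["spr"] == 0.0


class TestEmdFuzzy:
    def test_sinusoid_yields_finite_pair(self):
        t = np.arange(800) / 160.0
        f = emd_fuzzy_features(np.sin(2 * np.pi * 5 * t))
        assert np.isfinite([f["emd_fuzzyent_q1"], f["emd_fuzzyent_q3"]]).all()

    def test_quartiles_match_sort_based_oracle(self, rng):
        x = rng.standard_normal(800)
        imfs = emd(x, max_imfs=5)
        fes = [fuzzy_entropy(i) for i in imfs]
        f = emd_fuzzy_features(x)
        assert f["emd_fuzzyent_q1"] == pytest.approx(oracles.quantile_naive(fes, 0.25), abs=1e-10)
        assert f["emd_fuzzyent_q3"] == pytest.approx(oracles.quantile_naive(fes, 0.75), abs=1e-10)

    def test_deterministic_on_fixed_input(self, rng):
        x = rng.standard_normal(512)
        a = emd_fuzzy_features(x)
        b = emd_fuzzy_features(x.copy())
        assert a == b

    def test_imfs_reconstruct_signal_with_residual(self, rng):
        x = rng.standard_normal(512)
        imfs = emd(x, max_imfs=5)
        residual = x - np.sum(imfs, axis=0)
        assert np.isfinite(residual).all()
        assert len(imfs) >= 2


class TestSubbandEntropyOracles:
    """Each vectorized estimator against an explicit brute-force oracle."""

    @pytest.mark.parametrize(
        "fn,oracle,tol",
        [
            (lambda x: sample_entropy(x, 2, 0.2), oracles.sample_entropy_naive, 1e-10),
            (lambda x: permutation_entropy(x, 3), oracles.permutation_entropy_naive, 1e-10),
            (lambda x: renyi_entropy(x, 2.0), oracles.renyi_entropy_naive, 1e-8),
            (shannon_entropy, oracles.shannon_entropy_naive, 1e-8),
            (lambda x: kraskov_entropy(x, 4), oracles.kraskov_entropy_naive, 1e-8),
            (lambda x: svd_entropy(x, 10), oracles.svd_entropy_naive, 1e-6),
            (petrosian_fd, oracles.petrosian_naive, 1e-10),
            (katz_fd, oracles.katz_naive, 1e-10),
            (lambda x: higuchi_fd(x, 10), oracles.higuchi_naive, 1e-8),
        ],
        ids=["sample", "permutation", "renyi", "shannon", "kraskov", "svd", "pfd", "kfd", "hfd"],
    )
    def test_against_bruteforce(self, fn, oracle, tol):
        x = _ar1(300, phi=0.9, seed=42)
        assert fn(x) == pytest.approx(oracle(x), abs=tol)

    def test_energy_is_sum_of_squares(self):
        from ieegfuse.features import _SUBBAND_FUNCS

        assert _SUBBAND_FUNCS["energy"](np.array([3.0, 4.0]), FeatureConfig()) == 25.0

    def test_renyi_uniform_distribution_gives_log_n(self):
        x = np.ones(32)  # equal-energy coefficients -> p_i = 1/N
        assert renyi_entropy(x, 2.0) == pytest.approx(np.log(32), abs=1e-12)

    def test_permutation_entropy_of_monotone_sequence_is_zero(self):
        assert permutation_entropy(np.arange(100.0), 3) == 0.0

    def test_sample_entropy_matches_oracle_on_ar1_512(self):
        x = _ar1(512, phi=0.9, seed=7)
        assert sample_entropy(x) == pytest.approx(
            oracles.sample_entropy_naive(x), abs=1e-10
        )

    def test_entropies_nonnegative_on_noise(self, rng):
        x = rng.standard_normal(256)
        assert shannon_entropy(x) >= 0
        assert permutation_entropy(x) >= 0
        assert 0 <= svd_entropy(x) <= 1 + 1e-12


class TestAssembly:
    def test_vector_has_all_70_names_in_order(self):
        seg = generate_segment(SynthConfig(duration=5, seed=1))
        vec = extract_feature_vector(seg)
        assert list(vec) == FEATURE_NAMES
        assert len(vec) == 70
        assert np.isfinite(list(vec.values())).all()

    def test_identical_segments_identical_vectors(self):
        seg = generate_segment(SynthConfig(duration=5, seed=2))
        assert extract_feature_vector(seg) == extract_feature_vector(seg)

    def test_sequence_shape_is_timesteps_by_70(self):
        seg = generate_segment(SynthConfig(duration=8, seed=3))
        seq = extract_feature_sequence(seg, 4)
        assert seq.values.shape == (4, 70)
        assert seq.values.size == 280

    def test_single_timestep_equals_whole_segment_vector(self):
        seg = generate_segment(SynthConfig(duration=5, seed=4))
        seq = extract_feature_sequence(seg, 1)
        vec = extract_feature_vector(seg)
        np.testing.assert_allclose(seq.values[0], [vec[n] for n in FEATURE_NAMES])

    def test_amplitude_scaling_invariances(self):
        seg = generate_segment(SynthConfig(duration=5, seed=5))
        big = Segment(samples=10.0 * seg.samples, fs=seg.fs, label=seg.label)
        a = extract_feature_vector(seg)
        b = extract_feature_vector(big)
        for name in ("cv", "spectral_entropy", "permutation_A4", "pfd_D1",
                     "kfd_D2", "hfd_D3", "svd_entropy_A4"):
            assert b[name] == pytest.approx(a[name], abs=1e-6)
        for band in ("A4", "D1"):
            assert b[f"energy_{band}"] == pytest.approx(100.0 * a[f"energy_{band}"], rel=1e-9)
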