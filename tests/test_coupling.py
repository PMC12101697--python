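"""Unit and property tests for the pairwise coupling features."""

import math

import numpy as np
import pytest

from heartcouple import (
    EmbeddingConfig,
    SpectralConfig,
    cosine_similarity,
    cross_fuzzy_entropy,
    cross_sample_entropy,
    cpsd_features,
    euclidean_distance,
    extract_features,
    joint_distribution_entropy,
    msc_features,
    pair_features,
    pearson_correlation,
    phase_locking_value,
)
from heartcouple.coupling import MEASURES, PAIR_ORDER_5, cpsd, feature_names

from naive_reference import (
    naive_cross_fuzzy_entropy,
    naive_cross_sample_entropy,
    naive_euclidean,
    naive_joint_distribution_entropy,
    naive_pearson,
)


class TestCrossSampleEntropy:
    def test_huge_tolerance_gives_analytic_floor(self, rng):
        # with every template pair matching, the match fraction at length m is
        # (n_m - 1)/n_m (self-index excluded, template count in the
        # denominator), so the entropy collapses to a tiny analytic constant
        # that vanishes as N grows
        n_samples, m = 60, 2
        x = rng.standard_normal(n_samples)
        y = rng.standard_normal(n_samples)
        r = 1e3 * np.concatenate([x, y]).std()
        n_m = n_samples - m + 1
        n_m1 = n_samples - m
        expected = -math.log(((n_m1 - 1) / n_m1) / ((n_m - 1) / n_m))
        got = cross_sample_entropy(x, y, m=m, r=r)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 < got < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        r = 0.2 * np.concatenate([x, y]).std()
        got = cross_sample_entropy(x, y, m=2, r=r)
        ref = naive_cross_sample_entropy(x.tolist(), y.tolist(), 2, r)
        assert got == pytest.approx(ref, rel=1e-12)

    def test_coupled_pair_less_entropic_than_noise(self):
        # identical sinusoids are maximally regular; independent noise is not
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(500) / 500
            s = np.sin(2 * np.pi * 5 * t)
            n1 = rng.standard_normal(500)
            n2 = rng.standard_normal(500)
            v_sine = cross_sample_entropy(s, s.copy(), m=2, r=0.15 * s.std())
            v_noise = cross_sample_entropy(n1, n2, m=2, r=0.15 * np.concatenate([n1, n2]).std())
            if v_sine < v_noise:
                wins += 1
        assert wins >= 18

    def test_undefined_when_no_matches(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 100.0
        with pytest.warns(RuntimeWarning):
            assert math.isnan(cross_sample_entropy(x, y, m=2, r=1e-8))

    def test_rejects_bad_input(self, rng):
        with pytest.raises(ValueError):
            cross_sample_entropy(rng.standard_normal(10), rng.standard_normal(9), 2, 0.2)
        with pytest.raises(ValueError):
            cross_sample_entropy(np.zeros(3), np.zeros(3), 2, 0.2)


class TestCrossFuzzyEntropy:
    @pytest.mark.parametrize("kernel", ["exponential", "gaussian"])
    def test_matches_brute_force(self, rng, kernel):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        got = cross_fuzzy_entropy(x, y, m=2, r=0.2, kernel=kernel)
        ref = naive_cross_fuzzy_entropy(x.tolist(), y.tolist(), 2, 0.2, kernel)
        assert got == pytest.approx(ref, rel=1e-12)

    def test_identical_inputs_reduce_to_self_entropy(self, rng):
        x = rng.standard_normal(80)
        assert cross_fuzzy_entropy(x, x.copy(), 2, 0.2) == pytest.approx(
            cross_fuzzy_entropy(x, x, 2, 0.2), rel=1e-12
        )

    def test_continuous_in_tolerance(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        a = cross_fuzzy_entropy(x, y, 2, 0.2)
        b = cross_fuzzy_entropy(x, y, 2, 0.2 + 1e-6)
        assert abs(a - b) < 1e-3

    def test_always_finite_even_for_distant_signals(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) + 50.0
        assert math.isfinite(cross_fuzzy_entropy(x, y, 2, 0.2))


class TestJointDistributionEntropy:
    def test_constant_difference_gives_zero_bits(self):
        x = np.full(20, 2.0)
        y = np.full(20, 5.0)  # every template distance identical -> one bin
        assert joint_distribution_entropy(x, y, m=2, B=16) == 0.0

    def test_uniform_bins_give_log2_bits(self):
        # x spans 0..63, y constant, m=1: every cross distance equals x_i, so
        # the 8 equal-width bins over [0, 63] each hold exactly 1/8 of the mass
        x = np.arange(64.0)
        y = np.zeros(64)
        val = joint_distribution_entropy(x, y, m=1, B=8)
        assert val == pytest.approx(3.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        got = joint_distribution_entropy(x, y, m=2, B=64)
        ref = naive_joint_distribution_entropy(x.tolist(), y.tolist(), 2, 64)
        assert got == pytest.approx(ref, rel=1e-12)


class TestPhaseLockingValue:
    def test_identical_signals_fully_locked(self, rng):
        x = rng.standard_normal(256)
        assert phase_locking_value(x, x.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_shift_fully_locked(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = np.sin(2 * np.pi * 10 * t + np.pi / 2)
        assert phase_locking_value(x, y) > 0.999

    def test_independent_noise_near_zero(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = phase_locking_value(rng.standard_normal(2000), rng.standard_normal(2000))
            if v < 0.1:
                low += 1
        assert low >= 18


class TestSpectralFeatures:
    def test_msc_of_scaled_copy_is_one(self, rng):
        x = rng.standard_normal(2048)
        cfg = SpectralConfig(window_length=256, overlap_fraction=0.5, band=(0.0, 500.0))
        mean, std = msc_features(x, 2.0 * x, cfg, fs=1000.0)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert std == pytest.approx(0.0, abs=1e-9)

    def test_msc_symmetric_in_pair_order(self, rng):
        x = rng.standard_normal(2048)
        y = rng.standard_normal(2048)
        cfg = SpectralConfig(window_length=256, overlap_fraction=0.5, band=(0.0, 500.0))
        assert msc_features(x, y, cfg, 1000.0) == pytest.approx(
            msc_features(y, x, cfg, 1000.0), abs=1e-12
        )

    def test_msc_requires_two_segments(self, rng):
        cfg = SpectralConfig(window_length=256, overlap_fraction=0.0)
        with pytest.raises(ValueError):
            msc_features(rng.standard_normal(256), rng.standard_normal(256), cfg, 1000.0)

    def test_cpsd_single_rect_window_matches_dft_product(self, rng):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        cfg = SpectralConfig(window_length=64, overlap_fraction=0.0,
                             window_shape="boxcar", band=(0.0, 500.0))
        _, s = cpsd(x, y, cfg, fs=1000.0)
        ref = np.fft.rfft(x) * np.conj(np.fft.rfft(y))
        np.testing.assert_allclose(s, ref, atol=1e-9)

    def test_cpsd_hermitian_under_swap(self, rng):
        x = rng.standard_normal(1024)
        y = rng.standard_normal(1024)
        cfg = SpectralConfig(window_length=256, overlap_fraction=0.5, band=(0.0, 500.0))
        re_m, re_s, im_m, im_s = cpsd_features(x, y, cfg, 1000.0)
        re_m2, re_s2, im_m2, im_s2 = cpsd_features(y, x, cfg, 1000.0)
        assert re_m == pytest.approx(re_m2, rel=1e-12)
        assert re_s == pytest.approx(re_s2, rel=1e-12)
        assert im_m == pytest.approx(-im_m2, rel=1e-12)
        assert im_s == pytest.approx(im_s2, rel=1e-12)

    def test_autospectrum_imaginary_part_vanishes(self, rng):
        x = rng.standard_normal(1024)
        cfg = SpectralConfig(window_length=256, overlap_fraction=0.5, band=(0.0, 500.0))
        _, _, im_m, _ = cpsd_features(x, x.copy(), cfg, 1000.0)
        assert im_m == pytest.approx(0.0, abs=1e-9)


class TestWaveformSimilarity:
    def test_pearson_affine_and_sign(self, rng):
        x = rng.standard_normal(100)
        assert pearson_correlation(x, 3 * x + 7) == pytest.approx(1.0, abs=1e-12)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0, abs=1e-12)
        ref = naive_pearson(x.tolist(), (x**2).tolist())
        assert pearson_correlation(x, x**2) == pytest.approx(ref, rel=1e-10)

    def test_pearson_rejects_constant(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.arange(10.0))

    def test_cosine_identities(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(x, x) == pytest.approx(1.0, abs=1e-12)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_similarity(x, -x) == pytest.approx(-1.0, abs=1e-12)
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), x)

    def test_euclidean_identities_and_oracle(self, rng):
        assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        assert euclidean_distance(x, y) == pytest.approx(
            naive_euclidean(x.tolist(), y.tolist()), abs=1e-10
        )
        assert euclidean_distance(x, x.copy()) == 0.0


class TestPairAndVectorAssembly:
    def test_pair_block_has_13_canonical_values(self, rng, fast_emb, fast_spec):
        x = rng.standard_normal(1024)
        y = rng.standard_normal(1024)
        pf = pair_features(x, y, fast_emb, fast_spec, fs=1000.0)
        assert pf.as_array().shape == (13,)
        assert len(MEASURES) == 13

    def test_identity_pair_feature_values(self, rng, fast_emb, fast_spec):
        x = rng.standard_normal(1024)
        pf = pair_features(x, x.copy(), fast_emb, fast_spec, fs=1000.0)
        assert pf.plv == pytest.approx(1.0, abs=1e-12)
        assert pf.pearson == pytest.approx(1.0, abs=1e-12)
        assert pf.cossim == pytest.approx(1.0, abs=1e-12)
        assert pf.euclid == 0.0

    def test_swap_symmetry_audit(self, rng, fast_emb, fast_spec):
        """12 of 13 features are order-invariant; cpsd_im_mean negates."""
        x = rng.standard_normal(1024)
        y = 0.5 * x + rng.standard_normal(1024)
        a = pair_features(x, y, fast_emb, fast_spec, 1000.0).as_array()
        b = pair_features(y, x, fast_emb, fast_spec, 1000.0).as_array()
        im_mean_idx = MEASURES.index("cpsd_im_mean")
        for i, meas in enumerate(MEASURES):
            if i == im_mean_idx:
                assert a[i] == pytest.approx(-b[i], rel=1e-9, abs=1e-12)
            else:
                assert a[i] == pytest.approx(b[i], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "drop,expected_len",
        [((), 130), (("E",), 78), (("E", "T", "M"), 13)],
    )
    def test_vector_length_scales_with_pairs(
        self, abnormal_recording, fast_emb, fast_spec, drop, expected_len
    ):
        rec = abnormal_recording
        channels = {s: x for s, x in rec.channels.items() if s not in drop}
        from heartcouple import MultiChannelRecording

        sub = MultiChannelRecording(channels=channels, fs=rec.fs, label=rec.label)
        fv = extract_features(sub, fast_emb, fast_spec)
        assert fv.values.size == expected_len
        assert len(fv.names) == expected_len

    def test_five_channel_pair_enumeration_order(self, abnormal_recording, fast_emb, fast_spec):
        fv = extract_features(abnormal_recording, fast_emb, fast_spec)
        assert tuple(fv.pair_order) == PAIR_ORDER_5
        assert fv.names[:13] == [f"AP_{m}" for m in MEASURES]
        assert feature_names("APTME") == fv.names

    def test_bounded_features_respect_ranges_on_random_pairs(self):
        """plv/msc in [0,1], pearson/cossim in [-1,1], spreads >= 0."""
        emb = EmbeddingConfig(max_points=64)
        spec = SpectralConfig(window_length=64, overlap_fraction=0.5, band=(0.0, 500.0))
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(256)
            y = rng.standard_normal(256)
            pf = pair_features(x, y, emb, spec, fs=1000.0)
            assert 0.0 <= pf.plv <= 1.0
            assert 0.0 <= pf.msc_mean <= 1.0
            assert -1.0 <= pf.pearson <= 1.0
            assert -1.0 <= pf.cossim <= 1.0
            assert pf.euclid >= 0.0
            assert pf.msc_std >= 0.0
            assert pf.cpsd_re_std >= 0.0
            assert pf.cpsd_im_std >= 0.0
            assert pf.jdisten >= 0.0
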