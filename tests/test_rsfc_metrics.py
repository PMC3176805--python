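import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from restkit import (
    CovariateSet,
    FrequencyBand,
    Mask,
    TimeCourse,
    Volume4D,
    alff_map,
    falff_map,
    fisher_z,
    kcc,
    partial_r,
    pearson_r,
    power_spectrum,
    reho_map,
    roi_wise_fc,
    seed_fc_map,
    standardize_by_mask_mean,
)
from restkit.rsfc_metrics import NEIGHBOR_OFFSETS, MetricMap
from restkit.synthetic_fixtures import default_affine

TR = 2.0


def tc(values, tr=TR):
    return TimeCourse(values=np.asarray(values, float), tr=tr)


def brute_force_kcc(cluster):
    """Independent oracle: explicit per-course ranking and rank-sum sums,
    in exact rational arithmetic (ranks are integers or half-integers)."""
    from fractions import Fraction

    cluster = np.asarray(cluster, float)
    k, n = cluster.shape
    ranks = np.array([sps.rankdata(row) for row in cluster])
    r = [Fraction(sum(ranks[i][t] for i in range(k))) for t in range(n)]
    rbar = Fraction(k * (n + 1), 2)
    num = sum(ri**2 for ri in r) - n * rbar**2
    return float(num / (Fraction(1, 12) * k**2 * (n**3 - n)))


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = tc(rng.standard_normal(30))
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = rng.standard_normal(30)
        assert pearson_r(tc(x), tc(-x)) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        x, y = np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 5])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_r(tc(x), tc(y)) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(tc(np.ones(10)), tc(np.arange(10.0)))


class TestPartialR:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = tc(rng.standard_normal(40)), tc(rng.standard_normal(40))
        empty = CovariateSet.empty(40)
        assert partial_r(x, y, empty) == pytest.approx(pearson_r(x, y))

    def test_shared_covariate_explains_correlation_away(self, rng):
        c = rng.standard_normal(60)
        x = tc(c.copy())
        y = tc(c + 0.05 * rng.standard_normal(60))
        covs = CovariateSet(matrix=c[:, None], names=["c"])
        with pytest.raises(ValueError):
            # x is exactly the covariate: zero-variance residual
            partial_r(x, y, covs)
        x2 = tc(c + 0.05 * rng.standard_normal(60))
        assert abs(partial_r(x2, y, covs)) < 0.5

    def test_matches_recursive_formula_oracle(self, rng):
        n = 50
        x, y, z = rng.standard_normal((3, n))
        covs = CovariateSet(matrix=z[:, None], names=["z"])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_r(tc(x), tc(y), covs) == pytest.approx(expected, abs=1e-10)


class TestKCC:
    def test_perfect_concordance_attains_one(self):
        cluster = np.tile(np.arange(1.0, 101.0), (27, 1))
        assert kcc(cluster) == 1.0

    def test_mean_rank_sum_constant(self):
        # with 27 courses of 100 points the mean rank sum is 27*101/2
        assert 27 * (100 + 1) / 2 == 1363.5

    def test_small_instance_matches_brute_force_exactly(self, rng):
        cluster = rng.standard_normal((3, 4))
        assert kcc(cluster) == brute_force_kcc(cluster)

    @given(st.integers(2, 27), st.integers(3, 30), st.integers(0, 10**6))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_oracle_equivalence_and_bounds(self, k, n, seed):
        cluster = np.random.default_rng(seed).standard_normal((k, n))
        w = kcc(cluster)
        assert w == brute_force_kcc(cluster)
        assert 0.0 <= w <= 1.0

    def test_ties_use_average_ranks(self):
        cluster = np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]])
        assert kcc(cluster) == brute_force_kcc(cluster)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            kcc(np.ones((1, 10)))


class TestSeedFC:
    def test_seed_equal_to_voxel_series_gives_r_one(self, small_vol, full_mask):
        seed = tc(small_vol.data[1, 2, 3])
        rmap, _ = seed_fc_map(small_vol, seed, full_mask)
        assert rmap.data[1, 2, 3] == pytest.approx(1.0)

    def test_planted_network_recovered(self, default_fixture):
        vol, truth = default_fixture
        net = truth["components"][0]["mask"]
        mask = truth["mask"]
        seed = tc(vol.data[net].mean(axis=0), tr=vol.tr)
        rmap, _ = seed_fc_map(vol, seed, mask)
        in_mean = rmap.data[net].mean()
        out_mean = rmap.data[~net & mask.data].mean()
        assert in_mean > out_mean + 0.3

    def test_fisher_z_of_zero_is_zero(self):
        assert fisher_z(np.array([0.0]))[0] == 0.0

    def test_constant_voxel_gets_zero_and_qc(self, small_vol, full_mask):
        vol = Volume4D(small_vol.data.copy(), small_vol.affine, small_vol.tr)
        vol.data[0, 0, 0] = 5.0
        seed = tc(vol.data[1, 1, 1])
        rmap, zmap = seed_fc_map(vol, seed, full_mask, fisher=True)
        assert rmap.data[0, 0, 0] == 0.0
        assert rmap.qc["zero_variance_voxels"] == 1
        assert np.isfinite(zmap.data).all()

    def test_out_of_mask_voxels_zero(self, small_vol):
        m = np.zeros(small_vol.spatial_shape, bool)
        m[:3] = True
        mask = Mask(m, small_vol.affine)
        rmap, _ = seed_fc_map(small_vol, tc(small_vol.data[0, 0, 0]), mask)
        assert (rmap.data[~m] == 0).all()

    def test_partial_fc_with_covariates(self, small_vol, full_mask, rng):
        covs = CovariateSet(matrix=rng.standard_normal((40, 2)), names=["a", "b"])
        seed = tc(small_vol.data[2, 2, 2])
        rmap, _ = seed_fc_map(small_vol, seed, full_mask, covs=covs)
        expected = partial_r(seed, tc(small_vol.data[4, 4, 4]), covs)
        assert rmap.data[4, 4, 4] == pytest.approx(expected, abs=1e-10)


class TestRoiWiseFC:
    def test_identical_series_give_unit_offdiagonal(self, rng):
        x = rng.standard_normal(30)
        m = roi_wise_fc([tc(x), tc(x.copy())])
        assert m[0, 1] == pytest.approx(1.0)

    def test_matrix_matches_elementwise_oracle(self, rng):
        tcs = [tc(rng.standard_normal(30)) for _ in range(3)]
        m = roi_wise_fc(tcs)
        assert np.allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)
        for i in range(3):
            for j in range(i + 1, 3):
                assert m[i, j] == pytest.approx(pearson_r(tcs[i], tcs[j]))


class TestReHo:
    def test_shared_series_gives_w_one_in_interior(self, rng):
        series = rng.standard_normal(50)
        data = np.tile(series, (6, 6, 6, 1))
        vol = Volume4D(data, default_affine(), tr=TR)
        mask = Mask(np.ones((6, 6, 6), bool), vol.affine)
        out = reho_map(vol, mask, neighbors=26)
        np.testing.assert_allclose(out.data[1:-1, 1:-1, 1:-1], 1.0, atol=1e-12)

    def test_white_noise_matches_permutation_null(self, rng):
        """Map mean near the null expectation E[W] ~ (K+1)/(K*n) for
        independent courses; spot-check 3 voxels against the direct
        cluster KCC."""
        n = 100
        vol = Volume4D(rng.standard_normal((8, 8, 8, n)), default_affine(), tr=TR)
        mask = Mask(np.ones((8, 8, 8), bool), vol.affine)
        out = reho_map(vol, mask, neighbors=26)
        interior = out.data[1:-1, 1:-1, 1:-1]
        null_mean = 1.0 / 27 * (1 + 26 / n * 0)  # leading term 1/K
        assert abs(interior.mean() - 1 / 27) < 0.02
        for vx in [(2, 3, 4), (4, 4, 4), (5, 2, 6)]:
            cluster = [vol.data[vx]]
            for off in NEIGHBOR_OFFSETS[26]:
                nb = tuple(np.add(vx, off))
                cluster.append(vol.data[nb])
            assert out.data[vx] == pytest.approx(kcc(np.array(cluster)), abs=1e-12)

    def test_stencil_offsets_hand_enumerated(self):
        assert {tuple(o) for o in NEIGHBOR_OFFSETS[6]} == {
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)}
        assert len(NEIGHBOR_OFFSETS[18]) == 18
        assert len(NEIGHBOR_OFFSETS[26]) == 26
        assert {tuple(o) for o in NEIGHBOR_OFFSETS[6]} <= {tuple(o) for o in NEIGHBOR_OFFSETS[18]}

    def test_values_within_unit_interval_for_all_stencils(self, small_vol, full_mask):
        for nb in (6, 18, 26):
            out = reho_map(small_vol, full_mask, neighbors=nb)
            assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_planted_homogeneous_region_detected(self, default_fixture):
        vol, truth = default_fixture
        region = truth["components"][1]["mask"]
        mask = truth["mask"]
        out = reho_map(vol, mask, neighbors=26)
        inside = out.data[region]
        outside = out.data[~region & mask.data]
        stat = sps.mannwhitneyu(inside, outside, alternative="greater")
        assert stat.pvalue < 0.01


class TestALFF:
    def test_constant_series_gives_zero(self):
        vol = Volume4D(np.full((2, 2, 2, 64), 7.0), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = alff_map(vol, FrequencyBand(0.01, 0.08), mask)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_amplitude_homogeneity(self):
        t = np.arange(100) * TR
        sig = np.sin(2 * np.pi * 0.05 * t)
        data = np.stack([np.tile(sig, (2, 2, 1)), np.tile(2 * sig, (2, 2, 1))])
        vol = Volume4D(data.reshape(2, 2, 2, 100), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = alff_map(vol, FrequencyBand(0.01, 0.08), mask)
        assert out.data[1, 0, 0] / out.data[0, 0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_matches_periodogram_oracle(self, rng):
        n = 200
        x = rng.standard_normal(n)
        vol = Volume4D(np.tile(x, (2, 2, 2, 1)), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = alff_map(vol, FrequencyBand(0.01, 0.08), mask)
        n_pad = 200  # 200 = 2^3 * 5^2
        freqs = np.fft.rfftfreq(n_pad, d=TR)
        amp = np.abs(np.fft.rfft(x, n=n_pad)) / np.sqrt(n_pad)
        band = (freqs >= 0.01) & (freqs <= 0.08) & (freqs > 0)
        assert out.data[0, 0, 0] == pytest.approx(amp[band].mean(), abs=1e-10)

    def test_dc_invariance(self, small_vol, full_mask):
        shifted = Volume4D(small_vol.data + 50.0, small_vol.affine, small_vol.tr)
        a = alff_map(small_vol, FrequencyBand(0.01, 0.08), full_mask)
        b = alff_map(shifted, FrequencyBand(0.01, 0.08), full_mask)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_band_above_nyquist_rejected(self, small_vol, full_mask):
        with pytest.raises(ValueError, match="Nyquist"):
            alff_map(small_vol, FrequencyBand(0.01, 0.3), full_mask)


class TestFALFF:
    def test_band_limited_signal_near_one(self):
        t = np.arange(100) * TR
        sig = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.03 * t)
        vol = Volume4D(np.tile(sig, (2, 2, 2, 1)), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = falff_map(vol, FrequencyBand(0.01, 0.08), mask)
        assert out.data[0, 0, 0] >= 0.99

    def test_out_of_band_signal_near_zero(self):
        t = np.arange(100) * TR
        sig = np.sin(2 * np.pi * 0.2 * t)
        vol = Volume4D(np.tile(sig, (2, 2, 2, 1)), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = falff_map(vol, FrequencyBand(0.01, 0.08), mask)
        assert out.data[0, 0, 0] < 0.01

    def test_mixed_signal_matches_ratio_of_sums_oracle(self, rng):
        x = rng.standard_normal(200)
        vol = Volume4D(np.tile(x, (2, 2, 2, 1)), default_affine(), tr=TR)
        mask = Mask(np.ones((2, 2, 2), bool), vol.affine)
        out = falff_map(vol, FrequencyBand(0.01, 0.08), mask)
        freqs = np.fft.rfftfreq(200, d=TR)
        amp = np.abs(np.fft.rfft(x, n=200)) / np.sqrt(200)
        band = (freqs >= 0.01) & (freqs <= 0.08) & (freqs > 0)
        expected = amp[band].sum() / amp[freqs > 0].sum()
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_in_unit_interval_and_constant_gets_qc(self, small_vol, full_mask):
        vol = Volume4D(small_vol.data.copy(), small_vol.affine, small_vol.tr)
        vol.data[0, 0, 0] = 3.0
        out = falff_map(vol, FrequencyBand(0.01, 0.08), full_mask)
        assert (out.data >= 0).all() and (out.data <= 1).all()
        assert out.data[0, 0, 0] == 0.0
        assert out.qc["zero_amplitude_voxels"] == 1


class TestStandardize:
    def test_uniform_map_becomes_ones(self, small_vol, full_mask):
        m = MetricMap(small_vol.spatial_volume3d(np.full(small_vol.spatial_shape, 4.2)),
                      "reho")
        out = standardize_by_mask_mean(m, full_mask)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_in_mask_mean_is_one(self, small_vol, full_mask, rng):
        m = MetricMap(small_vol.spatial_volume3d(
            rng.uniform(0.5, 2.0, small_vol.spatial_shape)), "alff")
        out = standardize_by_mask_mean(m, full_mask)
        assert out.data[full_mask.data].mean() == pytest.approx(1.0, abs=1e-12)

    def test_two_voxel_hand_arithmetic(self):
        arr = np.zeros((3, 1, 1))
        arr[0, 0, 0], arr[1, 0, 0] = 2.0, 4.0
        mdata = np.zeros((3, 1, 1), bool)
        mdata[0, 0, 0] = mdata[1, 0, 0] = True
        from restkit import Volume3D
        m = MetricMap(Volume3D(arr, np.eye(4)), "alff")
        out = standardize_by_mask_mean(m, Mask(mdata, np.eye(4)))
        assert out.data[0, 0, 0] == pytest.approx(2 / 3)
        assert out.data[1, 0, 0] == pytest.approx(4 / 3)


class TestPowerSpectrum:
    def test_pure_sinusoid_dominates_its_bin(self):
        t = np.arange(100) * TR
        freqs, power = power_spectrum(tc(np.sin(2 * np.pi * 0.05 * t)))
        assert freqs[np.argmax(power)] == pytest.approx(0.05)

    def test_detrend_lowers_lowest_bin_power(self, rng):
        x = 0.5 * np.arange(100) + rng.standard_normal(100)
        f_raw, p_raw = power_spectrum(tc(x), detrend_first=False)
        f_dt, p_dt = power_spectrum(tc(x), detrend_first=True)
        first = np.flatnonzero(f_raw > 0)[0]
        assert p_dt[first] < p_raw[first]

    def test_parseval_identity(self, rng):
        x = rng.standard_normal(100)
        _, power = power_spectrum(tc(x))
        assert power.sum() == pytest.approx(((x - x.mean()) ** 2).sum(), abs=1e-8)

    def test_frequencies_cover_zero_to_nyquist(self, rng):
        freqs, _ = power_spectrum(tc(rng.standard_normal(64)))
        assert freqs[0] == 0.0
        assert freqs[-1] == pytest.approx(0.25)
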