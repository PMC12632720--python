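import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynbag.fnc import (
    CleanOptions,
    ConnectivityMatrix,
    DegenerateDataError,
    Timecourses,
    clean_timecourses,
    compute_dfnc,
    compute_sfnc,
    make_taper,
    matrix_from_upper,
    pearson,
    subnetwork_slice,
    vectorize_upper,
    weighted_pearson,
    window_duration_seconds,
    TaperedWindow,
)


# ---------------------------------------------------------------------------
# Pearson correlation


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_negative_affine_transform_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # direct evaluation of the correlation formula by hand:
        # both series have mean 2.5; sum of products = 3;
        # both sums of squares = 5 -> r = 3/5
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_raises_explicitly(self):
        with pytest.raises(DegenerateDataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pearson(3.2 * x + 1, 0.5 * y - 4) == pytest.approx(pearson(x, y))


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_plain_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert weighted_pearson(x, y, np.ones(40)) == pytest.approx(
            pearson(x, y), abs=1e-12
        )

    def test_matches_bruteforce_weighted_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        w = rng.uniform(0.1, 1.0, size=30)
        # independent brute-force evaluation
        wn = w / w.sum()
        mx, my = wn @ x, wn @ y
        cov = wn @ ((x - mx) * (y - my))
        r_oracle = cov / np.sqrt((wn @ (x - mx) ** 2) * (wn @ (y - my) ** 2))
        assert weighted_pearson(x, y, w) == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_weighted_variance_raises(self):
        w = np.array([1.0, 1.0, 0.0])
        with pytest.raises(DegenerateDataError):
            weighted_pearson([2.0, 2.0, 9.0], [1.0, 2.0, 3.0], w)


# ---------------------------------------------------------------------------
# static FNC


class TestStaticFnc:
    def test_53_components_give_1378_features(self):
        rng = np.random.default_rng(3)
        tc = Timecourses(data=rng.normal(size=(120, 53)), tr=2.0)
        vec = vectorize_upper(compute_sfnc(tc))
        assert vec.shape == (1378,)

    def test_matrix_equals_bruteforce_pairwise_loop(self):
        rng = np.random.default_rng(4)
        tc = Timecourses(data=rng.normal(size=(60, 6)), tr=2.0)
        m = compute_sfnc(tc).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert m[i, j] == pytest.approx(
                    pearson(tc.data[:, i], tc.data[:, j]), abs=1e-12
                )

    def test_independent_noise_has_small_offdiagonals(self):
        rng = np.random.default_rng(5)
        tc = Timecourses(data=rng.normal(size=(10_000, 53)), tr=2.0)
        m = compute_sfnc(tc).values
        off = np.abs(m[np.triu_indices(53, 1)])
        assert off.max() < 0.05

    def test_invariant_under_column_standardization(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 8)) * rng.uniform(0.5, 4, 8) + rng.normal(size=8)
        a = compute_sfnc(Timecourses(data=x, tr=2.0)).values
        xs = (x - x.mean(0)) / x.std(0)
        b = compute_sfnc(Timecourses(data=xs, tr=2.0)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_variance_component_identified(self):
        x = np.random.default_rng(7).normal(size=(50, 3))
        x[:, 1] = 4.0
        with pytest.raises(DegenerateDataError, match="component 1"):
            compute_sfnc(Timecourses(data=x, tr=2.0))


# ---------------------------------------------------------------------------
# tapered window


class TestTaper:
    def test_matches_direct_convolution_oracle(self):
        w = make_taper(20, 3.0).weights
        # brute-force discrete convolution of rect(20) with the Gaussian
        radius = int(np.ceil(4 * 3.0))
        t = np.arange(-radius, radius + 1)
        kern = np.exp(-0.5 * (t / 3.0) ** 2)
        kern /= kern.sum()
        full = np.zeros(20 + 2 * radius)
        for i in range(20):
            for j, kv in enumerate(kern):
                full[i + j] += kv
        start = (full.size - 20) // 2
        oracle = full[start:start + 20]
        oracle /= oracle.max()
        np.testing.assert_allclose(w, oracle, atol=1e-10)

    def test_symmetry(self):
        w = make_taper(20, 3.0).weights
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)

    def test_sigma_to_zero_limit_is_rectangular(self):
        w = make_taper(10, 1e-6).weights
        np.testing.assert_allclose(w, np.ones(10), atol=1e-9)

    def test_window_duration_arithmetic(self):
        assert window_duration_seconds(20, 2.0) == pytest.approx(40.0)
        assert window_duration_seconds(20, 0.735) == pytest.approx(14.7)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            make_taper(2, 3.0)


# ---------------------------------------------------------------------------
# dynamic FNC


class TestDynamicFnc:
    def test_window_count_formula(self):
        rng = np.random.default_rng(8)
        tc = Timecourses(data=rng.normal(size=(490, 4)), tr=2.0)
        d = compute_dfnc(tc, make_taper(20, 3.0), stride=1)
        assert d.n_windows == 471  # floor((490-20)/1) + 1

    @pytest.mark.parametrize("stride", [1, 2, 5])
    def test_window_count_with_stride(self, stride):
        rng = np.random.default_rng(9)
        t = 137
        tc = Timecourses(data=rng.normal(size=(t, 3)), tr=2.0)
        d = compute_dfnc(tc, make_taper(20, 3.0), stride=stride)
        assert d.n_windows == (t - 20) // stride + 1
        assert d.starts[-1] + 20 <= t

    def test_each_window_is_a_valid_correlation_matrix(self):
        rng = np.random.default_rng(10)
        tc = Timecourses(data=rng.normal(size=(90, 5)), tr=2.0)
        d = compute_dfnc(tc, make_taper(20, 3.0))
        for w in d.windows:
            np.testing.assert_allclose(w, w.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(w), 1.0, atol=1e-12)
            assert np.abs(w).max() <= 1.0 + 1e-12

    def test_full_length_uniform_window_equals_static_fnc(self):
        rng = np.random.default_rng(11)
        t = 64
        tc = Timecourses(data=rng.normal(size=(t, 5)), tr=2.0)
        uniform = TaperedWindow(length=t, sigma=1.0, weights=np.ones(t))
        d = compute_dfnc(tc, uniform, stride=1)
        assert d.n_windows == 1
        np.testing.assert_allclose(d.windows[0], compute_sfnc(tc).values, atol=1e-12)

    def test_windowed_values_match_weighted_pearson(self):
        rng = np.random.default_rng(12)
        tc = Timecourses(data=rng.normal(size=(50, 3)), tr=2.0)
        taper = make_taper(20, 3.0)
        d = compute_dfnc(tc, taper, stride=7)
        for wi, s in enumerate(d.starts):
            seg = tc.data[s:s + 20]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert d.windows[wi, i, j] == pytest.approx(
                        weighted_pearson(seg[:, i], seg[:, j], taper.weights),
                        abs=1e-10,
                    )

    def test_degenerate_window_names_index(self):
        x = np.random.default_rng(13).normal(size=(60, 3))
        x[25:50, 2] = 0.5  # flat inside later windows
        with pytest.raises(DegenerateDataError, match="window"):
            compute_dfnc(Timecourses(data=x, tr=2.0), make_taper(20, 3.0))


# ---------------------------------------------------------------------------
# vectorization and slicing


class TestVectorize:
    def test_smallest_case(self):
        m = ConnectivityMatrix(values=np.array([[1.0, 0.3], [0.3, 1.0]]))
        assert vectorize_upper(m).tolist() == [0.3]

    @given(st.integers(min_value=2, max_value=12))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_roundtrip_reconstructs_matrix(self, c):
        rng = np.random.default_rng(c)
        a = rng.uniform(-1, 1, size=(c, c))
        a = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(a, 1.0)
        vec = vectorize_upper(a)
        assert vec.shape == (c * (c - 1) // 2,)
        np.testing.assert_allclose(matrix_from_upper(vec), a, atol=1e-15)

    def test_row_major_order(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.1
        a[0, 2] = a[2, 0] = 0.2
        a[1, 2] = a[2, 1] = 0.3
        assert vectorize_upper(a).tolist() == [0.1, 0.2, 0.3]


class TestSubnetworkSlice:
    def test_slices_partition_the_components(self, small_cohort, small_spec):
        part = small_spec.partition
        _, scans = small_cohort
        m = compute_sfnc(list(scans.values())[0])
        seen = []
        for net in part.networks:
            sub = subnetwork_slice(m, part, net)
            assert sub.n_components == len(part.indices(net))
            seen.extend(part.indices(net))
        assert sorted(seen) == list(range(part.n_components))

    def test_slice_values_equal_parent_entries(self, small_cohort, small_spec):
        part = small_spec.partition
        _, scans = small_cohort
        tc = list(scans.values())[0]
        m = compute_sfnc(tc)
        d = compute_dfnc(tc, make_taper(20, 3.0), stride=10)
        net = part.networks[4]  # CCN: largest
        idx = np.asarray(part.indices(net))
        sub_m = subnetwork_slice(m, part, net)
        np.testing.assert_array_equal(sub_m.values, m.values[np.ix_(idx, idx)])
        sub_d = subnetwork_slice(d, part, net)
        np.testing.assert_array_equal(
            sub_d.windows, d.windows[:, idx[:, None], idx[None, :]]
        )

    def test_unknown_network_lists_valid_labels(self, small_spec):
        m = ConnectivityMatrix(values=np.eye(10))
        with pytest.raises(KeyError, match="valid labels"):
            subnetwork_slice(m, small_spec.partition, "FOO")


# ---------------------------------------------------------------------------
# denoising


class TestCleaning:
    def test_cubic_polynomial_annihilated_by_detrending(self):
        t = np.linspace(0, 1, 200)
        x = np.column_stack([1 + 2 * t - t**2 + 0.5 * t**3,
                             -3 + t + 4 * t**3])
        opts = CleanOptions(detrend_order=3, clip_mad=None, lowpass_hz=None)
        out = clean_timecourses(Timecourses(data=x, tr=2.0), opts)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_all_stages_disabled_is_identity(self):
        x = np.random.default_rng(14).normal(size=(80, 4))
        opts = CleanOptions(detrend_order=0, clip_mad=None, lowpass_hz=None)
        out = clean_timecourses(Timecourses(data=x, tr=2.0), opts)
        np.testing.assert_array_equal(out.data, x)

    def test_slow_oscillation_passes_lowpass(self):
        t = np.arange(500) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)[:, None] * np.ones((1, 3))
        out = clean_timecourses(Timecourses(data=x, tr=2.0))
        assert (out.data**2).sum() >= 0.9 * (x**2).sum()

    def test_fast_oscillation_attenuated_at_short_tr(self):
        t = np.arange(1000) * 0.72
        x = np.sin(2 * np.pi * 0.25 * t)[:, None] * np.ones((1, 2))
        out = clean_timecourses(Timecourses(data=x, tr=0.72))
        assert (out.data**2).sum() <= 0.05 * (x**2).sum()

    def test_cutoff_at_or_above_nyquist_rejected_with_value(self):
        x = np.random.default_rng(15).normal(size=(50, 2))
        with pytest.raises(ValueError, match="0.125"):
            clean_timecourses(Timecourses(data=x, tr=4.0))

    def test_nuisance_regression_removes_injected_confound(self):
        rng = np.random.default_rng(16)
        motion = rng.normal(size=(300, 2))
        x = rng.normal(size=(300, 3)) + motion @ np.array([[2.0, 0.0, 1.0],
                                                           [0.0, 3.0, -1.0]])
        opts = CleanOptions(detrend_order=0, nuisance=motion,
                            nuisance_derivatives=False, clip_mad=None,
                            lowpass_hz=None)
        out = clean_timecourses(Timecourses(data=x, tr=2.0), opts)
        for j in range(3):
            for k in range(2):
                assert abs(pearson(out.data[:, j], motion[:, k])) < 1e-10
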