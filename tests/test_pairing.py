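"""Pair pooling and bivariate-Gaussian coefficient statistics."""
import numpy as np
import pytest

from plumespect.corrmodels import coefficient_covariance
from plumespect.pairing import (
    build_pairs,
    coupling_stats,
    pair_statistics,
    principal_variances,
    sigma2,
    stack,
)
from plumespect.spectral import TrigCoefficients, WindowSpec, decompose
from plumespect.fixtures import make_fixture


def _collinear(n, spacing):
    return np.column_stack([np.zeros(n), np.arange(n) * spacing])


def _coeffs_from_array(arr):
    """Wrap an (W, S, H+1, 2) array as TrigCoefficients (odd-length)."""
    H = arr.shape[2] - 1
    return TrigCoefficients(
        coeffs=np.asarray(arr, dtype=float),
        segment_length=2 * H + 1,
        sample_rate=float(2 * H + 1),
        window=WindowSpec(1.0, "boxcar"),
    )


class TestBuildPairs:
    def test_three_collinear_sources(self):
        ps = build_pairs(_collinear(3, 0.01))
        nonzero = sorted(s for s in ps.separations if s != 0)
        assert np.allclose(nonzero, [-0.02, -0.01, 0.01, 0.02])
        assert len(ps.pairs(0.01)) == 2
        assert len(ps.pairs(0.02)) == 1
        assert len(ps.pairs(0.0)) == 3  # self-pairs

    def test_sixteen_equally_spaced(self):
        ps = build_pairs(_collinear(16, 0.0075))
        assert len(ps.pairs(0.0075)) == 15
        assert len(ps.pairs(-0.0075)) == 15
        assert ps.n_of(0.0075, n_windows=10) == 2 * 10 * 15

    def test_cross_stream_grid_matches_brute_force_census(self):
        # mirrored centreline grid: y = +/-(0.00375 + 0.0075 k), k = 0..7
        y = np.concatenate(
            [0.00375 + 0.0075 * np.arange(8), -(0.00375 + 0.0075 * np.arange(8))]
        )
        pos = np.column_stack([np.zeros(16), y])
        ps = build_pairs(pos, tol=1e-9)
        census: dict = {}
        for i in range(16):
            for j in range(16):
                d = round((y[i] - y[j]) / 1e-9) * 1e-9
                census[d] = census.get(d, 0) + 1
        assert len(ps.separations) == len(census)
        for s in ps.separations:
            key = min(census, key=lambda k: abs(k - s))
            assert abs(key - s) < 1e-9
            assert len(ps.pairs(s)) == census[key]

    def test_pitch_units(self):
        ps = build_pairs(_collinear(3, 0.0075), units="pitch", pitch=0.025)
        assert np.isclose(ps.separations, 0.3).any()

    def test_missing_separation_gives_empty_flagged_group(self):
        ps = build_pairs(_collinear(3, 0.01), distances=[0.01, 0.005])
        assert ps.pairs(0.005) == []
        assert len(ps.pairs(0.01)) == 2

    def test_folding_merges_signed_separations(self):
        ps = build_pairs(_collinear(3, 0.01)).folded()
        assert (ps.separations >= 0).all()
        assert len(ps.pairs(0.01)) == 4


class TestStack:
    def test_column_count_is_two_windows_pairs(self, rng):
        arr = rng.standard_normal((3, 2, 5, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(2, 0.01))
        data = stack(c, ps, n=1, s=0.01)
        assert data.shape == (2, 6)  # 2 x (2 components x 3 windows x 1 pair)

    def test_self_separation_gives_identical_rows(self, rng):
        arr = rng.standard_normal((4, 3, 5, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(3, 0.01))
        data = stack(c, ps, n=2, s=0.0)
        assert np.array_equal(data[0], data[1])

    def test_matches_naive_assembly(self, rng):
        arr = rng.standard_normal((5, 4, 6, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(4, 0.01))
        n, s = 3, 0.01
        top, bot = [], []
        for i, j in ps.pairs(s):
            for comp in (0, 1):
                for w in range(5):
                    top.append(arr[w, i, n, comp])
                    bot.append(arr[w, j, n, comp])
        data = stack(c, ps, n, s)
        assert np.allclose(data, np.vstack([top, bot]))

    def test_harmonic_out_of_range_raises(self, rng):
        c = _coeffs_from_array(rng.standard_normal((3, 2, 5, 2)))
        ps = build_pairs(_collinear(2, 0.01))
        with pytest.raises(ValueError):
            stack(c, ps, n=9, s=0.01)


class TestPrincipalVariances:
    def test_identical_rows(self, rng):
        row = rng.standard_normal(500)
        lam, mu = principal_variances(np.vstack([row, row]))
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert lam == pytest.approx(2 * np.mean(row**2), rel=1e-12)

    def test_negated_rows(self, rng):
        row = rng.standard_normal(500)
        lam, mu = principal_variances(np.vstack([row, -row]))
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_correlation(self, rng):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=100_000).T
        lam, mu = principal_variances(X)
        assert (lam - mu) / (lam + mu) == pytest.approx(0.6, abs=0.01)


class TestSigma2:
    def test_unit_coefficients(self):
        arr = np.ones((4, 2, 3, 2))
        arr[::2] = -1.0
        c = _coeffs_from_array(arr)
        assert sigma2(c, None, 1) == pytest.approx(1.0)

    def test_quadratic_scaling(self, rng):
        arr = rng.standard_normal((4, 2, 3, 2))
        c1 = _coeffs_from_array(arr)
        c2 = _coeffs_from_array(3.0 * arr)
        assert sigma2(c2, None, 1) == pytest.approx(9.0 * sigma2(c1, None, 1))

    def test_matches_pooled_second_moment(self, rng):
        arr = rng.standard_normal((6, 3, 4, 2))
        c = _coeffs_from_array(arr)
        assert sigma2(c, None, 2) == pytest.approx(np.mean(arr[:, :, 2, :] ** 2))

    def test_equals_half_lambda_at_zero_separation(self, rng):
        arr = rng.standard_normal((6, 3, 4, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(3, 0.01))
        lam0, _ = principal_variances(stack(c, ps, 2, 0.0))
        assert sigma2(c, ps, 2) == pytest.approx(lam0 / 2.0, rel=1e-12)


class TestCouplingStats:
    def test_self_pairs_have_identity_coupling(self, rng):
        arr = rng.standard_normal((8, 3, 4, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(3, 0.01))
        st = coupling_stats(c, ps, 1, 0.0)
        assert st.rho == pytest.approx(1.0, rel=1e-12)
        assert st.rho_perp == pytest.approx(0.0, abs=1e-12)
        assert st.beta == pytest.approx(1.0, rel=1e-12)
        assert st.theta == pytest.approx(0.0, abs=1e-12)
        assert st.eta2 == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_pair_has_out_of_phase_correlation(self):
        series = make_fixture("quadrature")
        c = decompose(series, WindowSpec(1.0, "boxcar"))
        ps = build_pairs(series.positions)
        st = coupling_stats(c, ps, 3, 0.0075)
        assert abs(st.rho) < 0.05
        assert abs(st.rho_perp) == pytest.approx(1.0, abs=0.05)

    def test_recovers_known_coupling_from_coefficient_model(self, rng):
        # sample coefficient quadruples with beta=0.8, theta=0.3
        beta, theta, n = 0.8, 0.3, 100_000
        cov = coefficient_covariance(1.0, beta, theta)
        X = rng.multivariate_normal(np.zeros(4), cov, size=n)
        arr = np.zeros((n, 2, 2, 2))
        arr[:, 0, 1, 0] = X[:, 0]
        arr[:, 0, 1, 1] = X[:, 1]
        arr[:, 1, 1, 0] = X[:, 2]
        arr[:, 1, 1, 1] = X[:, 3]
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(2, 0.01))
        st = coupling_stats(c, ps, 1, -0.01)  # pair (1, 0): c,d given a,b
        assert st.rho == pytest.approx(beta * np.cos(theta), abs=0.01)
        assert st.rho_perp == pytest.approx(beta * np.sin(theta), abs=0.01)

    def test_degenerate_harmonic_raises(self):
        arr = np.zeros((4, 2, 3, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(2, 0.01))
        with pytest.raises(ValueError, match="degenerate"):
            coupling_stats(c, ps, 1, 0.01)


class TestEstimatorEquivalence:
    def test_principal_variance_route_equals_product_route(self, rng):
        # (lambda - mu) / 2 == pooled <ac + bd> / 2 exactly
        arr = rng.standard_normal((7, 4, 5, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(4, 0.01))
        for s in (0.01, 0.02):
            st = coupling_stats(c, ps, 2, s)
            assert (st.lam - st.mu) / 2 == pytest.approx(
                st.rho * 2 * st.sigma2 / 2, rel=1e-10
            )

    def test_mean_component_correlation_equals_sigma2_rho(self, rng):
        # <r_n> at separation s equals sigma_n^2 rho_n(s): same data two routes
        from plumespect.spectral import harmonic_correlations

        arr = rng.standard_normal((7, 4, 5, 2))
        c = _coeffs_from_array(arr)
        ps = build_pairs(_collinear(4, 0.01))
        s, n = 0.01, 2
        st = coupling_stats(c, ps, n, s)
        rs = []
        for i, j in ps.pairs(s):
            r = harmonic_correlations(arr[:, i], arr[:, j], c.segment_length)
            rs.append(r[:, n])
        assert np.mean(rs) == pytest.approx(st.sigma2 * st.rho, abs=1e-9)

    def test_surrogate_location_independence(self, equal_informative_sample):
        # translation-invariant kernel: per-pair rho at equal s agree
        sample = equal_informative_sample
        coeffs = sample.as_trig_coefficients()
        pos = np.column_stack(
            [np.zeros(sample.spec.M), np.arange(sample.spec.M, dtype=float)]
        )
        ps = build_pairs(pos)
        n, s = 3, 1.0
        per_pair = []
        s2 = sigma2(coeffs, ps, n)
        for i, j in ps.pairs(s):
            sub = build_pairs(pos[[i, j]], include_self=False)
            st = coupling_stats(coeffs, sub, n, 1.0, sigma2_n=s2)
            per_pair.append(st.rho)
        # Monte-Carlo error of each per-pair estimate ~ 1/sqrt(2 * 2000)
        assert np.std(per_pair) < 4.0 / np.sqrt(2 * 2000)


def test_pair_statistics_table_schema(small_series, boxcar):
    c = decompose(small_series, boxcar)
    ps = build_pairs(small_series.positions, units="pitch", pitch=small_series.pitch)
    table = pair_statistics(c, ps, harmonics=np.array([1, 2]))
    assert {"harmonic_hz", "separation", "sigma2", "rho", "rho_perp", "beta",
            "theta", "n_samples"} <= set(table.columns)
    # eta2 = sigma2 (1 - beta^2) and rho^2 + rho_perp^2 = beta^2
    assert np.allclose(table["eta2"], table["sigma2"] * (1 - table["beta"] ** 2))
    assert np.allclose(
        table["rho"] ** 2 + table["rho_perp"] ** 2, table["beta"] ** 2, atol=1e-9
    )
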