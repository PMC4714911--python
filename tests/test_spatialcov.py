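import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import wishart as scipy_wishart

from geogen.freqstats import centering_matrix, projection_matrix
from geogen.spatialcov import (
    AdmixtureParams,
    CovParams,
    LocationSet,
    admixed_cov,
    distance_matrix,
    model_cov,
    spatial_cov,
    wishart_loglik,
)


def wishart_logpdf_oracle(A, Sigma, df):
    """Textbook Wishart log density, written independently of the package
    (explicit multivariate gamma as a sum of log gammas)."""
    p = A.shape[0]
    sign_a, logdet_a = np.linalg.slogdet(A)
    sign_s, logdet_s = np.linalg.slogdet(Sigma)
    assert sign_a > 0 and sign_s > 0
    log_gamma_p = (p * (p - 1) / 4.0) * np.log(np.pi) + sum(
        gammaln(df / 2.0 + (1 - j) / 2.0) for j in range(1, p + 1)
    )
    return (
        0.5 * (df - p - 1) * logdet_a
        - 0.5 * np.trace(np.linalg.solve(Sigma, A))
        - 0.5 * df * p * np.log(2.0)
        - 0.5 * df * logdet_s
        - log_gamma_p
    )


def random_instance(K, seed, metric="euclidean"):
    r = np.random.default_rng(seed)
    if metric == "euclidean":
        coords = r.uniform(0, 4, size=(K, 2))
    else:
        coords = np.column_stack(
            [r.uniform(-60, 60, K), r.uniform(-40, 40, K)]
        )
    G = LocationSet(coords, metric=metric)
    p = CovParams(
        alpha0=r.uniform(0.5, 2.0),
        alpha1=r.uniform(0.3, 1.5),
        alpha2=r.uniform(0.5, 1.5),
    )
    eta = r.uniform(0.01, 0.3, K)
    sbar = r.uniform(5, 20, K)
    return G, p, eta, sbar, r


class TestDistances:
    def test_identical_points_zero(self):
        a = LocationSet([[12.0, 34.0]], metric="sphere")
        assert distance_matrix(a)[0, 0] == 0.0

    def test_quarter_arc_along_equator(self):
        a = LocationSet([[0.0, 0.0]], metric="sphere")
        b = LocationSet([[90.0, 0.0]], metric="sphere")
        assert distance_matrix(a, b)[0, 0] == pytest.approx(np.pi / 2)

    def test_antipodal_points(self):
        a = LocationSet([[0.0, 0.0]], metric="sphere")
        b = LocationSet([[180.0, 0.0]], metric="sphere")
        assert distance_matrix(a, b)[0, 0] == pytest.approx(np.pi)

    def test_euclidean_mode(self):
        a = LocationSet([[0.0, 0.0], [3.0, 4.0]], metric="euclidean")
        D = distance_matrix(a)
        assert D[0, 1] == pytest.approx(5.0)
        assert D[1, 0] == pytest.approx(5.0)

    def test_mixed_metrics_rejected(self):
        a = LocationSet([[0.0, 0.0]], metric="sphere")
        b = LocationSet([[0.0, 0.0]], metric="euclidean")
        with pytest.raises(ValueError, match="mix metrics"):
            distance_matrix(a, b)


class TestCovarianceModel:
    def test_zero_distance_gives_sill(self):
        p = CovParams(2.0, 1.3, 0.8)
        assert spatial_cov(np.array([[0.0]]), p)[0, 0] == pytest.approx(0.5)

    def test_closed_form_at_log_two(self):
        p = CovParams(1.0, 1.0, 1.0)
        v = spatial_cov(np.array([[np.log(2.0)]]), p)[0, 0]
        assert v == pytest.approx(0.5)

    def test_strictly_decreasing_in_distance(self):
        p = CovParams(1.0, 0.7, 1.4)
        d = np.linspace(0, 5, 50)[None, :]
        vals = spatial_cov(d, p)[0]
        assert np.all(np.diff(vals) < 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CovParams(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            CovParams(1.0, 1.0, 2.5)
        with pytest.raises(ValueError):
            CovParams(1.0, 1.0, 0.1)

    def test_model_cov_diagonal_and_offdiagonal(self):
        G, p, eta, sbar, _ = random_instance(4, 1)
        Om = model_cov(G, p, eta, sbar)
        D = distance_matrix(G)
        F = spatial_cov(D, p)
        np.testing.assert_allclose(
            np.diag(Om), 1.0 / p.alpha0 + eta + 1.0 / sbar
        )
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(Om[off], F[off])

    def test_model_cov_size_mismatch(self):
        G, p, eta, sbar, _ = random_instance(4, 2)
        with pytest.raises(ValueError, match="mismatch"):
            model_cov(G, p, eta[:3], sbar)

    def test_admixture_zero_reduces_to_plain_model(self):
        G, p, eta, sbar, r = random_instance(5, 3)
        sources = LocationSet(r.uniform(0, 4, (5, 2)), metric="euclidean")
        adm = AdmixtureParams(np.zeros(5), sources)
        np.testing.assert_allclose(
            admixed_cov(G, adm, p, eta, sbar),
            model_cov(G, p, eta, sbar),
            atol=1e-14,
        )

    def test_half_admixture_from_own_location_is_identity(self):
        G, p, eta, sbar, _ = random_instance(5, 4)
        adm = AdmixtureParams(np.full(5, 0.5), G)
        np.testing.assert_allclose(
            admixed_cov(G, adm, p, eta, sbar),
            model_cov(G, p, eta, sbar),
            atol=1e-14,
        )

    def test_two_population_four_term_sum_oracle(self):
        # brute-force evaluation of the mixture of spatial covariances
        G = LocationSet([[0.0, 0.0], [2.0, 1.0]], metric="euclidean")
        sources = LocationSet([[4.0, 4.0], [1.0, 3.0]], metric="euclidean")
        w = np.array([0.4, 0.0])
        p = CovParams(1.3, 0.6, 1.1)
        eta = np.array([0.1, 0.2])
        sbar = np.array([8.0, 12.0])
        Om = admixed_cov(G, AdmixtureParams(w, sources), p, eta, sbar)

        def f(a, b):
            d = np.hypot(a[0] - b[0], a[1] - b[1])
            return np.exp(-((p.alpha1 * d) ** p.alpha2)) / p.alpha0

        pts = {0: G.coords[0], 1: G.coords[1],
               "0*": sources.coords[0], "1*": sources.coords[1]}
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                expected[i, j] = (
                    (1 - w[i]) * (1 - w[j]) * f(pts[i], pts[j])
                    + w[i] * (1 - w[j]) * f(pts[f"{i}*"], pts[j])
                    + w[j] * (1 - w[i]) * f(pts[i], pts[f"{j}*"])
                    + w[i] * w[j] * f(pts[f"{i}*"], pts[f"{j}*"])
                )
            expected[i, i] += eta[i] + 1.0 / sbar[i]
        np.testing.assert_allclose(Om, expected, atol=1e-12)

    def test_admixture_proportion_cap(self):
        G = LocationSet([[0.0, 0.0], [1.0, 0.0]], metric="euclidean")
        with pytest.raises(ValueError, match="0.5"):
            AdmixtureParams(np.array([0.6, 0.0]), G)


class TestWishartLoglik:
    @pytest.mark.parametrize("K", [3, 4, 5])
    def test_matches_independent_density_oracle(self, K):
        G, p, eta, sbar, r = random_instance(K, K + 10)
        Om = model_cov(G, p, eta, sbar)
        T = centering_matrix(sbar)
        psi = projection_matrix(T)
        L = 50
        X = np.linalg.cholesky(Om) @ r.standard_normal((K, L))
        omega_hat = X @ X.T / L
        got = wishart_loglik(omega_hat, Om, psi, L)
        A = L * psi.T @ omega_hat @ psi
        Sigma = psi.T @ Om @ psi
        assert got == pytest.approx(
            wishart_logpdf_oracle(A, Sigma, L), rel=1e-10
        )
        assert got == pytest.approx(
            scipy_wishart.logpdf(A, df=L, scale=Sigma), rel=1e-10
        )

    def test_insufficient_loci_rejected(self):
        G, p, eta, sbar, _ = random_instance(5, 20)
        Om = model_cov(G, p, eta, sbar)
        psi = projection_matrix(centering_matrix(sbar))
        with pytest.raises(ValueError, match="insufficient loci"):
            wishart_loglik(Om, Om, psi, 3)

    def test_non_positive_definite_scale_returns_neg_inf(self):
        K = 4
        sbar = np.full(K, 10.0)
        psi = projection_matrix(centering_matrix(sbar))
        omega_hat = np.eye(K)
        v = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2.0)
        bad = np.eye(K) - 1.5 * np.outer(v, v)  # negative in centered space
        assert wishart_loglik(omega_hat, bad, psi, 100) == -np.inf

    def test_invariant_to_rigid_motion_of_all_locations(self):
        K = 5
        G, p, eta, sbar, r = random_instance(K, 30)
        sources = LocationSet(r.uniform(0, 4, (K, 2)), metric="euclidean")
        w = r.uniform(0, 0.4, K)
        omega_hat = model_cov(G, p, eta, sbar)
        psi = projection_matrix(centering_matrix(sbar))
        base = wishart_loglik(
            omega_hat,
            admixed_cov(G, AdmixtureParams(w, sources), p, eta, sbar),
            psi, 100,
        )
        for seed in range(5):
            rr = np.random.default_rng(seed)
            theta = rr.uniform(0, 2 * np.pi)
            R = np.array(
                [[np.cos(theta), -np.sin(theta)],
                 [np.sin(theta), np.cos(theta)]]
            )
            t = rr.uniform(-10, 10, 2)
            G2 = LocationSet(G.coords @ R + t, metric="euclidean")
            S2 = LocationSet(sources.coords @ R + t, metric="euclidean")
            moved = wishart_loglik(
                omega_hat,
                admixed_cov(G2, AdmixtureParams(w, S2), p, eta, sbar),
                psi, 100,
            )
            assert moved == pytest.approx(base, abs=1e-8)

    def test_invariant_to_sphere_rotation(self):
        K = 4
        r = np.random.default_rng(5)
        lonlat = np.column_stack([r.uniform(-90, 90, K), r.uniform(-45, 45, K)])
        G = LocationSet(lonlat, metric="sphere")
        p = CovParams(1.0, 1.0, 1.0)
        eta = np.full(K, 0.1)
        sbar = np.full(K, 10.0)
        omega_hat = model_cov(G, p, eta, sbar)
        psi = projection_matrix(centering_matrix(sbar))
        base = wishart_loglik(
            omega_hat, model_cov(G, p, eta, sbar), psi, 100
        )
        # rotate all points about an arbitrary 3-D axis
        rad = np.deg2rad(lonlat)
        xyz = np.column_stack(
            [np.cos(rad[:, 1]) * np.cos(rad[:, 0]),
             np.cos(rad[:, 1]) * np.sin(rad[:, 0]),
             np.sin(rad[:, 1])]
        )
        axis = r.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = 1.234
        Kx = np.array(
            [[0, -axis[2], axis[1]],
             [axis[2], 0, -axis[0]],
             [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(ang) * Kx + (1 - np.cos(ang)) * Kx @ Kx
        xyz2 = xyz @ R.T
        lonlat2 = np.column_stack(
            [np.rad2deg(np.arctan2(xyz2[:, 1], xyz2[:, 0])),
             np.rad2deg(np.arcsin(np.clip(xyz2[:, 2], -1, 1)))]
        )
        rotated = wishart_loglik(
            omega_hat,
            model_cov(LocationSet(lonlat2, metric="sphere"), p, eta, sbar),
            psi, 100,
        )
        assert rotated == pytest.approx(base, abs=1e-8)

    def test_invariant_to_choice_of_projection_basis(self):
        K = 4
        G, p, eta, sbar, r = random_instance(K, 40)
        Om = model_cov(G, p, eta, sbar)
        omega_hat = Om + 0.01 * np.eye(K)
        psi = projection_matrix(centering_matrix(sbar))
        base = wishart_loglik(omega_hat, Om, psi, 200)
        for seed in range(5):
            rr = np.random.default_rng(seed)
            M = rr.normal(size=(K - 1, K - 1))
            Q, _ = np.linalg.qr(M)
            alt = wishart_loglik(omega_hat, Om, psi @ Q, 200)
            assert alt == pytest.approx(base, abs=1e-8)

    def test_gaussian_sufficiency_constant_offset(self):
        """Summed per-locus Gaussian log likelihoods differ from the Wishart
        log likelihood by a constant that does not depend on the model
        covariance."""
        K = 4
        r = np.random.default_rng(9)
        sbar = np.full(K, 10.0)
        psi = projection_matrix(centering_matrix(sbar))
        L = 60
        X = r.standard_normal((K, L))
        omega_hat = X @ X.T / L
        offsets = []
        for seed in (1, 2, 3):
            G, p, eta, _, _ = random_instance(K, 100 + seed)
            Om = model_cov(G, p, eta, sbar)
            Sigma = psi.T @ Om @ psi
            Y = psi.T @ X
            sign, logdet = np.linalg.slogdet(Sigma)
            gauss = (
                -0.5 * L * (K - 1) * np.log(2 * np.pi)
                - 0.5 * L * logdet
                - 0.5 * np.trace(np.linalg.solve(Sigma, Y @ Y.T))
            )
            offsets.append(gauss - wishart_loglik(omega_hat, Om, psi, L))
        assert np.ptp(offsets) < 1e-7
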