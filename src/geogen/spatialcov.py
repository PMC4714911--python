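"""Parametric spatial covariance of allele frequencies and its likelihood.

The model: covariance between the standardized allele frequencies of two
populations decays with the distance between their locations on a latent
("geogenetic") surface as a powered exponential,

    F(d) = (1/alpha0) * exp(-(alpha1 * d) ** alpha2),

with a per-population nugget ``eta_k`` and a finite-sample term ``1/sbar_k``
added on the diagonal. Admixture lets population k draw a fraction ``w_k`` of
its alleles from a second location, which mixes the four pairwise spatial
covariances between the two populations' own and source locations.

Because the data covariance is rank K-1 after mean centering, the Wishart
likelihood is evaluated on a (K-1)-dimensional orthonormal projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import multigammaln

EARTH_METRICS = ("sphere", "euclidean")


@dataclass(frozen=True)
class CovParams:
    """Decay-curve parameters: inverse sill, rate, and shape."""

    alpha0: float  # 1/alpha0 is the covariance at distance zero (the sill)
    alpha1: float  # decay rate per unit distance
    alpha2: float  # decay shape, in (0.1, 2]

    def __post_init__(self) -> None:
        if not self.alpha0 > 0:
            raise ValueError(f"alpha0 must be positive, got {self.alpha0}")
        if not self.alpha1 > 0:
            raise ValueError(f"alpha1 must be positive, got {self.alpha1}")
        if not 0.1 < self.alpha2 <= 2:
            raise ValueError(
                f"alpha2 must be in (0.1, 2], got {self.alpha2}"
            )


@dataclass(frozen=True)
class LocationSet:
    """Point configuration with an attached geometry.

    ``coords`` is ``(n, 2)``: (longitude, latitude) in degrees for the
    ``"sphere"`` metric (distances are great-circle arcs on the unit sphere,
    in radians), or abstract (x, y) for ``"euclidean"``.
    """

    coords: np.ndarray
    metric: str = "sphere"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.atleast_2d(np.asarray(self.coords, float))
        )
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if self.metric not in EARTH_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "sphere":
            lon, lat = self.coords[:, 0], self.coords[:, 1]
            if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
                raise ValueError("spherical coordinates out of range")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class AdmixtureParams:
    """Admixture proportions (capped at 0.5) and source locations."""

    w: np.ndarray
    sources: LocationSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.atleast_1d(np.asarray(self.w, float)))
        if np.any(self.w < 0) or np.any(self.w > 0.5):
            raise ValueError(
                "admixture proportions must lie in [0, 0.5] (capped at 0.5 "
                "for identifiability)"
            )
        if len(self.sources) != self.w.size:
            raise ValueError("one source location per population required")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter state of the admixed spatial covariance model."""

    cov: CovParams
    eta: np.ndarray
    locations: LocationSet
    admixture: AdmixtureParams

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eta", np.atleast_1d(np.asarray(self.eta, float))
        )
        if np.any(self.eta < 0):
            raise ValueError("nuggets must be nonnegative")
        K = len(self.locations)
        if not (self.eta.size == K == self.admixture.w.size):
            raise ValueError("parameter dimensions disagree")


def great_circle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle arc lengths (radians) on the unit sphere.

    ``a`` is ``(n, 2)`` and ``b`` ``(m, 2)``, both (lon, lat) in degrees;
    the haversine form is used for numerical stability at short arcs.
    """
    a = np.deg2rad(np.atleast_2d(a))
    b = np.deg2rad(np.atleast_2d(b))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_matrix(
    a: LocationSet, b: LocationSet | None = None
) -> np.ndarray:
    """Pairwise distances between two location sets (or within one).

    Great-circle arcs on the unit sphere for the spherical metric, Euclidean
    distances for the planar one. Mixing metrics is an error.
    """
    if b is None:
        b = a
    if a.metric != b.metric:
        raise ValueError(
            f"cannot mix metrics: {a.metric!r} vs {b.metric!r}"
        )
    if a.metric == "sphere":
        D = great_circle_distance(a.coords, b.coords)
    else:
        diff = a.coords[:, None, :] - b.coords[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
    if b is a:
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    return D


def spatial_cov(D: np.ndarray, p: CovParams) -> np.ndarray:
    """Powered-exponential decay applied elementwise to a distance matrix."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    return np.exp(-((p.alpha1 * D) ** p.alpha2)) / p.alpha0


def model_cov(
    G: LocationSet, p: CovParams, eta: np.ndarray, sbar: np.ndarray
) -> np.ndarray:
    """Covariance without admixture: F(D) plus the diagonal nugget terms."""
    eta = np.atleast_1d(np.asarray(eta, float))
    sbar = np.atleast_1d(np.asarray(sbar, float))
    K = len(G)
    if not (eta.size == sbar.size == K):
        raise ValueError(
            f"size mismatch: {K} locations, {eta.size} nuggets, "
            f"{sbar.size} sample sizes"
        )
    if np.any(eta < 0):
        raise ValueError("nuggets must be nonnegative")
    Om = spatial_cov(distance_matrix(G), p)
    Om[np.diag_indices(K)] += eta + 1.0 / sbar
    return Om


def admixed_cov(
    G: LocationSet,
    adm: AdmixtureParams,
    p: CovParams,
    eta: np.ndarray,
    sbar: np.ndarray,
) -> np.ndarray:
    """Covariance with admixture.

    Each population is a two-point mixture of its own location and its source
    location, so the covariance between populations i and j combines the four
    pairwise spatial covariances among {G_i, G*_i} x {G_j, G*_j} weighted by
    the mixture proportions; the nugget and sampling terms stay diagonal.
    With all w = 0 this reduces exactly to :func:`model_cov`.
    """
    eta = np.atleast_1d(np.asarray(eta, float))
    sbar = np.atleast_1d(np.asarray(sbar, float))
    K = len(G)
    w = adm.w
    if not (eta.size == sbar.size == K == w.size):
        raise ValueError("size mismatch between locations and parameters")
    if np.any(eta < 0):
        raise ValueError("nuggets must be nonnegative")
    if G.metric != adm.sources.metric:
        raise ValueError("locations and sources must share a metric")
    all_points = LocationSet(
        np.vstack([G.coords, adm.sources.coords]), metric=G.metric
    )
    F = spatial_cov(distance_matrix(all_points), p)
    Fgg = F[:K, :K]
    Fsg = F[K:, :K]  # F(D_{i*, j})
    Fgs = F[:K, K:]  # F(D_{i, j*})
    Fss = F[K:, K:]
    wi = w[:, None]
    wj = w[None, :]
    Om = (
        (1 - wi) * (1 - wj) * Fgg
        + wi * (1 - wj) * Fsg
        + wj * (1 - wi) * Fgs
        + wi * wj * Fss
    )
    Om[np.diag_indices(K)] += eta + 1.0 / sbar
    return Om


def wishart_loglik(
    omega_hat: np.ndarray,
    omega_star: np.ndarray,
    psi: np.ndarray,
    n_loci: int,
) -> float:
    """Log density of the projected sample covariance under the model.

    Evaluates ``log W(L * psi' omega_hat psi | psi' omega_star psi, L)`` for
    the (K-1)-dimensional Wishart with L degrees of freedom, including the
    full normalizing constant, so log posteriors are comparable across runs.
    Returns ``-inf`` when the projected model covariance is not positive
    definite (the sampler treats such states as rejections).
    """
    K = omega_hat.shape[0]
    p = K - 1
    if n_loci < p:
        raise ValueError(
            f"insufficient loci for full-rank projected covariance: "
            f"need at least K-1 = {p}, got {n_loci}"
        )
    if psi.shape != (K, p):
        raise ValueError(f"psi must be ({K}, {p}), got {psi.shape}")
    L = float(n_loci)
    A = L * psi.T @ omega_hat @ psi
    Sigma = psi.T @ omega_star @ psi
    try:
        c, lower = cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    if np.any(np.diag(c) <= 0):
        return -np.inf
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    trace_term = np.trace(cho_solve((c, lower), A))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return (
        0.5 * (L - p - 1) * logdet_a
        - 0.5 * trace_term
        - 0.5 * L * p * np.log(2.0)
        - 0.5 * L * logdet_sigma
        - multigammaln(L / 2.0, p)
    )


def wishart_norm_const(
    omega_hat: np.ndarray, psi: np.ndarray, n_loci: int
) -> float:
    """Terms of the Wishart log density that do not depend on the model.

    The fast inference engine evaluates only the model-dependent part
    ``-(L/2) logdet Sigma - (1/2) tr(Sigma^-1 A)``; adding this constant
    recovers the full log density of :func:`wishart_loglik`.
    """
    K = omega_hat.shape[0]
    p = K - 1
    L = float(n_loci)
    A = L * psi.T @ omega_hat @ psi
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("projected sample covariance is singular")
    return (
        0.5 * (L - p - 1) * logdet_a
        - 0.5 * L * p * np.log(2.0)
        - multigammaln(L / 2.0, p)
    )
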