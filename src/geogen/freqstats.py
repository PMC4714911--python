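"""Standardized allele frequencies and the projected sample covariance.

This module turns raw allele-count matrices into the objects the spatial
likelihood consumes: the matrix of standardized sample frequencies, their
empirical covariance, the size-weighted mean-centering matrix ``T`` and an
orthonormal projection ``Psi`` onto the (K-1)-dimensional centered space.

Centering by the size-weighted global mean frequency removes one degree of
freedom per locus, so the covariance of the standardized frequencies has rank
at most K-1 and the Wishart likelihood must be evaluated on a full-rank
projection of it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Warn when mean sample sizes differ between populations by more than this
#: factor; the global centering matrix assumes sizes are roughly comparable.
SIZE_RATIO_WARN = 5.0


class NoUsableLociError(ValueError):
    """All loci were dropped during standardization."""


@dataclass
class AlleleCounts:
    """Counted-allele and sample-size matrices for K populations x L loci.

    Parameters
    ----------
    counts
        ``(K, L)`` integer matrix; entry ``[k, l]`` is the number of copies of
        the (arbitrarily chosen) counted allele observed at locus ``l`` in
        population ``k``.
    sizes
        ``(K, L)`` integer matrix of total alleles typed.
    labels
        K population labels.
    observed_locations
        Optional ``(K, 2)`` array of coordinates. Interpreted as
        (longitude, latitude) in degrees when ``metric == "sphere"``, or as
        abstract planar (x, y) when ``metric == "euclidean"``.
    metric
        Geometry the coordinates live in; only used for validation here.
    """

    counts: np.ndarray
    sizes: np.ndarray
    labels: list[str]
    observed_locations: np.ndarray | None = None
    metric: str = "sphere"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sizes = np.asarray(self.sizes)
        if self.counts.ndim != 2 or self.counts.shape != self.sizes.shape:
            raise ValueError(
                f"counts {self.counts.shape} and sizes {self.sizes.shape} "
                "must be 2-D matrices of identical shape"
            )
        K, L = self.counts.shape
        if K < 2:
            raise ValueError(f"need at least 2 populations, got {K}")
        if L < 1:
            raise ValueError("need at least 1 locus")
        if len(self.labels) != K:
            raise ValueError(f"{len(self.labels)} labels for {K} populations")
        if np.any(self.counts < 0) or np.any(self.sizes < 0):
            raise ValueError("counts and sizes must be nonnegative")
        bad = np.argwhere(self.counts > self.sizes)
        if bad.size:
            k, l = bad[0]
            raise ValueError(
                f"counts exceed sizes at population {self.labels[k]!r} "
                f"(row {k}), locus {l}: {self.counts[k, l]} > "
                f"{self.sizes[k, l]}"
            )
        if self.observed_locations is not None:
            self.observed_locations = np.asarray(
                self.observed_locations, dtype=float
            )
            if self.observed_locations.shape != (K, 2):
                raise ValueError(
                    f"observed_locations must be ({K}, 2), got "
                    f"{self.observed_locations.shape}"
                )
            if self.metric == "sphere":
                lon = self.observed_locations[:, 0]
                lat = self.observed_locations[:, 1]
                if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
                    raise ValueError(
                        "spherical coordinates out of range: longitude must "
                        "be in [-180, 180], latitude in [-90, 90]"
                    )

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]


@dataclass
class StandardizedData:
    """Standardized frequencies and derived matrices ready for inference.

    Attributes
    ----------
    xhat
        ``(K, L_eff)`` standardized sample frequencies.
    fbar
        Per-locus size-weighted mean frequencies (``None`` for data generated
        directly on the standardized scale).
    sbar
        Per-population mean sample sizes over retained loci.
    T
        ``(K, K)`` size-weighted mean-centering matrix.
    psi
        ``(K, K-1)`` projection with orthonormal columns spanning col(T).
    omega_hat
        ``(K, K)`` sample covariance ``xhat @ xhat.T / L_eff``.
    n_loci
        Number of retained loci (L_eff).
    dropped_loci
        ``(index, reason)`` pairs for loci removed before covariance
        computation.
    """

    xhat: np.ndarray
    fbar: np.ndarray | None
    sbar: np.ndarray
    T: np.ndarray
    psi: np.ndarray
    omega_hat: np.ndarray
    n_loci: int
    labels: list[str]
    observed_locations: np.ndarray | None = None
    metric: str = "sphere"
    dropped_loci: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_populations(self) -> int:
        return self.omega_hat.shape[0]


def centering_matrix(sbar: np.ndarray) -> np.ndarray:
    """Size-weighted mean-centering matrix ``T[i,j] = d_ij - sbar_j / sum(sbar)``.

    Each row sums to zero, so ``T @ ones = 0`` and applying ``T`` to a vector
    of per-population values subtracts their sbar-weighted mean.
    """
    sbar = np.asarray(sbar, dtype=float)
    if sbar.ndim != 1 or sbar.size < 2:
        raise ValueError("sbar must be a vector of length >= 2")
    if np.any(sbar <= 0):
        raise ValueError("mean sample sizes must be strictly positive")
    K = sbar.size
    return np.eye(K) - np.tile(sbar / sbar.sum(), (K, 1))


def projection_matrix(T: np.ndarray) -> np.ndarray:
    """Orthonormal basis of col(T): first K-1 columns of the QR factor of T.

    The QR sign convention is fixed by forcing the diagonal of the triangular
    factor to be nonnegative, so the result is reproducible bit-for-bit. The
    projected Wishart likelihood is invariant to the choice of orthonormal
    basis, so the convention is cosmetic (and tested to be so).
    """
    T = np.asarray(T, dtype=float)
    K = T.shape[0]
    Q, R = np.linalg.qr(T)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    # T has rank K-1 by construction; the first K-1 diagonal entries of R
    # must be nonzero or the weights were degenerate.
    if np.any(np.abs(np.diag(R)[: K - 1]) < 1e-12 * max(1.0, abs(R[0, 0]))):
        raise ValueError("centering matrix is rank deficient beyond K-1")
    return np.ascontiguousarray(Q[:, : K - 1])


def standardize(
    counts: AlleleCounts, min_minor_count: int = 1
) -> StandardizedData:
    """Standardize sample frequencies and assemble the projected covariance.

    At each retained locus the sample frequency ``f_hat = C/S`` is centered by
    the size-weighted global mean ``fbar = sum_k f_hat_k S_k / sum_k S_k`` and
    scaled by ``sqrt(fbar (1 - fbar))``. Loci that are monomorphic in the
    pooled sample (or whose pooled minor-allele count falls below
    ``min_minor_count``), and loci untyped in any population, are dropped and
    recorded in ``dropped_loci``.

    Raises
    ------
    NoUsableLociError
        If every locus is dropped.
    """
    C = counts.counts.astype(float)
    S = counts.sizes.astype(float)
    K, L = C.shape

    dropped: list[tuple[int, str]] = []
    keep = np.ones(L, dtype=bool)

    untyped = (S == 0).any(axis=0)
    for l in np.flatnonzero(untyped):
        k = int(np.flatnonzero(S[:, l] == 0)[0])
        dropped.append((int(l), f"untyped in population {counts.labels[k]!r}"))
        logger.warning(
            "locus %d dropped: no alleles typed in population %r",
            l, counts.labels[k],
        )
    keep &= ~untyped

    pooled = C.sum(axis=0)
    pooled_tot = S.sum(axis=0)
    minor = np.minimum(pooled, pooled_tot - pooled)
    low = (minor < min_minor_count) & keep
    for l in np.flatnonzero(low):
        reason = (
            "monomorphic in pooled sample"
            if minor[l] == 0
            else f"pooled minor-allele count {int(minor[l])} < "
            f"{min_minor_count}"
        )
        dropped.append((int(l), reason))
    keep &= ~low

    if not keep.any():
        raise NoUsableLociError(
            "no usable loci: all loci were dropped during standardization"
        )

    C = C[:, keep]
    S = S[:, keep]
    L_eff = int(keep.sum())

    f_hat = C / S
    fbar = (f_hat * S).sum(axis=0) / S.sum(axis=0)
    xhat = (f_hat - fbar) / np.sqrt(fbar * (1.0 - fbar))

    sbar = S.mean(axis=1)
    ratio = sbar.max() / sbar.min()
    if ratio > SIZE_RATIO_WARN:
        warnings.warn(
            f"mean sample sizes differ by a factor of {ratio:.1f} between "
            "populations; the global centering matrix assumes comparable "
            "sizes, so interpret results with care",
            UserWarning,
            stacklevel=2,
        )

    T = centering_matrix(sbar)
    psi = projection_matrix(T)
    omega_hat = xhat @ xhat.T / L_eff

    return StandardizedData(
        xhat=xhat,
        fbar=fbar,
        sbar=sbar,
        T=T,
        psi=psi,
        omega_hat=omega_hat,
        n_loci=L_eff,
        labels=list(counts.labels),
        observed_locations=counts.observed_locations,
        metric=counts.metric,
        dropped_loci=dropped,
    )
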