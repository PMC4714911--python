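"""Bayesian inference of geogenetic maps: priors, proposals, MCMC, protocol.

Four model variants are supported, differing in which parameters are free:

1. fixed locations, no admixture        (alpha, eta)
2. inferred locations, no admixture     (alpha, eta, G)
3. fixed locations, admixture           (alpha, eta, G*, w)
4. inferred locations, admixture        (alpha, eta, G, G*, w)

Every update is a symmetric Metropolis proposal on a single parameter block;
proposal scales are tuned adaptively toward a per-parameter acceptance
proportion of 0.44. The production sampler is a numba kernel
(:mod:`geogen._engine`); a pure-Python :func:`mh_step` implements the same
update for testing and for stepping through chains interactively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from .freqstats import StandardizedData
from .spatialcov import (
    AdmixtureParams,
    CovParams,
    LocationSet,
    admixed_cov,
    distance_matrix,
    wishart_loglik,
    wishart_norm_const,
)

logger = logging.getLogger(__name__)

VARIANTS = {
    1: "fixed locations, no admixture",
    2: "inferred locations, no admixture",
    3: "fixed locations, admixture",
    4: "inferred locations, admixture",
}

#: Acceptance proportion the adaptive tuning steers toward (optimal for
#: one-dimensional proposals).
TARGET_ACCEPTANCE = 0.44


def _to_internal(coords: np.ndarray, metric: str) -> np.ndarray:
    """Degrees -> radians for spherical coordinates; identity for planar."""
    coords = np.asarray(coords, dtype=float)
    return np.deg2rad(coords) if metric == "sphere" else coords.copy()


def _from_internal(coords: np.ndarray, metric: str) -> np.ndarray:
    return np.rad2deg(coords) if metric == "sphere" else np.asarray(coords)


def _metric_code(metric: str) -> int:
    if metric == "sphere":
        return 1
    if metric == "euclidean":
        return 0
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass
class Priors:
    """Prior hyperparameters.

    Rates are for exponential priors (``alpha0 ~ Exp(1/100)`` gives prior
    mean 100, a weak prior on the inverse sill). The admixture prior is
    ``2w ~ Beta(1, w_beta_b)``, heavily weighted toward zero to make
    admixture inference conservative. Location priors are isotropic
    Gaussians in distance from per-population centers (scale set from the
    mean pairwise distance between observed locations); admixture-source
    priors are much flatter and centered on the centroid.
    """

    loc_centers: np.ndarray  # (K, 2), degrees (sphere) or xy (plane)
    loc_sd: float  # internal distance units (radians on the unit sphere)
    src_center: np.ndarray  # (2,)
    src_sd: float
    metric: str = "sphere"
    alpha0_rate: float = 1.0 / 100.0
    alpha1_rate: float = 1.0
    alpha2_bounds: tuple[float, float] = (0.1, 2.0)
    eta_rate: float = 1.0
    w_beta_b: float = 100.0

    def __post_init__(self) -> None:
        self.loc_centers = np.asarray(self.loc_centers, dtype=float)
        self.src_center = np.asarray(self.src_center, dtype=float)


def mean_pairwise_distance(locations: LocationSet) -> float:
    """Mean off-diagonal pairwise distance D-bar between locations."""
    D = distance_matrix(locations)
    K = len(locations)
    if K < 2:
        raise ValueError("need at least two locations")
    return float(D.sum() / (K * (K - 1)))


def _centroid(locations: LocationSet) -> np.ndarray:
    if locations.metric == "euclidean":
        return locations.coords.mean(axis=0)
    rad = np.deg2rad(locations.coords)
    xyz = np.stack(
        [
            np.cos(rad[:, 1]) * np.cos(rad[:, 0]),
            np.cos(rad[:, 1]) * np.sin(rad[:, 0]),
            np.sin(rad[:, 1]),
        ],
        axis=1,
    ).mean(axis=0)
    norm = np.linalg.norm(xyz)
    if norm < 1e-12:
        return np.zeros(2)
    xyz /= norm
    return np.array(
        [np.rad2deg(np.arctan2(xyz[1], xyz[0])),
         np.rad2deg(np.arcsin(np.clip(xyz[2], -1, 1)))]
    )


def default_priors(observed: LocationSet) -> Priors:
    """Table-of-defaults priors anchored at the observed locations."""
    dbar = mean_pairwise_distance(observed)
    return Priors(
        loc_centers=observed.coords.copy(),
        loc_sd=0.5 * dbar,
        src_center=_centroid(observed),
        src_sd=2.0 * dbar,
        metric=observed.metric,
    )


def random_prior_centers(
    observed: LocationSet, rng: np.random.Generator
) -> Priors:
    """Priors with centers drawn uniformly within the observed bounding box.

    Used to check that inferred maps are driven by the data rather than the
    spatial prior; the prior scales (from D-bar of the *observed* locations)
    are unchanged.
    """
    pri = default_priors(observed)
    lo = observed.coords.min(axis=0)
    hi = observed.coords.max(axis=0)
    K = len(observed)
    pri.loc_centers = rng.uniform(lo, hi, size=(K, 2))
    return pri


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Which model variant to fit and how to run its chain."""

    variant: int
    n_iter: int
    thin: int = 1
    metric: str = "sphere"
    priors: Priors | None = None
    adapt: bool = True
    adapt_window: int = 50
    zeta_cap: float = 10.0
    #: optional explicit list of update-block indices, overriding the
    #: variant's free set (useful for conditioning on all but a few
    #: parameters, e.g. in sampler-validation experiments)
    update_blocks: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {sorted(VARIANTS)}, "
                f"got {self.variant}"
            )
        if self.n_iter < 1 or self.thin < 1:
            raise ValueError("n_iter and thin must be positive")

    @property
    def locations_free(self) -> bool:
        return self.variant in (2, 4)

    @property
    def admixture_free(self) -> bool:
        return self.variant in (3, 4)


def block_names(labels: list[str]) -> list[str]:
    """Stable names for the 3 + 4K update blocks."""
    return (
        ["alpha0", "alpha1", "alpha2"]
        + [f"eta_{s}" for s in labels]
        + [f"w_{s}" for s in labels]
        + [f"G_{s}" for s in labels]
        + [f"Gs_{s}" for s in labels]
    )


def free_block_indices(variant: int, K: int) -> np.ndarray:
    blocks = [0, 1, 2] + list(range(3, 3 + K))  # alpha and eta always free
    if variant in (3, 4):
        blocks += list(range(3 + K, 3 + 2 * K))  # w
    if variant in (2, 4):
        blocks += list(range(3 + 2 * K, 3 + 3 * K))  # G
    if variant in (3, 4):
        blocks += list(range(3 + 3 * K, 3 + 4 * K))  # G*
    return np.array(sorted(blocks), dtype=np.int64)


def _update_blocks(cfg: ModelConfig, K: int) -> np.ndarray:
    if cfg.update_blocks is not None:
        return np.asarray(cfg.update_blocks, dtype=np.int64)
    return free_block_indices(cfg.variant, K)


@dataclass
class MCMCState:
    """A full parameter state plus sampler bookkeeping.

    Locations are in user units ((lon, lat) degrees on the sphere, (x, y) in
    the plane). ``zeta`` holds the log proposal standard deviations, one per
    update block.
    """

    alpha: np.ndarray  # (3,)
    eta: np.ndarray  # (K,)
    w: np.ndarray  # (K,)
    G: np.ndarray  # (K, 2)
    Gs: np.ndarray  # (K, 2)
    zeta: np.ndarray  # (3 + 4K,)
    log_lik: float = np.nan
    log_prior: float = np.nan
    accept_counts: np.ndarray | None = None
    prop_counts: np.ndarray | None = None
    win_acc: np.ndarray | None = None
    win_prop: np.ndarray | None = None
    win_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        K = self.eta.size
        nblocks = 3 + 4 * K
        for name in (
            "accept_counts", "prop_counts", "win_acc", "win_prop", "win_index"
        ):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(nblocks, dtype=np.int64))

    @property
    def K(self) -> int:
        return self.eta.size

    @property
    def log_post(self) -> float:
        return self.log_lik + self.log_prior

    @property
    def cov_params(self) -> CovParams:
        return CovParams(*self.alpha)

    def copy(self) -> "MCMCState":
        return MCMCState(
            alpha=self.alpha.copy(),
            eta=self.eta.copy(),
            w=self.w.copy(),
            G=self.G.copy(),
            Gs=self.Gs.copy(),
            zeta=self.zeta.copy(),
            log_lik=self.log_lik,
            log_prior=self.log_prior,
            accept_counts=self.accept_counts.copy(),
            prop_counts=self.prop_counts.copy(),
            win_acc=self.win_acc.copy(),
            win_prop=self.win_prop.copy(),
            win_index=self.win_index.copy(),
        )


# ---------------------------------------------------------------------------
# log prior and likelihood of a state
# ---------------------------------------------------------------------------


def log_prior(state: MCMCState, cfg: ModelConfig) -> float:
    """Sum of log prior densities over the variant's free parameters.

    Location terms are isotropic Gaussians in (great-circle or Euclidean)
    distance from the prior centers, without their normalizing constants;
    the admixture term includes the factor 2 from the change of variables
    2w ~ Beta(1, b). Out-of-support values give ``-inf``.
    """
    pri = cfg.priors
    if pri is None:
        raise ValueError("config has no priors attached")
    m = _metric_code(cfg.metric)
    K = state.K
    blocks = _update_blocks(cfg, K)
    X = np.vstack(
        [_to_internal(state.G, cfg.metric), _to_internal(state.Gs, cfg.metric)]
    )
    return float(
        _engine.total_log_prior(
            state.alpha,
            state.eta,
            state.w,
            X,
            m,
            pri.alpha0_rate,
            pri.alpha1_rate,
            pri.alpha2_bounds[0],
            pri.alpha2_bounds[1],
            pri.eta_rate,
            pri.w_beta_b,
            _to_internal(pri.loc_centers, cfg.metric),
            pri.loc_sd,
            _to_internal(pri.src_center, cfg.metric),
            pri.src_sd,
            bool(np.any((blocks >= 3) & (blocks < 3 + K))),
            bool(np.any((blocks >= 3 + K) & (blocks < 3 + 2 * K))),
            bool(np.any((blocks >= 3 + 2 * K) & (blocks < 3 + 3 * K))),
            bool(np.any(blocks >= 3 + 3 * K)),
        )
    )


def log_likelihood(state: MCMCState, data: StandardizedData,
                   cfg: ModelConfig) -> float:
    """Projected Wishart log likelihood of the state (full density)."""
    G = LocationSet(state.G, metric=cfg.metric)
    adm = AdmixtureParams(
        w=np.clip(state.w, 0.0, 0.5),
        sources=LocationSet(state.Gs, metric=cfg.metric),
    )
    try:
        omega = admixed_cov(G, adm, state.cov_params, state.eta, data.sbar)
    except ValueError:
        return -np.inf
    return wishart_loglik(data.omega_hat, omega, data.psi, data.n_loci)


# ---------------------------------------------------------------------------
# proposals and adaptation
# ---------------------------------------------------------------------------


def propose_scalar(
    value: float, zeta: float, rng: np.random.Generator
) -> float:
    """Symmetric normal proposal with standard deviation exp(zeta)."""
    return value + rng.normal(0.0, np.exp(zeta))


def propose_location(
    loc: np.ndarray,
    zeta: float,
    rng: np.random.Generator,
    metric: str = "sphere",
) -> np.ndarray:
    """Propose a new location.

    On the sphere, draw an arc length ``|N(0, exp(zeta)^2)|`` (radians) and a
    uniform bearing, and move to the great-circle destination point; this
    keeps the proposed step length independent of latitude. In the plane,
    fall back to isotropic Gaussian jitter. Input and output are (lon, lat)
    in degrees for the sphere.
    """
    loc = np.asarray(loc, dtype=float)
    step = np.exp(zeta)
    if metric == "euclidean":
        return loc + rng.normal(0.0, step, size=2)
    arc = abs(rng.normal(0.0, step))
    bearing = rng.uniform(0.0, 2.0 * np.pi)
    lon, lat = np.deg2rad(loc)
    lon2, lat2 = _engine.destination_point(lon, lat, bearing, arc)
    return np.rad2deg([lon2, lat2])


def adapt_tuning(
    zeta: float, window_rate: float, n: int, cap: float = 10.0
) -> float:
    """One adaptation step of a log proposal scale.

    Raise ``zeta`` by ``min(0.01, n^(-1/2))`` if the window's acceptance
    proportion exceeded 0.44, lower it otherwise (a tie counts as "not
    greater", i.e. decrease); clamp to ``[-cap, cap]``.
    """
    if n < 1:
        raise ValueError("adaptation epoch index must be >= 1")
    a = _engine.adapt_amount(n)
    zeta = zeta + a if window_rate > TARGET_ACCEPTANCE else zeta - a
    return float(np.clip(zeta, -cap, cap))


# ---------------------------------------------------------------------------
# one Metropolis-Hastings update (reference Python path)
# ---------------------------------------------------------------------------


def _block_prior_delta(
    state: MCMCState, cfg: ModelConfig, block: int, new: float | np.ndarray
) -> float:
    """Prior log-density change for a single-block update."""
    pri = cfg.priors
    K = state.K
    m = _metric_code(cfg.metric)
    if block == 0:
        return _engine.logp_exponential(new, pri.alpha0_rate) - \
            _engine.logp_exponential(state.alpha[0], pri.alpha0_rate)
    if block == 1:
        return _engine.logp_exponential(new, pri.alpha1_rate) - \
            _engine.logp_exponential(state.alpha[1], pri.alpha1_rate)
    if block == 2:
        lo, hi = pri.alpha2_bounds
        return _engine.logp_uniform(new, lo, hi) - _engine.logp_uniform(
            state.alpha[2], lo, hi
        )
    if block < 3 + K:
        k = block - 3
        return _engine.logp_exponential(new, pri.eta_rate) - \
            _engine.logp_exponential(state.eta[k], pri.eta_rate)
    if block < 3 + 2 * K:
        k = block - 3 - K
        return _engine.logp_admixture(new, pri.w_beta_b) - \
            _engine.logp_admixture(state.w[k], pri.w_beta_b)
    if block < 3 + 3 * K:
        k = block - 3 - 2 * K
        mu = _to_internal(pri.loc_centers[k], cfg.metric)
        old = _to_internal(state.G[k], cfg.metric)
        newi = _to_internal(np.asarray(new), cfg.metric)
        return _engine.logp_location(
            newi[0], newi[1], mu[0], mu[1], pri.loc_sd, m
        ) - _engine.logp_location(old[0], old[1], mu[0], mu[1], pri.loc_sd, m)
    k = block - 3 - 3 * K
    mu = _to_internal(pri.src_center, cfg.metric)
    old = _to_internal(state.Gs[k], cfg.metric)
    newi = _to_internal(np.asarray(new), cfg.metric)
    return _engine.logp_location(
        newi[0], newi[1], mu[0], mu[1], pri.src_sd, m
    ) - _engine.logp_location(old[0], old[1], mu[0], mu[1], pri.src_sd, m)


def mh_step(
    state: MCMCState,
    data: StandardizedData,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> MCMCState:
    """One Metropolis-Hastings update of a randomly chosen free block.

    All proposals are symmetric so the acceptance probability is
    ``min(1, exp(delta log lik + delta log prior))``. Proposal and acceptance
    counters on the state are updated in place. The state's stored log
    posterior must be finite on entry.
    """
    if not np.isfinite(state.log_post):
        raise ValueError(
            "state has non-finite log posterior; it was corrupted or never "
            "initialized in the prior support"
        )
    K = state.K
    free = _update_blocks(cfg, K)
    block = int(free[rng.integers(free.size)])
    zeta = state.zeta[block]

    is_location = block >= 3 + 2 * K
    if is_location:
        if block < 3 + 3 * K:
            old_val = state.G[block - 3 - 2 * K].copy()
        else:
            old_val = state.Gs[block - 3 - 3 * K].copy()
        new_val = propose_location(old_val, zeta, rng, cfg.metric)
    else:
        if block < 3:
            old_val = float(state.alpha[block])
        elif block < 3 + K:
            old_val = float(state.eta[block - 3])
        else:
            old_val = float(state.w[block - 3 - K])
        new_val = propose_scalar(old_val, zeta, rng)

    d_prior = _block_prior_delta(state, cfg, block, new_val)
    accept = False
    if np.isfinite(d_prior):
        proposal = state.copy()
        _assign_block(proposal, block, new_val)
        new_lik = log_likelihood(proposal, data, cfg)
        log_r = (new_lik - state.log_lik) + d_prior
        if np.log(rng.random()) < log_r:
            accept = True
            _assign_block(state, block, new_val)
            state.log_lik = new_lik
            state.log_prior += d_prior

    state.prop_counts[block] += 1
    state.win_prop[block] += 1
    if accept:
        state.accept_counts[block] += 1
        state.win_acc[block] += 1
    return state


def _assign_block(
    state: MCMCState, block: int, value: float | np.ndarray
) -> None:
    K = state.K
    if block < 3:
        state.alpha[block] = value
    elif block < 3 + K:
        state.eta[block - 3] = value
    elif block < 3 + 2 * K:
        state.w[block - 3 - K] = value
    elif block < 3 + 3 * K:
        state.G[block - 3 - 2 * K] = value
    else:
        state.Gs[block - 3 - 3 * K] = value


# ---------------------------------------------------------------------------
# chain trace
# ---------------------------------------------------------------------------


@dataclass
class ChainTrace:
    """Thinned posterior samples plus acceptance and tuning summaries."""

    alpha: np.ndarray  # (n, 3)
    eta: np.ndarray  # (n, K)
    w: np.ndarray  # (n, K)
    G: np.ndarray  # (n, K, 2)
    Gs: np.ndarray  # (n, K, 2)
    log_lik: np.ndarray
    log_prior: np.ndarray
    iterations: np.ndarray
    labels: list[str]
    config: ModelConfig
    seed: int
    accept_counts: np.ndarray
    prop_counts: np.ndarray
    q_accept: np.ndarray  # final-quarter accounting
    q_prop: np.ndarray
    zeta_final: np.ndarray
    final_state: MCMCState | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.log_lik.size

    @property
    def K(self) -> int:
        return self.eta.shape[1]

    @property
    def log_post(self) -> np.ndarray:
        return self.log_lik + self.log_prior

    def acceptance_rates(self, final_quarter: bool = False) -> np.ndarray:
        """Per-block acceptance proportions (NaN for never-proposed blocks)."""
        acc = self.q_accept if final_quarter else self.accept_counts
        prop = self.q_prop if final_quarter else self.prop_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(prop > 0, acc / np.maximum(prop, 1), np.nan)

    def state_at(self, index: int) -> MCMCState:
        """Reconstruct the parameter state of thinned sample ``index``."""
        index = int(index)
        return MCMCState(
            alpha=self.alpha[index].copy(),
            eta=self.eta[index].copy(),
            w=self.w[index].copy(),
            G=self.G[index].copy(),
            Gs=self.Gs[index].copy(),
            zeta=self.zeta_final.copy(),
            log_lik=float(self.log_lik[index]),
            log_prior=float(self.log_prior[index]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"iteration": self.iterations}
        for i, name in enumerate(("alpha0", "alpha1", "alpha2")):
            cols[name] = self.alpha[:, i]
        for k, lab in enumerate(self.labels):
            cols[f"eta_{lab}"] = self.eta[:, k]
        for k, lab in enumerate(self.labels):
            cols[f"w_{lab}"] = self.w[:, k]
        for k, lab in enumerate(self.labels):
            cols[f"G_{lab}_x"] = self.G[:, k, 0]
            cols[f"G_{lab}_y"] = self.G[:, k, 1]
        for k, lab in enumerate(self.labels):
            cols[f"Gs_{lab}_x"] = self.Gs[:, k, 0]
            cols[f"Gs_{lab}_y"] = self.Gs[:, k, 1]
        cols["log_lik"] = self.log_lik
        cols["log_prior"] = self.log_prior
        cols["log_post"] = self.log_post
        return pd.DataFrame(cols)

    def save(self, outdir: str | Path) -> None:
        """Write the trace table (TSV) and a machine-readable manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(
            outdir / "trace.tsv", sep="\t", index=False, float_format="%.10g"
        )
        names = block_names(self.labels)
        meta = {
            "seed": int(self.seed),
            "variant": self.config.variant,
            "n_iter": self.config.n_iter,
            "thin": self.config.thin,
            "metric": self.config.metric,
            "labels": self.labels,
            "priors": _priors_to_dict(self.config.priors),
            "acceptance": {
                n: [int(a), int(p)]
                for n, a, p in zip(
                    names, self.accept_counts, self.prop_counts
                )
            },
            "zeta_final": self.zeta_final.tolist(),
            "extras": _jsonable(self.extras),
        }
        (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))


def _priors_to_dict(pri: Priors | None) -> dict | None:
    if pri is None:
        return None
    return {
        "loc_centers": pri.loc_centers.tolist(),
        "loc_sd": pri.loc_sd,
        "src_center": pri.src_center.tolist(),
        "src_sd": pri.src_sd,
        "metric": pri.metric,
        "alpha0_rate": pri.alpha0_rate,
        "alpha1_rate": pri.alpha1_rate,
        "alpha2_bounds": list(pri.alpha2_bounds),
        "eta_rate": pri.eta_rate,
        "w_beta_b": pri.w_beta_b,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# chain initialization and execution
# ---------------------------------------------------------------------------


def _resolve_priors(data: StandardizedData, cfg: ModelConfig) -> ModelConfig:
    if cfg.priors is not None:
        return cfg
    if data.observed_locations is None:
        raise ValueError(
            "no priors given and the data carry no observed locations; "
            "supply cfg.priors explicitly"
        )
    pri = default_priors(
        LocationSet(data.observed_locations, metric=cfg.metric)
    )
    return replace(cfg, priors=pri)


def initial_state(
    data: StandardizedData,
    cfg: ModelConfig,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> MCMCState:
    """Draw a starting state: scale parameters from their priors, locations
    at the prior centers (or the observed locations for fixed-location
    variants), admixture sources uniform in the observed coordinate range.

    Redraws up to ``max_tries`` times if the posterior is not finite.
    """
    cfg = _resolve_priors(data, cfg)
    pri = cfg.priors
    K = data.n_populations
    if cfg.variant in (1, 3):
        if data.observed_locations is None:
            raise ValueError(
                "fixed-location variants require observed locations"
            )
        G0 = np.asarray(data.observed_locations, dtype=float)
    else:
        G0 = pri.loc_centers.copy()
    ref = (
        data.observed_locations
        if data.observed_locations is not None
        else pri.loc_centers
    )
    lo = np.min(ref, axis=0)
    hi = np.max(ref, axis=0)

    for _ in range(max_tries):
        alpha = np.array(
            [
                rng.exponential(1.0 / pri.alpha0_rate),
                rng.exponential(1.0 / pri.alpha1_rate),
                rng.uniform(*pri.alpha2_bounds),
            ]
        )
        eta = rng.exponential(1.0 / pri.eta_rate, size=K)
        if cfg.admixture_free:
            w = rng.beta(1.0, pri.w_beta_b, size=K) / 2.0
        else:
            w = np.zeros(K)
        Gs0 = rng.uniform(lo, hi, size=(K, 2))
        state = MCMCState(
            alpha=alpha,
            eta=eta,
            w=w,
            G=G0.copy(),
            Gs=Gs0,
            zeta=np.zeros(3 + 4 * K),
        )
        state.log_prior = log_prior(state, cfg)
        state.log_lik = log_likelihood(state, data, cfg)
        if np.isfinite(state.log_post):
            return state
    raise RuntimeError(
        f"cannot initialize in support: {max_tries} prior draws all gave a "
        "non-finite posterior"
    )


def run_mcmc(
    data: StandardizedData,
    cfg: ModelConfig,
    init: MCMCState | None = None,
    seed: int | None = None,
    engine: str = "numba",
) -> ChainTrace:
    """Run one adaptive Metropolis-within-Gibbs chain and return its trace.

    ``engine="numba"`` uses the compiled kernel (production path);
    ``engine="python"`` loops :func:`mh_step` (reference path, for small
    chains and tests). Both adapt proposal scales at window boundaries of
    ``cfg.adapt_window`` iterations, tuning each parameter that was proposed
    at least once in the window using its own acceptance proportion and
    epoch count.
    """
    cfg = _resolve_priors(data, cfg)
    rng = np.random.default_rng(seed)
    if init is None:
        init = initial_state(data, cfg, rng)
    else:
        init = init.copy()
        init.log_prior = log_prior(init, cfg)
        init.log_lik = log_likelihood(init, data, cfg)
        if not np.isfinite(init.log_post):
            raise RuntimeError(
                "cannot initialize in support: supplied initial state has "
                "non-finite posterior"
            )
    if engine == "numba":
        return _run_numba(data, cfg, init, rng, seed)
    if engine == "python":
        return _run_python(data, cfg, init, rng, seed)
    raise ValueError(f"unknown engine {engine!r}")


def _run_numba(
    data: StandardizedData,
    cfg: ModelConfig,
    init: MCMCState,
    rng: np.random.Generator,
    seed: int | None,
) -> ChainTrace:
    pri = cfg.priors
    K = data.n_populations
    m = _metric_code(cfg.metric)
    psi = np.ascontiguousarray(data.psi)
    A = data.n_loci * psi.T @ data.omega_hat @ psi
    U = np.linalg.cholesky(A)
    lik_const = wishart_norm_const(data.omega_hat, psi, data.n_loci)
    X0 = np.vstack(
        [_to_internal(init.G, cfg.metric), _to_internal(init.Gs, cfg.metric)]
    )
    engine_seed = int(rng.integers(2**31 - 1))
    out = _engine.run_chain(
        engine_seed,
        cfg.n_iter,
        cfg.thin,
        cfg.adapt_window,
        cfg.adapt,
        m,
        psi,
        U,
        float(data.n_loci),
        1.0 / np.asarray(data.sbar, dtype=float),
        _update_blocks(cfg, K),
        pri.alpha0_rate,
        pri.alpha1_rate,
        pri.alpha2_bounds[0],
        pri.alpha2_bounds[1],
        pri.eta_rate,
        pri.w_beta_b,
        _to_internal(pri.loc_centers, cfg.metric),
        pri.loc_sd,
        _to_internal(pri.src_center, cfg.metric),
        pri.src_sd,
        init.alpha,
        init.eta,
        init.w,
        X0,
        init.zeta,
        cfg.zeta_cap,
    )
    (
        ok_init,
        s_alpha,
        s_eta,
        s_w,
        s_X,
        s_lik,
        s_prior,
        s_iter,
        accept_counts,
        prop_counts,
        q_accept,
        q_prop,
        zeta,
        f_alpha,
        f_eta,
        f_w,
        f_X,
        f_lik,
        f_prior,
    ) = out
    if not ok_init:
        raise RuntimeError(
            "cannot initialize in support: engine found non-finite posterior "
            "at the initial state"
        )
    final = MCMCState(
        alpha=f_alpha,
        eta=f_eta,
        w=f_w,
        G=_from_internal(f_X[:K], cfg.metric),
        Gs=_from_internal(f_X[K:], cfg.metric),
        zeta=zeta.copy(),
        log_lik=float(f_lik + lik_const),
        log_prior=float(f_prior),
        accept_counts=accept_counts.copy(),
        prop_counts=prop_counts.copy(),
    )
    return ChainTrace(
        alpha=s_alpha,
        eta=s_eta,
        w=s_w,
        G=_from_internal(s_X[:, :K, :], cfg.metric),
        Gs=_from_internal(s_X[:, K:, :], cfg.metric),
        log_lik=s_lik + lik_const,
        log_prior=s_prior,
        iterations=s_iter,
        labels=list(data.labels),
        config=cfg,
        seed=-1 if seed is None else int(seed),
        accept_counts=accept_counts,
        prop_counts=prop_counts,
        q_accept=q_accept,
        q_prop=q_prop,
        zeta_final=zeta,
        final_state=final,
    )


def _run_python(
    data: StandardizedData,
    cfg: ModelConfig,
    init: MCMCState,
    rng: np.random.Generator,
    seed: int | None,
) -> ChainTrace:
    K = data.n_populations
    state = init
    n_samples = cfg.n_iter // cfg.thin
    s_alpha = np.empty((n_samples, 3))
    s_eta = np.empty((n_samples, K))
    s_w = np.empty((n_samples, K))
    s_G = np.empty((n_samples, K, 2))
    s_Gs = np.empty((n_samples, K, 2))
    s_lik = np.empty(n_samples)
    s_prior = np.empty(n_samples)
    s_iter = np.empty(n_samples, dtype=np.int64)
    nblocks = 3 + 4 * K
    q_accept = np.zeros(nblocks, dtype=np.int64)
    q_prop = np.zeros(nblocks, dtype=np.int64)
    quarter_start = (3 * cfg.n_iter) // 4

    for it in range(cfg.n_iter):
        before_acc = state.accept_counts.copy()
        before_prop = state.prop_counts.copy()
        state = mh_step(state, data, cfg, rng)
        if it >= quarter_start:
            q_accept += state.accept_counts - before_acc
            q_prop += state.prop_counts - before_prop
        if cfg.adapt and (it + 1) % cfg.adapt_window == 0:
            for b in np.flatnonzero(state.win_prop > 0):
                state.win_index[b] += 1
                rate = state.win_acc[b] / state.win_prop[b]
                state.zeta[b] = adapt_tuning(
                    state.zeta[b], rate, int(state.win_index[b]), cfg.zeta_cap
                )
                state.win_acc[b] = 0
                state.win_prop[b] = 0
        if (it + 1) % cfg.thin == 0:
            s = (it + 1) // cfg.thin - 1
            s_alpha[s] = state.alpha
            s_eta[s] = state.eta
            s_w[s] = state.w
            s_G[s] = state.G
            s_Gs[s] = state.Gs
            s_lik[s] = state.log_lik
            s_prior[s] = state.log_prior
            s_iter[s] = it + 1

    return ChainTrace(
        alpha=s_alpha,
        eta=s_eta,
        w=s_w,
        G=s_G,
        Gs=s_Gs,
        log_lik=s_lik,
        log_prior=s_prior,
        iterations=s_iter,
        labels=list(data.labels),
        config=cfg,
        seed=-1 if seed is None else int(seed),
        accept_counts=state.accept_counts.copy(),
        prop_counts=state.prop_counts.copy(),
        q_accept=q_accept,
        q_prop=q_prop,
        zeta_final=state.zeta.copy(),
        final_state=state,
    )


# ---------------------------------------------------------------------------
# analysis protocol: short exploratory chains, then one long chain
# ---------------------------------------------------------------------------


def run_protocol(
    data: StandardizedData,
    cfg: ModelConfig,
    n_short: int = 5,
    short_len: int = 100_000,
    long_len: int | None = None,
    seed: int | None = None,
) -> ChainTrace:
    """Best-of-short-runs initialization followed by one long chain.

    ``n_short`` independent location-only chains (no admixture) are run for
    ``short_len`` iterations each; the final state with the highest posterior
    seeds the long chain of the target variant (``cfg.variant``), with
    admixture proportions initialized at zero and admixture sources at the
    origin. Returns the long chain's trace; the short runs' final log
    posteriors and the selected index are recorded in ``trace.extras``.
    """
    if n_short < 1:
        raise ValueError("n_short must be >= 1")
    cfg = _resolve_priors(data, cfg)
    if long_len is None:
        long_len = cfg.n_iter
    rng = np.random.default_rng(seed)
    short_variant = 1 if cfg.variant in (1, 3) else 2
    short_cfg = replace(
        cfg, variant=short_variant, n_iter=short_len,
        thin=max(1, short_len // 100),
    )
    finals: list[MCMCState] = []
    short_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_short)]
    for i, s in enumerate(short_seeds):
        trace = run_mcmc(data, short_cfg, seed=s)
        finals.append(trace.final_state)
        logger.info(
            "short run %d/%d: final log posterior %.2f",
            i + 1, n_short, finals[-1].log_post,
        )
    short_posts = np.array([st.log_post for st in finals])
    best = int(np.argmax(short_posts))

    K = data.n_populations
    best_state = finals[best]
    init = MCMCState(
        alpha=best_state.alpha.copy(),
        eta=best_state.eta.copy(),
        w=np.zeros(K),
        G=best_state.G.copy(),
        Gs=np.zeros((K, 2)),
        zeta=np.zeros(3 + 4 * K),
    )
    long_cfg = replace(cfg, n_iter=long_len)
    long_seed = int(rng.integers(2**31 - 1))
    trace = run_mcmc(data, long_cfg, init=init, seed=long_seed)
    trace.extras["short_final_log_posts"] = short_posts
    trace.extras["best_short_run"] = best
    trace.extras["short_seeds"] = short_seeds
    trace.extras["long_seed"] = long_seed
    return trace
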