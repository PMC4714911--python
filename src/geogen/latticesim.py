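"""Synthetic data: stepping-stone lattices and an exact Gaussian generator.

Two generators live here:

* :func:`simulate_counts` — a structured-coalescent simulation (msprime as
  the engine) of demes on a rectangular lattice with nearest-neighbor and
  diagonal migration, optional barrier / expansion / admixture-pulse events,
  and exactly one segregating site per locus (a single mutation placed
  uniformly on each genealogy's total branch length). This emulates the
  validation scenarios for the geogenetic-map method.
* :func:`simulate_mvn` — data drawn exactly from the parametric covariance
  model (independent zero-mean Gaussian loci), used as an oracle for
  parameter-recovery and calibration tests.

Lattice conventions: the full lattice has ``n_rows`` x ``n_cols`` demes on a
unit-spaced planar grid, deme (r, c) at (x=c, y=r) with row 0 the southern
edge. Every other deme (even rows and columns) is sampled; sampled
populations are numbered from 1 at the southwest corner, south-to-north
within each column of the sampled grid, columns west-to-east, so the
northeast corner carries the highest number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .freqstats import AlleleCounts, StandardizedData, centering_matrix, \
    projection_matrix
from .spatialcov import ModelParams, admixed_cov

#: "Immediate past" for expansion and admixture events, in coalescent time.
EPSILON_TIME = 1e-6

SCENARIO_KINDS = (
    "homogeneous",
    "barrier",
    "expansion",
    "corner_admixture",
    "barrier_admixture",
)


@dataclass(frozen=True)
class AdmixtureEvent:
    """A mass-migration pulse: the recipient draws ``proportion`` of its
    ancestry from the source population at ``time`` (in the immediate past
    by default)."""

    recipient: int  # 1-based sampled-population number
    source: int
    proportion: float
    time: float = EPSILON_TIME

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("admixture proportion must be in (0, 1)")
        if self.time <= 0:
            raise ValueError("event time must be positive")


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one lattice simulation.

    ``migration`` is the per-generation migration fraction between
    nearest-neighbor demes; with ``deme_size`` N the default gives a scaled
    rate 4Nm = 2 between adjacent demes, i.e. an effective 4Nm of about 1
    between *sampled* demes (which sit two lattice steps apart, so migration
    between them composes two adjacent-deme links in series). Diagonal
    neighbors exchange migrants at ``migration * diag_factor``. A barrier
    divides the rate of every edge crossing the vertical line
    ``x = barrier_x`` by ``barrier_divisor``.
    """

    n_rows: int = 9
    n_cols: int = 11
    deme_size: float = 1.0
    migration: float = 0.5
    diag_factor: float = 0.5
    barrier_x: float | None = None
    barrier_divisor: float = 5.0
    expansion_cols: tuple[int, ...] = ()
    expansion_parent_col: int | None = None
    expansion_time: float = EPSILON_TIME
    admixture_events: tuple[AdmixtureEvent, ...] = ()
    sample_step: int = 2
    haploids: int = 10
    n_loci: int = 10_000

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.barrier_divisor <= 0:
            raise ValueError("barrier divisor must be positive")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.haploids < 1:
            raise ValueError("need at least one haploid per sampled deme")

    # -- lattice geometry ---------------------------------------------------

    def deme_index(self, r: int, c: int) -> int:
        return r * self.n_cols + c

    @property
    def n_demes(self) -> int:
        return self.n_rows * self.n_cols

    def sampled_demes(self) -> list[tuple[int, int]]:
        """(row, col) of sampled demes in population-number order."""
        rows = range(0, self.n_rows, self.sample_step)
        cols = range(0, self.n_cols, self.sample_step)
        return [(r, c) for c in cols for r in rows]

    @property
    def n_sampled(self) -> int:
        return len(self.sampled_demes())

    def population_coords(self) -> np.ndarray:
        return np.array(
            [(c, r) for r, c in self.sampled_demes()], dtype=float
        )

    def population_labels(self) -> list[str]:
        return [f"pop_{i + 1:02d}" for i in range(self.n_sampled)]

    def deme_of_population(self, pop: int) -> tuple[int, int]:
        """Full-lattice (row, col) of 1-based sampled population ``pop``."""
        demes = self.sampled_demes()
        if not 1 <= pop <= len(demes):
            raise ValueError(f"no sampled population {pop}")
        return demes[pop - 1]

    # -- migration structure ------------------------------------------------

    def edges(self) -> list[tuple[int, int, float]]:
        """(deme_i, deme_j, rate) for every migration edge, barrier applied."""
        out = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < self.n_rows and 0 <= c2 < self.n_cols):
                        continue
                    rate = self.migration
                    if abs(dr) + abs(dc) == 2:
                        rate *= self.diag_factor
                    if self.barrier_x is not None and c != c2:
                        lo, hi = min(c, c2), max(c, c2)
                        if lo <= self.barrier_x <= hi:
                            rate /= self.barrier_divisor
                    if rate > 0:
                        out.append(
                            (self.deme_index(r, c), self.deme_index(r2, c2),
                             rate)
                        )
        return out


def build_scenario(kind: str, **overrides) -> SimScenario:
    """Canonical simulation designs.

    ``homogeneous``
        plain lattice, uniform migration.
    ``barrier``
        migration across the central line of longitude divided by 5.
    ``expansion``
        the five easternmost columns expanded, in the immediate past, from
        the nearest population in their row.
    ``corner_admixture``
        the northeast-corner population draws half its ancestry from the
        southwest-corner population immediately before sampling.
    ``barrier_admixture``
        barrier plus one cross-barrier pulse; ``design="inland"`` (10% into
        the recipient one sampled column inland from the barrier) or
        ``design="neighbor"`` (40% into the recipient immediately across
        the barrier from its source).
    """
    design = overrides.pop("design", "inland")
    if kind not in SCENARIO_KINDS:
        raise ValueError(
            f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}"
        )
    base = SimScenario(**overrides)
    if kind == "homogeneous":
        return base
    center_x = (base.n_cols - 1) / 2.0
    if kind == "barrier":
        return replace(base, barrier_x=center_x)
    if kind == "expansion":
        parent = base.n_cols - 6
        daughters = tuple(range(base.n_cols - 5, base.n_cols))
        return replace(
            base, expansion_cols=daughters, expansion_parent_col=parent
        )
    if kind == "corner_admixture":
        ev = AdmixtureEvent(
            recipient=base.n_sampled, source=1, proportion=0.5
        )
        return replace(base, admixture_events=(ev,))
    # barrier_admixture: source population sits just west of the barrier in
    # the central row; the recipient is across the barrier, either the
    # adjacent sampled column (neighbor) or one further east (inland).
    n_srows = len(range(0, base.n_rows, base.sample_step))
    mid_row = n_srows // 2
    scols = list(range(0, base.n_cols, base.sample_step))
    west_cols = [i for i, c in enumerate(scols) if c < center_x]
    east_cols = [i for i, c in enumerate(scols) if c > center_x]
    src_col = west_cols[-1]
    if design == "neighbor":
        rec_col = east_cols[0]
        prop = 0.40
    elif design == "inland":
        rec_col = east_cols[1]
        prop = 0.10
    else:
        raise ValueError(f"unknown barrier_admixture design {design!r}")
    source = src_col * n_srows + mid_row + 1
    recipient = rec_col * n_srows + mid_row + 1
    ev = AdmixtureEvent(recipient=recipient, source=source, proportion=prop)
    return replace(base, barrier_x=center_x, admixture_events=(ev,))


def _check_connected(scn: SimScenario) -> None:
    """Sampled demes must be joined by nonzero migration (possibly through
    unsampled demes) or lineages could never coalesce."""
    adj: dict[int, list[int]] = {i: [] for i in range(scn.n_demes)}
    for i, j, rate in scn.edges():
        if rate > 0:
            adj[i].append(j)
            adj[j].append(i)
    sampled = [scn.deme_index(r, c) for r, c in scn.sampled_demes()]
    seen = {sampled[0]}
    stack = [sampled[0]]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    missing = [d for d in sampled if d not in seen]
    if missing:
        raise ValueError(
            "disconnected lattice: sampled demes "
            f"{missing} are unreachable by migration from deme "
            f"{sampled[0]}; coalescence of all sampled lineages is "
            "impossible. Raise the migration rate or connect the components."
        )


def _build_demography(scn: SimScenario):
    import msprime

    dem = msprime.Demography()
    for r in range(scn.n_rows):
        for c in range(scn.n_cols):
            dem.add_population(
                name=f"d_{r}_{c}", initial_size=scn.deme_size
            )
    for i, j, rate in scn.edges():
        dem.set_symmetric_migration_rate([i, j], rate)

    events = []  # (time, kind, payload)
    for ev in scn.admixture_events:
        r_rec, c_rec = scn.deme_of_population(ev.recipient)
        r_src, c_src = scn.deme_of_population(ev.source)
        events.append(
            (
                ev.time,
                scn.deme_index(r_rec, c_rec),
                scn.deme_index(r_src, c_src),
                ev.proportion,
            )
        )
    if scn.expansion_cols:
        parent = scn.expansion_parent_col
        if parent is None or not 0 <= parent < scn.n_cols:
            raise ValueError("expansion needs a valid parent column")
        for r in range(scn.n_rows):
            for c in scn.expansion_cols:
                events.append(
                    (
                        scn.expansion_time,
                        scn.deme_index(r, c),
                        scn.deme_index(r, parent),
                        1.0,
                    )
                )
    for time, source, dest, prop in sorted(events, key=lambda e: e[0]):
        # msprime's "source" is backwards in time: lineages currently in the
        # recipient move to the admixture source with probability prop.
        dem.add_mass_migration(
            time=time, source=source, dest=dest, proportion=prop
        )
    dem.sort_events()
    return dem


def _place_single_mutation(ts, rng: np.random.Generator) -> np.ndarray:
    """Counts of the derived allele per population for one genealogy.

    One mutation is placed on the tree with probability proportional to
    branch length, which conditions the locus on exactly one segregating
    site; any edge choice splits the samples non-trivially, so every locus
    is polymorphic in the pooled sample.
    """
    tree = ts.first()
    parent = tree.parent_array
    time = ts.tables.nodes.time
    n_nodes = ts.num_nodes
    bl = np.zeros(n_nodes)
    for u in range(n_nodes):
        p = parent[u]
        if p != -1:
            bl[u] = time[p] - time[u]
    cum = np.cumsum(bl)
    u = int(np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right"))
    node_pop = ts.tables.nodes.population
    carriers = np.fromiter(tree.samples(u), dtype=np.int64)
    return np.bincount(node_pop[carriers], minlength=ts.num_populations)


def simulate_counts(
    scn: SimScenario, seed: int | np.random.Generator | None = None
) -> AlleleCounts:
    """Simulate allele counts for every locus of a lattice scenario.

    Each locus is an independent genealogy of the sampled haploids under the
    structured coalescent on the lattice, carrying a single segregating
    site. Returns counts of the derived allele with constant sample sizes.
    """
    import msprime

    _check_connected(scn)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dem = _build_demography(scn)
    sampled = scn.sampled_demes()
    samples = {
        scn.deme_index(r, c): scn.haploids for r, c in sampled
    }
    ms_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        num_replicates=scn.n_loci,
        random_seed=ms_seed,
    )
    K = scn.n_sampled
    sampled_idx = np.array(
        [scn.deme_index(r, c) for r, c in sampled], dtype=np.int64
    )
    counts = np.empty((K, scn.n_loci), dtype=np.int64)
    for l, ts in enumerate(reps):
        per_deme = _place_single_mutation(ts, rng)
        counts[:, l] = per_deme[sampled_idx]
    sizes = np.full((K, scn.n_loci), scn.haploids, dtype=np.int64)
    return AlleleCounts(
        counts=counts,
        sizes=sizes,
        labels=scn.population_labels(),
        observed_locations=scn.population_coords(),
        metric="euclidean",
    )


def simulate_mvn(
    params: ModelParams,
    sbar: np.ndarray,
    n_loci: int,
    rng: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> StandardizedData:
    """Exact model-faithful generator: Gaussian loci with covariance Omega*.

    Each locus is an independent zero-mean Gaussian vector with the admixed
    parametric covariance; the frequency standardization is bypassed and the
    generated values are mean-centered with the size-weighted centering
    matrix, after which the sample covariance is assembled exactly as for
    real counts. Raises if the parametric covariance is not positive
    definite.
    """
    rng = (
        rng if isinstance(rng, np.random.Generator)
        else np.random.default_rng(rng)
    )
    sbar = np.asarray(sbar, dtype=float)
    K = len(params.locations)
    if sbar.size != K:
        raise ValueError("sbar length must match the number of populations")
    omega = admixed_cov(
        params.locations, params.admixture, params.cov, params.eta, sbar
    )
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "parametric covariance is not positive definite for these "
            "parameters"
        ) from err
    X = chol @ rng.standard_normal((K, n_loci))
    T = centering_matrix(sbar)
    psi = projection_matrix(T)
    xc = T @ X
    omega_hat = xc @ xc.T / n_loci
    if labels is None:
        labels = [f"pop_{i + 1:02d}" for i in range(K)]
    return StandardizedData(
        xhat=xc,
        fbar=None,
        sbar=sbar,
        T=T,
        psi=psi,
        omega_hat=omega_hat,
        n_loci=n_loci,
        labels=labels,
        observed_locations=params.locations.coords.copy(),
        metric=params.locations.metric,
        dropped_loci=[],
    )
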