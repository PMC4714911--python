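# Methods

## The model

`geogen` infers a **geogenetic map**: a configuration of population
locations on a two-dimensional surface chosen so that pairwise distance
predicts the covariance of standardized allele frequencies. The data are
allele counts `C` and sample sizes `S` for `K` populations at `L` unlinked
biallelic loci. Sample frequencies `f = C/S` are standardized per locus as

    X[k,l] = (f[k,l] - fbar[l]) / sqrt(fbar[l] (1 - fbar[l]))

with `fbar` the size-weighted mean frequency across populations. The
standardization makes the result invariant to which allele is counted and
gives each locus roughly unit variance under weak drift. Mean-centering
removes one degree of freedom, so the covariance of `X` has rank `K - 1`;
the centering is represented by the matrix `T[i,j] = d_ij - sbar_j /
sum(sbar)` (applied once globally with the per-population mean sample sizes
`sbar`, since a per-locus `T` would be computationally prohibitive), and all
likelihood evaluations happen in the `(K-1)`-dimensional space spanned by an
orthonormal basis `Psi` of col(T) (first `K-1` columns of the QR factor of
`T`, sign-fixed for reproducibility; the likelihood is provably invariant to
the basis choice and a test asserts this).

Between-population covariance is modeled as a powered-exponential decay in
distance,

    F(d) = (1/alpha0) exp(-(alpha1 d)^alpha2),

plus a diagonal term `1/sbar_k + eta_k` combining binomial sampling noise
and a per-population **nugget** `eta_k` (variance unexplained by the spatial
model: bottlenecks, endogamy, isolation). `1/alpha0` is the sill (covariance
at distance zero), `alpha1` the decay rate per unit distance, `alpha2` in
(0.1, 2] the decay shape.

**Admixture.** Population `k` may draw a proportion `w_k` (capped at 0.5 for
identifiability) of its alleles from a second location `G*_k`, its admixture
source. The covariance between populations `i` and `j` then mixes the four
pairwise spatial covariances between their own and source locations with
weights `(1-w_i)(1-w_j)`, `w_i(1-w_j)`, `w_j(1-w_i)`, `w_i w_j`. At `w = 0`,
or at `w = 0.5` with the source at the population's own location, this
reduces exactly to the plain model. Admixture is identified chiefly by
covariance that is anomalously strong over long distances and by the
variance deficit of an admixed population (a mixture of two distant
frequency fields has lower variance than either), which no rearrangement of
a single location per population can mimic.

**Likelihood.** With `L` independent loci the scaled sample covariance is
approximately Wishart: `L Psi' Omega_hat Psi ~ W(Psi' Omega* Psi, L)`. The
full log density (multivariate-gamma normalizing constant included, so log
posteriors are comparable across runs) is evaluated after a Cholesky
factorization of the projected model covariance; a factorization failure —
possible because the powered exponential on great-circle distances is not
guaranteed positive definite for `alpha2 > 1` — yields log likelihood
`-inf` and the proposed state is simply rejected. No jitter or silent
regularization is applied. Linkage disequilibrium between loci would
inflate the effective degrees of freedom; the package treats loci as
independent and leaves LD thinning to the user.

## Priors (defaults)

| parameter | prior | rationale |
| --- | --- | --- |
| alpha0 | Exponential(rate 1/100) | weak; prior mean sill 1/100 .. broad |
| alpha1 | Exponential(rate 1) | decay rate per unit distance |
| alpha2 | Uniform(0.1, 2] | full supported shape range |
| eta_k | Exponential(rate 1) | nuggets near zero unless data demand |
| G_k | Gaussian in distance around a center, sd = D/2 | weak anchoring |
| G*_k | Gaussian around the centroid, sd = 2 D | very weak |
| w_k | 2w ~ Beta(1, 100) | conservative: heavy weight near zero |

`D` is the mean pairwise distance between the observed locations. Location
priors are isotropic Gaussians in (great-circle or Euclidean) distance from
their centers, `log p = -d^2 / (2 sigma^2)` up to a constant; the constant
is irrelevant to Metropolis-Hastings and is omitted, which is the one
unnormalized term in reported log posteriors. The admixture prior density
on `w` includes the factor 2 from the change of variables. Prior centers
may be the observed locations or (to check prior sensitivity, and always in
the lattice validation runs) points drawn uniformly within the observed
bounding box.

Distances are great-circle arcs on a unit sphere for (longitude, latitude)
data and Euclidean for abstract planar coordinates (the simulated
lattices). Spherical geometry is the default for empirical data — location
proposals walk on the sphere, so the covariance model uses the matching
metric — with the planar mode reserved for simulated lattices.

## Sampling

Four model variants: (1) fixed locations, no admixture; (2) inferred
locations; (3) fixed locations with admixture; (4) locations and admixture.
One iteration of the Metropolis-within-Gibbs sampler picks one update block
uniformly from the variant's free set — `alpha0`, `alpha1`, `alpha2`, one
`eta_k`, `w_k`, `G_k` or `G*_k` — and proposes symmetrically: scalars by a
normal step, locations on the sphere by a uniform bearing and a
`|Normal(0, exp(zeta)^2)|` arc length through the standard destination
formulas (latitude via `asin(sin phi cos d + cos phi sin d cos bearing)`),
which keeps the step length independent of latitude; in the plane by
isotropic Gaussian jitter. Proposals outside the prior support are rejected
outright. Acceptance follows the plain Metropolis ratio (all proposals are
symmetric).

**Adaptive tuning.** Each block has a log proposal scale `zeta`, initialized
at 0. At every 50-iteration window boundary, each parameter that was
proposed at least once in the window is adapted: `zeta` moves up by
`min(0.01, n^-1/2)` if its acceptance proportion in the window exceeded
0.44 (the one-dimensional optimum) and down otherwise (ties decrease),
where `n` counts that parameter's own adapted windows; `zeta` is clamped to
[-10, 10] (proposal variance at most e^20 ~ 4.85e8). Windows are defined
over iterations, not per-parameter proposal counts: with 3 + 4K blocks a
given parameter is proposed in only a fraction of iterations, and windows
of 50 proposals per parameter would adapt `zeta` so slowly (at most 2e-4
per proposal) that desk-scale chains could never reach equilibrium; the
iteration-window form measured here brings every parameter's acceptance
into 0.40-0.46 within 2e5 iterations on a 10-population problem.

**Engine.** The inner loop is a numba kernel. The decay matrix over all 2K
locations is maintained incrementally (a location move touches one
row/column; `alpha1`/`alpha2` moves trigger a full refill; `alpha0`, `eta`
and `w` moves reuse it), and each likelihood evaluation does an in-place
Cholesky of the projected covariance plus triangular solves against the
precomputed Cholesky factor of the data matrix — about 15 microseconds per
iteration at K = 30. A pure-Python step function implements the identical
update for tests; a trace-consistency test recomputes every thinned
sample's log posterior through the Python path (scipy's Wishart machinery)
and requires agreement to 1e-6.

**Protocol.** Analyses follow a best-of-short-runs scheme: several
independent location-only chains are run, the final state with the highest
posterior seeds the long chain of the target variant (admixture proportions
restart at zero, sources at the origin), and only the long chain is
retained. Parameter-recovery and validation runs here use 5 short chains of
2.5e5 iterations and a long chain of 2e6 iterations thinned to 1000 draws;
these lengths are the package's own desk-scale choice — a full lattice
scenario fits in minutes on one core, and posterior summaries of the
admixture proportions were checked to be stable between 2e6 and 2e7
iterations. Production analyses of real data should use longer chains (the
protocol scales linearly). Summaries discard the first 50% of thinned
samples as burn-in (configurable).

## Post-processing

Translation, rotation, scale and chirality of a configuration are nuisance
parameters (the likelihood sees only pairwise distances), so maps are
presented after a full Procrustes superimposition — best-fit rotation,
dilation, translation, and by default reflection — of the MAP population
locations onto the observed coordinates, with the fitted transform then
applied to the admixture sources (fitting on the concatenation would let
sources distort the frame). The MAP estimate is the thinned sample with the
highest stored log posterior (earliest index on ties). Uncertainty ellipses
for each location are 95% Gaussian coverage ellipses of the post-burn-in
draws after aligning every draw to the MAP configuration, without which
rotational drift of the whole map would masquerade as per-population
uncertainty. Alignment treats (lon, lat) as planar coordinates — a
presentation-layer approximation. Rendered maps label axes Eastings /
Northings and draw admixture arrows from source to recipient with width and
opacity proportional to the posterior mean proportion (suppressed below
0.01 by default).

## Synthetic data

**Lattice coalescent (`simulate_counts`).** The validation scenarios are
stepping-stone lattices: a 9 x 11 grid of demes (unit spacing), symmetric
migration to the four nearest neighbors at rate `m` and to the four
diagonal neighbors at `m/2`, with every other deme sampled (even rows and
columns: 30 sampled populations in a 5 x 6 grid, numbered from 1 at the
southwest corner, south-to-north within columns, west-to-east). Ten
haploids are sampled per sampled deme at 10,000 independent loci. Each
locus is one genealogy simulated under the structured coalescent (msprime
is the engine) carrying exactly one segregating site: a single mutation
placed on the tree with probability proportional to branch length, so every
locus is polymorphic in the pooled sample by construction. Scenario
embellishments: a **barrier** divides the rate of every edge crossing the
central north-south line by 5 (the unsampled center column becomes a
low-migration strip); an **expansion** merges the five easternmost columns
into their row's nearest remaining column in the immediate past; an
**admixture pulse** moves a fraction of the recipient's lineages into the
source deme immediately before sampling (scaled time 1e-6). The shipped
barrier-admixture designs place the source just west of the barrier in the
central row (population 13) with the recipient either directly across
(population 18, 40% pulse) or one sampled column further east (population
23, 10% pulse); the corner design pulses 50% from population 1 (SW) into
population 30 (NE).

Default magnitudes: deme size 1, nearest-neighbor migration 0.5 per
generation — a scaled 4Nm of 2 between adjacent demes, i.e. an effective
4Nm of about 1 between *sampled* demes, which sit two migration links
apart. These magnitudes are the package's declared defaults, chosen to
produce clear isolation by distance with realistic drift; consequences are
discussed under Limitations. A disconnected migration graph (coalescence
impossible) is rejected with a diagnostic rather than hanging.

**Model-true Gaussian generator (`simulate_mvn`).** For sampler-calibration
tests, loci are drawn exactly from the parametric model: independent
zero-mean Gaussian vectors with covariance `Omega*`, mean-centered with
`T`. Data from this generator exercise the likelihood and sampler with no
model misfit; coverage of credible intervals and the conservatism of the
admixture prior are tested against it. What it does **not** emulate:
binomial sampling of finite allele counts, the bounded support of
frequencies, mutation-order effects, or any coalescent correlation
structure — so passing calibration tests on it validates the inference
machinery, not the model's adequacy for real data (the lattice coalescent
scenarios probe that).

## Numerical choices

- Monomorphic loci (pooled minor-allele count below 1, configurable) and
  loci untyped in any population are dropped and logged; populations with
  mean sample sizes differing by more than 5x trigger a warning, since the
  global centering matrix assumes comparable sizes.
- Wishart evaluations use Cholesky factorizations throughout; the data-side
  factor is computed once per chain.
- Non-positive-definite proposals are rejections, never errors, and never
  silently regularized.
- Chain initialization draws scale parameters from their priors, starts
  locations at the prior centers (observed locations for fixed-location
  variants) and sources uniformly in the observed coordinate range, and
  retries up to 100 times if the posterior is not finite.
- All randomness flows from one integer seed per run; short-run seeds are
  derived deterministically from it. Traces are bit-reproducible.
- Burn-in defaults to 50% of thinned samples; tie-breaks (MAP, adaptation)
  are deterministic and documented in the docstrings.

## Known limitations

- Estimated admixture proportions are biased downward from the simulated
  truths: the conservative Beta(1, 100) prior and the freedom of the
  recipient's location to drift toward its source both absorb part of the
  signal. How much depends on how sharply the likelihood pins `w`, which in
  turn depends on the differentiation level of the data. Under the shipped
  lattice magnitudes, the corner scenario (50% pulse between distant
  corners, strongly identified by the recipient's variance deficit) yields
  a 95% interval of about 0.36-0.40, while the barrier designs — where
  recipient and source are close, so the variance deficit is small — come
  out nearer their truths (mean ~0.09-0.12 for the 10% pulse; interval up
  to ~0.35 for the 40% pulse), with the recipient's inferred location
  crossing the barrier toward its source. These summaries are stable to
  10x longer chains. Different migration magnitudes shift the balance
  between location compensation and explicit admixture, so absolute `w`
  estimates on real data should be read as conservative lower bounds.
- One admixture source per population; covariance decays isotropically;
  no LD-aware degrees-of-freedom correction.
- The Wishart approximation degrades for small L or strongly non-Gaussian
  frequency distributions (rare alleles, extreme drift).
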