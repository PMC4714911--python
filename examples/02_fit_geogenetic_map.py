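"""Infer a geogenetic map from model-true data and align it to the truth.

Draws Gaussian allele-frequency data from the spatial covariance model on a
known planar configuration, runs the location-inference model (variant 2),
and reports how well the Procrustes-aligned MAP configuration recovers the
true locations.
"""

import numpy as np

import geogen as gg

rng = np.random.default_rng(1)
K = 10
coords = rng.uniform(0.0, 5.0, size=(K, 2))
locs = gg.LocationSet(coords, metric="euclidean")
truth = gg.ModelParams(
    cov=gg.CovParams(alpha0=1.0, alpha1=0.5, alpha2=1.0),
    eta=np.full(K, 0.05),
    locations=locs,
    admixture=gg.AdmixtureParams(np.zeros(K), locs),
)
data = gg.simulate_mvn(truth, sbar=np.full(K, 10.0), n_loci=5000, rng=rng)

cfg = gg.ModelConfig(
    variant=2, n_iter=300_000, thin=1000, metric="euclidean",
    priors=gg.default_priors(locs),
)
trace = gg.run_mcmc(data, cfg, seed=2)
gmap = gg.summarize(trace, burn_in_fraction=0.5, reference=coords)

rmse = np.sqrt(np.mean(np.sum((gmap.locations - coords) ** 2, axis=1)))
span = np.ptp(coords, axis=0).max()
print(f"chain: {trace.n_samples} thinned samples, "
      f"final log posterior {trace.log_post[-1]:.1f}")
print(f"aligned MAP vs true locations: RMSE {rmse:.3f} "
      f"({100 * rmse / span:.1f}% of the configuration span)")
print("posterior mean decay parameters "
      f"(truth alpha0=1, alpha1=0.5, alpha2=1): "
      f"{np.round(trace.alpha[trace.n_samples // 2:].mean(axis=0), 3)}")
print("Distances on the inferred map predict allele-frequency covariance; "
      "a small RMSE means geogenetic and true geography agree.")
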