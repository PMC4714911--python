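"""File I/O and the command-line surface.

Tab-separated text is the canonical interchange format: count and size
matrices have one row per population (first column the label) and one column
per locus; coordinate tables have columns (population, longitude, latitude).
Every output directory receives a machine-readable manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .freqstats import AlleleCounts, standardize
from .geomap import render, summarize
from .inference import (
    ChainTrace,
    LocationSet,
    ModelConfig,
    default_priors,
    random_prior_centers,
    run_protocol,
)
from .latticesim import SCENARIO_KINDS, build_scenario, simulate_counts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for one inference run."""

    counts: Path
    sizes: Path
    coords: Path | None
    outdir: Path
    variant: int = 4
    n_short: int = 5
    short_len: int = 100_000
    long_len: int = 1_000_000
    thin: int = 1_000
    location_prior: str = "observed"  # or "random"
    metric: str = "sphere"
    seed: int = 0
    min_minor_count: int = 1

    def validate(self) -> None:
        for p in (self.counts, self.sizes):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.coords is not None and not Path(self.coords).exists():
            raise FileNotFoundError(f"coordinates file not found: {self.coords}")
        if self.location_prior not in ("observed", "random"):
            raise ValueError("location_prior must be 'observed' or 'random'")


def read_inputs(cfg: RunConfig) -> AlleleCounts:
    """Read and validate count/size matrices (and optional coordinates)."""
    cfg.validate()
    counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    sizes = pd.read_csv(cfg.sizes, sep="\t", index_col=0)
    if counts.shape != sizes.shape:
        raise ValueError(
            f"shape mismatch: counts is {counts.shape}, sizes is "
            f"{sizes.shape}"
        )
    if list(counts.index) != list(sizes.index):
        raise ValueError(
            "population labels differ between counts and sizes files"
        )
    locations = None
    if cfg.coords is not None:
        coords = pd.read_csv(cfg.coords, sep="\t")
        required = {"population", "longitude", "latitude"}
        if not required.issubset(coords.columns):
            raise ValueError(
                f"coordinates file must have columns {sorted(required)}"
            )
        coords = coords.set_index("population")
        missing = [p for p in counts.index if p not in coords.index]
        if missing:
            raise ValueError(
                "coordinates file is missing populations: "
                + ", ".join(map(str, missing))
            )
        locations = coords.loc[
            counts.index, ["longitude", "latitude"]
        ].to_numpy(dtype=float)
    return AlleleCounts(
        counts=counts.to_numpy(dtype=np.int64),
        sizes=sizes.to_numpy(dtype=np.int64),
        labels=[str(i) for i in counts.index],
        observed_locations=locations,
        metric=cfg.metric,
    )


def write_counts(ac: AlleleCounts, outdir: str | Path) -> None:
    """Write an AlleleCounts object as counts/sizes/coords TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = [f"locus_{i + 1}" for i in range(ac.n_loci)]
    pd.DataFrame(ac.counts, index=ac.labels, columns=loci).to_csv(
        outdir / "counts.tsv", sep="\t", index_label="population"
    )
    pd.DataFrame(ac.sizes, index=ac.labels, columns=loci).to_csv(
        outdir / "sizes.tsv", sep="\t", index_label="population"
    )
    if ac.observed_locations is not None:
        pd.DataFrame(
            {
                "population": ac.labels,
                "longitude": ac.observed_locations[:, 0],
                "latitude": ac.observed_locations[:, 1],
            }
        ).to_csv(outdir / "coords.tsv", sep="\t", index=False)


def load_trace(outdir: str | Path) -> ChainTrace:
    """Reload a saved chain trace (table + manifest) for post-processing."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "run_meta.json").read_text())
    df = pd.read_csv(outdir / "trace.tsv", sep="\t")
    labels = meta["labels"]
    K = len(labels)
    n = len(df)
    G = np.empty((n, K, 2))
    Gs = np.empty((n, K, 2))
    for k, lab in enumerate(labels):
        G[:, k, 0] = df[f"G_{lab}_x"]
        G[:, k, 1] = df[f"G_{lab}_y"]
        Gs[:, k, 0] = df[f"Gs_{lab}_x"]
        Gs[:, k, 1] = df[f"Gs_{lab}_y"]
    nblocks = 3 + 4 * K
    cfg = ModelConfig(
        variant=meta["variant"],
        n_iter=meta["n_iter"],
        thin=meta["thin"],
        metric=meta["metric"],
    )
    return ChainTrace(
        alpha=df[["alpha0", "alpha1", "alpha2"]].to_numpy(),
        eta=df[[f"eta_{lab}" for lab in labels]].to_numpy(),
        w=df[[f"w_{lab}" for lab in labels]].to_numpy(),
        G=G,
        Gs=Gs,
        log_lik=df["log_lik"].to_numpy(),
        log_prior=df["log_prior"].to_numpy(),
        iterations=df["iteration"].to_numpy(),
        labels=labels,
        config=cfg,
        seed=meta.get("seed", -1),
        accept_counts=np.zeros(nblocks, dtype=np.int64),
        prop_counts=np.zeros(nblocks, dtype=np.int64),
        q_accept=np.zeros(nblocks, dtype=np.int64),
        q_prop=np.zeros(nblocks, dtype=np.int64),
        zeta_final=np.array(meta.get("zeta_final", np.zeros(nblocks))),
        extras=meta.get("extras", {}),
    )


def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        stream=sys.stderr,
    )


def _write_manifest(outdir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["geogen_version"] = __version__
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.version_option(__version__)
@click.option("-v", "--verbose", count=True, help="Increase log verbosity.")
def cli(verbose: int) -> None:
    """Geogenetic maps: spatial population structure with admixture."""
    _setup_logging(verbose)


@cli.command()
@click.option("--kind", type=click.Choice(SCENARIO_KINDS), required=True)
@click.option("--design", type=click.Choice(["inland", "neighbor"]),
              default="inland", show_default=True,
              help="Barrier-admixture sub-design.")
@click.option("--loci", type=int, default=10_000, show_default=True)
@click.option("--haploids", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", type=click.Path(path_type=Path),
              required=True)
def simulate(kind, design, loci, haploids, seed, outdir):
    """Simulate a lattice scenario and write count matrices."""
    scn = build_scenario(kind, design=design, n_loci=loci, haploids=haploids)
    logger.info("simulating %s scenario: %d loci", kind, loci)
    ac = simulate_counts(scn, seed=seed)
    write_counts(ac, outdir)
    _write_manifest(
        outdir,
        {
            "command": "simulate",
            "kind": kind,
            "design": design,
            "n_loci": loci,
            "haploids": haploids,
            "seed": seed,
        },
    )
    click.echo(f"wrote {ac.n_populations} x {ac.n_loci} counts to {outdir}")


@cli.command()
@click.option("--counts", type=click.Path(path_type=Path), required=True)
@click.option("--sizes", type=click.Path(path_type=Path), required=True)
@click.option("--coords", type=click.Path(path_type=Path), default=None)
@click.option("--variant", type=click.IntRange(1, 4), default=4,
              show_default=True)
@click.option("--n-short", type=int, default=5, show_default=True)
@click.option("--short-len", type=int, default=100_000, show_default=True)
@click.option("--long-len", type=int, default=1_000_000, show_default=True)
@click.option("--thin", type=int, default=1_000, show_default=True)
@click.option("--metric", type=click.Choice(["sphere", "euclidean"]),
              default="sphere", show_default=True)
@click.option("--location-prior", type=click.Choice(["observed", "random"]),
              default="observed", show_default=True)
@click.option("--min-minor-count", type=int, default=1, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", type=click.Path(path_type=Path),
              required=True)
def run(counts, sizes, coords, variant, n_short, short_len, long_len, thin,
        metric, location_prior, min_minor_count, seed, outdir):
    """Standardize counts and run the short-runs/long-run protocol."""
    cfg_paths = RunConfig(
        counts=counts, sizes=sizes, coords=coords, outdir=outdir,
        variant=variant, n_short=n_short, short_len=short_len,
        long_len=long_len, thin=thin, location_prior=location_prior,
        metric=metric, seed=seed, min_minor_count=min_minor_count,
    )
    try:
        ac = read_inputs(cfg_paths)
        data = standardize(ac, min_minor_count=min_minor_count)
    except (ValueError, FileNotFoundError) as err:
        raise click.ClickException(str(err))
    rng = np.random.default_rng(seed)
    if data.observed_locations is not None:
        obs = LocationSet(data.observed_locations, metric=metric)
    else:
        obs = LocationSet(
            rng.uniform(0, 1, size=(data.n_populations, 2)), metric=metric
        )
    if location_prior == "random":
        priors = random_prior_centers(obs, rng)
    else:
        priors = default_priors(obs)
    cfg = ModelConfig(
        variant=variant, n_iter=long_len, thin=thin, metric=metric,
        priors=priors,
    )
    logger.info(
        "running protocol: %d short x %d, long %d (variant %d)",
        n_short, short_len, long_len, variant,
    )
    trace = run_protocol(
        data, cfg, n_short=n_short, short_len=short_len,
        long_len=long_len, seed=seed,
    )
    outdir.mkdir(parents=True, exist_ok=True)
    trace.save(outdir)
    _write_manifest(
        outdir,
        {
            "command": "run",
            "seed": seed,
            "variant": variant,
            "n_short": n_short,
            "short_len": short_len,
            "long_len": long_len,
            "thin": thin,
            "metric": metric,
            "location_prior": location_prior,
            "n_loci": data.n_loci,
            "n_populations": data.n_populations,
            "dropped_loci": len(data.dropped_loci),
        },
    )
    click.echo(
        f"chain finished: {trace.n_samples} thinned samples in {outdir}"
    )


@cli.command("map")
@click.option("--trace-dir", type=click.Path(path_type=Path), required=True)
@click.option("--coords", type=click.Path(path_type=Path), default=None,
              help="Observed coordinates to Procrustes-align against.")
@click.option("--burn-in", type=float, default=0.5, show_default=True)
@click.option("--out", "outprefix", type=click.Path(path_type=Path),
              required=True)
def map_cmd(trace_dir, coords, burn_in, outprefix):
    """Summarize a trace into a geogenetic-map table and figure."""
    try:
        trace = load_trace(trace_dir)
        reference = None
        if coords is not None:
            tbl = pd.read_csv(coords, sep="\t").set_index("population")
            reference = tbl.loc[
                trace.labels, ["longitude", "latitude"]
            ].to_numpy(dtype=float)
        gmap = summarize(
            trace, burn_in_fraction=burn_in, reference=reference
        )
    except (ValueError, KeyError, FileNotFoundError) as err:
        raise click.ClickException(str(err))
    outprefix.parent.mkdir(parents=True, exist_ok=True)
    table = outprefix.with_suffix(".tsv")
    figure = outprefix.with_suffix(".png")
    gmap.save(table)
    render(gmap, figure)
    click.echo(f"wrote {table} and {figure}")


@cli.command()
@click.option("--counts", type=click.Path(path_type=Path), required=True)
@click.option("--sizes", type=click.Path(path_type=Path), required=True)
@click.option("--coords", type=click.Path(path_type=Path), default=None)
@click.option("--metric", type=click.Choice(["sphere", "euclidean"]),
              default="sphere", show_default=True)
def validate(counts, sizes, coords, metric):
    """Check input files and report dataset shape."""
    cfg = RunConfig(
        counts=counts, sizes=sizes, coords=coords, outdir=Path("."),
        metric=metric,
    )
    try:
        ac = read_inputs(cfg)
    except (ValueError, FileNotFoundError) as err:
        raise click.ClickException(str(err))
    click.echo(
        f"OK: {ac.n_populations} populations x {ac.n_loci} loci"
        + ("" if ac.observed_locations is None else " with coordinates")
    )
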