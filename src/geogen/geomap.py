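"""Posterior post-processing: MAP maps, Procrustes alignment, rendering.

The likelihood depends only on pairwise distances, so the absolute position,
orientation and chirality of an inferred configuration are nuisance
quantities; maps are therefore presented after a full Procrustes
superimposition (best-fit rotation, translation and dilation, optionally
reflection) onto the observed coordinates, with axes labeled Eastings and
Northings. Alignment treats (lon, lat) as planar coordinates — a
presentation-layer approximation for spherical chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ChainTrace, MCMCState


@dataclass
class ProcrustesFit:
    """Similarity transform ``x -> scale * x @ rotation + translation``."""

    rotation: np.ndarray  # (2, 2) orthogonal, det +1 or -1
    scale: float
    translation: np.ndarray  # (2,)
    residual: float  # sum of squared distances after alignment

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(coords) @ self.rotation + \
            self.translation


@dataclass
class GeogeneticMap:
    """Aligned MAP locations with admixture summaries, ready to plot."""

    labels: list[str]
    locations: np.ndarray  # (K, 2) aligned MAP G
    sources: np.ndarray  # (K, 2) aligned MAP G*
    w_mean: np.ndarray
    w_lower: np.ndarray  # equal-tailed 95% interval bounds
    w_upper: np.ndarray
    ellipses: list[dict] | None = None  # per-population 95% location ellipses
    fit: ProcrustesFit | None = None
    map_state: MCMCState | None = None
    extras: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.labels,
                "easting": self.locations[:, 0],
                "northing": self.locations[:, 1],
                "source_easting": self.sources[:, 0],
                "source_northing": self.sources[:, 1],
                "w_mean": self.w_mean,
                "w_lo": self.w_lower,
                "w_hi": self.w_upper,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )


def map_estimate(trace: ChainTrace, burn_in_fraction: float = 0.0) -> MCMCState:
    """The thinned sample with maximal log posterior (after burn-in).

    Ties are broken toward the earliest index.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn-in fraction must be in [0, 1)")
    start = int(np.floor(burn_in_fraction * trace.n_samples))
    lp = trace.log_post[start:]
    best = start + int(np.argmax(lp))  # argmax returns the first maximum
    return trace.state_at(best)


def procrustes(
    source: np.ndarray,
    reference: np.ndarray,
    allow_reflection: bool = True,
) -> ProcrustesFit:
    """Full Procrustes superimposition of ``source`` onto ``reference``.

    Finds the similarity transform (rotation + dilation + translation, and
    reflection when permitted) minimizing the sum of squared distances to the
    reference configuration.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("source and reference must both be (n, 2)")
    if X.shape[0] < 2:
        raise ValueError("need at least two points")
    if np.allclose(Y, Y[0]):
        raise ValueError("degenerate reference: all points identical")
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xc = X - mx
    Yc = Y - my
    ssx = float((Xc**2).sum())
    if ssx < 1e-30:
        raise ValueError("degenerate source: all points identical")
    M = Xc.T @ Yc
    Uu, s, Vt = np.linalg.svd(M)
    R = Uu @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        Uu[:, -1] *= -1.0
        s = s.copy()
        s[-1] *= -1.0
        R = Uu @ Vt
    scale = float(s.sum() / ssx)
    translation = my - scale * mx @ R
    fitted = scale * X @ R + translation
    residual = float(((fitted - Y) ** 2).sum())
    return ProcrustesFit(
        rotation=R, scale=scale, translation=translation, residual=residual
    )


def _coverage_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """Gaussian 95% coverage ellipse of a 2-D point cloud."""
    from scipy.stats import chi2

    mean = points.mean(axis=0)
    if points.shape[0] < 3:
        return {"center": mean, "width": 0.0, "height": 0.0, "angle": 0.0}
    cov = np.cov(points.T)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    vals = np.clip(vals, 0.0, None)
    r = np.sqrt(chi2.ppf(level, df=2))
    angle = float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1])))
    return {
        "center": mean,
        "width": float(2 * r * np.sqrt(vals[1])),
        "height": float(2 * r * np.sqrt(vals[0])),
        "angle": angle,
    }


def summarize(
    trace: ChainTrace,
    burn_in_fraction: float = 0.5,
    reference: np.ndarray | None = None,
    ci: float = 0.95,
    ellipses: bool = True,
) -> GeogeneticMap:
    """Condense a chain into an aligned MAP map with admixture summaries.

    The Procrustes fit is computed on the MAP population locations against
    the reference (when given) and the same transform is applied to the
    admixture sources, so sources cannot distort the frame. Equal-tailed
    credible intervals for each admixture proportion come from the
    post-burn-in samples; location uncertainty ellipses are computed after
    aligning every posterior draw to the MAP configuration (otherwise
    rotational drift of the whole map would inflate them).
    """
    if burn_in_fraction >= 1.0:
        raise ValueError("burn-in fraction must be < 1")
    state = map_estimate(trace, burn_in_fraction)
    start = int(np.floor(burn_in_fraction * trace.n_samples))
    w_post = trace.w[start:]
    lo = (1.0 - ci) / 2.0
    w_mean = w_post.mean(axis=0)
    w_lower = np.quantile(w_post, lo, axis=0)
    w_upper = np.quantile(w_post, 1.0 - lo, axis=0)

    if reference is not None:
        fit = procrustes(state.G, np.asarray(reference, dtype=float))
        G_al = fit.apply(state.G)
        Gs_al = fit.apply(state.Gs)
    else:
        fit = None
        G_al = state.G.copy()
        Gs_al = state.Gs.copy()

    ell = None
    if ellipses and trace.n_samples - start >= 3:
        K = trace.K
        aligned = np.empty((trace.n_samples - start, K, 2))
        for i, idx in enumerate(range(start, trace.n_samples)):
            draw = trace.G[idx]
            try:
                f = procrustes(draw, state.G)
                aligned[i] = f.apply(draw)
            except ValueError:
                aligned[i] = draw
        if fit is not None:
            aligned = np.stack([fit.apply(a) for a in aligned])
        ell = [_coverage_ellipse(aligned[:, k, :], ci) for k in range(K)]

    return GeogeneticMap(
        labels=list(trace.labels),
        locations=G_al,
        sources=Gs_al,
        w_mean=w_mean,
        w_lower=w_lower,
        w_upper=w_upper,
        ellipses=ell,
        fit=fit,
        map_state=state,
        extras={"burn_in_fraction": burn_in_fraction, "ci": ci},
    )


def arrow_indices(
    gmap: GeogeneticMap, threshold: float = 0.01
) -> np.ndarray:
    """Populations whose admixture arrow is drawn (mean w >= threshold)."""
    return np.flatnonzero(gmap.w_mean >= threshold)


def render(
    gmap: GeogeneticMap,
    output_path: str | Path,
    arrow_threshold: float = 0.01,
    show_ellipses: bool = True,
    figsize: tuple[float, float] = (7.0, 7.0),
) -> Path:
    """Draw the geogenetic map to an image file.

    Population labels are placed at their aligned locations; an arrow is
    drawn from each admixture source to its recipient with width and opacity
    proportional to the posterior mean admixture proportion (suppressed below
    ``arrow_threshold``).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse, FancyArrowPatch

    fig, ax = plt.subplots(figsize=figsize)
    if show_ellipses and gmap.ellipses is not None:
        for e in gmap.ellipses:
            ax.add_patch(
                Ellipse(
                    xy=e["center"], width=e["width"], height=e["height"],
                    angle=e["angle"], facecolor="#78a8d8", alpha=0.25,
                    edgecolor="none",
                )
            )
    drawn = set(arrow_indices(gmap, arrow_threshold).tolist())
    for k, lab in enumerate(gmap.labels):
        wk = gmap.w_mean[k]
        if k in drawn:
            ax.add_patch(
                FancyArrowPatch(
                    tuple(gmap.sources[k]),
                    tuple(gmap.locations[k]),
                    arrowstyle="-|>",
                    mutation_scale=12,
                    linewidth=1.0 + 12.0 * wk,
                    color="seagreen",
                    alpha=float(min(1.0, 0.15 + 1.7 * wk)),
                    zorder=2,
                )
            )
            ax.annotate(
                lab, gmap.sources[k], fontsize=7, style="italic",
                color="seagreen", ha="center", va="center", zorder=3,
            )
        ax.annotate(
            lab, gmap.locations[k], fontsize=8, ha="center", va="center",
            zorder=4,
        )
    allpts = np.vstack([gmap.locations] + (
        [gmap.sources[gmap.w_mean >= arrow_threshold]]
        if np.any(gmap.w_mean >= arrow_threshold) else []
    ))
    pad = 0.08 * max(np.ptp(allpts, axis=0).max(), 1e-6)
    ax.set_xlim(allpts[:, 0].min() - pad, allpts[:, 0].max() + pad)
    ax.set_ylim(allpts[:, 1].min() - pad, allpts[:, 1].max() + pad)
    ax.set_xlabel("Eastings")
    ax.set_ylabel("Northings")
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    output_path = Path(output_path)
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path
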