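"""Proteome-to-pocketome scaling: the power-law exponent and its nulls.

Across species, the number of unique binding pockets N_p (communities plus
singletons found in the within-species similarity graph) is modelled as a
power law of the number of fold clusters N_FS, N_p ~ c * N_FS^a.  The
exponent a is the OLS slope of ln(N_p) on ln(N_FS); a < 1 means the pocket
repertoire grows sub-linearly with fold diversity.  Null exponents are
obtained by randomizing each species graph (degree-preserving rewiring,
matched-density random graphs, or score-matrix permutation), re-clustering,
recounting, and refitting.

Natural logarithms throughout; the intercept is reported on the ln scale.
The slope and the Pearson correlation of the log-log points are invariant
to the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from . import graph as graphmod
from .model import SimilarityMatrix


@dataclass
class SpeciesClusterStats:
    species: str
    n_fs: int
    n_pocket_clusters: int  # communities + singletons
    n_communities: int

    def __post_init__(self) -> None:
        if self.n_pocket_clusters < self.n_communities:
            raise ValueError(f"{self.species}: unique count below community count")


@dataclass
class ScalingFit:
    slope: float  # the exponent a
    intercept: float  # natural-log scale
    pearson_r: float
    n_points: int


def fit_power_law(
    stats: list[SpeciesClusterStats], response: str = "unique"
) -> ScalingFit:
    """OLS of ln(response) on ln(N_FS) across species.

    ``response`` is ``"unique"`` (communities + singletons) or
    ``"communities"``.  Any zero or negative count is an error (the
    logarithm is undefined there).
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 species for a fit")
    x = np.array([s.n_fs for s in stats], dtype=float)
    if response == "unique":
        y = np.array([s.n_pocket_clusters for s in stats], dtype=float)
    elif response == "communities":
        y = np.array([s.n_communities for s in stats], dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("all counts must be > 0 to take logarithms")
    fit = linregress(np.log(x), np.log(y))
    return ScalingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_points=len(stats),
    )


def stats_from_clusterings(
    results: list[graphmod.ClusteringResult], n_fs: dict[str, int]
) -> list[SpeciesClusterStats]:
    return [
        SpeciesClusterStats(
            species=r.species,
            n_fs=n_fs[r.species],
            n_pocket_clusters=r.n_unique,
            n_communities=r.n_communities,
        )
        for r in results
    ]


def _cluster_null(
    sim: SimilarityMatrix,
    null_kind: str,
    seed: int,
    edge_threshold: float,
    resolution: float,
) -> graphmod.ClusteringResult:
    if null_kind == "score_permutation":
        null_sim = graphmod.randomize_score_matrix(sim, seed=seed)
        return graphmod.cluster_similarity(
            null_sim, edge_threshold=edge_threshold, resolution=resolution, seed=seed
        )
    g = graphmod.build_graph(sim, edge_threshold=edge_threshold)
    if null_kind == "degree_preserving":
        null_g = graphmod.rewire_degree_preserving(g, seed=seed)
    elif null_kind == "erdos_renyi":
        null_g = graphmod.random_graph_same_density(g, seed=seed)
    else:
        raise ValueError(f"unknown null kind {null_kind!r}")
    return graphmod.leiden_communities(
        null_g,
        resolution=resolution,
        seed=seed,
        alignment_singletons=graphmod.find_singletons(sim),
    )


def null_scaling(
    sims: list[SimilarityMatrix],
    n_fs: dict[str, int],
    null_kind: str = "degree_preserving",
    n_replicates: int = 5,
    seed: int = 0,
    response: str = "unique",
    edge_threshold: float = 0.1,
    resolution: float = 0.01,
) -> tuple[float, float, list[float]]:
    """Mean and s.d. of the scaling exponent over null-model replicates.

    For each replicate every species graph is randomized with the chosen
    null (``degree_preserving``, ``erdos_renyi`` or ``score_permutation``),
    re-clustered with Leiden, the unique-pocket counts recounted, and the
    exponent refit.  Returns (mean, sd, per-replicate slopes).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates to report a standard deviation")
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        results = [
            _cluster_null(sim, null_kind, rep_seed + k, edge_threshold, resolution)
            for k, sim in enumerate(sims)
        ]
        fit = fit_power_law(stats_from_clusterings(results, n_fs), response=response)
        slopes.append(fit.slope)
    return float(np.mean(slopes)), float(np.std(slopes, ddof=1)), slopes
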