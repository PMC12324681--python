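"""Synthetic generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes so
every downstream stage is testable without any download: random-coil
proteins with confidence annotations, spatially contiguous pockets with a
plantable known-site recovery rate and per-class enrichment odds,
within-species similarity matrices with planted communities / singletons
and a planted proteome-to-pocketome scaling exponent, and embedding
vectors with a controllable kingdom association.

All generators are pure functions of (config, seed): per-generator random
streams are derived from the master seed with fixed offsets, so the same
config reproduces the same fixture set byte for byte.

What is emulated and what is not: sizes, rates, overlaps, class odds,
community structure and scaling follow the study conditions (pocket size
median 24 vs known-site median 6; found fraction 52.1%; sub-linear unique
pocket scaling), but the chains are random coils, not folds, and the
alignment scores are drawn, not computed from geometry.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence

from . import io as pio
from .datasets import compound_class_counts, compound_class_roots
from .model import (
    AMINO_ACIDS,
    CompoundOntology,
    EmbeddingSet,
    KnownSite,
    PocketRecord,
    ProteinRecord,
    ResidueRef,
    SimilarityMatrix,
)

KINGDOMS = ("Bacteria", "Fungi", "Plantae", "Animalia")

# stream offsets: one independent substream per generator
_STREAM_PROTEOME = 1
_STREAM_POCKETS = 2
_STREAM_SIMILARITY = 3
_STREAM_EMBEDDINGS = 4


@dataclass
class SyntheticConfig:
    """Study-condition knobs for all generators (defaults = study conditions)."""

    seed: int = 0
    # proteome
    n_species: int = 3
    proteins_per_species: int = 12
    mean_protein_length: int = 160
    plddt_beta_params: tuple[float, float] = (8.0, 2.0)  # scaled to [0, 100]
    pae_scale: float = 0.05  # Å of aligned error per unit |i − j|
    pae_noise: float = 0.5
    fragment_fraction: float = 0.0
    tm_fraction: float = 0.0
    # pockets and known sites
    pocket_rate: float = 2.0  # mean pockets per protein
    site_rate: float = 1.5  # mean known sites per protein
    pocket_size_median: int = 24
    site_size_median: int = 6
    min_site_size: int = 4
    probability_beta_params: tuple[float, float] = (5.0, 2.0)
    found_fraction: float = 0.521
    enrichment_odds: dict[str, float] = field(default_factory=dict)
    class_probs: dict[str, float] | None = None
    # similarity ensemble
    ensemble_species: int = 11
    fold_cluster_range: tuple[int, int] = (100, 1000)
    a_true: float = 0.5
    scaling_coeff: float = 3.0
    pockets_per_fold: float = 1.0
    noise_cv: float = 0.0  # multiplicative noise on planted unique counts
    singleton_fraction: float = 0.6  # singleton share of unique pockets
    community_size_power: float = 2.0
    within_community_density: float = 0.35
    score_range: tuple[float, float] = (2.0, 10.0)
    # embeddings
    kingdom_mixture: dict[str, tuple[float, float]] | None = None  # kingdom -> (separation, sd)

    def __post_init__(self) -> None:
        if min(self.n_species, self.proteins_per_species, self.mean_protein_length) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.found_fraction <= 1.0:
            raise ValueError("found_fraction must be in [0, 1]")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if self.a_true <= 0:
            raise ValueError("a_true must be > 0")


def _rng(cfg: SyntheticConfig, stream: int, tag: str = "") -> np.random.Generator:
    salt = zlib.crc32(tag.encode()) if tag else 0
    return np.random.default_rng([cfg.seed, stream, salt])


# ---------------------------------------------------------------------------
# proteomes

def _random_walk(rng: np.random.Generator, n: int, step: float = 3.8, min_sep: float = 3.4):
    """Self-avoiding-ish 3D random walk with fixed step length."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(30):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + step * direction
            prev = coords[: max(0, i - 1)]
            if prev.size == 0 or (np.linalg.norm(prev - candidate, axis=1) >= min_sep).all():
                break
        coords[i] = candidate
    return coords

_BACKBONE = [  # atom name, element, offset from CA in the local frame
    ("N", "N", np.array([-1.46, 0.0, 0.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([1.52, 0.0, 0.0])),
    ("O", "O", np.array([2.15, 1.05, 0.0])),
    ("CB", "C", np.array([0.0, -1.53, 0.4])),
]


def _atom_array(sequence: str, ca_coords: np.ndarray, plddt: np.ndarray, rng) -> struc.AtomArray:
    n_res = len(sequence)
    n_atoms = n_res * len(_BACKBONE)
    atoms = struc.AtomArray(n_atoms)
    atoms.set_annotation("b_factor", np.zeros(n_atoms))
    k = 0
    for i, aa in enumerate(sequence):
        jitter = rng.normal(scale=0.05, size=(len(_BACKBONE), 3))
        jitter[1] = 0.0  # the CA atom sits exactly on the trace coordinate
        for (name, element, offset), eps in zip(_BACKBONE, jitter):
            atoms.chain_id[k] = "A"
            atoms.res_id[k] = i + 1
            atoms.res_name[k] = ProteinSequence.convert_letter_1to3(aa).upper()
            atoms.atom_name[k] = name
            atoms.element[k] = element
            atoms.hetero[k] = False
            atoms.coord[k] = ca_coords[i] + offset + eps
            atoms.b_factor[k] = plddt[i]
            k += 1
    return atoms


def generate_proteome(cfg: SyntheticConfig, species: str) -> list[ProteinRecord]:
    """Random-coil proteins with pLDDT from a scaled Beta distribution and a
    PAE matrix growing with sequence separation."""
    rng = _rng(cfg, _STREAM_PROTEOME, species)
    a, b = cfg.plddt_beta_params
    proteins = []
    for k in range(cfg.proteins_per_species):
        length = max(30, int(rng.poisson(cfg.mean_protein_length)))
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        ca = _random_walk(rng, length)
        plddt = 100.0 * rng.beta(a, b, size=length)
        sep = np.abs(np.subtract.outer(np.arange(length), np.arange(length)))
        pae = cfg.pae_scale * sep + np.abs(rng.normal(scale=cfg.pae_noise, size=(length, length)))
        np.fill_diagonal(pae, 0.0)
        pae = np.clip(pae, 0.0, None)
        proteins.append(
            ProteinRecord(
                protein_id=f"{species}_P{k:04d}",
                species=species,
                sequence=sequence,
                ca_coords=ca,
                plddt=plddt,
                pae=pae,
                atoms=_atom_array(sequence, ca, plddt, rng),
                is_fragment=bool(rng.random() < cfg.fragment_fraction),
                tm_checks_passed=(
                    int(rng.integers(0, 7)) if rng.random() < cfg.tm_fraction else None
                ),
            )
        )
    return proteins


# ---------------------------------------------------------------------------
# compound ontology

def generate_ontology(cfg: SyntheticConfig, children_per_root: int = 3) -> CompoundOntology:
    """Two-level synthetic ontology beneath the bundled compound-class roots.

    Each root gets ``children_per_root`` direct children and one grandchild
    per child, so class assignment exercises multi-step ancestor traversal.
    """
    edges: dict[str, set[str]] = {}
    for name, roots in compound_class_roots():
        slug = zlib.crc32(name.encode()) % 10**4
        for root in sorted(roots):
            for c in range(children_per_root):
                child = f"CHEBI:9{slug:04d}{c}"
                edges.setdefault(child, set()).add(root)
                grandchild = f"CHEBI:8{slug:04d}{c}"
                edges.setdefault(grandchild, set()).add(child)
    return CompoundOntology(edges=edges, class_roots=compound_class_roots())


def _default_class_probs() -> dict[str, float]:
    """Class sampling weights proportional to the surveyed class totals."""
    df = compound_class_counts()
    totals = (df["n_found"] + df["n_not_found"]).astype(float)
    return (totals / totals.sum()).to_dict()


def _class_ligand_pool(ontology: CompoundOntology) -> dict[str, list[str]]:
    """ChEBI ids usable as ligands of each class (roots, children, grandchildren)."""
    pool: dict[str, list[str]] = {}
    child_map: dict[str, list[str]] = {}
    for child, parents in ontology.edges.items():
        for p in parents:
            child_map.setdefault(p, []).append(child)
    for name, roots in ontology.class_roots:
        ids: list[str] = []
        for root in sorted(roots):
            ids.append(root)
            for c in sorted(child_map.get(root, [])):
                ids.append(c)
                ids.extend(sorted(child_map.get(c, [])))
        pool[name] = ids
    pool["Other compounds"] = ["CHEBI:0000001", "CHEBI:0000002"]
    return pool


# ---------------------------------------------------------------------------
# pockets and known sites

def _lognormal_size(rng, median: int, sigma: float, low: int, high: int) -> int:
    size = int(round(rng.lognormal(mean=np.log(median), sigma=sigma)))
    return int(np.clip(size, low, high))


def generate_pockets_and_sites(
    cfg: SyntheticConfig,
    proteome: list[ProteinRecord],
    ontology: CompoundOntology | None = None,
) -> tuple[list[PocketRecord], list[KnownSite]]:
    """Spatially contiguous pockets plus known sites with planted recovery.

    Pockets are the k residues spatially nearest a seed residue (a ball
    around the seed, not a sequence window); sizes are lognormal with the
    configured medians.  Each known site first draws a compound class, then
    a found/not-found status whose class odds against the baseline equal
    ``cfg.enrichment_odds`` (default 1.0); found sites share at least one
    residue with a pocket, not-found sites avoid all pockets of their
    protein.
    """
    rng = _rng(cfg, _STREAM_POCKETS, proteome[0].species if proteome else "")
    ontology = ontology or generate_ontology(cfg)
    ligand_pool = _class_ligand_pool(ontology)
    class_probs = cfg.class_probs or _default_class_probs()
    class_names = sorted(class_probs)
    weights = np.array([class_probs[c] for c in class_names], dtype=float)
    weights /= weights.sum()

    pockets: list[PocketRecord] = []
    pockets_by_protein: dict[str, list[PocketRecord]] = {}
    for protein in proteome:
        n_pockets = rng.poisson(cfg.pocket_rate)
        if n_pockets and cfg.pocket_size_median > len(protein):
            raise ValueError(
                f"pocket size median {cfg.pocket_size_median} incompatible with "
                f"protein length {len(protein)}"
            )
        drawn = []
        for j in range(n_pockets):
            size = _lognormal_size(rng, cfg.pocket_size_median, 0.35, 4, len(protein))
            seed_idx = int(rng.integers(len(protein)))
            dist = np.linalg.norm(protein.ca_coords - protein.ca_coords[seed_idx], axis=1)
            members = np.argsort(dist, kind="stable")[:size]
            drawn.append(
                (
                    float(rng.beta(*cfg.probability_beta_params)),
                    frozenset(ResidueRef("A", int(i) + 1) for i in members),
                )
            )
        drawn.sort(key=lambda t: -t[0])
        for rank, (prob, residues) in enumerate(drawn, start=1):
            pocket = PocketRecord(
                pocket_id=f"{protein.protein_id}:pocket{rank}",
                protein_id=protein.protein_id,
                rank=rank,
                probability=prob,
                residues=residues,
            )
            pockets.append(pocket)
            pockets_by_protein.setdefault(protein.protein_id, []).append(pocket)

    proteins_with_pockets = [p for p in proteome if pockets_by_protein.get(p.protein_id)]
    baseline_odds = (
        cfg.found_fraction / (1.0 - cfg.found_fraction)
        if cfg.found_fraction < 1.0
        else np.inf
    )
    sites: list[KnownSite] = []
    n_sites_total = rng.poisson(cfg.site_rate * len(proteome))
    for s in range(n_sites_total):
        cls = class_names[rng.choice(len(class_names), p=weights)]
        odds = cfg.enrichment_odds.get(cls, 1.0) * baseline_odds
        q = 1.0 if np.isinf(odds) else odds / (1.0 + odds)
        found = bool(rng.random() < q) and bool(proteins_with_pockets)
        ligands = ligand_pool.get(cls) or ligand_pool["Other compounds"]
        ligand = ligands[rng.integers(len(ligands))]
        size = _lognormal_size(rng, cfg.site_size_median, 0.4, cfg.min_site_size, 10**6)
        if found:
            protein = proteins_with_pockets[rng.integers(len(proteins_with_pockets))]
            plist = pockets_by_protein[protein.protein_id]
            pocket = plist[rng.integers(len(plist))]
            pocket_res = sorted(pocket.residues)
            n_inside = int(rng.integers(1, min(size, len(pocket_res)) + 1))
            inside = [pocket_res[i] for i in rng.choice(len(pocket_res), n_inside, replace=False)]
            outside_pool = [
                i + 1
                for i in range(len(protein))
                if ResidueRef("A", i + 1) not in pocket.residues
            ]
            n_outside = min(size - n_inside, len(outside_pool))
            outside = rng.choice(outside_pool, n_outside, replace=False) if n_outside else []
            residues = frozenset(inside) | frozenset(ResidueRef("A", int(i)) for i in outside)
        else:
            protein = proteome[rng.integers(len(proteome))]
            covered = frozenset().union(
                *(p.residues for p in pockets_by_protein.get(protein.protein_id, [])), frozenset()
            )
            free = [i + 1 for i in range(len(protein)) if ResidueRef("A", i + 1) not in covered]
            if len(free) < cfg.min_site_size:
                continue  # protein too crowded to host a clean miss
            chosen = rng.choice(free, min(size, len(free)), replace=False)
            residues = frozenset(ResidueRef("A", int(i)) for i in chosen)
        sites.append(
            KnownSite(
                site_id=f"{protein.protein_id}:site{s}",
                protein_id=protein.protein_id,
                residues=residues,
                ligand_chebi=ligand,
            )
        )
    return pockets, sites


# ---------------------------------------------------------------------------
# similarity ensemble

@dataclass
class GroundTruthPartition:
    species: str
    n_fs: int
    communities: list[frozenset[str]]
    singletons: frozenset[str]

    @property
    def n_unique(self) -> int:
        return len(self.communities) + len(self.singletons)

    @property
    def n_pockets(self) -> int:
        return sum(len(c) for c in self.communities) + len(self.singletons)


def sample_powerlaw_sizes(
    rng: np.random.Generator, n: int, exponent: float, s_min: int = 2, s_max: int = 200
) -> np.ndarray:
    """Discrete power-law community sizes: P(s) ∝ s^(−exponent) on [s_min, s_max]."""
    support = np.arange(s_min, s_max + 1)
    probs = support.astype(float) ** (-exponent)
    probs /= probs.sum()
    return rng.choice(support, size=n, p=probs)


def _partition_sizes(
    rng: np.random.Generator, n_comm: int, total: int, exponent: float
) -> list[int]:
    """Power-law-shaped community sizes (each >= 2) summing exactly to total."""
    if n_comm == 0:
        if total:
            raise ValueError("no communities to hold the clustered pockets")
        return []
    if total < 2 * n_comm:
        raise ValueError(
            f"infeasible partition: {total} clustered pockets cannot fill "
            f"{n_comm} communities of size >= 2"
        )
    raw = sample_powerlaw_sizes(rng, n_comm, exponent).astype(float)
    sizes = np.maximum(2, np.floor(raw * total / raw.sum()).astype(int))
    # repair the rounding residual on the largest communities
    diff = total - sizes.sum()
    order = np.argsort(-sizes, kind="stable")
    k = 0
    while diff != 0:
        idx = order[k % n_comm]
        if diff > 0:
            sizes[idx] += 1
            diff -= 1
        elif sizes[idx] > 2:
            sizes[idx] -= 1
            diff += 1
        k += 1
    return sizes.tolist()


def planted_partition_matrix(
    species: str,
    community_sizes: list[int],
    n_singletons: int,
    seed: int = 0,
    density: float = 0.35,
    score_range: tuple[float, float] = (2.0, 10.0),
) -> tuple[SimilarityMatrix, GroundTruthPartition]:
    """Similarity matrix with exactly the planted communities and singletons.

    Within-community pairs get positive scores (a connected random subgraph
    at the requested density); between-community scores are absent, so the
    planted partition is exactly the component structure.
    """
    import scipy.sparse as sp

    rng = np.random.default_rng([seed, zlib.crc32(species.encode())])
    pocket_ids = []
    communities = []
    rows, cols, vals = [], [], []
    lo, hi = score_range
    offset = 0
    for c, size in enumerate(community_sizes):
        members = [f"{species}:pk{offset + i:05d}" for i in range(size)]
        offset += size
        pocket_ids.extend(members)
        communities.append(frozenset(members))
        base = offset - size
        # connected backbone: a random spanning path over the shuffled members
        order = rng.permutation(size)
        pairs = {(min(order[i], order[i + 1]), max(order[i], order[i + 1])) for i in range(size - 1)}
        target = max(size - 1, int(round(density * size * (size - 1) / 2)))
        while len(pairs) < target:
            i, j = rng.integers(0, size, 2)
            if i != j:
                pairs.add((min(int(i), int(j)), max(int(i), int(j))))
        for i, j in sorted(pairs):
            rows.append(base + i)
            cols.append(base + j)
            vals.append(rng.uniform(lo, hi))
    singles = [f"{species}:sg{k:05d}" for k in range(n_singletons)]
    pocket_ids.extend(singles)
    n = len(pocket_ids)
    scores = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    sim = SimilarityMatrix(species=species, pocket_ids=pocket_ids, scores=scores)
    truth = GroundTruthPartition(
        species=species, n_fs=0, communities=communities, singletons=frozenset(singles)
    )
    return sim, truth


def generate_similarity_ensemble(
    cfg: SyntheticConfig,
) -> tuple[list[SimilarityMatrix], list[GroundTruthPartition]]:
    """Per-species similarity matrices with a planted scaling law.

    Fold-cluster counts N_FS are log-spaced over ``cfg.fold_cluster_range``;
    unique pocket counts follow N_unique = round(c · N_FS^a) (optionally
    with multiplicative lognormal noise of coefficient of variation
    ``noise_cv``); the singleton share of unique pockets is
    ``cfg.singleton_fraction``; total pockets grow linearly with N_FS; and
    community sizes are power-law shaped.  Infeasible combinations (too few
    clustered pockets for the implied community count) raise an error.
    """
    rng = _rng(cfg, _STREAM_SIMILARITY)
    lo, hi = cfg.fold_cluster_range
    n_fs_values = np.unique(
        np.round(np.geomspace(lo, hi, cfg.ensemble_species)).astype(int)
    )
    sims, truths = [], []
    for idx, n_fs in enumerate(n_fs_values):
        species = f"SYN{idx:02d}"
        n_pockets = max(2, int(round(cfg.pockets_per_fold * n_fs)))
        noise = rng.lognormal(mean=0.0, sigma=cfg.noise_cv) if cfg.noise_cv > 0 else 1.0
        n_unique = max(1, int(round(cfg.scaling_coeff * n_fs**cfg.a_true * noise)))
        if cfg.singleton_fraction >= 1.0:
            n_singletons, n_comm = n_pockets, 0
        else:
            n_singletons = int(round(cfg.singleton_fraction * n_unique))
            n_comm = n_unique - n_singletons
            if n_comm < 1:
                raise ValueError(
                    f"{species}: singleton fraction {cfg.singleton_fraction} leaves "
                    "no room for communities"
                )
        clustered = n_pockets - n_singletons
        sizes = _partition_sizes(rng, n_comm, clustered, cfg.community_size_power)
        sim, truth = planted_partition_matrix(
            species,
            sizes,
            n_singletons,
            seed=int(rng.integers(0, 2**31 - 1)),
            density=cfg.within_community_density,
            score_range=cfg.score_range,
        )
        truth.n_fs = int(n_fs)
        sims.append(sim)
        truths.append(truth)
    return sims, truths


# ---------------------------------------------------------------------------
# embeddings

def generate_embeddings(
    cfg: SyntheticConfig,
    pockets: "list[PocketRecord] | int",
    kingdoms: list[str] | None = None,
) -> EmbeddingSet:
    """128-d Gaussian-mixture vectors with controllable kingdom association.

    ``cfg.kingdom_mixture`` maps each kingdom to (separation, sd): each
    kingdom's component mean is ``separation`` times a kingdom-specific
    random unit vector.  Separation 0 for all kingdoms puts every kingdom
    in one shared component (no association); large separations segregate
    the kingdoms completely.
    """
    import pandas as pd

    rng = _rng(cfg, _STREAM_EMBEDDINGS)
    if isinstance(pockets, int):
        pocket_ids = [f"emb:pk{k:06d}" for k in range(pockets)]
        species = [f"SYN{k % cfg.n_species:02d}" for k in range(pockets)]
    else:
        pocket_ids = [p.pocket_id for p in pockets]
        species = [p.protein_id.split("_")[0] for p in pockets]
    if kingdoms is None:
        uniq = sorted(set(species))
        k_map = {s: KINGDOMS[i % len(KINGDOMS)] for i, s in enumerate(uniq)}
        kingdoms = [k_map[s] for s in species]
    mixture = cfg.kingdom_mixture or {k: (0.0, 1.0) for k in set(kingdoms)}
    means: dict[str, np.ndarray] = {}
    for kingdom in sorted(set(kingdoms)):
        sep, _ = mixture.get(kingdom, (0.0, 1.0))
        direction = np.random.default_rng(
            [cfg.seed, _STREAM_EMBEDDINGS, zlib.crc32(kingdom.encode())]
        ).normal(size=EmbeddingSet.DIM)
        direction /= np.linalg.norm(direction)
        means[kingdom] = sep * direction
    vectors = np.empty((len(pocket_ids), EmbeddingSet.DIM))
    for i, kingdom in enumerate(kingdoms):
        _, sd = mixture.get(kingdom, (0.0, 1.0))
        vectors[i] = means[kingdom] + rng.normal(scale=sd, size=EmbeddingSet.DIM)
    labels = pd.DataFrame(
        {"species": species, "kingdom": kingdoms, "compound_class": "unannotated"},
        index=pd.Index(pocket_ids, name="pocket_id"),
    )
    return EmbeddingSet(pocket_ids=pocket_ids, vectors=vectors, labels=labels)


# ---------------------------------------------------------------------------
# fixture tree

def write_fixture_tree(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, object]:
    """Write the full synthetic input set into a directory tree.

    Layout: ``structures/<species>/<protein>.pdb``, ``pae/<protein>.json``,
    ``pockets/<protein>.csv``, ``annotations.tsv``, ``ontology_edges.tsv``,
    ``fold_clusters.tsv``, ``domains.tsv``, ``similarity/<species>.tsv`` (+
    ``.nodes.tsv``), ``embeddings.tsv`` and ``embedding_labels.tsv``.

    Similarity matrices are planted over each species' generated pocket ids
    so the whole tree is mutually consistent.  Returns a manifest of the
    in-memory objects (useful for ground-truth checks in tests).
    """
    outdir = Path(outdir)
    for sub in ("structures", "pae", "pockets", "similarity"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(cfg)
    pio.write_ontology_edges(ontology.edges, outdir / "ontology_edges.tsv")

    species_names = [f"SYN{i:02d}" for i in range(cfg.n_species)]
    all_sites: list[KnownSite] = []
    all_pockets: list[PocketRecord] = []
    fold_clusters: dict[str, str] = {}
    domains: dict[str, object] = {}
    manifest: dict[str, object] = {"species": species_names, "truth": {}}
    rng = _rng(cfg, _STREAM_SIMILARITY, "fixture")
    from .model import DomainAnnotation

    for sp_idx, species in enumerate(species_names):
        proteome = generate_proteome(cfg, species)
        sdir = outdir / "structures" / species
        sdir.mkdir(exist_ok=True)
        # fold diversity grows across species so the scaling stage has spread
        n_folds = max(2, round(cfg.proteins_per_species * (sp_idx + 1) / (cfg.n_species + 1)))
        for protein in proteome:
            pio.write_pdb(protein.atoms, sdir / f"{protein.protein_id}.pdb")
            pio.write_pae_json(protein.pae, outdir / "pae" / f"{protein.protein_id}.json")
            fold_clusters[protein.protein_id] = f"{species}_F{rng.integers(n_folds):03d}"
            if rng.random() < 0.7:
                start = int(rng.integers(1, max(2, len(protein) - 30)))
                end = min(len(protein), start + int(rng.integers(20, 60)))
                domains[protein.protein_id] = DomainAnnotation(
                    protein.protein_id,
                    [(f"DOM{rng.integers(5):02d}", start, end, bool(rng.random() < 0.1))],
                )
        pockets, sites = generate_pockets_and_sites(cfg, proteome, ontology)
        all_pockets.extend(pockets)
        all_sites.extend(sites)
        for protein in proteome:
            mine = [p for p in pockets if p.protein_id == protein.protein_id]
            if mine:
                pio.write_p2rank_table(mine, outdir / "pockets" / f"{protein.protein_id}.csv")
        # similarity over this species' pocket ids
        ids = [p.pocket_id for p in pockets]
        n = len(ids)
        n_sing = int(round(min(1.0, cfg.singleton_fraction) * 0.5 * n))
        clustered = n - n_sing
        n_comm = max(1, clustered // 8) if clustered >= 2 else 0
        sizes = _partition_sizes(rng, n_comm, clustered, cfg.community_size_power) if n_comm else []
        sim, truth = planted_partition_matrix(
            species, sizes, n_sing, seed=int(rng.integers(0, 2**31 - 1)),
            density=cfg.within_community_density, score_range=cfg.score_range,
        )
        # rename planted ids onto the real pocket ids (deterministic order)
        renaming = dict(zip(sim.pocket_ids, ids))
        sim = SimilarityMatrix(species, [renaming[i] for i in sim.pocket_ids], sim.scores)
        truth = GroundTruthPartition(
            species=species,
            n_fs=len({fold_clusters[p.protein_id] for p in pockets}) if pockets else 0,
            communities=[frozenset(renaming[m] for m in c) for c in truth.communities],
            singletons=frozenset(renaming[m] for m in truth.singletons),
        )
        manifest["truth"][species] = truth
        pio.write_similarity_matrix(sim, outdir / "similarity" / f"{species}.tsv")
        (outdir / "similarity" / f"{species}.nodes.tsv").write_text(
            "pocket_id\n" + "\n".join(sim.pocket_ids) + "\n"
        )
    pio.write_annotation_table(all_sites, outdir / "annotations.tsv")
    pio.write_fold_clusters(fold_clusters, outdir / "fold_clusters.tsv")
    pio.write_domains(domains, outdir / "domains.tsv")
    emb = generate_embeddings(cfg, all_pockets)
    pio.write_embeddings(emb, outdir / "embeddings.tsv", outdir / "embedding_labels.tsv")
    manifest["n_pockets"] = len(all_pockets)
    manifest["n_sites"] = len(all_sites)
    return manifest
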