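"""Known-site processing, compound-class enrichment, and group contrasts.

Covers inter-chain site splitting (Cα distance graph, 12 Å, connected
components), overlap matching of known vs predicted pockets (any shared
residue counts), recursive ChEBI compound-class assignment, Fisher-exact
enrichment with Benjamini–Yekutieli FDR control, pocket domain
classification, and singleton/non-singleton descriptor contrasts (Welch
t-test plus Cohen's d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import fisher_exact, ttest_ind
from statsmodels.stats.multitest import multipletests

from .model import CompoundOntology, DomainAnnotation, KnownSite, PocketRecord, ResidueRef

OTHER_COMPOUND = "Other compounds"


# ---------------------------------------------------------------------------
# inter-chain site splitting

def split_interchain_site(
    site: KnownSite,
    ca_coords: dict[str, np.ndarray],
    distance_threshold: float = 12.0,
    min_residues: int = 4,
) -> list[KnownSite]:
    """Split a site into spatially connected components.

    Residues are nodes; an edge joins two residues whose Cα–Cα distance is
    <= ``distance_threshold`` (inclusive).  One output site per connected
    component; components smaller than ``min_residues`` are dropped.
    ``ca_coords`` maps chain id to that chain's (n, 3) Cα array (1-based
    residue indices).
    """
    residues = sorted(site.residues)
    coords = []
    for ref in residues:
        chain_coords = ca_coords.get(ref.chain)
        if chain_coords is None or ref.index > len(chain_coords):
            raise ValueError(f"{site.site_id}: no coordinates for residue {ref}")
        coords.append(chain_coords[ref.index - 1])
    coords = np.asarray(coords)
    adjacency = csr_matrix(cdist(coords, coords) <= distance_threshold)
    n_comp, labels = connected_components(adjacency, directed=False)
    out = []
    for comp in range(n_comp):
        members = frozenset(r for r, l in zip(residues, labels) if l == comp)
        if len(members) >= min_residues:
            out.append(
                KnownSite(
                    site_id=f"{site.site_id}.{comp}" if n_comp > 1 else site.site_id,
                    protein_id=site.protein_id,
                    residues=members,
                    ligand_chebi=site.ligand_chebi,
                )
            )
    return out


# ---------------------------------------------------------------------------
# known vs predicted overlap

@dataclass
class MatchResult:
    found: bool
    matched_pockets: list[str]


def match_known_to_predicted(
    known: list[KnownSite], predicted: list[PocketRecord]
) -> dict[str, MatchResult]:
    """Mark each known site 'found' iff it shares >= 1 (chain, index) residue
    with a predicted pocket on the same protein."""
    by_protein: dict[str, list[PocketRecord]] = {}
    for p in predicted:
        by_protein.setdefault(p.protein_id, []).append(p)
    out = {}
    for site in known:
        matched = [
            p.pocket_id
            for p in by_protein.get(site.protein_id, [])
            if p.residues & site.residues
        ]
        out[site.site_id] = MatchResult(found=bool(matched), matched_pockets=matched)
    return out


# ---------------------------------------------------------------------------
# compound-class assignment

def assign_compound_class(chebi_id: str | None, ontology: CompoundOntology) -> frozenset[str]:
    """Ascend parent edges from ``chebi_id``; return every compound class
    whose root set is reached (a root id reaches itself in zero steps).

    An id reaching no class root maps to the 'Other compounds' fallback.
    A cycle in the ontology is an error.
    """
    if chebi_id is None:
        return frozenset({OTHER_COMPOUND})
    # iterative DFS with white/grey/black coloring; a grey->grey edge is a cycle
    GREY, BLACK = 1, 2
    color: dict[str, int] = {}
    ancestors: set[str] = set()
    stack: list[tuple[str, bool]] = [(chebi_id, False)]
    while stack:
        node, done = stack.pop()
        if done:
            color[node] = BLACK
            continue
        if color.get(node) == BLACK:
            continue
        color[node] = GREY
        ancestors.add(node)
        stack.append((node, True))
        for parent in ontology.edges.get(node, ()):
            if color.get(parent) == GREY:
                raise ValueError(f"cycle in ontology through {parent}")
            if color.get(parent) != BLACK:
                stack.append((parent, False))
    classes = frozenset(
        name for name, roots in ontology.class_roots if ancestors & roots
    )
    return classes if classes else frozenset({OTHER_COMPOUND})


# ---------------------------------------------------------------------------
# enrichment

@dataclass
class EnrichmentRow:
    class_name: str
    n_found: int
    n_not_found: int
    odds_ratio: float
    p_value: float
    p_adj: float


def sample_odds_ratio(a: int, b: int, total_found: int, total_not_found: int) -> float:
    """Cross-product odds ratio (a/b) / ((F−a)/(NF−b)) with 0/∞ conventions."""
    c, d = total_found - a, total_not_found - b
    if c < 0 or d < 0:
        raise ValueError("class counts exceed the unique-site totals")
    num = np.inf if b == 0 and a > 0 else (a / b if b else 0.0)
    den = np.inf if d == 0 and c > 0 else (c / d if d else 0.0)
    if num == 0.0:
        return 0.0
    if np.isinf(num):
        return np.inf
    if den == 0.0:
        return np.inf
    if np.isinf(den):
        return 0.0
    return num / den


def enrichment_table(
    class_counts: dict[str, tuple[int, int]],
    total_found: int,
    total_not_found: int,
) -> list[EnrichmentRow]:
    """Per-class Fisher-exact enrichment of 'found' status.

    ``class_counts`` maps class name to (found, not found) counts of unique
    known sites in that class; ``total_found``/``total_not_found`` are the
    unique-site totals over ALL classes.  Because a ligand may belong to
    several classes, the per-class found counts may sum to more than
    ``total_found``; the totals are invariant to that multiplicity.  P-values
    are two-sided and corrected by the Benjamini–Yekutieli procedure across
    classes.
    """
    names, pvals, rows = [], [], []
    for name, (a, b) in class_counts.items():
        c, d = total_found - a, total_not_found - b
        if c < 0 or d < 0:
            raise ValueError(f"{name}: counts ({a}, {b}) exceed totals")
        orat = sample_odds_ratio(a, b, total_found, total_not_found)
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        names.append(name)
        pvals.append(p)
        rows.append((name, a, b, orat, p))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_by")
    return [
        EnrichmentRow(name, a, b, orat, p, float(pa))
        for (name, a, b, orat, p), pa in zip(rows, p_adj)
    ]


def class_counts_from_sites(
    sites: list[KnownSite],
    found_flags: dict[str, bool],
    ontology: CompoundOntology,
) -> tuple[dict[str, tuple[int, int]], int, int]:
    """Tally per-class (found, not found) counts over unique sites.

    Returns (class_counts, total_found, total_not_found); the totals count
    each site once even when its ligand maps to several classes.
    """
    counts: dict[str, list[int]] = {}
    total_found = total_not_found = 0
    for site in sites:
        found = found_flags[site.site_id]
        if found:
            total_found += 1
        else:
            total_not_found += 1
        for cls in assign_compound_class(site.ligand_chebi, ontology):
            counts.setdefault(cls, [0, 0])[0 if found else 1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}, total_found, total_not_found


# ---------------------------------------------------------------------------
# domain classification

DOMAIN_CATEGORIES = ("no_domain", "single_domain", "inter_domain", "domain_no_domain", "DUF")


def classify_pocket_domains(
    pocket: PocketRecord, domains: DomainAnnotation | None
) -> tuple[str, frozenset[str]]:
    """Assign a pocket to a domain-context category.

    A pocket is assigned every domain interval containing at least one of
    its residues.  Categories: ``no_domain`` (no residue in any interval),
    ``domain_no_domain`` (residues both inside and outside domains),
    ``inter_domain`` (two or more distinct domain ids), ``DUF`` (all
    assigned domains are domains of unknown function), else
    ``single_domain``.
    """
    intervals = domains.intervals if domains is not None else []
    assigned: set[str] = set()
    duf_flags: dict[str, bool] = {}
    in_domain = 0
    for ref in pocket.residues:
        hit = False
        for dom_id, start, end, is_duf in intervals:
            if start <= ref.index <= end:
                assigned.add(dom_id)
                duf_flags[dom_id] = is_duf
                hit = True
        in_domain += hit
    outside = len(pocket.residues) - in_domain
    if not assigned:
        return "no_domain", frozenset()
    if in_domain and outside:
        return "domain_no_domain", frozenset(assigned)
    if all(duf_flags[d] for d in assigned):
        return "DUF", frozenset(assigned)
    if len(assigned) >= 2:
        return "inter_domain", frozenset(assigned)
    return "single_domain", frozenset(assigned)


# ---------------------------------------------------------------------------
# singleton vs non-singleton contrasts

@dataclass
class ContrastRow:
    property_name: str
    cohens_d: float
    p_value: float
    median_a: float
    median_b: float


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        # degenerate groups: equal constants have no difference; unequal
        # constants are infinitely separated on the pooled-SD scale
        return 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
    return float(diff / np.sqrt(pooled_var))


def contrast_groups(
    table: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> list[ContrastRow]:
    """Welch t-test and Cohen's d per descriptor column between two pocket
    groups (e.g. non-singletons vs singletons), given their pocket ids."""
    rows = []
    sub_a, sub_b = table.loc[group_a], table.loc[group_b]
    for col in table.columns:
        a = sub_a[col].dropna().to_numpy(dtype=float)
        b = sub_b[col].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        _, p = ttest_ind(a, b, equal_var=False)
        rows.append(
            ContrastRow(
                property_name=col,
                cohens_d=cohens_d(a, b),
                p_value=float(p),
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
            )
        )
    return rows
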