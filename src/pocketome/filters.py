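"""Protein- and pocket-level inclusion rules.

Proteins are excluded when they are UniProt fragments, shorter than 100
residues, or transmembrane models passing fewer than six database quality
checks.  Pockets are excluded when the predictor's probability score falls
below 0.5, when the mean pLDDT over the lining residues is below 70, or when
the mean pairwise aligned error over those residues exceeds 10 Å.  The
pLDDT/PAE rules use strict inequalities for exclusion, so a pocket sitting
exactly on a boundary is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .model import KnownSite, PocketRecord, ProteinRecord


@dataclass
class FilterConfig:
    min_protein_length: int = 100
    min_tm_checks: int = 6
    probability_threshold: float = 0.5
    min_pocket_plddt: float = 70.0
    max_pocket_pae: float = 10.0
    min_known_site_residues: int = 4


# reason codes, in the order the rules are checked
REASON_OK = "ok"
REASON_FRAGMENT = "fragment"
REASON_LENGTH = "length"
REASON_TM_CHECKS = "tm_checks"
REASON_PROBABILITY = "probability"
REASON_PLDDT = "plddt"
REASON_PAE = "pae"
REASON_PROTEIN_FAILED = "protein_failed"


def protein_passes(protein: ProteinRecord, cfg: FilterConfig | None = None) -> tuple[bool, str]:
    """Apply the protein-level inclusion rules; returns (passed, reason)."""
    cfg = cfg or FilterConfig()
    if protein.is_fragment:
        return False, REASON_FRAGMENT
    if len(protein) < cfg.min_protein_length:
        return False, REASON_LENGTH
    if protein.tm_checks_passed is not None and protein.tm_checks_passed < cfg.min_tm_checks:
        return False, REASON_TM_CHECKS
    return True, REASON_OK


def _pocket_indices(pocket: PocketRecord, protein: ProteinRecord) -> np.ndarray:
    idx = np.array(sorted(r.index for r in pocket.residues), dtype=int)
    if idx.max() > len(protein):
        bad = idx[idx > len(protein)]
        raise ValueError(
            f"{pocket.pocket_id}: residues {bad.tolist()} outside protein "
            f"{protein.protein_id} (length {len(protein)})"
        )
    return idx - 1  # to 0-based


def pocket_mean_plddt(pocket: PocketRecord, protein: ProteinRecord) -> float:
    """Arithmetic mean pLDDT over the pocket's lining residues."""
    return float(protein.plddt[_pocket_indices(pocket, protein)].mean())


def pocket_mean_pae(pocket: PocketRecord, protein: ProteinRecord) -> float:
    """Mean aligned error over ALL ordered residue pairs of the pocket.

    The average runs over the full k x k submatrix of the (possibly
    asymmetric) PAE matrix, including the diagonal.
    """
    if protein.pae is None:
        raise ValueError(f"{protein.protein_id}: no PAE matrix available")
    idx = _pocket_indices(pocket, protein)
    return float(protein.pae[np.ix_(idx, idx)].mean())


def pocket_passes(
    pocket: PocketRecord, protein: ProteinRecord, cfg: FilterConfig | None = None
) -> tuple[bool, str]:
    """Apply the pocket-level inclusion rules; returns (passed, reason).

    Exclusion is strict (< plddt floor, > pae ceiling), inclusion of the
    probability is >= the threshold, so all three boundaries pass.
    """
    cfg = cfg or FilterConfig()
    if pocket.probability < cfg.probability_threshold:
        return False, REASON_PROBABILITY
    if pocket_mean_plddt(pocket, protein) < cfg.min_pocket_plddt:
        return False, REASON_PLDDT
    if protein.pae is not None and pocket_mean_pae(pocket, protein) > cfg.max_pocket_pae:
        return False, REASON_PAE
    return True, REASON_OK


@dataclass
class FilterSummary:
    """Accounting of how many records failed each rule."""

    protein_reasons: Counter = field(default_factory=Counter)
    pocket_reasons: Counter = field(default_factory=Counter)


def filter_cohort(
    pockets: list[PocketRecord],
    proteins: dict[str, ProteinRecord],
    cfg: FilterConfig | None = None,
) -> tuple[list[PocketRecord], FilterSummary]:
    """Filter a pocket cohort; a pocket on a failing protein is removed
    regardless of its own scores (reason code ``protein_failed``).

    Order-independent and idempotent: each record is judged in isolation.
    """
    cfg = cfg or FilterConfig()
    summary = FilterSummary()
    protein_ok: dict[str, bool] = {}
    for pid, protein in proteins.items():
        ok, reason = protein_passes(protein, cfg)
        protein_ok[pid] = ok
        summary.protein_reasons[reason] += 1
    kept = []
    for pocket in pockets:
        if not protein_ok.get(pocket.protein_id, False):
            summary.pocket_reasons[REASON_PROTEIN_FAILED] += 1
            continue
        ok, reason = pocket_passes(pocket, proteins[pocket.protein_id], cfg)
        summary.pocket_reasons[reason] += 1
        if ok:
            kept.append(pocket)
    return kept, summary


def recall_vs_threshold(
    pockets: list[PocketRecord],
    known_sites: list[KnownSite],
    thresholds: list[float],
    min_known_site_residues: int = 4,
) -> dict[float, float]:
    """Recall of known sites as a function of the probability threshold.

    recall(t) = fraction of known sites (with at least
    ``min_known_site_residues`` residues) sharing >= 1 residue with a
    same-protein pocket of probability >= t.  Non-increasing in t.
    """
    sites = [s for s in known_sites if len(s.residues) >= min_known_site_residues]
    if not sites:
        raise ValueError("no known sites of sufficient size to compute recall")
    by_protein: dict[str, list[PocketRecord]] = {}
    for p in pockets:
        by_protein.setdefault(p.protein_id, []).append(p)
    # the best probability of any pocket overlapping each site
    best: list[float] = []
    for site in sites:
        probs = [
            p.probability
            for p in by_protein.get(site.protein_id, [])
            if p.residues & site.residues
        ]
        best.append(max(probs) if probs else -np.inf)
    best_arr = np.asarray(best)
    return {float(t): float((best_arr >= t).mean()) for t in thresholds}
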