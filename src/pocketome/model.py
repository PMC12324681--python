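"""Core domain types shared across the pipeline.

Residue numbering follows the UniProt convention: 1-based sequence indices,
intervals inclusive on both ends.  A pocket or known binding site is defined
by the set of residues lining it, identified as (chain, index) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A single residue identified by chain id and 1-based sequence index."""

    chain: str
    index: int

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("chain id must be non-empty")
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")

    def __str__(self) -> str:  # the CHAIN_INDEX token used in tabular files
        return f"{self.chain}_{self.index}"

    @classmethod
    def from_token(cls, token: str) -> "ResidueRef":
        chain, _, idx = token.partition("_")
        if not idx:
            raise ValueError(f"malformed residue token {token!r}; expected CHAIN_INDEX")
        return cls(chain=chain, index=int(idx))


@dataclass
class ProteinRecord:
    """One predicted protein structure with its confidence annotations.

    ``plddt`` is the per-residue model confidence in [0, 100]; ``pae`` is the
    pairwise predicted aligned error matrix in Å (stored as given, possibly
    asymmetric).  ``tm_checks_passed`` is the number of transmembrane-model
    quality checks passed (0-6) or None for soluble proteins.
    """

    protein_id: str
    species: str
    sequence: str
    ca_coords: np.ndarray
    plddt: np.ndarray
    pae: np.ndarray | None = None
    atoms: object | None = None  # biotite AtomArray with all-atom coordinates
    is_fragment: bool = False
    tm_checks_passed: int | None = None
    fold_cluster: str | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.plddt.shape != (n,):
            raise ValueError(
                f"{self.protein_id}: plddt length {self.plddt.shape} != sequence length {n}"
            )
        if self.ca_coords.shape != (n, 3):
            raise ValueError(f"{self.protein_id}: ca_coords must be ({n}, 3)")
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            if self.pae.shape != (n, n):
                raise ValueError(f"{self.protein_id}: pae must be square of side {n}")
            if (self.pae < 0).any():
                raise ValueError(f"{self.protein_id}: pae entries must be >= 0")
        if self.tm_checks_passed is not None and not 0 <= self.tm_checks_passed <= 6:
            raise ValueError("tm_checks_passed must be in [0, 6]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PocketRecord:
    """One predicted binding pocket: lining residues plus ligandability score."""

    pocket_id: str
    protein_id: str
    rank: int
    probability: float
    residues: frozenset[ResidueRef]
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)
        if not self.residues:
            raise ValueError(f"{self.pocket_id}: pocket must have at least one residue")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.pocket_id}: probability {self.probability} not in [0, 1]")
        if self.rank < 1:
            raise ValueError(f"{self.pocket_id}: rank must be >= 1")


@dataclass
class KnownSite:
    """An annotated (known) binding site, optionally with its ligand's ChEBI id."""

    site_id: str
    protein_id: str
    residues: frozenset[ResidueRef]
    ligand_chebi: str | None = None

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)
        if not self.residues:
            raise ValueError(f"{self.site_id}: site must have at least one residue")


@dataclass
class DomainAnnotation:
    """Per-protein domain intervals (1-based, inclusive)."""

    protein_id: str
    intervals: list[tuple[str, int, int, bool]]  # (domain_id, start, end, is_DUF)

    def __post_init__(self) -> None:
        for dom, start, end, _ in self.intervals:
            if start > end:
                raise ValueError(f"{self.protein_id}/{dom}: start {start} > end {end}")


@dataclass
class CompoundOntology:
    """Child-to-parent ChEBI edges plus the named compound-class roots.

    ``class_roots`` is an ordered list of (class name, set of root ChEBI ids);
    a ligand belongs to a class when any of that class's roots is reachable by
    transitive ascent of parent edges.
    """

    edges: dict[str, set[str]]
    class_roots: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for child, parents in self.edges.items():
            if child in parents:
                raise ValueError(f"self-edge on {child}")
        self.class_roots = [(name, frozenset(roots)) for name, roots in self.class_roots]

    def class_names(self) -> list[str]:
        return [name for name, _ in self.class_roots]


class SimilarityMatrix:
    """Sparse symmetric nonnegative pairwise pocket-alignment scores.

    An absent entry means the two pockets could not be aligned; the diagonal
    is ignored.  Symmetric completion is applied on construction and is
    idempotent.
    """

    def __init__(self, species: str, pocket_ids: list[str], scores: sp.spmatrix):
        n = len(pocket_ids)
        scores = sp.coo_matrix(scores, shape=(n, n))
        if (scores.data < 0).any():
            raise ValueError("similarity scores must be >= 0")
        # drop diagonal, complete symmetrically by taking max(S, S.T)
        mask = scores.row != scores.col
        scores = sp.coo_matrix(
            (scores.data[mask], (scores.row[mask], scores.col[mask])), shape=(n, n)
        ).tocsr()
        self.species = species
        self.pocket_ids = list(pocket_ids)
        self.scores = scores.maximum(scores.T)
        self.scores.eliminate_zeros()

    @property
    def n_pockets(self) -> int:
        return len(self.pocket_ids)

    def max_score(self) -> float:
        return float(self.scores.data.max()) if self.scores.nnz else 0.0

    def degrees(self) -> np.ndarray:
        """Number of nonzero partners per pocket (pre-threshold)."""
        return np.asarray((self.scores > 0).sum(axis=1)).ravel()

    def triplets(self) -> list[tuple[str, str, float]]:
        """Upper-triangle (i < j) triplets, deterministic order."""
        coo = sp.triu(self.scores, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return [
            (self.pocket_ids[coo.row[k]], self.pocket_ids[coo.col[k]], float(coo.data[k]))
            for k in order
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return (
            self.species == other.species
            and self.pocket_ids == other.pocket_ids
            and (self.scores != other.scores).nnz == 0
        )


@dataclass
class EmbeddingSet:
    """Pocket embedding vectors (pocket x 128) with per-pocket labels."""

    pocket_ids: list[str]
    vectors: np.ndarray
    labels: "object"  # pandas DataFrame indexed like pocket_ids

    DIM = 128

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.DIM:
            raise ValueError(
                f"embedding vectors must be (n, {self.DIM}); got {self.vectors.shape}"
            )
        if self.vectors.shape[0] != len(self.pocket_ids):
            raise ValueError("vectors row count must match pocket_ids")
        if list(self.labels.index) != list(self.pocket_ids):
            raise ValueError("labels must be aligned with pocket_ids")

    @property
    def n_pockets(self) -> int:
        return len(self.pocket_ids)


def residues_from_tokens(tokens: Iterable[str]) -> frozenset[ResidueRef]:
    return frozenset(ResidueRef.from_token(t) for t in tokens)


def residue_token_field(residues: Iterable[ResidueRef]) -> str:
    return " ".join(str(r) for r in sorted(residues))
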