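"""Readers and writers for every file format the pipeline touches.

Formats
-------
* Pocket prediction tables: CSV with columns ``name, rank, probability,
  residue_ids`` where ``residue_ids`` is a space-separated list of
  ``CHAIN_INDEX`` tokens (the dialect emitted by ligandability predictors
  such as P2Rank); extra columns are ignored.
* Structures: PDB or mmCIF, read-only, with per-residue model confidence
  (pLDDT) stored in the B-factor column as AlphaFold does.  A PDB writer is
  provided for synthetic fixtures.
* Pairwise aligned-error matrices: AlphaFold-DB JSON with key
  ``predicted_aligned_error``.
* Known-site annotations, fold-cluster assignments, domain intervals,
  compound-ontology edges: TSV with documented headers.
* Similarity matrices: TSV triplets ``pocket_i<TAB>pocket_j<TAB>score``.
* Embeddings: dense TSV matrix keyed by pocket id plus a labels TSV.

Every reader enforces the domain-type invariants on load; every writer
round-trips losslessly with its reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx
from biotite.sequence import ProteinSequence

from .model import (
    DomainAnnotation,
    EmbeddingSet,
    KnownSite,
    PocketRecord,
    ResidueRef,
    SimilarityMatrix,
    residue_token_field,
    residues_from_tokens,
)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


# ---------------------------------------------------------------------------
# pocket prediction tables

_P2RANK_COLUMNS = ("name", "rank", "probability", "residue_ids")


def read_p2rank_table(path: str | Path, protein_id: str | None = None) -> list[PocketRecord]:
    """Read a pocket prediction CSV; one PocketRecord per row.

    ``protein_id`` defaults to the file stem.  Missing columns raise a
    :class:`FormatError` naming the column; malformed residue tokens raise a
    row-level error with the data line number.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    df = pd.read_csv(path, skipinitialspace=True, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    for col in _P2RANK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        tokens = str(getattr(row, "residue_ids")).split()
        try:
            residues = residues_from_tokens(tokens)
        except ValueError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
        records.append(
            PocketRecord(
                pocket_id=f"{protein_id}:{getattr(row, 'name')}",
                protein_id=protein_id,
                rank=int(getattr(row, "rank")),
                probability=float(getattr(row, "probability")),
                residues=residues,
            )
        )
    return records


def write_p2rank_table(pockets: list[PocketRecord], path: str | Path) -> None:
    rows = [
        {
            "name": p.pocket_id.split(":", 1)[1] if ":" in p.pocket_id else p.pocket_id,
            "rank": p.rank,
            "probability": p.probability,
            "residue_ids": residue_token_field(p.residues),
        }
        for p in pockets
    ]
    pd.DataFrame(rows, columns=list(_P2RANK_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# structures

def _load_atoms(path: Path):
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        cif = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(cif, model=1, extra_fields=["b_factor"])
    else:
        pdbf = pdb.PDBFile.read(str(path))
        atoms = pdbf.get_structure(model=1, extra_fields=["b_factor"])
    return atoms[struc.filter_amino_acids(atoms)]


def read_structure(path: str | Path):
    """Read a structure file into a biotite AtomArray (amino acids only)."""
    try:
        atoms = _load_atoms(Path(path))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse structure ({exc})") from exc
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no amino-acid atoms found")
    return atoms


def read_structure_confidence(path: str | Path):
    """Extract (sequence, ca_coords, plddt) from a structure file.

    The per-residue confidence is taken from the Cα atom's B-factor.  A
    residue with atoms disagreeing on the B-factor triggers a warning (the
    Cα value is used); a residue without a Cα atom is an error.
    """
    atoms = read_structure(path)
    sequence = []
    ca_coords = []
    plddt = []
    for res in struc.residue_iter(atoms):
        res_tag = f"{res.chain_id[0]} {res.res_name[0]} {res.res_id[0]}"
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            raise FormatError(f"{path}: residue {res_tag} has no CA atom")
        if not np.allclose(res.b_factor, res.b_factor[0]):
            warnings.warn(
                f"{path}: residue {res_tag} has mixed B-factors; using the CA value",
                stacklevel=2,
            )
        sequence.append(ProteinSequence.convert_letter_3to1(res.res_name[0]))
        ca_coords.append(ca.coord[0])
        plddt.append(float(ca.b_factor[0]))
    return "".join(sequence), np.asarray(ca_coords, dtype=float), np.asarray(plddt, dtype=float)


def write_pdb(atoms, path: str | Path) -> None:
    """Write an AtomArray (with b_factor annotation) as a PDB file."""
    pdbf = pdb.PDBFile()
    pdbf.set_structure(atoms)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# predicted aligned error

def read_pae_json(path: str | Path) -> np.ndarray:
    """Read a pairwise aligned-error matrix from AlphaFold-DB-style JSON.

    The matrix is stored as given (it may be asymmetric); ragged rows and
    negative entries are rejected.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):  # AlphaFold-DB wraps the object in a list
        payload = payload[0]
    if "predicted_aligned_error" not in payload:
        raise FormatError(f"{path}: missing key 'predicted_aligned_error'")
    rows = payload["predicted_aligned_error"]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1 or (rows and lengths != {len(rows)}):
        raise FormatError(f"{path}: predicted_aligned_error must be a square matrix")
    pae = np.asarray(rows, dtype=float)
    if pae.size and (pae < 0).any():
        raise ValueError(f"{path}: negative aligned-error entry")
    return pae


def write_pae_json(pae: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"predicted_aligned_error": np.asarray(pae, dtype=float).tolist()}, fh)


# ---------------------------------------------------------------------------
# annotations and assignments (TSV dialects)

def read_annotation_table(path: str | Path) -> list[KnownSite]:
    """Known-site TSV: protein_id, site_id, residues, ligand_chebi (optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "site_id", "residues"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sites = []
    for row in df.itertuples(index=False):
        ligand = getattr(row, "ligand_chebi", "") or None
        sites.append(
            KnownSite(
                site_id=row.site_id,
                protein_id=row.protein_id,
                residues=residues_from_tokens(row.residues.split()),
                ligand_chebi=ligand,
            )
        )
    return sites


def write_annotation_table(sites: list[KnownSite], path: str | Path) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "site_id": s.site_id,
            "residues": residue_token_field(s.residues),
            "ligand_chebi": s.ligand_chebi or "",
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["protein_id", "site_id", "residues", "ligand_chebi"]).to_csv(
        path, sep="\t", index=False
    )


def read_fold_clusters(path: str | Path) -> dict[str, str]:
    """Fold-cluster TSV: protein_id, fold_cluster."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "fold_cluster"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df["protein_id"], df["fold_cluster"]))


def write_fold_clusters(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["protein_id", "fold_cluster"]
    ).to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> dict[str, DomainAnnotation]:
    """Domain TSV: protein_id, domain_id, start, end, is_duf (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    out: dict[str, DomainAnnotation] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, DomainAnnotation(row.protein_id, [])).intervals.append(
            (row.domain_id, int(row.start), int(row.end), bool(int(row.is_duf)))
        )
    for ann in out.values():
        DomainAnnotation(ann.protein_id, ann.intervals)  # re-validate
    return out


def write_domains(domains: dict[str, DomainAnnotation], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "domain_id": d, "start": s, "end": e, "is_duf": int(f)}
        for pid, ann in sorted(domains.items())
        for d, s, e, f in ann.intervals
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_id", "start", "end", "is_duf"]).to_csv(
        path, sep="\t", index=False
    )


def read_ontology_edges(path: str | Path) -> dict[str, set[str]]:
    """Compound-ontology edge TSV: child, parent (one edge per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child", "parent"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    edges: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        edges.setdefault(row.child, set()).add(row.parent)
    return edges


def write_ontology_edges(edges: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"child": c, "parent": p} for c in sorted(edges) for p in sorted(edges[c])
    ]
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# similarity matrices

def read_similarity_matrix(
    path: str | Path, species: str, pocket_ids: list[str] | None = None
) -> SimilarityMatrix:
    """Read sparse triplets ``pocket_i<TAB>pocket_j<TAB>score``.

    ``pocket_ids`` supplies the full node universe (needed because pockets
    with no alignment partner — singletons — never appear in the triplets);
    without it the universe is the set of ids seen in the file.  A duplicated
    (i, j) pair is an error.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"pocket_i": str, "pocket_j": str}, float_precision="round_trip"
    )
    for col in ("pocket_i", "pocket_j", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if pocket_ids is None:
        pocket_ids = sorted(set(df["pocket_i"]) | set(df["pocket_j"]))
    index = {pid: k for k, pid in enumerate(pocket_ids)}
    seen: set[tuple[int, int]] = set()
    rows, cols, vals = [], [], []
    for r in df.itertuples(index=False):
        try:
            i, j = index[r.pocket_i], index[r.pocket_j]
        except KeyError as exc:
            raise FormatError(f"{path}: pocket id {exc} not in the supplied universe")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise FormatError(f"{path}: duplicate triplet for pair ({r.pocket_i}, {r.pocket_j})")
        seen.add(key)
        rows.append(i)
        cols.append(j)
        vals.append(float(r.score))
    import scipy.sparse as sp

    n = len(pocket_ids)
    scores = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return SimilarityMatrix(species=species, pocket_ids=list(pocket_ids), scores=scores)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(
        sim.triplets(), columns=["pocket_i", "pocket_j", "score"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# embeddings

def read_embeddings(vectors_path: str | Path, labels_path: str | Path) -> EmbeddingSet:
    """Read a dense pocket x 128 matrix TSV plus an aligned labels TSV."""
    vec = pd.read_csv(
        vectors_path, sep="\t", index_col="pocket_id", float_precision="round_trip"
    )
    if vec.shape[1] != EmbeddingSet.DIM:
        raise FormatError(
            f"{vectors_path}: expected {EmbeddingSet.DIM} vector columns, got {vec.shape[1]}"
        )
    labels = pd.read_csv(labels_path, sep="\t", index_col="pocket_id", dtype=str)
    labels = labels.reindex(vec.index)
    if labels.isna().all(axis=1).any():
        raise FormatError(f"{labels_path}: labels missing for some pocket ids")
    return EmbeddingSet(
        pocket_ids=list(vec.index), vectors=vec.to_numpy(dtype=float), labels=labels
    )


def write_embeddings(emb: EmbeddingSet, vectors_path: str | Path, labels_path: str | Path) -> None:
    cols = [f"v{k:03d}" for k in range(EmbeddingSet.DIM)]
    pd.DataFrame(emb.vectors, index=pd.Index(emb.pocket_ids, name="pocket_id"), columns=cols).to_csv(
        vectors_path, sep="\t"
    )
    emb.labels.rename_axis("pocket_id").to_csv(labels_path, sep="\t")
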