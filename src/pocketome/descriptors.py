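"""Physicochemical and confidence descriptors of a binding pocket.

Five descriptors per pocket, plus the residue count:

* hydrophobicity — grand average of hydropathy (GRAVY): the mean
  Kyte–Doolittle scale value over the lining residues;
* aromaticity — relative frequency of Phe, Trp, Tyr among the lining
  residues;
* net charge — Asp/Glu −1, Lys/Arg +1, His +0.5 (pH 7 heuristic), others 0;
* relative SASA — Shrake–Rupley solvent-accessible surface area of the
  lining residues (computed in whole-protein context), divided by the sum
  of the theoretical maximum ASA values (Tien et al. 2013) of those
  residues' types;
* mean pLDDT and mean PAE — structure-confidence means from the filters
  module.

Hydrophobicity, aromaticity and net charge depend only on the residue-type
multiset and are therefore permutation invariant; net charge is additive
over disjoint multisets.  SASA is made exactly invariant to rigid motion by
canonicalizing the pose (centroid plus principal axes with a third-moment
sign convention) before sphere-point sampling; see docs/methods.md.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .filters import pocket_mean_pae, pocket_mean_plddt
from .model import AMINO_ACIDS, PocketRecord, ProteinRecord

# Theoretical maximum accessible surface area per residue type, Å²
# (Tien et al. 2013, "theoretical" column).
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

AROMATIC = frozenset("FWY")

RESIDUE_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
RESIDUE_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5})


def _check_residues(residue_types: Iterable[str]) -> list[str]:
    types = list(residue_types)
    if not types:
        raise ValueError("empty residue multiset")
    unknown = sorted({t for t in types if t not in MAX_ASA_THEORETICAL})
    if unknown:
        raise ValueError(f"unknown residue code(s): {unknown}")
    return types


def hydrophobicity(residue_types: Iterable[str]) -> float:
    """Mean Kyte–Doolittle hydropathy over the residue multiset (GRAVY)."""
    types = _check_residues(residue_types)
    return float(np.mean([KYTE_DOOLITTLE[t] for t in types]))


def aromaticity(residue_types: Iterable[str]) -> float:
    """Fraction of aromatic residues (F, W, Y) in the multiset."""
    types = _check_residues(residue_types)
    return sum(t in AROMATIC for t in types) / len(types)


def net_charge(residue_types: Iterable[str]) -> float:
    """Sum of per-residue charges at pH 7 (His counted as +0.5)."""
    types = _check_residues(residue_types)
    return float(sum(RESIDUE_CHARGE[t] for t in types))


def canonical_pose(coords: np.ndarray) -> np.ndarray:
    """Map coordinates to a canonical rigid-motion-invariant frame.

    Centers on the centroid and rotates onto the principal axes of the
    coordinate covariance; each axis sign is fixed by requiring a
    nonnegative third moment of the projections.  Any proper rotation or
    translation of the input yields identical output (up to floating-point
    error); near-symmetric point sets with degenerate axes are outside the
    guarantee.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvecs = eigvecs[:, ::-1]  # descending variance
    proj = centered @ eigvecs
    skew = (proj**3).sum(axis=0)
    signs = np.where(skew < 0, -1.0, 1.0)
    return proj * signs


def residue_sasa(
    protein: ProteinRecord, probe_radius: float = 1.4, point_number: int = 960
) -> dict[int, float]:
    """Shrake–Rupley SASA per residue index, whole-protein context."""
    atoms = protein.atoms
    if atoms is None:
        raise ValueError(f"{protein.protein_id}: no all-atom coordinates available")
    atoms = atoms.copy()
    atoms.coord = canonical_pose(atoms.coord)
    per_atom = struc.sasa(
        atoms, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
    )
    out: dict[int, float] = {}
    for res_id in np.unique(atoms.res_id):
        out[int(res_id)] = float(np.nansum(per_atom[atoms.res_id == res_id]))
    return out


def relative_sasa(
    pocket: PocketRecord,
    protein: ProteinRecord,
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> float:
    """Pocket SASA divided by the summed theoretical maximum ASA.

    Σ(per-residue SASA over pocket residues) / Σ(max ASA of their types);
    a single ratio per pocket, not the mean of per-residue ratios.
    """
    per_res = residue_sasa(protein, probe_radius=probe_radius, point_number=point_number)
    total_sasa = 0.0
    total_max = 0.0
    missing = []
    for ref in sorted(pocket.residues):
        if ref.index not in per_res:
            missing.append(str(ref))
            continue
        total_sasa += per_res[ref.index]
        total_max += MAX_ASA_THEORETICAL[protein.sequence[ref.index - 1]]
    if missing:
        raise ValueError(f"{pocket.pocket_id}: no atoms for residue(s) {missing}")
    return total_sasa / total_max


@dataclass
class PocketDescriptors:
    pocket_id: str
    hydrophobicity: float
    aromaticity: float
    net_charge: float
    rel_sasa: float | None
    mean_plddt: float
    mean_pae: float | None
    n_residues: int


def pocket_residue_types(pocket: PocketRecord, protein: ProteinRecord) -> list[str]:
    return [protein.sequence[r.index - 1] for r in sorted(pocket.residues)]


def compute_all(
    pockets: list[PocketRecord],
    proteins: dict[str, ProteinRecord],
    with_sasa: bool = True,
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> pd.DataFrame:
    """Descriptor table, one row per pocket, indexed by pocket_id."""
    sasa_cache: dict[str, dict[int, float]] = {}
    rows = []
    for pocket in pockets:
        protein = proteins[pocket.protein_id]
        types = pocket_residue_types(pocket, protein)
        rel = None
        if with_sasa and protein.atoms is not None:
            if pocket.protein_id not in sasa_cache:
                sasa_cache[pocket.protein_id] = residue_sasa(
                    protein, probe_radius=probe_radius, point_number=point_number
                )
            per_res = sasa_cache[pocket.protein_id]
            total = sum(per_res[r.index] for r in pocket.residues)
            denom = sum(MAX_ASA_THEORETICAL[t] for t in types)
            rel = total / denom
        rows.append(
            PocketDescriptors(
                pocket_id=pocket.pocket_id,
                hydrophobicity=hydrophobicity(types),
                aromaticity=aromaticity(types),
                net_charge=net_charge(types),
                rel_sasa=rel,
                mean_plddt=pocket_mean_plddt(pocket, protein),
                mean_pae=pocket_mean_pae(pocket, protein) if protein.pae is not None else None,
                n_residues=len(pocket.residues),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows])
    return df.set_index("pocket_id") if len(df) else df
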