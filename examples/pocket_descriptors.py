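"""Physicochemical descriptors of binding pockets.

Computes, for each pocket of a synthetic protein, the Kyte-Doolittle
hydrophobicity (GRAVY), aromatic-residue fraction, net charge at pH 7
(His = +0.5), relative solvent-accessible surface area (Shrake-Rupley SASA
normalized by theoretical maximum ASA), and the structure-confidence means
(pLDDT over residues, PAE over all residue pairs).
"""

from pocketome.descriptors import compute_all
from pocketome.synthetic import SyntheticConfig, generate_pockets_and_sites, generate_proteome

cfg = SyntheticConfig(seed=7, proteins_per_species=4, mean_protein_length=120)
proteome = generate_proteome(cfg, "DEMO1")
pockets, _ = generate_pockets_and_sites(cfg, proteome)
table = compute_all(pockets, {p.protein_id: p for p in proteome})

print(table.round(3).to_string())
print(
    "\nGRAVY > 0 marks hydrophobic pockets; rel_sasa near 0 means buried,"
    "\nnear 1 fully exposed; mean_pae is in Angstroms (lower = more confident)."
)
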