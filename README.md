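# pocketome

Cross-species analysis of predicted protein binding-pocket repertoires
("pocketomes"): the complete sets of compound-binding sites detected on a
species' predicted protein structures.

The package is aimed at structural bioinformaticians who consume the outputs
of upstream tools — ligandability predictors (P2Rank-style pocket tables),
predicted structures with per-residue confidence (pLDDT in the B-factor
column) and pairwise aligned-error (PAE) matrices, pocket-alignment score
matrices (ProBiS-style), fold-cluster assignments (FoldSeek-style), and
128-dimensional pocket embeddings (DeeplyTough-style) — and want a tested,
reproducible analysis chain on top of them:

* **Confidence filtering** — exclude fragments, proteins under 100 residues,
  and poor membrane models; keep pockets with probability ≥ 0.5, mean pocket
  pLDDT ≥ 70, and mean pocket PAE ≤ 10 Å.
* **Descriptors** — Kyte–Doolittle hydrophobicity (GRAVY), aromatic fraction,
  net charge at pH 7 (His = +0.5), relative Shrake–Rupley SASA normalized by
  theoretical maximum ASA, and the confidence means.
* **Known-site annotation and enrichment** — split inter-chain sites by Cα
  connected components (12 Å), mark a known site "found" when it shares any
  residue with a predicted pocket, map ligands to compound classes by
  recursive ChEBI ancestor search, and test per-class enrichment with
  Fisher's exact test (sample odds ratio) under Benjamini–Yekutieli FDR.
* **Similarity-graph clustering** — per species, normalize alignment scores
  by the species maximum, set edges where the normalized score exceeds 0.1,
  detect communities with Leiden (CPM, resolution 0.01), track singletons
  (pockets with no alignment at all), and compare against degree-preserving
  rewiring, matched-density random graphs, and score-permutation nulls.
* **Scaling law** — fit ln *N*<sub>p</sub> = ln *c* + *a* ln *N*<sub>FS</sub>,
  where *N*<sub>p</sub> is the number of unique pockets (communities +
  singletons) and *N*<sub>FS</sub> the number of fold clusters; *a* < 1 is
  sub-linear growth of pocket diversity with fold diversity.
* **Entropy maps** — project embeddings to 2D (tSNE/UMAP/PCA/ICA) and compute
  the per-bin label entropy *S* = −Σ *p*<sub>i</sub> ln *p*<sub>i</sub> of the
  kingdom or species distribution, masking bins with fewer than 20 pockets.

A first-class synthetic-data module generates every input format with
plantable statistical structure (community sizes, singleton share, scaling
exponent, enrichment odds, label mixtures), so the entire chain is testable
without any external download.

## Worked example

Enrichment of ligand classes among known sites recovered by the pocket
predictor, recomputed from the bundled survey counts
(`python examples/enrichment_analysis.py`):

```
class                                       found  missed      OR       p_adj
Nucleobases, nucleosides & nucleotides       8092    2244    8.55           0
Inorganic ions                               1191    7265    0.05           0
Other compounds                              1114     296    3.72    6.2e-102
Carbohydrates & derivatives                   548     103    5.08    4.14e-67
...
11662 of 22371 unique sites found (52.1%)
```

Nucleotide-binding sites are recovered 8.55 times more often (odds) than all
other classes combined; inorganic-ion sites — typically a few residues with
little cavity geometry — are recovered far less often (OR 0.05).

Scaling-law recovery on a synthetic eleven-species ensemble with a planted
sub-linear exponent (`python examples/scaling_exponent.py`):

```
planted exponent: 0.5
fitted exponent:  0.577  (intercept 0.647, Pearson r 0.968, 11 species)
degree-preserving null exponent: 1.202 +/- 0.006 (s.d., 3 runs)
```

The fit recovers the planted exponent up to the configured 10% count noise of
this single replicate, and the degree-preserving null — same degree sequence,
community structure randomized away — sits far above it, near linearity: the
signature of pocket-community reuse.

The other scripts in `examples/` demonstrate filtering, descriptors,
clustering with null models, and entropy maps, each printing a few annotated
numbers. A thin CLI wraps the same library:

```bash
pocketome synth --outdir demo_tree --seed 1   # write a synthetic input tree
pocketome run --input-dir demo_tree --outdir demo_out --seed 1
```

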