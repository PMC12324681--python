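# Methods

This note documents the models, conventions, and numerical choices behind
the package, the conditions its synthetic-data generators emulate, and the
limitations of both.

## Coordinates and identifiers

Residues are identified as (chain, index) pairs with 1-based indices and
inclusive intervals (the UniProt convention). Pocket/known-site overlap is
computed on these pairs; any shared residue marks a known site as "found".
Structure numbering is assumed to coincide with annotation numbering, which
holds for database monomer models. The pocket-table dialect is pinned to the
columns `name, rank, probability, residue_ids`; extra columns are ignored.
PAE matrices are stored as given and never symmetrized (aligned error is
directional).

## Filtering

Protein-level rules: fragments excluded; length < 100 residues excluded
(short chains are systematically under-predicted by ligandability tools);
membrane models passing fewer than 6 of the 6 database quality checks
excluded. Pocket-level rules: probability ≥ 0.5 (inclusive), mean pocket
pLDDT < 70 excluded, mean pocket PAE > 10 Å excluded — the exclusion
inequalities are strict as printed in the source conventions, so a pocket
sitting exactly on a boundary is kept, and this boundary behavior is
tested. The pocket PAE is the mean over *all ordered residue pairs* of the
pocket, diagonal included, on the possibly asymmetric matrix. A pocket on a
failing protein is removed regardless of its own scores.

## Descriptors

* Hydrophobicity: mean Kyte–Doolittle value (GRAVY) over the lining
  residues; the scale table is imported from biopython, and the
  implementation is cross-checked in tests against biopython's
  `ProteinAnalysis` as an independent oracle.
* Aromaticity: relative frequency of Phe/Trp/Tyr.
* Net charge: Asp/Glu −1, Lys/Arg +1, His +0.5, others 0 — a fixed pH-7
  heuristic, not a pKa model.
* Relative SASA: Shrake–Rupley (probe 1.4 Å, 960 sphere points per atom by
  default, configurable) in whole-protein context, summed over pocket
  residues, divided by the sum of the Tien et al. (2013) *theoretical*
  maximum ASA values of those residue types. Sum-over-sum, giving a single
  ratio per pocket, not a mean of per-residue ratios. Whole-protein context
  is used because computing SASA on an isolated pocket would inflate
  accessibility at the cut surfaces.
* Nonstandard residue codes are an error, never silently skipped.

**Rotation invariance.** Sphere-point SASA with a fixed global point
template is only quadrature-level invariant under rotation (~1% at 960
points). The implementation therefore canonicalizes the pose first:
coordinates are centered and rotated onto the principal axes of their
covariance, with each axis sign fixed by a nonnegative third moment of the
projections. Any proper rigid motion of the input then yields the same
canonical coordinates, making the descriptor exactly rotation/translation
invariant (tested at 1e-6 relative). The trade-offs: near-degenerate
principal axes (highly symmetric point sets) void the guarantee, and adding
even a distant, non-occluding atom shifts the canonical pose slightly, so
"locality" holds only to quadrature accuracy (~1%), which is how it is
tested.

## Annotation and enrichment

Inter-chain sites are split on the Cα–Cα distance graph with a 12 Å
threshold (inclusive — the boundary convention is fixed and documented
here), using connected components; components with fewer than 4 residues
are dropped. Compound classes are assigned by transitive ascent of
child→parent ontology edges to a fixed set of 12 named class roots; an id
reaching no root falls back to "Other compounds"; cycles are an error. A
ligand may reach several class roots and is counted in each.

Enrichment uses, per class, the 2×2 table [[a, b], [F−a, NF−b]] where a/b
are the class's found/not-found counts and F/NF the *unique-site* totals
(each site counted once however many classes its ligand maps to). The
reported odds ratio is the sample (cross-product) odds ratio
(a/b)/((F−a)/(NF−b)) — not the conditional MLE — because that is the
estimator consistent with the published per-class values; p-values are
two-sided Fisher exact, corrected with Benjamini–Yekutieli (valid under
arbitrary dependence). One published value is knowingly not reproduced: the
glycan odds ratio is printed as 8.52 in the source table, but the formula
that reproduces every other row yields 16.86 for counts 73/4 with the same
totals; the package implements the consistent formula and does not assert
that row.

Group contrasts (singletons vs non-singletons) report Welch's t-test —
chosen over Student's because equal variances are not guaranteed and the
variant is otherwise unstated — and Cohen's d with the pooled standard
deviation. For degenerate constant groups, d is 0 when the means agree and
signed infinity otherwise.

## Graphs, communities, nulls

Per species, raw alignment scores are normalized by the species maximum;
the unweighted graph keeps an edge where the normalized score is strictly
greater than 0.1. Singletons are defined on *raw* scores (no alignment to
any other pocket), before normalization or thresholding; nodes isolated by
the threshold, and size-1 clusters emitted by the partitioner, are counted
with the singletons in the unique-pocket total but tracked under separate
labels, since the published accounting does not distinguish them.

Leiden uses the CPM objective at resolution 0.01 by default (the cited
clustering function's default objective), seed-pinned, with modularity
selectable. The degree-preserving null uses double-edge swaps with a
default budget of 10·|E| swap attempts: a literal 10 attempts cannot mix a
graph of this size, so the default favors a well-mixed null while the
literal setting remains selectable via `n_swaps`. Graphs with no valid swap
are returned unchanged. The other nulls are a uniform random graph with
matched node/edge counts and a symmetric permutation of the off-diagonal
score multiset.

The community-size-distribution slope is fit on logarithmically binned
histograms (density per bin, geometric bin centers); raw per-size
frequencies bias the slope severely because large sizes are each observed
once.

## Scaling law

Ordinary least squares of ln(unique pockets) on ln(fold clusters), natural
logarithms throughout; the intercept is reported on the ln scale (the
published intercept/slope pair is only consistent with natural logs — in
base 10 the implied magnitudes are impossible). Fold-cluster counts are an
input, never computed (fold clustering is an external tool's job). Null
exponents re-cluster every species' randomized graph and refit; at least
two replicates are required so a standard deviation exists.

## Synthetic data

All generators are pure functions of (config, seed); per-generator streams
are derived from the master seed with fixed offsets. Defaults encode the
study conditions: pocket-size median 24 and known-site median 6 residues,
found fraction 52.1%, class sampling weights proportional to the surveyed
class totals, pLDDT from a Beta(8, 2) scaled to [0, 100], PAE growing with
sequence separation.

* Proteins are 3.8 Å-step self-avoiding-ish random walks with a five-atom
  pseudo-backbone per residue — geometry sufficient for SASA and distance
  computations, not a physical fold.
* Pockets are spatial balls (the k residues nearest a seed residue), not
  sequence windows. Found sites share ≥ 1 residue with a pocket; not-found
  sites are placed strictly outside all pockets of their protein, so the
  planted recovery rate is exact in expectation. Per-class found odds are
  planted as odds-ratio multiples of the baseline found odds.
* The similarity ensemble plants N_unique = round(c · N_FS^a) unique
  pockets per species with total pockets linear in N_FS, power-law-shaped
  community sizes (scaled to the exact clustered-pocket budget), fully
  intra-community edges at a configurable density (0.35) with a connected
  backbone, and no inter-community edges — so Leiden recovery of the
  planted partition is exact and the planted exponent is identifiable. The
  singleton fraction is the singleton share of *unique* pockets: a constant
  share of all pockets is jointly infeasible with sub-linear unique counts
  (singletons would outgrow the unique total), and the chosen semantics
  reproduces the empirical pattern of singleton fractions declining with
  proteome size. `singleton_fraction=1` is the degenerate all-singleton
  case. Infeasible parameter combinations raise errors rather than being
  silently repaired.
* Embeddings are 128-d Gaussian mixtures; each kingdom's component mean is
  `separation ×` a kingdom-specific random unit vector, so separation 0
  yields one shared component (no kingdom signal) and large separations
  fully segregate kingdoms.

What passing tests on these fixtures do **not** show: robustness to
alignment-score noise between communities (the generator plants none),
realistic pocket geometry or fold structure, or annotation noise in real
databases.

## Pipeline

Stages run in a fixed order over a documented input tree; inputs are
validated before any computation, every stage writes a TSV plus a count
log, and a summary JSON collects the accounting. Identical configuration
and seed give byte-identical outputs; for that reason the pipeline's
default projection is PCA (deterministic), with tSNE under the pinned
defaults (perplexity 50, 5000 iterations, random init, auto learning rate)
selectable in the config. UMAP defaults to 50 neighbors with min_dist 0.

## Problem sizes

The test-suite and acceptance-script ensembles use 11 species with
fold-cluster counts log-spaced over 80–800 (recovery) and 60–600 (null
ordering), 50–100 replicate ensembles for exponent recovery, and 12–20
degree-preserving null runs — sizes at which the planted exponent is
recovered to ±0.05 and the null ordering is unambiguous, while a full run
stays in the minutes range on one core.

## Known limitations

* The exact published exponents (0.398 actual, 0.882 degree-preserving
  null) require the original full-scale similarity matrices and per-species
  fold-cluster counts, which are not printed in any table the package
  bundles; the package reproduces the *ordering* and the exact refit of the
  published regression line instead.
* SASA canonicalization fails for pathologically symmetric coordinate sets.
* The enrichment module assumes unique-site totals are supplied or derived
  from unique sites; it does not deduplicate sites itself beyond site ids.
* Inter-species pocket alignment is out of scope (consumed, never
  computed), as are the upstream predictors themselves.
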