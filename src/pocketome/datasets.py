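"""Bundled summary tables from the eleven-species pocketome survey.

Three small plain-text tables ship with the package:

* per-species counts of predicted structures, known sites, and predicted
  pockets that survived the probability cut,
* per-compound-class counts of known sites recovered ("found") or missed
  ("not found") by the pocket predictor, together with the ChEBI class roots
  defining each compound class,
* per-species clustering statistics (communities, singletons, largest
  community) from the within-species similarity-graph analysis.

They serve as published inputs: enrichment statistics, correlations, and
fraction summaries can be recomputed from them without any raw data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import CompoundOntology

# Unique known sites classified as found / not found across all species.
# The per-class found counts sum to slightly more than the found total
# because a ligand may belong to more than one compound class.
TOTAL_FOUND = 11_662
TOTAL_NOT_FOUND = 10_709


def _read(name: str) -> pd.DataFrame:
    with resources.files("pocketome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def species_summary() -> pd.DataFrame:
    """Per-species structure/pocket counts, indexed by species mnemonic."""
    return _read("species_pocket_counts.tsv").set_index("species")


def compound_class_counts() -> pd.DataFrame:
    """Per-class found/not-found counts of unique known sites."""
    df = _read("compound_class_counts.tsv")
    df["chebi_roots"] = df["chebi_roots"].fillna("").map(
        lambda s: frozenset(s.split(",")) if s else frozenset()
    )
    return df.set_index("class_name")


def clustering_summary() -> pd.DataFrame:
    """Per-species community/singleton counts, indexed by species mnemonic."""
    return _read("clustering_stats.tsv").set_index("species")


def compound_class_roots() -> list[tuple[str, frozenset[str]]]:
    """Ordered (class name, ChEBI root id set) pairs for classes with roots.

    'Other compounds' has no roots (it is the fallback class) and is omitted.
    """
    df = compound_class_counts()
    return [
        (name, roots)
        for name, roots in df["chebi_roots"].items()
        if roots
    ]


def default_ontology(edges: dict[str, set[str]] | None = None) -> CompoundOntology:
    """A CompoundOntology carrying the bundled class roots.

    With no ``edges`` the ontology can classify only ids that are themselves
    class roots; supply an edge map (e.g. from :func:`pocketome.io.read_ontology`)
    for real ancestor traversal.
    """
    return CompoundOntology(edges=edges or {}, class_roots=compound_class_roots())
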