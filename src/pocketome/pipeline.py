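"""End-to-end orchestration over a directory tree of pipeline inputs.

The expected input layout is the one :func:`pocketome.synthetic.write_fixture_tree`
writes (and which mirrors the upstream tools' outputs):

    structures/<species>/<protein>.pdb     per-residue confidence in B-factor
    pae/<protein>.json                     pairwise aligned-error matrices
    pockets/<protein>.csv                  pocket prediction tables
    annotations.tsv                        known binding sites
    ontology_edges.tsv                     compound-ontology child->parent edges
    fold_clusters.tsv                      protein -> fold cluster
    domains.tsv                            domain intervals (optional)
    similarity/<species>.tsv (+ .nodes.tsv)  pairwise alignment scores
    embeddings.tsv, embedding_labels.tsv   pocket embedding matrix + labels

Stages run in a fixed order (load, filter, annotate/enrich, descriptors,
cluster, scaling, embedding/entropy); every stage writes a TSV and logs its
record counts, and a summary JSON collects the per-stage accounting.  All
randomness flows from the single configured seed, so identical
configurations produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import descriptors as desc
from . import embedding as emb
from . import filters as flt
from . import graph as gr
from . import io as pio
from . import scaling as sc
from .datasets import default_ontology
from .model import CompoundOntology, ProteinRecord

log = logging.getLogger("pocketome.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    filters: flt.FilterConfig = field(default_factory=flt.FilterConfig)
    edge_threshold: float = 0.1
    leiden_resolution: float = 0.01
    null_kind: str = "degree_preserving"
    null_replicates: int = 0  # 0 disables the null-model pass
    projection_method: str = "pca"
    projection_params: dict = field(default_factory=dict)
    entropy_bins: int = 50
    entropy_min_count: int = 20
    sasa_point_number: int = 960

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = flt.FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filt, **raw)


REQUIRED_INPUTS = (
    "structures",
    "pae",
    "pockets",
    "annotations.tsv",
    "fold_clusters.tsv",
    "similarity",
    "embeddings.tsv",
    "embedding_labels.tsv",
)


@dataclass
class PipelineInputs:
    proteins: dict[str, ProteinRecord]
    pockets: list
    sites: list
    ontology: CompoundOntology
    domains: dict
    similarities: list
    embeddings: object


def validate_inputs(input_dir: str | Path) -> Path:
    root = Path(input_dir)
    missing = [name for name in REQUIRED_INPUTS if not (root / name).exists()]
    if missing:
        raise PipelineError("validate", f"missing input path(s): {missing} under {root}")
    return root


def load_inputs(input_dir: str | Path) -> PipelineInputs:
    root = validate_inputs(input_dir)
    fold_clusters = pio.read_fold_clusters(root / "fold_clusters.tsv")
    proteins: dict[str, ProteinRecord] = {}
    pockets = []
    for species_dir in sorted((root / "structures").iterdir()):
        if not species_dir.is_dir():
            continue
        for pdb_path in sorted(species_dir.glob("*.pdb")):
            pid = pdb_path.stem
            seq, ca, plddt = pio.read_structure_confidence(pdb_path)
            pae_path = root / "pae" / f"{pid}.json"
            pae = pio.read_pae_json(pae_path) if pae_path.exists() else None
            proteins[pid] = ProteinRecord(
                protein_id=pid,
                species=species_dir.name,
                sequence=seq,
                ca_coords=ca,
                plddt=plddt,
                pae=pae,
                atoms=pio.read_structure(pdb_path),
                fold_cluster=fold_clusters.get(pid),
            )
            pocket_path = root / "pockets" / f"{pid}.csv"
            if pocket_path.exists():
                pockets.extend(pio.read_p2rank_table(pocket_path, protein_id=pid))
    sites = pio.read_annotation_table(root / "annotations.tsv")
    edges_path = root / "ontology_edges.tsv"
    ontology = default_ontology(
        pio.read_ontology_edges(edges_path) if edges_path.exists() else None
    )
    domains_path = root / "domains.tsv"
    domains = pio.read_domains(domains_path) if domains_path.exists() else {}
    similarities = []
    for sim_path in sorted((root / "similarity").glob("*.tsv")):
        if sim_path.name.endswith(".nodes.tsv"):
            continue
        species = sim_path.stem
        nodes_path = sim_path.with_name(f"{species}.nodes.tsv")
        node_ids = None
        if nodes_path.exists():
            node_ids = [l for l in nodes_path.read_text().splitlines()[1:] if l]
        similarities.append(pio.read_similarity_matrix(sim_path, species, node_ids))
    embeddings = pio.read_embeddings(root / "embeddings.tsv", root / "embedding_labels.tsv")
    return PipelineInputs(
        proteins=proteins,
        pockets=pockets,
        sites=sites,
        ontology=ontology,
        domains=domains,
        similarities=similarities,
        embeddings=embeddings,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write per-stage outputs, and return the summary."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}}

    def record(stage: str, **counts) -> None:
        summary["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    inputs = load_inputs(cfg.input_dir)
    record(
        "load",
        proteins=len(inputs.proteins),
        pockets=len(inputs.pockets),
        known_sites=len(inputs.sites),
        species=len(inputs.similarities),
    )

    # ---- filter ----------------------------------------------------------
    try:
        kept, filter_summary = flt.filter_cohort(inputs.pockets, inputs.proteins, cfg.filters)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("filter", str(exc)) from exc
    pd.DataFrame(
        [
            {"level": level, "reason": reason, "count": count}
            for level, counter in (
                ("protein", filter_summary.protein_reasons),
                ("pocket", filter_summary.pocket_reasons),
            )
            for reason, count in sorted(counter.items())
        ]
    ).to_csv(outdir / "filter_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "pocket_id": p.pocket_id,
                "protein_id": p.protein_id,
                "rank": p.rank,
                "probability": p.probability,
                "n_residues": len(p.residues),
            }
            for p in kept
        ]
    ).to_csv(outdir / "filtered_pockets.tsv", sep="\t", index=False)
    record("filter", pockets_in=len(inputs.pockets), pockets_out=len(kept))

    # ---- split / match / enrich -----------------------------------------
    try:
        split_sites = []
        for site in inputs.sites:
            protein = inputs.proteins.get(site.protein_id)
            if protein is None:
                continue
            split_sites.extend(
                ann.split_interchain_site(
                    site,
                    {"A": protein.ca_coords},
                    min_residues=cfg.filters.min_known_site_residues,
                )
            )
        matches = ann.match_known_to_predicted(split_sites, kept)
        found_flags = {sid: m.found for sid, m in matches.items()}
        class_counts, total_found, total_not_found = ann.class_counts_from_sites(
            split_sites, found_flags, inputs.ontology
        )
        enrichment = (
            ann.enrichment_table(class_counts, total_found, total_not_found)
            if total_found and total_not_found
            else []
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
    pd.DataFrame([vars(r) for r in enrichment]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False
    )
    record(
        "enrich",
        sites_in=len(inputs.sites),
        sites_after_split=len(split_sites),
        found=total_found,
        not_found=total_not_found,
        found_fraction=round(total_found / max(1, total_found + total_not_found), 4),
    )

    # ---- descriptors -----------------------------------------------------
    try:
        table = desc.compute_all(
            kept, inputs.proteins, point_number=cfg.sasa_point_number
        )
    except Exception as exc:
        raise PipelineError("descriptors", str(exc)) from exc
    table.to_csv(outdir / "descriptors.tsv", sep="\t")
    domain_rows = [
        {"pocket_id": p.pocket_id, "category": cat, "domains": ";".join(sorted(doms))}
        for p in kept
        for cat, doms in [ann.classify_pocket_domains(p, inputs.domains.get(p.protein_id))]
    ]
    pd.DataFrame(domain_rows).to_csv(outdir / "pocket_domains.tsv", sep="\t", index=False)
    record("descriptors", pockets_in=len(kept), rows=len(table))

    # ---- graph / cluster -------------------------------------------------
    try:
        results = [
            gr.cluster_similarity(
                sim,
                edge_threshold=cfg.edge_threshold,
                resolution=cfg.leiden_resolution,
                seed=cfg.seed,
            )
            for sim in inputs.similarities
        ]
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    cluster_df = pd.DataFrame(
        [
            {
                "species": r.species,
                "n_communities": r.n_communities,
                "n_singletons": r.n_singletons,
                "singleton_fraction": round(r.singleton_fraction(), 2),
                "largest_community": r.largest_community,
                "n_unique": r.n_unique,
                "n_pockets": r.n_pockets,
            }
            for r in results
        ]
    )
    cluster_df.to_csv(outdir / "clustering.tsv", sep="\t", index=False)
    record("cluster", species=len(results), communities=int(cluster_df["n_communities"].sum()))

    # ---- scaling ---------------------------------------------------------
    scaling_out: dict = {}
    n_fs = {
        sim.species: len(
            {
                p.fold_cluster
                for p in inputs.proteins.values()
                if p.species == sim.species and p.fold_cluster
            }
        )
        for sim in inputs.similarities
    }
    usable = [r for r in results if n_fs.get(r.species) and r.n_unique > 0]
    if len(usable) >= 3:
        try:
            fit = sc.fit_power_law(sc.stats_from_clusterings(usable, n_fs))
            scaling_out = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "pearson_r": fit.pearson_r,
                "n_points": fit.n_points,
            }
            if cfg.null_replicates >= 2:
                mean, sd, slopes = sc.null_scaling(
                    [s for s in inputs.similarities if s.species in n_fs],
                    n_fs,
                    null_kind=cfg.null_kind,
                    n_replicates=cfg.null_replicates,
                    seed=cfg.seed,
                    edge_threshold=cfg.edge_threshold,
                    resolution=cfg.leiden_resolution,
                )
                scaling_out["null"] = {"kind": cfg.null_kind, "mean": mean, "sd": sd}
        except Exception as exc:
            raise PipelineError("scaling", str(exc)) from exc
    with open(outdir / "scaling.json", "w") as fh:
        json.dump(scaling_out, fh, indent=2)
    record("scaling", points=len(usable), **{k: v for k, v in scaling_out.items() if k == "slope"})

    # ---- embedding / entropy --------------------------------------------
    try:
        proj = emb.project(
            inputs.embeddings,
            method=cfg.projection_method,
            params=cfg.projection_params,
            seed=cfg.seed,
        )
        grid = emb.binned_entropy(
            proj,
            inputs.embeddings.labels["kingdom"].to_numpy(),
            n_bins_x=cfg.entropy_bins,
            n_bins_y=cfg.entropy_bins,
            min_count=cfg.entropy_min_count,
        )
    except Exception as exc:
        raise PipelineError("embed", str(exc)) from exc
    pd.DataFrame(
        {
            "pocket_id": inputs.embeddings.pocket_ids,
            "x": proj.coords[:, 0],
            "y": proj.coords[:, 1],
        }
    ).to_csv(outdir / "projection.tsv", sep="\t", index=False)
    ii, jj = np.nonzero(~np.isnan(grid.entropy))
    pd.DataFrame(
        {
            "bin_x": ii,
            "bin_y": jj,
            "count": grid.counts[ii, jj],
            "entropy": grid.entropy[ii, jj],
        }
    ).to_csv(outdir / "entropy.tsv", sep="\t", index=False)
    record(
        "embed",
        pockets=inputs.embeddings.n_pockets,
        occupied_bins=int((grid.counts > 0).sum()),
        unmasked_bins=int((~np.isnan(grid.entropy)).sum()),
    )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
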