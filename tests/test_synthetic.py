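"""The generators are deterministic, honor their contracts, and plant
recoverable statistical structure."""

import numpy as np
import pytest

from pocketome import graph as gr
from pocketome.annotation import (
    assign_compound_class,
    class_counts_from_sites,
    match_known_to_predicted,
    sample_odds_ratio,
)
from pocketome.model import SimilarityMatrix
from pocketome.synthetic import (
    SyntheticConfig,
    generate_embeddings,
    generate_ontology,
    generate_pockets_and_sites,
    generate_proteome,
    generate_similarity_ensemble,
    planted_partition_matrix,
)


class TestProteome:
    def test_shape_contract_single_protein(self):
        cfg = SyntheticConfig(seed=1, proteins_per_species=1, mean_protein_length=100)
        (protein,) = generate_proteome(cfg, "SOLO0")
        n = len(protein)
        assert protein.pae.shape == (n, n)
        assert protein.plddt.shape == (n,)
        assert protein.ca_coords.shape == (n, 3)

    def test_same_seed_identical(self):
        cfg = SyntheticConfig(seed=7, proteins_per_species=3)
        a = generate_proteome(cfg, "SYN00")
        b = generate_proteome(cfg, "SYN00")
        for pa, pb in zip(a, b):
            assert pa.sequence == pb.sequence
            np.testing.assert_array_equal(pa.ca_coords, pb.ca_coords)
            np.testing.assert_array_equal(pa.pae, pb.pae)

    def test_species_streams_differ(self):
        cfg = SyntheticConfig(seed=7, proteins_per_species=1)
        a = generate_proteome(cfg, "SYN00")[0]
        b = generate_proteome(cfg, "SYN01")[0]
        assert a.sequence != b.sequence

    def test_plddt_mean_matches_beta_law(self):
        cfg = SyntheticConfig(
            seed=3, proteins_per_species=70, mean_protein_length=150,
            plddt_beta_params=(8.0, 2.0),
        )
        proteome = generate_proteome(cfg, "SYN00")
        values = np.concatenate([p.plddt for p in proteome])
        assert len(values) > 10_000
        assert values.mean() == pytest.approx(100 * 8 / 10, abs=2.0)

    def test_step_length_is_virtual_bond(self, proteome):
        steps = np.linalg.norm(np.diff(proteome[0].ca_coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, rtol=1e-6)


class TestPocketsAndSites:
    def test_pockets_are_spatial_balls(self, proteome, pockets_and_sites):
        pockets, _ = pockets_and_sites
        by_id = {p.protein_id: p for p in proteome}
        for pocket in pockets[:10]:
            protein = by_id[pocket.protein_id]
            idx = np.array(sorted(r.index - 1 for r in pocket.residues))
            coords = protein.ca_coords[idx]
            center = coords.mean(axis=0)
            inside_max = np.linalg.norm(coords - center, axis=1).max()
            outside = np.setdiff1d(np.arange(len(protein)), idx)
            # members are the spatially nearest residues to their seed, so no
            # outside residue can be closer to the pocket centroid than the
            # median member distance
            med = np.median(np.linalg.norm(coords - center, axis=1))
            closer = np.linalg.norm(protein.ca_coords[outside] - center, axis=1) < med
            assert closer.mean() < 0.5
            assert inside_max < 60.0

    def test_zero_found_fraction_means_no_overlap(self):
        cfg = SyntheticConfig(seed=5, proteins_per_species=10, found_fraction=0.0)
        proteome = generate_proteome(cfg, "SYN00")
        pockets, sites = generate_pockets_and_sites(cfg, proteome)
        matches = match_known_to_predicted(sites, pockets)
        assert sites and not any(m.found for m in matches.values())

    def test_null_odds_planting(self):
        # all classes at odds 1.0: realized per-class odds ratios stay near 1
        cfg = SyntheticConfig(
            seed=9, proteins_per_species=120, mean_protein_length=120,
            site_rate=8.0, found_fraction=0.5,
        )
        proteome = generate_proteome(cfg, "SYN00")
        pockets, sites = generate_pockets_and_sites(cfg, proteome)
        assert len(sites) > 800
        matches = match_known_to_predicted(sites, pockets)
        flags = {s: m.found for s, m in matches.items()}
        ontology = generate_ontology(cfg)
        counts, F, NF = class_counts_from_sites(sites, flags, ontology)
        for name, (a, b) in counts.items():
            if a + b >= 80:  # enough sites for a stable ratio
                assert 0.5 < sample_odds_ratio(a, b, F, NF) < 2.0, name

    def test_size_medians_match_planting(self, pockets_and_sites):
        pockets, sites = pockets_and_sites
        assert np.median([len(p.residues) for p in pockets]) == pytest.approx(24, abs=4)
        assert np.median([len(s.residues) for s in sites]) == pytest.approx(6, abs=2)

    def test_pocket_rate_incompatible_with_length(self):
        cfg = SyntheticConfig(
            seed=2, proteins_per_species=4, mean_protein_length=30, pocket_size_median=100
        )
        proteome = generate_proteome(cfg, "SYN00")
        with pytest.raises(ValueError, match="incompatible"):
            generate_pockets_and_sites(cfg, proteome)


class TestSimilarityEnsemble:
    def test_all_singletons_when_fraction_one(self):
        cfg = SyntheticConfig(seed=4, ensemble_species=3, fold_cluster_range=(20, 80),
                              singleton_fraction=1.0)
        sims, truths = generate_similarity_ensemble(cfg)
        for sim, truth in zip(sims, truths):
            assert sim.scores.nnz == 0
            assert truth.singletons == frozenset(sim.pocket_ids)
            assert not truth.communities

    def test_planted_partition_recovered_by_leiden(self):
        sim, truth = planted_partition_matrix("SP", [12, 9, 7, 5, 3], 4, seed=2)
        result = gr.cluster_similarity(sim, seed=0)
        assert result.n_communities == 5
        assert sorted(map(sorted, result.communities)) == sorted(
            map(sorted, truth.communities)
        )
        assert result.singletons == truth.singletons

    def test_planted_singletons_recovered_exactly(self):
        cfg = SyntheticConfig(seed=6, ensemble_species=4, fold_cluster_range=(40, 200),
                              singleton_fraction=0.4)
        sims, truths = generate_similarity_ensemble(cfg)
        for sim, truth in zip(sims, truths):
            assert gr.find_singletons(sim) == truth.singletons

    def test_unique_counts_follow_planted_power_law(self):
        cfg = SyntheticConfig(seed=8, ensemble_species=11, fold_cluster_range=(80, 800),
                              a_true=0.5)
        _, truths = generate_similarity_ensemble(cfg)
        for t in truths:
            planted = 3.0 * t.n_fs**0.5
            assert t.n_unique == pytest.approx(planted, abs=1.0)

    def test_infeasible_singleton_fraction_raises(self):
        # tiny unique budget but a huge singleton demand leaves no communities
        cfg = SyntheticConfig(seed=1, ensemble_species=2, fold_cluster_range=(8, 10),
                              scaling_coeff=0.4, a_true=0.3, singleton_fraction=0.99)
        with pytest.raises(ValueError):
            generate_similarity_ensemble(cfg)

    def test_generated_matrices_satisfy_invariants(self):
        cfg = SyntheticConfig(seed=3, ensemble_species=3, fold_cluster_range=(30, 120))
        sims, _ = generate_similarity_ensemble(cfg)
        for sim in sims:
            assert (sim.scores != sim.scores.T).nnz == 0  # symmetric
            assert (sim.scores.data > 0).all()
            # idempotent symmetric completion
            assert SimilarityMatrix(sim.species, sim.pocket_ids, sim.scores) == sim


class TestEmbeddings:
    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(seed=12)
        a = generate_embeddings(cfg, 50)
        b = generate_embeddings(cfg, 50)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_dimension_and_labels_aligned(self):
        emb = generate_embeddings(SyntheticConfig(seed=1), 30)
        assert emb.vectors.shape == (30, 128)
        assert list(emb.labels.index) == emb.pocket_ids
        assert set(emb.labels.columns) >= {"species", "kingdom"}

    def test_segregated_kingdoms_have_distant_means(self):
        mixture = {k: (40.0, 1.0) for k in ("Bacteria", "Fungi", "Plantae", "Animalia")}
        cfg = SyntheticConfig(seed=2, n_species=4, kingdom_mixture=mixture)
        emb = generate_embeddings(cfg, 200)
        means = {
            k: emb.vectors[(emb.labels["kingdom"] == k).to_numpy()].mean(axis=0)
            for k in set(emb.labels["kingdom"])
        }
        keys = list(means)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                assert np.linalg.norm(means[keys[i]] - means[keys[j]]) > 20.0
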