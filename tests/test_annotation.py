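"""Site splitting, overlap matching, class assignment, enrichment
statistics, domain categories, and group contrasts."""

import math

import numpy as np
import pytest

from conftest import make_pocket
from pocketome import annotation as ann
from pocketome.datasets import TOTAL_FOUND, TOTAL_NOT_FOUND, compound_class_counts, default_ontology
from pocketome.model import CompoundOntology, DomainAnnotation, KnownSite, ResidueRef


def site(indices, chain="A", protein_id="P1", site_id="s1", ligand=None):
    return KnownSite(
        site_id, protein_id, frozenset(ResidueRef(chain, i) for i in indices), ligand
    )


class TestSplitInterchain:
    def test_two_distant_groups_split(self):
        coords_a = np.zeros((4, 3)) + np.arange(4)[:, None] * [3.0, 0, 0]
        coords_b = coords_a + [100.0, 0, 0]
        s = KnownSite(
            "s", "P1",
            frozenset({ResidueRef("A", i) for i in range(1, 5)}
                      | {ResidueRef("B", i) for i in range(1, 5)}),
        )
        parts = ann.split_interchain_site(s, {"A": coords_a, "B": coords_b})
        assert len(parts) == 2
        chains = sorted({r.chain for p in parts for r in p.residues})
        assert chains == ["A", "B"]

    def test_chain_connectivity_at_eleven_angstroms(self):
        coords = np.column_stack([11.0 * np.arange(6), np.zeros(6), np.zeros(6)])
        s = site(range(1, 7))
        parts = ann.split_interchain_site(s, {"A": coords})
        assert len(parts) == 1
        assert parts[0].residues == s.residues

    def test_small_components_dropped(self):
        coords = np.zeros((10, 3))
        coords[:3] += [0.0, 0, 0]
        coords[3:] += [100.0, 0, 0]
        parts = ann.split_interchain_site(site(range(1, 11)), {"A": coords})
        assert len(parts) == 1 and len(parts[0].residues) == 7

    def test_missing_coordinates_error(self):
        with pytest.raises(ValueError, match="coordinates"):
            ann.split_interchain_site(site([1, 2, 3, 4]), {"A": np.zeros((2, 3))})

    def test_random_configurations_match_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            coords = rng.uniform(0, 40, size=(30, 3))
            s = site(range(1, 31))
            parts = ann.split_interchain_site(s, {"A": coords}, min_residues=1)
            # brute-force union-find over the same adjacency
            parent = list(range(30))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(30):
                for j in range(i + 1, 30):
                    if np.linalg.norm(coords[i] - coords[j]) <= 12.0:
                        parent[find(i)] = find(j)
            oracle = {}
            for i in range(30):
                oracle.setdefault(find(i), set()).add(i + 1)
            got = sorted(sorted(r.index for r in p.residues) for p in parts)
            want = sorted(sorted(m) for m in oracle.values())
            assert got == want

    def test_output_partitions_input(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 30, size=(25, 3))
        s = site(range(1, 26))
        parts = ann.split_interchain_site(s, {"A": coords}, min_residues=1)
        union = frozenset().union(*(p.residues for p in parts))
        assert union == s.residues
        assert sum(len(p.residues) for p in parts) == 25


class TestMatching:
    def test_identical_sets_found(self):
        s = site([1, 2, 3, 4])
        p = make_pocket([1, 2, 3, 4])
        assert ann.match_known_to_predicted([s], [p])["s1"].found

    def test_disjoint_not_found(self):
        assert not ann.match_known_to_predicted(
            [site([1, 2, 3, 4])], [make_pocket([10, 11])]
        )["s1"].found

    def test_single_shared_residue_found(self):
        match = ann.match_known_to_predicted(
            [site([4, 5, 6, 7])], [make_pocket([7, 30, 31])]
        )["s1"]
        assert match.found and match.matched_pockets == ["P1:p1"]

    def test_other_protein_never_matches(self):
        assert not ann.match_known_to_predicted(
            [site([1, 2, 3, 4], protein_id="P2")], [make_pocket([1, 2, 3, 4])]
        )["s1"].found


class TestCompoundClasses:
    def test_root_id_zero_step(self, ontology):
        assert ann.assign_compound_class("CHEBI:36914", ontology) == {"Inorganic ions"}

    def test_unmapped_id_is_other(self, ontology):
        assert ann.assign_compound_class("CHEBI:0000001", ontology) == {"Other compounds"}

    def test_missing_ligand_is_other(self, ontology):
        assert ann.assign_compound_class(None, ontology) == {"Other compounds"}

    def test_atp_ascends_to_nucleotide_class(self):
        # ATP -> ADP-like parent -> nucleotide root, a two-step ascent
        ontology = default_ontology(
            {"CHEBI:30616": {"CHEBI:61404"}, "CHEBI:61404": {"CHEBI:36976"}}
        )
        assert ann.assign_compound_class("CHEBI:30616", ontology) == {
            "Nucleobases, nucleosides & nucleotides"
        }

    def test_multi_class_ligand(self):
        ontology = default_ontology(
            {"CHEBI:X": {"CHEBI:16646", "CHEBI:35381"}}
        )
        assert ann.assign_compound_class("CHEBI:X", ontology) == {
            "Carbohydrates & derivatives",
            "Monosaccharides & derivatives",
        }

    def test_cycle_is_error(self):
        ontology = default_ontology({"CHEBI:A": {"CHEBI:B"}, "CHEBI:B": {"CHEBI:A"}})
        with pytest.raises(ValueError, match="cycle"):
            ann.assign_compound_class("CHEBI:A", ontology)

    def test_diamond_is_fine(self):
        ontology = default_ontology(
            {
                "CHEBI:A": {"CHEBI:B", "CHEBI:C"},
                "CHEBI:B": {"CHEBI:D"},
                "CHEBI:C": {"CHEBI:D"},
                "CHEBI:D": {"CHEBI:30413"},
            }
        )
        assert ann.assign_compound_class("CHEBI:A", ontology) == {"Hemes"}


class TestEnrichment:
    def test_published_odds_ratios_reproduced(self):
        df = compound_class_counts()
        expected = {
            "Nucleobases, nucleosides & nucleotides": 8.55,
            "Inorganic ions": 0.05,
            "Carbohydrates & derivatives": 5.08,
            "Hemes": 5.97,
            "Hetero nuclear clusters": 0.17,
            "Nucleic acids": 0.0,
            "Oligo- & polypeptides": 0.79,
        }
        for name, want in expected.items():
            a, b = int(df.loc[name, "n_found"]), int(df.loc[name, "n_not_found"])
            assert round(ann.sample_odds_ratio(a, b, TOTAL_FOUND, TOTAL_NOT_FOUND), 2) == want

    def test_zero_found_gives_zero_or(self):
        assert ann.sample_odds_ratio(0, 7, 100, 100) == 0.0

    def test_zero_not_found_gives_infinite_or(self):
        assert math.isinf(ann.sample_odds_ratio(7, 0, 100, 100))

    def test_counts_exceeding_totals_error(self):
        with pytest.raises(ValueError):
            ann.sample_odds_ratio(101, 0, 100, 100)
        with pytest.raises(ValueError):
            ann.enrichment_table({"c": (101, 0)}, 100, 100)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # independent oracle: exact two-sided Fisher p by enumerating the
        # hypergeometric distribution with integer-exact binomials
        def oracle(a, b, c, d):
            r1, n = a + b, a + b + c + d
            k = a + c
            denom = math.comb(n, k)
            probs = [
                math.comb(r1, x) * math.comb(n - r1, k - x) / denom
                for x in range(max(0, k - (n - r1)), min(r1, k) + 1)
            ]
            p_obs = math.comb(r1, a) * math.comb(n - r1, k - a) / denom
            return sum(p for p in probs if p <= p_obs * (1 + 1e-9))

        rows = ann.enrichment_table({"c": (2, 1)}, 3, 3)
        assert rows[0].p_value == pytest.approx(oracle(2, 1, 1, 2), rel=1e-9)

    def test_by_adjustment_monotone_and_above_raw(self):
        counts = {f"c{k}": (k, 10 - k) for k in range(1, 10)}
        rows = ann.enrichment_table(counts, 60, 60)
        for r in rows:
            assert r.p_adj >= r.p_value - 1e-12
        by_raw = sorted(rows, key=lambda r: r.p_value)
        adj = [r.p_adj for r in by_raw]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_unique_totals_invariant_to_multiclass(self):
        ontology = default_ontology(
            {"CHEBI:X": {"CHEBI:16646", "CHEBI:35381"}}
        )
        sites = [
            site([1, 2, 3, 4], site_id="s1", ligand="CHEBI:X"),
            site([5, 6, 7, 8], site_id="s2", ligand="CHEBI:30413"),
        ]
        counts, F, NF = ann.class_counts_from_sites(
            sites, {"s1": True, "s2": False}, ontology
        )
        assert F == 1 and NF == 1
        assert sum(v[0] for v in counts.values()) == 2  # s1 counted in two classes


class TestDomains:
    def test_no_domain(self):
        cat, doms = ann.classify_pocket_domains(make_pocket([1, 2]), None)
        assert cat == "no_domain" and not doms

    def test_inter_domain(self):
        d = DomainAnnotation("P1", [("D1", 1, 5, False), ("D2", 6, 10, False)])
        cat, doms = ann.classify_pocket_domains(make_pocket([3, 8]), d)
        assert cat == "inter_domain" and doms == {"D1", "D2"}

    def test_domain_no_domain(self):
        d = DomainAnnotation("P1", [("D1", 1, 5, False)])
        cat, _ = ann.classify_pocket_domains(make_pocket([3, 50]), d)
        assert cat == "domain_no_domain"

    def test_duf(self):
        d = DomainAnnotation("P1", [("DUF1", 1, 10, True)])
        cat, _ = ann.classify_pocket_domains(make_pocket([2, 3]), d)
        assert cat == "DUF"

    def test_single_domain(self):
        d = DomainAnnotation("P1", [("D1", 1, 10, False)])
        cat, _ = ann.classify_pocket_domains(make_pocket([2, 3]), d)
        assert cat == "single_domain"


class TestContrasts:
    def test_identical_groups_zero_effect(self):
        assert ann.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computable_effect_size(self):
        # means 0.5 vs 1.5, pooled variance 0.5 -> d = -1/sqrt(0.5)
        assert ann.cohens_d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(-math.sqrt(2))

    def test_degenerate_separated_groups(self):
        assert ann.cohens_d([0.0, 0.0], [1.0, 1.0]) == -math.inf

    def test_planted_standardized_shift_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.74, 1.0, size=5000)
        b = rng.normal(0.0, 1.0, size=5000)
        assert ann.cohens_d(a, b) == pytest.approx(0.74, abs=0.05)

    def test_contrast_table(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        ids = [f"p{k}" for k in range(200)]
        values = np.concatenate([rng.normal(1.0, 1.0, 100), rng.normal(0.0, 1.0, 100)])
        table = pd.DataFrame({"prob": values}, index=ids)
        rows = ann.contrast_groups(table, ids[:100], ids[100:])
        (row,) = rows
        assert row.property_name == "prob"
        assert row.p_value < 0.01
        assert row.cohens_d == pytest.approx(1.0, abs=0.3)
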