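import json

import pandas as pd
import pytest

from netpharm.chem import passes_filter, select_candidates
from netpharm.enrichment import enrich
from netpharm.ppi_network import build_graph, summarize, topology
from netpharm.synthetic_data import (
    DEFAULT_HERBS,
    HerbSpec,
    gen_annotations,
    gen_disease_lists,
    gen_ingredients,
    gen_ppi,
    gen_target_maps,
)
from netpharm.target_sets import GeneSet, integrate_disease_targets, union_targets, venn


class TestGenIngredients:
    def test_default_shape_yields_nine_candidates(self):
        tables, truth = gen_ingredients(seed=7)
        assert [len(tables[h.latin]) for h in DEFAULT_HERBS] == [47, 17, 10]
        cands = select_candidates(list(tables.values()))
        assert len(cands) == 9
        shared = [c for c in cands if len(c.herbs) > 1]
        assert len(shared) == 1 and len(shared[0].herbs) == 2

    def test_planted_pass_fail_exact(self):
        tables, truth = gen_ingredients(seed=3)
        for spec in DEFAULT_HERBS:
            passed = {r.name for r in tables[spec.latin] if passes_filter(r)}
            assert sorted(passed) == truth.planted_pass_names[spec.latin]
            assert len(passed) == spec.n_pass

    def test_zero_passes(self):
        herbs = (HerbSpec("A", "a", "TCMSP", 5, 0), HerbSpec("B", "b", "BATMAN", 4, 0))
        tables, _ = gen_ingredients(herbs, seed=1, cross_herb_duplicates=())
        assert select_candidates(list(tables.values())) == []

    def test_deterministic(self):
        t1, _ = gen_ingredients(seed=5)
        t2, _ = gen_ingredients(seed=5)
        assert t1 == t2
        t3, _ = gen_ingredients(seed=6)
        assert t1 != t3

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError):
            HerbSpec("A", "a", "TCMSP", 3, 4)
        with pytest.raises(ValueError):
            gen_ingredients(
                (HerbSpec("A", "a", "TCMSP", 5, 0), HerbSpec("B", "b", "TCMSP", 5, 1)),
                cross_herb_duplicates=((0, 1),),
            )


class TestGenTargetMaps:
    CANDS = {"H1": ["i1", "i2", "i3"], "H2": ["i4", "i5"], "H3": ["i6"]}

    def test_exact_collapse_131_to_71(self):
        counts = {"H1": 58, "H2": 46, "H3": 27}
        table, truth = gen_target_maps(self.CANDS, counts, union_size=71, seed=2)
        per_herb = table.groupby("herb")["target"].nunique().to_dict()
        assert per_herb == counts
        sets = [GeneSet(ing, list(g["target"])) for ing, g in table.groupby("ingredient")]
        assert len(union_targets(sets)) == 71

    def test_disjoint_allocation(self):
        counts = {"H1": 5, "H2": 4, "H3": 3}
        table, _ = gen_target_maps(self.CANDS, counts, union_size=12, seed=0)
        assert table["target"].nunique() == 12

    def test_nested_allocation(self):
        counts = {"H1": 6, "H2": 4, "H3": 2}
        table, _ = gen_target_maps(self.CANDS, counts, union_size=6, seed=0)
        assert table["target"].nunique() == 6

    def test_infeasible_sizes(self):
        with pytest.raises(ValueError):
            gen_target_maps(self.CANDS, {"H1": 5, "H2": 4, "H3": 3}, union_size=13)
        with pytest.raises(ValueError):
            gen_target_maps(self.CANDS, {"H1": 5, "H2": 4, "H3": 3}, union_size=4)

    def test_deterministic(self):
        counts = {"H1": 10, "H2": 8, "H3": 6}
        t1, _ = gen_target_maps(self.CANDS, counts, union_size=15, seed=4)
        t2, _ = gen_target_maps(self.CANDS, counts, union_size=15, seed=4)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenDiseaseLists:
    DRUG = [f"DR{i:03d}" for i in range(71)]

    def test_printed_venn_recovered(self):
        a, b, truth = gen_disease_lists(self.DRUG, 245, 93, 17, 29, seed=8)
        disease = integrate_disease_targets(a, b)
        assert (len(a), len(b), len(disease)) == (245, 93, 321)
        summary, overlap = venn(GeneSet("drug", self.DRUG), disease)
        assert summary.size_intersection == 29
        assert summary.pct_of_b == 9.03

    def test_zero_ab_overlap(self):
        a, b, _ = gen_disease_lists(self.DRUG, 245, 93, 0, 29, seed=8)
        assert len(integrate_disease_targets(a, b)) == 338

    def test_planted_intersection_12(self):
        a, b, _ = gen_disease_lists(self.DRUG, 40, 30, 5, 12, seed=9)
        disease = integrate_disease_targets(a, b)
        summary, _ = venn(GeneSet("drug", self.DRUG), disease)
        assert summary.size_intersection == 12

    def test_infeasible(self):
        with pytest.raises(ValueError):
            gen_disease_lists(self.DRUG, 10, 5, 6, 2)
        with pytest.raises(ValueError):
            gen_disease_lists(self.DRUG[:5], 10, 5, 2, 6)

    def test_deterministic(self):
        a1, b1, _ = gen_disease_lists(self.DRUG, 50, 30, 5, 10, seed=2)
        a2, b2, _ = gen_disease_lists(self.DRUG, 50, 30, 5, 10, seed=2)
        assert a1.genes == a2.genes and b1.genes == b2.genes


class TestGenPpi:
    NODES = [f"N{i}" for i in range(29)]

    def test_exact_edge_count(self):
        table, truth = gen_ppi(self.NODES, n_edges=86, seed=4)
        g = build_graph(table, score_threshold=0.0)
        assert summarize(g).n_edges == 86
        assert truth.planted_graph["n_edges"] == 86

    def test_zero_edges(self):
        table, truth = gen_ppi(self.NODES, n_edges=0, seed=4)
        assert len(table) == 0 and truth.planted_graph["connected_nodes"] == []

    def test_truth_connected_nodes_recovered(self):
        table, truth = gen_ppi(self.NODES, n_edges=86, seed=5)
        g = build_graph(table, score_threshold=0.4, drop_isolated=True)
        assert sorted(g.nodes) == truth.planted_graph["connected_nodes"]

    def test_planted_clique_coreness(self):
        module = self.NODES[:5]
        table, truth = gen_ppi(
            self.NODES, model="planted_module", module_nodes=module, n_edges=30, seed=6
        )
        g = build_graph(table, score_threshold=0.4)
        core = {r.gene: r.coreness for r in topology(g)}
        assert all(core[v] >= 4 for v in module)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            gen_ppi(["A", "B", "C"], n_edges=4)

    def test_scores_in_range(self):
        table, _ = gen_ppi(self.NODES, n_edges=50, seed=7)
        assert table["combined_score"].between(0.15, 0.999).all()

    def test_deterministic(self):
        t1, _ = gen_ppi(self.NODES, n_edges=40, seed=3)
        t2, _ = gen_ppi(self.NODES, n_edges=40, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenAnnotations:
    UNIVERSE = [f"G{i}" for i in range(150)]
    QUERY = UNIVERSE[:15]

    def test_factor_one_plants_nothing(self):
        table, truth = gen_annotations(self.UNIVERSE, self.QUERY, n_planted=3, enrichment_factor=1.0, seed=1)
        assert truth.planted_terms == {}
        assert all(name.startswith("decoy") for name in table.terms)

    def test_term_sizes_within_range(self):
        table, _ = gen_annotations(self.UNIVERSE, self.QUERY, term_size_range=(5, 50), n_terms=25, seed=2)
        assert all(5 <= len(g) <= 50 for g in table.terms.values())

    def test_planted_term_recorded_with_expectation(self):
        table, truth = gen_annotations(
            self.UNIVERSE, self.QUERY, n_planted=1, enrichment_factor=8.0, seed=3
        )
        assert len(truth.planted_terms) == 1
        (info,) = truth.planted_terms.values()
        assert info["enrichment_factor"] == 8.0
        assert info["expected_overlap"] > 0

    def test_deterministic(self):
        t1, _ = gen_annotations(self.UNIVERSE, self.QUERY, seed=4)
        t2, _ = gen_annotations(self.UNIVERSE, self.QUERY, seed=4)
        assert t1.terms == t2.terms

    def test_infeasible(self):
        with pytest.raises(ValueError):
            gen_annotations(self.UNIVERSE, self.QUERY, n_terms=2, n_planted=3)
        with pytest.raises(ValueError):
            gen_annotations(self.UNIVERSE, self.QUERY, term_size_range=(10, 9999))


class TestBundle:
    def test_truth_json_written(self, bundle):
        path, truth = bundle
        data = json.loads((path / "truth.json").read_text())
        assert data["seed"] == truth.seed
        assert data["planted_target_union"] == 71
        assert data["planted_venn"]["disease_union"] == 321

    def test_bundle_deterministic(self, tmp_path):
        from netpharm.synthetic_data import gen_bundle

        p1, _ = gen_bundle(tmp_path / "a", seed=13)
        p2, _ = gen_bundle(tmp_path / "b", seed=13)
        for f in sorted(p1.iterdir()):
            assert (p2 / f.name).read_bytes() == f.read_bytes(), f.name
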