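import numpy as np
import pandas as pd
import pytest

from netprio.io import ParameterError, TermSet
from netprio.synth import (
    SyntheticTruth,
    simulate_annotation,
    simulate_deg_table,
    simulate_study,
    simulate_term_network,
)


class TestDegTable:
    @pytest.mark.parametrize("n, frac, expected", [(1000, 0.1, 100), (10, 0.1, 1)])
    def test_exact_deg_count(self, n, frac, expected):
        table, truth = simulate_deg_table(n, frac, 0.3, seed=1)
        assert (table["padj"] < 0.05).sum() == expected
        assert len(truth.deg_genes) == expected
        assert set(table.loc[table["padj"] < 0.05, "gene"]) == truth.deg_genes

    def test_symbols_unique_and_q_partitioned(self):
        table, truth = simulate_deg_table(500, 0.2, 0.5, seed=3)
        assert table["gene"].is_unique
        non_deg = table[~table["gene"].isin(truth.deg_genes)]
        assert (non_deg["padj"] >= 0.05).all()

    def test_deterministic_under_seed(self):
        a, _ = simulate_deg_table(200, 0.1, 0.3, seed=42)
        b, _ = simulate_deg_table(200, 0.1, 0.3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 5}, {"frac_deg": 0.0}, {"frac_deg": 1.0}, {"effect_sd": -1.0},
    ])
    def test_parameter_validation(self, kwargs):
        args = {"n_genes": 100, "frac_deg": 0.1, "effect_sd": 0.3, "seed": 0}
        args.update(kwargs)
        with pytest.raises(ParameterError):
            simulate_deg_table(**args)


class TestAnnotation:
    def _truth(self, universe, frac, seed=0):
        rng = np.random.default_rng(seed)
        degs = set(rng.choice(universe, size=round(frac * len(universe)), replace=False))
        return SyntheticTruth(seed=seed, deg_genes=degs)

    def test_sizes_and_count(self):
        universe = [f"G{i:04d}" for i in range(100)]
        truth = self._truth(universe, 0.1)
        terms, _ = simulate_annotation(universe, 3, (5, 10), 0, 1.0, truth, seed=1)
        assert len(terms) == 3
        assert all(5 <= len(t.members) <= 10 for t in terms)

    def test_children_are_subsets_and_acyclic(self):
        universe = [f"G{i:04d}" for i in range(200)]
        truth = self._truth(universe, 0.1)
        terms, hierarchy = simulate_annotation(universe, 6, (10, 40), 6, 3.0, truth, seed=2)
        by_id = {t.term_id: t for t in terms}
        assert len(hierarchy) == 3
        for parent, child in hierarchy:
            assert by_id[child].members <= by_id[parent].members
            assert child in by_id[parent].children

    def test_null_odds_matches_universe_fraction(self):
        """With odds 1 the DEG share inside terms is the universe share."""
        universe = [f"G{i:04d}" for i in range(500)]
        truth = self._truth(universe, 0.2)
        fracs = []
        for s in range(200):
            terms, _ = simulate_annotation(universe, 1, (100, 100), 0, 1.0, truth, seed=s)
            fracs.append(len(terms[0].members & truth.deg_genes) / 100)
        # 3 sigma of the mean of 200 binomial(100, 0.2) fractions
        assert abs(np.mean(fracs) - 0.2) < 3 * np.sqrt(0.2 * 0.8 / (100 * 200))

    def test_enriched_odds_raises_deg_fraction(self):
        """Odds 10 puts the term DEG share above the universe share almost always."""
        universe = [f"G{i:04d}" for i in range(2000)]
        truth = self._truth(universe, 0.1)
        hits = 0
        for s in range(200):
            terms, _ = simulate_annotation(universe, 1, (200, 200), 1, 10.0, truth, seed=s)
            hits += len(terms[0].members & truth.deg_genes) / 200 > 0.1
        assert hits >= 0.95 * 200
        assert truth.enriched_terms == {"T0001"}

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            simulate_annotation([], 1, (2, 3), 0, 1.0, SyntheticTruth(seed=0), seed=0)


class TestTermNetwork:
    def _term(self, n, seed=0):
        rng = np.random.default_rng(seed)
        genes = sorted(rng.choice([f"G{i:04d}" for i in range(10 * n)], n, replace=False))
        return TermSet("T0001", "t", set(genes))

    def test_planted_hub_degree_dominates_background(self):
        term = self._term(50)
        base, _ = simulate_term_network(term, 2.0, 0, 1.0, seed=11)
        hubbed, hubs = simulate_term_network(term, 2.0, 1, 10.0, seed=11)
        degrees = pd.concat([hubbed["node1"], hubbed["node2"]]).value_counts()
        base_deg = pd.concat([base["node1"], base["node2"]]).value_counts()
        assert degrees[hubs[0]] > base_deg.max()

    def test_tiny_term_simple_graph_bound(self):
        term = TermSet("T", "t", {"A", "B", "C"})
        edges, _ = simulate_term_network(term, 2.0, 0, 1.0, seed=0)
        assert 2 <= len(edges) <= 3  # path or triangle on 3 nodes

    def test_scores_at_least_string_highest_confidence(self, small_study):
        for edges in small_study.networks.values():
            assert (edges["combined_score"] >= 0.900).all()

    def test_hub_expected_degree_near_contract(self):
        """Mean planted-hub degree tracks hub_degree_factor * mean_degree."""
        term = self._term(200, seed=5)
        degs = []
        for s in range(10):
            edges, hubs = simulate_term_network(term, 6.0, 2, 8.0, seed=s)
            counts = pd.concat([edges["node1"], edges["node2"]]).value_counts()
            degs += [counts[h] for h in hubs]
        assert np.mean(degs) == pytest.approx(48, rel=0.15)

    def test_n_hubs_must_fit(self):
        term = TermSet("T", "t", {"A", "B", "C"})
        with pytest.raises(ParameterError):
            simulate_term_network(term, 2.0, 3, 2.0, seed=0)

    def test_deterministic_under_seed(self):
        term = self._term(60)
        a, _ = simulate_term_network(term, 4.0, 2, 8.0, seed=9)
        b, _ = simulate_term_network(term, 4.0, 2, 8.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestStudy:
    def test_truth_invariants(self, small_study):
        universe = set(small_study.deg_tables[small_study.primary_contrast]["gene"])
        assert small_study.truth.deg_genes <= universe
        by_id = {t.term_id: t for t in small_study.terms}
        for term_id, hubs in small_study.truth.planted_hubs.items():
            assert hubs <= by_id[term_id].members

    def test_categories_cover_all_terms_once(self, small_study):
        assigned = [t for tids in small_study.category_map.values() for t in tids]
        assert sorted(assigned) == sorted(t.term_id for t in small_study.terms)
        assert len(assigned) == len(set(assigned))

    def test_regeneration_is_byte_identical(self, tmp_path, small_study):
        from netprio.pipeline import write_study

        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_study(small_study, d1)
        write_study(
            simulate_study(
                7,
                n_genes=600, frac_deg=0.15, effect_sd=0.6, n_term_pairs=4,
                size_range=(40, 80), mean_degree=6.0, n_hubs=2,
                hub_degree_factor=8.0,
            ),
            d2,
        )
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
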