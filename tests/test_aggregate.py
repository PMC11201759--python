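import math

import numpy as np
import pandas as pd
import pytest

from netprio.aggregate import (
    ConfigurationError,
    resolve_gene_weights,
    shared_deg_overlap,
    structure_fc_summary,
    structure_weighted_summary,
    top_fraction,
)
from netprio.io import ParameterError, TermSet
from netprio.scoring import GeneWeight


def _degs(pairs):
    return pd.DataFrame(
        {
            "gene": [g for g, _ in pairs],
            "log2fc": [fc for _, fc in pairs],
            "qvalue": [0.01] * len(pairs),
        }
    )


CMAP = {"mito": ["T1", "T2"], "er": ["T3"]}


class TestResolve:
    def test_max_weight_wins_within_category(self):
        weights = [GeneWeight("A", "T1", 1.2), GeneWeight("A", "T2", 3.4)]
        resolved = resolve_gene_weights(weights, CMAP)
        row = resolved["mito"].iloc[0]
        assert (row["w"], row["term_id"]) == (3.4, "T2")

    def test_single_term_identity(self):
        resolved = resolve_gene_weights([GeneWeight("A", "T3", -0.5)], CMAP)
        assert resolved["er"]["w"].tolist() == [-0.5]

    def test_categories_independent(self):
        weights = [GeneWeight("A", "T1", 1.0), GeneWeight("A", "T3", 2.0)]
        resolved = resolve_gene_weights(weights, CMAP)
        assert resolved["mito"]["w"].tolist() == [1.0]
        assert resolved["er"]["w"].tolist() == [2.0]

    def test_uncategorized_term_rejected(self):
        with pytest.raises(ConfigurationError, match="T9"):
            resolve_gene_weights([GeneWeight("A", "T9", 1.0)], CMAP)


class TestFcSummary:
    TERMS = [
        TermSet("T1", "t1", {"A", "B"}),
        TermSet("T2", "t2", {"B", "C"}),
        TermSet("T3", "t3", {"D"}),
    ]

    def test_signed_sums(self):
        degs = _degs([("A", 0.5), ("B", -0.3)])
        out = structure_fc_summary(degs, CMAP, self.TERMS).set_index("category")
        row = out.loc["mito"]
        assert row["sum_abs_fc"] == pytest.approx(0.8)
        assert row["sum_pos_fc"] == pytest.approx(0.5)
        assert row["sum_neg_fc"] == pytest.approx(-0.3)
        assert row["n_genes"] == 2

    def test_gene_in_two_terms_counted_once(self):
        degs = _degs([("B", 1.0)])
        out = structure_fc_summary(degs, CMAP, self.TERMS).set_index("category")
        assert out.loc["mito", "sum_abs_fc"] == pytest.approx(1.0)
        assert out.loc["mito", "n_genes"] == 1

    def test_empty_category_is_zero(self):
        degs = _degs([("A", 0.5)])
        out = structure_fc_summary(degs, CMAP, self.TERMS).set_index("category")
        assert out.loc["er", "n_genes"] == 0
        assert out.loc["er", "sum_abs_fc"] == 0.0

    def test_abs_bound(self):
        degs = _degs([("A", 0.5), ("B", -0.3), ("C", 1.1), ("D", -2.0)])
        out = structure_fc_summary(degs, CMAP, self.TERMS)
        assert (
            out["sum_abs_fc"] >= (out["sum_pos_fc"] + out["sum_neg_fc"]).abs() - 1e-12
        ).all()
        assert np.allclose(out["sum_abs_fc"], out["sum_pos_fc"] - out["sum_neg_fc"])


class TestWeightedSummary:
    def test_single_gene_product(self):
        degs = _degs([("A", 0.2)])
        resolved = {"mito": pd.DataFrame({"gene": ["A"], "w": [5.0], "term_id": ["T1"]})}
        out = structure_weighted_summary(degs, resolved)
        assert out["mean_weighted_fc"].iloc[0] == pytest.approx(1.0)

    def test_symmetric_fc_cancels(self):
        degs = _degs([("A", 0.2), ("B", -0.2)])
        resolved = {
            "mito": pd.DataFrame(
                {"gene": ["A", "B"], "w": [5.0, 5.0], "term_id": ["T1", "T1"]}
            )
        }
        out = structure_weighted_summary(degs, resolved)
        assert out["mean_weighted_fc"].iloc[0] == pytest.approx(0.0)

    def test_constant_weight_is_linear(self):
        degs = _degs([("A", 0.4), ("B", -0.1), ("C", 0.3)])
        resolved = {
            "mito": pd.DataFrame(
                {"gene": list("ABC"), "w": [2.5] * 3, "term_id": ["T1"] * 3}
            )
        }
        out = structure_weighted_summary(degs, resolved)
        assert out["mean_weighted_fc"].iloc[0] == pytest.approx(2.5 * np.mean([0.4, -0.1, 0.3]))

    def test_empty_category_flagged_not_zero(self):
        degs = _degs([("A", 0.4)])
        resolved = {"er": pd.DataFrame({"gene": [], "w": [], "term_id": []})}
        out = structure_weighted_summary(degs, resolved)
        assert out["n_genes"].iloc[0] == 0
        assert math.isnan(out["mean_weight"].iloc[0])


class TestSharedOverlap:
    TERMS = [
        TermSet("T1", "t1", {"A", "B"}),
        TermSet("T2", "t2", {"A", "B", "X"}),
        TermSet("T3", "t3", {"A", "B", "C"}),
    ]

    def test_pairwise_counts(self):
        degs = _degs([("A", 1.0), ("B", -1.0), ("C", 0.5)])
        mat, gene_table = shared_deg_overlap(CMAP, self.TERMS, degs)
        assert mat.loc["mito", "er"] == 2  # A and B shared
        assert mat.loc["mito", "mito"] == 2
        assert mat.loc["er", "er"] == 3
        shared = gene_table.set_index("gene")
        assert shared.loc["A", "categories"] == "er;mito"
        assert shared.loc["A", "regulation"] == "up"
        assert shared.loc["B", "regulation"] == "down"

    def test_disjoint_categories_zero(self):
        terms = [TermSet("T1", "t", {"A"}), TermSet("T3", "t", {"B"})]
        degs = _degs([("A", 1.0), ("B", 1.0)])
        mat, _ = shared_deg_overlap(CMAP, terms, degs)
        assert mat.loc["mito", "er"] == 0


class TestTopFraction:
    def _resolved(self, genes_weights):
        return {
            "mito": pd.DataFrame(
                {
                    "gene": [g for g, _ in genes_weights],
                    "w": [w for _, w in genes_weights],
                    "term_id": ["T1"] * len(genes_weights),
                }
            )
        }

    def test_ceiling_rule(self):
        pairs = [(f"G{i}", float(i)) for i in range(7)]
        degs = _degs([(g, 0.1) for g, _ in pairs])
        out = top_fraction(self._resolved(pairs), degs, 0.10)
        assert len(out) == 1  # ceil(0.7)
        assert out["gene"].iloc[0] == "G6"

    def test_tie_broken_by_abs_fc_then_symbol(self):
        pairs = [("A", 9.0), ("B", 8.0), ("C", 8.0), ("D", 1.0)]
        degs = _degs([("A", 0.1), ("B", 0.2), ("C", -0.9), ("D", 2.0)])
        out = top_fraction(self._resolved(pairs), degs, 0.5)
        assert out["gene"].tolist() == ["A", "C"]  # C beats B on |fc|

    def test_fraction_one_returns_all_sorted(self):
        pairs = [("A", 1.0), ("B", 3.0), ("C", 2.0)]
        degs = _degs([(g, 0.1) for g, _ in pairs])
        out = top_fraction(self._resolved(pairs), degs, 1.0)
        assert out["gene"].tolist() == ["B", "C", "A"]
        assert out["rank"].tolist() == [1, 2, 3]

    def test_fraction_out_of_range(self):
        with pytest.raises(ParameterError):
            top_fraction(self._resolved([("A", 1.0)]), _degs([("A", 0.1)]), 0.0)

    def test_row_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        pairs = [(f"G{i}", float(rng.normal())) for i in range(30)]
        degs = _degs([(g, float(rng.normal())) for g, _ in pairs])
        out1 = top_fraction(self._resolved(pairs), degs, 0.2)
        shuffled = self._resolved(pairs)
        shuffled["mito"] = shuffled["mito"].sample(frac=1.0, random_state=1).reset_index(drop=True)
        out2 = top_fraction(shuffled, degs.sample(frac=1.0, random_state=2), 0.2)
        pd.testing.assert_frame_equal(out1, out2)
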