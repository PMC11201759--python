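"""Overrepresentation of DEGs in gene sets, and the term-retention rules.

Builds a small universe in memory, tests each term with Fisher's exact
test, adjusts with Benjamini-Hochberg, and applies the selection rules:
FDR < 0.05, positive direction, size at most the network-buildable limit,
and deepest child only.
"""

from netprio import TermSet, fisher_overrepresentation, select_terms

universe = {f"G{i:03d}" for i in range(400)}
degs = {f"G{i:03d}" for i in range(60)}  # 15% of the universe

terms = [
    # parent/child pair, both packed with DEGs -> only the child is kept
    TermSet("GO:P1", "organelle membrane", {f"G{i:03d}" for i in range(80)},
            children={"GO:C1"}),
    TermSet("GO:C1", "inner membrane complex", {f"G{i:03d}" for i in range(40)}),
    # a set that avoids DEGs entirely -> significant but negative
    TermSet("GO:N1", "depleted set", {f"G{i:03d}" for i in range(60, 360)}),
    # a random-looking set -> not significant
    TermSet("GO:R1", "background set", {f"G{i:03d}" for i in range(55, 95)}),
]

results = fisher_overrepresentation(degs, universe, terms)
retained, exclusions = select_terms(results, terms, fdr_threshold=0.05,
                                    max_term_size=2000)

for r in results:
    print(
        f"{r.term_id:6s} overlap={r.n_overlap:3d} expected={r.expected:6.2f} "
        f"fold={r.fold_enrichment:5.2f} {r.direction:8s} fdr={r.fdr:.3g}"
    )
print(f"retained: {retained}")
print(f"excluded: {exclusions}")
print(
    "GO:C1 survives alone: its parent is significant too but the deepest\n"
    "child carries the specific signal; the depleted and background sets\n"
    "fall to the direction and FDR rules."
)
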