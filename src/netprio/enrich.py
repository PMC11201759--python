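"""Gene-set overrepresentation of DEGs and term-selection rules.

For each gene set the 2x2 table (overlap, DEG-only, term-only, neither)
is tested with Fisher's exact test and adjusted across terms with the
Benjamini–Hochberg step-up procedure.  A term's direction is *positive*
when the observed overlap strictly exceeds the expectation
``n_deg * n_term / n_universe`` and *negative* otherwise (an overlap
exactly at expectation is not over-represented).

Term selection mirrors the analysis protocol: keep terms that are
significant after FDR, positively over-represented and small enough to
build a PPI network for (the STRING node limit), then keep only the
deepest children — a retained term is dropped whenever one of its
hierarchy descendants is also retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ParameterError, TermSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "fisher_overrepresentation",
    "bh_adjust",
    "select_terms",
    "enrichment_frame",
]


@dataclass
class EnrichmentResult:
    """Overrepresentation statistics for one gene set."""

    term_id: str
    n_universe: int
    n_term: int
    n_deg: int
    n_overlap: int
    expected: float
    fold_enrichment: float
    direction: str  # "positive" | "negative"
    p_raw: float
    fdr: float = math.nan


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_overrepresentation(
    deg_genes: set[str],
    universe: set[str],
    terms: list[TermSet],
    *,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Fisher exact overrepresentation of ``deg_genes`` in each term.

    Term members are intersected with the universe before testing; terms
    disjoint from the universe are skipped with a warning.  Results are
    BH-adjusted across all tested terms and sorted by term id.
    """
    if not universe:
        raise ParameterError("gene universe is empty")
    deg_genes = set(deg_genes)
    universe = set(universe)
    if not deg_genes <= universe:
        missing = sorted(deg_genes - universe)[:5]
        raise ParameterError(f"DEGs not contained in the universe, e.g. {missing}")

    n_universe = len(universe)
    n_deg = len(deg_genes)
    results: list[EnrichmentResult] = []
    for term in sorted(terms, key=lambda t: t.term_id):
        members = term.members & universe
        if not members:
            logger.warning("term %s disjoint from universe: skipped", term.term_id)
            continue
        n_term = len(members)
        n_overlap = len(members & deg_genes)
        expected = n_deg * n_term / n_universe
        table = [
            [n_overlap, n_deg - n_overlap],
            [n_term - n_overlap, n_universe - n_deg - n_term + n_overlap],
        ]
        _, p_raw = stats.fisher_exact(table, alternative=alternative)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                n_universe=n_universe,
                n_term=n_term,
                n_deg=n_deg,
                n_overlap=n_overlap,
                expected=expected,
                fold_enrichment=n_overlap / expected if expected > 0 else 0.0,
                direction="positive" if n_overlap > expected else "negative",
                p_raw=float(p_raw),
            )
        )
    fdrs = bh_adjust([r.p_raw for r in results])
    for r, fdr in zip(results, fdrs):
        r.fdr = float(fdr)
    return results


def _descendants(terms: list[TermSet]) -> dict[str, set[str]]:
    """Transitive closure of the parent -> child relation."""
    children = {t.term_id: set(t.children) for t in terms}
    closure: dict[str, set[str]] = {}

    def visit(tid: str, stack: tuple[str, ...]) -> set[str]:
        if tid in closure:
            return closure[tid]
        if tid in stack:
            raise ParameterError(f"hierarchy cycle through {tid!r}")
        acc: set[str] = set()
        for child in children.get(tid, ()):
            acc.add(child)
            acc |= visit(child, stack + (tid,))
        closure[tid] = acc
        return acc

    for tid in children:
        visit(tid, ())
    return closure


def select_terms(
    results: list[EnrichmentResult],
    terms: list[TermSet],
    fdr_threshold: float = 0.05,
    max_term_size: int = 2000,
) -> tuple[list[str], dict[str, str]]:
    """Apply the retention rules and return ``(retained_ids, exclusions)``.

    A term is retained iff fdr < ``fdr_threshold``, direction is positive,
    its (universe-restricted) size is at most ``max_term_size`` and no
    retained descendant exists.  ``exclusions`` maps each excluded term id
    to its reason: ``"fdr"``, ``"direction"``, ``"size"`` or ``"ancestor"``.
    """
    exclusions: dict[str, str] = {}
    candidates: list[str] = []
    for r in results:
        if not r.fdr < fdr_threshold:
            exclusions[r.term_id] = "fdr"
        elif r.direction != "positive":
            exclusions[r.term_id] = "direction"
        elif r.n_term > max_term_size:
            exclusions[r.term_id] = "size"
        else:
            candidates.append(r.term_id)

    desc = _descendants(terms)
    retained_set = set(candidates)
    retained: list[str] = []
    for tid in candidates:
        if desc.get(tid, set()) & retained_set:
            exclusions[tid] = "ancestor"
        else:
            retained.append(tid)
    for tid, reason in sorted(exclusions.items()):
        logger.info("term %s excluded: %s", tid, reason)
    return sorted(retained), exclusions


def enrichment_frame(
    results: list[EnrichmentResult],
    retained: list[str],
    exclusions: dict[str, str],
) -> pd.DataFrame:
    """Tabulate enrichment results with retention status for reporting."""
    retained_set = set(retained)
    rows = []
    for r in results:
        rows.append(
            {
                "term_id": r.term_id,
                "n_universe": r.n_universe,
                "n_term": r.n_term,
                "n_deg": r.n_deg,
                "n_overlap": r.n_overlap,
                "expected": r.expected,
                "fold_enrichment": r.fold_enrichment,
                "direction": r.direction,
                "p_raw": r.p_raw,
                "fdr": r.fdr,
                "retained": r.term_id in retained_set,
                "exclusion_reason": exclusions.get(r.term_id, ""),
            }
        )
    return pd.DataFrame(rows)
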