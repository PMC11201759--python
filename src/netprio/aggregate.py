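"""Structure-level aggregation, gene sharing and top-gene ranking.

Ontology terms are grouped into named subcellular-structure categories
(e.g. mitochondria, endoplasmic reticulum, nucleus, intracellular
complexes) by a user-supplied category map.  Within a category a gene may
be annotated to several terms and hence carry several network weights;
the maximum weight wins and the winning term is kept as provenance.

Two kinds of per-structure summaries are produced:

* fold-change summaries over all DEGs annotated to the category's terms
  (sum of absolute, positive and negative log2 fold changes), and
* weight summaries over the weight-bearing DEGs (mean W and the mean of
  log2fc * W, a signed, importance-scaled regulation measure).

Finally each category's genes are ranked by W and the top fraction
(default 10%) reported with fold change and winning term.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ParameterError, TermSet
from .scoring import GeneWeight

logger = logging.getLogger(__name__)

__all__ = [
    "load_category_map",
    "resolve_gene_weights",
    "structure_fc_summary",
    "structure_weighted_summary",
    "shared_deg_overlap",
    "top_fraction",
]


class ConfigurationError(ValueError):
    """The category map does not cover the data it is applied to."""


def load_category_map(path: str | Path) -> dict[str, list[str]]:
    """Load a YAML category map (structure label -> list of term ids)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ConfigurationError(f"{path}: expected a non-empty mapping")
    cmap: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for category, term_ids in raw.items():
        if not term_ids:
            raise ConfigurationError(f"{path}: category {category!r} is empty")
        ids = [str(t) for t in term_ids]
        for tid in ids:
            if tid in seen:
                raise ConfigurationError(
                    f"{path}: term {tid!r} assigned to both "
                    f"{seen[tid]!r} and {category!r}"
                )
            seen[tid] = str(category)
        cmap[str(category)] = ids
    return cmap


def _term_to_category(cmap: dict[str, list[str]]) -> dict[str, str]:
    return {tid: cat for cat, tids in cmap.items() for tid in tids}


def resolve_gene_weights(
    weights: list[GeneWeight],
    cmap: dict[str, list[str]],
) -> dict[str, pd.DataFrame]:
    """Resolve per-term weights to one weight per gene per category.

    A gene present in several term networks of the same category keeps
    its maximum W; the winning term id is retained (smallest id on exact
    ties).  A gene annotated to terms of different categories appears in
    each category independently.
    """
    t2c = _term_to_category(cmap)
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for gw in weights:
        if gw.term_id not in t2c:
            raise ConfigurationError(
                f"term {gw.term_id!r} missing from the category map"
            )
        key = (t2c[gw.term_id], gw.gene)
        cur = best.get(key)
        cand = (gw.w, gw.term_id)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[key] = cand
    out: dict[str, pd.DataFrame] = {}
    for category in cmap:
        rows = sorted(
            (gene, w, tid)
            for (cat, gene), (w, tid) in best.items()
            if cat == category
        )
        out[category] = pd.DataFrame(rows, columns=["gene", "w", "term_id"])
    return out


def _category_members(
    cmap: dict[str, list[str]], terms: list[TermSet]
) -> dict[str, set[str]]:
    by_id = {t.term_id: t for t in terms}
    members: dict[str, set[str]] = {}
    for category, tids in cmap.items():
        acc: set[str] = set()
        for tid in tids:
            if tid in by_id:
                acc |= by_id[tid].members
        members[category] = acc
    return members


def structure_fc_summary(
    degs: pd.DataFrame,
    cmap: dict[str, list[str]],
    terms: list[TermSet],
) -> pd.DataFrame:
    """Per-category fold-change sums over distinct annotated DEGs.

    ``degs`` is a q-filtered DEG table (columns gene, log2fc, qvalue).
    A gene annotated to several terms of a category is counted once.
    """
    fc = dict(zip(degs["gene"], degs["log2fc"]))
    members = _category_members(cmap, terms)
    rows = []
    for category in sorted(cmap):
        genes = sorted(members[category] & fc.keys())
        vals = np.array([fc[g] for g in genes], dtype=float)
        rows.append(
            {
                "category": category,
                "n_genes": len(genes),
                "sum_abs_fc": float(np.abs(vals).sum()) if len(genes) else 0.0,
                "sum_pos_fc": float(vals[vals > 0].sum()) if len(genes) else 0.0,
                "sum_neg_fc": float(vals[vals < 0].sum()) if len(genes) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def structure_weighted_summary(
    degs: pd.DataFrame,
    resolved: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-category mean weight and mean weighted fold change.

    Only weight-bearing DEGs contribute (a DEG can be annotated to a term
    yet absent from its network).  Categories with no weighted DEG are
    reported with ``n_genes = 0`` and NaN means rather than silent zeros.
    """
    fc = dict(zip(degs["gene"], degs["log2fc"]))
    rows = []
    for category in sorted(resolved):
        table = resolved[category]
        mask = table["gene"].isin(fc.keys())
        sub = table[mask]
        n = len(sub)
        if n == 0:
            rows.append(
                {
                    "category": category,
                    "n_genes": 0,
                    "mean_weight": math.nan,
                    "mean_weighted_fc": math.nan,
                }
            )
            continue
        ws = sub["w"].to_numpy(dtype=float)
        fcs = np.array([fc[g] for g in sub["gene"]], dtype=float)
        rows.append(
            {
                "category": category,
                "n_genes": n,
                "mean_weight": float(ws.mean()),
                "mean_weighted_fc": float((fcs * ws).mean()),
            }
        )
    return pd.DataFrame(rows)


def shared_deg_overlap(
    cmap: dict[str, list[str]],
    terms: list[TermSet],
    degs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise shared-DEG counts between categories.

    Returns ``(matrix, gene_table)``: a symmetric category x category
    count matrix (diagonal = category DEG counts) and a per-gene table of
    the categories containing it plus its regulation sign — enough to
    regenerate a chord-style sharing diagram.
    """
    fc = dict(zip(degs["gene"], degs["log2fc"]))
    members = _category_members(cmap, terms)
    categories = sorted(cmap)
    deg_sets = {c: members[c] & fc.keys() for c in categories}

    mat = pd.DataFrame(0, index=categories, columns=categories, dtype=int)
    for i, a in enumerate(categories):
        for b in categories[i:]:
            n = len(deg_sets[a] & deg_sets[b])
            mat.loc[a, b] = n
            mat.loc[b, a] = n

    rows = []
    for gene in sorted(set().union(*deg_sets.values()) if deg_sets else set()):
        cats = [c for c in categories if gene in deg_sets[c]]
        rows.append(
            {
                "gene": gene,
                "categories": ";".join(cats),
                "n_categories": len(cats),
                "regulation": "up" if fc[gene] > 0 else "down",
            }
        )
    gene_table = pd.DataFrame(
        rows, columns=["gene", "categories", "n_categories", "regulation"]
    )
    return mat, gene_table


def top_fraction(
    resolved: dict[str, pd.DataFrame],
    degs: pd.DataFrame,
    fraction: float = 0.1,
) -> pd.DataFrame:
    """Rank each category's weight-bearing DEGs by W and keep the top slice.

    The top ``ceil(fraction * n)`` genes per category are returned, sorted
    by W descending with ties broken by |log2fc| descending and then by
    gene symbol — the machine-readable analogue of a "top 10% key genes"
    table.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction {fraction} outside (0, 1]")
    fc = dict(zip(degs["gene"], degs["log2fc"]))
    rows = []
    for category in sorted(resolved):
        table = resolved[category]
        sub = table[table["gene"].isin(fc.keys())].copy()
        if sub.empty:
            continue
        sub["log2fc"] = [fc[g] for g in sub["gene"]]
        order = sorted(
            sub.itertuples(index=False),
            key=lambda r: (-r.w, -abs(r.log2fc), r.gene),
        )
        k = math.ceil(fraction * len(order))
        for rank, rec in enumerate(order[:k], start=1):
            rows.append(
                {
                    "category": category,
                    "rank": rank,
                    "gene": rec.gene,
                    "log2fc": rec.log2fc,
                    "w": rec.w,
                    "term_id": rec.term_id,
                }
            )
    return pd.DataFrame(
        rows, columns=["category", "rank", "gene", "log2fc", "w", "term_id"]
    )
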