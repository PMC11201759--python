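"""Synthetic datasets with known ground truth for the whole pipeline.

Three generators emulate the pipeline's inputs:

* :func:`simulate_deg_table` — a differential-expression table over a
  gene universe in which a controlled minority of genes is truly
  differential (q-value below 0.05, log2 fold changes from a zero-mean
  normal).  q-values are drawn directly — uniform on [0, 0.05) for DEGs
  and on [0.05, 1] otherwise — because the pipeline never touches read
  counts, so simulating a count model would add nothing.
* :func:`simulate_annotation` — gene sets of controlled size whose DEG
  content is enriched by a chosen odds multiplier, plus a shallow
  parent/child hierarchy (children are subsets of their parents) so that
  deepest-child term selection is exercised.
* :func:`simulate_term_network` — an undirected PPI-style network on a
  term's members, written in the STRING edge-table dialect.  The bulk of
  the graph grows by preferential attachment; each planted hub is the
  sole gateway of a protein-complex-like clique (its satellites have no
  outside edges) and carries extra attraction mass, capped so its
  expected degree is ``hub_degree_factor * mean_degree``.  Nodes that
  attach to a hub close triangles into its complex, the way interactors
  of a complex core do in high-confidence PPI networks.  Hubs therefore
  combine high degree, betweenness, closeness *and* clustering — known
  ground truth for weight-ranking recovery tests.  Edge scores are
  uniform on [0.900, 0.999]: the pipeline thresholds edges on score but
  never weights them.

:func:`simulate_study` composes the three into a full on-disk-ready
study (two DE contrasts, term sets per structure category, one network
per term, category map and truth record).  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ParameterError, TermSet

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "StudyData",
    "simulate_deg_table",
    "simulate_annotation",
    "simulate_term_network",
    "simulate_study",
    "CATEGORIES",
]

#: structure categories used by the bundled synthetic study
CATEGORIES = (
    "mitochondria",
    "endoplasmic_reticulum",
    "nucleus",
    "intracellular_complexes",
)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset.

    ``deg_genes`` are the truly differential genes, ``enriched_terms``
    the term ids generated with a DEG odds multiplier > 1, and
    ``planted_hubs`` maps term ids to the genes seeded as network hubs.
    """

    seed: int
    deg_genes: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)
    planted_hubs: dict[str, set[str]] = field(default_factory=dict)


def simulate_deg_table(
    n_genes: int,
    frac_deg: float,
    effect_sd: float,
    seed: int,
    *,
    null_sd_factor: float = 0.2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a DE table with exactly ``round(frac_deg * n_genes)`` DEGs.

    DEG log2 fold changes are N(0, effect_sd); non-DEG genes get residual
    noise N(0, null_sd_factor * effect_sd).  Returns the table (columns
    ``gene``, ``log2FoldChange``, ``padj`` — the on-disk dialect) and the
    ground truth.
    """
    if n_genes < 10:
        raise ParameterError(f"n_genes must be >= 10, got {n_genes}")
    if not 0.0 < frac_deg < 1.0:
        raise ParameterError(f"frac_deg must be in (0, 1), got {frac_deg}")
    if effect_sd <= 0:
        raise ParameterError(f"effect_sd must be positive, got {effect_sd}")
    n_deg = int(round(frac_deg * n_genes))
    if n_deg < 1:
        raise ParameterError("frac_deg * n_genes must be >= 1")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(1, n_genes + 1)])
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[deg_idx] = True

    log2fc = rng.normal(0.0, null_sd_factor * effect_sd, size=n_genes)
    log2fc[is_deg] = rng.normal(0.0, effect_sd, size=n_deg)
    q = rng.uniform(0.05, 1.0, size=n_genes)
    q[is_deg] = rng.uniform(0.0, 0.05, size=n_deg)

    table = pd.DataFrame(
        {"gene": genes, "log2FoldChange": log2fc, "padj": q}
    )
    truth = SyntheticTruth(seed=seed, deg_genes=set(genes[is_deg]))
    return table, truth


def _weighted_sample(
    rng: np.random.Generator,
    pool: np.ndarray,
    size: int,
    odds: float,
    deg_genes: set[str],
) -> set[str]:
    """Sample ``size`` genes without replacement, DEGs up-weighted by ``odds``."""
    w = np.array([odds if g in deg_genes else 1.0 for g in pool], dtype=float)
    picked = rng.choice(pool, size=size, replace=False, p=w / w.sum())
    return set(picked)


def simulate_annotation(
    universe: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    enriched_terms: int,
    enrichment_odds: float,
    truth: SyntheticTruth,
    seed: int,
) -> tuple[list[TermSet], list[tuple[str, str]]]:
    """Simulate term memberships plus a shallow parent/child hierarchy.

    Terms at even index are sampled from the universe; each term at odd
    index is a child of its predecessor, sampled from the parent's
    members (so the deepest-child retention rule has real work to do).
    The first ``enriched_terms`` terms sample DEGs with the given odds
    multiplier; with ``enrichment_odds = 1`` the construction is null.
    Term ids enriched with odds > 1 are recorded in ``truth``.
    """
    if not universe:
        raise ParameterError("universe is empty")
    if n_terms < 1:
        raise ParameterError(f"n_terms must be positive, got {n_terms}")
    if enriched_terms > n_terms:
        raise ParameterError("enriched_terms exceeds n_terms")
    if enrichment_odds < 1.0:
        raise ParameterError(f"enrichment_odds must be >= 1, got {enrichment_odds}")
    lo, hi = size_range
    if lo < 2 or hi > len(universe) or lo > hi:
        raise ParameterError(
            f"size_range {size_range} outside [2, {len(universe)}]"
        )

    rng = np.random.default_rng(seed)
    pool = np.array(sorted(universe))
    terms: list[TermSet] = []
    hierarchy: list[tuple[str, str]] = []
    for i in range(n_terms):
        odds = enrichment_odds if i < enriched_terms else 1.0
        term_id = f"T{i + 1:04d}"
        if i % 2 == 1:  # child of the preceding term
            parent = terms[-1]
            parent_pool = np.array(sorted(parent.members))
            size = int(rng.integers(lo, min(hi, len(parent_pool)) + 1))
            members = _weighted_sample(rng, parent_pool, size, odds, truth.deg_genes)
            hierarchy.append((parent.term_id, term_id))
            parent.children.add(term_id)
        else:
            size = int(rng.integers(lo, hi + 1))
            members = _weighted_sample(rng, pool, size, odds, truth.deg_genes)
        terms.append(
            TermSet(term_id=term_id, term_name=f"synthetic term {i + 1}", members=members)
        )
        if odds > 1.0:
            truth.enriched_terms.add(term_id)
    return terms, hierarchy


def simulate_term_network(
    term: TermSet,
    mean_degree: float,
    n_hubs: int,
    hub_degree_factor: float,
    seed: int,
    *,
    hubs: list[str] | None = None,
    satellite_pool: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Grow an undirected simple network on a term's members.

    The background graph grows by preferential attachment with
    ``m = round(mean_degree / 2)`` edges per incoming node.  Each planted
    hub is the core of a protein-complex-like clique of about a third of
    its target degree, whose satellite members have no edges outside the
    complex; the hub additionally carries attraction mass, capped once
    its degree reaches ``hub_degree_factor * mean_degree`` so that this
    product is its expected degree.  A newcomer whose first edge lands on
    a hub spends its remaining edges on that hub's satellites, closing
    triangles the way interactors of a complex core do.  Hubs therefore
    stand out simultaneously in degree, betweenness, closeness and
    clustering.

    ``hubs`` may name the hub genes explicitly (they must be members);
    otherwise they are drawn at random.  ``satellite_pool`` optionally
    restricts which members are preferred as complex satellites (the
    study generator passes the non-DEG members, casting satellites as
    unperturbed complex partners).  Returns the edge table in the STRING
    dialect columns (``node1``, ``node2``, ``combined_score`` with scores
    >= 0.900) plus the list of planted hubs.
    """
    members = sorted(term.members)
    n = len(members)
    if n < 3:
        raise ParameterError(f"term {term.term_id!r} has fewer than 3 members")
    if n_hubs >= n:
        raise ParameterError(f"n_hubs {n_hubs} must be < term size {n}")
    if mean_degree <= 0:
        raise ParameterError(f"mean_degree must be positive, got {mean_degree}")
    if hub_degree_factor < 1.0:
        raise ParameterError("hub_degree_factor must be >= 1")

    rng = np.random.default_rng(seed)
    if hubs is None:
        hub_list = (
            sorted(str(g) for g in rng.choice(members, size=n_hubs, replace=False))
            if n_hubs
            else []
        )
    else:
        hub_list = sorted(hubs)
        if len(hub_list) != n_hubs:
            raise ParameterError("len(hubs) must equal n_hubs")
        if not set(hub_list) <= set(members):
            raise ParameterError("hubs must be members of the term")
    hub_set = set(hub_list)

    m = max(1, int(round(mean_degree / 2.0)))
    target = hub_degree_factor * mean_degree

    edges: set[tuple[str, str]] = set()
    degree: dict[str, int] = {g: 0 for g in members}

    def add_edge(a: str, b: str) -> None:
        key = (a, b) if a < b else (b, a)
        if a != b and key not in edges:
            edges.add(key)
            degree[a] += 1
            degree[b] += 1

    # complex cliques: about a third of the hub's target degree, but leave
    # at least half of the non-hub members for the attachment body
    satellites: dict[str, list[str]] = {}
    non_hubs = [g for g in members if g not in hub_set]
    if n_hubs:
        q = max(3, int(round(target / 3.0)))
        q = max(2, min(q, 1 + (n - n_hubs) // (2 * n_hubs)))
        preferred = sorted(set(satellite_pool or ()) & set(non_hubs))
        rng.shuffle(preferred)
        fallback = [g for g in non_hubs if g not in set(preferred)]
        rng.shuffle(fallback)
        queue = preferred + fallback
        for h in hub_list:
            sats = queue[: q - 1]
            queue = queue[q - 1:]
            satellites[h] = sats
            group = [h, *sats]
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    add_edge(a, b)
        rest = queue
    else:
        rest = list(non_hubs)
    rng.shuffle(rest)

    # seed of the preferential-attachment body
    n_seed = min(len(rest), max(m + 1 - n_hubs, 1))
    seed_nodes = rest[:n_seed]
    if hub_list:
        for s in seed_nodes:
            add_edge(s, hub_list[int(rng.integers(n_hubs))])
    else:
        for a, b in zip(seed_nodes, seed_nodes[1:]):
            add_edge(a, b)

    existing = hub_list + seed_nodes
    attraction = {
        h: 0.45 * max(target - (len(satellites.get(h, ())) ), 1.0) for h in hub_list
    }

    def pa_weights(exclude: set[str]) -> np.ndarray:
        w = np.empty(len(existing))
        for i, g in enumerate(existing):
            if g in exclude or (g in hub_set and degree[g] >= target):
                w[i] = 0.0
            else:
                w[i] = degree[g] + attraction.get(g, 1.0)
        return w

    for newcomer in rest[n_seed:]:
        w = pa_weights(set())
        if w.sum() == 0:
            break
        first = str(rng.choice(existing, p=w / w.sum()))
        targets = {first}
        for _ in range(m - 1):
            if first in satellites:
                closing = [s for s in satellites[first] if s not in targets]
                if closing:
                    targets.add(closing[int(rng.integers(len(closing)))])
                    continue
            w = pa_weights(targets)
            if w.sum() == 0:
                break
            targets.add(str(rng.choice(existing, p=w / w.sum())))
        for t in targets:
            add_edge(newcomer, t)
        existing.append(newcomer)

    rows = sorted(edges)
    scores = np.round(rng.uniform(0.900, 0.999, size=len(rows)), 3)
    table = pd.DataFrame(
        {
            "node1": [a for a, _ in rows],
            "node2": [b for _, b in rows],
            "combined_score": scores,
        }
    )
    return table, hub_list


@dataclass
class StudyData:
    """A complete synthetic study, ready to write to disk or analyse."""

    deg_tables: dict[str, pd.DataFrame]  # contrast label -> on-disk dialect table
    truth: SyntheticTruth
    terms: list[TermSet]
    hierarchy: list[tuple[str, str]]
    networks: dict[str, pd.DataFrame]  # term id -> edge table
    category_map: dict[str, list[str]]
    primary_contrast: str


def simulate_study(
    seed: int,
    *,
    n_genes: int = 2000,
    frac_deg: float = 0.15,
    effect_sd: float = 0.6,
    n_term_pairs: int = 4,
    size_range: tuple[int, int] = (150, 250),
    enrichment_odds: float = 6.0,
    mean_degree: float = 6.0,
    n_hubs: int = 2,
    hub_degree_factor: float = 10.0,
    hub_min_abs_fc: float = 0.3,
    contrast_labels: tuple[str, str] = ("ab_vs_cbnr20", "ctrl_vs_ab"),
) -> StudyData:
    """Compose a full two-contrast synthetic study.

    ``n_term_pairs`` parent/child term pairs are generated, all enriched,
    and assigned round-robin to the four structure categories.  Each
    term's network is grown with ``n_hubs`` hubs picked among the term's
    true DEGs with |log2fc| >= ``hub_min_abs_fc`` (parent and child share
    hubs, chosen from the child so they exist in both networks).  The
    first contrast label is the primary one (drives enrichment and term
    selection); the second is an independent companion contrast over the
    same universe.
    """
    n_terms = 2 * n_term_pairs
    primary, secondary = contrast_labels

    table1, truth = simulate_deg_table(n_genes, frac_deg, effect_sd, seed)
    table2, _ = simulate_deg_table(n_genes, frac_deg, effect_sd, seed + 1)
    deg_tables = {primary: table1, secondary: table2}

    universe = list(table1["gene"])
    terms, hierarchy = simulate_annotation(
        universe,
        n_terms=n_terms,
        size_range=size_range,
        enriched_terms=n_terms,
        enrichment_odds=enrichment_odds,
        truth=truth,
        seed=seed + 2,
    )

    fc = dict(zip(table1["gene"], table1["log2FoldChange"]))
    networks: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed + 3)
    for pair in range(n_term_pairs):
        parent, child = terms[2 * pair], terms[2 * pair + 1]
        candidates = sorted(
            g
            for g in child.members & truth.deg_genes
            if abs(fc[g]) >= hub_min_abs_fc
        )
        if len(candidates) < n_hubs:  # fall back to any DEG member
            candidates = sorted(child.members & truth.deg_genes)
        if len(candidates) < n_hubs:
            raise ParameterError(
                f"term {child.term_id!r} has too few DEG members to plant hubs"
            )
        hub_genes = sorted(
            str(g) for g in rng.choice(candidates, size=n_hubs, replace=False)
        )
        for k, term in enumerate((parent, child)):
            edges, planted = simulate_term_network(
                term,
                mean_degree=mean_degree,
                n_hubs=n_hubs,
                hub_degree_factor=hub_degree_factor,
                seed=seed + 10 + 2 * pair + k,
                hubs=hub_genes,
                satellite_pool=term.members - truth.deg_genes,
            )
            networks[term.term_id] = edges
            truth.planted_hubs[term.term_id] = set(planted)

    category_map = {
        CATEGORIES[pair % len(CATEGORIES)]: [] for pair in range(n_term_pairs)
    }
    for pair in range(n_term_pairs):
        cat = CATEGORIES[pair % len(CATEGORIES)]
        category_map[cat].extend(
            [terms[2 * pair].term_id, terms[2 * pair + 1].term_id]
        )

    return StudyData(
        deg_tables=deg_tables,
        truth=truth,
        terms=terms,
        hierarchy=hierarchy,
        networks=networks,
        category_map=category_map,
        primary_contrast=primary,
    )
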