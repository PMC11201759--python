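"""Per-node graph metrics and the topological gene weight W.

Each term's PPI network is treated as an undirected, unweighted simple
graph (edge scores only gate membership).  Six quantities are computed
per node:

* ``bc``  — betweenness centrality, unnormalized shortest-path pair counts;
* ``cce`` — closeness centrality, normalized within the node's connected
  component as ``(V - 1) / sum(distances)``;
* ``nc``  — neighborhood connectivity, the mean degree of the node's
  neighbors;
* ``cco`` — local clustering coefficient in [0, 1];
* ``avp`` — mean shortest-path length from the node to every other node
  of its component;
* ``v``   — the number of vertices of the node's component.

The weight combines them as::

    W = BC * CCe * log2(NC) * CCo**2 - log2(V * AVP)

so that a node must simultaneously be a bottleneck (BC), be close to the
rest of its module (CCe), sit among well-connected neighbors (NC) and in
a locally dense neighborhood (CCo) to score highly, while membership in
a large, sparse component (V * AVP) is penalized.

Because BC, CCe or CCo can legitimately be zero and would annihilate the
product, zeros of those three metrics are substituted per network by the
smallest non-zero value of that metric; when a metric is zero for every
node of a network, 1e-7 (lower than any observed value) is used instead.
NC, AVP and V are never substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import networkx as nx
import pandas as pd

from .io import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMetrics",
    "GeneWeight",
    "ALL_ZERO_FALLBACK",
    "compute_node_metrics",
    "substitute_zeros",
    "weight_formula",
    "compute_weight",
    "score_network",
]

#: replacement used when a substitutable metric is zero on every node
ALL_ZERO_FALLBACK = 1e-7

#: metrics subject to zero substitution
SUBSTITUTABLE = ("bc", "cce", "cco")


@dataclass(frozen=True)
class NodeMetrics:
    gene: str
    bc: float
    cce: float
    nc: float
    cco: float
    avp: float
    v: int
    component_id: int = 0


@dataclass(frozen=True)
class GeneWeight:
    """A gene's topological weight within one term network."""

    gene: str
    term_id: str
    w: float
    substituted: frozenset[str] = frozenset()


def _graph_from_edges(edges) -> nx.Graph:
    if isinstance(edges, pd.DataFrame):
        pairs = zip(edges["node1"], edges["node2"])
    else:
        pairs = ((a, b) for a, b, *_ in edges)
    g = nx.Graph()
    g.add_edges_from(pairs)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def compute_node_metrics(
    edges,
    *,
    betweenness_normalized: bool = False,
    whole_graph_v: bool = False,
) -> list[NodeMetrics]:
    """Compute the six per-node metrics of an edge table.

    ``edges`` is either an ``io.read_string_interactions`` DataFrame or an
    iterable of node pairs.  Distance-based metrics are computed within
    connected components; nodes exist only through edges, so every node
    has degree >= 1.  Results are sorted by gene symbol.
    """
    g = _graph_from_edges(edges)
    if g.number_of_nodes() == 0:
        logger.warning("empty network: no metrics computed")
        return []

    bc = nx.betweenness_centrality(g, normalized=betweenness_normalized)
    cce = nx.closeness_centrality(g, wf_improved=False)
    nc = nx.average_neighbor_degree(g)
    cco = nx.clustering(g)

    components = sorted(nx.connected_components(g), key=min)
    out: list[NodeMetrics] = []
    for comp_id, comp in enumerate(components):
        sub = g.subgraph(comp)
        n_comp = len(comp)
        for node in comp:
            dists = nx.single_source_shortest_path_length(sub, node)
            total = sum(dists.values())
            avp = total / (n_comp - 1) if n_comp > 1 else 0.0
            out.append(
                NodeMetrics(
                    gene=node,
                    bc=float(bc[node]),
                    cce=float(cce[node]),
                    nc=float(nc[node]),
                    cco=float(cco[node]),
                    avp=float(avp),
                    v=n_comp if not whole_graph_v else g.number_of_nodes(),
                    component_id=comp_id,
                )
            )
    out.sort(key=lambda m: m.gene)
    return out


def substitute_zeros(
    metrics: list[NodeMetrics],
) -> tuple[list[NodeMetrics], dict[str, frozenset[str]]]:
    """Replace zero BC/CCe/CCo values per network.

    Zeros of each substitutable metric are replaced by the minimum
    non-zero value of that metric across the network; if the metric is
    zero everywhere, by :data:`ALL_ZERO_FALLBACK`.  Returns the new
    metrics plus a map gene -> names of substituted metrics.  The
    operation is idempotent.
    """
    if not metrics:
        return [], {}
    replacements: dict[str, float] = {}
    for name in SUBSTITUTABLE:
        nonzero = [getattr(m, name) for m in metrics if getattr(m, name) > 0.0]
        replacements[name] = min(nonzero) if nonzero else ALL_ZERO_FALLBACK

    out: list[NodeMetrics] = []
    log: dict[str, frozenset[str]] = {}
    for m in metrics:
        subs = {name for name in SUBSTITUTABLE if getattr(m, name) == 0.0}
        if subs:
            m = replace(m, **{name: replacements[name] for name in subs})
        out.append(m)
        log[m.gene] = frozenset(subs)
    return out, log


def weight_formula(
    bc: float, cce: float, nc: float, cco: float, avp: float, v: float
) -> float:
    """W = BC * CCe * log2(NC) * CCo^2 - log2(V * AVP)."""
    return bc * cce * math.log2(nc) * cco**2 - math.log2(v * avp)


def compute_weight(
    m: NodeMetrics,
    term_id: str = "",
    substituted: frozenset[str] = frozenset(),
) -> GeneWeight:
    """Evaluate W for one node (zero substitution already applied)."""
    if m.nc < 1:
        raise ParameterError(
            f"node {m.gene!r}: neighborhood connectivity {m.nc} < 1"
        )
    if m.v * m.avp <= 0:
        raise ParameterError(f"node {m.gene!r}: V * AVP = {m.v * m.avp} <= 0")
    w = weight_formula(m.bc, m.cce, m.nc, m.cco, m.avp, m.v)
    if not math.isfinite(w):
        raise ParameterError(f"node {m.gene!r}: non-finite weight")
    return GeneWeight(gene=m.gene, term_id=term_id, w=w, substituted=substituted)


def score_network(
    edges,
    term_id: str = "",
    *,
    betweenness_normalized: bool = False,
    whole_graph_v: bool = False,
) -> pd.DataFrame:
    """Metrics -> zero substitution -> weights for one term network.

    Returns one row per node: gene, the six metrics (after substitution),
    component id, a ``substituted`` flag column (comma-joined metric
    names) and the weight ``w``.
    """
    raw = compute_node_metrics(
        edges,
        betweenness_normalized=betweenness_normalized,
        whole_graph_v=whole_graph_v,
    )
    subbed, sub_log = substitute_zeros(raw)
    rows = []
    for m in subbed:
        gw = compute_weight(m, term_id=term_id, substituted=sub_log[m.gene])
        rows.append(
            {
                "term_id": term_id,
                "gene": m.gene,
                "bc": m.bc,
                "cce": m.cce,
                "nc": m.nc,
                "cco": m.cco,
                "avp": m.avp,
                "v": m.v,
                "component_id": m.component_id,
                "substituted": ",".join(sorted(gw.substituted)),
                "w": gw.w,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "gene", "bc", "cce", "nc", "cco",
            "avp", "v", "component_id", "substituted", "w",
        ],
    )
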