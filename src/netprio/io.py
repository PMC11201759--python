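"""Readers and writers for the pipeline's plain-text formats.

Three input formats are supported:

* a differential-expression table (TSV with gene symbol, log2 fold change
  and BH-adjusted p-value columns, e.g. a DESeq2 result export),
* gene-set memberships in GMT (``term_id <TAB> term_name <TAB> gene ...``)
  plus an optional two-column parent/child hierarchy table,
* protein–protein interaction edge tables in the STRING
  ``string_interactions.tsv`` dialect (``#node1``, ``node2``,
  ``combined_score``).

Gene identity is by symbol, case-folded to upper case, so that DE tables
and STRING preferred names join on a common key.  All writers emit
deterministic, byte-stable TSV/JSON so a rerun of the same analysis
produces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ParameterError",
    "TermSet",
    "read_deg_table",
    "read_gmt",
    "read_hierarchy",
    "read_string_interactions",
    "write_deg_table",
    "write_gmt",
    "write_hierarchy",
    "write_string_interactions",
    "write_manifest",
    "file_sha256",
]

#: canonical in-memory column names of a DEG table
DEG_COLUMNS = ["gene", "log2fc", "qvalue"]

#: on-disk default column names (DESeq2-style)
DEFAULT_GENE_COL = "gene"
DEFAULT_FC_COL = "log2FoldChange"
DEFAULT_Q_COL = "padj"

_MISSING = {"", "NA", "N/A", "NaN", "nan", "NAN", "null", "None"}


class FormatError(ValueError):
    """An input file violates its format contract."""


class ParameterError(ValueError):
    """A parameter is outside its documented range."""


@dataclass
class TermSet:
    """A named gene set (e.g. a GO cellular-component term).

    ``children`` holds direct child term ids from the hierarchy table;
    ``category`` is the subcellular-structure label assigned by the
    category map (filled in by the aggregation stage).
    """

    term_id: str
    term_name: str
    members: set[str]
    children: set[str] = field(default_factory=set)
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.term_id:
            raise FormatError("term_id must be non-empty")
        if not self.members:
            raise FormatError(f"term {self.term_id!r} has no members")


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------

def _to_float(raw: object, *, path: str, line: int, col: str) -> float | None:
    """Parse one numeric cell; None for missing; FormatError otherwise."""
    if raw is None:
        return None
    s = str(raw).strip()
    if s in _MISSING:
        return None
    try:
        return float(s)
    except ValueError:
        raise FormatError(
            f"{path}: line {line}: non-numeric value {s!r} in column {col!r}"
        ) from None


def read_deg_table(
    path: str | Path,
    q_threshold: float | None = 0.05,
    *,
    gene_col: str = DEFAULT_GENE_COL,
    fc_col: str = DEFAULT_FC_COL,
    q_col: str = DEFAULT_Q_COL,
    uppercase: bool = True,
) -> pd.DataFrame:
    """Read a differential-expression table and keep q < ``q_threshold``.

    Rows with a missing adjusted p-value are treated as not significant
    and dropped (DESeq2 emits NA under independent filtering).  The
    threshold is a strict inequality; pass ``q_threshold=None`` to keep
    every record with a defined q-value (e.g. to recover the tested gene
    universe).

    Returns a DataFrame with columns ``gene``, ``log2fc``, ``qvalue``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (gene_col, fc_col, q_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    genes: list[str] = []
    fcs: list[float] = []
    qs: list[float] = []
    for idx in range(len(df)):
        line = idx + 2  # 1-based, after the header
        gene = df.iloc[idx][gene_col].strip()
        if not gene or gene in _MISSING:
            raise FormatError(f"{path}: line {line}: empty gene symbol")
        fc = _to_float(df.iloc[idx][fc_col], path=str(path), line=line, col=fc_col)
        q = _to_float(df.iloc[idx][q_col], path=str(path), line=line, col=q_col)
        if fc is None:
            raise FormatError(
                f"{path}: line {line}: missing fold change for gene {gene!r}"
            )
        if q is None:
            continue  # NA adjusted p: not significant, drop
        if not 0.0 <= q <= 1.0:
            raise FormatError(
                f"{path}: line {line}: q-value {q} outside [0, 1]"
            )
        genes.append(gene.upper() if uppercase else gene)
        fcs.append(fc)
        qs.append(q)

    out = pd.DataFrame({"gene": genes, "log2fc": fcs, "qvalue": qs})
    dup = out["gene"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicated gene symbols: "
            f"{sorted(out.loc[dup, 'gene'].unique())[:5]}"
        )
    if q_threshold is not None:
        out = out[out["qvalue"] < q_threshold].reset_index(drop=True)
    logger.info("%s: retained %d records (q_threshold=%s)", path, len(out), q_threshold)
    return out


def write_deg_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    gene_col: str = DEFAULT_GENE_COL,
    fc_col: str = DEFAULT_FC_COL,
    q_col: str = DEFAULT_Q_COL,
) -> None:
    """Write a DEG table (canonical columns) under on-disk column names."""
    out = df.rename(columns={"gene": gene_col, "log2fc": fc_col, "qvalue": q_col})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT gene sets and term hierarchy
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, *, uppercase: bool = True) -> list[TermSet]:
    """Read gene sets from a GMT file (>= 3 tab-separated fields per line)."""
    path = Path(path)
    terms: list[TermSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            term_id, term_name = fields[0].strip(), fields[1].strip()
            if term_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            members = {
                (g.strip().upper() if uppercase else g.strip())
                for g in fields[2:]
                if g.strip()
            }
            if not members:
                raise FormatError(f"{path}: line {lineno}: term {term_id!r} has no genes")
            terms.append(TermSet(term_id=term_id, term_name=term_name, members=members))
    return terms


def write_gmt(terms: list[TermSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.members)]) + "\n")


def read_hierarchy(path: str | Path, terms: list[TermSet]) -> list[tuple[str, str]]:
    """Read a 2-column parent/child TSV and fill ``TermSet.children``.

    Every id must exist in ``terms`` and the relation must be acyclic.
    """
    path = Path(path)
    known = {t.term_id: t for t in terms}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["parent_id", "child_id"]:
                continue  # optional header
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            parent, child = fields[0].strip(), fields[1].strip()
            for tid in (parent, child):
                if tid not in known:
                    raise FormatError(
                        f"{path}: line {lineno}: term id {tid!r} not present in the GMT"
                    )
            edges.append((parent, child))
    dag = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise FormatError(f"{path}: hierarchy contains a cycle: {cycle}")
    for parent, child in edges:
        known[parent].children.add(child)
    return edges


def write_hierarchy(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("parent_id\tchild_id\n")
        for parent, child in edges:
            fh.write(f"{parent}\t{child}\n")


# ---------------------------------------------------------------------------
# STRING interaction tables
# ---------------------------------------------------------------------------

def read_string_interactions(
    path: str | Path,
    score_threshold: float = 0.9,
    *,
    uppercase: bool = True,
) -> pd.DataFrame:
    """Read a ``string_interactions.tsv`` edge table.

    Edges below ``score_threshold`` are dropped, (A, B)/(B, A) duplicates
    collapsed and self-loops removed.  Returns a DataFrame with columns
    ``node1``, ``node2``, ``combined_score`` where ``node1 < node2``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lstrip("#"): c for c in df.columns}
    for need in ("node1", "node2", "combined_score"):
        if need not in cols:
            raise FormatError(f"{path}: missing required column {need!r}")

    seen: set[tuple[str, str]] = set()
    rows: list[tuple[str, str, float]] = []
    for idx in range(len(df)):
        line = idx + 2
        a = df.iloc[idx][cols["node1"]].strip()
        b = df.iloc[idx][cols["node2"]].strip()
        if uppercase:
            a, b = a.upper(), b.upper()
        score = _to_float(
            df.iloc[idx][cols["combined_score"]],
            path=str(path), line=line, col="combined_score",
        )
        if score is None:
            raise FormatError(f"{path}: line {line}: missing combined_score")
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{path}: line {line}: combined_score {score} outside [0, 1]"
            )
        if a == b:
            logger.warning("%s: line %d: dropping self-loop on %r", path, line, a)
            continue
        if score < score_threshold:
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        rows.append((*key, score))

    rows.sort()
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def write_string_interactions(edges: pd.DataFrame, path: str | Path) -> None:
    """Write an edge table in the STRING dialect (``#node1`` header)."""
    out = edges.rename(columns={"node1": "#node1"})
    out.to_csv(path, sep="\t", index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write the JSON run manifest with stable key order."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
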