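"""Reading, merging and exporting protein-protein interaction networks.

Interaction datasets arrive as tab-delimited edge lists in several dialects
(HPRD flat files, BioGRID tab layouts, plain two-column files). This module
parses them into raw symbol-pair lists, merges the lists into a single
undirected simple :class:`networkx.Graph`, and writes the standard exchange
formats (SIF, GraphML, attribute TSVs).

Gene symbols are matched case-insensitively — curation databases disagree on
capitalization — with the first-seen casing preserved for display.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeListDialect",
    "PLAIN",
    "HPRD",
    "BIOGRID",
    "DIALECTS",
    "read_edge_list",
    "merge_networks",
    "export_sif",
    "export_graphml",
    "import_graphml",
    "export_node_attributes",
    "export_edge_attributes",
]


class ParseError(ValueError):
    """Raised in strict mode when an edge-list row cannot be parsed."""


@dataclass(frozen=True)
class EdgeListDialect:
    """Column layout of one tab-delimited interaction file format.

    Parameters
    ----------
    name
        Identifier of the dialect (``plain``, ``hprd``, ``biogrid``).
    col_a, col_b
        Zero-based column indices of the two interactor symbols.
    comment_prefix
        Lines starting with this prefix are ignored.
    skip_rows
        Header rows to skip before data starts.
    organism_cols
        For BioGRID-style files: column indices holding the organism
        taxonomy id of each interactor; rows where either differs from
        ``organism_value`` are dropped.
    organism_value
        Taxonomy id to keep (human = ``"9606"``).
    """

    name: str
    col_a: int
    col_b: int
    comment_prefix: str = "#"
    skip_rows: int = 0
    organism_cols: tuple[int, int] | None = None
    organism_value: str | None = None

    def __post_init__(self) -> None:
        if self.col_a == self.col_b:
            raise ValueError("the two interactor columns must differ")


#: Two-column symbol pairs, no header.
PLAIN = EdgeListDialect("plain", 0, 1)
#: HPRD binary-interaction flat file: symbols in columns 0 and 3.
HPRD = EdgeListDialect("hprd", 0, 3)
#: BioGRID tab2 layout: official symbols in columns 7/8, organism ids in
#: 15/16. Column order drifted across releases, so indices are configurable
#: by constructing a custom dialect.
BIOGRID = EdgeListDialect(
    "biogrid", 7, 8, skip_rows=1, organism_cols=(15, 16), organism_value="9606"
)

DIALECTS: dict[str, EdgeListDialect] = {d.name: d for d in (PLAIN, HPRD, BIOGRID)}


def read_edge_list(
    path: str | Path,
    dialect: EdgeListDialect = PLAIN,
    strict: bool = False,
) -> list[tuple[str, str]]:
    """Parse an interaction file into an ordered list of symbol pairs.

    No deduplication is applied — the output is the file verbatim, minus
    comments, skipped headers, organism-filtered rows and (in lenient mode)
    malformed rows.
    """
    pairs: list[tuple[str, str]] = []
    needed = max(
        dialect.col_a, dialect.col_b, *(dialect.organism_cols or (0,))
    )
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if lineno <= dialect.skip_rows:
                continue
            if not row or row[0].startswith(dialect.comment_prefix):
                continue
            if len(row) <= needed or not row[dialect.col_a].strip() or not row[dialect.col_b].strip():
                msg = f"{path}:{lineno}: malformed row ({len(row)} fields)"
                if strict:
                    raise ParseError(msg)
                logger.warning("skipping %s", msg)
                continue
            if dialect.organism_cols is not None:
                ca, cb = dialect.organism_cols
                if (
                    row[ca].strip() != dialect.organism_value
                    or row[cb].strip() != dialect.organism_value
                ):
                    continue
            pairs.append((row[dialect.col_a].strip(), row[dialect.col_b].strip()))
    return pairs


def merge_networks(
    *pair_lists: Iterable[tuple[str, str]],
    sources: Sequence[str] | None = None,
) -> nx.Graph:
    """Merge raw pair lists into one undirected simple graph.

    Duplicate edges (including reversed pairs) collapse to one; self-loops
    are dropped; nodes left isolated after loop removal are removed. Symbols
    are matched case-insensitively, keeping the first-seen casing. Each edge
    carries a ``provenance`` attribute naming the source list(s) it came
    from (comma-joined, sorted).
    """
    lists = list(pair_lists)
    if not lists:
        raise ValueError("merge_networks needs at least one pair list")
    if sources is None:
        sources = [f"source{i + 1}" for i in range(len(lists))]
    if len(sources) != len(lists):
        raise ValueError("one source label per pair list required")

    g = nx.Graph()
    display: dict[str, str] = {}  # uppercase key -> first-seen casing

    def canon(symbol: str) -> str:
        key = symbol.upper()
        if key not in display:
            display[key] = symbol
        return display[key]

    provenance: dict[frozenset[str], set[str]] = {}
    for src, pairs in zip(sources, lists):
        for a, b in pairs:
            ca, cb = canon(a), canon(b)
            if ca == cb:
                continue  # self-interaction, redundant
            g.add_edge(ca, cb)
            provenance.setdefault(frozenset((ca, cb)), set()).add(src)

    for (u, v), srcs in ((tuple(k), v) for k, v in provenance.items()):
        g.edges[u, v]["provenance"] = ",".join(sorted(srcs))

    isolated = list(nx.isolates(g))
    g.remove_nodes_from(isolated)
    return g


def export_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write the edge list in Cytoscape SIF format (node TAB pp TAB node)."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{relation}\t{b}\n")


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """Write GraphML with all node/edge attributes; lossless round-trip."""
    nx.write_graphml(g, path, infer_numeric_types=False)


def import_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML file back into a graph."""
    return nx.read_graphml(path)


def export_node_attributes(g: nx.Graph, path: str | Path) -> None:
    """Write one TSV row per node with all its attributes (union of keys)."""
    keys = sorted({k for _, d in g.nodes(data=True) for k in d})
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(keys) + "\n")
        for n in sorted(g.nodes()):
            vals = [_fmt(g.nodes[n].get(k)) for k in keys]
            fh.write(str(n) + "\t" + "\t".join(vals) + "\n")


def export_edge_attributes(g: nx.Graph, path: str | Path) -> None:
    """Write one TSV row per edge with all its attributes."""
    keys = sorted({k for _, _, d in g.edges(data=True) for k in d})
    with open(path, "w") as fh:
        fh.write("source\ttarget\t" + "\t".join(keys) + "\n")
        for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((u, v))
            vals = [_fmt(g.edges[a, b].get(k)) for k in keys]
            fh.write(f"{a}\t{b}\t" + "\t".join(vals) + "\n")


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)
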