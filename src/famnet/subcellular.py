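"""Subcellular layering, exhaustive geodesic enumeration, and flow classing.

Proteins are stratified into seven subcellular layers — secreted, membrane,
cytoplasm, secreted/nucleus, membrane/nucleus, cytoplasm/nucleus, nucleus —
and every shortest path between two chosen endpoints is enumerated from the
BFS predecessor DAG. Each path is classified by how its layer ranks evolve:
monotone non-decreasing toward the nucleus is "inward" (the
extracellular → cytoplasm → nucleus signaling flow), non-increasing is
"outward", anything else "mixed". A barycenter-based layered layout places
the nodes on the seven rows without touching the edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "LAYERS",
    "LAYER_RANK",
    "PathRecord",
    "load_localization_vocabulary",
    "read_localizations",
    "assign_layers",
    "all_shortest_paths",
    "classify_flow",
    "layered_layout",
    "write_path_report",
]

#: The seven layers, ordered from the extracellular space to the nucleus.
LAYERS = (
    "secreted",
    "membrane",
    "cytoplasm",
    "secreted/nucleus",
    "membrane/nucleus",
    "cytoplasm/nucleus",
    "nucleus",
)

#: Monotone ranks for flow classification; the three dual layers sit
#: between cytoplasm and nucleus.
LAYER_RANK = {
    "secreted": 0.0,
    "membrane": 1.0,
    "cytoplasm": 2.0,
    "secreted/nucleus": 2.5,
    "membrane/nucleus": 2.5,
    "cytoplasm/nucleus": 2.5,
    "nucleus": 3.0,
}

_BASE_ORDER = ("secreted", "membrane", "cytoplasm")


class PathOverflowError(RuntimeError):
    """More geodesics than the enumeration cap allows."""


@dataclass(frozen=True)
class PathRecord:
    """One geodesic with per-node layer labels and its flow class."""

    nodes: tuple[str, ...]
    layers: tuple[str | None, ...]
    flow_class: str

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    def __str__(self) -> str:
        return " -> ".join(self.nodes)


def load_localization_vocabulary() -> dict[str, str]:
    """Packaged mapping of localization terms to the 4 base compartments."""
    vocab = {}
    with resources.files("famnet.data").joinpath("localization_vocabulary.tsv").open() as fh:
        next(fh)
        for line in fh:
            term, compartment = line.rstrip("\n").split("\t")
            vocab[term.lower()] = compartment
    return vocab


def read_localizations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: protein TAB localization term (one term per row)."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        protein, term = line.split("\t")[:2]
        out.setdefault(protein, set()).add(term)
    return out


def assign_layers(
    g: nx.Graph,
    annotations: dict[str, set[str]],
    vocabulary: dict[str, str] | None = None,
) -> dict[str, str]:
    """Collapse localization terms into one of the 7 layers per protein.

    Terms map to the base compartments secreted / membrane / cytoplasm /
    nucleus via the vocabulary; a nucleus annotation combined with one
    other base yields the corresponding dual layer (the base nearest the
    nucleus wins when several apply). Proteins with no mappable term get
    the attribute ``layer="unknown"`` and are excluded from flow classes.
    The assignment is also written onto the graph as a ``layer`` node
    attribute. A term may already be one of the 7 layer labels, in which
    case it is used directly.
    """
    if vocabulary is None:
        vocabulary = load_localization_vocabulary()
    layer_of: dict[str, str] = {}
    for node in g.nodes():
        terms = annotations.get(str(node), set())
        bases: set[str] = set()
        direct: str | None = None
        for t in terms:
            tl = t.lower()
            if tl in vocabulary:
                bases.add(vocabulary[tl])
            elif tl in LAYER_RANK:
                direct = tl
            else:
                logger.debug("unmapped localization term %r for %s", t, node)
        if direct is not None and not bases:
            layer = direct
        elif not bases:
            layer = "unknown"
        elif "nucleus" in bases:
            others = [b for b in _BASE_ORDER if b in bases]
            layer = f"{others[-1]}/nucleus" if others else "nucleus"
        else:
            # innermost compartment annotated
            layer = [b for b in _BASE_ORDER if b in bases][-1]
        layer_of[str(node)] = layer
        g.nodes[node]["layer"] = layer
    return layer_of


def all_shortest_paths(
    g: nx.Graph,
    source: str,
    target: str,
    layers: dict[str, str] | None = None,
    cap: int = 10_000,
) -> list[PathRecord]:
    """Every distinct geodesic from source to target.

    A breadth-first search from the source builds the shortest-path
    predecessor DAG; all paths are read off it by backward traversal, so
    each returned path's edge count equals the BFS distance. Paths are
    sorted lexicographically by node symbols. A disconnected pair yields
    an empty list (logged); exceeding ``cap`` paths raises
    :class:`PathOverflowError`.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if not g.has_node(node):
            raise KeyError(f"node {node!r} not in graph")
    # BFS predecessor DAG
    dist = {source: 0}
    preds: dict[str, list[str]] = {source: []}
    frontier = [source]
    while frontier and target not in dist:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        frontier = nxt
    if target not in dist:
        logger.info("no path between %s and %s", source, target)
        return []

    paths: list[tuple[str, ...]] = []

    def backtrack(node: str, suffix: tuple[str, ...]) -> None:
        if node == source:
            paths.append((source,) + suffix)
            if len(paths) > cap:
                raise PathOverflowError(f"more than {cap} shortest paths")
            return
        for p in preds[node]:
            backtrack(p, (node,) + suffix)

    backtrack(target, ())
    paths.sort()
    layers = layers or {
        str(n): d["layer"] for n, d in g.nodes(data=True) if "layer" in d
    }
    records = []
    for p in paths:
        lay = tuple(layers.get(n) for n in p)
        records.append(PathRecord(nodes=p, layers=lay, flow_class=_flow(lay)))
    return records


def _flow(layers: tuple[str | None, ...]) -> str:
    if any(l is None or l == "unknown" or l not in LAYER_RANK for l in layers):
        return "unknown"
    ranks = [LAYER_RANK[l] for l in layers]  # type: ignore[index]
    inward = all(a <= b for a, b in zip(ranks, ranks[1:]))
    outward = all(a >= b for a, b in zip(ranks, ranks[1:]))
    if inward and outward:
        return "inward"  # constant-rank path; treated as inward by convention
    if inward:
        return "inward"
    if outward:
        return "outward"
    return "mixed"


def classify_flow(record: PathRecord) -> str:
    """Flow class of a path: inward, outward, mixed or unknown."""
    return _flow(record.layers)


def layered_layout(
    g: nx.Graph,
    layer_of: dict[str, str],
    iterations: int = 50,
    spacing: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Deterministic pathway-style layout on the 7 layer rows.

    Rows follow the layer order top (secreted) to bottom (nucleus), with
    an extra bottom row for unknowns. x-positions start in lexicographic
    node order and relax to the barycenter of each node's neighbors,
    iterated with per-row rescaling to keep unit spacing; ties break
    lexicographically, so permuting the input order cannot change the
    result. Edges are untouched.
    """
    rows = list(LAYERS) + ["unknown"]
    row_y = {layer: -float(i) for i, layer in enumerate(rows)}
    by_row: dict[str, list[str]] = {r: [] for r in rows}
    for node in sorted(g.nodes(), key=str):
        by_row[layer_of.get(str(node), "unknown")].append(str(node))
    x: dict[str, float] = {}
    for r in rows:
        for i, node in enumerate(by_row[r]):
            x[node] = float(i) * spacing
    for _ in range(iterations):
        new_x = dict(x)
        for node in sorted(g.nodes(), key=str):
            nbrs = list(g.neighbors(node))
            if nbrs:
                new_x[str(node)] = sum(x[str(w)] for w in nbrs) / len(nbrs)
        # keep unit spacing within each row, preserving barycenter order
        for r in rows:
            ordered = sorted(by_row[r], key=lambda n: (new_x[n], n))
            for i, node in enumerate(ordered):
                new_x[node] = float(i) * spacing
        if new_x == x:
            break
        x = new_x
    return {n: (x[str(n)], row_y[layer_of.get(str(n), "unknown")]) for n in g.nodes()}


def write_path_report(records: list[PathRecord], path: str | Path) -> None:
    """One row per path: rank, arrow-joined nodes, length, flow class."""
    with open(path, "w") as fh:
        fh.write("no\tpath\tlength\tflow_class\n")
        for i, rec in enumerate(records, start=1):
            fh.write(f"{i}\t{rec}\t{rec.length}\t{rec.flow_class}\n")
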