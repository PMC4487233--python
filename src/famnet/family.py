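"""Seed-family mapping and first-neighbor subnetwork extraction.

A protein family of interest ("seed" proteins) is mapped onto a parental
interaction network; the family subnetwork is the induced subgraph on the
mapped seeds plus every protein interacting directly with a seed. All edges
among that node set are kept — including neighbor–neighbor edges — matching
the "first neighbors of selected nodes, all edges" extraction convention.
Self-loops, duplicate edges and isolated nodes are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import pandas as pd

__all__ = [
    "SeedSet",
    "SubnetworkCensus",
    "map_seeds",
    "extract_first_neighbor_subnetwork",
    "subnetwork_census",
    "read_seed_list",
    "load_family_table",
]


@dataclass
class SeedSet:
    """Family gene symbols, split into mapped and unmapped against a graph.

    ``unmapped`` holds the seeds with no node (hence no reported
    interaction) in the parental network; they are excluded from the
    subnetwork because isolated nodes are pruned.
    """

    symbols: list[str]
    unmapped: list[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("seed set must be non-empty")
        extra = set(self.unmapped) - set(self.symbols)
        if extra:
            raise ValueError(f"unmapped symbols not in seed list: {sorted(extra)}")

    @property
    def mapped(self) -> list[str]:
        un = set(self.unmapped)
        return [s for s in self.symbols if s not in un]


class SubnetworkCensus(NamedTuple):
    nodes: int
    edges: int
    seeds: int
    neighbors: int


def map_seeds(parent: nx.Graph, symbols: list[str]) -> SeedSet:
    """Match seed symbols to parental-graph nodes, case-insensitively.

    The returned :class:`SeedSet` carries the graph's own casing for
    mapped seeds and the input casing for unmapped ones.
    """
    lookup = {str(n).upper(): n for n in parent.nodes()}
    mapped, unmapped = [], []
    for s in symbols:
        node = lookup.get(s.upper())
        if node is None:
            unmapped.append(s)
        else:
            mapped.append(str(node))
    return SeedSet(symbols=mapped + unmapped, unmapped=unmapped)


def extract_first_neighbor_subnetwork(parent: nx.Graph, seeds: SeedSet) -> nx.Graph:
    """Induced subgraph on mapped seeds and their direct neighbors.

    Every parental edge with both endpoints inside the node set is kept,
    so neighbor–neighbor edges survive. Self-loops are removed, and nodes
    isolated afterwards are dropped. Each surviving node gets a boolean
    ``is_seed`` attribute.
    """
    mapped = [s for s in seeds.mapped if parent.has_node(s)]
    if not mapped:
        raise ValueError(
            "no seed maps to the parental network; unmapped: "
            + ", ".join(sorted(seeds.unmapped))
        )
    node_set: set = set(mapped)
    for s in mapped:
        node_set.update(parent.neighbors(s))
    sub = parent.subgraph(node_set).copy()
    sub.remove_edges_from(nx.selfloop_edges(sub))
    sub.remove_nodes_from(list(nx.isolates(sub)))
    seed_set = set(mapped)
    for n in sub.nodes():
        sub.nodes[n]["is_seed"] = n in seed_set
    return sub


def subnetwork_census(g: nx.Graph) -> SubnetworkCensus:
    """Node/edge/seed/neighbor counts of an extracted subnetwork."""
    seeds = sum(1 for _, d in g.nodes(data=True) if d.get("is_seed"))
    return SubnetworkCensus(
        nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        seeds=seeds,
        neighbors=g.number_of_nodes() - seeds,
    )


def read_seed_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    if not out:
        raise ValueError(f"no seed symbols found in {path}")
    return out


def load_family_table() -> pd.DataFrame:
    """The curated human lipocalin family table (37 records).

    Columns: ``symbol``, ``name``, ``gene_id``, ``chromosome``. This is the
    packaged seed list for the worked lipocalin analysis; 23 of the 37 have
    reported interactions in the merged HPRD+BioGRID parental network.
    """
    with resources.files("famnet.data").joinpath("lipocalin_family.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"gene_id": int})
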