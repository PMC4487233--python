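"""Packaged worked-example data: the curated family table and path table.

Both tables are tiny curated text fixtures shipped inside the package so
the worked lipocalin example runs without any download: the 37-member
human lipocalin family table, and the 20 published signaling paths from
LCN2 to RB1 whose consecutive protein pairs reconstruct the relevant
corner of the family subnetwork.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from .family import load_family_table

__all__ = ["load_family_table", "load_lcn2_rb1_paths", "paths_to_graph"]


def load_lcn2_rb1_paths() -> list[tuple[str, ...]]:
    """The 20 curated LCN2 → RB1 signaling paths, as node tuples."""
    with resources.files("famnet.data").joinpath("lcn2_rb1_paths.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [tuple(p.split(" -> ")) for p in df["path"]]


def paths_to_graph(paths: list[tuple[str, ...]]) -> nx.Graph:
    """Union of the consecutive node pairs of a path list, as a simple graph."""
    g = nx.Graph()
    for path in paths:
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b)
    return g
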