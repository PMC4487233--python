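"""Network topology statistics and the power-law degree-distribution fit.

Implements the NetworkAnalyzer-style statistics used to characterize
interaction networks as scale-free small worlds: the node-degree histogram
P(k) with a log-log least-squares power-law fit ``y = beta * k**a`` scored
by R², plus diameter, density, centralization, heterogeneity, clustering
coefficients, closeness centrality, topological coefficients and
neighborhood connectivity.

Conventions, fixed for reproducibility:

* The power-law fit is ordinary least squares of ``log(count)`` on
  ``log(k)`` over unbinned counts with degree >= 1 — the convention under
  which the customary R² quality score is meaningful — not a
  maximum-likelihood tail fit.
* Heterogeneity uses the population standard deviation of the degrees.
* Diameter and closeness are component-relative; disconnected pairs
  contribute nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "TopologySummary",
    "degree_distribution",
    "fit_power_law",
    "clustering_coefficients",
    "summary_statistics",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Exact histogram of node degrees: (k, number of nodes with degree k).

    Only degrees >= 1 are recorded; k values are distinct and ascending.
    """

    points: tuple[tuple[int, int], ...]

    @property
    def k(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of count = beta * k**a on log-log axes."""

    a: float
    beta: float
    r_squared: float


@dataclass
class TopologySummary:
    diameter: int
    density: float
    centralization: float
    heterogeneity: float
    mean_clustering: float
    node_table: pd.DataFrame  # closeness, clustering, topological, neighborhood connectivity


def degree_distribution(g: nx.Graph) -> DegreeDistribution:
    """Histogram of node degrees, excluding isolated (degree-0) nodes."""
    counts: dict[int, int] = {}
    for _, k in g.degree():
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    return DegreeDistribution(tuple(sorted(counts.items())))


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Fit ``count = beta * k**a`` by OLS on the log-log points.

    ``a`` is the slope and ``beta = exp(intercept)``; R² is the coefficient
    of determination of the straight line on log-log axes. A distribution
    whose log-counts have zero variance admits a perfect horizontal line,
    reported as R² = 1 with a warning.
    """
    if len(dist.points) < 2:
        raise ValueError("power-law fit needs at least 2 distinct degrees")
    x = np.log(dist.k)
    y = np.log(dist.counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn(
            "degree counts all equal: R^2 reported as 1 by convention",
            stacklevel=2,
        )
        r2 = 1.0
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(a=float(slope), beta=float(np.exp(intercept)), r_squared=r2)


def clustering_coefficients(
    g: nx.Graph,
) -> tuple[pd.Series, float, pd.Series]:
    """Per-node clustering coefficient, its mean, and the mean-by-degree curve.

    The coefficient of node *n* with degree k >= 2 is
    ``2 * triangles(n) / (k * (k - 1))``; nodes with k < 2 score 0. The
    mean is taken over nodes with k >= 2 (the nodes where the quantity is
    defined); the curve averages the coefficient within each degree class,
    the diagnostic whose decline with k signals hierarchical structure.
    """
    cc = pd.Series(nx.clustering(g), dtype=float).sort_index()
    deg = pd.Series(dict(g.degree())).sort_index()
    eligible = cc[deg >= 2]
    mean_cc = float(eligible.mean()) if len(eligible) else 0.0
    curve = cc.groupby(deg).mean()
    curve.index.name = "degree"
    return cc, mean_cc, curve


def _topological_coefficient(g: nx.Graph, n) -> float:
    kn = g.degree(n)
    if kn == 0:
        return 0.0
    nbrs = set(g.neighbors(n))
    partners: dict[object, int] = {}
    for w in nbrs:
        for m in g.neighbors(w):
            if m != n:
                partners[m] = partners.get(m, 0) + 1  # shared-neighbor count
    if not partners:
        return 0.0
    total = 0.0
    for m, shared in partners.items():
        j = shared + (1 if g.has_edge(n, m) else 0)
        total += j / kn
    return total / len(partners)


def summary_statistics(g: nx.Graph) -> TopologySummary:
    """All scalar topology parameters plus the per-node statistic table.

    Centralization is ``[N/(N-2)] * (max_k/(N-1) - density)``, 1 for a
    star; heterogeneity is the coefficient of variation of the degree
    sequence. Requires N >= 3 nodes (centralization undefined below that).
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("centralization undefined for networks with < 3 nodes")
    degrees = np.array([k for _, k in g.degree()], dtype=float)
    density = nx.density(g)
    centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    mean_k = degrees.mean()
    heterogeneity = float(degrees.std(ddof=0) / mean_k) if mean_k > 0 else 0.0

    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(map(str, c))))
    diameter = nx.diameter(g.subgraph(components[0])) if components[0] else 0

    closeness: dict[object, float] = {}
    for comp in components:
        sub = g.subgraph(comp)
        nc = len(comp)
        for node in comp:
            if nc == 1:
                closeness[node] = 0.0
            else:
                total = sum(nx.single_source_shortest_path_length(sub, node).values())
                closeness[node] = (nc - 1) / total

    cc, mean_cc, _ = clustering_coefficients(g)
    nodes = sorted(g.nodes(), key=str)
    table = pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "clustering": [cc[v] for v in nodes],
            "topological_coefficient": [_topological_coefficient(g, v) for v in nodes],
            "neighborhood_connectivity": [
                float(np.mean([g.degree(w) for w in g.neighbors(v)])) if g.degree(v) else 0.0
                for v in nodes
            ],
        },
        index=pd.Index(nodes, name="node"),
    )
    return TopologySummary(
        diameter=int(diameter),
        density=float(density),
        centralization=float(centralization),
        heterogeneity=heterogeneity,
        mean_clustering=mean_cc,
        node_table=table,
    )
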