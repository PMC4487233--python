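"""Over-representation testing and term-network construction.

Given a query gene list, annotation term sets and a gene universe, this
module computes exact one-sided hypergeometric enrichment p-values (the
Fisher-exact upper tail behind DAVID-style annotation charts), adjusts them
by Benjamini–Hochberg, and builds the two standard term-network views:

* an enrichment map — terms passing a p cutoff, connected when their gene
  sets overlap strongly (overlap coefficient ``|A∩B|/min(|A|,|B|)`` at or
  above a cutoff, default 0.6);
* a kappa-score term network — terms passing a stricter p cutoff,
  connected when Cohen's kappa between their membership indicator vectors
  over the universe reaches a threshold (default 0.3), with connected
  components as functional groups labeled by their most significant term.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "TermNetworkConfig",
    "hypergeometric_test",
    "adjust_bh",
    "enrich",
    "overlap_coefficient",
    "cohen_kappa",
    "enrichment_map",
    "kappa_term_network",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics.

    ``K`` is the term's size in the universe, ``n`` the query size, ``k``
    the overlap, ``p`` the exact upper-tail hypergeometric p-value.
    """

    term: str
    namespace: str
    K: int
    n: int
    k: int
    p: float
    p_adj: float
    genes: tuple[str, ...]


@dataclass(frozen=True)
class TermNetworkConfig:
    """Cutoffs for the two term-network constructions."""

    p_cutoff_map: float = 0.05
    overlap_cutoff: float = 0.6
    p_cutoff_kappa: float = 0.01
    kappa_threshold: float = 0.3
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        for name in ("p_cutoff_map", "overlap_cutoff", "p_cutoff_kappa", "kappa_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def hypergeometric_test(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact.

    ``ease=True`` applies the conservative EASE-score variant that tests
    P(X >= k) with one success removed (k−1 observed successes).
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if ease:
        k = max(k - 1, 0)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: list[str],
    terms: dict[str, set[str]],
    universe: set[str],
    namespaces: dict[str, str] | None = None,
    per_namespace: bool = False,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query list.

    Terms with no overlap (k = 0) are dropped. Results are sorted by raw
    p-value (ties by term id). Adjustment is applied jointly across all
    namespaces by default, or within each namespace if ``per_namespace``.
    """
    qset = {g for g in query} & universe
    n = len(qset)
    N = len(universe)
    if n == 0:
        raise ValueError("no query gene maps to the universe")
    namespaces = namespaces or {}
    results: list[EnrichmentResult] = []
    for term, genes in terms.items():
        tset = genes & universe
        overlap = tset & qset
        if not overlap:
            continue
        p = hypergeometric_test(len(overlap), len(tset), n, N, ease=ease)
        results.append(
            EnrichmentResult(
                term=term,
                namespace=namespaces.get(term, "default"),
                K=len(tset),
                n=n,
                k=len(overlap),
                p=p,
                p_adj=p,
                genes=tuple(sorted(overlap)),
            )
        )
    if per_namespace:
        for ns in {r.namespace for r in results}:
            grp = [r for r in results if r.namespace == ns]
            for r, padj in zip(grp, adjust_bh([r.p for r in grp])):
                r.p_adj = float(padj)
    else:
        for r, padj in zip(results, adjust_bh([r.p for r in results])):
            r.p_adj = float(padj)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A∩B| / min(|A|, |B|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def cohen_kappa(a: set[str], b: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two terms' membership indicators over a universe.

    Agreement beyond chance of the two binary gene-membership vectors:
    kappa = (p_o − p_e) / (1 − p_e), 1 for identical sets, <= 0 for
    complementary ones.
    """
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    a = a & universe
    b = b & universe
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = N - both - only_a - only_b
    po = (both + neither) / N
    pe = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / N**2
    if pe == 1.0:
        return 1.0  # both sets empty or both equal to the universe
    return (po - pe) / (1.0 - pe)


def _passing(results: list[EnrichmentResult], cutoff: float, use_adjusted: bool):
    key = (lambda r: r.p_adj) if use_adjusted else (lambda r: r.p)
    return [r for r in results if key(r) < cutoff]


def enrichment_map(
    results: list[EnrichmentResult],
    terms: dict[str, set[str]],
    cfg: TermNetworkConfig = TermNetworkConfig(),
) -> nx.Graph:
    """Overlap-coefficient term network (enrichment-map view).

    Nodes are terms with p below ``p_cutoff_map``; an edge joins two terms
    when the overlap coefficient of their annotated gene sets is at least
    ``overlap_cutoff`` (boundary inclusive), weighted by the coefficient.
    Node attributes carry the overlap size (drawn as node size) and
    −log10 p (drawn as color depth).
    """
    g = nx.Graph()
    passing = _passing(results, cfg.p_cutoff_map, cfg.use_adjusted)
    for r in passing:
        g.add_node(r.term, namespace=r.namespace, size=r.k, neg_log10_p=float(-np.log10(r.p)))
    for i, r1 in enumerate(passing):
        for r2 in passing[i + 1 :]:
            coef = overlap_coefficient(terms[r1.term], terms[r2.term])
            if coef >= cfg.overlap_cutoff:
                g.add_edge(r1.term, r2.term, weight=coef)
    return g


def kappa_term_network(
    results: list[EnrichmentResult],
    terms: dict[str, set[str]],
    universe: set[str] | None = None,
    cfg: TermNetworkConfig = TermNetworkConfig(),
) -> nx.Graph:
    """Kappa-score term network with functional-group labels.

    Nodes are terms with p below ``p_cutoff_kappa``; an edge joins terms
    whose membership kappa over the universe is at least
    ``kappa_threshold`` (inclusive). Connected components are functional
    groups; each node's ``group`` attribute names the component's most
    significant term. The default universe is the union of the genes
    annotated to any tested term.
    """
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    g = nx.Graph()
    passing = _passing(results, cfg.p_cutoff_kappa, cfg.use_adjusted)
    for r in passing:
        g.add_node(r.term, namespace=r.namespace, size=r.k, neg_log10_p=float(-np.log10(r.p)))
    for i, r1 in enumerate(passing):
        for r2 in passing[i + 1 :]:
            kappa = cohen_kappa(terms[r1.term], terms[r2.term], universe)
            if kappa >= cfg.kappa_threshold:
                g.add_edge(r1.term, r2.term, kappa=float(kappa))
    pmap = {r.term: r.p for r in passing}
    for comp in nx.connected_components(g):
        label = min(comp, key=lambda t: (pmap[t], t))
        for t in comp:
            g.nodes[t]["group"] = label
    return g


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read GMT term sets: term TAB description TAB gene TAB gene ...

    Returns (term → gene set, term → description).
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        terms[fields[0]] = {g for g in fields[2:] if g}
        descriptions[fields[0]] = fields[1]
    return terms, descriptions


def write_gmt(
    terms: dict[str, set[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{descriptions.get(term, term)}\t{genes}\n")
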