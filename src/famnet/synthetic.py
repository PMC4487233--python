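"""Synthetic input bundles with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here with known ground
truth, so each stage is testable by parameter recovery without downloads:

* a scale-free (preferential-attachment) background interaction network
  with an embedded seed family — degree distributions fit a power law,
  so topology checks are meaningful;
* a log2-scale expression matrix over three sample groups (default 19
  normal, 21 EAC, 9 ESCC) with planted group-mean
  fold changes and latent-factor correlated gene blocks;
* annotation term sets with terms planted to be enriched in the family;
* subcellular localization labels over the seven layers;
* an aligned sequence family with planted fully conserved blocks and two
  identity subgroups.

All outputs are deterministic for a fixed seed. Writers emit the exact
text formats the readers consume (edge-list TSV, expression + group TSVs,
GMT, localization TSV, FASTA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .seqfam import write_fasta

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_interaction_graph",
           "generate_expression", "generate_annotations", "generate_localizations",
           "generate_family_sequences", "generate_bundle", "write_bundle"]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: Layer frequencies loosely shaped like a real interactome annotation:
#: most proteins cytoplasmic or nuclear, dual layers rare.
_DEFAULT_LAYER_FREQS = (0.10, 0.15, 0.30, 0.02, 0.03, 0.10, 0.30)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of one synthetic bundle.

    ``planted_fold_changes`` maps gene → (group, fold >= 1, "up"/"down");
    the fold is realized as a ±log2(fold) shift of the group mean.
    ``correlated_blocks`` lists (gene tuple, r_block) pairs realized by a
    shared latent factor, giving expected pairwise correlation r_block.
    """

    seed: int = 0
    n_background: int = 2000
    n_family: int = 37
    attachment_edges: int = 2
    groups: tuple[tuple[str, int], ...] = (("normal", 19), ("EAC", 21), ("ESCC", 9))
    planted_fold_changes: dict[str, tuple[str, float, str]] = field(default_factory=dict)
    correlated_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_terms: int = 50
    planted_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    term_size_range: tuple[int, int] = (10, 40)
    layer_frequencies: tuple[float, ...] = _DEFAULT_LAYER_FREQS
    family_block_count: int = 4
    family_subgroups: int = 2
    alignment_length: int = 160
    block_width: int = 10
    subgroup_margin: float = 0.3
    within_subgroup_mutation: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_family, self.attachment_edges) <= 0:
            raise ValueError("all counts must be positive")
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("every group needs a positive sample count")
        if abs(sum(self.layer_frequencies) - 1.0) > 1e-9:
            raise ValueError("layer frequencies must sum to 1")
        if len(self.layer_frequencies) != 7:
            raise ValueError("exactly 7 layer frequencies required")
        for gene, (_, fold, direction) in self.planted_fold_changes.items():
            if fold < 1:
                raise ValueError(f"planted fold for {gene} must be >= 1")
            if direction not in ("up", "down"):
                raise ValueError(f"direction for {gene} must be 'up' or 'down'")
        for genes, r in self.correlated_blocks:
            if not 0 <= r < 1:
                raise ValueError(f"block correlation must lie in [0,1), got {r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def family_genes(self) -> list[str]:
        return [f"FAM{i:03d}" for i in range(1, self.n_family + 1)]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i:05d}" for i in range(1, self.n_background + 1)]


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent substreams per generator so adding one output never
    # perturbs another
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def generate_interaction_graph(cfg: SyntheticConfig) -> nx.Graph:
    """Preferential-attachment background graph with the family embedded.

    Background growth: each new node attaches to ``attachment_edges``
    distinct existing nodes with probability proportional to degree
    (linear preferential attachment), which yields the power-law degree
    distribution real interactomes show. Family members then attach with
    1–3 edges each, each endpoint chosen preferentially with probability
    0.5 and uniformly otherwise, so the family reaches hubs and the
    extracted subnetwork is nontrivial.
    """
    rng = _rng(cfg, 1)
    m = cfg.attachment_edges
    bg = cfg.background_genes
    if cfg.n_background <= m:
        raise ValueError("n_background must exceed attachment_edges")
    g = nx.Graph()
    g.add_nodes_from(bg[: m + 1])
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            g.add_edge(bg[i], bg[j])
    # repeated-nodes list for degree-proportional sampling
    repeated: list[str] = []
    for u, v in g.edges():
        repeated.extend((u, v))
    for node in bg[m + 1 :]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            g.add_edge(node, t)
            repeated.extend((node, t))
    nodes_list = list(bg)
    for fam in cfg.family_genes:
        k = int(rng.integers(1, 4))
        targets = set()
        while len(targets) < k:
            if rng.random() < 0.5:
                targets.add(repeated[rng.integers(len(repeated))])
            else:
                targets.add(nodes_list[rng.integers(len(nodes_list))])
        for t in sorted(targets):
            g.add_edge(fam, t)
            repeated.extend((fam, t))
    return g


def generate_expression(
    cfg: SyntheticConfig, genes: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Log2-scale expression for ``genes`` over the configured groups.

    Each gene draws a baseline mean; planted fold changes shift the target
    group's mean by ±log2(fold); correlated-block genes share a latent
    per-sample factor with variance chosen so the expected pairwise
    correlation is r_block (factor_var / (factor_var + noise_sd²) =
    r_block); independent Gaussian noise (sd ``noise_sd``) is added
    everywhere. Returns the matrix and the sample → group map.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    rng = _rng(cfg, 2)
    samples: list[str] = []
    group_of: dict[str, str] = {}
    for gname, count in cfg.groups:
        for i in range(1, count + 1):
            s = f"{gname}_{i:02d}"
            samples.append(s)
            group_of[s] = gname
    n_s = len(samples)
    gene_index = {gn: i for i, gn in enumerate(genes)}
    known_groups = {gname for gname, _ in cfg.groups}

    baseline = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(len(genes))
    values = np.tile(baseline[:, None], (1, n_s))

    for gene, (gname, fold, direction) in sorted(cfg.planted_fold_changes.items()):
        if gene not in gene_index:
            logger.warning("planted fold-change gene %s absent from gene list; ignored", gene)
            continue
        if gname not in known_groups:
            raise ValueError(f"planted group {gname!r} not among configured groups")
        shift = math.log2(fold) * (1 if direction == "up" else -1)
        cols = [j for j, s in enumerate(samples) if group_of[s] == gname]
        values[gene_index[gene], cols] += shift

    for genes_in_block, r in cfg.correlated_blocks:
        if r > 0 and cfg.noise_sd > 0:
            factor_sd = cfg.noise_sd * math.sqrt(r / (1.0 - r))
            factor = factor_sd * rng.standard_normal(n_s)
            for gene in genes_in_block:
                if gene not in gene_index:
                    logger.warning("block gene %s absent from gene list; ignored", gene)
                    continue
                values[gene_index[gene]] += factor

    values += cfg.noise_sd * rng.standard_normal(values.shape)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return df, group_of


def generate_annotations(
    cfg: SyntheticConfig, genes: list[str]
) -> dict[str, set[str]]:
    """Term → gene-set map: planted enriched terms plus uniform background.

    Planted terms keep exactly the configured member genes (by default a
    planted term over the family is maximally over-represented in a family
    query); background terms draw uniform-size-and-membership gene sets
    from the full list.
    """
    rng = _rng(cfg, 3)
    terms: dict[str, set[str]] = {}
    for name, members in sorted(cfg.planted_terms.items()):
        terms[name] = set(members)
    lo, hi = cfg.term_size_range
    pool = np.array(genes)
    for i in range(1, cfg.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        picked = rng.choice(pool, size=min(size, len(pool)), replace=False)
        terms[f"TERM{i:04d}"] = set(map(str, picked))
    return terms


def generate_localizations(
    cfg: SyntheticConfig, proteins: list[str]
) -> dict[str, str]:
    """One of the 7 layer labels per protein, multinomial per the config."""
    from .subcellular import LAYERS

    rng = _rng(cfg, 4)
    if not proteins:
        return {}
    draws = rng.choice(len(LAYERS), size=len(proteins), p=list(cfg.layer_frequencies))
    return {p: LAYERS[d] for p, d in zip(proteins, draws)}


def generate_family_sequences(cfg: SyntheticConfig) -> dict[str, str]:
    """Aligned family with planted conserved blocks and two subgroups.

    Construction: a random ancestral sequence of ``alignment_length``
    columns; ``family_block_count`` evenly spaced blocks of
    ``block_width`` columns are frozen in every member (the SCRs). Outside
    the blocks, each subgroup's consensus diverges from the ancestor at
    rate ``subgroup_margin`` (subgroup 2 only), and each member further
    mutates from its subgroup consensus at rate
    ``within_subgroup_mutation`` — so within-subgroup identity exceeds
    between-subgroup identity by a margin controlled by
    ``subgroup_margin``. Members are named ``FAM001``… and split evenly
    into the two subgroups (``FAM001``…``FAM0ceil(n/2)`` in subgroup 1).
    """
    rng = _rng(cfg, 5)
    L = cfg.alignment_length
    n = cfg.n_family
    blocks = _planted_block_spans(cfg)
    in_block = np.zeros(L, dtype=bool)
    for s, e in blocks:
        in_block[s - 1 : e] = True
    alphabet = np.array(list(_AMINO))
    ancestor = rng.integers(0, 20, size=L)

    def mutate(base: np.ndarray, rate: float, free: np.ndarray) -> np.ndarray:
        out = base.copy()
        hit = (rng.random(L) < rate) & free
        for i in np.where(hit)[0]:
            choices = [a for a in range(20) if a != out[i]]
            out[i] = choices[rng.integers(19)]
        return out

    free = ~in_block
    consensus = {1: ancestor, 2: mutate(ancestor, cfg.subgroup_margin, free)}
    half = (n + 1) // 2
    seqs: dict[str, str] = {}
    for idx, name in enumerate(cfg.family_genes):
        grp = 1 if idx < half else 2
        s = mutate(consensus[grp], cfg.within_subgroup_mutation, free)
        seqs[name] = "".join(alphabet[s])
    return seqs


def _planted_block_spans(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    """1-based inclusive column spans of the planted conserved blocks."""
    L, b, w = cfg.alignment_length, cfg.family_block_count, cfg.block_width
    if b * w > L:
        raise ValueError("conserved blocks do not fit in the alignment")
    gap = (L - b * w) // (b + 1)
    spans = []
    pos = gap
    for _ in range(b):
        spans.append((pos + 1, pos + w))
        pos += w + gap
    return spans


@dataclass
class SyntheticBundle:
    """All generated inputs plus their ground truth."""

    cfg: SyntheticConfig
    graph: nx.Graph
    expression: pd.DataFrame
    groups: dict[str, str]
    terms: dict[str, set[str]]
    localizations: dict[str, str]
    sequences: dict[str, str]
    block_spans: list[tuple[int, int]]


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate every pipeline input from one config."""
    graph = generate_interaction_graph(cfg)
    genes = sorted(graph.nodes(), key=str)
    expr, groups = generate_expression(cfg, genes)
    terms = generate_annotations(cfg, genes)
    locs = generate_localizations(cfg, genes)
    seqs = generate_family_sequences(cfg)
    return SyntheticBundle(
        cfg=cfg,
        graph=graph,
        expression=expr,
        groups=groups,
        terms=terms,
        localizations=locs,
        sequences=seqs,
        block_spans=_planted_block_spans(cfg),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the text formats the pipeline readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "seeds": out / "seeds.txt",
        "terms": out / "terms.gmt",
        "localizations": out / "localizations.tsv",
        "family_aln": out / "family.aln.fa",
        "family_fa": out / "family.fa",
    }
    with open(paths["edges"], "w") as fh:
        for u, v in sorted(bundle.graph.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\n")
    bundle.expression.to_csv(paths["expression"], sep="\t")
    with open(paths["groups"], "w") as fh:
        for s in bundle.expression.columns:
            fh.write(f"{s}\t{bundle.groups[s]}\n")
    paths["seeds"].write_text("\n".join(bundle.cfg.family_genes) + "\n")
    from .enrichment import write_gmt

    write_gmt(bundle.terms, paths["terms"])
    with open(paths["localizations"], "w") as fh:
        for p in sorted(bundle.localizations):
            fh.write(f"{p}\t{bundle.localizations[p]}\n")
    write_fasta(bundle.sequences, paths["family_aln"])
    write_fasta(
        {k: v.replace("-", "") for k, v in bundle.sequences.items()},
        paths["family_fa"],
    )
    return paths
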