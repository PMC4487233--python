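"""Expression integration: fold changes, co-expression, correlation clustering.

A gene × sample log2 expression matrix with sample group labels (e.g.
normal / EAC / ESCC) is the second data layer of the analysis. Tumor vs
normal effects are summarized GEO2R-style as differences of group means on
the log2 scale, reported as a fold >= 1 plus an up/down direction. Pairwise
Pearson correlations between interacting proteins become edge weights, and
the within-family correlation matrix is hierarchically clustered to expose
co-expression groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FoldChange",
    "CorrelationAnalysis",
    "read_expression",
    "read_series_matrix",
    "fold_changes",
    "pearson",
    "weight_edges",
    "correlation_matrix",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with a sample→group assignment.

    ``values`` has unique gene row labels (duplicate probes are collapsed
    before construction) and one column per sample; ``log2_scale`` records
    whether the values are log2 intensities (the microarray convention all
    downstream arithmetic assumes).
    """

    values: pd.DataFrame
    groups: dict[str, str]
    log2_scale: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene labels; collapse probes first")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def samples_in(self, group: str | None) -> list[str]:
        """Columns belonging to ``group`` (all columns when ``None``)."""
        if group is None:
            return list(self.values.columns)
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class FoldChange:
    """One gene's tumor-vs-reference effect.

    ``log2fc`` is mean(log2 tumor) − mean(log2 reference); ``fold`` is its
    magnitude on the linear scale (2**|log2fc|, always >= 1) and
    ``direction`` carries the sign, matching the "upregulated 4.23-fold" /
    "downregulated 1.68-fold" reporting convention.
    """

    gene: str
    comparison: str
    log2fc: float
    fold: float
    direction: str

    @property
    def signed_fold(self) -> float:
        return self.fold if self.log2fc >= 0 else -self.fold


def _collapse(values: pd.DataFrame, policy: str) -> pd.DataFrame:
    if not values.index.duplicated().any():
        return values
    if policy == "mean":
        return values.groupby(level=0, sort=False).mean()
    if policy == "max_iqr":
        iqr = (values.quantile(0.75, axis=1) - values.quantile(0.25, axis=1)).to_numpy()
        keep_rows = []
        for _, idx in pd.Series(range(len(values)), index=values.index).groupby(level=0, sort=False):
            rows = idx.to_numpy()
            keep_rows.append(rows[np.argmax(iqr[rows])])
        return values.iloc[sorted(keep_rows)]
    raise ValueError(f"unknown probe-collapse policy: {policy}")


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    log2_scale: bool = True,
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Read an expression TSV (genes as rows) and a sample-group TSV.

    The group file has two columns, sample and group. Multiple rows per
    gene are collapsed (default: mean of the log2 values). Non-numeric
    cells raise with the offending gene/sample named.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() and not raw.isna().any().any():
        bad = numeric.isna()
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {sample!r}")
    values = _collapse(numeric, collapse)
    gdf = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
    groups = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
    return ExpressionMatrix(values=values, groups=groups, log2_scale=log2_scale)


def read_series_matrix(
    path: str | Path,
    group_field: str | None = None,
    gene_map: dict[str, str] | None = None,
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Convert a GEO series-matrix text file into an :class:`ExpressionMatrix`.

    The series-matrix format is plain text: ``!``-prefixed metadata lines
    (one value per sample) followed by a tab-delimited probe × sample table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    ``group_field`` selects the metadata line used as the group label
    (default: the first ``!Sample_characteristics_ch1`` line); ``gene_map``
    optionally maps probe ids to gene symbols before probe collapsing.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
        elif line.startswith("!series_matrix_table_end"):
            in_table = False
        elif in_table:
            table_lines.append(line)
        elif line.startswith("!"):
            key, _, rest = line.partition("\t")
            vals = [v.strip('"') for v in rest.split("\t")]
            meta.setdefault(key.lstrip("!"), []).append(vals)  # type: ignore[arg-type]
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.map(lambda p: str(p).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    field_name = group_field or "Sample_characteristics_ch1"
    if field_name not in meta:
        raise ValueError(f"{path}: metadata field {field_name!r} absent")
    labels = meta[field_name][0]
    if len(labels) != df.shape[1]:
        raise ValueError("group labels do not align with sample columns")
    groups = dict(zip(df.columns, labels))
    if gene_map is not None:
        df = df.rename(index=gene_map)
    values = _collapse(df.apply(pd.to_numeric, errors="raise"), collapse)
    return ExpressionMatrix(values=values, groups=groups, log2_scale=True)


def fold_changes(
    m: ExpressionMatrix, tumor_group: str, reference_group: str
) -> list[FoldChange]:
    """Per-gene log2 mean-difference fold changes, tumor vs reference."""
    tumor = m.samples_in(tumor_group)
    ref = m.samples_in(reference_group)
    if not tumor:
        raise ValueError(f"no samples in tumor group {tumor_group!r}")
    if not ref:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    comparison = f"{tumor_group} vs {reference_group}"
    l2 = m.values[tumor].mean(axis=1) - m.values[ref].mean(axis=1)
    out = []
    for gene, lfc in l2.items():
        lfc = float(lfc)
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        out.append(
            FoldChange(
                gene=str(gene),
                comparison=comparison,
                log2fc=lfc,
                fold=float(2.0 ** abs(lfc)),
                direction=direction,
            )
        )
    return out


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with its two-sided p-value (t transform, n−2 df).

    Requires equal lengths of at least 3 and nonzero variance in both
    vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def weight_edges(
    g: nx.Graph,
    m: ExpressionMatrix,
    group: str | None = None,
    tumor_groups: tuple[str, ...] = (),
    reference_group: str | None = None,
) -> nx.Graph:
    """Attach co-expression edge weights and fold-change node attributes.

    Every edge whose endpoints both have expression gets
    ``correlation_<group>`` = Pearson r over the group's samples (``all``
    when no group restriction); edges with a missing endpoint are retained
    and flagged ``correlation_missing``. If ``tumor_groups`` and
    ``reference_group`` are given, each node additionally gets signed-fold
    attributes ``fold_<tumor>`` per comparison; genes absent from the
    matrix are representable as a missing attribute.
    """
    g = g.copy()
    label = group if group is not None else "all"
    samples = m.samples_in(group)
    expr = {str(i).upper(): row for i, row in m.values[samples].iterrows()}
    for u, v in g.edges():
        xu, xv = expr.get(str(u).upper()), expr.get(str(v).upper())
        try:
            if xu is None or xv is None:
                raise ValueError("endpoint absent")
            r, p, n = pearson(xu.to_numpy(), xv.to_numpy())
        except ValueError:
            g.edges[u, v]["correlation_missing"] = True
            continue
        g.edges[u, v][f"correlation_{label}"] = r
        g.edges[u, v][f"correlation_{label}_p"] = p
    for tumor in tumor_groups:
        if reference_group is None:
            raise ValueError("reference_group required with tumor_groups")
        fc = {f.gene.upper(): f for f in fold_changes(m, tumor, reference_group)}
        for node in g.nodes():
            f = fc.get(str(node).upper())
            if f is not None:
                g.nodes[node][f"fold_{tumor}"] = f.signed_fold
    return g


@dataclass
class CorrelationAnalysis:
    """Clustered correlation matrix of a gene subset within one group."""

    matrix: pd.DataFrame
    linkage: np.ndarray
    order: list[str]
    pairs: pd.DataFrame  # gene_a, gene_b, r, p, p_adj, significant
    group: str

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]].reset_index(drop=True)


def correlation_matrix(
    m: ExpressionMatrix,
    genes: list[str],
    group: str | None = None,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
) -> CorrelationAnalysis:
    """Pairwise Pearson matrix over a gene subset, clustered and flagged.

    Average-linkage hierarchical clustering on distance 1 − r orders the
    genes; pairs with r >= ``r_threshold`` and Benjamini–Hochberg adjusted
    p < ``alpha`` are flagged significant (the report of notable
    co-expressed pairs). Genes absent from the matrix are dropped with a
    logged notice.
    """
    present = [gn for gn in genes if gn in m.values.index]
    dropped = sorted(set(genes) - set(present))
    if dropped:
        logger.info("genes absent from expression matrix: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 genes present in the matrix")
    samples = m.samples_in(group)
    sub = m.values.loc[present, samples]

    k = len(present)
    corr = np.eye(k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            r, p, n = pearson(sub.iloc[i].to_numpy(), sub.iloc[j].to_numpy())
            corr[i, j] = corr[j, i] = r
            rows.append((present[i], present[j], r, p, n))
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "n"])
    pairs["p_adj"] = multipletests(pairs["p"], method="fdr_bh")[1] if len(pairs) else []
    pairs["significant"] = (pairs["r"] >= r_threshold) & (pairs["p_adj"] < alpha)
    pairs = pairs.sort_values(["p", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)

    matrix = pd.DataFrame(corr, index=present, columns=present)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    linkage = hierarchy.average(dist)
    order = [present[i] for i in hierarchy.leaves_list(linkage)]
    return CorrelationAnalysis(
        matrix=matrix,
        linkage=linkage,
        order=order,
        pairs=pairs,
        group=group if group is not None else "all",
    )
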