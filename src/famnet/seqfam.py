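"""Sequence-level family analysis: identity matrix, subgroups, conserved blocks.

A protein family is characterized at the sequence level three ways:

* a pairwise percent-identity matrix from global (Needleman–Wunsch)
  alignments under a fixed BLOSUM62 / affine-gap parameterization;
* hierarchical clustering of that matrix into subgroups (the lipocalin
  worked example splits into two: the FABP/RBP-like intracellular carriers
  versus the classic secreted lipocalins);
* detection of structurally conserved regions (SCRs) — maximal runs of
  highly conserved columns — on a multiple alignment supplied by an
  external aligner (alignments are consumed, not built here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SimilarityMatrix",
    "ConservedBlock",
    "FamilyClustering",
    "make_aligner",
    "global_percent_identity",
    "identity_matrix",
    "cluster_family",
    "detect_conserved_blocks",
    "read_fasta",
    "write_fasta",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SimilarityMatrix:
    """Symmetric percent-identity matrix over family members.

    Values lie in [0, 100] with a 100 diagonal.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v.to_numpy(), v.to_numpy().T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v.to_numpy()), 100.0):
            raise ValueError("identity matrix diagonal must be 100")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ConservedBlock:
    """One conserved alignment region: 1-based inclusive column range."""

    start: int
    end: int
    conservation: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("block start must not exceed end")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class FamilyClustering:
    assignment: dict[str, int]
    linkage: np.ndarray
    labels: list[str]

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, grp in self.assignment.items():
            out.setdefault(grp, []).append(label)
        return {g: sorted(members) for g, members in out.items()}

    def to_newick(self) -> str:
        """Dendrogram in Newick format with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def make_aligner(gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    """Global protein aligner: BLOSUM62, affine gaps (defaults 10 / 0.5)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"empty sequence: {name}")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in {name}: {sorted(bad)}")
    return seq


def global_percent_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
    denominator: str = "alignment",
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = identical aligned columns / denominator × 100, where the
    denominator is the full alignment length including gap columns
    (``"alignment"``, the default) or the shorter sequence length
    (``"min_length"``).
    """
    a = _validate(str(seq_a), "seq_a")
    b = _validate(str(seq_b), "seq_b")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    if denominator == "alignment":
        denom = aln.length
    elif denominator == "min_length":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator convention: {denominator}")
    return 100.0 * counts.identities / denom


def identity_matrix(
    sequences: dict[str, str],
    aligner: Align.PairwiseAligner | None = None,
    denominator: str = "alignment",
) -> SimilarityMatrix:
    """All-pairs percent identity (n(n−1)/2 global alignments)."""
    if aligner is None:
        aligner = make_aligner()
    labels = list(sequences)
    k = len(labels)
    m = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            pid = global_percent_identity(
                sequences[labels[i]], sequences[labels[j]], aligner, denominator
            )
            m[i, j] = m[j, i] = pid
    return SimilarityMatrix(pd.DataFrame(m, index=labels, columns=labels))


def cluster_family(
    m: SimilarityMatrix, k: int, log_transform: bool = True
) -> FamilyClustering:
    """Average-linkage clustering of the identity matrix into k subgroups.

    The identity is optionally log10(identity + 1)-scaled (mirroring the
    Cluster 3.0-style workflow; skip with ``log_transform=False``) and
    converted to a distance normalized to [0, 1]. Labels are processed in
    lexicographic order so the dendrogram is independent of input order.
    """
    if k < 1 or k > len(m.labels):
        raise ValueError("k must be between 1 and the number of members")
    labels = sorted(m.labels)
    vals = m.values.loc[labels, labels].to_numpy()
    if log_transform:
        sim = np.log10(vals + 1.0) / np.log10(101.0)
    else:
        sim = vals / 100.0
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    if len(labels) == 1:
        return FamilyClustering({labels[0]: 1}, np.empty((0, 4)), labels)
    linkage = hierarchy.average(squareform(dist, checks=False))
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber clusters by first occurrence for determinism
    remap: dict[int, int] = {}
    assignment = {}
    for label, c in zip(labels, flat):
        assignment[label] = remap.setdefault(int(c), len(remap) + 1)
    return FamilyClustering(assignment, linkage, labels)


def column_conservation(column: list[str]) -> float:
    """Conservation of one alignment column.

    Frequency of the modal non-gap residue among non-gap rows, damped by
    the non-gap fraction; an all-gap column scores 0.
    """
    residues = [c for c in column if c not in "-."]
    if not residues:
        return 0.0
    modal = max(residues.count(r) for r in set(residues))
    return (modal / len(residues)) * (len(residues) / len(column))


def detect_conserved_blocks(
    alignment: dict[str, str], tau: float = 0.9, min_width: int = 5
) -> list[ConservedBlock]:
    """Maximal runs of >= ``min_width`` columns with conservation >= ``tau``.

    This is the SCR detector: on the lipocalin alignment it marks the four
    structurally conserved regions. Coordinates are 1-based inclusive
    alignment columns.
    """
    seqs = list(alignment.values())
    if not seqs:
        return []
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("alignment rows have unequal length")
    cons = [column_conservation([s[i] for s in seqs]) for i in range(width)]
    blocks: list[ConservedBlock] = []
    start = None
    for i, c in enumerate(cons):
        if c >= tau and start is None:
            start = i
        elif c < tau and start is not None:
            if i - start >= min_width:
                blocks.append(
                    ConservedBlock(start + 1, i, float(np.mean(cons[start:i])))
                )
            start = None
    if start is not None and width - start >= min_width:
        blocks.append(ConservedBlock(start + 1, width, float(np.mean(cons[start:]))))
    return blocks


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered name → sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
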