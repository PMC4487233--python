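"""Percent identity, family clustering, and conserved-block detection.

The alignment oracle is an independent Gotoh dynamic program under the
same BLOSUM62 / affine-gap parameters (gap of length L scores
open + (L-1)*extend, matching the production aligner's convention).
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from famnet.seqfam import (
    ConservedBlock,
    SimilarityMatrix,
    cluster_family,
    column_conservation,
    detect_conserved_blocks,
    global_percent_identity,
    identity_matrix,
    make_aligner,
    read_fasta,
    write_fasta,
)
from famnet.synthetic import SyntheticConfig, generate_family_sequences

BLOSUM62 = substitution_matrices.load("BLOSUM62")
OPEN, EXTEND = -10.0, -0.5
NEG = float("-inf")


def gotoh(a: str, b: str):
    """Independent affine-gap global alignment DP; returns the 3 matrices."""
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Ix = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        Ix[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, lb + 1):
        Iy[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(
                M[i - 1][j] + OPEN, Ix[i - 1][j] + EXTEND, Iy[i - 1][j] + OPEN
            )
            Iy[i][j] = max(
                M[i][j - 1] + OPEN, Iy[i][j - 1] + EXTEND, Ix[i][j - 1] + OPEN
            )
    return M, Ix, Iy


def oracle_score(a: str, b: str) -> float:
    M, Ix, Iy = gotoh(a, b)
    return max(M[len(a)][len(b)], Ix[len(a)][len(b)], Iy[len(a)][len(b)])


def oracle_identities(a: str, b: str) -> set[float]:
    """Percent identities (alignment-length denominator) over all optimal
    alignments, enumerated by backtracking the DP."""
    M, Ix, Iy = gotoh(a, b)
    la, lb = len(a), len(b)
    best = max(M[la][lb], Ix[la][lb], Iy[la][lb])
    out: set[float] = set()

    def walk(i, j, state, ident, length):
        if i == 0 and j == 0 and state == "M":
            out.add(100.0 * ident / length)
            return
        if state == "M":
            if i and j:
                s = BLOSUM62[a[i - 1], b[j - 1]]
                for prev in ("M", "Ix", "Iy"):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i - 1][j - 1]
                    if val + s == M[i][j] and val > NEG:
                        walk(
                            i - 1,
                            j - 1,
                            prev,
                            ident + (a[i - 1] == b[j - 1]),
                            length + 1,
                        )
        elif state == "Ix":
            if i:
                if i >= 1 and M[i - 1][j] + OPEN == Ix[i][j]:
                    walk(i - 1, j, "M", ident, length + 1)
                if Ix[i - 1][j] + EXTEND == Ix[i][j]:
                    walk(i - 1, j, "Ix", ident, length + 1)
                if Iy[i - 1][j] + OPEN == Ix[i][j]:
                    walk(i - 1, j, "Iy", ident, length + 1)
            elif j == 0:
                out.add(100.0 * ident / (length + i))
        elif state == "Iy":
            if j:
                if M[i][j - 1] + OPEN == Iy[i][j]:
                    walk(i, j - 1, "M", ident, length + 1)
                if Iy[i][j - 1] + EXTEND == Iy[i][j]:
                    walk(i, j - 1, "Iy", ident, length + 1)
                if Ix[i][j - 1] + OPEN == Iy[i][j]:
                    walk(i, j - 1, "Ix", ident, length + 1)
            elif i == 0:
                out.add(100.0 * ident / (length + j))

    for state, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
        if mat[la][lb] == best:
            walk(la, lb, state, 0, 0)
    return out


RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class TestPercentIdentity:
    def test_identical_sequences_are_100(self):
        assert global_percent_identity("ACDEFG", "ACDEFG") == 100.0

    def test_no_identical_columns_is_0(self):
        assert global_percent_identity("AAAA", "CCCC") == 0.0

    def test_invalid_or_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            global_percent_identity("", "ACD")
        with pytest.raises(ValueError):
            global_percent_identity("AC-D", "ACD")

    def test_worked_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aligner = make_aligner()
        assert aligner.score(a, b) == pytest.approx(oracle_score(a, b))
        pid = global_percent_identity(a, b)
        assert any(pid == pytest.approx(o) for o in oracle_identities(a, b))

    def test_score_equals_brute_force_on_short_random_pairs(self):
        rng = np.random.default_rng(15)
        aligner = make_aligner()
        for _ in range(30):
            a = "".join(rng.choice(list(RESIDUES), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(RESIDUES), size=rng.integers(1, 9)))
            assert aligner.score(a, b) == pytest.approx(oracle_score(a, b))

    def test_min_length_denominator_convention(self):
        pid = global_percent_identity("ACDEFGH", "ACD", denominator="min_length")
        assert pid == pytest.approx(100.0)


class TestIdentityMatrix:
    def test_two_identical_sequences(self):
        m = identity_matrix({"a": "ACDEF", "b": "ACDEF"})
        assert m.values.to_numpy().tolist() == [[100.0, 100.0], [100.0, 100.0]]

    def test_symmetry_and_diagonal_enforced(self):
        m = identity_matrix({"a": "ACDEFACDEF", "b": "ACDWFACDYF", "c": "WWWWYYYY"})
        v = m.values.to_numpy()
        assert (v == v.T).all()
        assert (np.diag(v) == 100.0).all()

    def test_synthetic_subgroups_separate_within_vs_between(self):
        cfg = SyntheticConfig(seed=16, n_family=8)
        seqs = generate_family_sequences(cfg)
        m = identity_matrix(seqs)
        names = list(seqs)
        g1, g2 = names[:4], names[4:]
        within = [m.values.loc[a, b] for g in (g1, g2) for a in g for b in g if a < b]
        between = [m.values.loc[a, b] for a in g1 for b in g2]
        assert np.mean(within) > np.mean(between)


class TestClusterFamily:
    def make_block_matrix(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 5.0)
        v[:2, :2] = 95.0
        v[2:, 2:] = 95.0
        np.fill_diagonal(v, 100.0)
        import pandas as pd

        return SimilarityMatrix(pd.DataFrame(v, index=labels, columns=labels))

    def test_two_perfect_blocks_recovered_at_k2(self):
        cl = cluster_family(self.make_block_matrix(), k=2)
        groups = set(map(frozenset, cl.groups().values()))
        assert groups == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_k_equals_n_gives_singletons(self):
        cl = cluster_family(self.make_block_matrix(), k=4)
        assert all(len(g) == 1 for g in cl.groups().values())

    def test_input_order_invariance(self):
        m = self.make_block_matrix()
        shuffled = SimilarityMatrix(
            m.values.loc[["b2", "a1", "b1", "a2"], ["b2", "a1", "b1", "a2"]]
        )
        c1 = cluster_family(m, k=2)
        c2 = cluster_family(shuffled, k=2)
        assert set(map(frozenset, c1.groups().values())) == set(
            map(frozenset, c2.groups().values())
        )

    def test_planted_subgroups_recovered_from_sequences(self):
        cfg = SyntheticConfig(seed=17, n_family=10)
        seqs = generate_family_sequences(cfg)
        m = identity_matrix(seqs)
        cl = cluster_family(m, k=2)
        names = list(seqs)
        expected = {frozenset(names[:5]), frozenset(names[5:])}
        assert set(map(frozenset, cl.groups().values())) == expected

    def test_newick_export_contains_all_leaves(self):
        cl = cluster_family(self.make_block_matrix(), k=2)
        nwk = cl.to_newick()
        assert nwk.endswith(";")
        for label in ("a1", "a2", "b1", "b2"):
            assert label in nwk


class TestConservedBlocks:
    def test_single_planted_block_at_exact_coordinates(self):
        rng = np.random.default_rng(18)
        n, width = 20, 30
        cols = []
        for i in range(width):
            if 2 <= i <= 7:  # columns 3..8, 1-based
                cols.append(["W"] * n)
            else:
                cols.append(list(rng.choice(list(RESIDUES), size=n)))
        aln = {f"s{j}": "".join(cols[i][j] for i in range(width)) for j in range(n)}
        blocks = detect_conserved_blocks(aln, tau=0.9, min_width=5)
        assert [(b.start, b.end) for b in blocks] == [(3, 8)]
        assert blocks[0].conservation == pytest.approx(1.0)

    def test_all_gap_column_breaks_a_run(self):
        aln = {"s1": "AAAA-AAAA", "s2": "AAAA-AAAA", "s3": "AAAA-AAAA"}
        blocks = detect_conserved_blocks(aln, tau=0.9, min_width=4)
        assert [(b.start, b.end) for b in blocks] == [(1, 4), (6, 9)]
        assert column_conservation(["-", "-", "-"]) == 0.0

    def test_gap_fraction_damps_conservation(self):
        assert column_conservation(["A", "A", "-", "-"]) == pytest.approx(0.5)

    def test_planted_block_count_recovered(self):
        cfg = SyntheticConfig(seed=19)
        seqs = generate_family_sequences(cfg)
        blocks = detect_conserved_blocks(seqs, tau=0.9, min_width=5)
        assert len(blocks) == cfg.family_block_count
        for block, (start, end) in zip(blocks, cfg_spans(cfg)):
            assert block.start <= start and block.end >= end

    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValueError):
            detect_conserved_blocks({"a": "AAA", "b": "AA"})

    def test_block_coordinates_validated(self):
        with pytest.raises(ValueError):
            ConservedBlock(5, 4, 1.0)


def cfg_spans(cfg):
    from famnet.synthetic import _planted_block_spans

    return _planted_block_spans(cfg)


def test_fasta_round_trip(tmp_path):
    seqs = {"a": "ACDEFG" * 15, "b": "WYWYWY"}
    p = tmp_path / "f.fa"
    write_fasta(seqs, p)
    assert read_fasta(p) == seqs
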