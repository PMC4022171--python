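"""Alignment, distances, neighbor joining, bootstrap, newick round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import brute_best_alignment_score, random_additive_tree
from wrkykit.phylo import (
    Alignment,
    DistanceMatrix,
    align_progressive,
    blosum62,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    pairwise_align,
    parse_newick,
    robinson_foulds,
    to_newick,
)
from wrkykit.synthetic_data import PlantedDomain, ProteinSpec, make_family, make_protein

short_peptides = st.text(alphabet="ARNDCQEGHILKMFPSTWYV", min_size=1, max_size=6)


class TestPairwiseAlign:
    def test_self_alignment_identity(self):
        a = pairwise_align("WRKYGQKDEF", "WRKYGQKDEF")
        assert a.identity == 1.0 and "-" not in a.aligned_a

    @given(short_peptides, short_peptides)
    def test_score_symmetric(self, a, b):
        assert pairwise_align(a, b).score == pytest.approx(pairwise_align(b, a).score)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_align("", "AA")

    @settings(max_examples=25)
    @given(short_peptides, short_peptides)
    def test_score_equals_exhaustive_enumeration(self, a, b):
        """DP score equals the best score over all explicitly enumerated
        global alignments (affine gap cost open + (L-1)*extend)."""
        sub = blosum62()
        expected = brute_best_alignment_score(a, b, sub, 10.0, 0.5)
        got = pairwise_align(a, b)
        assert got.score == pytest.approx(expected)
        # and the emitted alignment itself scores what it claims
        from oracle_utils import affine_alignment_score

        assert affine_alignment_score(
            got.aligned_a, got.aligned_b, sub, 10.0, 0.5
        ) == pytest.approx(got.score)

    @given(st.integers(0, 2**31 - 1))
    def test_score_agrees_with_biopython(self, seed):
        from Bio import Align

        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 30))
        b = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 25))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        assert pairwise_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestPDistance:
    def test_identical_zero(self):
        assert p_distance(pairwise_align("WRKY", "WRKY")) == 0.0

    def test_fully_mismatched_one(self):
        assert p_distance(Alignment("AAAA", "GGGG", 0.0)) == 1.0

    def test_hand_counted_with_gaps(self):
        # 10 columns, 2 with gaps (excluded), 3 mismatches among the 8 left
        aln = Alignment("ACDEFGHIK-", "A-DEFAAAKW", 0.0)
        assert p_distance(aln) == pytest.approx(3 / 8)

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError, match="no gap-free"):
            p_distance(Alignment("A-", "-A", 0.0))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]]))
        t = neighbor_joining(dm)
        lengths = {c.label: bl for c, bl in t.root.children}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:1) -> additive distances
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        t = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        nw = to_newick(t)
        assert "A:1" in nw and "B:2" in nw

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    @given(st.integers(0, 2**31 - 1))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, d, biparts = random_additive_tree(n, rng)
        t = neighbor_joining(DistanceMatrix(tuple(labels), d))
        assert t.bipartitions() == biparts

    def test_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(5)
        labels, d, _ = random_additive_tree(6, rng)
        t1 = neighbor_joining(DistanceMatrix(tuple(labels), d))
        perm = rng.permutation(6)
        t2 = neighbor_joining(
            DistanceMatrix(tuple(labels[i] for i in perm), d[np.ix_(perm, perm)])
        )
        assert robinson_foulds(t1, t2) == 0

    def test_topology_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(7)
        labels, d, _ = random_additive_tree(7, rng)
        d = (d + d.T) / 2  # remove float asymmetry from per-source path sums
        mine = neighbor_joining(DistanceMatrix(tuple(labels), d))
        sk_tree = sk_nj(SkDM(d, ids=list(labels)))
        theirs = parse_newick(str(sk_tree).strip())
        assert robinson_foulds(mine, theirs) == 0


class TestNewick:
    def test_three_leaf_round_trip(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]]))
        t = neighbor_joining(dm)
        t2 = parse_newick(to_newick(t))
        assert sorted(t2.leaves()) == ["A", "B", "C"]

    @given(st.integers(0, 2**31 - 1))
    def test_random_tree_round_trip_preserves_everything(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, d, _ = random_additive_tree(n, rng)
        t = neighbor_joining(DistanceMatrix(tuple(labels), d))
        # attach fake supports to exercise the label channel
        for child, _bl in t.root.children:
            if not child.is_leaf:
                child.support = int(rng.integers(0, 1000))
        t2 = parse_newick(to_newick(t))
        assert t2.bipartitions() == t.bipartitions()
        assert t2.supports() == t.supports()
        assert _edge_lengths(t2) == pytest.approx(_edge_lengths(t), abs=1e-9)

    @pytest.mark.parametrize("bad", ["(A,B", "(A,B));", "A:1.0", "(A,:1);", "(A,B):;"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)

    def test_output_parses_in_dendropy(self):
        import dendropy

        rng = np.random.default_rng(3)
        labels, d, _ = random_additive_tree(6, rng)
        t = neighbor_joining(DistanceMatrix(tuple(labels), d))
        nw = to_newick(t)
        dt = dendropy.Tree.get(data=nw, schema="newick")
        assert sorted(lf.taxon.label for lf in dt.leaf_node_iter()) == sorted(labels)


def _edge_lengths(tree):
    """Sorted list of all branch lengths (structure checked separately)."""
    out = []

    def walk(node):
        for child, bl in node.children:
            out.append(bl)
            walk(child)

    walk(tree.root)
    return sorted(out)


def _clean_msa():
    """Five taxa, two deep clades, heavily duplicated diagnostic columns."""
    blocks = {
        "A": "W" * 30 + "G" * 30 + "A" * 10,
        "B": "W" * 30 + "G" * 30 + "C" * 10,
        "C": "G" * 30 + "F" * 30 + "D" * 10,
        "D": "G" * 30 + "F" * 30 + "E" * 10,
        "E": "G" * 30 + "G" * 30 + "H" * 10,
    }
    return [(k, v) for k, v in blocks.items()]


class TestBootstrap:
    def test_clean_signal_gives_full_support(self):
        tree = bootstrap_support(_clean_msa(), n_boot=100, seed=0)
        sup = tree.supports()
        assert sup and all(v == 100 for v in sup.values())
        assert {frozenset(s) for s in sup} == tree.bipartitions()

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(_clean_msa(), n_boot=50, seed=123)
        t2 = bootstrap_support(_clean_msa(), n_boot=50, seed=123)
        assert to_newick(t1) == to_newick(t2)
        assert t1.supports() == t2.supports()

    def test_different_seeds_differ_on_noisy_data(self):
        rng = np.random.default_rng(0)
        msa = [
            (f"T{i}", "".join(rng.choice(list("ARND"), 40))) for i in range(5)
        ]
        s1 = bootstrap_support(msa, n_boot=30, seed=1).supports()
        s2 = bootstrap_support(msa, n_boot=30, seed=2).supports()
        assert s1.keys() == s2.keys()  # same reference tree
        assert s1 != s2  # resampling actually depends on the seed


class TestProgressiveMSA:
    def test_pairwise_identity_not_degraded(self):
        """Identity of any pair inside the MSA stays within 0.05 of its
        direct pairwise-alignment identity on synthetic families."""
        spec = ProteinSpec("s", 70, (PlantedDomain(0, "C-X5-C-X23-HXH"),), seed=2)
        seed_seq, _ = make_protein(spec)
        members = make_family({"IIa": seed_seq}, 5, 0.15, seed=8)
        records = [(m[0], m[2]) for m in members]
        msa = dict(align_progressive(records))
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                ra, rb = msa[records[i][0]], msa[records[j][0]]
                cols = [(x, y) for x, y in zip(ra, rb) if not (x == "-" and y == "-")]
                msa_ident = sum(x == y and x != "-" for x, y in cols) / len(cols)
                direct = pairwise_align(records[i][1], records[j][1]).identity
                assert msa_ident >= direct - 0.05

    def test_row_content_preserved(self):
        spec = ProteinSpec("s", 60, (PlantedDomain(0, "C-X4-C-X23-HXH"),), seed=4)
        seed_seq, _ = make_protein(spec)
        members = make_family({"IIc": seed_seq}, 4, 0.1, seed=9)
        records = [(m[0], m[2]) for m in members]
        msa = align_progressive(records)
        assert [r[0] for r in msa] == [r[0] for r in records]
        for (rid, seq), (_, aligned) in zip(records, msa):
            assert aligned.replace("-", "") == seq
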