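import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ceparch.phylo import (
    Alignment,
    DistanceMatrix,
    NewickParseError,
    SaturationError,
    bootstrap_support,
    cut_clusters,
    distances_from_alignment,
    global_align,
    jc_distance,
    neighbor_joining,
    p_distance,
    percent_identity,
    progressive_align,
    read_newick,
    write_newick,
)
from ceparch.seq_io import SequenceRecord
from ceparch.synthetic import random_binary_tree, tree_distance_matrix

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_score(a, b, gap_open=-11.0, gap_extend=-1.0):
    """Independent oracle: enumerate every global alignment (affine gaps).

    A gap of length L costs gap_open + (L-1) * gap_extend, matching the
    aligner's convention. Exponential — only for tiny sequences.
    """

    best = [-math.inf]

    def recur(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recur(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            recur(i + 1, j, score + cost, "A")
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            recur(i, j + 1, score + cost, "B")

    recur(0, 0, 0.0, "M")
    return best[0]


def ls_topology_oracle(dm):
    """Least-squares fit over the three unrooted 4-taxon topologies."""
    labels = dm.labels
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    y = np.array([dm.values[i, j] for i, j in pairs])
    best = None
    # splits: which pair groups with labels[0]
    for partner in (1, 2, 3):
        group_a = {0, partner}
        # edges: 4 leaf edges + 1 internal
        rows = []
        for i, j in pairs:
            row = np.zeros(5)
            row[i] = 1
            row[j] = 1
            if (i in group_a) != (j in group_a):
                row[4] = 1
            rows.append(row)
        X = np.array(rows)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = ((X @ coef - y) ** 2).sum()
        split = frozenset({labels[k] for k in range(4) if k not in group_a})
        if best is None or resid < best[0]:
            best = (resid, split)
    return best[1]


class TestGlobalAlign:
    def test_self_alignment_is_gap_free(self):
        aln = global_align("MKWVL", "MKWVL")
        assert aln.rows[0] == aln.rows[1] == "MKWVL"
        assert aln.score == sum(BLOSUM62[c, c] for c in "MKWVL")

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            a = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            aln = global_align(a, b)
            assert aln.score == pytest.approx(brute_force_score(a, b)), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")

    def test_rows_reproduce_inputs_without_gaps(self):
        aln = global_align("MKWVLAA", "MKVL")
        assert aln.rows[0].replace("-", "") == "MKWVLAA"
        assert aln.rows[1].replace("-", "") == "MKVL"


class TestPercentIdentity:
    def test_identical_rows(self):
        aln = Alignment(rows=("MKWV", "MKWV"))
        assert percent_identity(aln) == 1.0

    def test_gap_free_mismatch(self):
        aln = Alignment(rows=("AAAA", "AAAT"))
        assert percent_identity(aln) == 0.75

    def test_gapped_columns_excluded(self):
        # gapless columns 1,2,3,7 with identities at 1,3,7; 3 gapped columns ignored
        aln = Alignment(rows=("AAC--TG", "ATCGG-G"))
        assert percent_identity(aln) == pytest.approx(3 / 4)

    def test_all_gap_columns_undefined(self):
        with pytest.raises(ValueError):
            percent_identity(Alignment(rows=("A---", "-TTT")))


class TestJukesCantor:
    def test_zero_at_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        # d = -(19/20) ln(1 - (20/19) * 0.3)
        assert jc_distance(0.3, 20) == pytest.approx(0.36052, abs=5e-6)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            jc_distance(0.95, 20)
        with pytest.raises(SaturationError):
            jc_distance(0.75, 4)

    def test_small_p_limit(self):
        for p in (1e-4, 1e-5):
            assert jc_distance(p, 20) == pytest.approx(p, rel=1e-3)

    def test_increasing_and_convex(self):
        ps = np.linspace(0.0, 0.9, 50)
        ds = [jc_distance(p, 20) for p in ps]
        diffs = np.diff(ds)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) > 0)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 3.2], [3.2, 0]]))
        tree = neighbor_joining(dm)
        assert tree.path_length("A", "B") == pytest.approx(3.2)

    def test_four_taxon_topologies_match_ls_oracle(self):
        for seed in range(100):
            true = random_binary_tree(4, seed)
            dm = tree_distance_matrix(true)
            nj = neighbor_joining(dm)
            nj_splits = nj.bipartitions()
            if not nj_splits:  # star-like tree: oracle split is ambiguous
                continue
            assert ls_topology_oracle(dm) in nj_splits | {
                frozenset(dm.labels) - s for s in nj_splits
            }

    @pytest.mark.parametrize("n_taxa", [5, 6])
    def test_additive_matrices_recover_topology(self, n_taxa):
        for seed in range(50):
            true = random_binary_tree(n_taxa, seed)
            dm = tree_distance_matrix(true)
            nj = neighbor_joining(dm)
            assert nj.bipartitions() == true.bipartitions(), seed

    def test_additive_path_lengths_reproduced(self):
        true = random_binary_tree(6, 99)
        dm = tree_distance_matrix(true)
        nj = neighbor_joining(dm)
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                assert nj.path_length(a, b) == pytest.approx(
                    true.path_length(a, b), abs=1e-9
                )

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, -1], [-1, 0]], float))


class TestBootstrap:
    def make_perfect_alignment(self):
        # two pairs differing only between pairs: a single internal edge
        rows = ("AAAAAAAAAA", "AAAAAAAAAA", "TTTAAAAAAA", "TTTAAAAAAA")
        return Alignment(rows=rows, ids=("a1", "a2", "b1", "b2"))

    def test_perfect_signal_support_100(self):
        tree = bootstrap_support(self.make_perfect_alignment(), n_replicates=50, seed=1)
        supports = [
            n.support for n in _internal_nodes(tree.root) if n.support is not None
        ]
        assert supports == [100.0]

    def test_supports_bounded_and_leaves_unsupported(self):
        rng = np.random.default_rng(8)
        base = rng.choice(list("ACDEFGHIKL"), size=60)
        rows = []
        for _ in range(5):  # correlated rows keep p well below JC saturation
            mutated = base.copy()
            mask = rng.random(60) < 0.2
            mutated[mask] = rng.choice(list("ACDEFGHIKL"), size=int(mask.sum()))
            rows.append("".join(mutated))
        rows = tuple(rows)
        tree = bootstrap_support(Alignment(rows=rows), n_replicates=30, seed=2)
        for node in _internal_nodes(tree.root):
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0
        for leaf in tree.root.leaves():
            assert leaf.support is None

    def test_same_seed_reproducible(self):
        aln = self.make_perfect_alignment()
        t1 = bootstrap_support(aln, n_replicates=25, seed=7)
        t2 = bootstrap_support(aln, n_replicates=25, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.make_perfect_alignment(), n_replicates=0)


def _internal_nodes(node):
    if node.children:
        yield node
        for c in node.children:
            yield from _internal_nodes(c)


class TestCutClusters:
    def test_large_height_one_cluster(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert cut_clusters(tree, 100.0) == [{"A", "B", "C", "D"}]

    def test_zero_height_singletons(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clusters = cut_clusters(tree, 0.0)
        assert sorted(map(sorted, clusters)) == [["A"], ["B"], ["C"], ["D"]]

    def test_caterpillar_long_edge_splits_two(self):
        tree = read_newick("((A:0.1,B:0.1):5,(C:0.1,D:0.1):5);")
        clusters = cut_clusters(tree, 1.0)
        assert sorted(map(sorted, clusters)) == [["A", "B"], ["C", "D"]]

    def test_negative_height_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            cut_clusters(tree, -0.5)


class TestNewick:
    def test_two_leaf_parse(self):
        tree = read_newick("(A:1,B:1);")
        assert sorted(tree.leaf_names()) == ["A", "B"]

    def test_round_trip_topology_lengths_supports(self):
        for seed in range(5):
            tree = random_binary_tree(7, seed)
            text = write_newick(tree)
            back = read_newick(text)
            assert back.bipartitions() == tree.bipartitions()
            for a in tree.leaf_names():
                for b in tree.leaf_names():
                    if a < b:
                        assert back.path_length(a, b) == pytest.approx(
                            tree.path_length(a, b), rel=1e-5
                        )

    def test_supports_round_trip(self):
        aln = Alignment(
            rows=("AAAAAAAAAA", "AAAAAAAAAA", "TTTAAAAAAA", "TTTAAAAAAA"),
            ids=("a1", "a2", "b1", "b2"),
        )
        tree = bootstrap_support(aln, n_replicates=20, seed=3)
        back = read_newick(write_newick(tree))
        sup = [n.support for n in _internal_nodes(back.root) if n.support is not None]
        assert sup == [100.0]

    def test_malformed_newick_raises(self):
        with pytest.raises(NewickParseError):
            read_newick("(A:1,(B:1);")


class TestProgressiveAlignment:
    def test_rows_reproduce_inputs(self):
        records = [
            SequenceRecord(id="s1", residues="MKWVLAAG"),
            SequenceRecord(id="s2", residues="MKVLAAG"),
            SequenceRecord(id="s3", residues="MKWVLSAG"),
        ]
        aln = progressive_align(records)
        by_id = dict(zip(aln.ids, aln.rows))
        for rec in records:
            assert by_id[rec.id].replace("-", "") == rec.residues

    def test_distances_from_alignment_symmetric(self):
        records = [
            SequenceRecord(id="s1", residues="MKWVLAAGHHKL"),
            SequenceRecord(id="s2", residues="MKVVLAAGHHKL"),
            SequenceRecord(id="s3", residues="MKWVLSTGHHKL"),
        ]
        dm = distances_from_alignment(progressive_align(records))
        assert np.allclose(dm.values, dm.values.T)
        assert p_distance("MKWV", "MKVV") == 0.25
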