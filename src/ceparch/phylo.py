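"""Distance-based phylogenetics: alignment, Jukes-Cantor, neighbor joining.

The CEP comparison rests on a classical distance pipeline: pairwise global
alignments give mismatch proportions, the Jukes-Cantor correction turns
them into substitutions per site, and Saitou-Nei neighbor joining (NJ)
builds the tree, with column-bootstrap supports on internal edges.

The protein Jukes-Cantor correction uses the s-state generalization

    d = -((s-1)/s) * ln(1 - (s/(s-1)) * p),   s = 20 for proteins,

which reduces to the familiar 4-state nucleotide form at s = 4.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices

from ceparch.seq_io import SequenceRecord

GAP = "-"


class SaturationError(ValueError):
    """Mismatch proportion at or beyond the Jukes-Cantor saturation bound."""


class NewickParseError(ValueError):
    """Malformed newick input."""


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Gapped rows of equal length plus the substitution-matrix score."""

    rows: tuple[str, ...]
    ids: tuple[str, ...] = ()
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("all alignment rows must have equal length")
        if not self.ids:
            object.__setattr__(self, "ids", tuple(f"seq{i}" for i in range(len(self.rows))))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(a: str | SequenceRecord, b: str | SequenceRecord,
                 matrix: str = "BLOSUM62", gap_open: float = -11.0,
                 gap_extend: float = -1.0) -> Alignment:
    """Optimal global (Needleman-Wunsch/Gotoh) alignment under affine gaps.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``. The first
    optimal traceback is taken, which is deterministic for a given input.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    ida = a.id if isinstance(a, SequenceRecord) else "a"
    idb = b.id if isinstance(b, SequenceRecord) else "b"
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    return Alignment(rows=(str(aln[0]), str(aln[1])), ids=(ida, idb), score=aln.score)


def percent_identity(aln: Alignment) -> float:
    """Identities over columns where neither of the two rows has a gap."""
    if len(aln.rows) != 2:
        raise ValueError("percent_identity is defined for 2-row alignments")
    a, b = aln.rows
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        raise ValueError("undefined identity: no gapless columns")
    return sum(x == y for x, y in pairs) / len(pairs)


def p_distance(row_a: str, row_b: str) -> float:
    """Mismatch proportion over gapless column pairs of two gapped rows."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not pairs:
        raise ValueError("no gapless columns between rows")
    return sum(x != y for x, y in pairs) / len(pairs)


def jc_distance(p: float, states: int = 20) -> float:
    """Jukes-Cantor corrected distance (substitutions/site) from mismatch proportion."""
    s = states
    bound = (s - 1) / s
    if not 0 <= p:
        raise ValueError("p must be non-negative")
    if p >= bound:
        raise SaturationError(f"p = {p} saturates the {s}-state Jukes-Cantor correction (bound {bound:.4f})")
    return -bound * math.log(1.0 - p / bound)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distance matrix entries must be non-negative")

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("\t" + "\t".join(self.labels) + "\n")
        for lab, row in zip(self.labels, self.values):
            out.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        return out.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        first = lines[0].split()
        if len(first) == 1 and first[0].isdigit():  # PHYLIP square
            n = int(first[0])
            labels, rows = [], []
            for ln in lines[1 : n + 1]:
                parts = ln.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1 : n + 1]])
            return cls(tuple(labels), np.array(rows))
        labels = tuple(lines[0].lstrip("\t").split("\t"))
        rows = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
        return cls(labels, np.array(rows))


def distances_from_alignment(aln: Alignment, states: int = 20) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances from the gapless columns of an MSA."""
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(p_distance(aln.rows[i], aln.rows[j]), states)
    return DistanceMatrix(aln.ids, d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0           # branch length to the parent
    support: float | None = None  # bootstrap percentage on the parent edge
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Rooted representation of an (unrooted) NJ tree."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is canonicalized as the side that does not contain
        the lexicographically smallest leaf, making the set invariant to
        rooting and to leaf input order.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if anchor in below else below
                parts.add(side)
            return below

        walk(self.root)
        return parts

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def find(node: TreeNode, target: str, acc: list[TreeNode]) -> bool:
            acc.append(node)
            if node.is_leaf and node.name == target:
                return True
            for c in node.children:
                if find(c, target, acc):
                    return True
            acc.pop()
            return False

        pa: list[TreeNode] = []
        pb: list[TreeNode] = []
        if not find(self.root, a, pa) or not find(self.root, b, pb):
            raise KeyError(f"leaf not in tree: {a!r} or {b!r}")
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j is
    joined (ties broken by lexicographic label order); branch lengths come
    from the standard formulas. Negative branch lengths are clamped to 0
    with the deficit transferred to the sister edge unless
    ``clamp_negative`` is False. The unrooted result is reported rooted at
    the final join.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    reps: list[str] = list(dm.labels)  # smallest leaf label per cluster, for tie-breaks
    d = dm.values.astype(float).copy()

    def _clamped(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(0.0, li + lj), 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(reps[i], reps[j]), max(reps[i], reps[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamped(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        newrep = min(reps[i], reps[j])
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dn[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [newrep]
        d = d2

    if len(nodes) == 2:
        a, b = nodes
        a.length, b.length = 0.5 * d[0, 1], 0.5 * d[0, 1]
        return PhyloTree(root=TreeNode(children=[a, b]))
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if clamp_negative:
        la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    a.length, b.length, c.length = la, lb, lc
    return PhyloTree(root=TreeNode(children=[a, b, c]))


def bootstrap_support(aln: Alignment, n_replicates: int = 100, seed: int = 0,
                      states: int = 20) -> PhyloTree:
    """NJ tree from an MSA with column-bootstrap supports on internal edges.

    Columns are resampled with replacement (seeded); each replicate runs
    p-distance -> Jukes-Cantor -> NJ; the support of an internal edge is
    the percentage of replicate trees containing the same leaf bipartition.
    Supports are reported on the point-estimate tree; leaf edges carry none.
    """
    if len(aln.rows) < 3:
        raise ValueError("bootstrap needs an alignment of at least 3 rows")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = neighbor_joining(distances_from_alignment(aln, states))
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(row[i] for i in idx) for row in aln.rows)
        rep_tree = neighbor_joining(
            distances_from_alignment(Alignment(rows=rows, ids=aln.ids), states)
        )
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(point.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if anchor in below else below
            node.support = 100.0 * counts[side] / n_replicates
        return below

    annotate(point.root)
    return point


def cut_clusters(tree: PhyloTree, height: float) -> list[set[str]]:
    """Partition leaves by removing edges whose depth exceeds *height*.

    Depth of a node is its path length from the root of its component.
    The cut is deterministic; height 0 yields singletons (for strictly
    positive branch lengths) and a height above the tree depth yields a
    single cluster.
    """
    if height < 0:
        raise ValueError("height must be non-negative")
    clusters: list[set[str]] = []

    def walk(node: TreeNode, depth: float, cluster: set[str]) -> None:
        if node.is_leaf:
            cluster.add(node.name)
            return
        for child in node.children:
            child_depth = depth + child.length
            if child_depth > height:
                fresh: set[str] = set()
                clusters.append(fresh)
                walk(child, 0.0, fresh)
            else:
                walk(child, child_depth, cluster)

    top: set[str] = set()
    clusters.append(top)
    walk(tree.root, 0.0, top)
    return [c for c in clusters if c]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths (6 significant digits) and supports as
    internal-node labels."""

    def fmt(node: TreeNode, is_root: bool = False) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{node.length:.6g}"

    return fmt(tree.root, is_root=True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse newick text (supports read back from internal-node labels)."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from None

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon is not None else None
        support = None
        if children and dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = dnode.label
        return TreeNode(
            name=name,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            support=support,
            children=children,
        )

    root = convert(dtree.seed_node)
    if not root.leaves() or all(l.name is None for l in root.leaves()):
        raise NewickParseError("malformed newick: no labeled leaves")
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Progressive multiple alignment (guide-tree based)
# ---------------------------------------------------------------------------

def _profile_consensus(rows: Sequence[str]) -> str:
    cols = []
    for i in range(len(rows[0])):
        col = [r[i] for r in rows if r[i] != GAP]
        if not col:
            cols.append("X")
        else:
            top = max(col.count(c) for c in set(col))
            cols.append(min(c for c in set(col) if col.count(c) == top))
    return "".join(cols)


def _merge_profiles(pa: tuple[tuple[str, ...], tuple[str, ...]],
                    pb: tuple[tuple[str, ...], tuple[str, ...]],
                    matrix: str, gap_open: float, gap_extend: float):
    rows_a, ids_a = pa
    rows_b, ids_b = pb
    ca, cb = _profile_consensus(rows_a), _profile_consensus(rows_b)
    aln = global_align(ca, cb, matrix, gap_open, gap_extend)
    ga, gb = aln.rows

    def expand(rows: tuple[str, ...], gapped: str) -> tuple[str, ...]:
        out = []
        for row in rows:
            buf, k = [], 0
            for ch in gapped:
                if ch == GAP:
                    buf.append(GAP)
                else:
                    buf.append(row[k])
                    k += 1
            out.append("".join(buf))
        return tuple(out)

    return expand(rows_a, ga) + expand(rows_b, gb), ids_a + ids_b


def progressive_align(records: Sequence[SequenceRecord], matrix: str = "BLOSUM62",
                      gap_open: float = -11.0, gap_extend: float = -1.0) -> Alignment:
    """Progressive MSA over an NJ guide tree of pairwise alignment distances.

    Pairwise identities come from global alignments; the guide tree is NJ
    on the corresponding mismatch proportions; profiles are merged by
    aligning column-majority consensus sequences. This is a light-weight
    stand-in adequate for distance and bootstrap machinery, not a
    high-fidelity MSA.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], matrix, gap_open, gap_extend)
            d[i, j] = d[j, i] = 1.0 - percent_identity(aln)
    guide = neighbor_joining(DistanceMatrix(tuple(r.id for r in records), d))
    by_id = {r.id: r for r in records}

    def build(node: TreeNode):
        if node.is_leaf:
            rec = by_id[node.name]
            return (rec.residues,), (rec.id,)
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof = _merge_profiles(prof, build(child), matrix, gap_open, gap_extend)
        return prof

    rows, ids = build(guide.root)
    return Alignment(rows=rows, ids=ids)
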