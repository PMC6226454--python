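"""Distance-based phylogeny: pairwise-gap-deletion distances, a
Saitou-Nei neighbor-joining implementation, bootstrap supports, subfamily
extraction by longest-edge cutting, and sister-pair (cherry) listing.

Distances are computed on pairwise global alignments (BLOSUM62, affine
gaps 10/0.5) rather than one progressive multiple alignment; each pair's
alignment columns containing a gap are deleted before counting
mismatches.  The bootstrap accordingly resamples per-pair alignment
columns, with all per-pair draws flowing from one seeded generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .duplication import smith_waterman
from .models import ParalogPair, ProteinRecord


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("non-zero diagonal")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def alignment_columns(proteins: list[ProteinRecord]) -> dict[tuple[int, int], np.ndarray]:
    """For every protein pair, the boolean mismatch vector over the
    gap-free columns of their global alignment (the unit the bootstrap
    resamples)."""
    aligner = _make_aligner()
    cols: dict[tuple[int, int], np.ndarray] = {}
    for i, j in itertools.combinations(range(len(proteins)), 2):
        aln = aligner.align(proteins[i].sequence, proteins[j].sequence)[0]
        sa, sb = str(aln[0]), str(aln[1])
        arr_a = np.frombuffer(sa.encode(), dtype="S1")
        arr_b = np.frombuffer(sb.encode(), dtype="S1")
        keep = (arr_a != b"-") & (arr_b != b"-")
        cols[(i, j)] = (arr_a[keep] != arr_b[keep])
    return cols


def _distances_from_columns(
    taxa: list[str],
    cols: dict[tuple[int, int], np.ndarray],
    model: str,
    resample: np.random.Generator | None = None,
) -> DistanceMatrix:
    n = len(taxa)
    d = np.zeros((n, n))
    for (i, j), mism in cols.items():
        if mism.size == 0:
            p = 0.0
        elif resample is not None:
            idx = resample.integers(0, mism.size, mism.size)
            p = float(mism[idx].mean())
        else:
            p = float(mism.mean())
        if model == "poisson":
            if p >= 1.0:
                raise ValueError(
                    f"Poisson distance undefined for fully diverged pair "
                    f"({taxa[i]}, {taxa[j]})"
                )
            p = -np.log(1.0 - p)
        elif model != "p-distance":
            raise ValueError(f"unknown distance model {model!r}")
        d[i, j] = d[j, i] = p
    return DistanceMatrix(list(taxa), d)


def pairwise_distances(
    proteins: list[ProteinRecord], model: str = "p-distance"
) -> DistanceMatrix:
    """Pairwise-gap-deletion distances from pairwise global alignments.

    ``model`` is ``p-distance`` (mismatches over compared columns) or
    ``poisson`` (-ln(1-p)).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    cols = alignment_columns(proteins)
    return _distances_from_columns([p.id for p in proteins], cols, model)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap support of the edge to parent
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset((self.name,))
        return frozenset().union(*(c.leaf_names() for c in self.children))


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root (the final
    neighbor-joining join, a trifurcation)."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def internal_edges(self) -> list[TreeNode]:
        """Edges (identified by their child node) whose removal splits the
        leaf set into two parts of size >= 2."""
        total = len(self.leaves())
        out = []
        for node in self.nodes():
            if node.parent is None or node.is_leaf:
                continue
            below = len(node.leaf_names())
            if 2 <= below <= total - 2:
                out.append(node)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical bipartitions induced by internal edges: the side not
        containing the lexicographically smallest taxon."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out = set()
        for node in self.internal_edges():
            side = node.leaf_names()
            out.add(all_leaves - side if ref in side else side)
        return out

    def cherries(self) -> list[tuple[str, str]]:
        """Leaf pairs adjacent to a common internal node, sorted."""
        out = []
        for node in self.nodes():
            leaf_children = sorted(c.name for c in node.children if c.is_leaf)
            if len(leaf_children) >= 2:
                for a, b in itertools.combinations(leaf_children, 2):
                    out.append((a, b))
        return sorted(out)

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6f}"

        return fmt(self.root) + ";"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative NJ estimates: clamp to 0, moving the deficit to the sibling
    if la < 0:
        lb, la = lb + la, 0.0
    if lb < 0:
        la, lb = la + lb, 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j, ties
    broken by the lexicographically smallest (min-leaf, max-leaf) label
    pair of the candidate nodes.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    labels = [t for t in dm.taxa]  # min leaf name under each active node
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            la, lb = sorted((labels[active[ai]], labels[active[aj]]))
            key = (q, la, lb)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            child.parent = parent
            child.length = length
            parent.children.append(child)
        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    a = (d[i, j] + d[i, k] - d[j, k]) / 2
    b = (d[i, j] + d[j, k] - d[i, k]) / 2
    c = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = TreeNode()
    for child, length in ((nodes[i], a), (nodes[j], b), (nodes[k], c)):
        child.parent = root
        child.length = max(length, 0.0)
        root.children.append(child)
    return PhyloTree(root)


def tree_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Path-length distance between two leaves."""
    by_name = {leaf.name: leaf for leaf in tree.leaves()}
    na, nb = by_name[a], by_name[b]

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    pa = path_to_root(na)
    pb = path_to_root(nb)
    ancestors_a = {id(x): i for i, x in enumerate(pa)}
    for x in pb:
        if id(x) in ancestors_a:
            lca = x
            break
    dist = 0.0
    node = na
    while node is not lca:
        dist += node.length
        node = node.parent
    node = nb
    while node is not lca:
        dist += node.length
        node = node.parent
    return dist


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_supports(
    proteins: list[ProteinRecord],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p-distance",
    resample: bool = True,
) -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Per replicate, each pair's gap-deleted alignment columns are resampled
    with replacement (all draws from one seeded generator); the support of
    an edge is 100 x the fraction of replicate trees containing its
    bipartition.  ``resample=False`` scores the original columns in every
    replicate (a determinism check: every support becomes 100).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = [p.id for p in proteins]
    cols = alignment_columns(proteins)
    tree = nj_tree(_distances_from_columns(taxa, cols, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        dm = _distances_from_columns(taxa, cols, model, resample=rng if resample else None)
        for bp in nj_tree(dm).bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    for node in tree.internal_edges():
        side = node.leaf_names()
        bp = all_leaves - side if ref in side else side
        node.support = 100.0 * counts[bp] / n_reps
    return tree


# ---------------------------------------------------------------------------
# subfamilies and sister pairs

def _leaf_groups(tree: PhyloTree, cut: set[int]) -> list[set[str]]:
    """Leaf sets of the connected components left after removing the cut
    edges (each edge identified by the id of its child node)."""
    groups: list[set[str]] = []
    seen: set[int] = set()

    def collect(node: TreeNode, group: set[str]) -> None:
        seen.add(id(node))
        if node.is_leaf:
            group.add(node.name)
        for c in node.children:
            if id(c) not in cut and id(c) not in seen:
                collect(c, group)
        if (
            node.parent is not None
            and id(node) not in cut
            and id(node.parent) not in seen
        ):
            collect(node.parent, group)

    for node in tree.nodes():
        if id(node) not in seen:
            group: set[str] = set()
            collect(node, group)
            if group:
                groups.append(group)
    return groups


def cut_subfamilies(tree: PhyloTree, k: int) -> dict[str, str]:
    """Partition leaves into ``k`` groups by removing the longest internal
    edges (ties by higher support, then by bipartition label), then label
    groups A, B, ... by decreasing size, ties by smallest member id.

    When fewer than k-1 internal edges exist (k close to the leaf count),
    terminal edges are cut as well, longest first, until k leaf groups
    remain.
    """
    leaves = tree.leaf_names()
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k={k} outside [1, {len(leaves)}]")

    def sort_key(node: TreeNode):
        return (
            -node.length,
            -(node.support if node.support is not None else -1.0),
            tuple(sorted(node.leaf_names())),
        )

    candidates = sorted(tree.internal_edges(), key=sort_key) + sorted(
        (n for n in tree.nodes() if n.is_leaf and n.parent is not None),
        key=sort_key,
    )
    cut: set[int] = set()
    groups = _leaf_groups(tree, cut)
    for node in candidates:
        if len(groups) >= k:
            break
        cut.add(id(node))
        groups = _leaf_groups(tree, cut)

    groups.sort(key=lambda g: (-len(g), min(g)))
    labels = {}
    for idx, group in enumerate(groups):
        label = chr(ord("A") + idx)
        for name in group:
            labels[name] = label
    return labels


def sister_pairs(
    tree: PhyloTree,
    proteins: list[ProteinRecord],
    identity_min: float = 0.95,
) -> list[ParalogPair]:
    """Terminal cherries whose Smith-Waterman identity reaches
    ``identity_min``, as candidate paralog pairs."""
    seq_of = {p.id: p.sequence for p in proteins}
    out = []
    for a, b in tree.cherries():
        identity = smith_waterman(seq_of[a], seq_of[b]).identity
        if identity >= identity_min:
            out.append(ParalogPair(a, b, identity))
    return out
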