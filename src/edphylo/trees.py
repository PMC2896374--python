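"""Rooted phylogenetic trees: Newick/Nexus I/O, rooting, pruning, the
Brownian-motion variance–covariance matrix, and majority-rule consensus.

Trees are rooted, may contain polytomies, and carry non-negative branch
lengths (absent lengths are recorded as ``None``, never coerced to zero).
Internal nodes may carry a support value in [0, 1], e.g. a Bayesian posterior
probability or a consensus split frequency.

Parsing is delegated to :mod:`dendropy`; the parsed tree is converted into a
small internal node structure so that the semantics of rerooting, pruning and
consensus building are fully under this module's control.  Writing is
canonical: children are ordered by their lexicographically smallest descendant
label, so structurally equal trees serialize identically.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSample",
    "Bipartition",
    "CovMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "root_on_outgroup",
    "prune",
    "vcv_matrix",
    "majority_rule_consensus",
    "discard_burnin",
]


class NewickParseError(ValueError):
    """Malformed Newick/Nexus input."""


class TreeValidationError(ValueError):
    """A tree (or tree sample) violates a structural invariant."""


# ---------------------------------------------------------------------------
# Core structure
# ---------------------------------------------------------------------------

_UNQUOTED_LABEL = re.compile(r"^[A-Za-z0-9_.+|-]+$")


@dataclass(eq=False)  # identity semantics: nodes are places in a tree
class _Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def clone(self) -> "_Node":
        return _Node(
            self.label,
            self.length,
            self.support,
            [c.clone() for c in self.children],
        )


class PhyloTree:
    """A rooted tree with labelled leaves and optional branch lengths.

    Instances are lightweight wrappers around a recursive node structure;
    all mutating-style operations (:meth:`root_on_outgroup`, :meth:`prune`)
    return new trees and leave the receiver untouched.
    """

    def __init__(self, root: _Node):
        self._root = root
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def _validate(self) -> None:
        labels: list[str] = []
        stack = [(self._root, True)]
        while stack:
            node, is_root = stack.pop()
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf with empty label")
                labels.append(node.label)
            else:
                if not is_root and len(node.children) < 1:
                    raise TreeValidationError("internal node without children")
                for c in node.children:
                    stack.append((c, False))
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length!r} "
                    f"above {node.label or 'an internal node'}"
                )
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {sorted(dupes)}")

    # -- basic queries ------------------------------------------------------

    @property
    def root(self) -> _Node:
        return self._root

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in canonical (sorted-subtree) traversal order."""
        out: list[str] = []

        def walk(n: _Node) -> None:
            if n.is_leaf:
                out.append(n.label)  # type: ignore[arg-type]
            else:
                for c in _canonical_children(n):
                    walk(c)

        walk(self._root)
        return tuple(out)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._root.clone())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_leaves} leaves)"

    # -- metrics ------------------------------------------------------------

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-tip path length per leaf; raises if a length is absent."""
        depths: dict[str, float] = {}

        def walk(n: _Node, d: float, is_root: bool) -> None:
            if not is_root:
                if n.length is None:
                    raise TreeValidationError(
                        f"missing branch length above "
                        f"{n.label or 'an internal node'}"
                    )
                d += n.length
            if n.is_leaf:
                depths[n.label] = d  # type: ignore[index]
            else:
                for c in n.children:
                    walk(c, d, False)

        walk(self._root, 0.0, True)
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = list(self.leaf_depths().values())
        span = max(d) - min(d)
        return span <= rel_tol * max(max(d), 1.0)

    def clades(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Leaf-label sets below each edge (the rooted analogue of splits).

        The root's full leaf set is always excluded; singleton (tip) clades
        are included only when ``include_trivial`` is set.
        """
        out: set[frozenset[str]] = set()

        def walk(n: _Node, is_root: bool) -> frozenset[str]:
            if n.is_leaf:
                s = frozenset([n.label])
                if include_trivial:
                    out.add(s)
                return s
            s = frozenset().union(*(walk(c, False) for c in n.children))
            if not is_root:
                out.add(s)
            return s

        walk(self._root, True)
        return out

    # -- operations (method forms of the module-level functions) ------------

    def to_newick(self) -> str:
        return write_newick(self)

    def root_on_outgroup(self, outgroup_label: str) -> "PhyloTree":
        return root_on_outgroup(self, outgroup_label)

    def prune(self, keep_labels: Iterable[str]) -> "PhyloTree":
        return prune(self, keep_labels)

    def vcv(self, label_order: Sequence[str] | None = None) -> "CovMatrix":
        return vcv_matrix(self, label_order)


@dataclass(frozen=True)
class Bipartition:
    """An unordered two-sided partition of the leaf set.

    Equality ignores which side is ``side_a``; consensus machinery mostly
    works with rooted clades, but this type is the unrooted view of an edge.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise TreeValidationError("bipartition side may not be empty")
        if self.side_a & self.side_b:
            raise TreeValidationError("bipartition sides must be disjoint")

    def _key(self) -> frozenset[frozenset[str]]:
        return frozenset((self.side_a, self.side_b))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


class TreeSample:
    """An ordered collection of rooted trees over one common leaf set."""

    def __init__(
        self,
        trees: Sequence[PhyloTree],
        generation_index: Sequence[int] | None = None,
    ):
        trees = list(trees)
        if not trees:
            raise TreeValidationError("empty tree sample")
        ref = set(trees[0].leaf_labels)
        for i, t in enumerate(trees[1:], start=1):
            if set(t.leaf_labels) != ref:
                raise TreeValidationError(
                    f"tree {i} has a different leaf set from tree 0"
                )
        if generation_index is not None and len(generation_index) != len(trees):
            raise TreeValidationError("generation_index length mismatch")
        self.trees = trees
        self.generation_index = (
            list(generation_index) if generation_index is not None else None
        )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.trees[0].leaf_labels)


@dataclass(frozen=True)
class CovMatrix:
    """Species covariance implied by shared root-to-node path lengths.

    ``values[i, j]`` is the branch-length distance from the root to the most
    recent common ancestor of species ``labels[i]`` and ``labels[j]``; the
    diagonal holds root-to-tip distances.  Symmetric and positive
    semi-definite by construction.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TreeValidationError("covariance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise TreeValidationError("labels do not match matrix dimension")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12):
            raise TreeValidationError("covariance matrix must be symmetric")

    def submatrix(self, labels: Sequence[str]) -> "CovMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CovMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Newick / Nexus I/O
# ---------------------------------------------------------------------------


def _support_from_label(label: str | None) -> float | None:
    # Numeric internal labels are read as supports: [0,1] directly,
    # (1,100] as percentages.
    if label is None:
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    if 0.0 <= v <= 1.0:
        return v
    if 1.0 < v <= 100.0:
        return v / 100.0
    return None


def _from_dendropy(dnode: "dendropy.Node", is_root: bool) -> _Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = _Node(label=label, length=dnode.edge.length)
    else:
        node = _Node(
            length=None if is_root else dnode.edge.length,
            support=_support_from_label(dnode.label),
            children=[_from_dendropy(c, False) for c in dnode.child_nodes()],
        )
    return node


def _suppress_unifurcations(node: _Node) -> _Node:
    node.children = [_suppress_unifurcations(c) for c in node.children]
    if len(node.children) == 1:
        child = node.children[0]
        if node.length is not None and child.length is not None:
            child.length = node.length + child.length
        elif node.length is not None:
            child.length = node.length
        return child
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted tree from a Newick string.

    Branch lengths are optional and recorded as absent (``None``) when not
    given.  Quoted labels, scientific-notation lengths, and numeric internal
    labels (read as supports) are accepted.  A trailing semicolon is
    tolerated absent.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    if not text.endswith(";"):
        text += ";"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            raise TreeValidationError(f"duplicate leaf labels: {msg}") from None
        raise NewickParseError(f"malformed Newick: {msg}") from None
    root = _from_dendropy(dtree.seed_node, True)
    root = _suppress_unifurcations(root)
    root.length = None
    return PhyloTree(root)


def _fmt_length(x: float) -> str:
    s = np.format_float_positional(float(x), trim="-")
    return s


def _fmt_label(label: str) -> str:
    if _UNQUOTED_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _min_descendant(n: _Node) -> str:
    if n.is_leaf:
        return n.label  # type: ignore[return-value]
    return min(_min_descendant(c) for c in n.children)


def _canonical_children(n: _Node) -> list[_Node]:
    return sorted(n.children, key=_min_descendant)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to canonical Newick.

    Children are ordered by their lexicographically smallest descendant
    label; supports are emitted as internal-node labels (3 significant
    digits); a trailing semicolon is always present.
    """

    def fmt(n: _Node, is_root: bool) -> str:
        if n.is_leaf:
            s = _fmt_label(n.label)  # type: ignore[arg-type]
        else:
            inner = ",".join(fmt(c, False) for c in _canonical_children(n))
            s = f"({inner})"
            if n.support is not None:
                s += f"{n.support:.3g}"
        if not is_root and n.length is not None:
            s += f":{_fmt_length(n.length)}"
        return s

    return fmt(tree.root, True) + ";"


def read_tree_sample(source: str, path: bool | None = None) -> TreeSample:
    """Read a multi-tree file: Newick one-per-line, or a Nexus trees block.

    ``source`` is a file path unless it contains a newline/parenthesis, in
    which case it is treated as raw text (``path`` forces either reading).
    Nexus input (detected by the ``#NEXUS`` magic) is read with dendropy's
    translate-table-aware reader; all non-tree blocks are ignored.
    """
    if path is None:
        path = "(" not in source and "\n" not in source
    if path:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source
    if not text.strip():
        raise NewickParseError("no trees in input")
    if text.lstrip().lower().startswith("#nexus"):
        try:
            dtrees = dendropy.TreeList.get(
                data=text,
                schema="nexus",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise NewickParseError(f"malformed Nexus: {exc}") from None
        trees = []
        for dt in dtrees:
            root = _from_dendropy(dt.seed_node, True)
            root = _suppress_unifurcations(root)
            root.length = None
            trees.append(PhyloTree(root))
        return TreeSample(trees)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    return TreeSample([parse_newick(ln) for ln in lines])


# ---------------------------------------------------------------------------
# Rooting and pruning
# ---------------------------------------------------------------------------


def root_on_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Reroot so the named leaf is a direct child of the root.

    The root is placed at the midpoint of the outgroup's branch (halving its
    length); if the tree is already rooted on the outgroup it is returned
    unchanged (a copy).  Supports along the reversed path are dropped, since
    the clades they annotated no longer exist.
    """
    if outgroup_label not in set(tree.leaf_labels):
        raise KeyError(f"outgroup label {outgroup_label!r} not in tree")
    root = tree.root.clone()
    root_child = next(
        (
            c
            for c in root.children
            if c.is_leaf and c.label == outgroup_label
        ),
        None,
    )
    if root_child is not None:
        if len(root.children) == 2:
            return PhyloTree(root)
        # Polytomous ("unrooted-style") root: split the outgroup branch.
        half = None if root_child.length is None else root_child.length / 2.0
        others = [c for c in root.children if c is not root_child]
        ingroup = _Node(length=half, children=others)
        leaf = _Node(label=outgroup_label, length=half)
        return PhyloTree(_Node(children=[leaf, ingroup]))

    # locate the ancestor path parent(outgroup leaf) -> ... -> root
    path: list[_Node] = []

    def find(n: _Node) -> bool:
        if n.is_leaf:
            return n.label == outgroup_label
        for c in n.children:
            if find(c):
                path.append(n)
                return True
        return False

    find(root)
    parents = path  # [parent-of-leaf, ..., root]
    leaf = next(
        c for c in parents[0].children if c.is_leaf and c.label == outgroup_label
    )

    def _add(a: float | None, b: float | None) -> float | None:
        if a is None and b is None:
            return None
        return (a or 0.0) + (b or 0.0)

    # Reverse the path: p0 (the leaf's parent) becomes a child of the new
    # root; each former parent p_{i+1} hangs below p_i with the edge length
    # that previously pointed the other way.  Returns (node, splice) where a
    # non-None splice means the old root was bifurcating and its two incident
    # edges must be merged into one by the caller.
    def reversed_node(i: int) -> tuple[_Node, float | None]:
        p = parents[i]
        drop = leaf if i == 0 else parents[i - 1]
        kids = [c for c in p.children if c is not drop]
        if i + 1 < len(parents):
            up, splice = reversed_node(i + 1)
            up = up if splice is None else up.clone()
            up.length = p.length if splice is None else _add(p.length, splice)
            kids.append(up)
        if len(kids) == 1:
            return kids[0], kids[0].length
        return _Node(children=kids), None

    half = None if leaf.length is None else leaf.length / 2.0
    ingroup, splice = reversed_node(0)
    ingroup.length = half if splice is None else _add(half, splice)
    new_leaf = _Node(label=outgroup_label, length=half)
    return PhyloTree(_Node(children=[new_leaf, ingroup]))


def prune(
    tree: PhyloTree, keep_labels: Iterable[str], keep_stem: bool = False
) -> PhyloTree:
    """Restrict the tree to ``keep_labels``.

    Degree-2 internal nodes created by the removal are suppressed with their
    branch lengths summed, so path lengths among retained leaves are
    preserved.  By default any stem above the retained subtree's most basal
    node is discarded — the MRCA of the kept leaves becomes the root at
    depth 0, the comparative-methods convention under which the covariance
    matrix is defined relative to the ingroup root.  With ``keep_stem`` the
    original root's position is preserved (the stem length stays on the edge
    below it), so root-to-tip distances of retained leaves are unchanged and
    the pruned tree's covariance equals the corresponding submatrix of the
    full tree's.
    """
    keep = set(keep_labels)
    have = set(tree.leaf_labels)
    unknown = keep - have
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 labels to keep")

    def walk(n: _Node) -> _Node | None:
        if n.is_leaf:
            return n.clone() if n.label in keep else None
        kids = [w for w in (walk(c) for c in n.children) if w is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            if n.length is not None and only.length is not None:
                only.length = n.length + only.length
            elif n.length is not None:
                only.length = n.length
            return only
        return _Node(length=n.length, support=n.support, children=kids)

    root = walk(tree.root)
    assert root is not None
    if keep_stem:
        if root is not tree.root and root.length is not None:
            # the kept MRCA sits below the old root: keep its depth by
            # hanging it from a fresh root on its accumulated stem edge
            root = _Node(children=[root])
    else:
        while len(root.children) == 1:
            root = root.children[0]
    root.length = None
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------


def vcv_matrix(
    tree: PhyloTree, label_order: Sequence[str] | None = None
) -> CovMatrix:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA(i, j) distance.

    Under Brownian trait evolution with rate sigma^2, tip values are jointly
    normal with covariance sigma^2 * C; the diagonal is each species'
    root-to-tip distance.  All branch lengths must be present.
    """
    if label_order is None:
        label_order = list(tree.leaf_labels)
    else:
        label_order = list(label_order)
        missing = set(label_order) - set(tree.leaf_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(label_order) != tree.n_leaves:
            raise TreeValidationError(
                "label_order must cover every leaf exactly once"
            )
    idx = {l: i for i, l in enumerate(label_order)}
    n = len(label_order)
    C = np.zeros((n, n))

    def walk(node: _Node, depth: float, is_root: bool) -> list[int]:
        if not is_root:
            if node.length is None:
                raise TreeValidationError(
                    f"missing branch length above "
                    f"{node.label or 'an internal node'}"
                )
            depth += node.length
        if node.is_leaf:
            i = idx[node.label]  # type: ignore[index]
            C[i, i] = depth
            return [i]
        groups = [walk(c, depth, False) for c in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depth
        return [i for g in groups for i in g]

    walk(tree.root, 0.0, True)
    return CovMatrix(tuple(label_order), C)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def majority_rule_consensus(
    sample: TreeSample, threshold: float = 0.5
) -> PhyloTree:
    """Strict majority-rule consensus of a rooted tree sample.

    The consensus contains exactly the clades whose sample frequency is
    strictly greater than ``threshold`` (ties at the threshold excluded, so
    mutually incompatible splits can never co-occur for threshold >= 0.5).
    Retained internal nodes carry support = frequency; regions without a
    majority resolution collapse to polytomies.  Branch lengths are the mean
    over the trees that contain the clade (trees lacking it contribute
    nothing); compatible minority clades are never added.
    """
    if not 0.5 <= threshold < 1.0:
        raise TreeValidationError("threshold must be in [0.5, 1)")
    n_trees = len(sample)
    labels = sorted(sample.leaf_labels)
    full = frozenset(labels)

    counts: dict[frozenset[str], int] = {}
    length_sum: dict[frozenset[str], float] = {}
    length_n: dict[frozenset[str], int] = {}

    def record(clade: frozenset[str], length: float | None) -> None:
        counts[clade] = counts.get(clade, 0) + 1
        if length is not None:
            length_sum[clade] = length_sum.get(clade, 0.0) + length
            length_n[clade] = length_n.get(clade, 0) + 1

    for t in sample:
        def walk(n: _Node, is_root: bool) -> frozenset[str]:
            if n.is_leaf:
                s = frozenset([n.label])
                record(s, n.length)
                return s
            s = frozenset().union(*(walk(c, False) for c in n.children))
            if not is_root:
                record(s, n.length)
            return s

        walk(t.root, True)

    cut = threshold * n_trees
    kept = [
        (clade, c)
        for clade, c in counts.items()
        if c > cut and len(clade) > 1 and clade != full
    ]
    # Nest clades: sort by size descending; every kept clade's parent is the
    # smallest kept superset (or the root).  Strict-majority clades are
    # pairwise compatible, so this nesting is well defined.
    kept.sort(key=lambda kc: (-len(kc[0]), sorted(kc[0])[0]))

    def mean_len(clade: frozenset[str]) -> float | None:
        if length_n.get(clade, 0) == 0:
            return None
        return length_sum[clade] / length_n[clade]

    nodes: dict[frozenset[str], _Node] = {
        full: _Node(children=[])
    }
    parent_of: dict[frozenset[str], frozenset[str]] = {}
    ordered: list[frozenset[str]] = [full]
    for clade, c in kept:
        candidates = [s for s in ordered if clade < s]
        parent = min(candidates, key=len)
        node = _Node(
            length=mean_len(clade),
            support=c / n_trees,
            children=[],
        )
        nodes[clade] = node
        parent_of[clade] = parent
        ordered.append(clade)

    # attach internal nodes
    for clade, _c in kept:
        nodes[parent_of[clade]].children.append(nodes[clade])
    # attach leaves to the smallest containing clade
    for label in labels:
        containing = [s for s in ordered if label in s]
        host = min(containing, key=len)
        leaf_clade = frozenset([label])
        nodes[host].children.append(
            _Node(label=label, length=mean_len(leaf_clade))
        )
    return PhyloTree(nodes[full])


def discard_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Drop the first ceil(fraction * N) trees, preserving order."""
    if not 0.0 <= fraction < 1.0:
        raise TreeValidationError("burn-in fraction must be in [0, 1)")
    n = len(sample)
    drop = math.ceil(fraction * n)
    if drop >= n:
        raise TreeValidationError("burn-in removes the entire sample")
    gi = (
        sample.generation_index[drop:]
        if sample.generation_index is not None
        else None
    )
    return TreeSample(sample.trees[drop:], gi)
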