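"""Rooted phylogenies over genome identifiers.

The tree is the substrate for every comparative statistic in the package:
covariance construction for the regressions, sister-clade recursions for the
D statistic, and monophyletic host-clade detection. Trees are held as flat
node arrays (parent pointers, children lists, branch lengths) indexed so
that tips come first, which keeps the numerical kernels simple and fast.
Newick parsing is delegated to dendropy; serialization is done in-package
so that branch lengths survive a round trip bit-faithfully.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeError",
    "HostClade",
    "read_newick",
    "find_host_clades",
]

FREE_LIVING = "free-living"


class TreeError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


@dataclass
class HostClade:
    """A maximal monophyletic clade whose tips all share one host category."""

    clade_root: int
    host_category: str
    member_tips: List[str]

    def __len__(self) -> int:
        return len(self.member_tips)


class PhyloTree:
    """Rooted tree with branch lengths; tips are genome identifiers.

    Node indexing: tips occupy indices ``0 .. n_tips-1`` (in the order of
    ``tip_labels``); internal nodes follow. ``parent[root] == -1``.
    ``branch_length[i]`` is the length of the edge above node ``i`` (0 for
    the root). Polytomies are permitted.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_length: Sequence[Optional[float]],
        tip_labels: Sequence[str],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.n_nodes = len(self.parent)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        bl = [0.0 if b is None else float(b) for b in branch_length]
        self.has_lengths = all(b is not None for b in branch_length[: self.n_nodes])
        self.branch_length = np.asarray(bl, dtype=np.float64)
        self._validate()
        self.children: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        (root,) = np.flatnonzero(self.parent == -1)
        self.root = int(root)
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        if self.n_tips < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            dups = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {', '.join(dups)}")
        if any(not t for t in self.tip_labels):
            raise TreeError("empty tip label")
        n_roots = int(np.sum(self.parent == -1))
        if n_roots != 1:
            raise TreeError(f"expected exactly one root, found {n_roots}")
        if np.any(self.branch_length < 0):
            i = int(np.argmin(self.branch_length))
            raise TreeError(f"negative branch length {self.branch_length[i]} at node {i}")

    def _postorder(self) -> np.ndarray:
        order: List[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse one Newick string (';'-terminated). Internal labels are
        permitted and ignored; polytomies are permitted."""
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse failure: {exc}") from exc
        tips = [lf for lf in dtree.leaf_node_iter()]
        labels = []
        for lf in tips:
            lab = lf.taxon.label if lf.taxon is not None else None
            if not lab:
                raise TreeError("tip without label in Newick input")
            labels.append(lab)
        index: Dict[int, int] = {}
        for i, lf in enumerate(tips):
            index[id(lf)] = i
        internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(tips) + len(internals)
        parent = [-1] * n
        blen: List[Optional[float]] = [None] * n
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length
            else:
                blen[i] = 0.0 if nd.edge.length is None else nd.edge.length
        return cls(parent, blen, labels)

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                s = f"({inner})"
            else:
                s = self.tip_labels[i]
            if self.parent[i] >= 0:
                s += f":{float(self.branch_length[i])!r}"
            return s

        return fmt(self.root) + ";"

    # -- basic queries ------------------------------------------------

    def tip_index(self) -> Dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        depth = np.zeros(self.n_nodes)
        for i in self.preorder:
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.branch_length[i]
        return depth

    def height(self) -> float:
        d = self.node_depths()
        return float(d[: self.n_tips].max())

    def tip_sets(self) -> List[set]:
        """Set of tip indices subtended by each node."""
        sets: List[set] = [set() for _ in range(self.n_nodes)]
        for i in self.postorder:
            if not self.children[i]:
                sets[i] = {i}
            else:
                for c in self.children[i]:
                    sets[i] |= sets[c]
        return sets

    def n_tips_below(self) -> np.ndarray:
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.postorder:
            cnt[i] = 1 if not self.children[i] else sum(cnt[c] for c in self.children[i])
        return cnt

    def vcv(self) -> np.ndarray:
        """Phylogenetic variance-covariance matrix over tips.

        ``V[i, j]`` is the shared root-to-MRCA path length of tips i and j;
        the diagonal holds root-to-tip depths. Requires branch lengths.
        """
        if not self.has_lengths:
            raise TreeError("tree has missing branch lengths; covariance undefined")
        depth = self.node_depths()
        n = self.n_tips
        V = np.zeros((n, n))
        sets = self.tip_sets()
        for i in self.postorder:
            kids = self.children[i]
            if not kids:
                V[i, i] = depth[i]
                continue
            for a in range(len(kids)):
                ta = sorted(sets[kids[a]])
                for b in range(a + 1, len(kids)):
                    tb = sorted(sets[kids[b]])
                    V[np.ix_(ta, tb)] = depth[i]
                    V[np.ix_(tb, ta)] = depth[i]
        return V

    def rescaled(self, factor: float) -> "PhyloTree":
        out = PhyloTree(
            self.parent.copy(), list(self.branch_length * factor), list(self.tip_labels)
        )
        return out

    def __repr__(self) -> str:
        return f"PhyloTree(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


def _open_text(path) -> _io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_newick(path) -> PhyloTree:
    """Read a single rooted Newick tree from a (possibly gzipped) file."""
    with _open_text(path) as fh:
        text = fh.read().strip()
    if not text.endswith(";"):
        raise TreeError(f"{path}: Newick string must be terminated by ';'")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def find_host_clades(tree: PhyloTree, labels: Dict[str, str]) -> List[HostClade]:
    """All maximal monophyletic clades (>= 2 tips) pure for one host category.

    ``labels`` maps every tip label to a host category or ``"free-living"``.
    Free-living tips never form clades. Clades are maximal (the parent of a
    reported clade root subtends a tip of another category or a free-living
    tip) and therefore pairwise disjoint. Singleton host tips are not
    reported.
    """
    missing = [t for t in tree.tip_labels if t not in labels]
    if missing:
        raise TreeError(f"tips without host label: {', '.join(missing[:5])}")
    # category of each node: the shared host category of all subtended tips,
    # or None if mixed / free-living
    cat: List[Optional[str]] = [None] * tree.n_nodes
    for i in tree.postorder:
        if not tree.children[i]:
            c = labels[tree.tip_labels[i]]
            cat[i] = None if c == FREE_LIVING else c
        else:
            kid_cats = {cat[c] for c in tree.children[i]}
            cat[i] = kid_cats.pop() if len(kid_cats) == 1 else None
    sets = tree.tip_sets()
    clades = []
    for i in tree.postorder:
        if not tree.children[i] or cat[i] is None:
            continue
        p = tree.parent[i]
        if p >= 0 and cat[p] is not None:
            continue  # not maximal
        members = sorted(tree.tip_labels[t] for t in sets[i])
        if len(members) >= 2:
            clades.append(HostClade(int(i), cat[i], members))
    clades.sort(key=lambda c: c.member_tips[0])
    return clades
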