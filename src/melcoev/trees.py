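"""Light array-backed phylogeny container.

Likelihood code in this package works on flat arrays (postorder node ids,
parent pointers, branch lengths), which is much faster to traverse than a
node-object tree.  Parsing and serialisation of Newick go through dendropy;
this module only keeps the minimal structure the numerics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class Tree:
    """Rooted tree as flat arrays.

    Nodes ``0 .. n_leaves-1`` are leaves (in the order of ``leaf_names``);
    internal nodes follow, with the root last.  ``parent[root] == -1``.
    ``blen[i]`` is the length of the branch above node ``i`` (0.0 for the
    root).  A "branch" of the tree is any non-root node id.
    """

    parent: np.ndarray
    blen: np.ndarray
    leaf_names: list[str]
    children: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen < 0):
            raise TreeError("negative branch length")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def branches(self) -> np.ndarray:
        """Ids of all non-root nodes (each identifies its parent branch)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root])

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def leaf_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.leaf_names)}

    def total_length(self) -> float:
        return float(self.blen.sum())

    def with_blen(self, blen: np.ndarray) -> "Tree":
        return Tree(self.parent.copy(), np.asarray(blen, float).copy(),
                    list(self.leaf_names), [list(c) for c in self.children])

    def scaled(self, factor: float) -> "Tree":
        return self.with_blen(self.blen * factor)

    # -- leaf-set utilities ----------------------------------------------
    def leafsets(self) -> dict[int, frozenset[str]]:
        """Leaf-name set under every node."""
        out: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if not self.children[v]:
                out[v] = frozenset([self.leaf_names[v]])
            else:
                s: frozenset[str] = frozenset()
                for c in self.children[v]:
                    s |= out[c]
                out[v] = s
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each as its smaller-side-free
        canonical form (the side not containing the first leaf name)."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        for v, s in self.leafsets().items():
            if v == self.root or len(s) < 2 or len(s) > len(all_leaves) - 2:
                continue
            parts.add(s if anchor not in s else all_leaves - s)
        return parts

    def root_to_tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if self.parent[v] >= 0:
                depth[v] = depth[self.parent[v]] + self.blen[v]
        return depth[: self.n_leaves]

    # -- Newick I/O ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        dtree = dtree.clone(depth=1)
        dtree.resolve_polytomies()
        nodes = list(dtree.preorder_node_iter())
        leaves = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        if any(lf.taxon is None for lf in leaves):
            raise TreeError("unlabelled leaf in tree")
        ids: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            ids[id(lf)] = i
        # root last so that preorder arrays have parents before children
        for j, nd in enumerate(reversed(internals)):
            ids[id(nd)] = len(leaves) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in nodes:
            i = ids[id(nd)]
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        names = [lf.taxon.label for lf in leaves]
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels")
        return cls(parent, blen, names, children)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, digits: int = 6) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                label = self.leaf_names[v]
            else:
                label = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if self.parent[v] < 0:
                return label
            return f"{label}:{self.blen[v]:.{digits}g}"

        return fmt(self.root) + ";"

    def write(self, path, digits: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(digits=digits) + "\n")
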