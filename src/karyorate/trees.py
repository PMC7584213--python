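"""Array-backed rooted phylogenies.

Trees are parsed with dendropy and flattened into integer arrays (parent
pointers, branch lengths, post-order traversal) so that the pruning
likelihood can run as tight numeric loops.  Tips occupy node ids
``0 .. n_tips-1`` in the order they appear in the newick string; internal
nodes follow in post-order, with the root last.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths (in Myr unless rescaled).

    ``parent[i]`` is the parent node id of node ``i`` (-1 at the root) and
    ``brlen[i]`` the length of the branch above node ``i`` (0 at the root).
    """

    tip_labels: Tuple[str, ...]
    parent: np.ndarray
    brlen: np.ndarray
    children: Tuple[Tuple[int, ...], ...]
    postorder: np.ndarray
    label: str = ""

    # flattened child arrays for the numeric kernels, built lazily
    _flat: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    # ------------------------------------------------------------------ io

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, label: str = "") -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        leaves = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        labels = []
        for nd in leaves:
            name = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            labels.append(" ".join(str(name).split()))
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")
        ids = {}
        for i, nd in enumerate(leaves):
            ids[nd] = i
        for j, nd in enumerate(internals):
            ids[nd] = len(leaves) + j

        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        brlen = np.zeros(n, dtype=float)
        children: List[Tuple[int, ...]] = [() for _ in range(n)]
        for nd in nodes:
            i = ids[nd]
            if nd.parent_node is not None:
                parent[i] = ids[nd.parent_node]
            edge = nd.edge.length
            brlen[i] = 0.0 if edge is None else float(edge)
            if brlen[i] < 0:
                raise TreeError(f"negative branch length at node {i}")
            children[i] = tuple(ids[ch] for ch in nd.child_nodes())
        postorder = np.array([ids[nd] for nd in nodes], dtype=np.int64)
        return cls(
            tip_labels=tuple(labels),
            parent=parent,
            brlen=brlen,
            children=tuple(children),
            postorder=postorder,
            label=label,
        )

    @classmethod
    def from_newick(cls, newick: str, label: str = "") -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree, label=label)

    def to_newick(self) -> str:
        def quote(name: str) -> str:
            if any(ch in name for ch in " \t,();:[]'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def render(node: int) -> str:
            if not self.children[node]:
                name = quote(self.tip_labels[node])
                return f"{name}:{self.brlen[node]:.10g}"
            inner = ",".join(render(ch) for ch in self.children[node])
            if self.parent[node] == -1:
                return f"({inner})"
            return f"({inner}):{self.brlen[node]:.10g}"

        return render(self.root) + ";"

    # ------------------------------------------------------------ geometry

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depths = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            p = self.parent[node]
            if p >= 0:
                depths[node] = depths[p] + self.brlen[node]
        return depths

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    @property
    def height(self) -> float:
        """Root-to-tip depth (maximum over tips)."""
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = self.tip_depths()
        height = depths.max()
        if height <= 0:
            return False
        return bool(np.all(np.abs(depths - height) <= rtol * height))

    def with_branch_lengths(self, brlen: Sequence[float], label: str = None) -> "Phylogeny":
        brlen = np.asarray(brlen, dtype=float)
        if brlen.shape != self.brlen.shape:
            raise ValueError("branch length array has the wrong shape")
        return Phylogeny(
            tip_labels=self.tip_labels,
            parent=self.parent.copy(),
            brlen=brlen,
            children=self.children,
            postorder=self.postorder.copy(),
            label=self.label if label is None else label,
        )

    # --------------------------------------------------------- flat arrays

    def flat_children(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(children_flat, child_start, child_count) for the numeric kernels."""
        if self._flat is None:
            start = np.zeros(self.n_nodes, dtype=np.int64)
            count = np.array([len(c) for c in self.children], dtype=np.int64)
            start[1:] = np.cumsum(count)[:-1]
            flat = np.array(
                [ch for node in range(self.n_nodes) for ch in self.children[node]],
                dtype=np.int64,
            )
            object.__setattr__(self, "_flat", (flat, start, count))
        return self._flat


def read_tree_set(path) -> List[Phylogeny]:
    """Read a multi-tree file: one newick per line, or a Nexus TREES block.

    Blank lines are ignored.  Malformed newicks raise with the tree index.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"tree file {path} is empty")
    trees: List[Phylogeny] = []
    if text.lstrip().lower().startswith("#nexus"):
        tl = dendropy.TreeList.get(data=text, schema="nexus", preserve_underscores=True)
        for k, t in enumerate(tl):
            trees.append(Phylogeny.from_dendropy(t, label=f"tree_{k}"))
    else:
        for k, line in enumerate(s for s in text.splitlines() if s.strip()):
            try:
                trees.append(Phylogeny.from_newick(line, label=f"tree_{k}"))
            except Exception as exc:
                raise TreeError(f"malformed newick at tree index {k}: {exc}") from exc
    if not trees:
        raise TreeError(f"no trees found in {path}")
    return trees


def write_tree_set(trees: Sequence[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")
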