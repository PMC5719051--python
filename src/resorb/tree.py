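"""Rooted phylogenies for comparative analyses.

A :class:`Phylogeny` is a rooted tree with branch lengths and uniquely
labelled tips.  Newick parsing is delegated to :mod:`dendropy`; the class
itself keeps a minimal node structure so that pruning-algorithm traversals
(independent contrasts, Brownian simulation) stay cheap and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Node", "Phylogeny", "PruningSchedule"]


@dataclass
class Node:
    """One node of a rooted phylogeny.

    ``length`` is the length of the branch subtending this node (``None``
    for the root or for trees read without branch lengths).
    """

    length: float | None = None
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and species-labelled tips.

    Invariants: exactly one root; tip labels unique and non-empty; branch
    lengths non-negative (the root branch may be absent).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ #
    # construction / serialisation
    # ------------------------------------------------------------------ #

    @classmethod
    def from_newick(
        cls,
        newick: str,
        default_branch_length: float = 1.0,
        resolve_polytomies: bool = True,
    ) -> "Phylogeny":
        """Parse a Newick string.

        Missing branch lengths default to ``default_branch_length`` (logged);
        polytomies are resolved to binary nodes with zero-length inserted
        branches so that independent contrasts are defined.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ValueError(f"Newick parse error: {exc}") from exc

        def convert(dnode: dendropy.Node) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(length=dnode.edge.length, label=label)
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.parent = node
                node.children.append(cn)
            return node

        root = convert(dtree.seed_node)
        tree = cls.__new__(cls)
        tree.root = root
        n_missing = sum(
            1 for nd in tree._iter_postorder() if nd is not tree.root and nd.length is None
        )
        if n_missing:
            logger.info(
                "%d branch lengths missing; defaulting to %g", n_missing, default_branch_length
            )
            for nd in tree._iter_postorder():
                if nd is not tree.root and nd.length is None:
                    nd.length = float(default_branch_length)
        if resolve_polytomies:
            tree.resolve_polytomies()
        tree._validate()
        return tree

    @classmethod
    def read(cls, path, **kwargs) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    def to_newick(self) -> str:
        """Serialise to Newick with full float precision (round-trip safe)."""

        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if node.length is not None:
                s += f":{node.length!r}"
            return s

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------ #
    # topology utilities
    # ------------------------------------------------------------------ #

    def _iter_postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def postorder(self) -> list[Node]:
        return list(self._iter_postorder())

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[Node]:
        return [nd for nd in self._iter_postorder() if nd.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def is_binary(self) -> bool:
        return all(len(nd.children) == 2 for nd in self._iter_postorder() if not nd.is_tip)

    def resolve_polytomies(self) -> None:
        """Resolve multifurcations in input child order with zero-length branches.

        Left-folds the child list, which leaves the tip variance-covariance
        matrix unchanged.
        """
        for node in self.postorder():
            while len(node.children) > 2:
                c1, c2 = node.children[0], node.children[1]
                merged = Node(length=0.0, children=[c1, c2], parent=node)
                c1.parent = merged
                c2.parent = merged
                node.children = [merged] + node.children[2:]

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is self.root:
                continue
            d = depth[id(node.parent)] + (node.length or 0.0)
            depth[id(node)] = d
            if node.is_tip:
                out[node.label] = d  # type: ignore[index]
        return out

    def max_depth(self) -> float:
        return max(self.depths().values())

    def scale_to_depth(self, depth: float = 1.0) -> None:
        """Rescale all branch lengths so the deepest tip sits at ``depth``."""
        cur = self.max_depth()
        if cur <= 0:
            raise ValueError("tree has zero depth; cannot rescale")
        factor = depth / cur
        for node in self.postorder():
            if node.length is not None:
                node.length *= factor

    def grafen_lengths(self) -> None:
        """Assign Grafen (1989)-style branch lengths from node heights.

        Each node's height is the number of tips below it minus one, scaled
        to unit depth; branch length = parent height - child height.
        """
        n_below: dict[int, int] = {}
        for node in self._iter_postorder():
            n_below[id(node)] = 1 if node.is_tip else sum(
                n_below[id(c)] for c in node.children
            )
        total = n_below[id(self.root)] - 1
        if total <= 0:
            raise ValueError("Grafen scaling needs >= 2 tips")
        for node in self.preorder():
            if node is self.root:
                continue
            h_parent = (n_below[id(node.parent)] - 1) / total
            h_child = (n_below[id(node)] - 1) / total
            node.length = h_parent - h_child

    # ------------------------------------------------------------------ #
    # comparative-methods machinery
    # ------------------------------------------------------------------ #

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Phylogenetic variance-covariance matrix.

        ``C[i, j]`` is the shared root-to-tip path length of tips i and j;
        the diagonal holds tip depths.  Returns the matrix and the tip-label
        order of its rows.
        """
        tips = self.tips()
        labels = [t.label for t in tips]
        index = {id(t): i for i, t in enumerate(tips)}
        n = len(tips)
        C = np.zeros((n, n))
        depth: dict[int, float] = {id(self.root): 0.0}
        tipsets: dict[int, list[int]] = {}
        for node in self.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        for node in self._iter_postorder():
            if node.is_tip:
                i = index[id(node)]
                tipsets[id(node)] = [i]
                C[i, i] = depth[id(node)]
            else:
                child_sets = [tipsets[id(c)] for c in node.children]
                d = depth.get(id(node), 0.0)
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                C[i, j] = C[j, i] = d
                tipsets[id(node)] = [i for s in child_sets for i in s]
        if np.any(np.diag(C) <= 0):
            raise ValueError("tip with zero root-to-tip depth; VCV singular")
        return C, labels  # type: ignore[return-value]

    def pruning_schedule(self) -> "PruningSchedule":
        return PruningSchedule.from_tree(self)

    # ------------------------------------------------------------------ #

    def _validate(self) -> None:
        labels = self.tip_labels
        if any(lbl in (None, "") for lbl in labels):
            raise ValueError("every tip must carry a non-empty label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._iter_postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValueError("negative branch length")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


class PruningSchedule:
    """Precomputed Felsenstein-pruning traversal of a binary tree.

    Branch-length adjustments of the contrasts algorithm do not depend on
    trait values, so they are computed once; contrasts for many traits (or
    many permutations of one trait) are then evaluated with vectorised
    array operations.

    Attributes
    ----------
    tip_labels : tip-label order of the first ``n`` value slots.
    merges : array (n-1, 3) of (child1, child2, node) value-slot indices in
        post-order.
    b1, b2 : adjusted branch lengths entering each merge.
    """

    def __init__(self, tip_labels, merges, b1, b2):
        self.tip_labels = tip_labels
        self.merges = merges
        self.b1 = b1
        self.b2 = b2

    @classmethod
    def from_tree(cls, tree: Phylogeny) -> "PruningSchedule":
        if not tree.is_binary:
            raise ValueError("contrasts require a binary tree; resolve polytomies first")
        tips = tree.tips()
        slot = {id(t): i for i, t in enumerate(tips)}
        adj: dict[int, float] = {}  # adjusted subtending branch length
        merges, b1s, b2s = [], [], []
        next_slot = len(tips)
        for node in tree._iter_postorder():
            if node.is_tip:
                adj[id(node)] = float(node.length or 0.0)
                continue
            c1, c2 = node.children
            v1, v2 = adj[id(c1)], adj[id(c2)]
            if v1 + v2 == 0:
                raise ValueError("zero-length contrast denominator")
            merges.append((slot[id(c1)], slot[id(c2)], next_slot))
            b1s.append(v1)
            b2s.append(v2)
            slot[id(node)] = next_slot
            next_slot += 1
            adj[id(node)] = float(node.length or 0.0) + v1 * v2 / (v1 + v2)
        return cls(
            [t.label for t in tips],
            np.asarray(merges, dtype=np.intp).reshape(-1, 3),
            np.asarray(b1s),
            np.asarray(b2s),
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def contrasts(self, X: np.ndarray) -> np.ndarray:
        """Standardised contrasts for trait matrix ``X`` of shape (m, n_tips).

        Returns shape (m, n_tips - 1), post-order over internal nodes.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m, n = X.shape
        if n != self.n_tips:
            raise ValueError(f"expected {self.n_tips} tip values, got {n}")
        V = np.empty((m, 2 * n - 1))
        V[:, :n] = X
        out = np.empty((m, n - 1))
        denom = np.sqrt(self.b1 + self.b2)
        # weight (1/b1)/(1/b1+1/b2) rewritten as b2/(b1+b2): stable when a
        # zero-length branch from polytomy resolution makes one b vanish
        w1 = self.b2 / (self.b1 + self.b2)
        for k, (i, j, t) in enumerate(self.merges):
            out[:, k] = (V[:, i] - V[:, j]) / denom[k]
            V[:, t] = w1[k] * V[:, i] + (1 - w1[k]) * V[:, j]
        return out
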