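"""Rooted, ultrametric time-calibrated species trees.

A :class:`TimeTree` wraps a dendropy tree whose branch lengths are in
millions of years (My) and precomputes the quantities the comparative
analyses need: node depths/ages, the tip-tip shared-time (phylogenetic
covariance) matrix, and clade membership.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "TreeError"]


class TreeError(ValueError):
    """Raised for trees that violate the rooted-ultrametric contract."""


@dataclass
class _Node:
    index: int
    label: str | None
    depth: float          # time from root, My
    parent: int | None
    children: list[int] = field(default_factory=list)
    tip_indices: frozenset[int] = frozenset()


class TimeTree:
    """A rooted ultrametric timetree with branch lengths in My.

    Parameters
    ----------
    newick:
        Newick string with branch lengths. The tree must be rooted (a
        polytomy at the root is treated as a rooted multifurcation, e.g.
        a star tree) and ultrametric within ``rel_tol * height``.
    """

    def __init__(self, newick: str, rel_tol: float = 1e-6):
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        seed = tree.seed_node
        if len(seed.child_nodes()) < 2:
            raise TreeError("tree has a single-child root")

        # assign depths in preorder
        self._nodes: list[_Node] = []
        dnode_index: dict[int, int] = {}
        for dnode in tree.preorder_node_iter():
            parent = dnode.parent_node
            pidx = dnode_index[id(parent)] if parent is not None else None
            edge = dnode.edge.length
            if parent is None:
                depth = 0.0
            else:
                if edge is None:
                    raise TreeError("branch length missing")
                depth = self._nodes[pidx].depth + float(edge)
            label = dnode.taxon.label if dnode.taxon is not None else None
            idx = len(self._nodes)
            dnode_index[id(dnode)] = idx
            self._nodes.append(_Node(index=idx, label=label, depth=depth,
                                     parent=pidx))
            if pidx is not None:
                self._nodes[pidx].children.append(idx)

        tip_nodes = [n for n in self._nodes if not n.children]
        if any(n.label is None for n in tip_nodes):
            raise TreeError("unlabeled tip")
        self.taxa: list[str] = [n.label for n in tip_nodes]  # preorder tip order
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate tip labels")
        self._tip_index = {n.label: k for k, n in enumerate(tip_nodes)}
        self._tip_node_index = [n.index for n in tip_nodes]

        depths = np.array([n.depth for n in tip_nodes])
        self.height: float = float(depths.max())
        if self.height <= 0:
            raise TreeError("tree has zero height")
        if np.any(np.abs(depths - self.height) > rel_tol * self.height):
            raise TreeError(
                "tree is not ultrametric: tip depths range "
                f"[{depths.min():.6g}, {depths.max():.6g}] My"
            )

        # clade tip sets, bottom-up
        for n in reversed(self._nodes):
            if not n.children:
                n.tip_indices = frozenset([self._tip_index[n.label]])
            else:
                s: set[int] = set()
                for c in n.children:
                    s |= self._nodes[c].tip_indices
                n.tip_indices = frozenset(s)

        self._vcv = self._build_vcv()
        self._newick = newick

    # ------------------------------------------------------------------
    def _build_vcv(self) -> np.ndarray:
        n = len(self.taxa)
        C = np.zeros((n, n))
        for node in self._nodes:
            if not node.children:
                i = self._tip_index[node.label]
                C[i, i] = node.depth
                continue
            # pairs of tips whose MRCA is this node: tips in different children
            child_sets = [sorted(self._nodes[c].tip_indices)
                          for c in node.children]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = node.depth
        return C

    # -- public API -----------------------------------------------------
    @classmethod
    def from_file(cls, path, **kw) -> "TimeTree":
        with open(path) as fh:
            return cls(fh.read(), **kw)

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def vcv(self) -> np.ndarray:
        """Shared root-to-MRCA path lengths between tips (My)."""
        return self._vcv.copy()

    def tip_depths(self) -> np.ndarray:
        return np.diag(self._vcv).copy()

    def mrca_depth(self, taxa) -> float:
        """Depth (time from root, My) of the MRCA of a set of tip labels."""
        want = frozenset(self._tip_index[t] for t in taxa)
        if not want:
            raise ValueError("empty taxon set")
        best = None
        for n in self._nodes:
            if want <= n.tip_indices:
                if best is None or n.depth > best:
                    best = n.depth
        return best

    def mrca_age(self, taxa) -> float:
        """Age (My before present) of the MRCA of a set of tip labels."""
        return self.height - self.mrca_depth(taxa)

    def divergence_time(self, a: str, b: str) -> float:
        """Time (My) before present at which tips *a* and *b* diverged."""
        return self.mrca_age([a, b])

    def internal_nodes(self):
        """Yield ``(node_id, clade_tip_labels, age_my)`` in preorder.

        ``node_id`` is ``"n0"`` for the root, then preorder.
        """
        k = 0
        for n in self._nodes:
            if n.children:
                tips = tuple(sorted(self.taxa[i] for i in n.tip_indices))
                yield f"n{k}", tips, self.height - n.depth
                k += 1

    def clades(self) -> list[tuple[frozenset[str], float]]:
        """All internal clades as ``(tip label set, crown age My)``."""
        out = []
        for n in self._nodes:
            if n.children:
                out.append((frozenset(self.taxa[i] for i in n.tip_indices),
                            self.height - n.depth))
        return out

    # shared-depth matrices against internal nodes (for ancestral states)
    def node_tip_shared_depths(self) -> tuple[list[str], np.ndarray]:
        """Shared depths between each internal node and each tip.

        Returns ``(node_ids, M)`` with ``M[k, i]`` = depth of the MRCA of
        internal node *k* and tip *i*.
        """
        ids, rows = [], []
        k = 0
        for n in self._nodes:
            if not n.children:
                continue
            ids.append(f"n{k}")
            k += 1
            row = np.empty(self.n_tips)
            for i in range(self.n_tips):
                if i in n.tip_indices:
                    row[i] = n.depth
                else:
                    # walk up until the clade contains tip i
                    anc = n
                    while i not in anc.tip_indices:
                        anc = self._nodes[anc.parent]
                    row[i] = anc.depth
            rows.append(row)
        return ids, np.vstack(rows)

    def edges(self):
        """Yield ``(parent_id, child_id)`` over all edges.

        Internal nodes use their ``"n{k}"`` ids, tips their labels.
        """
        names = {}
        k = 0
        for n in self._nodes:
            if n.children:
                names[n.index] = f"n{k}"
                k += 1
            else:
                names[n.index] = n.label
        for n in self._nodes:
            if n.parent is not None:
                yield names[n.parent], names[n.index]

    def newick(self) -> str:
        return self._newick

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree({self.n_tips} tips, height={self.height:.3g} My)"
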