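"""Clone phylogeny from mutation clusters via the statistical pigeonhole principle.

If two clusters' combined cellular fractions exceed 100% in some
microbiopsy, some cells must carry both sets of mutations, so one clone is
nested in the other; which one is the parent is decided by consistent CF
dominance across microbiopsies.  Clusters whose combined CF never exceeds
100% yield only weak evidence of nesting and are pruned from the burden
set, as are un-nested clusters of low median VAF (≤ 0.3), where a single
"cluster" may in truth be a mixture of independent clones at similar VAFs.

Branch lengths are cluster mutation counts; the root-to-tip sum defines a
clone's mutation burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CloneNode",
    "CloneTree",
    "pigeonhole_nesting",
    "build_forest",
    "prune_uncertain",
    "clone_burdens",
]


@dataclass
class CloneNode:
    cluster_id: str
    parent: Optional[str]           # None = child of germline root
    branch_length: float
    cf: Optional[np.ndarray] = None  # cellular fraction per microbiopsy
    median_vaf: float = float("nan")
    evidence: str = "none"           # nesting evidence for the edge to parent
    members: list = field(default_factory=list)


@dataclass
class CloneTree:
    """A forest of clusters rooted at the (implicit) germline."""

    nodes: dict

    def __post_init__(self):
        self._check_acyclic()

    def _check_acyclic(self):
        for start in self.nodes:
            seen = {start}
            cur = self.nodes[start].parent
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cyclic nesting involving {sorted(seen)}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def children(self, node_id: Optional[str]) -> list:
        return [k for k, v in self.nodes.items() if v.parent == node_id]

    def roots(self) -> list:
        return self.children(None)

    def tips(self) -> list:
        have_child = {v.parent for v in self.nodes.values() if v.parent}
        return [k for k in self.nodes if k not in have_child]

    def root_path(self, node_id: str) -> list:
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def total_branch_length(self) -> float:
        return float(sum(v.branch_length for v in self.nodes.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        return all(
            self.nodes[k].parent == other.nodes[k].parent
            and np.isclose(self.nodes[k].branch_length, other.nodes[k].branch_length)
            for k in self.nodes
        )


# --------------------------------------------------------------------------
# Pigeonhole nesting
# --------------------------------------------------------------------------


def pigeonhole_nesting(clusters, eps: float = 0.05) -> dict:
    """Grade nesting evidence for every ordered cluster pair.

    Returns ``{"edges": {(parent, child): "strong"|"weak"}, "independent":
    set of frozensets, "conflicts": set of frozensets}``.  For an ordered
    pair (A, B), evidence that B ⊂ A is *strong* when some microbiopsy has
    cf_A + cf_B > 1 and cf_B ≤ cf_A + eps in every microbiopsy where both
    are observed, and *weak* when only the dominance condition holds.
    Pairs with strong evidence in both directions are flagged as conflicts
    and left unresolved.
    """
    edges = {}
    independent = set()
    conflicts = set()
    by_id = {c.cluster_id: c for c in clusters}
    ids = list(by_id)
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            ca, cb = np.asarray(by_id[a].cf_centroid), np.asarray(by_id[b].cf_centroid)
            ok = np.isfinite(ca) & np.isfinite(cb)
            if not ok.any():
                continue
            ca, cb = ca[ok], cb[ok]
            comb = bool(np.any(ca + cb > 1.0))
            dom_ab = bool(np.all(cb <= ca + eps))   # B under A
            dom_ba = bool(np.all(ca <= cb + eps))
            if dom_ab and dom_ba:
                if comb:
                    conflicts.add(frozenset((a, b)))
                else:
                    # near-equal CFs everywhere: take the larger clone as parent
                    parent, child = (a, b) if ca.sum() >= cb.sum() else (b, a)
                    edges[(parent, child)] = "weak"
                continue
            if dom_ab:
                edges[(a, b)] = "strong" if comb else "weak"
            elif dom_ba:
                edges[(b, a)] = "strong" if comb else "weak"
            else:
                independent.add(frozenset((a, b)))
    return {"edges": edges, "independent": independent, "conflicts": conflicts}


def build_forest(clusters, nesting: dict) -> CloneTree:
    """Attach each cluster to its smallest strong (else weak) superset.

    The choice of the smallest superset performs the transitive reduction
    of the nesting relation: in a chain A ⊃ B ⊃ C, C attaches to B, not A.
    Unattached clusters become root-level clones.  A cycle surviving the
    tolerance is an error listing the clusters involved.
    """
    by_id = {c.cluster_id: c for c in clusters}
    edges = nesting["edges"]
    nodes = {}
    for cid, c in by_id.items():
        strong = [p for (p, ch) in edges if ch == cid and edges[(p, ch)] == "strong"]
        weak = [p for (p, ch) in edges if ch == cid and edges[(p, ch)] == "weak"]
        pool, grade = (strong, "strong") if strong else (weak, "weak")
        parent = None
        if pool:
            parent = min(pool, key=lambda p: float(np.nansum(by_id[p].cf_centroid)))
        nodes[cid] = CloneNode(
            cluster_id=cid,
            parent=parent,
            branch_length=float(c.size),
            cf=np.asarray(c.cf_centroid, dtype=float),
            median_vaf=float(c.median_vaf),
            evidence=grade if parent is not None else "none",
            members=list(c.members),
        )
    return CloneTree(nodes=nodes)


def prune_uncertain(tree: CloneTree, vaf_threshold: float = 0.3) -> CloneTree:
    """Drop branches where the pigeonhole principle is not incontrovertible.

    Nested nodes supported only by weak evidence (combined CF never > 1)
    are removed, with their children re-attached to the grandparent.
    Root-level clusters with no retained children are kept only if their
    median VAF exceeds ``vaf_threshold``.
    """
    nodes = {k: replace(v) for k, v in tree.nodes.items()}

    # remove weak-evidence nested nodes, reattaching children upward
    removed = True
    while removed:
        removed = False
        for k, v in list(nodes.items()):
            if v.parent is not None and v.evidence == "weak":
                for other in nodes.values():
                    if other.parent == k:
                        other.parent = v.parent
                del nodes[k]
                removed = True

    # drop low-VAF root-level singleton branches
    have_child = {v.parent for v in nodes.values() if v.parent}
    for k, v in list(nodes.items()):
        if v.parent is None and k not in have_child:
            if not (v.median_vaf > vaf_threshold):
                del nodes[k]
    return CloneTree(nodes=nodes)


def clone_burdens(tree: CloneTree) -> dict:
    """Root-to-tip branch-length sums: the mutation burden of each clone."""
    return {
        tip: float(sum(tree.nodes[k].branch_length for k in tree.root_path(tip)))
        for tip in tree.tips()
    }


def check_cf_monotonic(tree: CloneTree, eps: float = 0.05) -> bool:
    """CF never increases along any root-to-tip path (within tolerance)."""
    for tip in tree.tips():
        path = tree.root_path(tip)[::-1]  # root-most first
        for up, down in zip(path, path[1:]):
            a, b = tree.nodes[up].cf, tree.nodes[down].cf
            if a is None or b is None:
                continue
            ok = np.isfinite(a) & np.isfinite(b)
            if np.any(b[ok] > a[ok] + eps):
                return False
    return True
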