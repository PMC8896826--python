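"""Two-stage representative selection on a phylogenetic tree.

Stage 1 partitions the leaves into clusters whose pairwise patristic
diameter does not exceed a threshold, in either of two diameter-constrained
variants:

``max_clade``
    clusters must be clades: a clade is kept whole iff its leaf-pair
    diameter is <= threshold, otherwise recurse into its children
    (the default of threshold-based tree-clustering tools).
``max``
    clusters are arbitrary leaf sets; a greedy bottom-up sweep cuts the
    deepest subtree whenever two lineages meeting at a node would exceed
    the threshold, which yields the minimum possible number of clusters
    for a tree metric.

Stage 2 splits each cluster into ``max(1, ceil(f * n_c))`` subclusters by
agglomerative hierarchical clustering on the patristic submatrix, and stage
3 selects one representative per subcluster, privileging externally
supplied priorities (e.g. reference strains, previously assayed sequences),
then the subcluster medoid, then the lexicographically smallest label.

All tie-breaks are fixed so that identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import PatristicMatrix, PhyloTree

__all__ = [
    "ClusterAssignment",
    "SubclusterPlan",
    "RepresentativeSet",
    "threshold_clusters",
    "plan_subclusters",
    "pick_representatives",
    "sample_tree",
]

_MODES = ("max_clade", "max")
_LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterAssignment:
    """Partition of leaves into diameter-bounded clusters (ids 1..K)."""

    assignment: dict[str, int]
    mode: str
    threshold: float

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values(), default=0)

    def members(self, cluster_id: int) -> list[str]:
        return [leaf for leaf, c in self.assignment.items() if c == cluster_id]

    def clusters(self) -> list[list[str]]:
        return [self.members(c) for c in range(1, self.n_clusters + 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"leaf_label": list(self.assignment), "cluster": list(self.assignment.values())}
        )


@dataclass
class SubclusterPlan:
    """Per-cluster subcluster membership; sampling fraction f gives
    k_c = max(1, ceil(f * n_c)) target subclusters per cluster."""

    subclusters: dict[int, list[list[str]]]  # cluster id -> list of leaf lists
    fraction: float
    linkage: str

    def n_subclusters(self, cluster_id: int) -> int:
        return len(self.subclusters[cluster_id])

    @property
    def total_subclusters(self) -> int:
        return sum(len(v) for v in self.subclusters.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.subclusters):
            for sid, members in enumerate(self.subclusters[cid], start=1):
                for leaf in members:
                    rows.append((leaf, cid, sid))
        return pd.DataFrame(rows, columns=["leaf_label", "cluster", "subcluster"])


@dataclass
class Representative:
    leaf_label: str
    cluster: int
    subcluster: int
    selection_reason: str  # priority | medoid | lexicographic


@dataclass
class RepresentativeSet:
    records: list[Representative]

    @property
    def labels(self) -> list[str]:
        return [r.leaf_label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.leaf_label, r.cluster, r.subcluster, r.selection_reason)
                for r in self.records
            ],
            columns=["leaf_label", "cluster", "subcluster", "selection_reason"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage 1: threshold clustering
# ---------------------------------------------------------------------------


def threshold_clusters(
    tree: PhyloTree,
    matrix: PatristicMatrix,
    threshold: float,
    mode: str = "max_clade",
) -> ClusterAssignment:
    """Partition leaves so every cluster's patristic diameter <= threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if mode not in _MODES:
        raise ValueError(f"unknown clustering mode {mode!r}; choose from {_MODES}")

    if mode == "max_clade":
        groups = _max_clade_groups(tree, threshold)
    else:
        groups = _max_groups(tree, threshold)

    # cluster ids in leaf post-order of each group's first member
    order = {lab: i for i, lab in enumerate(tree.leaf_labels)}
    groups.sort(key=lambda g: min(order[leaf] for leaf in g))
    assignment = {leaf: cid for cid, g in enumerate(groups, start=1) for leaf in g}
    return ClusterAssignment(assignment, mode=mode, threshold=threshold)


def _clade_metrics(tree: PhyloTree):
    """Per-node (leaf list, height, diameter), bottom-up.

    height = max distance node -> descendant leaf; diameter = max leaf-pair
    distance within the clade (max of child diameters and cross-child
    height sums).
    """
    info: dict[int, tuple[list[str], float, float]] = {}
    for node in tree.postorder_nodes():
        if node.is_leaf():
            info[id(node)] = ([node.taxon.label], 0.0, 0.0)
            continue
        leaves: list[str] = []
        heights = []
        diam = 0.0
        for child in node.child_nodes():
            c_leaves, c_h, c_d = info[id(child)]
            leaves.extend(c_leaves)
            heights.append(c_h + child.edge.length)
            diam = max(diam, c_d)
        heights.sort(reverse=True)
        if len(heights) >= 2:
            diam = max(diam, heights[0] + heights[1])
        info[id(node)] = (leaves, heights[0] if heights else 0.0, diam)
    return info


def _max_clade_groups(tree: PhyloTree, threshold: float) -> list[list[str]]:
    info = _clade_metrics(tree)
    groups: list[list[str]] = []

    def descend(node):
        leaves, _h, diam = info[id(node)]
        if diam <= threshold or node.is_leaf():
            groups.append(leaves)
        else:
            for child in node.child_nodes():
                descend(child)

    descend(tree.root)
    return groups


def _max_groups(tree: PhyloTree, threshold: float) -> list[list[str]]:
    """Greedy min-cardinality diameter-constrained partition.

    Bottom-up: each node carries its still-active leaves and the largest
    node-to-active-leaf distance per incoming lineage.  Whenever the two
    deepest lineages at a node would join two leaves at distance >
    threshold, the deeper lineage is cut off as a finished cluster (ties
    cut the lineage whose subtree has the lower post-order index).
    """
    groups: list[list[str]] = []
    post_index: dict[int, int] = {}
    for i, node in enumerate(tree.postorder_nodes()):
        post_index[id(node)] = i

    # per-node: list of active leaves, max distance node->active leaf
    active: dict[int, tuple[list[str], float]] = {}
    for node in tree.postorder_nodes():
        if node.is_leaf():
            active[id(node)] = ([node.taxon.label], 0.0)
            continue
        entries = []  # (depth through edge, post-order idx, leaves)
        for child in node.child_nodes():
            leaves, depth = active.pop(id(child))
            if leaves:
                entries.append([depth + child.edge.length, post_index[id(child)], leaves])
        entries.sort(key=lambda e: (-e[0], e[1]))
        while len(entries) >= 2 and entries[0][0] + entries[1][0] > threshold:
            # cut the deepest lineage; among equals, the lower post-order idx
            deepest = entries[0][0]
            tied = [e for e in entries if e[0] == deepest]
            cut = min(tied, key=lambda e: e[1])
            entries.remove(cut)
            groups.append(cut[2])
        if entries:
            active[id(node)] = (
                [leaf for e in entries for leaf in e[2]],
                entries[0][0],
            )
        else:
            active[id(node)] = ([], 0.0)
    leftover, _ = active[id(tree.root)]
    if leftover:
        groups.append(leftover)
    return groups


# ---------------------------------------------------------------------------
# stage 2: agglomerative subclustering
# ---------------------------------------------------------------------------


def subcluster_count(n_c: int, fraction: float) -> int:
    """Target subcluster count: max(1, ceil(f * n_c)), capped at n_c."""
    return min(n_c, max(1, math.ceil(fraction * n_c)))


def plan_subclusters(
    clusters: ClusterAssignment | Iterable[Sequence[str]],
    matrix: PatristicMatrix,
    fraction: float = 0.2,
    linkage: str = "average",
) -> SubclusterPlan:
    """Split each cluster into subclusters by hierarchical clustering.

    Plain agglomerative clustering on the patristic submatrix, merging the
    closest pair of groups under the chosen linkage until
    ``subcluster_count(n_c, fraction)`` groups remain.  Merge ties go to
    the pair with the lexicographically smallest (min-label, min-label)
    signature, so the plan is fully deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {_LINKAGES}")

    if isinstance(clusters, ClusterAssignment):
        cluster_lists = {cid: clusters.members(cid) for cid in range(1, clusters.n_clusters + 1)}
    else:
        cluster_lists = {cid: list(members) for cid, members in enumerate(clusters, start=1)}

    plan: dict[int, list[list[str]]] = {}
    for cid, members in cluster_lists.items():
        if not members:
            raise ValueError(f"cluster {cid} is empty")
        k = subcluster_count(len(members), fraction)
        plan[cid] = _agglomerate(members, matrix, k, linkage)
    return SubclusterPlan(plan, fraction=fraction, linkage=linkage)


def _linkage_distance(a: list[str], b: list[str], matrix: PatristicMatrix, linkage: str) -> float:
    sub = matrix.values[
        np.ix_([matrix.index_of(x) for x in a], [matrix.index_of(x) for x in b])
    ]
    if linkage == "average":
        return float(sub.mean())
    if linkage == "complete":
        return float(sub.max())
    return float(sub.min())


def _agglomerate(
    members: Sequence[str], matrix: PatristicMatrix, k: int, linkage: str
) -> list[list[str]]:
    groups: list[list[str]] = [[m] for m in sorted(members)]
    while len(groups) > k:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = _linkage_distance(groups[i], groups[j], matrix, linkage)
                sig = tuple(sorted((groups[i][0], groups[j][0])))
                cand = (d, sig, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        merged = sorted(groups[i] + groups[j])
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)]
        groups.append(merged)
    # deterministic presentation order
    return sorted(groups, key=lambda g: g[0])


# ---------------------------------------------------------------------------
# stage 3: representative selection
# ---------------------------------------------------------------------------


def pick_representatives(
    plan: SubclusterPlan,
    matrix: PatristicMatrix,
    priorities: Mapping[str, int] | None = None,
) -> RepresentativeSet:
    """One representative per subcluster.

    Highest priority rank wins (unlisted leaves rank 0); ties fall back to
    the subcluster medoid (minimum summed patristic distance to the other
    members); remaining ties to the lexicographically smallest label.
    """
    priorities = dict(priorities or {})
    for leaf, rank in priorities.items():
        if not isinstance(rank, (int, np.integer)) or rank < 0:
            raise ValueError(f"priority rank for {leaf!r} must be a non-negative integer")
    records: list[Representative] = []
    for cid in sorted(plan.subclusters):
        for sid, members in enumerate(plan.subclusters[cid], start=1):
            label, reason = _select_one(members, matrix, priorities)
            records.append(Representative(label, cid, sid, reason))
    return RepresentativeSet(records)


def _select_one(
    members: Sequence[str], matrix: PatristicMatrix, priorities: Mapping[str, int]
) -> tuple[str, str]:
    ranks = {m: priorities.get(m, 0) for m in members}
    top = max(ranks.values())
    candidates = sorted(m for m in members if ranks[m] == top)
    if top > 0 and len(candidates) == 1:
        return candidates[0], "priority"
    if len(candidates) == 1:
        # singleton subcluster (or a single rank-0 leaf): nothing to compare
        return candidates[0], "lexicographic"
    # tie on rank: medoid of the subcluster among the tied candidates
    idx_all = [matrix.index_of(m) for m in members]
    sums = {
        m: float(matrix.values[matrix.index_of(m), idx_all].sum()) for m in candidates
    }
    best = min(sums.values())
    tied = sorted(m for m, s in sums.items() if abs(s - best) <= 1e-12)
    if len(tied) == 1:
        return tied[0], "medoid"
    return tied[0], "lexicographic"


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def sample_tree(
    tree: PhyloTree,
    threshold: float = 1.75,
    fraction: float = 0.2,
    mode: str = "max_clade",
    linkage: str = "average",
    priorities: Mapping[str, int] | None = None,
    matrix: PatristicMatrix | None = None,
) -> tuple[RepresentativeSet, dict]:
    """Run clustering, subclustering, and selection; return the
    representative set plus a provenance report."""
    from .tree import patristic_matrix

    if matrix is None:
        matrix = patristic_matrix(tree)
    clusters = threshold_clusters(tree, matrix, threshold=threshold, mode=mode)
    plan = plan_subclusters(clusters, matrix, fraction=fraction, linkage=linkage)
    reps = pick_representatives(plan, matrix, priorities=priorities)
    provenance = {
        "n_leaves": tree.n_leaves,
        "threshold": threshold,
        "fraction": fraction,
        "mode": mode,
        "linkage": linkage,
        "n_clusters": clusters.n_clusters,
        "subclusters_per_cluster": {
            str(cid): plan.n_subclusters(cid) for cid in sorted(plan.subclusters)
        },
        "n_selected": len(reps),
        "selection_reasons": reps.to_frame()["selection_reason"].value_counts().to_dict(),
    }
    return reps, provenance
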