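"""Heterotic grouping: UPGMA clustering of a GD matrix and group propagation.

Parents are agglomerated with average linkage (UPGMA) on the genetic-distance
matrix; cutting the tree at a fixed ``k`` yields heterotic candidate groups
(the conventional ``k`` values are 5 for SNP-based GD and 3 for SSR-based
GD).  Group labels propagate from female parents to their F1 crosses, since
in an NC II factorial every female meets every male and the female's group is
what distinguishes crosses.

The agglomeration is written out explicitly rather than delegated so that
ties break deterministically (prefer the pair whose lexicographically
smallest member label is smallest); heights are then bit-reproducible under
any input label order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "upgma_cluster",
    "cut_groups",
    "assign_f1_groups",
    "group_gd_summary",
]


@dataclasses.dataclass
class Dendrogram:
    """UPGMA merge history over a set of leaves.

    ``merges`` follows the scipy linkage convention: row ``i`` merges nodes
    ``(a, b)`` (leaves are ``0..n-1``, internal node ``n+i``) at ``height``,
    forming a cluster of ``size`` leaves.  UPGMA heights are non-decreasing.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError(f"expected {n-1} merges for {n} leaves")
        h = self.merges[:, 2]
        if len(h) and np.any(np.diff(h) < -1e-12):
            raise ValueError("UPGMA merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_newick(self) -> str:
        """Newick rendering; branch lengths are merge-height differences
        (leaves sit at height 0)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, h, _s) in enumerate(self.merges):
            node = n + i
            children[node] = (int(a), int(b))
            height[node] = float(h)

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.10g}"
            a, b = children[node]
            return f"({render(a, height[node])},{render(b, height[node])}):{bl:.10g}"

        if n == 1:
            return f"{self.labels[0]};"
        root = n + len(self.merges) - 1
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclasses.dataclass
class ClusterAssignment:
    """Mapping of labels to groups ``1..k`` (every group non-empty)."""

    groups: pd.Series  # label -> group id
    k: int
    within_gd: pd.Series | None = None  # group id -> mean within-group GD

    def __post_init__(self) -> None:
        ids = set(self.groups.unique())
        if ids != set(range(1, self.k + 1)):
            raise ValueError(f"group ids must be exactly 1..{self.k}, got {sorted(ids)}")

    def sizes(self) -> pd.Series:
        return self.groups.value_counts().sort_index()

    def of(self, label: str) -> int:
        return int(self.groups[label])


def upgma_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a complete distance matrix.

    Undefined entries are rejected (the offending pairs are listed); ties are
    broken by preferring the candidate pair whose lexicographically smallest
    member label sorts first, then by the other member.
    """
    n = len(dm.labels)
    off_diag = ~np.eye(n, dtype=bool)
    bad = np.argwhere(np.isnan(dm.values) & off_diag)
    if bad.size:
        pairs = sorted(
            {tuple(sorted((dm.labels[i], dm.labels[j]))) for i, j in bad}
        )
        raise ValueError(f"undefined distances for pairs: {pairs[:10]}")
    d = dm.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))  # current cluster -> scipy-style node id
    leader = list(dm.labels)  # lexicographically smallest leaf label
    size = np.ones(n)
    merges = np.zeros((n - 1, 4))
    alive = np.ones(n, dtype=bool)
    for step in range(n - 1):
        masked = np.where(np.outer(alive, alive), d, np.inf)
        m = masked.min()
        cand = np.argwhere(np.isclose(masked, m, rtol=0, atol=0))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(
            cand,
            key=lambda p: tuple(sorted((leader[p[0]], leader[p[1]]))),
        )
        merges[step] = (active[i], active[j], m, size[i] + size[j])
        # average-linkage update into slot i
        others = alive.copy()
        others[[i, j]] = False
        new = (size[i] * d[i, others] + size[j] * d[j, others]) / (size[i] + size[j])
        d[i, others] = new
        d[others, i] = new
        size[i] += size[j]
        alive[j] = False
        active[i] = n + step
        leader[i] = min(leader[i], leader[j])
    return Dendrogram(labels=list(dm.labels), merges=merges)


def cut_groups(tree: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the ``k-1`` highest merges, yielding exactly ``k`` groups.

    Group ids 1..k are assigned by decreasing group size, ties broken by the
    lexicographically smallest member label.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(n + max(n - 1, 0)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # UPGMA heights are non-decreasing, so the k-1 highest merges are the
    # last k-1 rows; apply only the first n-k merges.
    for step in range(n - k):
        a, b, _h, _s = tree.merges[step]
        node = n + step
        parent[find(int(a))] = node
        parent[find(int(b))] = node
    members: dict[int, list[str]] = {}
    for leaf in range(n):
        members.setdefault(find(leaf), []).append(tree.labels[leaf])
    ordered = sorted(
        members.values(), key=lambda labs: (-len(labs), min(labs))
    )
    mapping = {
        lab: gid for gid, labs in enumerate(ordered, start=1) for lab in labs
    }
    groups = pd.Series({lab: mapping[lab] for lab in tree.labels}, name="group")
    return ClusterAssignment(groups=groups, k=k)


def assign_f1_groups(
    female_groups: ClusterAssignment, design: pd.DataFrame
) -> ClusterAssignment:
    """Propagate female-parent groups to F1 crosses.

    Each cross inherits its female's group, so each F1 group has size
    (females in group) x (number of males).  An ungrouped female raises.
    """
    missing = sorted(set(design["female"]) - set(female_groups.groups.index))
    if missing:
        raise KeyError(f"females without a group assignment: {missing[:10]}")
    groups = pd.Series(
        design["female"].map(female_groups.groups).to_numpy(),
        index=design["cross"],
        name="group",
    )
    present = sorted(groups.unique())
    # Re-densify ids in case some female group has no cross in the design.
    remap = {g: i for i, g in enumerate(present, start=1)}
    return ClusterAssignment(groups=groups.map(remap), k=len(present))


def group_gd_summary(
    assignment: ClusterAssignment, cross_gd: pd.DataFrame
) -> pd.DataFrame:
    """Arithmetic mean GD (per marker system) of the crosses in each group."""
    tab = cross_gd.set_index("cross")
    covered = tab.index.intersection(assignment.groups.index)
    missing = set(assignment.groups.index) - set(covered)
    if missing:
        raise KeyError(f"crosses without GD rows: {sorted(missing)[:10]}")
    tab = tab.loc[assignment.groups.index]
    tab = tab.assign(group=assignment.groups.to_numpy())
    out = (
        tab.groupby("group")[["gd_ssr", "gd_snp"]]
        .agg(["size", "mean"])
        .pipe(lambda df: df.set_axis(["_n1", "gd_ssr_mean", "_n2", "gd_snp_mean"], axis=1))
    )
    out["n_crosses"] = out.pop("_n1").astype(int)
    out = out.drop(columns=["_n2"]).reset_index()
    return out[["group", "n_crosses", "gd_ssr_mean", "gd_snp_mean"]]
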