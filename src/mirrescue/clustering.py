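"""Profile clustering: SOTA, sample dendrograms and rescue-pattern labels.

The Self-Organizing Tree Algorithm (SOTA) grows a binary tree of
centroid "cells". Training presents every profile to its nearest leaf
and moves the winning centroid (and, when its sibling is also a leaf,
the parent and sibling) toward the profile by three decreasing learning
rates. When the within-cycle error stabilizes, the leaf with the
largest *resource* — the mean distance of its members to its centroid —
splits into two children seeded at its centroid, and training resumes.
Growth stops after ``max_cycles`` splits (the initial two-leaf system
counts as the first) or when every leaf's resource falls below
``variability_threshold``.

Cluster centroids averaged within the four conditions are classified
into rescue patterns: ``up_rescued`` profiles rise in disease (D) and
return to control (C) levels under treatment (D+P) without moving the
treated controls (C+P); ``down_rescued`` is the mirror image.

Sample relationships are summarized by agglomerative complete-linkage
clustering under either Pearson dissimilarity (1 - r) or the average
dot product of standardized profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import GROUPS, ExpressionMatrix

UP, DOWN, OTHER = "up_rescued", "down_rescued", "other"


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# profiles and pattern labels


def relative_profiles(values: pd.DataFrame | ExpressionMatrix) -> pd.DataFrame:
    """Center each row on its across-sample mean (log2 ratio to average)."""
    if isinstance(values, ExpressionMatrix):
        values = values.values
    if values.isna().all(axis=1).any():
        raise ClusteringError("all-NA rows cannot be centered")
    return values.sub(values.mean(axis=1, skipna=True), axis=0)


def classify_pattern(group_means, delta: float) -> str:
    """Label a centroid's four group means as a rescue pattern.

    ``up_rescued`` iff D sits more than ``delta`` above C while both
    C+P and D+P stay within ``delta`` of C; ``down_rescued`` mirrors
    this below C; anything else is ``other``. Invariant to adding a
    constant to all four means.
    """
    if delta <= 0:
        raise ClusteringError("delta must be > 0")
    try:
        c, cp, d, dp = (float(group_means[g]) for g in GROUPS)
    except (KeyError, IndexError) as exc:
        raise ClusteringError(f"missing group mean: {exc}") from exc
    controls_flat = abs(cp - c) <= delta and abs(dp - c) <= delta
    if d - c > delta and controls_flat:
        return UP
    if d - c < -delta and controls_flat:
        return DOWN
    return OTHER


def default_delta(de_diffs: np.ndarray | pd.Series) -> float:
    """Half the median |D - C| log2 difference over DE genes."""
    diffs = np.abs(np.asarray(de_diffs, float))
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size == 0:
        raise ClusteringError("no differences to derive delta from")
    return 0.5 * float(np.median(diffs))


# ---------------------------------------------------------------------------
# SOTA


@dataclass
class SotaParams:
    alpha_winner: float = 0.01
    alpha_parent: float = 0.005
    alpha_sister: float = 0.001
    epochs_per_cycle: int = 1000
    max_cycles: int = 10
    epsilon: float = 1e-8
    variability_threshold: float | None = None
    distance: str = "pearson"  # pearson | dot_product | euclidean
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha_winner >= self.alpha_parent
                >= self.alpha_sister > 0):
            raise ClusteringError(
                "learning rates must satisfy winner >= parent >= sister > 0")
        if self.max_cycles < 1:
            raise ClusteringError("max_cycles must be >= 1")
        if self.distance not in ("pearson", "dot_product", "euclidean"):
            raise ClusteringError(f"unknown distance: {self.distance!r}")


@dataclass
class SotaNode:
    node_id: int
    centroid: np.ndarray
    parent: int | None = None
    children: tuple[int, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SotaTree:
    nodes: dict[int, SotaNode]
    root: int
    resources: dict[int, float] = field(default_factory=dict)

    @property
    def leaf_ids(self) -> list[int]:
        return [i for i, n in sorted(self.nodes.items()) if n.is_leaf]

    def to_newick(self) -> str:
        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                return f"c{nid}"
            a, b = node.children
            return f"({rec(a)},{rec(b)})"
        return rec(self.root) + ";"


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # profile id -> leaf id
    centroids: pd.DataFrame           # leaf id x samples, member means
    patterns: pd.Series | None = None  # leaf id -> rescue-pattern label

    def pattern_of(self, profile_id: str) -> str:
        if self.patterns is None:
            raise ClusteringError("patterns not assigned yet")
        return self.patterns[self.labels[profile_id]]


def _dist_to_centroids(x: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.sqrt(((C - x) ** 2).sum(axis=1))
    xc = x - x.mean()
    Cc = C - C.mean(axis=1, keepdims=True)
    nx = np.sqrt((xc ** 2).sum())
    nC = np.sqrt((Cc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = Cc @ xc / (nC * nx)
    r = np.where(np.isfinite(r), r, 0.0)
    return 1.0 - r


def _all_dists(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    """(n, L) distance matrix between profiles and centroids."""
    if metric == "euclidean":
        return np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    nX = np.sqrt((Xc ** 2).sum(axis=1))
    nC = np.sqrt((Cc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Cc.T) / np.outer(nX, nC)
    r = np.where(np.isfinite(r), r, 0.0)
    return 1.0 - r


def _train_cycle(X: np.ndarray, tree: SotaTree, leaves: list[int],
                 params: SotaParams, rng: np.random.Generator) -> None:
    n = X.shape[0]
    leaf_index = {lid: k for k, lid in enumerate(leaves)}
    C = np.stack([tree.nodes[lid].centroid for lid in leaves])
    prev_err = None
    for _ in range(params.epochs_per_cycle):
        order = rng.permutation(n) if params.shuffle else range(n)
        for i in order:
            x = X[i]
            d = _dist_to_centroids(x, C, params.distance)
            w = int(np.argmin(d))  # ties -> lowest index, deterministic
            wid = leaves[w]
            C[w] += params.alpha_winner * (x - C[w])
            parent_id = tree.nodes[wid].parent
            if parent_id is not None:
                pnode = tree.nodes[parent_id]
                sib = next(c for c in pnode.children if c != wid)
                if tree.nodes[sib].is_leaf:
                    pnode.centroid += params.alpha_parent * (x - pnode.centroid)
                    k = leaf_index[sib]
                    C[k] += params.alpha_sister * (x - C[k])
        err = float(_all_dists(X, C, params.distance).min(axis=1).sum())
        if prev_err is not None and \
                abs(prev_err - err) <= params.epsilon * max(abs(prev_err), 1e-12):
            break
        prev_err = err
    for k, lid in enumerate(leaves):
        tree.nodes[lid].centroid = C[k]


def sota_cluster(profiles: pd.DataFrame,
                 params: SotaParams | None = None
                 ) -> tuple[SotaTree, ClusterAssignment]:
    """Grow a SOTA tree over row profiles and assign each to a leaf.

    Profiles are presented in input order (deterministic) unless
    ``params.shuffle`` asks for a seeded permutation per epoch. The
    final assignment maps every profile to its nearest leaf centroid;
    per-leaf resources are stored on the returned tree.
    """
    params = params or SotaParams()
    X = profiles.to_numpy(float)
    if np.isnan(X).any():
        raise ClusteringError("profiles contain NaN; impute or drop first")
    if X.shape[0] < 2:
        raise ClusteringError("need at least 2 profiles")
    rng = np.random.default_rng(params.seed)

    root = SotaNode(0, X.mean(axis=0))
    tree = SotaTree(nodes={0: root}, root=0)
    tree.nodes[1] = SotaNode(1, root.centroid.copy(), parent=0)
    tree.nodes[2] = SotaNode(2, root.centroid.copy(), parent=0)
    root.children = (1, 2)
    leaves = [1, 2]
    next_id = 3
    cycles = 1  # the initial two-cell system is the first growth cycle

    while True:
        _train_cycle(X, tree, leaves, params, rng)
        C = np.stack([tree.nodes[lid].centroid for lid in leaves])
        D = _all_dists(X, C, params.distance)
        assign = D.argmin(axis=1)
        res = {}
        for k, lid in enumerate(leaves):
            member_d = D[assign == k, k]
            res[lid] = float(member_d.mean()) if member_d.size else 0.0
        tree.resources = res
        if cycles >= params.max_cycles:
            break
        ranked = sorted(leaves, key=lambda lid: (-res[lid], lid))
        worst = ranked[0]
        if params.variability_threshold is not None and \
                res[worst] <= params.variability_threshold:
            break
        if res[worst] <= 0.0:
            break  # every member identical to its centroid
        for _ in range(2):
            tree.nodes[next_id] = SotaNode(
                next_id, tree.nodes[worst].centroid.copy(), parent=worst)
            next_id += 1
        tree.nodes[worst].children = (next_id - 2, next_id - 1)
        leaves = tree.leaf_ids
        cycles += 1

    labels = pd.Series([leaves[a] for a in assign], index=profiles.index,
                       name="cluster")
    centroids = {}
    for lid in leaves:
        members = labels.index[labels == lid]
        if len(members):
            centroids[lid] = profiles.loc[members].mean(axis=0)
    centroid_df = pd.DataFrame(centroids).T
    centroid_df.index.name = "cluster"
    return tree, ClusterAssignment(labels=labels, centroids=centroid_df)


def assign_patterns(assignment: ClusterAssignment, groups: pd.Series,
                    delta: float) -> ClusterAssignment:
    """Label each cluster centroid with its rescue pattern."""
    patterns = {}
    for lid, centroid in assignment.centroids.iterrows():
        means = {g: centroid[[s for s in centroid.index
                              if groups[s] == g]].mean() for g in GROUPS}
        patterns[lid] = classify_pattern(means, delta)
    assignment.patterns = pd.Series(patterns, name="pattern")
    return assignment


# ---------------------------------------------------------------------------
# hierarchical sample clustering


def sample_distance_matrix(matrix: ExpressionMatrix | pd.DataFrame,
                           distance: str = "pearson") -> pd.DataFrame:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    samples = list(values.columns)
    m = len(samples)
    if m < 2:
        raise ClusteringError("need at least 2 samples")
    V = values.to_numpy(float)
    D = np.zeros((m, m))
    if distance == "pearson":
        for i in range(m):
            for j in range(i + 1, m):
                mask = ~np.isnan(V[:, i]) & ~np.isnan(V[:, j])
                xi, xj = V[mask, i], V[mask, j]
                for vec, s in ((xi, samples[i]), (xj, samples[j])):
                    if vec.size < 2 or np.std(vec) == 0:
                        raise ClusteringError(
                            f"sample {s!r} is constant; Pearson distance "
                            "undefined")
                r = np.corrcoef(xi, xj)[0, 1]
                D[i, j] = D[j, i] = 1.0 - r
    elif distance == "dot_product":
        # average dot product of z-standardized profiles, converted to a
        # dissimilarity by subtracting from the dataset maximum similarity
        S = np.zeros((m, m))
        Z = np.full_like(V, np.nan)
        for i in range(m):
            col = V[:, i]
            mask = ~np.isnan(col)
            sd = np.std(col[mask])
            if mask.sum() < 2 or sd == 0:
                raise ClusteringError(
                    f"sample {samples[i]!r} is constant; standardized dot "
                    "product undefined")
            Z[mask, i] = (col[mask] - col[mask].mean()) / sd
        for i in range(m):
            for j in range(i + 1, m):
                mask = ~np.isnan(Z[:, i]) & ~np.isnan(Z[:, j])
                S[i, j] = S[j, i] = float(np.mean(Z[mask, i] * Z[mask, j]))
        s_max = S[np.triu_indices(m, 1)].max()
        D = s_max - S
        np.fill_diagonal(D, 0.0)
    else:
        raise ClusteringError(f"unknown distance: {distance!r}")
    return pd.DataFrame(D, index=samples, columns=samples)


def hcluster_samples(matrix: ExpressionMatrix | pd.DataFrame,
                     distance: str = "pearson",
                     linkage: str = "complete"
                     ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative sample clustering; returns (scipy linkage, labels)."""
    D = sample_distance_matrix(matrix, distance)
    Z = hierarchy.linkage(squareform(D.to_numpy(), checks=False),
                          method=linkage)
    return Z, list(D.columns)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch
    lengths equal to merge-height differences."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        bl = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{bl:.6g}"

    return rec(tree, tree.dist) + ";"
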