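"""Pairwise distances, hierarchical genotype groups, subsampling curves.

How many clones must be sequenced per time point to see the genotype
diversity present?  Clones from one day are clustered (agglomerative, on
the symmetric-difference distance), the dendrogram is cut into k groups,
and random subsamples of increasing size are scored for how many of the k
groups they detect — alongside the closed-form expectation
``E[detected] = sum_i (1 - C(N - N_i, m) / C(N, m))`` for group sizes N_i.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .lineage import genotype_distance


def pairwise_distance_matrix(mutation_sets: Sequence[frozenset]) -> np.ndarray:
    """Symmetric matrix of set distances between clones (>= 2 required)."""
    n = len(mutation_sets)
    if n < 2:
        raise ValueError("need at least two clones")
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = genotype_distance(mutation_sets[i],
                                                  mutation_sets[j])
    return d


def cluster_genotype_groups(distance_matrix: np.ndarray, k: int,
                            linkage: str = "average") -> np.ndarray:
    """Cut an agglomerative clustering of the distance matrix into k groups.

    Linkage defaults to average (UPGMA); "complete" and "single" are also
    accepted.  Returned labels are renumbered 1..k by lowest member index,
    so the labelling is deterministic for a given input order.
    """
    n = distance_matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    condensed = squareform(np.asarray(distance_matrix, dtype=float),
                           checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return _canonical_labels(raw)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    return np.array([order[lab] for lab in raw])


def linkage_tree(distance_matrix: np.ndarray,
                 linkage: str = "average") -> np.ndarray:
    condensed = squareform(np.asarray(distance_matrix, dtype=float),
                           checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def dendrogram_to_newick(tree: np.ndarray,
                         leaf_names: Optional[Sequence[str]] = None) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    root = hierarchy.to_tree(tree)
    names = (list(leaf_names) if leaf_names is not None
             else [str(i) for i in range(root.get_count())])

    def walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:g}"

    return f"({walk(root.get_left(), root.dist)}," \
           f"{walk(root.get_right(), root.dist)});"


@dataclass
class DetectionCurve:
    """Mean detected group count per subsample size, plus the analytic value."""
    table: pd.DataFrame  # columns: size, mean, sd, expected
    k: int
    n_reps: int
    seed: int


def expected_groups_detected(group_sizes: Sequence[int], m: int) -> float:
    """Closed-form expectation of groups present in a size-m subsample.

    Sampling without replacement from N = sum(N_i) clones, group i is missed
    with probability C(N - N_i, m)/C(N, m) (hypergeometric zero class).
    """
    sizes = [int(s) for s in group_sizes]
    n = sum(sizes)
    if not 0 <= m <= n:
        raise ValueError(f"subsample size {m} outside [0, {n}]")
    denom = comb(n, m)
    return float(sum(1.0 - comb(n - s, m) / denom for s in sizes))


def subsampling_detection_curve(labels: Sequence[int], sizes: Sequence[int],
                                n_reps: int = 1000,
                                seed: int = 0) -> DetectionCurve:
    """Monte-Carlo detection curve with the analytic expectation alongside.

    For each subsample size, ``n_reps`` random subsamples (without
    replacement, seeded) are drawn and the number of distinct group labels
    present is averaged.
    """
    labels = np.asarray(labels)
    n = len(labels)
    k = len(set(labels.tolist()))
    group_sizes = [int((labels == g).sum()) for g in sorted(set(labels.tolist()))]
    rng = np.random.default_rng(seed)
    rows = []
    for m in sizes:
        if m > n:
            raise ValueError(f"subsample size {m} exceeds {n} clones")
        detected = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.choice(n, size=m, replace=False)
            detected[r] = len(set(labels[idx].tolist()))
        rows.append((m, float(detected.mean()), float(detected.std(ddof=1))
                     if n_reps > 1 else 0.0,
                     expected_groups_detected(group_sizes, m)))
    table = pd.DataFrame(rows, columns=["size", "mean", "sd", "expected"])
    return DetectionCurve(table=table, k=k, n_reps=n_reps, seed=seed)
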