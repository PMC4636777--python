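"""Profile clustering: Pearson-distance hierarchical clustering and SOTA.

Clustering operates on per-miRNA expression profiles across groups
(e.g. day x reproductive status), conventionally mean-centered
log2(CPM + 1) group means.  Hierarchical clustering uses average linkage on
the Pearson correlation distance d = 1 - r.  SOTA (self-organizing tree
algorithm) grows a binary tree of cells: profiles are repeatedly presented
to the tree, the closest leaf and its neighborhood adapt toward them, and
after each training cycle the leaf with the highest resource (mean member
distance to its centroid) is split, until the growth criterion is met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform


def mean_centered_profiles(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's mean (the conventional profile preprocessing)."""
    return values.sub(values.mean(axis=1), axis=0)


def group_mean_profiles(cpm: pd.DataFrame, groups: dict[str, str], center: bool = True) -> pd.DataFrame:
    """log2(CPM+1) averaged within groups, optionally mean-centered per row."""
    logx = np.log2(cpm + 1.0)
    cols = {g: logx[[s for s in cpm.columns if groups[s] == g]].mean(axis=1)
            for g in dict.fromkeys(groups.values())}
    prof = pd.DataFrame(cols)
    return mean_centered_profiles(prof) if center else prof


def pearson_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d = 1 - Pearson r between rows; constant rows are excluded.

    The result is symmetric with zero diagonal and values in [0, 2].
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 columns per profile")
    sd = profiles.std(axis=1, ddof=0)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant profile(s): "
            f"correlation distance undefined"
        )
    sub = profiles.loc[~constant]
    r = np.corrcoef(sub.values)
    d = 1.0 - np.atleast_2d(r)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sub.index, columns=sub.index)


def hcl(distances: pd.DataFrame, linkage: str = "average") -> pd.DataFrame:
    """Agglomerative clustering on a distance matrix; returns the merge list.

    Wraps scipy's linkage.  The result has n-1 rows with columns
    (node_a, node_b, height, size); leaves are numbered 0..n-1 in row order
    of ``distances``, internal nodes n, n+1, ...
    """
    n = len(distances)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(distances.values, checks=False)
    z = sch.linkage(condensed, method=linkage)
    merges = pd.DataFrame(z, columns=["node_a", "node_b", "height", "size"])
    merges[["node_a", "node_b", "size"]] = merges[["node_a", "node_b", "size"]].astype(int)
    merges.attrs["leaves"] = list(distances.index)
    return merges


# ---------------------------------------------------------------------------
# SOTA


@dataclass
class SotaParams:
    """SOTA tuning. Learning rates follow winner >= parent >= sibling.

    Growth stops at ``max_clusters`` leaves, or earlier when
    ``variability_threshold`` is set and no leaf's resource exceeds it.
    """

    max_clusters: int = 7
    max_epochs: int = 1000
    lr_winner: float = 0.01
    lr_parent: float = 0.005
    lr_sibling: float = 0.001
    variability_threshold: float | None = None
    tol: float = 1e-9
    metric: str = "pearson"  # or "euclidean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.lr_winner, self.lr_parent, self.lr_sibling):
            if not (0 < r <= 1):
                raise ValueError("learning rates must be in (0, 1]")
        if not (self.lr_winner >= self.lr_parent >= self.lr_sibling):
            raise ValueError("expect winner >= parent >= sibling learning rate")


@dataclass
class _Cell:
    idx: int
    centroid: np.ndarray
    parent: int | None = None
    children: tuple[int, int] | None = None


def _dist_rows(x: np.ndarray, c: np.ndarray, metric: str) -> np.ndarray:
    """Distances from each row of x to each row of c (profiles x cells)."""
    if metric == "euclidean":
        return np.linalg.norm(x[:, None, :] - c[None, :, :], axis=2)
    xs = x - x.mean(axis=1, keepdims=True)
    cs = c - c.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xs, axis=1)
    cn = np.linalg.norm(cs, axis=1)
    denom = np.outer(xn, cn)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs @ cs.T) / denom
    r = np.where(denom > 0, r, 0.0)  # constant profile or centroid: r treated as 0
    return 1.0 - r


@dataclass
class SotaResult:
    labels: pd.Series           # profile id -> leaf cell index
    centroids: pd.DataFrame     # leaf cell index -> centroid
    tree: list[tuple[int, int | None]]  # (cell, parent) edges in creation order


def sota(profiles: pd.DataFrame, params: SotaParams | None = None) -> SotaResult:
    """Cluster row profiles with the self-organizing tree algorithm.

    Deterministic under ``params.rng_seed``; returns exactly
    ``params.max_clusters`` leaves when the data allow it (cells holding a
    single profile, or zero-variability cells when a variability threshold is
    set, are not split).
    """
    params = params or SotaParams()
    x = profiles.values.astype(float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 profiles")
    if params.max_clusters > n:
        raise ValueError("max_clusters exceeds number of profiles")
    rng = np.random.default_rng(params.rng_seed)

    cells: list[_Cell] = [_Cell(0, x.mean(axis=0))]
    leaves = [0]

    def split(leaf: int, members: np.ndarray) -> None:
        """Replace a leaf by two children seeded at distant members."""
        cell = cells[leaf]
        if len(members) >= 2:
            sub = x[members]
            d0 = _dist_rows(sub, cell.centroid[None, :], params.metric)[:, 0]
            i = int(np.argmax(d0))
            d1 = _dist_rows(sub, sub[i][None, :], params.metric)[:, 0]
            j = int(np.argmax(d1))
            if j == i:
                j = (i + 1) % len(members)
            c1, c2 = sub[i].copy(), sub[j].copy()
        else:  # degenerate: duplicate the centroid with a tiny jitter
            eps = 1e-8 * (1.0 + np.abs(cell.centroid))
            c1 = cell.centroid + rng.normal(0, 1, cell.centroid.shape) * eps
            c2 = cell.centroid - rng.normal(0, 1, cell.centroid.shape) * eps
        a, b = len(cells), len(cells) + 1
        cells.append(_Cell(a, c1, parent=leaf))
        cells.append(_Cell(b, c2, parent=leaf))
        cells[leaf].children = (a, b)
        leaves.remove(leaf)
        leaves.extend([a, b])

    # initial bifurcation of the root
    split(0, np.arange(n))

    while True:
        # training cycle: adapt leaves to the profiles
        prev_error = np.inf
        for _ in range(params.max_epochs):
            cent = np.array([cells[l].centroid for l in leaves])
            d = _dist_rows(x, cent, params.metric)
            winners = d.argmin(axis=1)
            for i in range(n):  # sequential presentation, fixed order
                w = leaves[winners[i]]
                cells[w].centroid += params.lr_winner * (x[i] - cells[w].centroid)
                p = cells[w].parent
                if p is not None:
                    cells[p].centroid += params.lr_parent * (x[i] - cells[p].centroid)
                    sib = [c for c in cells[p].children if c != w][0]
                    if cells[sib].children is None:
                        cells[sib].centroid += params.lr_sibling * (x[i] - cells[sib].centroid)
            error = float(d[np.arange(n), winners].sum())
            if abs(prev_error - error) <= params.tol * max(1.0, abs(prev_error)):
                break
            prev_error = error

        cent = np.array([cells[l].centroid for l in leaves])
        d = _dist_rows(x, cent, params.metric)
        winners = d.argmin(axis=1)
        if len(leaves) >= params.max_clusters:
            break
        # resource of each leaf: mean distance of its members to the centroid
        resources = np.full(len(leaves), -1.0)
        for k in range(len(leaves)):
            mem = np.flatnonzero(winners == k)
            if len(mem) >= 2:
                resources[k] = d[mem, k].mean()
        if params.variability_threshold is not None and resources.max() <= params.variability_threshold:
            break
        if resources.max() < 0:  # nothing splittable with >= 2 members
            # honor a fixed target cluster count by peeling singletons off
            sizes = np.bincount(winners, minlength=len(leaves))
            k = int(np.argmax(sizes))
            if sizes[k] < 2:
                break
            split(leaves[k], np.flatnonzero(winners == k))
            continue
        k = int(np.argmax(resources))
        split(leaves[k], np.flatnonzero(winners == k))

    cent = np.array([cells[l].centroid for l in leaves])
    d = _dist_rows(x, cent, params.metric)
    winners = d.argmin(axis=1)
    labels = pd.Series([leaves[w] for w in winners], index=profiles.index, name="cluster")
    centroids = pd.DataFrame(cent, index=leaves, columns=profiles.columns)
    tree = [(c.idx, c.parent) for c in cells]
    return SotaResult(labels=labels, centroids=centroids, tree=tree)
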