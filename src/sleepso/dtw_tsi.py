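"""Windowed dynamic time warping, LB-Keogh, DBA, and budgeted 1-NN search.

DTW aligns two series by a monotone warping path minimising the accumulated
local cost; the local cost here is the squared sample difference and the
accumulated cost is returned without a square root (internally consistent
for nearest-neighbour ranking).  A Sakoe-Chiba band of half-width ``window``
constrains the path (|i - j| <= window), preventing pathological alignments
and cutting cost; the band half-width defaults to 10% of the longest
training series.

LB-Keogh is a cheap envelope-based lower bound on windowed DTW used to skip
full DTW computations during nearest-neighbour search.  It is an exact lower
bound for equal-length series; for unequal lengths the shorter series is
linearly resampled to the longer one's length first, which makes the bound
heuristic (documented implementation choice).

The time-series index (TSI) is a hierarchical k-means tree: each internal
node partitions its series into up to ``branching`` clusters (DBA centroids,
DTW assignment), recursing until clusters hold at most ``leaf_max`` series.
A query descends best-first by centroid distance; at leaves, LB-Keogh prunes
series that cannot beat the current nearest neighbour, and the search stops
once a budget of fully compared training series ("examples seen") is
exhausted.  With a budget covering the whole training set and no effective
pruning ambiguity, the result equals exhaustive 1-NN with ties broken by the
lowest training-series index.
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .exceptions import ParameterError, ValidationError


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_cost(a, b, window):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    INF = np.inf
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = i - window
        if jlo < 1:
            jlo = 1
        jhi = i + window
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            c = (a[i - 1] - b[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[n, m]


@njit(cache=True)
def _dtw_matrix(a, b, window):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    INF = np.inf
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = i - window
        if jlo < 1:
            jlo = 1
        jhi = i + window
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            c = (a[i - 1] - b[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D


@njit(cache=True)
def _lb_keogh_equal(q, c, window):  # pragma: no cover - compiled
    n = q.shape[0]
    total = 0.0
    for i in range(n):
        lo = i - window
        if lo < 0:
            lo = 0
        hi = i + window + 1
        if hi > n:
            hi = n
        u = q[lo]
        l = q[lo]
        for k in range(lo + 1, hi):
            if q[k] > u:
                u = q[k]
            if q[k] < l:
                l = q[k]
        x = c[i]
        if x > u:
            total += (x - u) ** 2
        elif x < l:
            total += (l - x) ** 2
    return total


def _as_series(x) -> np.ndarray:
    arr = np.ascontiguousarray(np.asarray(x, dtype=np.float64))
    if arr.ndim != 1 or arr.size == 0:
        raise ParameterError("series must be non-empty and 1-D")
    return arr


def _effective_window(n: int, m: int, window: int | None) -> int:
    if window is None:
        return max(n, m)
    window = int(window)
    if window < abs(n - m):
        raise ParameterError(
            f"window {window} smaller than length difference {abs(n - m)}"
        )
    return window


def dtw_distance(a, b, window: int | None = None) -> float:
    """Windowed DTW distance (squared-difference local cost, no square root).

    ``window`` is the Sakoe-Chiba band half-width in samples; ``None`` means
    unconstrained.  An explicit window smaller than the length difference is
    rejected (no admissible path exists).
    """
    a = _as_series(a)
    b = _as_series(b)
    w = _effective_window(a.size, b.size, window)
    return float(_dtw_cost(a, b, w))


def dtw_path(a, b, window: int | None = None) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance plus one optimal warping path (list of index pairs)."""
    a = _as_series(a)
    b = _as_series(b)
    w = _effective_window(a.size, b.size, window)
    D = _dtw_matrix(a, b, w)
    i, j = a.size, b.size
    path = [(i - 1, j - 1)]
    while i > 1 or j > 1:
        moves = []
        if i > 1 and j > 1:
            moves.append((D[i - 1, j - 1], i - 1, j - 1))
        if i > 1:
            moves.append((D[i - 1, j], i - 1, j))
        if j > 1:
            moves.append((D[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return float(D[a.size, b.size]), path


def resample_series(x, length: int) -> np.ndarray:
    """Linear resampling to ``length`` samples (endpoints preserved)."""
    x = _as_series(x)
    if length < 1:
        raise ParameterError("length must be >= 1")
    if x.size == length:
        return x.copy()
    if x.size == 1:
        return np.full(length, x[0])
    old = np.linspace(0.0, 1.0, x.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, x)


def lb_keogh(query, candidate, window: int) -> float:
    """Envelope-based lower bound on windowed DTW.

    Exact (``lb_keogh <= dtw_distance``) for equal-length series; when the
    lengths differ, the shorter series is linearly resampled to the longer
    one's length first and the bound becomes heuristic.
    """
    q = _as_series(query)
    c = _as_series(candidate)
    if window < 0:
        raise ParameterError("window must be >= 0")
    n = max(q.size, c.size)
    if q.size != c.size:
        q = resample_series(q, n)
        c = resample_series(c, n)
    return float(_lb_keogh_equal(q, c, int(window)))


# ---------------------------------------------------------------------------
# DBA
# ---------------------------------------------------------------------------

def _dba_objective(centroid: np.ndarray, series: list[np.ndarray], window) -> float:
    return sum(dtw_distance(centroid, s, _safe_window(centroid.size, s.size, window))
               for s in series)


def _safe_window(n: int, m: int, window: int | None) -> int | None:
    if window is None:
        return None
    return max(int(window), abs(n - m))


def dba_centroid(
    series: list,
    n_iterations: int = 10,
    window: int | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """DTW Barycenter Averaging.

    Starting from an initial centroid (the first series by default), each
    iteration aligns every series to the centroid along an optimal warping
    path and replaces each centroid sample by the mean of the samples aligned
    to it.  The within-set sum of DTW distances is non-increasing across
    iterations; the update is rejected if it would increase the objective
    (numerical guard), so the audit trail is monotone by construction.
    """
    if not series:
        raise ParameterError("dba_centroid requires a non-empty series set")
    series = [_as_series(s) for s in series]
    if len(series) == 1:
        return series[0].copy()
    centroid = _as_series(init) if init is not None else series[0].copy()
    best_obj = _dba_objective(centroid, series, window)
    for _ in range(n_iterations):
        sums = np.zeros(centroid.size)
        counts = np.zeros(centroid.size)
        for s in series:
            w = _safe_window(centroid.size, s.size, window)
            _, path = dtw_path(centroid, s, w)
            for ci, si in path:
                sums[ci] += s[si]
                counts[ci] += 1
        new_centroid = np.where(counts > 0, sums / np.maximum(counts, 1), centroid)
        new_obj = _dba_objective(new_centroid, series, window)
        if new_obj >= best_obj - 1e-12:
            break
        centroid, best_obj = new_centroid, new_obj
    return centroid


# ---------------------------------------------------------------------------
# TSI tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TSIConfig:
    """Index-construction and search parameters."""

    branching: int = 10
    leaf_max: int = 30
    window_fraction: float = 0.10
    budget: int = 1000
    seed: int = 0
    kmeans_max_iter: int = 10
    dba_iterations: int = 3

    def __post_init__(self) -> None:
        if self.branching < 2:
            raise ParameterError("branching must be >= 2")
        if self.leaf_max < 1:
            raise ParameterError("leaf_max must be >= 1")
        if not 0 < self.window_fraction <= 1:
            raise ParameterError("window_fraction must be in (0, 1]")
        if self.budget < 1:
            raise ParameterError("budget must be >= 1")


@dataclass
class TSINode:
    """One tree node: a leaf holds training indices, an internal node children."""

    centroid: np.ndarray
    children: list["TSINode"] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TSITree:
    """Hierarchical DTW index over a labeled training set."""

    root: TSINode
    series: list[np.ndarray]
    labels: np.ndarray
    window: int
    config: TSIConfig

    @property
    def n_series(self) -> int:
        return len(self.series)

    def leaf_indices(self) -> list[list[int]]:
        out: list[list[int]] = []

        def visit(node: TSINode) -> None:
            if node.is_leaf:
                out.append(list(node.indices))
            else:
                for child in node.children:
                    visit(child)

        visit(self.root)
        return out


def _kmeans_level(
    series: list[np.ndarray],
    indices: list[int],
    k: int,
    window: int,
    rng: np.random.Generator,
    cfg: TSIConfig,
) -> list[tuple[np.ndarray, list[int]]]:
    """One k-means partition of ``indices`` into <= k clusters."""
    chosen = rng.choice(len(indices), size=k, replace=False)
    centroids = [series[indices[c]].copy() for c in chosen]
    assignment = np.zeros(len(indices), dtype=np.int64)
    for _ in range(cfg.kmeans_max_iter):
        # assign
        dists = np.empty((len(indices), k))
        for a, idx in enumerate(indices):
            for c in range(k):
                w = _safe_window(series[idx].size, centroids[c].size, window)
                dists[a, c] = dtw_distance(series[idx], centroids[c], w)
        new_assignment = np.argmin(dists, axis=1)
        # repair empty clusters with the farthest member of the largest cluster
        for c in range(k):
            if np.any(new_assignment == c):
                continue
            sizes = np.bincount(new_assignment, minlength=k)
            donor = int(np.argmax(sizes))
            members = np.flatnonzero(new_assignment == donor)
            far = members[int(np.argmax(dists[members, donor]))]
            new_assignment[far] = c
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        # update centroids by DBA
        for c in range(k):
            members = [series[indices[a]] for a in np.flatnonzero(assignment == c)]
            if members:
                centroids[c] = dba_centroid(
                    members, n_iterations=cfg.dba_iterations, window=window
                )
    clusters = []
    for c in range(k):
        members = [indices[a] for a in np.flatnonzero(assignment == c)]
        if members:
            clusters.append((centroids[c], members))
    return clusters


def build_tsi(series: list, labels, cfg: TSIConfig | None = None) -> TSITree:
    """Build the hierarchical DTW index over a labeled training set.

    Deterministic given ``cfg.seed``.  Every training series ends up in
    exactly one leaf, and every leaf holds at most ``cfg.leaf_max`` series.
    """
    cfg = cfg or TSIConfig()
    series = [_as_series(s) for s in series]
    labels = np.asarray(labels)
    if not series:
        raise ParameterError("build_tsi requires at least one training series")
    if labels.shape[0] != len(series):
        raise ValidationError("labels and series lengths differ")
    longest = max(s.size for s in series)
    window = max(1, int(round(cfg.window_fraction * longest)))
    rng = np.random.default_rng(cfg.seed)

    def grow(indices: list[int], centroid: np.ndarray, depth: int) -> TSINode:
        if len(indices) <= cfg.leaf_max:
            return TSINode(centroid=centroid, indices=sorted(indices))
        k = min(cfg.branching, len(indices))
        clusters = _kmeans_level(series, indices, k, window, rng, cfg)
        if len(clusters) == 1:
            # degenerate split (e.g. identical series): chunk to guarantee progress
            idx_sorted = sorted(indices)
            children = [
                TSINode(centroid=series[chunk[0]].copy(), indices=list(chunk))
                for chunk in (
                    idx_sorted[i:i + cfg.leaf_max]
                    for i in range(0, len(idx_sorted), cfg.leaf_max)
                )
            ]
            return TSINode(centroid=centroid, children=children)
        children = [grow(members, cent, depth + 1) for cent, members in clusters]
        return TSINode(centroid=centroid, children=children)

    root_centroid = dba_centroid(
        [series[i] for i in range(min(len(series), 50))],
        n_iterations=1, window=window,
    ) if len(series) > 1 else series[0].copy()
    root = grow(list(range(len(series))), root_centroid, 0)
    return TSITree(root=root, series=series, labels=labels, window=window, config=cfg)


def tsi_classify(
    tree: TSITree, query, budget: int | None = None
) -> tuple[object, float, int]:
    """Budgeted approximate 1-NN classification through the index.

    The tree is explored best-first by centroid DTW distance.  At each leaf,
    LB-Keogh screens members against the current nearest-neighbour distance;
    surviving members are fully compared (each counts toward the budget).
    Ties in distance resolve to the lowest training-series index.

    Returns ``(label, nn_distance, n_seen)``.
    """
    budget = tree.config.budget if budget is None else int(budget)
    if budget < 1:
        raise ParameterError("budget must be >= 1")
    q = _as_series(query)
    w = tree.window

    best_dist = np.inf
    best_idx = -1
    n_seen = 0
    counter = itertools.count()
    heap: list[tuple[float, int, TSINode]] = [(0.0, next(counter), tree.root)]
    while heap and n_seen < budget:
        _, _, node = heapq.heappop(heap)
        if node.is_leaf:
            for idx in node.indices:
                if n_seen >= budget:
                    break
                s = tree.series[idx]
                if np.isfinite(best_dist) and s.size == q.size:
                    # prune only where the bound is exact (equal lengths)
                    lb = lb_keogh(q, s, w)
                    if lb > best_dist:
                        continue  # cannot beat the incumbent; no budget spent
                d = dtw_distance(q, s, _safe_window(q.size, s.size, w))
                n_seen += 1
                if d < best_dist or (d == best_dist and idx < best_idx):
                    best_dist, best_idx = d, idx
        else:
            for child in node.children:
                c = child.centroid
                d = dtw_distance(q, c, _safe_window(q.size, c.size, w))
                heapq.heappush(heap, (d, next(counter), child))
    if best_idx < 0:
        raise ValidationError("search terminated without comparing any series")
    return tree.labels[best_idx], float(best_dist), n_seen


def nn_bruteforce(series: list, labels, query, window: int | None = None):
    """Exhaustive 1-NN over a training set (tie-break: lowest index).

    Reference implementation used to validate the budgeted index search.
    """
    q = _as_series(query)
    best_dist, best_idx = np.inf, -1
    for i, s in enumerate(series):
        d = dtw_distance(q, s, _safe_window(q.size, _as_series(s).size, window))
        if d < best_dist:
            best_dist, best_idx = d, i
    return labels[best_idx], float(best_dist)


# ---------------------------------------------------------------------------
# Serialization (JSON hybrid: structure + flattened series)
# ---------------------------------------------------------------------------

def save_tsi(tree: TSITree, path: str | Path) -> None:
    def encode(node: TSINode) -> dict:
        return {
            "centroid": node.centroid.tolist(),
            "indices": node.indices,
            "children": [encode(c) for c in node.children],
        }

    payload = {
        "window": tree.window,
        "config": {
            "branching": tree.config.branching,
            "leaf_max": tree.config.leaf_max,
            "window_fraction": tree.config.window_fraction,
            "budget": tree.config.budget,
            "seed": tree.config.seed,
        },
        "labels": np.asarray(tree.labels).tolist(),
        "series": [s.tolist() for s in tree.series],
        "root": encode(tree.root),
    }
    Path(path).write_text(json.dumps(payload))


def load_tsi(path: str | Path) -> TSITree:
    payload = json.loads(Path(path).read_text())

    def decode(d: dict) -> TSINode:
        return TSINode(
            centroid=np.asarray(d["centroid"], dtype=np.float64),
            indices=list(d["indices"]),
            children=[decode(c) for c in d["children"]],
        )

    cfg = TSIConfig(**payload["config"])
    return TSITree(
        root=decode(payload["root"]),
        series=[np.asarray(s, dtype=np.float64) for s in payload["series"]],
        labels=np.asarray(payload["labels"]),
        window=int(payload["window"]),
        config=cfg,
    )
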