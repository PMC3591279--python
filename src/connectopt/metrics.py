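"""Comparison suite for reference and reconstructed spatial networks.

Covers hub identification by degree z-score, wiring locality, geographical
centrality, neighborhood density and its correlation with degree, balanced
link-recovery rates, degree-preserving null models, partition matching with a
shuffled-label null, spatial clustering of layouts, and the path-length impact
of removing the largest hub.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import (
    Digraph,
    Partition,
    PositionTable,
    SpatialNetwork,
    shortest_path_lengths,
)

__all__ = [
    "HubReport", "hub_zscores", "LocalityReport", "locality",
    "geographical_centrality", "DensityProfile", "neighborhood_density",
    "CorrelationReport", "degree_density_correlation", "shuffle_significance",
    "RecoveryReport", "recovery_rate", "degree_preserving_random",
    "MatchReport", "match_partitions", "shuffled_match_null",
    "spatial_clusters", "HubRemovalReport", "hub_removal_impact",
]


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------

@dataclass
class HubReport:
    """Per-node degrees and z-scores plus the hub set they imply."""

    frame: pd.DataFrame           # node, in_degree, out_degree, degree, z, is_hub
    mode: str
    z_threshold: float
    n_hub: int
    k_hub: float                  # mean (selected-variant) degree of the hubs

    @property
    def hub_indices(self) -> np.ndarray:
        return self.frame.index[self.frame["is_hub"]].to_numpy()


def hub_zscores(graph: Digraph, mode: str = "total",
                z_threshold: float = 2.0) -> HubReport:
    """Flag hubs as nodes whose degree z-score exceeds the threshold.

    z_i = (k_i - <k>) / sigma over the chosen degree variant (total = in+out
    by default; 'in' and 'out' variants are also used for real networks).  A
    degree-regular graph has sigma = 0 and therefore no hubs.
    """
    if graph.n < 2:
        raise ValueError("need at least 2 nodes")
    if mode not in ("total", "in", "out"):
        raise ValueError(f"unknown degree mode {mode!r}")
    kin, kout = graph.in_degree, graph.out_degree
    k = {"total": kin + kout, "in": kin, "out": kout}[mode]
    mean, sigma = float(k.mean()), float(k.std())
    z = np.zeros(graph.n) if sigma == 0 else (k - mean) / sigma
    is_hub = z > z_threshold
    frame = pd.DataFrame({
        "in_degree": kin, "out_degree": kout, "degree": k,
        "z": z, "is_hub": is_hub,
    })
    n_hub = int(is_hub.sum())
    k_hub = float(k[is_hub].mean()) if n_hub else float("nan")
    return HubReport(frame=frame, mode=mode, z_threshold=z_threshold,
                     n_hub=n_hub, k_hub=k_hub)


# ---------------------------------------------------------------------------
# Wiring locality
# ---------------------------------------------------------------------------

@dataclass
class LocalityReport:
    """Per-node and network-level locality of wiring.

    F_i = W_i_min / W_i, where W_i is the wiring actually spent on node i's
    links and W_i_min the minimum possible had its k_in inputs and k_out
    outputs attached to its nearest spatial neighbors (inputs and outputs
    minimized independently).  F = mean of F_i over connected nodes.
    """

    frame: pd.DataFrame           # W_i, W_i_min, F_i (NaN for isolated nodes)
    F: float


def locality(net: SpatialNetwork) -> LocalityReport:
    adj = net.graph.adjacency
    dist = net.dist
    n = net.n
    W_i = np.empty(n)
    W_min = np.empty(n)
    F_i = np.full(n, np.nan)
    for i in range(n):
        tgts = np.flatnonzero(adj[i])
        srcs = np.flatnonzero(adj[:, i])
        k_out, k_in = len(tgts), len(srcs)
        W_i[i] = dist[i, tgts].sum() + dist[srcs, i].sum()
        others = np.sort(np.delete(dist[i], i))
        W_min[i] = others[:k_in].sum() + others[:k_out].sum()
        if k_in + k_out == 0:
            continue
        F_i[i] = 1.0 if W_i[i] == 0 else W_min[i] / W_i[i]
    frame = pd.DataFrame({"W_i": W_i, "W_i_min": W_min, "F_i": F_i})
    return LocalityReport(frame=frame, F=float(np.nanmean(F_i)))


# ---------------------------------------------------------------------------
# Geographical centrality
# ---------------------------------------------------------------------------

def geographical_centrality(net: SpatialNetwork,
                            subset: np.ndarray | list | None = None
                            ) -> pd.DataFrame:
    """Rank nodes by total Euclidean distance to all (other) nodes in scope.

    Rank 1 = smallest total distance = most central.  With *subset* the sum
    runs only over subset members (regional centrality).  Ties share the
    lowest applicable rank and are flagged.
    """
    from scipy.stats import rankdata

    if subset is None:
        scope = np.arange(net.n)
    else:
        scope = np.asarray(subset, dtype=int)
        if len(scope) < 2:
            raise ValueError("subset must contain at least 2 nodes")
    D = net.dist[np.ix_(scope, scope)].sum(axis=1)
    # quantize to 9 significant digits so symmetric layouts tie exactly
    scale = D.max() if D.max() > 0 else 1.0
    Dq = np.round(D / scale, 9)
    rank = rankdata(Dq, method="min").astype(int)
    tied = pd.Series(rank).duplicated(keep=False).to_numpy()
    return pd.DataFrame({"node": scope, "D": D, "rank": rank, "tied": tied}
                        ).sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Neighborhood density
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Node counts and densities within spheres/discs of normalized radii.

    rho_i(r) = n_i(r) / V(r) with n_i(r) the number of *other* nodes within
    Euclidean distance r of node i, and V(r) the disc area (2-D) or sphere
    volume (3-D).  Radii are given normalized by d_max.
    """

    r_grid: np.ndarray            # normalized radii r / d_max
    radii: np.ndarray             # absolute radii
    counts: np.ndarray            # (n, len(r_grid)) ints
    rho: np.ndarray               # (n, len(r_grid))

    def frame(self) -> pd.DataFrame:
        n, m = self.counts.shape
        return pd.DataFrame({
            "node": np.repeat(np.arange(n), m),
            "r_norm": np.tile(self.r_grid, n),
            "count": self.counts.ravel(),
            "rho": self.rho.ravel(),
        })


def neighborhood_density(net: SpatialNetwork, r_grid) -> DensityProfile:
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(r_grid > 1):
        raise ValueError("normalized radii must lie in (0, 1]")
    d = net.positions.dim
    if d not in (2, 3):
        raise ValueError(f"density defined for 2-D or 3-D layouts, got d={d}")
    radii = r_grid * net.d_max
    within = net.dist[:, :, None] <= radii[None, None, :]
    counts = within.sum(axis=1) - 1            # exclude the node itself
    vol = np.pi * radii ** 2 if d == 2 else (4.0 / 3.0) * np.pi * radii ** 3
    rho = counts / vol[None, :]
    return DensityProfile(r_grid=r_grid, radii=radii,
                          counts=counts.astype(int), rho=rho)


# ---------------------------------------------------------------------------
# Degree-density correlation with shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Pearson correlation of degree vs neighborhood density, per radius,
    with a 2-sigma significance band from order-shuffled surrogates."""

    frame: pd.DataFrame           # r_norm, corr, band (2 sigma), significant
    mode: str
    surrogate_reps: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def shuffle_significance(x, y, reps: int = 100, seed: int = 0
                         ) -> tuple[float, float]:
    """Pearson correlation of x and y plus its 2-sigma shuffle band.

    The order of x is randomly reshuffled *reps* times; the band is twice the
    standard deviation of the surrogate correlations.  |corr| > band marks
    roughly 95% significance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    c = _pearson(x, y)
    sur = np.array([_pearson(rng.permutation(x), y) for _ in range(reps)])
    return c, 2.0 * float(np.nanstd(sur))


def degree_density_correlation(net: SpatialNetwork, r_grid,
                               mode: str = "total", surrogate_reps: int = 100,
                               seed: int = 0) -> CorrelationReport:
    """Correlate node degrees with neighborhood density across radii.

    Significance: the order of the degree vector is reshuffled
    *surrogate_reps* times; a correlation outside 2 standard deviations of
    the surrogate distribution is significant at roughly the 95% level.
    Zero-variance inputs yield NaN correlations, flagged not significant.
    """
    if surrogate_reps < 2:
        raise ValueError("surrogate_reps must be >= 2")
    rng = np.random.default_rng(seed)
    kin, kout = net.graph.in_degree, net.graph.out_degree
    k = {"total": kin + kout, "in": kin, "out": kout}[mode].astype(float)
    prof = neighborhood_density(net, r_grid)
    rows = []
    for ci, r in enumerate(prof.r_grid):
        rho = prof.rho[:, ci]
        c, band = shuffle_significance(
            k, rho, reps=surrogate_reps,
            seed=int(rng.integers(2 ** 31)))
        sig = bool(np.isfinite(c) and abs(c) > band)
        rows.append({"r_norm": r, "corr": c, "band": band, "significant": sig})
    return CorrelationReport(frame=pd.DataFrame(rows), mode=mode,
                             surrogate_reps=surrogate_reps)


# ---------------------------------------------------------------------------
# Recovery rate
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Balanced agreement between two adjacency matrices.

    R1 = N11/N1 and R0 = N00/N0 are the agreement rates on the reference's
    1-entries and 0-entries (off-diagonal, optionally restricted);
    R = (R1 + R0)/2 corrects for link sparsity.  A restriction selecting no
    1-entries (or no 0-entries) leaves that component and R undefined (NaN,
    flagged).
    """

    N1: int
    N0: int
    N11: int
    N00: int
    R1: float
    R0: float
    R: float
    flagged: bool = False


def recovery_rate(reference: Digraph, candidate: Digraph,
                  subset: tuple | None = None,
                  distance_bin: tuple | None = None,
                  spatial: SpatialNetwork | None = None) -> RecoveryReport:
    """Balanced recovery rate of *candidate* against *reference*.

    ``subset=(rows, cols)`` restricts to entries from one node set to
    another; ``distance_bin=(lo, hi)`` (requires *spatial*) restricts to
    pairs with lo <= distance < hi.
    """
    if reference.n != candidate.n:
        raise ValueError("networks must share a node set")
    n = reference.n
    mask = ~np.eye(n, dtype=bool)
    if subset is not None:
        rows, cols = (np.asarray(s, dtype=int) for s in subset)
        sel = np.zeros((n, n), dtype=bool)
        sel[np.ix_(rows, cols)] = True
        mask &= sel
    if distance_bin is not None:
        if spatial is None:
            raise ValueError("distance_bin restriction needs a SpatialNetwork")
        lo, hi = distance_bin
        mask &= (spatial.dist >= lo) & (spatial.dist < hi)
    ref = reference.adjacency
    cand = candidate.adjacency
    N1 = int((ref & mask).sum())
    N0 = int((~ref & mask).sum())
    N11 = int((ref & cand & mask).sum())
    N00 = int((~ref & ~cand & mask).sum())
    R1 = N11 / N1 if N1 else float("nan")
    R0 = N00 / N0 if N0 else float("nan")
    flagged = N1 == 0 or N0 == 0
    R = (R1 + R0) / 2 if not flagged else float("nan")
    return RecoveryReport(N1=N1, N0=N0, N11=N11, N00=N00,
                          R1=R1, R0=R0, R=R, flagged=flagged)


# ---------------------------------------------------------------------------
# Degree-preserving null model
# ---------------------------------------------------------------------------

def degree_preserving_random(reference: Digraph, reps: int = 1,
                             rng: np.random.Generator | int = 0,
                             swaps_per_link: int = 10) -> list[Digraph]:
    """Randomize links while keeping every in- and out-degree exactly.

    Directed double-edge swaps (i->j, k->l) => (i->l, k->j); proposals
    creating self-loops or duplicate links are rejected.  Each benchmark
    accumulates ``swaps_per_link * K`` accepted swaps (attempt-capped, so
    swap-rigid graphs such as a directed 3-cycle return unchanged copies).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    K = reference.K
    for _ in range(reps):
        adj = reference.adjacency.copy()
        edges = np.argwhere(adj)
        target = swaps_per_link * K
        attempts_cap = 100 * max(target, 1)
        accepted = attempts = 0
        while accepted < target and attempts < attempts_cap:
            attempts += 1
            e1, e2 = rng.integers(K), rng.integers(K)
            if e1 == e2:
                continue
            i, j = edges[e1]
            k, l = edges[e2]
            if i == l or k == j:
                continue
            if adj[i, l] or adj[k, j]:
                continue
            adj[i, j] = adj[k, l] = False
            adj[i, l] = adj[k, j] = True
            edges[e1] = (i, l)
            edges[e2] = (k, j)
            accepted += 1
        out.append(Digraph(adj))
    return out


# ---------------------------------------------------------------------------
# Partition matching
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    """Max-overlap assignment of partition B's groups onto partition A.

    Each B-group maps to the A-group covering most of its nodes (several
    B-groups may share one A-group); nodes of a B-group outside its assigned
    A-group are mismatched.
    """

    mapping: dict                 # B group -> A group
    ties: list                    # B groups whose best A group was tied
    matched: np.ndarray           # node indices
    mismatched: np.ndarray
    mismatch_rate: float


def match_partitions(A: Partition, B: Partition) -> MatchReport:
    if A.n != B.n:
        raise ValueError("partitions must cover the same node set")
    n = A.n
    # overlap[a-1, b-1] = |A_a intersect B_b|
    overlap = np.zeros((A.k, B.k), dtype=int)
    np.add.at(overlap, (A.labels - 1, B.labels - 1), 1)
    mapping = {}
    ties = []
    matched_mask = np.zeros(n, dtype=bool)
    for b in range(1, B.k + 1):
        col = overlap[:, b - 1]
        a_best = int(np.argmax(col)) + 1   # argmax -> lowest index on ties
        if (col == col[a_best - 1]).sum() > 1:
            ties.append(b)
        mapping[b] = a_best
        matched_mask |= (B.labels == b) & (A.labels == a_best)
    matched = np.flatnonzero(matched_mask)
    mismatched = np.flatnonzero(~matched_mask)
    return MatchReport(mapping=mapping, ties=ties, matched=matched,
                       mismatched=mismatched,
                       mismatch_rate=len(mismatched) / n)


def shuffled_match_null(A: Partition, B: Partition, reps: int = 1000,
                        seed: int = 0) -> float:
    """Mean mismatch rate of B against A after random label shuffling.

    Group sizes of B are preserved while node labels are fully permuted,
    giving the chance level of partition agreement.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(reps):
        perm = rng.permutation(B.n)
        total += match_partitions(A, Partition(B.labels[perm])).mismatch_rate
    return total / reps


# ---------------------------------------------------------------------------
# Spatial clustering
# ---------------------------------------------------------------------------

_LINKAGE_METHODS = ("centroid", "ward", "single", "complete", "average",
                    "weighted", "median")
CLUSTER_METHODS = _LINKAGE_METHODS + ("kmeans",)


def spatial_clusters(positions: PositionTable, k: int, method: str = "ward",
                     seed: int = 0) -> Partition:
    """Cluster the layout into exactly k spatial groups.

    Hierarchical variants agglomerate on Euclidean geometry ('ward' is the
    inner-squared-distance criterion, 'median' the weighted
    center-of-mass criterion) and cut the tree at k clusters; 'kmeans'
    minimizes within-cluster sums of point-to-centroid distances.
    """
    if not 1 <= k <= positions.n:
        raise ValueError(f"k must be in [1, {positions.n}], got {k}")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(positions.coords) + 1
        return Partition.from_labels(labels)
    if method not in _LINKAGE_METHODS:
        raise ValueError(f"unknown clustering method {method!r}; "
                         f"choose from {CLUSTER_METHODS}")
    Z = linkage(positions.coords, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Partition.from_labels(labels)


def robust_mismatch_union(positions: PositionTable, modules: Partition,
                          k: int | None = None, seed: int = 0) -> np.ndarray:
    """Mismatched-node union across all 8 clustering methods vs the modules.

    Returns the indices mismatched under at least one clustering method —
    the largest possible mismatched group once clustering uncertainty is
    taken into account.
    """
    k = modules.k if k is None else k
    union: set[int] = set()
    for method in CLUSTER_METHODS:
        clusters = spatial_clusters(positions, k, method, seed=seed)
        rep = match_partitions(clusters, modules)
        union.update(rep.mismatched.tolist())
    return np.array(sorted(union), dtype=int)


# ---------------------------------------------------------------------------
# Hub-removal robustness
# ---------------------------------------------------------------------------

@dataclass
class HubRemovalReport:
    """Path-length impact of deleting the largest-total-degree node.

    ratio = (mean shortest path after) / (mean shortest path before), using
    per-pair means because the pair counts differ; infinite (flagged, with
    the unreachable-pair count) when the removal disconnects the graph.
    """

    removed: int
    tie: bool
    ratio: float
    unreachable_pairs: int


def hub_removal_impact(graph: Digraph) -> HubRemovalReport:
    if graph.n < 3:
        raise ValueError("need at least 3 nodes")
    sp = shortest_path_lengths(graph.adjacency)
    if np.isinf(sp).any():
        raise ValueError("graph must be strongly connected")
    n = graph.n
    before = sp.sum() / (n * (n - 1))
    k = graph.total_degree
    v = int(np.argmax(k))                      # lowest index on ties
    tie = bool((k == k[v]).sum() > 1)
    keep = np.delete(np.arange(n), v)
    sub = graph.adjacency[np.ix_(keep, keep)]
    sp_after = shortest_path_lengths(sub)
    bad = int(np.isinf(sp_after).sum())
    if bad:
        return HubRemovalReport(removed=v, tie=tie, ratio=float("inf"),
                                unreachable_pairs=bad)
    m = n - 1
    after = sp_after.sum() / (m * (m - 1))
    return HubRemovalReport(removed=v, tie=tie, ratio=float(after / before),
                            unreachable_pairs=0)
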