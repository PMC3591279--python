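"""Synthetic spatial layouts and reference networks.

The generators emulate the three layout geometries the analysis is designed
around: a uniform 1-D ring; a two-cluster 3-D layout with heterogeneous local
density (cortical-parcellation-like); and a 2-D layout with a tiny dense
"head" holding most nodes, a sparse quasi-1-D "cord" and a small "tail"
cluster (nematode-like).  Reference networks plant the structure the metric
battery is validated against: distance-decaying connection probability,
spatially clustered modules and centrally placed hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Digraph, Partition, PositionTable, SpatialNetwork, \
    is_strongly_connected

__all__ = [
    "LayoutSpec", "ReferenceNetSpec", "GroundTruth",
    "ring_layout", "two_cluster_layout", "head_cord_tail_layout",
    "make_layout", "reference_network", "generate_reference",
    "macaque_like", "elegans_like",
]


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def ring_layout(n: int) -> PositionTable:
    """n nodes equally spaced on a unit circle in 2-D (chord distances)."""
    if n < 3:
        raise ValueError("ring needs at least 3 nodes")
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([np.cos(theta), np.sin(theta)])
    ids = tuple(f"n{i}" for i in range(n))
    return PositionTable(ids, coords)


def two_cluster_layout(n: int, frac_a: float = 0.5, separation: float = 10.0,
                       spreads: tuple = (2.0, 2.0), seed: int = 0
                       ) -> tuple[PositionTable, Partition]:
    """Two 3-D Gaussian clouds with heterogeneous within-cluster density.

    Per-node log-normal jitter scales make local density uneven, mimicking
    parcellations with unequal area sizes.  Returns the layout plus the
    planted two-group labels.
    """
    if not 0 < frac_a < 1:
        raise ValueError("frac_a must be in (0, 1)")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    n_a = round(n * frac_a)
    centers = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    labels = np.array([1] * n_a + [2] * (n - n_a))
    scale = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    coords = np.empty((n, 3))
    for g, spread in zip((1, 2), spreads):
        idx = np.flatnonzero(labels == g)
        coords[idx] = centers[g - 1] + rng.normal(size=(len(idx), 3)) \
            * spread * scale[idx, None]
    ids = tuple(f"n{i}" for i in range(n))
    return PositionTable(ids, coords), Partition(labels)


def head_cord_tail_layout(n: int, fractions: tuple = (0.6, 0.3, 0.1),
                          head_scale: float = 1.0, cord_length: float = 30.0,
                          seed: int = 0) -> tuple[PositionTable, Partition]:
    """2-D layout: dense head cluster, sparse linear cord, compact tail.

    Most nodes sit in a head cluster of diameter *head_scale* (much smaller
    than *cord_length*); cord nodes spread quasi-uniformly along a line; a
    small tail cluster sits at the far end.  Returns the layout plus planted
    head/cord/tail labels (1/2/3).
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != 3 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("three fractions summing to 1 required")
    rng = np.random.default_rng(seed)
    n_head = round(n * fractions[0])
    n_tail = max(round(n * fractions[2]), 1)
    n_cord = n - n_head - n_tail
    head = rng.normal(size=(n_head, 2)) * (head_scale / 4.0)
    # cord occupies the middle stretch of the axis, leaving clear gaps to
    # the head and tail clusters
    x0, x1 = 5.0 * head_scale, 0.65 * cord_length
    x = np.linspace(x0, x1, n_cord)
    x += rng.normal(scale=((x1 - x0) / n_cord) * 0.3, size=n_cord)
    cord = np.column_stack([x, rng.normal(scale=head_scale / 4.0, size=n_cord)])
    tail = np.array([cord_length, 0.0]) \
        + rng.normal(size=(n_tail, 2)) * (head_scale / 3.0)
    coords = np.vstack([head, cord, tail])
    labels = np.array([1] * n_head + [2] * n_cord + [3] * n_tail)
    ids = tuple(f"n{i}" for i in range(n))
    return PositionTable(ids, coords), Partition(labels)


@dataclass(frozen=True)
class LayoutSpec:
    """Declarative layout description: kind, size, geometry parameters, seed."""

    kind: str                     # ring1d | two_cluster_3d | head_cord_tail_2d
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_layout(spec: LayoutSpec) -> tuple[PositionTable, Partition | None]:
    if spec.kind == "ring1d":
        return ring_layout(spec.n), None
    if spec.kind == "two_cluster_3d":
        return two_cluster_layout(spec.n, seed=spec.seed, **spec.params)
    if spec.kind == "head_cord_tail_2d":
        return head_cord_tail_layout(spec.n, seed=spec.seed, **spec.params)
    raise ValueError(f"unknown layout kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Reference networks with planted structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceNetSpec:
    """Distance-decay reference network on a synthetic layout.

    Connection probability decays as exp(-d/lam); optional planted hubs are
    the nodes ranked *hub_ranks* by geographical centrality (within
    *hub_group* of the planted labels, or globally when None), whose incident
    link weights are multiplied by *hub_boost*.
    """

    layout: LayoutSpec
    K: int
    lam: float
    hub_ranks: tuple = ()
    hub_boost: float = 1.0
    hub_group: int | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    """What was planted: spatial group labels, hub nodes, repair count."""

    labels: Partition | None
    hubs: list
    repairs: int


def _hub_nodes(positions: PositionTable, labels: Partition | None,
               ranks, group: int | None) -> list[int]:
    from .metrics import geographical_centrality

    net = SpatialNetwork(Digraph(np.zeros((positions.n, positions.n), bool)),
                         positions)
    if group is not None:
        if labels is None:
            raise ValueError("hub_group given but layout has no planted labels")
        subset = np.flatnonzero(labels.labels == group)
        ranking = geographical_centrality(net, subset)
    else:
        ranking = geographical_centrality(net)
    return [int(ranking.iloc[r - 1]["node"]) for r in ranks]


def reference_network(positions: PositionTable, K: int, lam: float,
                      planted_hubs=(), hub_boost: float = 1.0,
                      seed: int = 0) -> tuple[SpatialNetwork, int]:
    """Sample K directed links with p ~ exp(-d/lam), repaired to strong
    connectivity.

    Sampling without replacement uses Gumbel-perturbed log-weights.  If the
    draw is not strongly connected, shortest absent links from condensation
    sinks to sources are added, then the lowest-weight surplus links whose
    removal preserves strong connectivity are dropped, keeping K exact.
    Returns the network and the number of repair substitutions.
    """
    from scipy.sparse.csgraph import connected_components

    n = positions.n
    if K < n or K > n * (n - 1):
        raise ValueError(f"K={K} infeasible for strong connectivity on n={n}")
    rng = np.random.default_rng(seed)
    net0 = SpatialNetwork(Digraph(np.zeros((n, n), bool)), positions)
    d = net0.dist
    with np.errstate(divide="ignore"):
        logw = -d / lam if np.isfinite(lam) else np.zeros_like(d)
    for h in planted_hubs:
        logw[h, :] += np.log(hub_boost)
        logw[:, h] += np.log(hub_boost)
    off = ~np.eye(n, dtype=bool)
    keys = np.full((n, n), -np.inf)
    g = rng.gumbel(size=(n, n))
    keys[off] = logw[off] + g[off]
    flat = np.argsort(keys, axis=None)[::-1][:K]
    adj = np.zeros((n, n), dtype=bool)
    adj[np.unravel_index(flat, (n, n))] = True

    repairs = 0
    guard = 0
    while not is_strongly_connected(adj):
        guard += 1
        if guard > 10 * n:
            raise RuntimeError("connectivity repair did not converge")
        ncomp, comp = connected_components(adj, directed=True,
                                           connection="strong")
        cond_out = np.zeros(ncomp, dtype=bool)
        cond_in = np.zeros(ncomp, dtype=bool)
        ii, jj = np.nonzero(adj)
        cross = comp[ii] != comp[jj]
        cond_out[comp[ii[cross]]] = True
        cond_in[comp[jj[cross]]] = True
        sinks = np.flatnonzero(~cond_out)
        sources = np.flatnonzero(~cond_in)
        # shortest absent link from any sink component to any source component
        cand_mask = off & ~adj \
            & np.isin(comp, sinks)[:, None] & np.isin(comp, sources)[None, :] \
            & (comp[:, None] != comp[None, :])
        if not cand_mask.any():
            cand_mask = off & ~adj & (comp[:, None] != comp[None, :])
        dd = np.where(cand_mask, d, np.inf)
        i, j = np.unravel_index(np.argmin(dd), dd.shape)
        adj[i, j] = True
        repairs += 1
    # drop surplus links, least-probable first, keeping strong connectivity
    surplus = int(adj.sum()) - K
    if surplus > 0:
        ii, jj = np.nonzero(adj)
        order = np.argsort(logw[ii, jj])
        for e in order:
            if surplus == 0:
                break
            i, j = ii[e], jj[e]
            if not adj[i, j]:
                continue
            adj[i, j] = False
            if is_strongly_connected(adj):
                surplus -= 1
            else:
                adj[i, j] = True
    if int(adj.sum()) != K:
        raise RuntimeError("could not restore exact K after repair")
    return net0.with_graph(Digraph(adj)), repairs


def generate_reference(spec: ReferenceNetSpec
                       ) -> tuple[SpatialNetwork, GroundTruth]:
    """Materialize a ReferenceNetSpec: layout, planted hubs, network."""
    positions, labels = make_layout(spec.layout)
    hubs = _hub_nodes(positions, labels, spec.hub_ranks, spec.hub_group) \
        if spec.hub_ranks else []
    net, repairs = reference_network(positions, spec.K, spec.lam,
                                     planted_hubs=hubs,
                                     hub_boost=spec.hub_boost,
                                     seed=spec.seed)
    return net, GroundTruth(labels=labels, hubs=hubs, repairs=repairs)


# ---------------------------------------------------------------------------
# Presets at the two printed scales
# ---------------------------------------------------------------------------

def macaque_like(seed: int = 0, **overrides) -> ReferenceNetSpec:
    """Two-cluster 3-D layout at the cortical-parcellation scale:
    103 nodes, 2518 directed links (connection density 0.237)."""
    kw = dict(layout=LayoutSpec("two_cluster_3d", n=103,
                                params={"frac_a": 0.55, "separation": 10.0,
                                        "spreads": (2.0, 2.0)}, seed=seed),
              K=2518, lam=2.0, seed=seed)
    kw.update(overrides)
    return ReferenceNetSpec(**kw)


def elegans_like(seed: int = 0, **overrides) -> ReferenceNetSpec:
    """Head/cord/tail 2-D layout at the nematode scale: 276 nodes with 166
    in the head, 2902 directed links."""
    kw = dict(layout=LayoutSpec("head_cord_tail_2d", n=276,
                                params={"fractions": (166 / 276, 0.3,
                                                      1 - 166 / 276 - 0.3),
                                        "head_scale": 1.0,
                                        "cord_length": 30.0}, seed=seed),
              K=2902, lam=2.0, seed=seed)
    kw.update(overrides)
    return ReferenceNetSpec(**kw)
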