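"""Network reconstruction under competing wiring-cost and efficiency constraints.

Given fixed node positions and a fixed number K of directed binary links, the
reconstruction seeks the connectivity minimizing

    E(alpha) = alpha * W / W0  +  (1 - alpha) * L / L0,

where W is the total Euclidean wiring length of the links, L is the sum of
directed shortest-path step counts over all ordered node pairs, and W0, L0 are
single-constraint benchmarks (the minimal W found at alpha=1 and the minimal L
found at alpha=0) that put both terms on a common scale.  alpha=1 optimizes
wiring cost only; alpha=0 optimizes path efficiency only.

The search is simulated annealing over link relocations: one existing link is
deleted and one absent ordered pair is added, conserving K.  Moves that break
strong connectivity are rejected outright (L must stay finite); remaining
moves are accepted by the Metropolis rule.

The public surface follows the model/results convention: build a
:class:`NetworkReconstruction` from a layout, call :meth:`fit`, inspect the
returned :class:`ReconstructionResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Digraph,
    PositionTable,
    SpatialNetwork,
    distance_matrix,
    is_strongly_connected,
    shortest_path_lengths,
)

__all__ = [
    "AnnealSchedule", "Benchmarks", "NetworkReconstruction",
    "ReconstructionResult", "SweepSummary", "wiring_length",
    "graph_distance_sum", "objective", "random_connected_digraph",
    "propose_move", "derive_seed",
]


# ---------------------------------------------------------------------------
# Objective ingredients
# ---------------------------------------------------------------------------

def wiring_length(net: SpatialNetwork) -> float:
    """Total wiring length W: sum of Euclidean link lengths.

    Reciprocal links i->j and j->i are distinct and each contributes its own
    length.
    """
    return float(net.dist[net.graph.adjacency].sum())


def graph_distance_sum(graph: Digraph) -> float:
    """Total graph distance L: directed shortest-path steps over all ordered
    pairs.  Raises if the graph is not strongly connected (L would be
    infinite)."""
    dist = shortest_path_lengths(graph.adjacency)
    total = dist.sum()
    if not np.isfinite(total):
        raise ValueError("graph is not strongly connected: L is infinite "
                         f"({int(np.isinf(dist).sum())} unreachable ordered pairs)")
    return float(total)


@dataclass(frozen=True)
class Benchmarks:
    """Single-constraint normalization constants.

    W0 : minimal total wiring length, from a wiring-only (alpha=1) run.
    L0 : minimal total graph distance, from an efficiency-only (alpha=0) run.
    """

    W0: float
    L0: float

    def __post_init__(self):
        if not self.W0 > 0:
            raise ValueError(f"W0 must be positive, got {self.W0}")
        if not self.L0 > 0:
            raise ValueError(f"L0 must be positive, got {self.L0}")


def objective(W: float, L: float, benchmarks: Benchmarks, alpha: float) -> float:
    """E = alpha*(W/W0) + (1-alpha)*(L/L0)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * (W / benchmarks.W0) + (1.0 - alpha) * (L / benchmarks.L0)


# ---------------------------------------------------------------------------
# Random initial networks and elementary moves
# ---------------------------------------------------------------------------

def _random_k_pairs(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """K distinct ordered non-diagonal index pairs, uniform without replacement."""
    flat = rng.choice(n * (n - 1), size=K, replace=False)
    i = flat // (n - 1)
    j = flat % (n - 1)
    j = j + (j >= i)          # skip the diagonal
    return np.column_stack([i, j])


def random_connected_digraph(n: int, K: int, rng: np.random.Generator,
                             max_uniform_tries: int = 100) -> Digraph:
    """Uniform-intent random digraph with exactly K links, strongly connected.

    Draws K ordered pairs uniformly and resamples until strongly connected.
    Near the feasibility floor K ~ n a uniform draw essentially never
    succeeds, so after *max_uniform_tries* failures the draw is repaired by
    seeding a random Hamiltonian cycle and filling the remaining links
    uniformly.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if K < n or K > n * (n - 1):
        raise ValueError(f"K={K} infeasible for strong connectivity on n={n}: "
                         f"need n <= K <= n(n-1)")
    for _ in range(max_uniform_tries):
        pairs = _random_k_pairs(n, K, rng)
        adj = np.zeros((n, n), dtype=bool)
        adj[pairs[:, 0], pairs[:, 1]] = True
        if is_strongly_connected(adj):
            return Digraph(adj)
    # repair path: random directed cycle through all nodes + uniform filler
    order = rng.permutation(n)
    adj = np.zeros((n, n), dtype=bool)
    adj[order, np.roll(order, -1)] = True
    absent = np.argwhere(~adj & ~np.eye(n, dtype=bool))
    extra = rng.choice(len(absent), size=K - n, replace=False)
    adj[absent[extra, 0], absent[extra, 1]] = True
    return Digraph(adj)


def propose_move(graph: Digraph, rng: np.random.Generator,
                 max_retries: int | None = None):
    """One connectivity-preserving link relocation, or None on failure.

    Deletes a uniformly chosen existing link and adds a uniformly chosen
    absent ordered non-self pair; proposals that break strong connectivity
    are resampled up to 10*n times (spec'd retry budget).  Returns
    ``(delete, add)`` index pairs, or ``None`` when the budget is exhausted
    or no absent pair exists.
    """
    n = graph.n
    if graph.K == 0 or graph.K == n * (n - 1):
        return None
    budget = 10 * n if max_retries is None else max_retries
    adj = graph.adjacency.copy()
    edges = graph.edges()
    for _ in range(budget):
        e = rng.integers(len(edges))
        i, j = int(edges[e, 0]), int(edges[e, 1])
        while True:
            k = int(rng.integers(n))
            l = int(rng.integers(n))
            if k != l and not adj[k, l]:
                break
        adj[i, j] = False
        adj[k, l] = True
        if is_strongly_connected(adj):
            return (i, j), (k, l)
        adj[i, j] = True
        adj[k, l] = False
    return None


# ---------------------------------------------------------------------------
# Annealing schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing controls.

    T0 : initial temperature in units of E.  ``None`` (default) calibrates it
        on 200 probe moves so the initial acceptance ratio of worsening moves
        is about 0.8, which makes behaviour invariant to the layout's length
        scale.
    cool : multiplicative cooling factor per temperature stage (0 < cool < 1).
    steps_per_T : rewiring attempts per temperature stage.
    T_stop : termination temperature; ``None`` means ``t_stop_ratio * T0``.
    """

    T0: float | None = None
    cool: float = 0.9
    steps_per_T: int = 1000
    T_stop: float | None = None
    t_stop_ratio: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.cool < 1.0:
            raise ValueError("cool must be in (0, 1)")
        if self.steps_per_T < 1:
            raise ValueError("steps_per_T must be >= 1")
        if self.T0 is not None and self.T_stop is not None:
            if not self.T0 > self.T_stop > 0:
                raise ValueError("need T0 > T_stop > 0")


def summary_stats(vals) -> tuple[float, float]:
    """(mean, sd) over realizations, ignoring NaN; sd is NaN below 2 values."""
    vals = np.asarray(vals, dtype=float)
    ok = vals[~np.isnan(vals)]
    mean = float(ok.mean()) if len(ok) else float("nan")
    sd = float(ok.std(ddof=1)) if len(ok) > 1 else float("nan")
    return mean, sd


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic per-task seed below 2**31 from a master seed and indices."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# The annealing engine
# ---------------------------------------------------------------------------

class _State:
    """Mutable SA state: adjacency, edge array, current W and L."""

    __slots__ = ("adj", "edges", "W", "L", "dist")

    def __init__(self, adj: np.ndarray, dist: np.ndarray, need_L: bool):
        self.adj = adj
        self.dist = dist
        self.edges = np.argwhere(adj)
        self.W = float(dist[adj].sum())
        self.L = _finite_L(adj) if need_L else math.nan


def _L_if_connected(adj: np.ndarray) -> float:
    """Total graph distance L, or inf when not strongly connected.

    Level-synchronous BFS from all sources at once; only the per-level pair
    counts are accumulated, not the full distance matrix.
    """
    n = adj.shape[0]
    a = adj.astype(np.float32)
    reach = np.eye(n, dtype=bool)
    frontier = reach
    L = 0.0
    reached = n
    d = 0
    while True:
        new = (frontier.astype(np.float32) @ a > 0) & ~reach
        c = int(new.sum())
        if c == 0:
            break
        d += 1
        L += d * c
        reach |= new
        reached += c
        frontier = new
    if reached < n * n:
        return math.inf
    return L


def _finite_L(adj: np.ndarray) -> float:
    s = _L_if_connected(adj)
    if not np.isfinite(s):
        raise ValueError("state not strongly connected")
    return float(s)


def _try_move(state: _State, rng: np.random.Generator, need_L: bool,
              budget: int) -> tuple | None:
    """Sample a connectivity-preserving move; leaves state *applied*.

    Returns (edge_index, old_pair, new_pair, W_new, L_new) or None if the
    retry budget is exhausted (state unchanged).
    """
    adj = state.adj
    n = adj.shape[0]
    n_edges = len(state.edges)
    if n_edges == 0 or n_edges == n * (n - 1):
        return None             # nothing to relocate / nowhere to relocate to
    for _ in range(budget):
        e = int(rng.integers(n_edges))
        i, j = int(state.edges[e, 0]), int(state.edges[e, 1])
        while True:
            k = int(rng.integers(n))
            l = int(rng.integers(n))
            if k != l and not adj[k, l]:
                break
        adj[i, j] = False
        adj[k, l] = True
        if need_L:
            L_new = _L_if_connected(adj)
            if not np.isfinite(L_new):
                adj[i, j] = True
                adj[k, l] = False
                continue
        else:
            if not is_strongly_connected(adj):
                adj[i, j] = True
                adj[k, l] = False
                continue
            L_new = math.nan
        W_new = state.W - state.dist[i, j] + state.dist[k, l]
        return e, (i, j), (k, l), float(W_new), float(L_new)
    return None


def _revert(state: _State, e: int, old: tuple, new: tuple) -> None:
    state.adj[new[0], new[1]] = False
    state.adj[old[0], old[1]] = True


def _apply_bookkeeping(state: _State, e: int, new: tuple,
                       W_new: float, L_new: float) -> None:
    state.edges[e] = new
    state.W = W_new
    state.L = L_new


def _calibrate_T0(state: _State, rng: np.random.Generator, eval_E, need_L: bool,
                  n_probe: int = 200, target_accept: float = 0.8) -> float:
    """T0 such that exp(-mean positive dE / T0) = target_accept."""
    E_cur = eval_E(state.W, state.L)
    worsen = []
    budget = 10 * state.adj.shape[0]
    for _ in range(n_probe):
        mv = _try_move(state, rng, need_L, budget)
        if mv is None:
            continue
        e, old, new, W_new, L_new = mv
        dE = eval_E(W_new, L_new) - E_cur
        _revert(state, e, old, new)
        if dE > 0:
            worsen.append(dE)
    if not worsen:
        return 1e-3
    return float(np.mean(worsen) / (-math.log(target_accept)))


def _anneal(dist: np.ndarray, K: int, alpha: float, schedule: AnnealSchedule,
            benchmarks: Benchmarks | None, seed: int,
            initial: np.ndarray | None = None):
    """Core SA loop on raw arrays.  Returns a dict of outcome fields."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    if initial is None:
        adj = random_connected_digraph(n, K, rng).adjacency.copy()
    else:
        adj = initial.copy()
    # alpha=1 never consults L, so the per-move all-pairs search is skipped
    # and only strong connectivity is verified.
    need_L = alpha < 1.0
    if benchmarks is None:
        if alpha == 0.0:
            def eval_E(W, L):
                return L
        elif alpha == 1.0:
            def eval_E(W, L):
                return W
        else:
            raise ValueError("benchmarks are required for 0 < alpha < 1")
    elif alpha == 1.0:
        def eval_E(W, L):                  # L is not tracked at alpha=1
            return W / benchmarks.W0
    elif alpha == 0.0:
        def eval_E(W, L):
            return L / benchmarks.L0
    else:
        def eval_E(W, L):
            return alpha * (W / benchmarks.W0) + (1 - alpha) * (L / benchmarks.L0)

    state = _State(adj, dist, need_L)
    T0 = schedule.T0
    if T0 is None:
        T0 = _calibrate_T0(state, rng, eval_E, need_L)
    T_stop = schedule.T_stop if schedule.T_stop is not None \
        else schedule.t_stop_ratio * T0

    E_cur = eval_E(state.W, state.L)
    best = {"E": E_cur, "W": state.W, "L": state.L, "adj": state.adj.copy()}
    trace = []
    budget = 10 * n
    n_noop = 0
    T = T0
    while T >= T_stop:
        n_acc = 0
        for _ in range(schedule.steps_per_T):
            mv = _try_move(state, rng, need_L, budget)
            if mv is None:
                n_noop += 1
                continue
            e, old, new, W_new, L_new = mv
            E_new = eval_E(W_new, L_new)
            dE = E_new - E_cur
            if dE <= 0 or rng.random() < math.exp(-dE / T):
                _apply_bookkeeping(state, e, new, W_new, L_new)
                E_cur = E_new
                n_acc += 1
                if E_new < best["E"]:
                    best = {"E": E_new, "W": W_new, "L": L_new,
                            "adj": state.adj.copy()}
            else:
                _revert(state, e, old, new)
        trace.append((T, E_cur, state.W, state.L,
                      n_acc / schedule.steps_per_T))
        T *= schedule.cool
    if not need_L:
        best["L"] = _finite_L(best["adj"])
        best["E"] = eval_E(best["W"], best["L"])
    return {"best": best, "trace": trace, "T0": T0, "T_stop": T_stop,
            "n_noop": n_noop, "seed": seed}


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class NetworkReconstruction:
    """Reconstruction model: fixed layout, fixed link budget, weight alpha.

    Parameters
    ----------
    positions : PositionTable
        Fixed node coordinates.
    K : int
        Number of directed links to place (conserved by the optimizer).
    alpha : float
        Weight of the wiring-cost term; alpha=0 is efficiency-only, alpha=1
        wiring-only.
    schedule : AnnealSchedule, optional
    benchmarks : Benchmarks, optional
        Normalization constants; computed on demand (and cached) when absent.

    Examples
    --------
    >>> from connectopt.synth import ring_layout
    >>> model = NetworkReconstruction(ring_layout(20), K=40, alpha=0.0)
    >>> res = model.fit(seed=1)          # efficiency-only reconstruction
    >>> res.network.graph.K, res.L == 2 * 20 * 19 - 40
    (40, True)
    """

    def __init__(self, positions: PositionTable, K: int, alpha: float = 0.5,
                 schedule: AnnealSchedule | None = None,
                 benchmarks: Benchmarks | None = None):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.positions = positions
        self.K = int(K)
        self.alpha = float(alpha)
        self.schedule = schedule if schedule is not None else AnnealSchedule()
        self.benchmarks_ = benchmarks
        self.dist = distance_matrix(positions.coords)

    @classmethod
    def from_files(cls, positions_path, K: int, alpha: float = 0.5,
                   dim: int | None = None, **kwargs) -> "NetworkReconstruction":
        from .core import load_positions
        return cls(load_positions(positions_path, dim), K, alpha, **kwargs)

    # -- benchmarks --------------------------------------------------------

    def compute_benchmarks(self, seeds: Sequence[int] = (0, 1, 2),
                           schedule: AnnealSchedule | None = None) -> Benchmarks:
        """Best W over wiring-only runs and best L over efficiency-only runs.

        Several seeds are run for each single-constraint problem and the best
        value is kept; the result is cached on the model.
        """
        sched = schedule if schedule is not None else self.schedule
        W0 = min(_anneal(self.dist, self.K, 1.0, sched, None, s)["best"]["W"]
                 for s in seeds)
        L0 = min(_anneal(self.dist, self.K, 0.0, sched, None, s)["best"]["L"]
                 for s in seeds)
        self.benchmarks_ = Benchmarks(W0=W0, L0=L0)
        return self.benchmarks_

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0, initial: Digraph | None = None
            ) -> "ReconstructionResult":
        """Run one simulated-annealing realization; deterministic given seed."""
        if self.benchmarks_ is None and 0.0 < self.alpha < 1.0:
            self.compute_benchmarks()
        out = _anneal(self.dist, self.K, self.alpha, self.schedule,
                      self.benchmarks_, int(seed),
                      initial.adjacency if initial is not None else None)
        best = out["best"]
        net = SpatialNetwork(Digraph(best["adj"]), self.positions)
        if self.benchmarks_ is not None:
            E = objective(best["W"], best["L"], self.benchmarks_, self.alpha)
        else:
            E = best["E"]
        trace = pd.DataFrame(out["trace"],
                             columns=["T", "E", "W", "L", "accept_rate"])
        return ReconstructionResult(
            model=self, network=net, alpha=self.alpha, E=float(E),
            W=float(best["W"]), L=float(best["L"]), seed=out["seed"],
            trace=trace, T0=out["T0"], T_stop=out["T_stop"],
            n_noop=out["n_noop"], benchmarks=self.benchmarks_)

    # -- sweeping ----------------------------------------------------------

    def sweep(self, alpha_grid: Sequence[float], realizations: int = 50,
              master_seed: int = 0, keep_results: bool = True
              ) -> "SweepSummary":
        """Independent realizations at each alpha; one benchmark pair shared.

        Per-realization seeds derive deterministically from
        ``(master_seed, alpha_index, realization_index)``.
        """
        if self.benchmarks_ is None:
            self.compute_benchmarks()
        from .metrics import hub_zscores, locality

        rows = []
        archive: list[list[ReconstructionResult]] = []
        for ai, a in enumerate(alpha_grid):
            sub = replace_alpha(self, a)
            reals = []
            stats = {"W": [], "L": [], "N_hub": [], "K_hub": [], "F_local": []}
            for ri in range(realizations):
                res = sub.fit(seed=derive_seed(master_seed, ai, ri))
                reals.append(res)
                hub = hub_zscores(res.network.graph)
                loc = locality(res.network)
                stats["W"].append(res.W)
                stats["L"].append(res.L)
                stats["N_hub"].append(hub.n_hub)
                stats["K_hub"].append(hub.k_hub)
                stats["F_local"].append(loc.F)
            for stat, vals in stats.items():
                mean, sd = summary_stats(vals)
                rows.append({
                    "alpha": a, "statistic": stat, "mean": mean, "sd": sd,
                    "n_realizations": realizations,
                })
            archive.append(reals if keep_results else [])
        return SweepSummary(table=pd.DataFrame(rows),
                            alpha_grid=list(alpha_grid),
                            results=archive, master_seed=master_seed)


def replace_alpha(model: NetworkReconstruction, alpha: float
                  ) -> NetworkReconstruction:
    """Clone the model at a different alpha, sharing layout and benchmarks."""
    m = NetworkReconstruction(model.positions, model.K, alpha,
                              schedule=model.schedule,
                              benchmarks=model.benchmarks_)
    m.dist = model.dist
    return m


@dataclass
class ReconstructionResult:
    """Outcome of one annealing realization (best-seen configuration)."""

    model: NetworkReconstruction
    network: SpatialNetwork
    alpha: float
    E: float
    W: float
    L: float
    seed: int
    trace: pd.DataFrame
    T0: float
    T_stop: float
    n_noop: int
    benchmarks: Benchmarks | None

    def summary(self) -> str:
        n = self.network.n
        lines = [
            "Network reconstruction (simulated annealing)",
            "=" * 46,
            f"nodes                 {n}",
            f"directed links K      {self.network.graph.K}",
            f"alpha                 {self.alpha:.4g}",
            f"objective E           {self.E:.6g}",
            f"wiring length W       {self.W:.6g}",
            f"graph distance L      {self.L:.6g}",
        ]
        if self.benchmarks is not None:
            lines += [
                f"W / W0                {self.W / self.benchmarks.W0:.4f}",
                f"L / L0                {self.L / self.benchmarks.L0:.4f}",
            ]
        lines += [
            f"T0 / T_stop           {self.T0:.3g} / {self.T_stop:.3g}",
            f"stages                {len(self.trace)}",
            f"seed                  {self.seed}",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Objective vs temperature stage (log-x temperature axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["T"], self.trace["E"], marker=".")
        ax.set_xscale("log")
        ax.invert_xaxis()
        ax.set_xlabel("temperature T")
        ax.set_ylabel("objective E")
        ax.set_title(f"alpha = {self.alpha:.3g}, seed = {self.seed}")
        return ax


@dataclass
class SweepSummary:
    """Ensemble statistics of reconstructions over an alpha grid.

    ``table`` is tidy: one row per (alpha, statistic) with mean, sd and the
    realization count; sd is NaN when only one realization was run.
    """

    table: pd.DataFrame
    alpha_grid: list
    results: list
    master_seed: int

    def stat(self, name: str) -> pd.DataFrame:
        return (self.table[self.table["statistic"] == name]
                .set_index("alpha")[["mean", "sd"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, statistics=("W", "L", "N_hub", "K_hub", "F_local"), axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(len(statistics), 1, sharex=True,
                                   figsize=(5, 2 * len(statistics)))
        for ax, stat in zip(np.atleast_1d(axes), statistics):
            d = self.stat(stat)
            ax.errorbar(d.index, d["mean"], yerr=d["sd"], marker="o")
            ax.set_ylabel(stat)
        np.atleast_1d(axes)[-1].set_xlabel("alpha")
        return axes
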