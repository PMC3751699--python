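"""Stochastic graph-level realization of the kinetic model.

An exact next-event (Gillespie) simulation of an evolving undirected
protein-interaction graph under the model's microscopic rules:

* birth of a class-X node at rate f0, wired to Poisson(xi0) distinct
  uniform partners (xi0 < 1 leaves most newborns isolated; isolated nodes
  count toward N but are excluded from degree histograms),
* inactivation of a uniform class-X node at rate ki per X node, removing
  the node with all its links (partner-side link loss is emergent),
* class transitions X->Y at kXY per X node and Y->X at kYX per Y node,
* duplication of a uniform node at rate k2 per node; the copy is class X
  and inherits every parent link (no parent-copy link, no self-loops),
* pair-link creation: each node carries weight w_i = mu (N-1-xi_i) +
  delta_eps * xi_i; link events fire at rate sum_i w_i / 2 and draw BOTH
  endpoints proportionally to their weights (partner restricted to
  non-partners), so each node's expected gain rate is w_i to first order
  and the per-node preferential-attachment structure of the mean-field
  degree equation is preserved. A uniform-partner variant is available via
  ``partner_mode="uniform"``.
* spontaneous loss of a uniform link at rate r per link.

Ensemble means of N(t), Y(t) follow the mean-field proteome ODEs exactly
(the counts are a linear birth-death process); L(t), the age-degree
relation and the pooled degree distribution match the mean-field theory to
first order while xi << N, which the test suite checks against the closed
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import KineticParameters
from .fitting import DegreeHistogram, build_degree_histogram

__all__ = [
    "NetworkState",
    "EventLog",
    "evolve_network",
    "replay",
    "degree_snapshot",
    "observables_trace",
    "ensemble_trace",
    "age_degree_profile",
    "pooled_degrees",
]


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

class NetworkState:
    """Evolving interactome: labelled nodes, simple undirected adjacency.

    Invariants: no self-loops, no multi-edges, classes in {"X", "Y"}.
    """

    __slots__ = ("node_class", "birth", "adj", "t", "next_id", "extinct")

    def __init__(self) -> None:
        self.node_class: dict[int, str] = {}
        self.birth: dict[int, float] = {}
        self.adj: dict[int, set[int]] = {}
        self.t: float = 0.0
        self.next_id: int = 0
        self.extinct: bool = False

    @classmethod
    def empty(cls, t: float = 0.0) -> "NetworkState":
        state = cls()
        state.t = t
        return state

    def copy(self) -> "NetworkState":
        new = NetworkState()
        new.node_class = dict(self.node_class)
        new.birth = dict(self.birth)
        new.adj = {u: set(nbrs) for u, nbrs in self.adj.items()}
        new.t = self.t
        new.next_id = self.next_id
        new.extinct = self.extinct
        return new

    @property
    def n_nodes(self) -> int:
        return len(self.node_class)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj.values()) // 2

    def degrees(self) -> dict[int, int]:
        return {u: len(nbrs) for u, nbrs in self.adj.items()}

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u, nbrs in self.adj.items() for v in nbrs if u < v)

    def add_node(self, node: int, klass: str, t: float) -> None:
        self.node_class[node] = klass
        self.birth[node] = t
        self.adj[node] = set()
        self.next_id = max(self.next_id, node + 1)

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        self.adj[u].add(v)
        self.adj[v].add(u)

    def remove_node(self, node: int) -> None:
        for nbr in self.adj.pop(node):
            self.adj[nbr].discard(node)
        del self.node_class[node]
        del self.birth[node]

    def to_networkx(self):
        import networkx as nx
        graph = nx.Graph()
        for u, klass in self.node_class.items():
            graph.add_node(u, klass=klass, birth=self.birth[u])
        graph.add_edges_from(self.edge_list())
        return graph


@dataclass
class EventLog:
    """Timestamped event records; replaying them regenerates the state."""

    t0: float
    t_end: float
    seed: int | None
    events: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


def replay(initial: NetworkState, log: EventLog) -> NetworkState:
    """Reconstruct the final state by applying the event log to a copy."""
    state = initial.copy()
    for event in log.events:
        kind, t = event[0], event[1]
        if kind == "birth":
            _, _, node, partners = event
            state.add_node(node, "X", t)
            for p in partners:
                state.add_edge(node, p)
        elif kind == "inact":
            state.remove_node(event[2])
        elif kind == "dup":
            _, _, parent, copy_id = event
            state.add_node(copy_id, "X", t)
            for nbr in list(state.adj[parent]):
                state.add_edge(copy_id, nbr)
        elif kind == "xy":
            state.node_class[event[2]] = "Y"
        elif kind == "yx":
            state.node_class[event[2]] = "X"
        elif kind == "gain":
            state.add_edge(event[2], event[3])
        elif kind == "loss":
            state.adj[event[2]].discard(event[3])
            state.adj[event[3]].discard(event[2])
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {kind!r}")
    state.t = log.t_end
    return state


# ---------------------------------------------------------------------------
# O(1) uniform sampling with add/remove
# ---------------------------------------------------------------------------

class _IndexedSet:
    __slots__ = ("items", "pos")

    def __init__(self, items: Iterable = ()) -> None:
        self.items: list = list(items)
        self.pos: dict = {x: i for i, x in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, x) -> bool:
        return x in self.pos

    def add(self, x) -> None:
        self.pos[x] = len(self.items)
        self.items.append(x)

    def remove(self, x) -> None:
        i = self.pos.pop(x)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def random(self, rng: np.random.Generator):
        return self.items[rng.integers(len(self.items))]


# ---------------------------------------------------------------------------
# the Gillespie loop
# ---------------------------------------------------------------------------

def evolve_network(kp: KineticParameters, t_end: float,
                   initial: NetworkState | None = None,
                   seed: int | None = None,
                   partner_mode: str = "weighted",
                   keep_log: bool = True) -> tuple[NetworkState, EventLog]:
    """Exact-time stochastic evolution of the interactome until ``t_end``.

    Rates are recomputed after every event (all channel totals are O(1)
    closed forms in N, L and the class counts). Reproducible for a given
    seed. Returns the final state and the event log; with
    ``keep_log=False`` the log is returned empty (bulk ensembles).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if partner_mode not in ("weighted", "uniform"):
        raise ValueError("partner_mode must be 'weighted' or 'uniform'")
    state = initial.copy() if initial is not None else NetworkState.empty()
    rng = np.random.default_rng(seed)
    log = EventLog(t0=state.t, t_end=state.t + t_end, seed=seed)

    nodes = _IndexedSet(state.node_class)
    xset = _IndexedSet(u for u, k in state.node_class.items() if k == "X")
    yset = _IndexedSet(u for u, k in state.node_class.items() if k == "Y")
    edges = _IndexedSet((u, v) for u, nbrs in state.adj.items()
                        for v in nbrs if u < v)
    adj = state.adj
    mu, de = kp.mu, kp.delta_eps

    def record(event: tuple) -> None:
        if keep_log:
            log.events.append(event)

    def pick_weighted_endpoint(n_nodes: int, n_edges: int, pairs: float):
        """One node drawn with probability ~ mu (N-1-xi) + delta_eps xi."""
        w_mu = mu * pairs
        w_de = de * 2.0 * n_edges
        if rng.random() * (w_mu + w_de) < w_mu:
            # weight N-1-xi: uniform node thinned by its open-slot fraction
            while True:
                u = nodes.random(rng)
                if rng.random() * (n_nodes - 1) < (n_nodes - 1 - len(adj[u])):
                    return u
        # weight xi: uniform edge, uniform endpoint
        e = edges.random(rng)
        return e[rng.integers(2)]

    def exact_weighted_partner(i: int):
        """Fallback: exact weighted draw among eligible partners (O(N))."""
        n_nodes = len(nodes)
        cand, weights = [], []
        for u in nodes.items:
            if u == i or u in adj[i]:
                continue
            w = mu * (n_nodes - 1 - len(adj[u])) + de * len(adj[u])
            if w > 0:
                cand.append(u)
                weights.append(w)
        if not cand:
            return None
        weights = np.asarray(weights)
        return cand[rng.choice(len(cand), p=weights / weights.sum())]

    t_stop = state.t + t_end
    while True:
        n_nodes = len(nodes)
        n_edges = len(edges)
        n_x, n_y = len(xset), len(yset)
        pairs = n_nodes * (n_nodes - 1) - 2 * n_edges  # open ordered slots

        r_birth = kp.f0
        r_inact = kp.ki * n_x
        r_dup = kp.k2 * n_nodes
        r_xy = kp.kXY * n_x
        r_yx = kp.kYX * n_y
        r_gain = 0.5 * (mu * pairs + de * 2.0 * n_edges) if n_nodes >= 2 else 0.0
        r_loss = kp.r * n_edges
        total = r_birth + r_inact + r_dup + r_xy + r_yx + r_gain + r_loss

        if total <= 0:
            state.extinct = n_nodes == 0
            break
        dt = rng.exponential(1.0 / total)
        if state.t + dt > t_stop:
            break
        state.t += dt
        u = rng.random() * total

        if u < r_birth:
            m = int(rng.poisson(kp.xi0))
            partners: list[int] = []
            if n_nodes > 0 and m > 0:
                if m >= n_nodes:
                    partners = list(nodes.items)
                else:
                    chosen: set[int] = set()
                    while len(chosen) < m:
                        chosen.add(nodes.random(rng))
                    partners = list(chosen)
            node = state.next_id
            state.add_node(node, "X", state.t)
            nodes.add(node)
            xset.add(node)
            for p in partners:
                state.add_edge(node, p)
                edges.add((min(node, p), max(node, p)))
            record(("birth", state.t, node, tuple(partners)))
            continue
        u -= r_birth

        if u < r_inact:
            node = xset.random(rng)
            for nbr in adj[node]:
                edges.remove((min(node, nbr), max(node, nbr)))
            state.remove_node(node)
            nodes.remove(node)
            xset.remove(node)
            record(("inact", state.t, node))
            continue
        u -= r_inact

        if u < r_dup:
            parent = nodes.random(rng)
            copy_id = state.next_id
            state.add_node(copy_id, "X", state.t)
            nodes.add(copy_id)
            xset.add(copy_id)
            for nbr in list(adj[parent]):
                state.add_edge(copy_id, nbr)
                edges.add((min(copy_id, nbr), max(copy_id, nbr)))
            record(("dup", state.t, parent, copy_id))
            continue
        u -= r_dup

        if u < r_xy:
            node = xset.random(rng)
            xset.remove(node)
            yset.add(node)
            state.node_class[node] = "Y"
            record(("xy", state.t, node))
            continue
        u -= r_xy

        if u < r_yx:
            node = yset.random(rng)
            yset.remove(node)
            xset.add(node)
            state.node_class[node] = "X"
            record(("yx", state.t, node))
            continue
        u -= r_yx

        if u < r_gain:
            # initiator ~ w_i, partner ~ w_j restricted to non-partners of i
            # (rejection with a weighted O(N) fallback); redrawing the
            # partner keeps the aggregate link-creation rate at exactly
            # sum_i w_i / 2, the model's own bookkeeping for dL/dt
            i = pick_weighted_endpoint(n_nodes, n_edges, pairs)
            j = None
            if len(adj[i]) < n_nodes - 1:
                if partner_mode == "uniform":
                    while True:
                        j = nodes.random(rng)
                        if j != i and j not in adj[i]:
                            break
                else:
                    for _ in range(50):
                        cand = pick_weighted_endpoint(n_nodes, n_edges, pairs)
                        if cand != i and cand not in adj[i]:
                            j = cand
                            break
                    else:
                        j = exact_weighted_partner(i)
            if j is None:
                continue  # saturated initiator: null event
            state.add_edge(i, j)
            edges.add((min(i, j), max(i, j)))
            record(("gain", state.t, min(i, j), max(i, j)))
            continue
        u -= r_gain

        # spontaneous link loss
        a, b = edges.random(rng)
        edges.remove((a, b))
        adj[a].discard(b)
        adj[b].discard(a)
        record(("loss", state.t, a, b))

    state.t = t_stop
    return state, log


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def degree_snapshot(state: NetworkState, tail_bin_count: int = 0,
                    tail_threshold: int = 20) -> DegreeHistogram:
    """Integer degree histogram of the current graph.

    Degree-0 nodes are excluded: interaction databases only report
    interacting proteins.
    """
    degrees = [d for d in state.degrees().values() if d > 0]
    if not degrees:
        raise ValueError("network has no interacting proteins")
    return build_degree_histogram(degrees, tail_bin_count=tail_bin_count,
                                  tail_threshold=tail_threshold)


def observables_trace(initial: NetworkState, log: EventLog, grid) -> pd.DataFrame:
    """Piecewise-constant N(t), Y(t), L(t) sampled on a time grid."""
    grid = np.asarray(grid, dtype=float)
    state = initial.copy()
    n = state.n_nodes
    y = sum(1 for k in state.node_class.values() if k == "Y")
    l = state.n_edges
    times = [log.t0]
    counts = [(n, y, l)]
    for event in log.events:
        kind, t = event[0], event[1]
        if kind == "birth":
            _, _, node, partners = event
            state.add_node(node, "X", t)
            for p in partners:
                state.add_edge(node, p)
            n += 1
            l += len(partners)
        elif kind == "inact":
            node = event[2]
            l -= len(state.adj[node])
            state.remove_node(node)
            n -= 1
        elif kind == "dup":
            _, _, parent, copy_id = event
            deg = len(state.adj[parent])
            state.add_node(copy_id, "X", t)
            for nbr in list(state.adj[parent]):
                state.add_edge(copy_id, nbr)
            n += 1
            l += deg
        elif kind == "xy":
            state.node_class[event[2]] = "Y"
            y += 1
        elif kind == "yx":
            state.node_class[event[2]] = "X"
            y -= 1
        elif kind == "gain":
            state.add_edge(event[2], event[3])
            l += 1
        elif kind == "loss":
            state.adj[event[2]].discard(event[3])
            state.adj[event[3]].discard(event[2])
            l -= 1
        times.append(t)
        counts.append((n, y, l))
    times = np.asarray(times)
    counts = np.asarray(counts, dtype=float)
    idx = np.clip(np.searchsorted(times, grid, side="right") - 1, 0, len(times) - 1)
    return pd.DataFrame({"t": grid, "N": counts[idx, 0],
                         "Y": counts[idx, 1], "L": counts[idx, 2]})


def ensemble_trace(kp: KineticParameters, t_end: float, grid,
                   n_replicates: int, seed: int | None = None,
                   initial: NetworkState | None = None,
                   partner_mode: str = "weighted",
                   return_states: bool = False):
    """Replicate the simulation and average N, Y, L on a common grid.

    Returns a frame with per-time mean and Monte-Carlo standard error of
    the mean for each observable (and the final states if requested).
    """
    grid = np.asarray(grid, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    traces = np.empty((n_replicates, len(grid), 3))
    states = []
    base = initial if initial is not None else NetworkState.empty()
    for i, s in enumerate(seeds):
        final, log = evolve_network(kp, t_end, initial=base, seed=int(s),
                                    partner_mode=partner_mode)
        tr = observables_trace(base, log, grid)
        traces[i] = tr[["N", "Y", "L"]].to_numpy()
        if return_states:
            states.append(final)
    mean = traces.mean(axis=0)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    out = pd.DataFrame({
        "t": grid,
        "N_mean": mean[:, 0], "N_sem": sem[:, 0],
        "Y_mean": mean[:, 1], "Y_sem": sem[:, 1],
        "L_mean": mean[:, 2], "L_sem": sem[:, 2],
    })
    return (out, states) if return_states else out


def age_degree_profile(states: Sequence[NetworkState],
                       age_edges) -> pd.DataFrame:
    """Mean node degree versus node age across replicate snapshots.

    Ages are measured backwards from each snapshot's clock; all nodes
    (including isolated ones) contribute, matching the mean-field degree
    trajectory which tracks every protein from birth. The reported
    standard error is across replicate means (nodes within one replicate
    share an environment and are not independent).
    """
    age_edges = np.asarray(age_edges, dtype=float)
    n_bins = len(age_edges) - 1
    rep_means = np.full((len(states), n_bins), np.nan)
    age_sum = np.zeros(n_bins)
    n_total = np.zeros(n_bins, dtype=int)
    for k, state in enumerate(states):
        ages = np.array([state.t - born for born in state.birth.values()])
        degs = np.array([len(state.adj[u]) for u in state.birth], dtype=float)
        idx = np.digitize(ages, age_edges) - 1
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                rep_means[k, b] = degs[mask].mean()
                age_sum[b] += ages[mask].sum()
                n_total[b] += int(mask.sum())
    rows = []
    for b in range(n_bins):
        vals = rep_means[:, b]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append({"age_lo": age_edges[b], "age_hi": age_edges[b + 1],
                     "age_mean": age_sum[b] / n_total[b],
                     "degree_mean": float(vals.mean()),
                     "degree_sem": float(sem),
                     "n": int(n_total[b]), "n_replicates": int(vals.size)})
    return pd.DataFrame(rows)


def pooled_degrees(states: Sequence[NetworkState]) -> np.ndarray:
    """Positive degrees pooled over snapshots (histogram raw material)."""
    out = [d for state in states for d in state.degrees().values() if d > 0]
    return np.asarray(out, dtype=int)
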