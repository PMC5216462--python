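"""Transition path theory: committors, reactive fluxes, ranked pathways.

Given a reversible MSM with stationary distribution pi and TPM T, and disjoint
source (bound) and target (released) state sets, the forward committor q_i is
the probability of visiting the target before the source when starting from
state i.  The gross reactive flux is

    f_ij = pi_i (1 - q_i) T_ij q_j   (i != j),

the net flux f+_ij = max(0, f_ij - f_ji), and the total reactive flux is the
net flow across the source cut.  Pathways are extracted iteratively: the
widest (maximum-bottleneck) source->target path is found with a Dijkstra
variant, its bottleneck flux is subtracted from every edge on it (zeroing the
bottleneck edge), and the procedure repeats — ranking pathways by the flux
they carry.

Macrostates are formed by sign-structure Perron cluster analysis: microstates
sharing the sign pattern of the dominant (non-Perron) right eigenvectors have
similar kinetics and are lumped together.  This is the deterministic
sign-based variant of PCCA, not the simplex-optimization PCCA+ refinement.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluxDecomposition",
    "MacrostateMap",
    "committor",
    "flux_matrix",
    "top_paths",
    "compute_flux",
    "pcca_lump",
    "macro_flux_report",
    "DEFAULT_N_MACROSTATES",
    "DEFAULT_N_PATHS",
]

DEFAULT_N_MACROSTATES = 15
DEFAULT_N_PATHS = 7


def committor(T: np.ndarray, source: set[int], target: set[int]) -> np.ndarray:
    """Forward committor: q=0 on source, q=1 on target, harmonic in between.

    Solves (I - T_II) q_I = T_IB 1_target on the interior states.  Interior
    states with no path to either boundary make the system singular and are
    reported by name in the raised error.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    source = set(int(s) for s in source)
    target = set(int(s) for s in target)
    if not source or not target:
        raise ValueError("source and target must be non-empty")
    if source & target:
        raise ValueError("source and target must be disjoint")
    if any(s < 0 or s >= n for s in source | target):
        raise ValueError("source/target state index out of range")
    q = np.zeros(n)
    for t in target:
        q[t] = 1.0
    interior = np.array(sorted(set(range(n)) - source - target), dtype=int)
    if interior.size == 0:
        return q
    # states that cannot reach the boundary leave the system singular
    reach = _reachable_from(T, source | target)
    stranded = [int(i) for i in interior if i not in reach]
    if stranded:
        raise ValueError(f"states with no path to source or target: {stranded}")
    A = np.eye(interior.size) - T[np.ix_(interior, interior)]
    b = T[np.ix_(interior, sorted(target))].sum(axis=1)
    q[interior] = np.linalg.solve(A, b)
    # clip tiny round-off excursions outside [0, 1]
    return np.clip(q, 0.0, 1.0)


def _reachable_from(T: np.ndarray, boundary: set[int]) -> set[int]:
    """States from which the boundary is reachable along positive-probability edges."""
    n = T.shape[0]
    rev = [[] for _ in range(n)]
    src, dst = np.nonzero(T > 0)
    for i, j in zip(src, dst):
        rev[j].append(i)
    seen = set(boundary)
    stack = list(boundary)
    while stack:
        j = stack.pop()
        for i in rev[j]:
            if i not in seen:
                seen.add(i)
                stack.append(i)
    return seen


@dataclass
class FluxDecomposition:
    """Committor, gross/net reactive fluxes and ranked pathways."""

    source: list[int]
    target: list[int]
    committor: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    paths: list[tuple[list[int], float, float]] = field(default_factory=list)
    # each path: (state sequence, flux carried, cumulative fraction of total)

    def path_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": r + 1,
                    "path": "->".join(map(str, p)),
                    "flux": f,
                    "percent": 100.0 * f / self.total_flux if self.total_flux > 0 else np.nan,
                    "cumulative_percent": 100.0 * c,
                }
                for r, (p, f, c) in enumerate(self.paths)
            ]
        )


def flux_matrix(
    pi: np.ndarray, q: np.ndarray, T: np.ndarray, source: set[int], target: set[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """(gross f, net f+, total flux) from stationary dist, committor and TPM."""
    pi = np.asarray(pi, dtype=float)
    q = np.asarray(q, dtype=float)
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    f = pi[:, None] * (1.0 - q)[:, None] * T * q[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.maximum(0.0, f - f.T)
    src = np.array(sorted(int(s) for s in source), dtype=int)
    not_src = np.array([i for i in range(n) if i not in set(src.tolist())], dtype=int)
    total = float(net[np.ix_(src, not_src)].sum()) if not_src.size else 0.0
    return f, net, total


def compute_flux(
    T: np.ndarray, pi: np.ndarray, source: set[int], target: set[int],
    n_paths: int = DEFAULT_N_PATHS,
) -> FluxDecomposition:
    """Full TPT decomposition: committor, fluxes and the top ``n_paths`` paths."""
    q = committor(T, source, target)
    f, net, total = flux_matrix(pi, q, T, source, target)
    paths = top_paths(net, source, target, n_paths, total_flux=total)
    return FluxDecomposition(
        source=sorted(int(s) for s in source),
        target=sorted(int(s) for s in target),
        committor=q,
        gross_flux=f,
        net_flux=net,
        total_flux=total,
        paths=paths,
    )


def _widest_width(F: np.ndarray, source: set[int], target: set[int]) -> float | None:
    """Maximum bottleneck width of any source->target path (Dijkstra variant)."""
    n = F.shape[0]
    width = np.full(n, -np.inf)
    heap = []
    for s in source:
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, s))
    visited = np.zeros(n, dtype=bool)
    while heap:
        _, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in target:
            return float(width[u])
        for v in np.nonzero(F[u] > 0)[0]:
            if not visited[v]:
                w = min(width[u], F[u, v])
                if w > width[v]:
                    width[v] = w
                    heapq.heappush(heap, (-w, int(v)))
    return None


def _widest_path(
    F: np.ndarray, source: set[int], target: set[int]
) -> tuple[list[int], float] | None:
    """Canonical maximum-bottleneck path: widest, then shortest, then
    lexicographically smallest.

    The bottleneck width is found by a Dijkstra variant; any path inside the
    subgraph of edges at least that wide is a widest path, so the canonical
    representative is the lexicographically smallest BFS-shortest path there.
    Ties in width are common once path fluxes have been subtracted, and the
    canonical choice makes the decomposition deterministic.
    """
    w_star = _widest_width(F, source, target)
    if w_star is None or w_star <= 0:
        return None
    n = F.shape[0]
    allowed = F >= w_star
    # BFS distances to the nearest target within the allowed subgraph
    dist = np.full(n, np.inf)
    frontier = sorted(target)
    for t in frontier:
        dist[t] = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.nonzero(allowed[:, u])[0]:
                if dist[v] == np.inf:
                    dist[v] = dist[u] + 1
                    nxt.append(int(v))
        frontier = sorted(nxt)
    starts = [s for s in sorted(source) if np.isfinite(dist[s])]
    if not starts:
        return None
    u = min(starts, key=lambda s: (dist[s], s))
    path = [u]
    while u not in target:
        nexts = [int(v) for v in np.nonzero(allowed[u])[0] if dist[v] == dist[u] - 1]
        u = min(nexts)
        path.append(u)
    return path, w_star


def top_paths(
    net_flux: np.ndarray,
    source: set[int],
    target: set[int],
    n_paths: int,
    total_flux: float | None = None,
    remove_edges: bool = False,
) -> list[tuple[list[int], float, float]]:
    """Iterative bottleneck decomposition of the net flux into ranked paths.

    Each round finds the path whose minimum edge flux is maximal, records
    (path, bottleneck flux, cumulative fraction), and subtracts that flux from
    every edge on the path — zeroing the bottleneck edge.  With
    ``remove_edges=True`` all edges of the extracted path are deleted instead.
    Stops at ``n_paths`` or when the flux is exhausted (shorter list, logged).
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    F = np.array(net_flux, dtype=float, copy=True)
    source = set(int(s) for s in source)
    target = set(int(s) for s in target)
    if total_flux is None:
        total_flux = float(
            sum(F[s, j] for s in source for j in range(F.shape[0]) if j not in source)
        )
    out: list[tuple[list[int], float, float]] = []
    cum = 0.0
    for _ in range(n_paths):
        found = _widest_path(F, source, target)
        if found is None or found[1] <= 0:
            logger.info("flux exhausted after %d paths", len(out))
            break
        path, bottleneck = found
        if remove_edges:
            for a, b in zip(path[:-1], path[1:]):
                F[a, b] = 0.0
        else:
            for a, b in zip(path[:-1], path[1:]):
                F[a, b] -= bottleneck
        cum += bottleneck / total_flux if total_flux > 0 else 0.0
        out.append((path, bottleneck, cum))
    return out


# --------------------------------------------------------------------------
# Macrostates
# --------------------------------------------------------------------------


@dataclass
class MacrostateMap:
    """Per-microstate macrostate labels (0..n_macro-1, all non-empty)."""

    labels: np.ndarray
    n_macro: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_macro)):
            raise ValueError("macrostate labels must cover 0..n_macro-1 with none empty")

    def members(self, m: int) -> np.ndarray:
        return np.where(self.labels == m)[0]


def pcca_lump(
    right_eigenvectors: np.ndarray,
    n_macro: int = DEFAULT_N_MACROSTATES,
    pi: np.ndarray | None = None,
    tol: float = 1e-10,
) -> MacrostateMap:
    """Sign-structure Perron cluster lumping of microstates.

    Microstates are keyed by the sign vector of right eigenvectors 2..m, with
    m the smallest count giving at least ``n_macro`` distinct patterns (or all
    available).  Surplus patterns are merged into exactly ``n_macro`` groups
    by agglomerating the smallest-population pattern into its nearest
    (Hamming-distance) neighbour.  If fewer distinct patterns exist than
    requested, n_macro is reduced with a log message.
    """
    V = np.asarray(right_eigenvectors, dtype=float)
    k = V.shape[0]
    if n_macro < 1:
        raise ValueError("n_macro must be >= 1")
    n_macro = min(n_macro, k)
    if n_macro == k:
        return MacrostateMap(np.arange(k), k)
    if n_macro == 1 or V.shape[1] < 2:
        return MacrostateMap(np.zeros(k, dtype=int), 1)
    weights = np.ones(k) / k if pi is None else np.asarray(pi, dtype=float)
    avail = V.shape[1] - 1
    signs = None
    for m in range(1, avail + 1):
        cand = V[:, 1 : 1 + m] >= tol  # sign pattern, zeros counted as negative
        n_distinct = np.unique(cand, axis=0).shape[0]
        signs = cand
        if n_distinct >= n_macro:
            break
    patterns, inverse = np.unique(signs, axis=0, return_inverse=True)
    n_pat = patterns.shape[0]
    if n_pat < n_macro:
        logger.info("only %d distinct sign patterns; reducing n_macro from %d", n_pat, n_macro)
        n_macro = n_pat
    # agglomerate smallest-population patterns into nearest Hamming neighbour
    groups: dict[int, set[int]] = {p: {p} for p in range(n_pat)}
    pop = np.zeros(n_pat)
    for p in range(n_pat):
        pop[p] = weights[inverse == p].sum()
    while len(groups) > n_macro:
        alive = sorted(groups)
        smallest = min(alive, key=lambda p: (pop[p], p))
        others = [p for p in alive if p != smallest]
        dists = [
            (int(np.abs(patterns[smallest].astype(int) - patterns[p].astype(int)).sum()), p)
            for p in others
        ]
        _, nearest = min(dists)
        groups[nearest] |= groups.pop(smallest)
        pop[nearest] += pop[smallest]
    label_of_pattern = np.empty(n_pat, dtype=int)
    for new, rep in enumerate(sorted(groups)):
        for p in groups[rep]:
            label_of_pattern[p] = new
    return MacrostateMap(label_of_pattern[inverse], n_macro)


def macro_flux_report(
    flux: FluxDecomposition,
    mapping: MacrostateMap,
    n_paths: int = DEFAULT_N_PATHS,
    pi: np.ndarray | None = None,
) -> dict:
    """Aggregate micro fluxes over macrostate pairs and rank macro pathways.

    The aggregation conserves the total reactive flux exactly; top paths are
    re-extracted on the macrostate graph between the macrostates containing
    the source and target microstates.  A macrostate holding both source and
    target microstates (possible with coarse lumpings) is assigned to the
    side carrying more of its stationary weight (member count if ``pi`` is
    not given), with a log message.
    """
    lab = mapping.labels
    if lab.size != flux.net_flux.shape[0]:
        raise ValueError("macrostate map size does not match flux state space")
    M = mapping.n_macro
    macro_net = np.zeros((M, M))
    np.add.at(macro_net, (lab[:, None], lab[None, :]), flux.net_flux)
    np.fill_diagonal(macro_net, 0.0)
    weights = np.ones(lab.size) if pi is None else np.asarray(pi, dtype=float)
    macro_source = {int(lab[s]) for s in flux.source}
    macro_target = {int(lab[t]) for t in flux.target}
    for m in sorted(macro_source & macro_target):
        w_src = sum(weights[s] for s in flux.source if lab[s] == m)
        w_tgt = sum(weights[t] for t in flux.target if lab[t] == m)
        side = macro_target if w_tgt > w_src else macro_source
        other = macro_source if side is macro_target else macro_target
        other.discard(m)
        logger.info("macrostate %d holds both source and target microstates; "
                    "kept on the %s side", m,
                    "target" if side is macro_target else "source")
    macro_source = sorted(macro_source)
    macro_target = sorted(macro_target)
    if not macro_source or not macro_target:
        raise ValueError("source and target collapse into the same macrostates; "
                         "use more macrostates or tighter tIC-1 thresholds")
    paths = top_paths(
        macro_net, set(macro_source), set(macro_target), n_paths, total_flux=flux.total_flux
    )
    pairs = [
        {"from": int(i), "to": int(j), "net_flux": float(macro_net[i, j])}
        for i in range(M)
        for j in range(M)
        if macro_net[i, j] > 0
    ]
    return {
        "n_macro": M,
        "macro_source": macro_source,
        "macro_target": macro_target,
        "total_flux": flux.total_flux,
        "net_flux_table": pd.DataFrame(pairs),
        "paths": paths,
        "path_table": pd.DataFrame(
            [
                {
                    "rank": r + 1,
                    "path": "->".join(map(str, p)),
                    "flux": f,
                    "percent": 100.0 * f / flux.total_flux if flux.total_flux > 0 else np.nan,
                    "cumulative_percent": 100.0 * c,
                }
                for r, (p, f, c) in enumerate(paths)
            ]
        ),
    }
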