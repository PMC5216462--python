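"""Microstate Markov state models.

The estimator is deliberately simple and transparent: tICA-space frames are
clustered with k-means into ~100 microstates, transitions are counted at an
integer frame lag with a sliding window, the count matrix is symmetrized with
its transpose (enforcing detailed balance), restricted to its largest
connected set, and row-normalized into a transition probability matrix (TPM).
The stationary distribution is then proportional to the symmetrized row sums,
and the spectrum is computed through the similarity transform
D^{1/2} T D^{-1/2} (D = diag(pi)), which is symmetric under detailed balance
and guarantees a real spectrum.

Relaxation timescales follow from the eigenvalues as implied timescales
tau_i = -tau' / ln(lambda_i); their invariance across lag times tau' is the
standard Markovianity diagnostic, here provided with trajectory-bootstrap
error bars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovModel",
    "cluster_microstates",
    "assign_to_centers",
    "count_transitions",
    "estimate_tpm",
    "eigensystem",
    "implied_timescales",
    "implied_timescale_scan",
    "fit_msm",
]

DEFAULT_N_MICROSTATES = 100
#: Default production lag (ns) for TPM construction; converted to frames via
#: the trajectory stride at pipeline level.
DEFAULT_MSM_LAG_NS = 48.0


def cluster_microstates(
    projections: list[np.ndarray], k: int, seed: int = 0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """k-means++ microstates in tICA space; returns (centers, assignments).

    Every frame is assigned to its nearest center (Euclidean).  Assignments
    keep the per-trajectory structure.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.concatenate(projections, axis=0)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} frames, got {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(X)
    if len(np.unique(labels)) < k:  # pragma: no cover - sklearn relocates empties
        km = KMeans(n_clusters=k, init="k-means++", n_init=5, random_state=seed + 1)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            raise RuntimeError("k-means produced empty clusters after re-seeding")
    out = []
    off = 0
    for p in projections:
        out.append(labels[off : off + p.shape[0]].astype(np.int64))
        off += p.shape[0]
    return km.cluster_centers_, out


def assign_to_centers(projections: list[np.ndarray], centers: np.ndarray) -> list[np.ndarray]:
    """Nearest-center (Euclidean) assignment of frames to fixed microstates."""
    out = []
    for p in projections:
        d2 = ((p[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        out.append(np.argmin(d2, axis=1).astype(np.int64))
    return out


def count_transitions(
    assignments: list[np.ndarray],
    lag: int,
    n_states: int | None = None,
    sliding: bool = True,
) -> np.ndarray:
    """Transition count matrix at integer frame lag, summed over trajectories.

    C[i, j] counts frame pairs (t, t + lag) in states (i, j); pairs never span
    a trajectory boundary.  ``sliding=False`` uses strided counting (pairs at
    t = 0, lag, 2*lag, ...).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    assignments = [np.asarray(a, dtype=np.int64) for a in assignments]
    if n_states is None:
        n_states = int(max(a.max() for a in assignments if a.size)) + 1
    C = np.zeros((n_states, n_states))
    counted = False
    for a in assignments:
        if a.size <= lag:
            continue
        counted = True
        if sliding:
            src, dst = a[:-lag], a[lag:]
        else:
            src, dst = a[:-lag:lag], a[lag::lag]
        np.add.at(C, (src, dst), 1.0)
    if not counted:
        raise ValueError(f"all trajectories shorter than lag+1 ({lag + 1}) frames")
    return C


def _largest_connected_set(C_sym: np.ndarray) -> np.ndarray:
    n, labels = connected_components(C_sym > 0, directed=False)
    if n > 1:
        sizes = np.bincount(labels)
        keep = int(np.argmax(sizes))
        logger.info("count graph has %d components; keeping largest (%d states)", n, sizes[keep])
        return np.where(labels == keep)[0]
    return np.arange(C_sym.shape[0])


def estimate_tpm(
    count_matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetrized TPM estimate: returns (T, pi, active_states).

    C_sym = (C + C^T)/2 restricted to the largest connected set; T is the
    row-normalized C_sym and pi the normalized row sums, so detailed balance
    pi_i T_ij = pi_j T_ji holds by construction.
    """
    C = np.asarray(count_matrix, dtype=float)
    if C.sum() == 0:
        raise ValueError("empty count matrix")
    C_sym = 0.5 * (C + C.T)
    # drop states with no counts at all, then keep the largest component
    seen = np.where(C_sym.sum(axis=1) > 0)[0]
    C_sym = C_sym[np.ix_(seen, seen)]
    comp = _largest_connected_set(C_sym)
    active = seen[comp]
    C_sym = C_sym[np.ix_(comp, comp)]
    rows = C_sym.sum(axis=1)
    T = C_sym / rows[:, None]
    pi = rows / rows.sum()
    return T, pi, active


def eigensystem(
    T: np.ndarray, pi: np.ndarray | None = None, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real spectrum of a reversible TPM: (eigenvalues desc, right, left).

    Solves the symmetric matrix D^{1/2} T D^{-1/2} (D = diag(pi)); columns of
    the right/left eigenvector matrices satisfy T r = lambda r and
    l^T T = lambda l^T, with l_1 = pi.  A TPM that is not reversible within
    ``tol`` (which would have a complex spectrum) raises an error.
    """
    T = np.asarray(T, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("T must be row-stochastic")
    if pi is None:
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, i].real)
        pi = pi / pi.sum()
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    if not np.allclose(S, S.T, atol=tol):
        raise ValueError(
            "TPM violates detailed balance beyond tolerance; eigenvalues would "
            "be complex — use the symmetrized count estimator"
        )
    vals, U = np.linalg.eigh(0.5 * (S + S.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    U = U[:, order]
    right = U / sqrt_pi[:, None]
    left = U * sqrt_pi[:, None]
    # normalize the Perron pair to the conventional (1, pi)
    right[:, 0] = right[:, 0] / right[0, 0] if right[0, 0] != 0 else right[:, 0]
    scale = left[:, 0].sum()
    if scale != 0:
        left[:, 0] = left[:, 0] / scale
    return vals, right, left


def implied_timescales(eigenvalues: np.ndarray, lag: float) -> np.ndarray:
    """tau_i = -lag / ln(lambda_i) for the non-Perron eigenvalues.

    ``lag`` may be in frames or ns; the result carries the same unit.
    Eigenvalues <= 0 yield NaN (no defined relaxation time); eigenvalues >= 1
    beyond the Perron mode yield +inf.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[1:]  # drop the stationary mode
    out = np.full(lam.shape, np.nan)
    pos = (lam > 0) & (lam < 1)
    out[pos] = -lag / np.log(lam[pos])
    out[lam >= 1] = np.inf
    return out


@dataclass
class MarkovModel:
    """A validated microstate MSM with spectrum and implied timescales."""

    centers: np.ndarray | None
    assignments: list[np.ndarray]
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    lag_frames: int
    lag_ns: float
    stationary: np.ndarray
    eigenvalues: np.ndarray
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray
    active_states: np.ndarray
    timescales_ns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.timescales_ns is None:
            self.timescales_ns = implied_timescales(self.eigenvalues, self.lag_ns)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def fit_msm(
    assignments: list[np.ndarray],
    lag_frames: int,
    stride_ns: float = 1.0,
    centers: np.ndarray | None = None,
    sliding: bool = True,
) -> MarkovModel:
    """Count, symmetrize, normalize and diagonalize at a production lag."""
    C = count_transitions(assignments, lag_frames, sliding=sliding)
    T, pi, active = estimate_tpm(C)
    vals, right, left = eigensystem(T, pi)
    return MarkovModel(
        centers=centers,
        assignments=assignments,
        count_matrix=C,
        transition_matrix=T,
        lag_frames=lag_frames,
        lag_ns=lag_frames * stride_ns,
        stationary=pi,
        eigenvalues=vals,
        right_eigenvectors=right,
        left_eigenvectors=left,
        active_states=active,
    )


def implied_timescale_scan(
    assignments: list[np.ndarray],
    lags: list[int],
    n_modes: int = 10,
    n_boot: int = 10,
    seed: int = 0,
    stride_ns: float = 1.0,
) -> pd.DataFrame:
    """Implied timescales vs lag with trajectory-bootstrap error bars.

    For each lag, the full-data estimate is reported with a bootstrap spread
    (percentile 2.5/97.5) over ``n_boot`` subsamples, each drawn by choosing
    ``len(assignments)`` trajectories with replacement.  Lags exceeding every
    trajectory length are dropped with a warning.  The returned table has
    columns (lag_frames, lag_ns, mode, timescale, ci_low, ci_high) plus a
    ``flatness`` attribute: the max relative change of the slowest timescale
    over the upper half of the lag ladder.
    """
    rng = np.random.default_rng(seed)
    lags = sorted(lags)
    maxlen = max(a.size for a in assignments)
    usable = [l for l in lags if l < maxlen]
    for l in lags:
        if l >= maxlen:
            logger.warning("lag %d exceeds every trajectory length; dropped", l)
    if not usable:
        raise ValueError("no usable lags")
    n_traj = len(assignments)
    boot_ids = [rng.integers(0, n_traj, size=n_traj) for _ in range(n_boot)]

    def scan_one(ids: np.ndarray | None) -> dict[int, np.ndarray]:
        trajs = assignments if ids is None else [assignments[i] for i in ids]
        res = {}
        for l in usable:
            try:
                C = count_transitions(trajs, l)
                T, pi, _ = estimate_tpm(C)
                vals, _, _ = eigensystem(T, pi)
                res[l] = implied_timescales(vals, l * stride_ns)[:n_modes]
            except ValueError:
                res[l] = np.full(n_modes, np.nan)
        return res

    full = scan_one(None)
    boots = [scan_one(ids) for ids in boot_ids]
    rows = []
    for l in usable:
        ts = full[l]
        bmat = np.full((n_boot, n_modes), np.nan)
        for r, b in enumerate(boots):
            v = b[l]
            bmat[r, : v.size] = v[:n_modes]
        for m in range(min(n_modes, ts.size)):
            col = bmat[:, m]
            col = col[np.isfinite(col)]
            if col.size:
                lo, hi = np.percentile(col, [2.5, 97.5])
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "lag_frames": l,
                    "lag_ns": l * stride_ns,
                    "mode": m + 1,
                    "timescale": ts[m],
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    df = pd.DataFrame(rows)
    upper = [l for l in usable if l >= usable[len(usable) // 2]]
    t1 = [full[l][0] for l in upper if np.isfinite(full[l][0])]
    df.attrs["flatness"] = (
        float((max(t1) - min(t1)) / max(t1)) if len(t1) > 1 and max(t1) > 0 else 0.0
    )
    return df
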