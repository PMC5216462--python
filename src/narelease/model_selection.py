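"""GMRQ cross-validation of MSM hyperparameters.

The generalized matrix Rayleigh quotient (GMRQ) scores how well the leading
eigenvectors V learned on a training TPM diagonalize a test TPM:

    score = Tr[ (V^T S V)^{-1} (V^T C V) ],   S = diag(pi_test),  C = S T_test.

When train equals test the score is exactly the sum of the top-n eigenvalues
of the TPM, and by the variational principle of conformation dynamics the
expected test score of any model is bounded above by the sum of the true
eigenvalues — so hyperparameters (number of tICs, number of microstates) are
chosen by the highest mean test score over trajectory splits.

States present in only one of the two sets are handled by intersecting the
active state spaces and renormalizing both TPMs on the intersection, which
keeps both matrices stochastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import msm as _msm

logger = logging.getLogger(__name__)

__all__ = [
    "GMRQResult",
    "split_trajectories",
    "gmrq_score",
    "hyperparameter_scan",
]


@dataclass
class GMRQResult:
    """One scored hyperparameter setting on one train/test split."""

    n_tics: int
    k: int
    lag_frames: int
    split_index: int
    train_ids: list[int]
    test_ids: list[int]
    train_score: float
    test_score: float
    n_modes: int


def split_trajectories(
    n_traj: int,
    fraction: float,
    seed: int,
    release_labels: np.ndarray | None = None,
) -> tuple[list[int], list[int]]:
    """Random disjoint (train, test) split of trajectory indices.

    ``fraction`` is the test fraction.  With ``release_labels`` (boolean
    per-trajectory outcome) the split is stratified so the release /
    no-release proportions are preserved as closely as integer counts allow —
    e.g. 50 trajectories with 12 releases at fraction 0.5 give a test set of
    6 release + 19 no-release trajectories.
    """
    if n_traj < 2:
        raise ValueError("need at least 2 trajectories to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.arange(n_traj)
    test: list[int] = []
    if release_labels is not None:
        labels = np.asarray(release_labels, dtype=bool)
        if labels.size != n_traj:
            raise ValueError("release_labels length must equal n_traj")
        for value in (True, False):
            grp = ids[labels == value]
            n_test = int(round(fraction * grp.size))
            n_test = min(max(n_test, 0), grp.size)
            test.extend(rng.choice(grp, size=n_test, replace=False).tolist())
    else:
        n_test = min(max(int(round(fraction * n_traj)), 1), n_traj - 1)
        test = rng.choice(ids, size=n_test, replace=False).tolist()
    test_set = set(test)
    train = [int(i) for i in ids if i not in test_set]
    if not train or not test:
        raise ValueError("degenerate split: one side is empty")
    return train, sorted(int(i) for i in test)


def gmrq_score(
    V_train: np.ndarray, T_test: np.ndarray, pi_test: np.ndarray, n: int | None = None
) -> float:
    """Tr[(V^T S V)^-1 (V^T C V)] with S = diag(pi_test), C = S @ T_test.

    Invariant to any invertible linear recombination of V's columns; equals
    the sum of the top-n test eigenvalues when V holds the test TPM's own
    leading right eigenvectors.
    """
    V = np.asarray(V_train, dtype=float)
    if V.ndim != 2:
        raise ValueError("V_train must be a (k, n) matrix of eigenvector columns")
    if n is not None:
        if n < 1:
            raise ValueError("n must be >= 1")
        V = V[:, :n]
    S = np.diag(pi_test)
    C = S @ T_test
    A = V.T @ S @ V
    B = V.T @ C @ V
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "V^T S V is singular; reduce the number of scored modes"
        ) from exc
    return float(np.trace(sol))


def _restrict_to_common(
    C_a: np.ndarray, C_b: np.ndarray, max_iter: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """TPMs of two count matrices re-estimated on their common active states.

    The raw (symmetrized-at-estimation) count matrices are restricted to the
    intersection of the two active sets and re-estimated, iterating until the
    active sets stabilize — restriction happens on counts, not on TPM rows,
    so detailed balance of each estimate is preserved exactly.
    """
    Ca, Cb = np.asarray(C_a, dtype=float), np.asarray(C_b, dtype=float)
    idx = np.arange(Ca.shape[0])
    for _ in range(max_iter):
        try:
            T_a, pi_a, act_a = _msm.estimate_tpm(Ca)
            T_b, pi_b, act_b = _msm.estimate_tpm(Cb)
        except ValueError:
            return None
        common = np.intersect1d(act_a, act_b)
        if common.size < 2:
            return None
        full = np.arange(Ca.shape[0])
        if np.array_equal(act_a, full) and np.array_equal(act_b, full):
            return T_a, pi_a, T_b, pi_b, idx
        idx = idx[common]
        Ca = Ca[np.ix_(common, common)]
        Cb = Cb[np.ix_(common, common)]
    return None


def _score_split(
    projections: list[np.ndarray],
    train_ids: list[int],
    test_ids: list[int],
    n_tics: int,
    k: int,
    lag_frames: int,
    n_modes: int,
    seed: int,
) -> tuple[float, float] | None:
    proj = [p[:, :n_tics] for p in projections]
    train = [proj[i] for i in train_ids]
    test = [proj[i] for i in test_ids]
    try:
        centers, train_assign = _msm.cluster_microstates(train, k, seed=seed)
    except ValueError:
        return None
    test_assign = _msm.assign_to_centers(test, centers)
    try:
        C_train = _msm.count_transitions(train_assign, lag_frames, n_states=k)
        C_test = _msm.count_transitions(test_assign, lag_frames, n_states=k)
    except ValueError:
        return None
    restricted = _restrict_to_common(C_train, C_test)
    if restricted is None:
        return None
    T_tr, pi_tr, T_te, pi_te, _ = restricted
    n = min(n_modes, T_tr.shape[0])
    try:
        vals_tr, right_tr, _ = _msm.eigensystem(T_tr, pi_tr)
    except ValueError:
        return None
    V = right_tr[:, :n]
    train_score = float(np.sum(vals_tr[:n]))
    try:
        test_score = gmrq_score(V, T_te, pi_te)
    except ValueError:
        return None
    return train_score, test_score


def hyperparameter_scan(
    projections: list[np.ndarray],
    n_tics_grid: list[int],
    k_grid: list[int],
    lag_frames: int,
    fraction: float = 0.5,
    n_splits: int = 5,
    seed: int = 0,
    n_modes: int = 10,
    release_labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mean GMRQ test score over splits for each (n_tics, k) grid point.

    Returns the full per-split table and the argmax setting (by mean test
    score).  Grid points that fail to build (e.g. a disconnected test chain)
    are scored as missing and logged.
    """
    if not n_tics_grid or not k_grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    split_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_splits)]
    splits = [
        split_trajectories(len(projections), fraction, s, release_labels=release_labels)
        for s in split_seeds
    ]
    rows = []
    for n_tics in n_tics_grid:
        for k in k_grid:
            for si, (train_ids, test_ids) in enumerate(splits):
                res = _score_split(
                    projections, train_ids, test_ids, n_tics, k, lag_frames, n_modes, seed
                )
                if res is None:
                    logger.info("grid point (n_tics=%d, k=%d, split=%d) failed; skipped", n_tics, k, si)
                    train_score = test_score = np.nan
                else:
                    train_score, test_score = res
                rows.append(
                    {
                        "n_tics": n_tics,
                        "k": k,
                        "split": si,
                        "train_score": train_score,
                        "test_score": test_score,
                    }
                )
    table = pd.DataFrame(rows)
    means = table.groupby(["n_tics", "k"])["test_score"].mean()
    if means.isna().all():
        raise ValueError("every grid point failed to build a scored model")
    best_n_tics, best_k = means.idxmax()
    best = {
        "n_tics": int(best_n_tics),
        "k": int(best_k),
        "mean_test_score": float(means.max()),
        "lag_frames": lag_frames,
    }
    return table, best
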