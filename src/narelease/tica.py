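"""Time-structure-based independent component analysis (tICA).

tICA finds the linear combinations of input features with the slowest
autocorrelation by solving the generalized eigenvalue problem

    C_TL(tau) V = C V Lambda,

where C = <x(t) x(t)^T> is the instantaneous covariance and
C_TL(tau) = <x(t) x(t+tau)^T> the time-lagged covariance of the mean-free
data.  Eigenvectors corresponding to the largest eigenvalues are the slowest
reaction coordinates; their eigenvalues are lag-tau autocorrelations of the
projected coordinates.

Numerical conventions: C_TL is symmetrized as (C_TL + C_TL^T)/2 before
solving (finite sampling makes it slightly asymmetric, which would yield
complex eigenpairs); C is ridge-regularized as C + eps*I with
eps = 1e-10 * trace(C)/d; eigenvectors are normalized to v^T C v = 1 and
sign-fixed so each eigenvector's largest-magnitude entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .geometry import FeatureSeries

logger = logging.getLogger(__name__)

__all__ = [
    "TICAModel",
    "estimate_covariances",
    "solve_tica",
    "project",
    "screen_components",
    "fit_tica",
]

#: Default lag (ns) for the time-lagged covariance matrix; converted to frames
#: via the ensemble stride by the pipeline.
DEFAULT_TICA_LAG_NS = 16.0


def _as_matrices(features) -> list[np.ndarray]:
    out = []
    for f in features:
        out.append(f.matrix if isinstance(f, FeatureSeries) else np.asarray(f, dtype=float))
    return out


def estimate_covariances(
    features: list[FeatureSeries] | list[np.ndarray], lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (mean, C, C_TL) over trajectories at integer frame lag ``lag``.

    The pooled mean over all frames of usable trajectories is subtracted;
    lagged pairs (t, t+lag) never span a trajectory boundary.  Trajectories
    shorter than ``lag + 1`` frames are skipped with a warning; if all are
    skipped an error is raised.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    mats = _as_matrices(features)
    usable = []
    for i, m in enumerate(mats):
        if m.shape[0] <= lag:
            logger.warning("trajectory %d shorter than lag+1 (%d <= %d); skipped", i, m.shape[0], lag)
        else:
            usable.append(m)
    if not usable:
        raise ValueError("all trajectories shorter than lag+1; cannot estimate covariances")
    mean = np.concatenate(usable).mean(axis=0)
    d = mean.size
    C = np.zeros((d, d))
    C_TL = np.zeros((d, d))
    n0 = 0
    n_lag = 0
    for m in usable:
        x = m - mean
        C += x.T @ x
        n0 += x.shape[0]
        a, b = x[:-lag], x[lag:]
        C_TL += a.T @ b
        n_lag += a.shape[0]
    return mean, C / n0, C_TL / n_lag


def solve_tica(
    C: np.ndarray, C_TL: np.ndarray, ridge: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve C_TL V = C V Lambda; eigenvalues descending, v^T C v = 1.

    ``ridge`` overrides the default regularization eps = 1e-10 * trace(C)/d.
    A singular regularized C raises an error advising feature pruning.
    """
    C = np.asarray(C, dtype=float)
    C_TL = np.asarray(C_TL, dtype=float)
    d = C.shape[0]
    if ridge is None:
        ridge = 1e-10 * np.trace(C) / d
    C_reg = C + ridge * np.eye(d)
    C_sym = 0.5 * (C_TL + C_TL.T)
    try:
        vals, vecs = scipy.linalg.eigh(C_sym, C_reg)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise ValueError(
            "covariance matrix is singular even after regularization; "
            "prune constant or perfectly correlated features"
        ) from exc
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # eigh(b=C_reg) returns v^T C_reg v = 1 already; re-normalize against the
    # unregularized C and fix signs for reproducibility.
    for j in range(d):
        norm = float(vecs[:, j] @ C @ vecs[:, j])
        if norm > 0:
            vecs[:, j] /= np.sqrt(norm)
        peak = np.argmax(np.abs(vecs[:, j]))
        if vecs[peak, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


@dataclass
class TICAModel:
    """Fitted tICA transform: moments, eigenpairs and the chosen lag."""

    mean: np.ndarray
    covariance: np.ndarray
    time_lagged_covariance: np.ndarray
    lag_frames: int
    lag_ns: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    n_selected: int = 2
    feature_names: list[str] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.mean.size


def fit_tica(
    features: list[FeatureSeries] | list[np.ndarray],
    lag_frames: int,
    stride_ns: float = 1.0,
    n_selected: int = 2,
    feature_names: list[str] | None = None,
) -> TICAModel:
    """Estimate covariances and solve the generalized eigenproblem."""
    mean, C, C_TL = estimate_covariances(features, lag_frames)
    vals, vecs = solve_tica(C, C_TL)
    if feature_names is None:
        f0 = features[0]
        feature_names = list(f0.names) if isinstance(f0, FeatureSeries) else []
    return TICAModel(
        mean=mean,
        covariance=C,
        time_lagged_covariance=C_TL,
        lag_frames=lag_frames,
        lag_ns=lag_frames * stride_ns,
        eigenvalues=vals,
        eigenvectors=vecs,
        n_selected=n_selected,
        feature_names=feature_names,
    )


def project(
    features: list[FeatureSeries] | list[np.ndarray] | FeatureSeries | np.ndarray,
    model: TICAModel,
    n_components: int | None = None,
) -> list[np.ndarray] | np.ndarray:
    """Project mean-free features onto the leading tICA eigenvectors.

    ``(X - mean) @ V[:, :n]`` per frame; trajectory structure is preserved
    (a list in, a list out).
    """
    n = model.n_selected if n_components is None else n_components
    if n > model.d:
        raise ValueError(f"n_components={n} exceeds feature dimension {model.d}")
    single = isinstance(features, (FeatureSeries, np.ndarray))
    mats = _as_matrices([features] if single else features)
    V = model.eigenvectors[:, :n]
    out = []
    for m in mats:
        if m.shape[1] != model.d:
            raise ValueError(f"feature dimension {m.shape[1]} != model dimension {model.d}")
        out.append((m - model.mean) @ V)
    return out[0] if single else out


def screen_components(
    projections: list[np.ndarray] | np.ndarray, alpha: float = 0.01
) -> dict:
    """Flag non-Gaussian tICA components (D'Agostino–Pearson omnibus test).

    Components whose projected distribution departs from normality carry the
    slow, multi-basin structure worth keeping; a purely Gaussian component is
    indistinguishable from equilibrated noise.  Returns per-component
    statistics, flags, degenerate (zero-variance) components, and the
    recommended number of components = count of flagged leading components.
    """
    if isinstance(projections, np.ndarray):
        data = projections
    else:
        data = np.concatenate(projections, axis=0)
    if data.shape[0] < 100:
        raise ValueError("need at least 100 frames to screen components")
    n_comp = data.shape[1]
    stats_out = np.full(n_comp, np.nan)
    pvals = np.full(n_comp, np.nan)
    flagged = np.zeros(n_comp, dtype=bool)
    degenerate = np.zeros(n_comp, dtype=bool)
    for j in range(n_comp):
        x = data[:, j]
        if np.std(x) == 0:
            degenerate[j] = True
            flagged[j] = True
            continue
        res = stats.normaltest(x)
        stats_out[j] = res.statistic
        pvals[j] = res.pvalue
        flagged[j] = res.pvalue < alpha
    recommended = 0
    for j in range(n_comp):
        if flagged[j] and not degenerate[j]:
            recommended += 1
        else:
            break
    return {
        "statistic": stats_out,
        "pvalue": pvals,
        "non_gaussian": flagged,
        "degenerate": degenerate,
        "recommended_n": recommended,
    }
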