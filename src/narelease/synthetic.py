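"""Ground-truth-known synthetic data generators.

Three generators stand in for an (undeposited) ensemble of ~50 unbiased MD
trajectories of a membrane transporter in which a Na+ ion escapes its binding
basin through a metastable intermediate in a minority of trajectories:

* :func:`simulate_chain` — discrete Markov chains with a known transition
  matrix, for validating counting, estimation and implied-timescale recovery.
* :func:`simulate_three_well` — overdamped Langevin (Euler–Maruyama) diffusion
  on a 2-D three-well potential whose middle well is strictly shallower,
  mirroring the bound / intermediate / released free-energy landscape.
* :func:`synthesize_frames` — labeled pseudo-atom coordinate frames (ions,
  gate-residue markers, water oxygens, K+ ions, lipid markers, a ligand proxy)
  on which the geometric featurizer reproduces the qualitative signatures of
  ion release: the Na2–Na1 distance crossing 10 Å, rising intracellular
  hydration, and K+ entry near D79 only after release.

Only the statistical and kinetic structure of the real data is emulated; no
physical realism of transporter forces is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import FrameEnsemble, FrameTrajectory

__all__ = [
    "GroundTruthChain",
    "ThreeWellParams",
    "simulate_chain",
    "simulate_chain_ensemble",
    "simulate_three_well",
    "simulate_three_well_ensemble",
    "assign_basins",
    "basin_boltzmann_weights",
    "boltzmann_marginal_profile",
    "synthesize_frames",
    "generate_release_ensemble",
    "default_release_chain",
    "RELEASE_THRESHOLD_A",
    "RELEASE_PERSISTENCE_FRAMES",
]

#: Na2–Na1 distance (Å) above which the tagged ion counts as released.  10 Å is
#: the post-release bin boundary used when classifying frames by the
#: two-sodium distance; the persistence guard avoids counting transient
#: flicker across the threshold as a release event.
RELEASE_THRESHOLD_A = 10.0
RELEASE_PERSISTENCE_FRAMES = 10


# --------------------------------------------------------------------------
# Discrete ground-truth chains
# --------------------------------------------------------------------------


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmax(vals.real))
    pi = np.abs(vecs[:, i].real)
    return pi / pi.sum()


@dataclass
class GroundTruthChain:
    """A row-stochastic transition matrix with known stationary distribution.

    ``labels`` tags each state as bound / intermediate / released; ``lag_unit_ns``
    is the physical time represented by one chain step.
    """

    transition_matrix: np.ndarray
    stationary_dist: np.ndarray | None = None
    lag_unit_ns: float = 1.0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition_matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition_matrix entries must be non-negative")
        rows = T.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1 (within 1e-12)")
        self.transition_matrix = T
        if self.stationary_dist is None:
            self.stationary_dist = _stationary_from_T(T)
        else:
            pi = np.asarray(self.stationary_dist, dtype=float)
            if not np.allclose(pi @ T, pi, atol=1e-10):
                raise ValueError("stationary_dist is not stationary for transition_matrix")
            self.stationary_dist = pi / pi.sum()
        if self.lag_unit_ns <= 0:
            raise ValueError("lag_unit_ns must be positive")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def default_release_chain(lag_unit_ns: float = 1.0) -> GroundTruthChain:
    """Reversible 3-state birth–death chain: bound <-> intermediate <-> released.

    The middle (intermediate) state is short-lived relative to the end states,
    so the slowest relaxation is the bound/released exchange.
    """
    T = np.array(
        [
            [0.98, 0.02, 0.00],
            [0.05, 0.90, 0.05],
            [0.00, 0.02, 0.98],
        ]
    )
    return GroundTruthChain(
        T, lag_unit_ns=lag_unit_ns, labels=("bound", "intermediate", "released")
    )


def simulate_chain(
    chain: GroundTruthChain,
    n_steps: int,
    seed: int | np.random.Generator,
    start: int | None = None,
) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` from the chain.

    ``start`` defaults to a draw from the stationary distribution.  Empirical
    transition frequencies converge to ``chain.transition_matrix`` as
    ``n_steps`` grows (at the usual n^-1/2 rate).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = chain.transition_matrix
    cum = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=np.int64)
    if start is None:
        start = int(rng.choice(chain.n_states, p=chain.stationary_dist))
    if not 0 <= start < chain.n_states:
        raise ValueError("start state out of range")
    out[0] = start
    u = rng.random(n_steps - 1)
    s = start
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        if s == chain.n_states:  # guard against u == 1.0 round-off
            s -= 1
        out[t] = s
    return out


def simulate_chain_ensemble(
    chain: GroundTruthChain,
    n_traj: int,
    n_steps: int,
    seed: int,
    start: int | None = None,
) -> list[np.ndarray]:
    """Independent chain realizations; trajectory i uses a child seed of ``seed``."""
    rng = np.random.default_rng(seed)
    return [simulate_chain(chain, n_steps, rng, start=start) for _ in range(n_traj)]


# --------------------------------------------------------------------------
# Continuous three-well diffusion
# --------------------------------------------------------------------------


@dataclass
class ThreeWellParams:
    """Parameters of a 2-D multi-well potential sampled by overdamped Langevin.

    The potential is the pointwise minimum of isotropic paraboloids,

        U(r) = min_i [ E_i + |r - c_i|^2 / (2 sigma^2) ],

    with offsets ``E_i = well_depths`` (kT; lower = deeper) at centers ``c_i``.
    The common width ``sigma`` is derived from ``barrier_heights`` b and the
    adjacent-center spacing L via sigma^2 = L^2 / (8 b), which places the
    saddle between equal-depth neighbours b (kT) above their bottoms.  The
    middle well must be strictly shallower (higher energy) than the end wells.
    """

    well_centers: np.ndarray = field(
        default_factory=lambda: np.array([[-2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
    )
    well_depths: np.ndarray = field(default_factory=lambda: np.array([0.0, 2.0, 0.5]))
    barrier_heights: float = 3.0
    diffusion_coeff: float = 1.0
    timestep: float = 0.01
    temperature_factor: float = 1.0
    labels: tuple[str, ...] = ("bound", "intermediate", "released")

    def __post_init__(self) -> None:
        self.well_centers = np.atleast_2d(np.asarray(self.well_centers, dtype=float))
        self.well_depths = np.atleast_1d(np.asarray(self.well_depths, dtype=float))
        if self.well_centers.shape[0] != self.well_depths.shape[0]:
            raise ValueError("one depth per well center required")
        if self.n_wells == 3:
            e = self.well_depths
            if not (e[1] > e[0] and e[1] > e[2]):
                raise ValueError(
                    "intermediate (middle) well must be strictly shallower "
                    "(higher energy) than the two end wells"
                )
        if self.barrier_heights < 0:
            raise ValueError("barrier_heights must be >= 0")
        if self.n_wells > 1 and self.barrier_heights == 0:
            raise ValueError("barrier_heights must be > 0 for a multi-well potential")
        if min(self.diffusion_coeff, self.timestep, self.temperature_factor) < 0:
            raise ValueError("diffusion_coeff, timestep, temperature_factor must be >= 0")

    @property
    def n_wells(self) -> int:
        return self.well_centers.shape[0]

    @property
    def sigma2(self) -> float:
        """Squared well width; 1.0 for a single well without barriers."""
        if self.n_wells == 1 or self.barrier_heights == 0:
            return 1.0
        c = self.well_centers
        seps = np.linalg.norm(np.diff(c, axis=0), axis=1)
        L = float(seps.min())
        return L * L / (8.0 * self.barrier_heights)

    def potential(self, points: np.ndarray) -> np.ndarray:
        """U(points) in kT units; points shape (..., 2)."""
        p = np.asarray(points, dtype=float)
        d2 = np.sum((p[..., None, :] - self.well_centers) ** 2, axis=-1)
        return np.min(self.well_depths + d2 / (2.0 * self.sigma2), axis=-1)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        diff = p[..., None, :] - self.well_centers  # (..., n_wells, 2)
        d2 = np.sum(diff**2, axis=-1)
        active = np.argmin(self.well_depths + d2 / (2.0 * self.sigma2), axis=-1)
        act = np.take_along_axis(diff, active[..., None, None], axis=-2)[..., 0, :]
        return act / self.sigma2

    def assign_basin(self, points: np.ndarray) -> np.ndarray:
        """Index of the active (nearest, depth-offset) well per point."""
        p = np.asarray(points, dtype=float)
        d2 = np.sum((p[..., None, :] - self.well_centers) ** 2, axis=-1)
        return np.argmin(self.well_depths + d2 / (2.0 * self.sigma2), axis=-1)


def _check_timestep(params: ThreeWellParams) -> None:
    # Stability of Euler–Maruyama on curvature 1/sigma^2 requires
    # D*dt/(kT*sigma^2) << 1; per-step diffusive displacement must also stay
    # small against the well separation.
    D, dt, kT = params.diffusion_coeff, params.timestep, params.temperature_factor
    if dt <= 0:
        raise ValueError("timestep must be positive")
    relax = D * dt / (kT * params.sigma2)
    if relax > 0.5:
        raise ValueError(
            f"unstable timestep: D*dt/(kT*sigma^2) = {relax:.3g} > 0.5; "
            f"use timestep < {0.5 * kT * params.sigma2 / D:.3g}"
        )
    if params.n_wells > 1:
        seps = np.linalg.norm(np.diff(params.well_centers, axis=0), axis=1)
        step = math.sqrt(2.0 * D * dt)
        if step > 0.25 * seps.min():
            raise ValueError(
                f"unstable timestep: rms step {step:.3g} exceeds a quarter of the "
                f"well separation; use timestep < {(0.25 * seps.min()) ** 2 / (2 * D):.3g}"
            )


def simulate_three_well_ensemble(
    params: ThreeWellParams,
    n_traj: int,
    n_steps: int,
    seed: int,
    start: np.ndarray | None = None,
    subsample: int = 1,
) -> list[np.ndarray]:
    """Euler–Maruyama paths on the potential, integrated jointly for speed.

    Returns ``n_traj`` arrays of shape (n_steps//subsample, 2).  The long-run
    histogram is proportional to exp(-U/kT).  ``start`` defaults to the
    deepest well center.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    _check_timestep(params)
    rng = np.random.default_rng(seed)
    D, dt, kT = params.diffusion_coeff, params.timestep, params.temperature_factor
    if start is None:
        start = params.well_centers[int(np.argmin(params.well_depths))]
    x = np.tile(np.asarray(start, dtype=float), (n_traj, 1))
    noise_scale = math.sqrt(2.0 * D * dt)
    keep = range(0, n_steps, subsample)
    out = np.empty((len(keep), n_traj, 2))
    k = 0
    for t in range(n_steps):
        if t % subsample == 0:
            out[k] = x
            k += 1
        if D > 0:
            x = x - (D * dt / kT) * params.gradient(x) + noise_scale * rng.standard_normal(x.shape)
        # D == 0: no drift, no noise -> constant trajectory
    return [out[:, i, :].copy() for i in range(n_traj)]


def simulate_three_well(
    params: ThreeWellParams,
    n_steps: int,
    seed: int,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Single overdamped-Langevin trajectory of shape (n_steps, 2)."""
    return simulate_three_well_ensemble(params, 1, n_steps, seed, start=start)[0]


def assign_basins(points: np.ndarray, params: ThreeWellParams) -> np.ndarray:
    return params.assign_basin(points)


def basin_boltzmann_weights(
    params: ThreeWellParams, extent: float = 4.0, n_grid: int = 400
) -> np.ndarray:
    """Relative basin populations by numerical integration of exp(-U/kT).

    The grid spans the well centers padded by ``extent`` in each direction.
    """
    c = params.well_centers
    lo = c.min(axis=0) - extent
    hi = c.max(axis=0) + extent
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    w = np.exp(-params.potential(pts) / params.temperature_factor)
    basins = params.assign_basin(pts)
    out = np.array([w[basins == i].sum() for i in range(params.n_wells)])
    return out / out.sum()


def boltzmann_marginal_profile(
    params: ThreeWellParams,
    direction: np.ndarray,
    bin_edges: np.ndarray,
    extent: float = 4.0,
    n_grid: int = 500,
) -> np.ndarray:
    """Exact (quadrature) free-energy profile along a unit direction, in kT.

    Boltzmann weight is integrated on a grid, binned by the projection onto
    ``direction``, and returned as -ln(p) shifted so the minimum over occupied
    bins is 0.  Empty bins are NaN.  This is the generator-side oracle against
    which histogram profiles from sampled data can be compared.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    c = params.well_centers
    lo = c.min(axis=0) - extent
    hi = c.max(axis=0) + extent
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    w = np.exp(-params.potential(pts) / params.temperature_factor).ravel()
    proj = pts.reshape(-1, 2) @ direction
    idx = np.digitize(proj, bin_edges) - 1
    n_bins = len(bin_edges) - 1
    p = np.zeros(n_bins)
    valid = (idx >= 0) & (idx < n_bins)
    np.add.at(p, idx[valid], w[valid])
    p /= p.sum()
    with np.errstate(divide="ignore"):
        F = -np.log(p)
    F[p == 0] = np.nan
    return F - np.nanmin(F)


# --------------------------------------------------------------------------
# Coordinate-frame synthesis
# --------------------------------------------------------------------------

# Static marker layout (Å).  z > 0 is the extracellular side; the binding site
# sits near the origin and the intracellular exit pathway runs toward -z.
_MARKERS = {
    "R60": (3.0, 2.0, -8.0),
    "Y335": (-2.0, 1.0, -7.0),
    "E428": (1.0, 1.0, -6.0),
    "R445": (2.5, 0.5, -7.0),
    "D436": (-1.0, -2.0, -8.0),
    "D79": (1.5, 0.0, 0.5),
    "F326": (0.0, 0.0, 5.0),  # C-beta proxy
    "T269": (0.0, 1.0, -4.0),  # backbone proxy
    "D345": (4.0, -1.0, -9.0),
    "K66": (4.5, -1.5, -9.5),
    "E446": (3.5, 2.0, -7.5),
    "D421": (-1.5, 0.5, 0.8),
}
_NA1_POS = np.array([0.0, 0.0, 2.0])
_NA2_BOUND = np.array([0.0, 0.0, 0.0])
_NA2_INTERMEDIATE = np.array([1.0, 1.0, -6.0])  # coordinated by E428
_NA2_RELEASED = np.array([0.0, 0.0, -15.0])
_DA_COM = np.array([0.0, 0.0, 3.0])
_K_FAR = np.array([-10.0, -10.0, -12.0])
_K_SITE = np.array([1.5, 0.0, -1.5])  # within 7 A of D79
_W_BULK = np.array([40.0, 40.0, -30.0])  # outside every cavity definition

MARKER_LABELS = tuple(_MARKERS)


def _ion_path(s: np.ndarray) -> np.ndarray:
    """Piecewise-linear bound -> intermediate -> released path, s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)[:, None]
    first = _NA2_BOUND + (2.0 * s) * (_NA2_INTERMEDIATE - _NA2_BOUND)
    second = _NA2_INTERMEDIATE + (2.0 * s - 1.0) * (_NA2_RELEASED - _NA2_INTERMEDIATE)
    return np.where(s <= 0.5, first, second)


def synthesize_frames(
    scenario: str,
    n_frames: int,
    seed: int,
    stride_ns: float = 2.0,
    n_waters: int = 60,
    n_potassium: int = 4,
    n_lipids: int = 24,
    release_frame: int | None = None,
    noise: float = 0.15,
) -> FrameEnsemble:
    """Generate one labeled pseudo-atom trajectory as a single-member ensemble.

    ``scenario`` is ``"release"`` or ``"no_release"``.  In a release trajectory
    the tagged Na2 ion leaves the binding basin through the intermediate
    position near the E428 marker, the Na2–Na1 distance crosses
    :data:`RELEASE_THRESHOLD_A` and stays above it, the intracellular cavity
    water count rises, and one K+ ion approaches the D79 marker only after
    release.  In ``no_release`` none of this happens.
    """
    if scenario not in ("release", "no_release"):
        raise ValueError("scenario must be 'release' or 'no_release'")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    if scenario == "release":
        if release_frame is None:
            release_frame = max(1, int(0.4 * n_frames))
        release_frame = int(np.clip(release_frame, 1, max(1, n_frames - 20)))
        ramp = 30  # frames from start of motion to full release
        s = np.clip((np.arange(n_frames) - release_frame) / ramp, 0.0, 1.0)
        # brief dwell in the intermediate (s ~ 0.5)
        dwell = 8
        s = np.where(
            (s > 0.45) & (np.arange(n_frames) < release_frame + ramp // 2 + dwell),
            np.minimum(s, 0.5),
            s,
        )
    else:
        s = np.zeros(n_frames)

    labels: list[str] = []
    roles: dict[str, str] = {}
    coords: list[np.ndarray] = []

    def add(label: str, role: str, traj: np.ndarray) -> None:
        labels.append(label)
        roles[label] = role
        coords.append(traj)

    jitter = lambda base, scale=noise: base + scale * rng.standard_normal((n_frames, 3))

    for name, pos in _MARKERS.items():
        base = np.asarray(pos, dtype=float)
        if name in ("R60", "R445") and scenario == "release":
            # intracellular gates drift open as the ion departs
            drift = np.outer(s, np.array([1.0, 0.8, -0.5]))
            add(name, "marker", jitter(base + drift))
        else:
            add(name, "marker", jitter(base))

    add("DA", "ligand", jitter(_DA_COM, 0.05))
    add("Na1", "ion", jitter(_NA1_POS, 0.05))
    add("Na2", "ion", _ion_path(s) + 0.05 * rng.standard_normal((n_frames, 3)))

    # K+ ions: all remote; in a release run the first one enters the site
    # once the ion has fully left (s == 1).
    for i in range(n_potassium):
        base = _K_FAR + np.array([2.0 * i, 0.0, 0.0])
        traj = jitter(base, 0.3)
        if scenario == "release" and i == 0:
            entered = s >= 1.0
            traj[entered] = _K_SITE + 0.3 * rng.standard_normal((entered.sum(), 3))
        add(f"K+{i}", "ion", traj)

    # lipid ring (static + jitter), radius 20 A, two leaflets
    for i in range(n_lipids):
        ang = 2.0 * math.pi * i / n_lipids
        z = 10.0 if i % 2 == 0 else -10.0
        base = np.array([20.0 * math.cos(ang), 20.0 * math.sin(ang), z])
        add(f"L{i}", "lipid", jitter(base, 0.2))

    # Waters.  Fixed population: hydration shell, EC vestibule/cavity,
    # IC channel + cavity baseline, lipid-adjacent (excluded by the 5 A
    # clause), and a mobile pool that migrates into the IC cavity on release.
    n_shell = 5
    n_ec = 18
    n_ic_base = 8
    n_lipid_adj = 2
    n_mobile = 12
    n_bulk = n_waters - (n_shell + n_ec + n_ic_base + n_lipid_adj + n_mobile)
    if n_bulk < 0:
        raise ValueError("n_waters too small for the fixed water populations")

    ion_xyz = _ion_path(s)
    w = 0

    # hydration shell around the tagged ion: 2 waters always, 5 once moving
    shell_dirs = rng.standard_normal((n_shell, 3))
    shell_dirs /= np.linalg.norm(shell_dirs, axis=1, keepdims=True)
    hydration = 2 + np.round(3 * np.clip(s * 2.0, 0.0, 1.0)).astype(int)
    for i in range(n_shell):
        near = ion_xyz + 2.3 * shell_dirs[i] + 0.1 * rng.standard_normal((n_frames, 3))
        traj = np.where((i < hydration)[:, None], near, _W_BULK + 3.0 * rng.standard_normal((n_frames, 3)))
        add(f"W{w}", "water", traj)
        w += 1

    # extracellular vestibule waters (a third of them inside the EC cavity)
    for i in range(n_ec):
        ang = 2.0 * math.pi * i / n_ec
        r = 4.0 + 6.0 * (i % 3)
        # z >= 8 keeps EC waters outside the IC-vestibule z-clause
        base = np.array([r * math.cos(ang), r * math.sin(ang), 8.0 + (i % 5) * 2.0])
        traj = jitter(base, 0.3)
        if scenario == "release":
            # EC solvation thins as the transporter closes outward: the last
            # few vestibule waters drift to bulk after release
            if i >= n_ec - 4:
                gone = s >= 1.0
                traj[gone] = _W_BULK + 3.0 * rng.standard_normal((gone.sum(), 3))
        add(f"W{w}", "water", traj)
        w += 1

    # baseline intracellular waters: half in the IC channel, half in the cavity
    ic_channel_base = np.array([0.0, -1.0, -5.0])
    ic_cavity_base = np.array([8.0, -8.0, -5.0])
    for i in range(n_ic_base):
        base = ic_channel_base if i % 2 == 0 else ic_cavity_base
        add(f"W{w}", "water", jitter(base + 0.5 * rng.standard_normal(3), 0.3))
        w += 1

    # lipid-adjacent waters: inside the 26 A sphere but within 5 A of a lipid
    for i in range(n_lipid_adj):
        base = np.array([18.0, 0.0, 8.0]) + np.array([0.0, 1.0 * i, 0.0])
        add(f"W{w}", "water", jitter(base, 0.2))
        w += 1

    # mobile pool: bulk -> IC cavity/channel as release progresses
    for i in range(n_mobile):
        frac = (i + 1) / n_mobile
        target = ic_cavity_base if i % 2 == 0 else ic_channel_base + np.array([1.0, 1.0, -1.0])
        target = target + 0.8 * rng.standard_normal(3)
        inside = s >= 0.5 * frac  # waters flow in progressively
        near = target + 0.3 * rng.standard_normal((n_frames, 3))
        far = _W_BULK + 3.0 * rng.standard_normal((n_frames, 3))
        add(f"W{w}", "water", np.where(inside[:, None], near, far))
        w += 1

    for i in range(n_bulk):
        base = _W_BULK + np.array([4.0 * (i % 5), 4.0 * (i // 5), 0.0])
        add(f"W{w}", "water", jitter(base, 1.0))
        w += 1

    xyz = np.stack(coords, axis=1)
    traj = FrameTrajectory(labels=labels, roles=roles, xyz=xyz, stride_ns=stride_ns)
    return FrameEnsemble([traj])


def generate_release_ensemble(
    n_traj: int = 50,
    n_release: int = 12,
    n_frames: int = 500,
    seed: int = 0,
    stride_ns: float = 2.0,
    release_window_ns: tuple[float, float] = (80.0, 900.0),
    **kwargs,
) -> tuple[FrameEnsemble, np.ndarray]:
    """Ensemble of coordinate trajectories with release engineered in a subset.

    Emulates the study design: ``n_traj`` independent trajectories of which
    ``n_release`` show spontaneous ion release, with release times dispersed
    uniformly over ``release_window_ns`` (rescaled when trajectories are
    shorter than the nominal 1 μs).  Returns the ensemble and the boolean
    ground-truth release labels.
    """
    if not 0 <= n_release <= n_traj:
        raise ValueError("n_release must be between 0 and n_traj")
    rng = np.random.default_rng(seed)
    total_ns = n_frames * stride_ns
    lo, hi = release_window_ns
    scale = min(1.0, (0.75 * total_ns) / hi)
    lo_f = max(1, int(lo * scale / stride_ns))
    hi_f = max(lo_f + 1, int(hi * scale / stride_ns))
    hi_f = min(hi_f, max(lo_f + 1, n_frames - 45))  # room for ramp + persistence

    which = np.zeros(n_traj, dtype=bool)
    which[rng.choice(n_traj, size=n_release, replace=False)] = True
    trajs = []
    for i in range(n_traj):
        sub = int(rng.integers(0, 2**31 - 1))
        if which[i]:
            rf = int(rng.integers(lo_f, hi_f + 1))
            ens = synthesize_frames(
                "release", n_frames, sub, stride_ns=stride_ns, release_frame=rf, **kwargs
            )
        else:
            ens = synthesize_frames("no_release", n_frames, sub, stride_ns=stride_ns, **kwargs)
        trajs.append(ens.trajectories[0])
    return FrameEnsemble(trajs), which
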