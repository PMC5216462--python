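"""Geometric featurization of labeled coordinate frames.

Computes the tICA input parameters (ion and gate-residue distances plus the
Na+ water-coordination number), the water-fillable cavity occupancies used to
quantify hydration (EC vestibule / EC cavity / IC vestibule split into IC
channel and IC cavity), residue interaction frequencies, lipid-mediated
contacts, and the probability of K+ occupancy near the D79 site binned by the
two-sodium distance.

Cavity definitions (distances in Å, z = membrane normal, positive toward the
extracellular side):

* EC vestibule: water oxygen within 26 of the F326 C-beta marker, not within
  5 of any lipid particle, and with z exceeding the F326 marker's z by no
  more than 23 (one-sided, exactly as defined).
* EC cavity: EC-vestibule waters within 10 of the ligand (dopamine) center.
* IC vestibule: water oxygen within 15 of the ligand center, not within 5 of
  any lipid, and with |z - z(D436 C-beta)| <= 15.5.
* IC channel: IC-vestibule waters within 12 of any T269 backbone particle;
  IC cavity: the remainder.  IC channel and IC cavity partition the vestibule.

No periodic-boundary imaging is applied by default; an optional minimum-image
correction is available for real MD input via ``box`` arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .frames import Frame, FrameEnsemble, FrameTrajectory

__all__ = [
    "FeatureSeries",
    "CavityCounts",
    "TABLE_FEATURES",
    "DEFAULT_COORDINATION_CUTOFF_A",
    "pair_distances",
    "coordination_number",
    "feature_series",
    "assign_ec_vestibule",
    "assign_ec_cavity",
    "assign_ic_vestibule_and_split",
    "cavity_counts",
    "interaction_frequency",
    "mediated_contact",
    "kplus_site_probability",
]

#: First-hydration-shell cutoff for the Na+ water-coordination number (Å).
#: Not fixed by the source analysis; 3.5 Å is the standard first-shell
#: convention and is configurable everywhere it is used.
DEFAULT_COORDINATION_CUTOFF_A = 3.5

#: The default 12-parameter feature set: four distances tracking the tagged
#: ion's exit (to the Na1 ion and to the E428/D421/D79 markers), seven
#: intracellular-gate distances tracking water penetration, plus the ion
#: water-coordination number appended by :func:`feature_series`.
ION_PAIRS = [("Na2", "Na1"), ("Na2", "E428"), ("Na2", "D421"), ("Na2", "D79")]
GATE_PAIRS = [
    ("R60", "Y335"),
    ("R60", "E446"),
    ("R60", "E428"),
    ("R60", "D436"),
    ("Y335", "E428"),
    ("D436", "R445"),
    ("E428", "R445"),
]
TABLE_FEATURES = ION_PAIRS + GATE_PAIRS


@dataclass
class FeatureSeries:
    """A T×d matrix of per-frame feature values with column names."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be (T, d) with one name per column")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class CavityCounts:
    """Per-frame water counts of the five cavity regions of one trajectory."""

    ec_vestibule: np.ndarray
    ec_cavity: np.ndarray
    ic_vestibule: np.ndarray
    ic_channel: np.ndarray
    ic_cavity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ec_cavity > self.ec_vestibule):
            raise ValueError("EC cavity count exceeds EC vestibule count")
        if np.any(self.ic_channel + self.ic_cavity != self.ic_vestibule):
            raise ValueError("IC channel + IC cavity must equal IC vestibule")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "EC_vestibule": self.ec_vestibule,
                "EC_cavity": self.ec_cavity,
                "IC_vestibule": self.ic_vestibule,
                "IC_channel": self.ic_channel,
                "IC_cavity": self.ic_cavity,
            }
        )


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def pair_distances(
    ensemble: FrameEnsemble | FrameTrajectory,
    pairs: list[tuple[str, str]],
) -> list[FeatureSeries]:
    """Euclidean distances (Å) between labeled particles, one column per pair."""
    trajs = ensemble.trajectories if isinstance(ensemble, FrameEnsemble) else [ensemble]
    names = [f"{a}-{b}" for a, b in pairs]
    out = []
    for traj in trajs:
        cols = []
        for a, b in pairs:
            ia, ib = traj.index(a), traj.index(b)
            cols.append(_dist(traj.xyz[:, ia], traj.xyz[:, ib]))
        out.append(FeatureSeries(np.column_stack(cols), list(names)))
    return out


def coordination_number(
    ensemble: FrameEnsemble | FrameTrajectory,
    ion_label: str = "Na2",
    cutoff: float = DEFAULT_COORDINATION_CUTOFF_A,
) -> list[np.ndarray]:
    """Count of water oxygens within ``cutoff`` Å of the ion, per frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    trajs = ensemble.trajectories if isinstance(ensemble, FrameEnsemble) else [ensemble]
    out = []
    for traj in trajs:
        ii = traj.index(ion_label)
        wi = traj.indices_by_role("water")
        if wi.size == 0:
            out.append(np.zeros(traj.n_frames, dtype=int))
            continue
        d = _dist(traj.xyz[:, wi], traj.xyz[:, ii][:, None, :])
        out.append((d <= cutoff).sum(axis=1))
    return out


def feature_series(
    ensemble: FrameEnsemble | FrameTrajectory,
    pairs: list[tuple[str, str]] | None = None,
    ion_label: str = "Na2",
    coordination_cutoff: float = DEFAULT_COORDINATION_CUTOFF_A,
) -> list[FeatureSeries]:
    """The full 12-parameter tICA input set: distances + coordination number."""
    pairs = TABLE_FEATURES if pairs is None else pairs
    dists = pair_distances(ensemble, pairs)
    coords = coordination_number(ensemble, ion_label, coordination_cutoff)
    out = []
    for fs, cn in zip(dists, coords):
        mat = np.column_stack([fs.matrix, cn.astype(float)])
        out.append(FeatureSeries(mat, fs.names + [f"{ion_label}-coordination"]))
    return out


# --------------------------------------------------------------------------
# Cavity assignment
# --------------------------------------------------------------------------


def _water_lipid_ok(frame: Frame, water_idx: np.ndarray, lipid_cutoff: float = 5.0) -> np.ndarray:
    """True for waters not within ``lipid_cutoff`` of any lipid particle."""
    li = frame.indices_by_role("lipid")
    if li.size == 0:
        return np.ones(water_idx.size, dtype=bool)
    d = np.linalg.norm(
        frame.xyz[water_idx][:, None, :] - frame.xyz[li][None, :, :], axis=-1
    )
    return ~np.any(d <= lipid_cutoff, axis=1)


def assign_ec_vestibule(
    frame: Frame,
    f326_label: str = "F326",
    sphere_cutoff: float = 26.0,
    lipid_cutoff: float = 5.0,
    z_above_max: float = 23.0,
) -> set[int]:
    """Water indices in the extracellular vestibule of one frame.

    A water oxygen belongs iff (a) it is within ``sphere_cutoff`` of the F326
    C-beta marker but not within ``lipid_cutoff`` of lipid particles, and (b)
    its z-coordinate exceeds the marker's by no more than ``z_above_max``.
    The z-clause is one-sided: waters far below the marker are only excluded
    if the sphere clause excludes them.
    """
    ref = frame.position(f326_label)
    wi = frame.indices_by_role("water")
    if wi.size == 0:
        return set()
    pos = frame.xyz[wi]
    in_sphere = np.linalg.norm(pos - ref, axis=1) <= sphere_cutoff
    z_ok = (pos[:, 2] - ref[2]) <= z_above_max
    lipid_ok = _water_lipid_ok(frame, wi, lipid_cutoff)
    return set(wi[in_sphere & z_ok & lipid_ok].tolist())


def assign_ec_cavity(
    frame: Frame,
    ec_vestibule_members: set[int],
    ligand_label: str = "DA",
    cutoff: float = 10.0,
) -> set[int]:
    """EC-vestibule waters within ``cutoff`` of the ligand center of mass."""
    ref = frame.position(ligand_label)
    members = np.array(sorted(ec_vestibule_members), dtype=int)
    if members.size == 0:
        return set()
    close = np.linalg.norm(frame.xyz[members] - ref, axis=1) <= cutoff
    return set(members[close].tolist())


def assign_ic_vestibule_and_split(
    frame: Frame,
    ligand_label: str = "DA",
    d436_label: str = "D436",
    t269_labels: tuple[str, ...] = ("T269",),
    ligand_cutoff: float = 15.0,
    lipid_cutoff: float = 5.0,
    z_max: float = 15.5,
    channel_cutoff: float = 12.0,
) -> tuple[set[int], set[int], set[int]]:
    """(IC vestibule, IC channel, IC cavity) water index sets of one frame.

    IC vestibule: within ``ligand_cutoff`` of the ligand center, not within
    ``lipid_cutoff`` of any lipid, and with absolute z-distance to the D436
    C-beta marker not exceeding ``z_max``.  The vestibule is partitioned into
    the IC channel (within ``channel_cutoff`` of any T269 backbone particle)
    and the IC cavity (the remainder).
    """
    lig = frame.position(ligand_label)
    zref = frame.position(d436_label)[2]
    t269 = np.stack([frame.position(lab) for lab in t269_labels])
    wi = frame.indices_by_role("water")
    if wi.size == 0:
        return set(), set(), set()
    pos = frame.xyz[wi]
    near_lig = np.linalg.norm(pos - lig, axis=1) <= ligand_cutoff
    z_ok = np.abs(pos[:, 2] - zref) <= z_max
    lipid_ok = _water_lipid_ok(frame, wi, lipid_cutoff)
    vest_mask = near_lig & z_ok & lipid_ok
    d_t269 = np.linalg.norm(pos[:, None, :] - t269[None, :, :], axis=-1).min(axis=1)
    channel_mask = vest_mask & (d_t269 <= channel_cutoff)
    vest = set(wi[vest_mask].tolist())
    channel = set(wi[channel_mask].tolist())
    cavity = vest - channel
    return vest, channel, cavity


def cavity_counts(
    ensemble: FrameEnsemble | FrameTrajectory, **kwargs
) -> list[CavityCounts]:
    """Per-frame water counts of all five cavity regions for each trajectory."""
    trajs = ensemble.trajectories if isinstance(ensemble, FrameEnsemble) else [ensemble]
    out = []
    for traj in trajs:
        T = traj.n_frames
        ecv = np.zeros(T, dtype=int)
        ecc = np.zeros(T, dtype=int)
        icv = np.zeros(T, dtype=int)
        icc = np.zeros(T, dtype=int)
        ica = np.zeros(T, dtype=int)
        for t in range(T):
            frame = traj.frame(t)
            ec = assign_ec_vestibule(frame)
            ecv[t] = len(ec)
            ecc[t] = len(assign_ec_cavity(frame, ec))
            v, ch, ca = assign_ic_vestibule_and_split(frame)
            icv[t], icc[t], ica[t] = len(v), len(ch), len(ca)
        out.append(CavityCounts(ecv, ecc, icv, icc, ica))
    return out


# --------------------------------------------------------------------------
# Interaction statistics
# --------------------------------------------------------------------------


def interaction_frequency(distance_series: np.ndarray, cutoff: float = 6.0) -> float:
    """Percent of frames in which the distance is within ``cutoff`` Å."""
    d = np.asarray(distance_series, dtype=float)
    if d.size == 0:
        raise ValueError("distance series is empty")
    return 100.0 * float(np.mean(d <= cutoff))


def mediated_contact(
    frame: Frame,
    partner_a_labels: list[str],
    partner_b_label: str,
    mediator_labels: list[str],
    cutoff: float = 6.0,
) -> bool:
    """True iff one mediator particle is within ``cutoff`` of partner B and of
    at least one partner-A particle simultaneously (e.g. the same PIP2 lipid
    bridging an N-terminal Arg/Lys and R443)."""
    b = frame.position(partner_b_label)
    a = np.stack([frame.position(lab) for lab in partner_a_labels])
    for lab in mediator_labels:
        m = frame.position(lab)
        if np.linalg.norm(m - b) <= cutoff and np.any(np.linalg.norm(a - m, axis=1) <= cutoff):
            return True
    return False


def _kplus_indicator(traj: FrameTrajectory, site_label: str, cutoff: float) -> np.ndarray:
    """Per-frame boolean: at least one K+ ion within ``cutoff`` of the site."""
    site = traj.index(site_label)
    k_idx = np.array(
        [i for i, lab in enumerate(traj.labels) if lab.startswith("K+")], dtype=int
    )
    if k_idx.size == 0:
        return np.zeros(traj.n_frames, dtype=bool)
    d = np.linalg.norm(traj.xyz[:, k_idx] - traj.xyz[:, site][:, None, :], axis=-1)
    return np.any(d <= cutoff, axis=1)


def kplus_site_probability(
    ensemble: FrameEnsemble,
    bin_edges: np.ndarray,
    site_label: str = "D79",
    cutoff: float = 7.0,
    ion_pair: tuple[str, str] = ("Na2", "Na1"),
    n_boot: int = 100,
    boot_range: tuple[int, int] = (26, 38),
    seed: int = 0,
) -> pd.DataFrame:
    """Probability of K+ occupancy near a site, binned by the two-sodium distance.

    Frames are binned by the Na2–Na1 distance; each bin's probability is the
    fraction of its frames with at least one K+ ion within ``cutoff`` Å of the
    site marker.  Confidence intervals come from a trajectory-level bootstrap
    (``n_boot`` replicates, each resampling a uniformly drawn number of
    trajectories in ``boot_range`` with replacement); p-values are Welch
    two-sample t-tests on the per-frame indicators of consecutive bins.
    Empty bins are excluded from the table.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    dists = pair_distances(ensemble, [ion_pair])
    per_traj_bin: list[np.ndarray] = []
    per_traj_ind: list[np.ndarray] = []
    for traj, fs in zip(ensemble, dists):
        per_traj_bin.append(np.digitize(fs.matrix[:, 0], edges) - 1)
        per_traj_ind.append(_kplus_indicator(traj, site_label, cutoff))

    def bin_probs(traj_ids: np.ndarray) -> np.ndarray:
        hits = np.zeros(n_bins)
        tot = np.zeros(n_bins)
        for i in traj_ids:
            b, ind = per_traj_bin[i], per_traj_ind[i]
            ok = (b >= 0) & (b < n_bins)
            np.add.at(tot, b[ok], 1.0)
            np.add.at(hits, b[ok], ind[ok].astype(float))
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, hits / np.maximum(tot, 1), np.nan)

    all_ids = np.arange(len(ensemble.trajectories))
    point = bin_probs(all_ids)
    boots = np.full((n_boot, n_bins), np.nan)
    lo, hi = boot_range
    hi = min(hi, len(all_ids)) if len(all_ids) >= lo else len(all_ids)
    for r in range(n_boot):
        size = int(rng.integers(min(lo, len(all_ids)), hi + 1))
        boots[r] = bin_probs(rng.choice(all_ids, size=size, replace=True))

    # per-frame indicator samples per bin, for consecutive-bin t-tests
    samples = [
        np.concatenate(
            [ind[(b == k)] for b, ind in zip(per_traj_bin, per_traj_ind)]
        ).astype(float)
        for k in range(n_bins)
    ]
    rows = []
    prev_k = None
    for k in range(n_bins):
        if samples[k].size == 0:
            continue  # empty bin: flagged by omission
        ci_lo, ci_hi = np.nanpercentile(boots[:, k], [2.5, 97.5])
        pval = np.nan
        if prev_k is not None:
            a, b = samples[prev_k], samples[k]
            if a.size > 1 and b.size > 1 and (a.std() > 0 or b.std() > 0):
                pval = float(ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "bin_low": edges[k],
                "bin_high": edges[k + 1],
                "n_frames": int(samples[k].size),
                "probability": float(point[k]),
                "ci_low": float(ci_lo),
                "ci_high": float(ci_hi),
                "p_vs_previous_bin": pval,
            }
        )
        prev_k = k
    return pd.DataFrame(rows)
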