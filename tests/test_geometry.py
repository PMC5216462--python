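"""Geometric operators against independent brute-force oracles.

Every cavity assignment, coordination count and contact flag is recomputed
here with explicit per-particle loops over the clause definitions, and the
vectorized implementations must agree exactly (integer counts / set members)
or to 1e-10 Å (distances) on random frames.
"""

import math

import numpy as np
import pytest
from scipy import stats

from narelease import geometry
from narelease.frames import FrameEnsemble, FrameTrajectory
from narelease.geometry import (
    assign_ec_cavity,
    assign_ec_vestibule,
    assign_ic_vestibule_and_split,
    coordination_number,
    interaction_frequency,
    kplus_site_probability,
    mediated_contact,
    pair_distances,
)

N_ORACLE_FRAMES = 100


def _tiny_traj(points: dict[str, tuple], roles: dict[str, str]) -> FrameTrajectory:
    labels = list(points)
    xyz = np.array([[points[lab] for lab in labels]], dtype=float)
    return FrameTrajectory(labels=labels, roles=roles, xyz=xyz)


# ---------------------------------------------------------------- distances


def test_pair_distance_345_triangle():
    traj = _tiny_traj({"A": (0, 0, 0), "B": (3, 4, 0)}, {"A": "marker", "B": "marker"})
    fs = pair_distances(traj, [("A", "B")])[0]
    assert fs.matrix[0, 0] == pytest.approx(5.0)
    assert fs.names == ["A-B"]


def test_pair_distance_identical_points_is_zero():
    traj = _tiny_traj({"A": (1, 2, 3), "B": (1, 2, 3)}, {"A": "marker", "B": "marker"})
    assert pair_distances(traj, [("A", "B")])[0].matrix[0, 0] == 0.0


def test_pair_distance_missing_label_named_in_error():
    traj = _tiny_traj({"A": (0, 0, 0)}, {"A": "marker"})
    with pytest.raises(KeyError, match="Zzz"):
        pair_distances(traj, [("A", "Zzz")])


def test_pair_distances_match_double_loop_oracle(random_trajectory_factory):
    rng = np.random.default_rng(0)
    traj = random_trajectory_factory(rng, n_frames=N_ORACLE_FRAMES)
    pairs = [("Na2", "Na1"), ("R60", "D436"), ("E428", "R445")]
    fs = pair_distances(traj, pairs)[0]
    for t in range(traj.n_frames):
        for j, (a, b) in enumerate(pairs):
            pa = traj.xyz[t, traj.index(a)]
            pb = traj.xyz[t, traj.index(b)]
            expect = math.sqrt(sum((pa[k] - pb[k]) ** 2 for k in range(3)))
            assert abs(fs.matrix[t, j] - expect) < 1e-10


# ----------------------------------------------------------- coordination


def test_coordination_number_counts_first_shell():
    pts = {"Na2": (0.0, 0.0, 0.0)}
    roles = {"Na2": "ion"}
    for i in range(4):
        pts[f"W{i}"] = (2.3, 0.0, 0.1 * i)
        roles[f"W{i}"] = "water"
    for i in range(4, 6):
        pts[f"W{i}"] = (5.0, 0.0, 0.0)
        roles[f"W{i}"] = "water"
    traj = _tiny_traj(pts, roles)
    assert coordination_number(traj, "Na2", cutoff=3.5)[0][0] == 4


def test_coordination_number_no_waters_is_zero():
    traj = _tiny_traj({"Na2": (0, 0, 0)}, {"Na2": "ion"})
    assert coordination_number(traj, "Na2")[0][0] == 0


def test_coordination_number_matches_all_pairs_oracle(random_trajectory_factory):
    rng = np.random.default_rng(1)
    traj = random_trajectory_factory(rng, n_frames=N_ORACLE_FRAMES, box=8.0)
    got = coordination_number(traj, "Na2", cutoff=3.5)[0]
    wi = traj.indices_by_role("water")
    for t in range(traj.n_frames):
        ion = traj.xyz[t, traj.index("Na2")]
        expect = sum(
            1 for i in wi if math.dist(traj.xyz[t, i], ion) <= 3.5
        )
        assert got[t] == expect


# ------------------------------------------------------------------ cavities


def _brute_ec_vestibule(frame) -> set[int]:
    ref = frame.position("F326")
    lipids = [frame.xyz[i] for i in frame.indices_by_role("lipid")]
    out = set()
    for i in frame.indices_by_role("water"):
        p = frame.xyz[i]
        if math.dist(p, ref) > 26.0:
            continue
        if any(math.dist(p, l) <= 5.0 for l in lipids):
            continue
        if (p[2] - ref[2]) > 23.0:
            continue
        out.add(int(i))
    return out


def _brute_ic_split(frame):
    lig = frame.position("DA")
    zref = frame.position("D436")[2]
    t269 = frame.position("T269")
    lipids = [frame.xyz[i] for i in frame.indices_by_role("lipid")]
    vest, chan, cav = set(), set(), set()
    for i in frame.indices_by_role("water"):
        p = frame.xyz[i]
        if math.dist(p, lig) > 15.0:
            continue
        if any(math.dist(p, l) <= 5.0 for l in lipids):
            continue
        if abs(p[2] - zref) > 15.5:
            continue
        vest.add(int(i))
        if math.dist(p, t269) <= 12.0:
            chan.add(int(i))
        else:
            cav.add(int(i))
    return vest, chan, cav


def test_ec_vestibule_simple_inclusion_and_sphere_exclusion():
    pts = {"F326": (0, 0, 0), "W0": (0, 0, 10.0), "W1": (0, 0, 30.0)}
    roles = {"F326": "marker", "W0": "water", "W1": "water"}
    traj = _tiny_traj(pts, roles)
    frame = traj.frame(0)
    members = assign_ec_vestibule(frame)
    assert traj.index("W0") in members  # dist 10 <= 26, dz 10 <= 23
    assert traj.index("W1") not in members  # dist 30 > 26


def test_ec_vestibule_z_clause_fires_before_sphere_boundary():
    # water at (10, 0, 24): distance to the marker is sqrt(676) = 26.0, which
    # passes the <= 26 sphere clause, but dz = 24 violates the z clause.
    pts = {"F326": (0.0, 0.0, 0.0), "W0": (10.0, 0.0, 24.0)}
    roles = {"F326": "marker", "W0": "water"}
    frame = _tiny_traj(pts, roles).frame(0)
    assert math.dist(pts["W0"], pts["F326"]) == pytest.approx(26.0)
    assert assign_ec_vestibule(frame) == set()
    # confirm with the clause-by-clause oracle
    assert _brute_ec_vestibule(frame) == set()
    # relaxing only the z clause admits the water, so the z clause is what fires
    assert assign_ec_vestibule(frame, z_above_max=25.0) == {1}


def test_ec_vestibule_missing_marker_raises():
    traj = _tiny_traj({"W0": (0, 0, 0)}, {"W0": "water"})
    with pytest.raises(KeyError, match="F326"):
        assign_ec_vestibule(traj.frame(0))


def test_ec_cavity_ten_angstrom_rule():
    pts = {
        "F326": (0, 0, 0),
        "DA": (0, 0, 3),
        "W0": (0, 0, 12.0),  # 9 from DA -> in cavity
        "W1": (0, 0, 14.5),  # 11.5 from DA -> vestibule only
    }
    roles = {"F326": "marker", "DA": "ligand", "W0": "water", "W1": "water"}
    traj = _tiny_traj(pts, roles)
    frame = traj.frame(0)
    vest = assign_ec_vestibule(frame)
    cav = assign_ec_cavity(frame, vest)
    assert traj.index("W0") in cav and traj.index("W1") not in cav
    assert cav <= vest


def test_ic_split_channel_vs_cavity():
    pts = {
        "DA": (0, 0, 3),
        "D436": (-1, -2, -8),
        "T269": (0, 1, -4),
        "W0": (0, 0, -2),  # 5 from DA, ~2.8 from T269 -> channel
        "W1": (12, 5, -2),  # 13 from DA, ~13 from T269 -> cavity
    }
    roles = {"DA": "ligand", "D436": "marker", "T269": "marker",
             "W0": "water", "W1": "water"}
    traj = _tiny_traj(pts, roles)
    vest, chan, cav = assign_ic_vestibule_and_split(traj.frame(0))
    assert traj.index("W0") in chan
    assert traj.index("W1") in cav
    assert chan | cav == vest and not (chan & cav)


def test_cavity_assignments_match_brute_force_on_random_frames(
    random_trajectory_factory,
):
    rng = np.random.default_rng(2)
    traj = random_trajectory_factory(rng, n_frames=N_ORACLE_FRAMES, box=25.0)
    for t in range(traj.n_frames):
        frame = traj.frame(t)
        ec = assign_ec_vestibule(frame)
        assert ec == _brute_ec_vestibule(frame)
        cav = assign_ec_cavity(frame, ec)
        lig = frame.position("DA")
        assert cav == {i for i in ec if math.dist(frame.xyz[i], lig) <= 10.0}
        vest, chan, icav = assign_ic_vestibule_and_split(frame)
        bv, bc, bca = _brute_ic_split(frame)
        assert (vest, chan, icav) == (bv, bc, bca)
        # partition invariants on every frame
        assert chan | icav == vest and not (chan & icav)


# ----------------------------------------------------------- interactions


def test_interaction_frequency_examples():
    assert interaction_frequency(np.array([3, 7, 5, 8]), cutoff=6) == 50.0
    assert interaction_frequency(np.array([1.0, 2.0]), cutoff=6) == 100.0
    with pytest.raises(ValueError):
        interaction_frequency(np.array([]), cutoff=6)


def test_interaction_frequency_matches_counting_oracle():
    rng = np.random.default_rng(3)
    d = rng.uniform(0, 12, size=500)
    expect = 100.0 * sum(1 for x in d if x <= 6.0) / 500
    assert interaction_frequency(d, cutoff=6.0) == pytest.approx(expect)
    assert 0.0 <= interaction_frequency(d, 6.0) <= 100.0


def test_mediated_contact_examples_and_oracle(random_trajectory_factory):
    pts = {"A0": (0, 0, 0), "B": (8, 0, 0), "M0": (4, 0, 0), "M1": (20, 0, 0)}
    roles = {"A0": "marker", "B": "marker", "M0": "lipid", "M1": "lipid"}
    frame = _tiny_traj(pts, roles).frame(0)
    assert mediated_contact(frame, ["A0"], "B", ["M0"], cutoff=6.0)  # 4 from both
    assert not mediated_contact(frame, ["A0"], "B", ["M1"], cutoff=6.0)
    # mediator near A only
    pts["M0"] = (-4, 0, 0)
    frame = _tiny_traj(pts, roles).frame(0)
    assert not mediated_contact(frame, ["A0"], "B", ["M0"], cutoff=6.0)

    rng = np.random.default_rng(4)
    traj = random_trajectory_factory(rng, n_frames=50, box=12.0)
    lipid_labels = [lab for lab in traj.labels if traj.roles[lab] == "lipid"]
    for t in range(traj.n_frames):
        frame = traj.frame(t)
        got = mediated_contact(frame, ["R60", "K66"], "R445", lipid_labels, cutoff=6.0)
        expect = any(
            math.dist(frame.position(m), frame.position("R445")) <= 6.0
            and (
                math.dist(frame.position(m), frame.position("R60")) <= 6.0
                or math.dist(frame.position(m), frame.position("K66")) <= 6.0
            )
            for m in lipid_labels
        )
        assert got == expect


# ------------------------------------------------------- K+ site statistics


def _kplus_ensemble(p_by_bin, n_frames, seed):
    """Two-trajectory ensemble whose frames sit in prescribed distance bins
    with prescribed K+-occupancy probabilities."""
    rng = np.random.default_rng(seed)
    trajs = []
    for _ in range(4):
        labels = ["Na2", "Na1", "D79", "K+0"]
        roles = {l: ("marker" if l == "D79" else "ion") for l in labels}
        xyz = np.zeros((n_frames, 4, 3))
        xyz[:, 1, 0] = 0.0  # Na1 at origin
        xyz[:, 2] = [20.0, 0.0, 0.0]  # D79
        for t in range(n_frames):
            b = t % len(p_by_bin)
            xyz[t, 0, 0] = 2.0 + 10.0 * b  # Na2-Na1 distance picks the bin
            near = rng.random() < p_by_bin[b]
            xyz[t, 3] = [22.0, 0.0, 0.0] if near else [60.0, 0.0, 0.0]
        trajs.append(FrameTrajectory(labels=labels, roles=roles, xyz=xyz))
    return FrameEnsemble(trajs)


def test_kplus_probability_zero_and_one_limits():
    ens = _kplus_ensemble([0.0, 0.0], 40, seed=0)
    df = kplus_site_probability(ens, bin_edges=[0, 10, 20], n_boot=10,
                                boot_range=(2, 4), seed=0)
    assert (df["probability"] == 0.0).all()
    ens = _kplus_ensemble([1.0, 1.0], 40, seed=0)
    df = kplus_site_probability(ens, bin_edges=[0, 10, 20], n_boot=10,
                                boot_range=(2, 4), seed=0)
    assert (df["probability"] == 1.0).all()


def test_kplus_two_group_difference_detected():
    # closed-form two-proportion oracle: with p=0.1 vs 0.6 at n=200 each the
    # z statistic is ~10 sigma, so Welch's t-test must reject at alpha=0.01
    ens = _kplus_ensemble([0.1, 0.6], 400, seed=5)
    df = kplus_site_probability(ens, bin_edges=[0, 10, 20], n_boot=20,
                                boot_range=(2, 4), seed=1)
    n = df.iloc[0]["n_frames"]
    p1, p2 = df["probability"]
    z = (p2 - p1) / math.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
    assert z > 5
    assert df.iloc[1]["p_vs_previous_bin"] < 0.01
    assert ((0 <= df["probability"]) & (df["probability"] <= 1)).all()
    assert ((df["ci_low"] <= df["probability"] + 1e-12)
            & (df["probability"] <= df["ci_high"] + 1e-12)).all()
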