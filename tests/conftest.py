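import numpy as np
import pytest

from narelease.frames import FrameEnsemble, FrameTrajectory
from narelease import synthetic


@pytest.fixture(scope="session")
def release_ensemble():
    """Small engineered ensemble: 10 trajectories, 3 with ion release."""
    ens, which = synthetic.generate_release_ensemble(
        n_traj=10, n_release=3, n_frames=150, seed=11, stride_ns=2.0
    )
    return ens, which


def random_frame_trajectory(
    rng: np.random.Generator,
    n_frames: int = 1,
    n_waters: int = 30,
    n_lipids: int = 8,
    n_potassium: int = 3,
    box: float = 30.0,
) -> FrameTrajectory:
    """Fully random frames carrying every label the geometry module needs.

    Positions are uniform in a cube, so every cavity clause gets exercised on
    both sides of its cutoff; used for brute-force oracle comparisons.
    """
    labels: list[str] = []
    roles: dict[str, str] = {}
    for m in synthetic.MARKER_LABELS:
        labels.append(m)
        roles[m] = "marker"
    labels.append("DA")
    roles["DA"] = "ligand"
    for ion in ("Na1", "Na2"):
        labels.append(ion)
        roles[ion] = "ion"
    for i in range(n_potassium):
        labels.append(f"K+{i}")
        roles[f"K+{i}"] = "ion"
    for i in range(n_waters):
        labels.append(f"W{i}")
        roles[f"W{i}"] = "water"
    for i in range(n_lipids):
        labels.append(f"L{i}")
        roles[f"L{i}"] = "lipid"
    xyz = rng.uniform(-box, box, size=(n_frames, len(labels), 3))
    return FrameTrajectory(labels=labels, roles=roles, xyz=xyz, stride_ns=1.0)


@pytest.fixture
def random_trajectory_factory():
    return random_frame_trajectory
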