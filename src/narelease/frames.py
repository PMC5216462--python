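"""Labeled coordinate frames for trajectory ensembles.

A :class:`FrameTrajectory` stores one trajectory as a ``(T, N, 3)`` array of
positions (Å) for ``N`` named particles, together with a role for each particle
(``ion``, ``water``, ``lipid``, ``marker`` or ``ligand``).  The z-axis is the
membrane normal with its positive direction toward the extracellular side.
An ensemble is simply a list of such trajectories sharing a time stride (ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = frozenset({"ion", "water", "lipid", "marker", "ligand"})


@dataclass
class Frame:
    """A single frame view: particle labels, roles and an (N, 3) position array."""

    labels: list[str]
    roles: dict[str, str]
    xyz: np.ndarray

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"particle label {label!r} not present in frame") from None

    def position(self, label: str) -> np.ndarray:
        return self.xyz[self.index(label)]

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if self.roles[lab] == role],
            dtype=int,
        )


@dataclass
class FrameTrajectory:
    """One trajectory of labeled 3-D coordinates with a uniform time stride."""

    labels: list[str]
    roles: dict[str, str]
    xyz: np.ndarray  # (T, N, 3), Å
    stride_ns: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (T, N, 3)")
        if self.xyz.shape[1] != len(self.labels):
            raise ValueError("number of labels does not match xyz particle axis")
        if self.stride_ns <= 0:
            raise ValueError("stride_ns must be positive")
        missing = [lab for lab in self.labels if lab not in self.roles]
        if missing:
            raise ValueError(f"labels without a role: {missing[:5]}")
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {sorted(ROLES)}")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"particle label {label!r} not present") from None

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if self.roles[lab] == role],
            dtype=int,
        )

    def frame(self, t: int) -> Frame:
        return Frame(self.labels, self.roles, self.xyz[t])


@dataclass
class FrameEnsemble:
    """A list of trajectories sharing one label set and time stride."""

    trajectories: list[FrameTrajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trajectories:
            strides = {t.stride_ns for t in self.trajectories}
            if len(strides) != 1:
                raise ValueError("all trajectories must share the same stride")

    @property
    def stride_ns(self) -> float:
        return self.trajectories[0].stride_ns

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __getitem__(self, i: int) -> FrameTrajectory:
        return self.trajectories[i]
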