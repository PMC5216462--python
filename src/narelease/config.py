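"""Pipeline configuration: YAML-backed, with lag/stride validation.

All times are nanoseconds; lags are converted to whole frame counts against
the trajectory stride at load time and must divide evenly.  Defaults are the
production settings of the analysis: a 16 ns tICA lag, a 48 ns MSM lag with a
geometric lag ladder for the Markovianity scan, ~100 microstates on the first
2 tICs, 15 macrostates and 7 transition pathways.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input: either a synthetic scenario or a saved ensemble archive
    scenario: str = "three_well"  # three_well | release | ensemble-file path via input_path
    input_path: str | None = None
    output_dir: str = "run"
    seed: int = 0

    # synthetic-ensemble shape
    n_trajectories: int = 50
    n_release: int = 12
    n_frames: int = 500
    stride_ns: float = 2.0
    # three-well scenario shape
    n_steps: int = 20000
    subsample: int = 10

    # featurization
    coordination_cutoff: float = 3.5
    interaction_cutoff: float = 6.0

    # tICA
    tica_lag_ns: float = 16.0
    n_tics: int = 2

    # MSM
    msm_lag_ns: float = 48.0
    n_microstates: int = 100
    lag_ladder_ns: list[float] = field(default_factory=list)
    n_timescales: int = 10
    n_bootstrap: int = 10

    # GMRQ
    gmrq_fraction: float = 0.5
    gmrq_splits: int = 5
    n_tics_grid: list[int] = field(default_factory=lambda: [2, 3])
    k_grid: list[int] = field(default_factory=lambda: [50, 100])

    # TPT
    n_macrostates: int = 15
    n_paths: int = 7
    # source/target selection on tIC 1: absolute thresholds, or quantiles of
    # the frame distribution when source_mode == "quantile"
    source_mode: str = "quantile"
    source_threshold: float = 0.15
    target_threshold: float = 0.85

    # thermodynamics
    n_bins: int = 50
    basin_min_depth: float = 1.0
    block_range_ns: tuple[float, float] = (110.0, 250.0)
    fe_bootstrap: int = 50

    def __post_init__(self) -> None:
        if self.stride_ns <= 0:
            raise ValueError("stride_ns must be positive")
        for name in ("tica_lag_ns", "msm_lag_ns"):
            self._frames_of(getattr(self, name), name)
        if not self.lag_ladder_ns:
            # geometric ladder (in whole frames) up to the production lag
            f = self._frames_of(self.msm_lag_ns, "msm_lag_ns")
            frames = []
            while f >= 1:
                frames.append(f)
                f //= 2
            self.lag_ladder_ns = sorted(round(f * self.stride_ns, 9) for f in frames)
        for l in self.lag_ladder_ns:
            self._frames_of(l, "lag_ladder_ns entry")
        if not 0 <= self.source_threshold < self.target_threshold:
            raise ValueError("source_threshold must be below target_threshold")

    def _frames_of(self, ns: float, name: str) -> int:
        frames = ns / self.stride_ns
        if abs(frames - round(frames)) > 1e-9 or round(frames) < 1:
            raise ValueError(
                f"{name} = {ns} ns is not a positive whole number of frames "
                f"at stride {self.stride_ns} ns"
            )
        return int(round(frames))

    @property
    def tica_lag_frames(self) -> int:
        return self._frames_of(self.tica_lag_ns, "tica_lag_ns")

    @property
    def msm_lag_frames(self) -> int:
        return self._frames_of(self.msm_lag_ns, "msm_lag_ns")

    @property
    def lag_ladder_frames(self) -> list[int]:
        return [self._frames_of(l, "lag_ladder_ns entry") for l in self.lag_ladder_ns]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_range_ns"] = list(self.block_range_ns)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "block_range_ns" in d:
            d["block_range_ns"] = tuple(d["block_range_ns"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
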