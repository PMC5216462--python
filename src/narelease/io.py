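"""Serialization: ensembles and models as array archives with JSON sidecars,
feature tables as delimited text, optional PDB/DCD export through mdtraj."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FrameEnsemble, FrameTrajectory
from .geometry import FeatureSeries
from .msm import MarkovModel
from .tica import TICAModel


def save_ensemble(path: str | Path, ensemble: FrameEnsemble) -> None:
    """Write a frame ensemble to a self-describing .npz archive."""
    path = Path(path)
    arrays = {}
    meta = {"stride_ns": ensemble.stride_ns, "n_traj": len(ensemble.trajectories)}
    labels = ensemble.trajectories[0].labels
    roles = ensemble.trajectories[0].roles
    meta["labels"] = labels
    meta["roles"] = roles
    for i, traj in enumerate(ensemble):
        arrays[f"xyz_{i}"] = traj.xyz
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_ensemble(path: str | Path) -> FrameEnsemble:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        trajs = [
            FrameTrajectory(
                labels=list(meta["labels"]),
                roles=dict(meta["roles"]),
                xyz=data[f"xyz_{i}"],
                stride_ns=float(meta["stride_ns"]),
            )
            for i in range(int(meta["n_traj"]))
        ]
    return FrameEnsemble(trajs)


def save_features(path: str | Path, features: list[FeatureSeries]) -> None:
    """Feature series as one TSV with a header row and a trajectory column."""
    frames = []
    for i, fs in enumerate(features):
        df = fs.to_frame()
        df.insert(0, "trajectory", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def load_features(path: str | Path) -> list[FeatureSeries]:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c != "trajectory"]
    return [
        FeatureSeries(sub[names].to_numpy(dtype=float), list(names))
        for _, sub in df.groupby("trajectory", sort=True)
    ]


def save_tica(path_prefix: str | Path, model: TICAModel) -> None:
    """Binary archive (<prefix>.npz) with a JSON sidecar (<prefix>.json)."""
    prefix = Path(path_prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        mean=model.mean,
        covariance=model.covariance,
        time_lagged_covariance=model.time_lagged_covariance,
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
    )
    sidecar = {
        "lag_frames": model.lag_frames,
        "lag_ns": model.lag_ns,
        "n_selected": model.n_selected,
        "eigenvalues": model.eigenvalues.tolist(),
        "feature_names": model.feature_names,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_tica(path_prefix: str | Path) -> TICAModel:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as data:
        return TICAModel(
            mean=data["mean"],
            covariance=data["covariance"],
            time_lagged_covariance=data["time_lagged_covariance"],
            lag_frames=int(sidecar["lag_frames"]),
            lag_ns=float(sidecar["lag_ns"]),
            eigenvalues=data["eigenvalues"],
            eigenvectors=data["eigenvectors"],
            n_selected=int(sidecar["n_selected"]),
            feature_names=list(sidecar["feature_names"]),
        )


def save_msm(path_prefix: str | Path, model: MarkovModel) -> None:
    prefix = Path(path_prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        count_matrix=model.count_matrix,
        transition_matrix=model.transition_matrix,
        stationary=model.stationary,
        eigenvalues=model.eigenvalues,
        right_eigenvectors=model.right_eigenvectors,
        left_eigenvectors=model.left_eigenvectors,
        active_states=model.active_states,
        centers=model.centers if model.centers is not None else np.zeros((0, 0)),
        **{f"assign_{i}": a for i, a in enumerate(model.assignments)},
    )
    sidecar = {
        "lag_frames": model.lag_frames,
        "lag_ns": model.lag_ns,
        "n_states": model.n_states,
        "n_traj": len(model.assignments),
        "eigenvalues": model.eigenvalues.tolist(),
        "timescales_ns": [None if not np.isfinite(t) else t for t in model.timescales_ns],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_msm(path_prefix: str | Path) -> MarkovModel:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as data:
        centers = data["centers"]
        return MarkovModel(
            centers=None if centers.size == 0 else centers,
            assignments=[data[f"assign_{i}"] for i in range(int(sidecar["n_traj"]))],
            count_matrix=data["count_matrix"],
            transition_matrix=data["transition_matrix"],
            lag_frames=int(sidecar["lag_frames"]),
            lag_ns=float(sidecar["lag_ns"]),
            stationary=data["stationary"],
            eigenvalues=data["eigenvalues"],
            right_eigenvectors=data["right_eigenvectors"],
            left_eigenvectors=data["left_eigenvectors"],
            active_states=data["active_states"],
        )


def export_pdb_dcd(ensemble: FrameEnsemble, out_dir: str | Path, prefix: str = "traj") -> list[Path]:
    """Write each trajectory as PDB topology + DCD coordinates (needs mdtraj).

    Particles become carbon pseudo-atoms in one residue per role, so any
    standard trajectory reader can load the result.
    """
    try:
        import mdtraj as md
        import mdtraj.core.element as elem
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("PDB/DCD export requires the optional mdtraj dependency") from exc
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, traj in enumerate(ensemble):
        top = md.Topology()
        chain = top.add_chain()
        for lab in traj.labels:
            res = top.add_residue(traj.roles[lab][:3].upper(), chain)
            top.add_atom("C", elem.carbon, res)
        t = md.Trajectory(traj.xyz / 10.0, top)  # Å -> nm
        pdb = out_dir / f"{prefix}_{i}.pdb"
        dcd = out_dir / f"{prefix}_{i}.dcd"
        t[0].save_pdb(pdb)
        t.save_dcd(dcd)
        written.extend([pdb, dcd])
    return written


def ensemble_from_mdtraj(
    trajectory_files: list[str | Path],
    topology: str | Path,
    label_atoms: dict[str, int],
    water_atoms: list[int] | None = None,
    lipid_atoms: list[int] | None = None,
    stride_ns: float = 1.0,
    roles: dict[str, str] | None = None,
) -> FrameEnsemble:
    """Adapter from standard MD formats (PDB topology + DCD/XTC frames).

    ``label_atoms`` maps marker/ion/ligand labels to atom indices; water and
    lipid atoms are enumerated separately and auto-labeled.  Coordinates are
    converted from nm to Å.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading MD formats requires the optional mdtraj dependency") from exc
    water_atoms = water_atoms or []
    lipid_atoms = lipid_atoms or []
    labels = list(label_atoms)
    role_map = dict(roles or {})
    for lab in labels:
        role_map.setdefault(lab, "marker")
    wlabels = [f"W{i}" for i in range(len(water_atoms))]
    llabels = [f"L{i}" for i in range(len(lipid_atoms))]
    for lab in wlabels:
        role_map[lab] = "water"
    for lab in llabels:
        role_map[lab] = "lipid"
    sel = list(label_atoms.values()) + list(water_atoms) + list(lipid_atoms)
    trajs = []
    for f in trajectory_files:
        t = md.load(str(f), top=str(topology))
        xyz = t.xyz[:, sel, :] * 10.0  # nm -> Å
        trajs.append(
            FrameTrajectory(
                labels=labels + wlabels + llabels,
                roles=role_map,
                xyz=xyz,
                stride_ns=stride_ns,
            )
        )
    return FrameEnsemble(trajs)
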