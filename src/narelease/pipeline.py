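"""End-to-end orchestration: featurize -> tICA -> MSM -> GMRQ -> TPT -> thermo.

:func:`run_pipeline` drives the whole analysis from a single
:class:`~narelease.config.PipelineConfig`, persisting every stage artifact
(feature tables, model archives, scan tables, flux reports) into a run
directory plus a ``summary.json`` with the headline quantities: the slowest
implied timescale, the free-energy basin table, and the top pathways with
their flux percentages.  Runs are deterministic given the config seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import geometry, io, model_selection, msm as msm_mod, synthetic, thermo, tica as tica_mod, tpt
from .config import PipelineConfig
from .frames import FrameEnsemble

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_fixtures", "select_source_target"]


def _prepare_input(config: PipelineConfig, out: Path):
    """Returns (feature matrices per trajectory, feature names, extras)."""
    extras: dict = {}
    rng_seed = config.seed
    if config.input_path:
        ensemble = io.load_ensemble(config.input_path)
        extras["ensemble"] = ensemble
        feats = geometry.feature_series(ensemble, coordination_cutoff=config.coordination_cutoff)
        names = feats[0].names
        mats = [f.matrix for f in feats]
        io.save_features(out / "features.tsv", feats)
    elif config.scenario == "three_well":
        params = synthetic.ThreeWellParams()
        extras["params"] = params
        trajs = synthetic.simulate_three_well_ensemble(
            params, config.n_trajectories, config.n_steps, rng_seed, subsample=config.subsample
        )
        extras["basin_labels"] = [synthetic.assign_basins(t, params) for t in trajs]
        mats = trajs
        names = ["x", "y"]
    elif config.scenario == "release":
        ensemble, which = synthetic.generate_release_ensemble(
            n_traj=config.n_trajectories,
            n_release=config.n_release,
            n_frames=config.n_frames,
            seed=rng_seed,
            stride_ns=config.stride_ns,
        )
        extras["ensemble"] = ensemble
        extras["true_release"] = which
        feats = geometry.feature_series(ensemble, coordination_cutoff=config.coordination_cutoff)
        names = feats[0].names
        mats = [f.matrix for f in feats]
        io.save_features(out / "features.tsv", feats)
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    return mats, names, extras


def select_source_target(
    model: msm_mod.MarkovModel,
    projections: list[np.ndarray],
    mode: str = "quantile",
    lo: float = 0.15,
    hi: float = 0.85,
    orient_by: list[np.ndarray] | None = None,
) -> tuple[set[int], set[int]]:
    """Source (bound) / target (released) microstate sets from tIC-1 thresholds.

    ``mode='quantile'`` interprets lo/hi as quantiles of the pooled tIC-1
    frame distribution; ``mode='absolute'`` uses them as raw thresholds.
    With ``orient_by`` (a per-trajectory scalar series, e.g. the tagged-ion
    distance), the target is placed on the side where that series is large;
    otherwise the low-tIC-1 side is the source.
    """
    tic1 = np.concatenate([p[:, 0] for p in projections])
    if mode == "quantile":
        t_lo, t_hi = np.quantile(tic1, [lo, hi])
    elif mode == "absolute":
        t_lo, t_hi = lo, hi
    else:
        raise ValueError("mode must be 'quantile' or 'absolute'")
    centers_tic1 = model.centers[model.active_states, 0]
    low = set(np.nonzero(centers_tic1 <= t_lo)[0].tolist())
    high = set(np.nonzero(centers_tic1 >= t_hi)[0].tolist())
    if not low or not high:
        raise ValueError("empty source or target set; loosen the tIC-1 thresholds")
    if orient_by is not None:
        d = np.concatenate([np.asarray(x, dtype=float).ravel() for x in orient_by])
        corr = np.corrcoef(tic1, d)[0, 1]
        if corr > 0:  # large distance (released) lies at high tIC 1
            return low, high
        return high, low
    return low, high


def run_pipeline(config: PipelineConfig, run_gmrq: bool = True) -> dict:
    """Run every stage and write artifacts + summary.json under the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    summary: dict = {"config_hash": config_hash, "scenario": config.scenario}
    stride = config.stride_ns

    stage = "featurize"
    try:
        mats, names, extras = _prepare_input(config, out)
        summary["n_trajectories"] = len(mats)
        summary["n_frames_total"] = int(sum(m.shape[0] for m in mats))
        logger.info("featurize: %d trajectories, %d frames, %d features",
                    len(mats), summary["n_frames_total"], len(names))

        # release bookkeeping (needs the tagged-ion distance feature)
        release_labels = None
        distance_series = None
        if "Na2-Na1" in names:
            j = names.index("Na2-Na1")
            distance_series = [m[:, j] for m in mats]
            rel = thermo.release_summary(distance_series, stride_ns=stride)
            rel.to_csv(out / "release_summary.tsv", sep="\t", index=False)
            release_labels = rel["released"].to_numpy()
            summary["release_counts"] = [
                int(rel.attrs["n_released"]),
                int(rel.attrs["n_not_released"]),
            ]
            summary["fastest_release_ns"] = rel.attrs["fastest_release_ns"]
            summary["slowest_release_ns"] = rel.attrs["slowest_release_ns"]

        stage = "tica"
        n_tics = min(config.n_tics, len(names))
        model_tica = tica_mod.fit_tica(
            mats, config.tica_lag_frames, stride_ns=stride,
            n_selected=n_tics, feature_names=list(names),
        )
        io.save_tica(out / "tica_model", model_tica)
        projections = tica_mod.project(mats, model_tica, n_tics)
        screen = tica_mod.screen_components(
            tica_mod.project(mats, model_tica, min(len(names), 12))
        )
        summary["tica_eigenvalues"] = [round(float(v), 6) for v in model_tica.eigenvalues[:5]]
        summary["tica_recommended_n"] = int(screen["recommended_n"])

        stage = "gmrq"
        if run_gmrq:
            n_frames_min = min(m.shape[0] for m in mats)
            grid_tics = [n for n in config.n_tics_grid if n <= len(names)] or [n_tics]
            grid_k = [k for k in config.k_grid if k < summary["n_frames_total"] // 4]
            all_proj = tica_mod.project(mats, model_tica, max(grid_tics))
            table, best = model_selection.hyperparameter_scan(
                all_proj, grid_tics, grid_k, config.msm_lag_frames,
                fraction=config.gmrq_fraction, n_splits=config.gmrq_splits,
                seed=config.seed, release_labels=release_labels,
            )
            table.to_csv(out / "gmrq_scan.tsv", sep="\t", index=False)
            summary["gmrq_best"] = best
            del n_frames_min

        stage = "msm"
        centers, assignments = msm_mod.cluster_microstates(
            projections, config.n_microstates, seed=config.seed
        )
        scan = msm_mod.implied_timescale_scan(
            assignments, config.lag_ladder_frames, n_modes=config.n_timescales,
            n_boot=config.n_bootstrap, seed=config.seed, stride_ns=stride,
        )
        scan.to_csv(out / "implied_timescales.tsv", sep="\t", index=False)
        model = msm_mod.fit_msm(assignments, config.msm_lag_frames, stride_ns=stride, centers=centers)
        io.save_msm(out / "msm_model", model)
        finite = model.timescales_ns[np.isfinite(model.timescales_ns)]
        summary["slowest_implied_timescale_ns"] = float(finite[0]) if finite.size else None
        summary["implied_timescales_ns"] = [
            None if not np.isfinite(t) else round(float(t), 3)
            for t in model.timescales_ns[: config.n_timescales]
        ]
        summary["timescale_flatness"] = round(float(scan.attrs["flatness"]), 4)
        summary["n_microstates_active"] = int(model.n_states)

        stage = "tpt"
        source, target = select_source_target(
            model, projections, mode=config.source_mode,
            lo=config.source_threshold, hi=config.target_threshold,
            orient_by=distance_series,
        )
        flux = tpt.compute_flux(
            model.transition_matrix, model.stationary, source, target,
            n_paths=config.n_paths,
        )
        flux.path_table().to_csv(out / "micro_paths.tsv", sep="\t", index=False)
        n_macro = min(config.n_macrostates, model.n_states)
        macro_map = tpt.pcca_lump(model.right_eigenvectors, n_macro, pi=model.stationary)
        report = tpt.macro_flux_report(flux, macro_map, n_paths=config.n_paths,
                                       pi=model.stationary)
        report["path_table"].to_csv(out / "macro_paths.tsv", sep="\t", index=False)
        report["net_flux_table"].to_csv(out / "macro_flux.tsv", sep="\t", index=False)
        summary["total_flux"] = float(flux.total_flux)
        summary["n_macrostates"] = int(macro_map.n_macro)
        summary["top_paths"] = [
            {
                "path": [int(s) for s in p],
                "flux": float(f),
                "percent": round(100.0 * f / flux.total_flux, 3) if flux.total_flux > 0 else None,
            }
            for p, f, c in report["paths"]
        ]
        summary["top_paths_cumulative_percent"] = (
            round(100.0 * report["paths"][-1][2], 3) if report["paths"] else 0.0
        )
        macro_of_micro = macro_map.labels

        stage = "thermo"
        if release_labels is not None:
            fe_proj = [p for p, r in zip(projections, release_labels) if r]
        else:
            fe_proj = projections
        tic1 = [p[:, 0] for p in fe_proj]
        n_avail = int(sum(t.size for t in tic1))
        profile = thermo.free_energy_1d(tic1, n_bins=config.n_bins,
                                        min_frames=min(1000, n_avail))
        errs = thermo.block_bootstrap_errors(
            tic1, profile.bin_edges,
            block_range_ns=config.block_range_ns, stride_ns=stride,
            n_boot=config.fe_bootstrap, seed=config.seed,
        )
        profile.errors = errs
        profile.basins = thermo.find_basins(profile, config.basin_min_depth)
        profile.to_frame().to_csv(out / "free_energy.tsv", sep="\t", index=False)
        summary["basins"] = [
            {
                "minimum_tic1": round(b["minimum"], 4),
                "free_energy_kT": round(b["free_energy"], 4),
                "depth_kT": round(b["depth"], 4),
            }
            for b in profile.basins
        ]
        summary["n_basins"] = len(profile.basins)

        # macrostate of each basin minimum (for pathway interpretation)
        if model.centers is not None:
            active_centers = model.centers[model.active_states]
            basin_macros = []
            for b in profile.basins:
                i = int(np.argmin(np.abs(active_centers[:, 0] - b["minimum"])))
                basin_macros.append(int(macro_of_micro[i]))
            summary["basin_macrostates"] = basin_macros
    except Exception:
        (out / "FAILED_STAGE.txt").write_text(stage)
        logger.exception("pipeline halted in stage %s", stage)
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def make_fixtures(scenario: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Small deterministic datasets for tests and documentation.

    Writes a discrete chain ensemble, a three-well diffusion ensemble, and a
    20-frame coordinate toy to ``out_dir``; all well under 10 MB.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    chain = synthetic.default_release_chain()
    dtrajs = synthetic.simulate_chain_ensemble(chain, 10, 2000, seed)
    p = out / "chain_ensemble.npz"
    np.savez_compressed(p, T_true=chain.transition_matrix,
                        **{f"dtraj_{i}": d for i, d in enumerate(dtrajs)})
    paths["chain"] = p

    params = synthetic.ThreeWellParams()
    trajs = synthetic.simulate_three_well_ensemble(params, 5, 5000, seed, subsample=5)
    p = out / "three_well_ensemble.npz"
    np.savez_compressed(p, centers=params.well_centers, depths=params.well_depths,
                        **{f"traj_{i}": t for i, t in enumerate(trajs)})
    paths["three_well"] = p

    toy = synthetic.synthesize_frames(
        "release", 20, seed, release_frame=4, n_waters=50, n_potassium=2, n_lipids=12
    )
    p = out / "coordinate_toy.npz"
    io.save_ensemble(p, toy)
    paths["coordinates"] = p
    return paths
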