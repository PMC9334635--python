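"""Configuration-driven orchestration of the analysis stages.

A run is described by a single flat mapping (typically loaded from YAML):
cavity geometry, a global seed, an output directory and per-stage parameter
blocks.  ``run_pipeline`` executes the selected stages in dependency order,
writes each stage's artifacts into its own subdirectory and returns a
machine-readable report (inputs, outputs, sha256 checksums and the key
statistics of each stage).  Re-running an identical configuration
reproduces all stochastic outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .fields import save_field
from .geometry import make_cavity
from .landscape_dynamics import BDConfig, Trajectory, landscape_from_probability, simulate_bd
from .meanfield import DEFAULT_G, DEFAULT_GRID_SPACING, solve_gsd
from .model_fit import fit_plasmid_model
from .potentials import (
    ExclusionParams,
    KernelParams,
    bin_to_resolution,
    boltzmann_distribution,
    exclusion_potential,
    total_potential,
    wall_potential,
)
from .synthetic_data import (
    TwoBlobConfig,
    make_crowded_variant,
    sample_boltzmann_positions,
    simulate_two_blob_ensemble,
)
from .trajectory_analysis import (
    average_msd,
    contour_profile,
    detect_swaps,
    distribution_edge,
    edge_shift,
    fit_double_exponential,
    fit_exponential_dwell,
    fit_msd_exponent,
    msd_per_axis,
    pole_dwell_times,
    position_histogram,
    separation_series,
    track_movie,
)

__all__ = ["run_pipeline", "load_config", "STAGES"]

STAGES = (
    "generate_two_blobs",
    "generate_plasmid",
    "track",
    "histogram",
    "fit",
    "simulate",
    "dwell",
    "msd",
    "crowding",
)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _kernel_from(block: dict) -> KernelParams:
    return KernelParams(
        family=block.get("family", "exponential"),
        wall_strength=float(block.get("wall_strength", 300.0)),
        decay_range=float(block.get("decay_range", 0.05)),
        epsilon=float(block.get("epsilon", 1.0)),
        sigma=float(block.get("sigma", 0.2)),
    )


def _write_trajectories(path: Path, trajs: list[Trajectory]) -> None:
    rows = []
    for i, t in enumerate(trajs):
        rows.append(pd.DataFrame({
            "t": t.times, "x_um": t.x, "y_um": t.y,
            "clip_id": i, "label": t.label,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _read_trajectories(path: Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("clip_id", sort=True):
        tvals = grp["t"].to_numpy()
        dt = float(tvals[1] - tvals[0])
        out.append(Trajectory(
            positions=grp[["x_um", "y_um"]].to_numpy(),
            frame_interval=dt,
            label=str(grp["label"].iloc[0]) if "label" in grp else str(cid),
        ))
    return out


def run_pipeline(config: dict, base_dir=None) -> dict:
    """Execute the selected stages; return the run report.

    ``config['stages']`` lists the stages to run (dependency order is the
    canonical :data:`STAGES` order).  Stage outputs are both written to
    ``output_dir`` and handed to downstream stages in memory.
    """
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    out_root = Path(base_dir or ".") / config.get("output_dir", "cavity_demix_run")
    out_root.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    cav_block = config.get("cavity", {})
    cavity = make_cavity(
        float(cav_block.get("eccentricity", 0.0)),
        float(cav_block.get("reference_radius_um", 1.0)),
        float(cav_block.get("depth_um", 0.2)),
    )

    report: dict = {"config": config, "stages": {}, "seed": seed}
    ctx: dict = {"cavity": cavity}

    def record(stage: str, outputs: list[Path], stats: dict) -> None:
        report["stages"][stage] = {
            "outputs": {str(p.relative_to(out_root)): _sha256(p) for p in outputs},
            "stats": stats,
        }

    for stage in STAGES:
        if stage not in stages:
            continue
        sdir = out_root / stage
        sdir.mkdir(exist_ok=True)
        block = config.get(stage, {}) or {}
        if stage == "generate_two_blobs":
            tb = TwoBlobConfig(
                cavity=cavity,
                pair_strength=float(block.get("pair_strength", 7.0)),
                pair_range=float(block.get("pair_range", 0.7)),
                wall_kernel=_kernel_from(block.get("kernel", {
                    "wall_strength": 20.0, "decay_range": 0.08})),
                diffusivity=float(block.get("diffusivity", 0.4)),
                time_step=float(block.get("time_step", 2.5e-3)),
                n_frames=int(block.get("n_frames", 2400)),
                frame_interval=float(block.get("frame_interval", 0.05)),
                seed=seed,
            )
            reps = simulate_two_blob_ensemble(tb, int(block.get("n_replicas", 1)))
            ctx["two_blob_pairs"] = reps
            flat = [t for pair in reps for t in pair]
            path = sdir / "trajectories.csv"
            _write_trajectories(path, flat)
            record(stage, [path], {"n_replicas": len(reps), "n_frames": tb.n_frames})

        elif stage == "generate_plasmid":
            density = solve_gsd(
                cavity,
                interaction_strength=float(block.get("interaction_strength", DEFAULT_G)),
                grid_spacing=float(block.get("grid_spacing_um", DEFAULT_GRID_SPACING)),
            )
            kernel = _kernel_from(block.get("kernel", {}))
            exclusion = ExclusionParams(float(block.get("a_coefficient", 1.1e-6)))
            wall = wall_potential(cavity, kernel, template=density)
            u_total = total_potential(exclusion_potential(density, exclusion), wall)
            n = int(block.get("n_positions", 20000))
            pts = sample_boltzmann_positions(u_total, n, seed=seed, cavity=cavity)
            traj = Trajectory(pts, frame_interval=float(block.get("frame_interval", 0.05)),
                              label="plasmid")
            ctx.update(density=density, potential=u_total, plasmid_positions=traj,
                       true_kernel=kernel, true_exclusion=exclusion)
            dpath = sdir / "density.h5"
            upath = sdir / "potential.h5"
            meta = {k: v for k, v in density.meta.items() if np.isscalar(v)}
            save_field(density, dpath, metadata=meta)
            save_field(u_total, upath)
            tpath = sdir / "positions.csv"
            _write_trajectories(tpath, [traj])
            truth = sdir / "ground_truth.json"
            truth.write_text(json.dumps({
                "a_coefficient": exclusion.a_coefficient,
                "kernel": {"family": kernel.family,
                           "wall_strength": kernel.wall_strength,
                           "decay_range": kernel.decay_range},
                "n_positions": n, "seed": seed,
            }, indent=2))
            record(stage, [dpath, upath, tpath, truth],
                   {"lambda": density.meta["lambda"], "n_positions": n})

        elif stage == "track":
            import tifffile
            movie_block = block.get("movies")
            if not movie_block:
                raise ConfigurationError("track stage needs a 'movies' mapping "
                                         "of channel -> TIFF path")
            movies = {ch: tifffile.imread(p) for ch, p in movie_block.items()}
            trajs = track_movie(
                movies,
                pixel_size=float(block.get("pixel_size_um", 0.05)),
                frame_interval=float(block.get("frame_interval", 0.05)),
                origin=tuple(block.get("origin_um", (-1.575, -1.575))),
            )
            ctx["tracked"] = trajs
            path = sdir / "trajectories.csv"
            _write_trajectories(path, list(trajs.values()))
            record(stage, [path], {"channels": list(trajs)})

        elif stage == "histogram":
            trajs = _stage_trajectories(ctx, block, out_root)
            template = ctx.get("density")
            hist = position_histogram(trajs, cavity,
                                      bin_size=float(block.get("bin_size_um", 0.05)),
                                      template=template)
            if template is not None:
                hist = bin_to_resolution(hist, float(block.get("bin_size_um", 0.05)))
            ctx["histogram"] = hist
            path = sdir / "position_histogram.h5"
            save_field(hist, path, metadata=hist.meta)
            record(stage, [path], {"n_positions": hist.meta.get("n_positions")})

        elif stage == "fit":
            if "histogram" not in ctx or "density" not in ctx:
                raise DataError("fit stage requires histogram and generate_plasmid "
                                "(or preloaded fields) upstream")
            fit = fit_plasmid_model(
                ctx["histogram"], cavity, ctx["density"],
                family=block.get("family", "exponential"), seed=seed,
            )
            ctx["fit"] = fit
            path = sdir / "fit_result.json"
            path.write_text(json.dumps({
                "objective": fit.objective,
                "params": {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                           for k, v in fit.params_dict.items()},
                "warning": fit.warning,
                "config": fit.config,
            }, indent=2))
            record(stage, [path], {"objective": fit.objective})

        elif stage == "simulate":
            if "histogram" in ctx:
                prob = ctx["histogram"]
            elif "potential" in ctx:
                prob = boltzmann_distribution(ctx["potential"])
            else:
                raise DataError("simulate stage needs a histogram or potential upstream")
            landscape = landscape_from_probability(
                prob, float(block.get("floor_fraction", 0.5)))
            bd = BDConfig(
                diffusivity=float(block.get("diffusivity", 0.5)),
                time_step=float(block.get("time_step", 4e-4)),
                n_steps=int(block.get("n_steps", 3000)),
                n_clips=int(block.get("n_clips", 250)),
                seed=seed,
            )
            clips = simulate_bd(landscape, cavity, bd)
            ctx["bd_clips"] = clips
            path = sdir / "bd_trajectories.csv"
            _write_trajectories(path, clips)
            record(stage, [path], {"n_clips": len(clips), "n_steps": bd.n_steps})

        elif stage == "dwell":
            stats: dict = {}
            if "two_blob_pairs" in ctx:
                dwells = []
                swaps = 0
                for t1, t2 in ctx["two_blob_pairs"]:
                    ss = separation_series(t1, t2, cavity)
                    st, sw = detect_swaps(ss)
                    dwells.append(st.dwell_samples)
                    swaps += sw
                samples = np.concatenate(dwells) if dwells else np.empty(0)
                stats["swap_count"] = swaps
                stats["n_dwells"] = int(len(samples))
                if len(samples) >= 5:
                    from .trajectory_analysis import DwellTimeStats
                    stats["tau_s"] = fit_exponential_dwell(
                        DwellTimeStats(samples, 0))
            clips = ctx.get("bd_clips")
            if clips:
                all_d = []
                for t in clips:
                    all_d.append(pole_dwell_times(t).dwell_samples)
                samples = np.concatenate(all_d)
                stats["n_pole_dwells"] = int(len(samples))
                if len(samples) >= 20:
                    from .trajectory_analysis import DwellTimeStats
                    tl, tsh, w = fit_double_exponential(DwellTimeStats(samples, 0))
                    stats.update(tau_long_s=tl, tau_short_s=tsh, weight_long=w)
            path = sdir / "dwell_stats.json"
            path.write_text(json.dumps(stats, indent=2))
            record(stage, [path], stats)

        elif stage == "msd":
            clips = ctx.get("bd_clips")
            if not clips:
                clips = _stage_trajectories(ctx, block, out_root)
            decimate = int(block.get("decimate", 2))
            dec = [Trajectory(t.positions[::decimate],
                              t.frame_interval * decimate, t.label)
                   for t in clips]
            max_lag = float(block.get("max_lag_s", 1.0))
            msd = average_msd([msd_per_axis(t, max_lag) for t in dec])
            window = (0.0, float(block.get("window_s", 1.0)))
            a_par, a_perp = fit_msd_exponent(msd, window)
            stats = {"alpha_parallel": a_par, "alpha_perpendicular": a_perp,
                     "n_clips": len(dec)}
            path = sdir / "msd.json"
            path.write_text(json.dumps({
                **stats,
                "lags_s": msd.lags.tolist(),
                "msd_parallel_um2": msd.msd_parallel.tolist(),
                "msd_perpendicular_um2": msd.msd_perpendicular.tolist(),
            }, indent=2))
            record(stage, [path], stats)

        elif stage == "crowding":
            if "density" not in ctx:
                raise DataError("crowding stage requires generate_plasmid upstream")
            density = ctx["density"]
            base_kernel = ctx.get("true_kernel") or _kernel_from(block.get("kernel", {}))
            base_excl = ctx.get("true_exclusion") or ExclusionParams(
                float(block.get("a_coefficient", 1.1e-6)))
            v_phi = float(block.get("crowding_level", 0.063))
            crowd_excl, crowd_kernel = make_crowded_variant(
                base_excl, base_kernel, v_phi,
                c1=float(block.get("c1", 5.0)), c2=float(block.get("c2", 5.0)))
            mode = block.get("mode", "elliptical")
            profiles = {}
            for tag, exc, ker in (("base", base_excl, base_kernel),
                                  ("crowded", crowd_excl, crowd_kernel)):
                wall = wall_potential(cavity, ker, template=density)
                u = total_potential(exclusion_potential(density, exc), wall)
                p = boltzmann_distribution(u)
                profiles[tag] = contour_profile(p, cavity, mode=mode)
            shift = edge_shift(profiles["base"], profiles["crowded"])
            stats = {
                "edge_base": distribution_edge(profiles["base"]),
                "edge_crowded": distribution_edge(profiles["crowded"]),
                "inward_shift_um": shift,
                "crowding_level": v_phi,
                "mode": mode,
            }
            path = sdir / "crowding.json"
            path.write_text(json.dumps(stats, indent=2))
            record(stage, [path], stats)

    rpath = out_root / "report.json"
    rpath.write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_trajectories(ctx: dict, block: dict, out_root: Path) -> list[Trajectory]:
    """Trajectories for a stage: from context, else from a CSV path."""
    if "trajectories_csv" in block:
        return _read_trajectories(Path(block["trajectories_csv"]))
    if "plasmid_positions" in ctx:
        return [ctx["plasmid_positions"]]
    if "two_blob_pairs" in ctx:
        return [t for pair in ctx["two_blob_pairs"] for t in pair]
    if "tracked" in ctx:
        return list(ctx["tracked"].values())
    raise DataError("no trajectories available: run a generator/track stage "
                    "or supply 'trajectories_csv'")
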