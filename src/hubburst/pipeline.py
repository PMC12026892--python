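"""Stage orchestration: ties the analysis modules into file-to-file steps.

Each stage reads standard inputs (movie, label volume, tables), runs one
module, and writes CSV/JSON outputs plus the exact config and seed that
produced them. Nucleus identities are re-derived deterministically from the
nuclear label volume in every stage that needs them, so stages stay
decoupled while agreeing on ids.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bursts as bursts_mod
from . import hubs as hubs_mod
from . import interactions as inter_mod
from . import ms2 as ms2_mod
from . import nuclei as nuclei_mod
from . import report as report_mod
from .config import RunConfig, SimulationConfig
from .io import (
    Movie,
    read_labels,
    read_movie,
    records_to_frame,
    save_config,
    write_labels,
    write_movie,
    write_tables,
)
from .synthetic import simulate_embryo_movie, simulate_traces

log = logging.getLogger(__name__)

__all__ = [
    "run_simulate",
    "run_segment_nuclei",
    "run_detect_hubs",
    "run_track_ms2",
    "run_interactions",
    "run_bursts",
    "run_report",
]


def _echo_config(config, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.json")


def run_simulate(sim: SimulationConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Generate a synthetic movie plus trace-level series and ground truth."""
    out_dir = Path(out_dir)
    _echo_config(sim, out_dir)
    movie_data, truth = simulate_embryo_movie(sim)
    movie = Movie(movie_data, sim.voxel_size_um, sim.frame_interval_s)
    paths = {"movie": write_movie(movie, out_dir / "movie.ome.tif")}
    traces = simulate_traces(sim)
    trace_rows = []
    for i in range(traces.n_nuclei):
        for f, t in enumerate(traces.times_min):
            trace_rows.append(
                dict(nucleus_id=i, frame=f, t_min=t,
                     ms2_intensity=traces.ms2[i, f],
                     hub_intensity=traces.hub_intensity[i, f],
                     hub_present=bool(traces.hub_present[i, f]))
            )
    tables = {
        "traces": pd.DataFrame(trace_rows),
        "truth_hubs": truth.hubs,
        "truth_bursts": truth.bursts,
        "truth_ms2_positions": truth.ms2_positions,
    }
    paths.update(write_tables(tables, out_dir))
    return paths


def _load_movie(cfg: RunConfig, movie_path: str | Path) -> Movie:
    movie = read_movie(
        movie_path, voxel_size_um=cfg.voxel_size_um,
        frame_interval_s=cfg.frame_interval_s,
    )
    if cfg.channel_map != {"tf": 0, "ms2": 1}:
        movie = movie.swap_channels(cfg.channel_map)
    return movie


def _tracks(cfg: RunConfig, labels4d: np.ndarray, voxel_zyx):
    return nuclei_mod.track_nuclei(list(labels4d), voxel_zyx, cfg.nuclei)


def run_segment_nuclei(cfg: RunConfig, movie_path: str | Path,
                       out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    movie = _load_movie(cfg, movie_path)
    vz = movie.frame(0, 0).voxel_size_zyx
    labels4d = np.stack([
        nuclei_mod.segment_nuclei_volume(movie.data[t, 0], cfg.nuclei, vz)
        for t in range(movie.n_frames)
    ])
    paths = {"labels": write_labels(labels4d, out_dir / "nuclei_labels.tif")}
    tracks = _tracks(cfg, labels4d, vz)
    frames = [
        nuclei_mod.nucleus_timeseries(tr, movie.data[:, 0], labels4d)
        for tr in tracks
    ]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    paths.update(write_tables({"nuclei": table}, out_dir))
    return paths


def run_detect_hubs(cfg: RunConfig, movie_path: str | Path,
                    labels_path: str | Path, out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    movie = _load_movie(cfg, movie_path)
    labels4d = read_labels(labels_path)
    vz = movie.frame(0, 0).voxel_size_zyx
    tracks = _tracks(cfg, labels4d, vz)

    hub_labels4d = np.zeros(labels4d.shape, dtype=np.int32)
    all_hubs: List[hubs_mod.HubRegion] = []
    for tr in tracks:
        for f in tr.frames:
            mask = labels4d[f] == tr.labels[f]
            norm = hubs_mod.normalize_nucleus(movie.data[f, 0], mask)
            hl = hubs_mod.detect_hubs(norm, mask, vz, cfg.hub)
            offset = hub_labels4d[f].max()
            hub_labels4d[f][hl > 0] = hl[hl > 0] + offset
            all_hubs.extend(
                hubs_mod.hub_regionprops(hl, norm, vz, frame=f,
                                         nucleus_id=tr.nucleus_id)
            )
    paths = {"hub_labels": write_labels(hub_labels4d, out_dir / "hub_labels.tif")}
    hub_df = records_to_frame(all_hubs)
    paths.update(write_tables({"hubs": hub_df}, out_dir))
    return paths


def run_track_ms2(cfg: RunConfig, movie_path: str | Path,
                  labels_path: str | Path, out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    movie = _load_movie(cfg, movie_path)
    labels4d = read_labels(labels_path)
    vz = movie.frame(0, 0).voxel_size_zyx
    tracks = _tracks(cfg, labels4d, vz)
    dt_min = cfg.frame_interval_min

    frames = []
    for tr in tracks:
        selections = []
        for f in range(movie.n_frames):
            if not tr.covers(f):
                selections.append(None)
                continue
            mask = labels4d[f] == tr.labels[f]
            cands = ms2_mod.detect_ms2_candidates(
                movie.data[f, 1], mask, vz, cfg.ms2
            )
            selections.append(ms2_mod.select_locus_spot(cands))
        if not any(s is not None for s in selections):
            log.info("nucleus %d: no MS2 detections", tr.nucleus_id)
            continue
        raw = ms2_mod.track_ms2(selections, cfg.ms2)
        filled = ms2_mod.fill_track(raw, tr, cfg.ms2)
        frames.append(filled.to_frame(dt_min))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["nucleus_id", "frame", "t_min", "z_um", "y_um", "x_um",
                 "intensity", "status"]
    )
    return write_tables({"ms2_tracks": table}, out_dir)


def run_interactions(cfg: RunConfig, movie_path: str | Path,
                     labels_path: str | Path, hub_labels_path: str | Path,
                     ms2_table_path: str | Path,
                     out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    movie = _load_movie(cfg, movie_path)
    labels4d = read_labels(labels_path)
    hub_labels4d = read_labels(hub_labels_path)
    ms2_table = pd.read_csv(ms2_table_path)
    vz = movie.frame(0, 0).voxel_size_zyx
    tracks = {t.nucleus_id: t for t in _tracks(cfg, labels4d, vz)}
    dt_min = cfg.frame_interval_min

    records: List[inter_mod.InteractionRecord] = []
    for (nid,), grp in ms2_table.groupby(["nucleus_id"]):
        tr = tracks.get(nid)
        if tr is None:
            continue
        for _, row in grp.iterrows():
            f = int(row["frame"])
            if not tr.covers(f):
                continue
            mask = labels4d[f] == tr.labels[f]
            norm = hubs_mod.normalize_nucleus(movie.data[f, 0], mask)
            pos = np.array([row["z_um"], row["y_um"], row["x_um"]])
            records.append(
                inter_mod.sphere_metrics(
                    norm, hub_labels4d[f], pos, vz, frame=f,
                    frame_interval_min=dt_min, nucleus_id=int(nid),
                    radius_um=cfg.interaction.radius_um,
                )
            )
    runs: List[inter_mod.InteractionRun] = []
    for nid in sorted({r.nucleus_id for r in records}):
        recs = [r for r in records if r.nucleus_id == nid]
        runs.extend(
            inter_mod.extract_runs(recs, dt_min, cfg.interaction.gap_tolerance)
        )
    mixture_payload = {"fitted": False}
    if len(runs) >= cfg.interaction.n_mixture_components:
        fit = inter_mod.fit_dwell_mixture(
            [r.duration_min for r in runs], seed=cfg.seed,
            n_components=cfg.interaction.n_mixture_components,
        )
        runs = inter_mod.classify_runs(runs, fit)
        mixture_payload = {
            "fitted": True,
            "weights": fit.weights.tolist(),
            "means_min": fit.means_min.tolist(),
            "sds_min": fit.sds_min.tolist(),
            "converged": fit.converged,
            "degenerate": fit.degenerate,
            "seed": fit.seed,
        }
    paths = write_tables(
        {
            "interactions": records_to_frame(records),
            "runs": records_to_frame(runs),
        },
        out_dir,
    )
    mpath = Path(out_dir) / "mixture.json"
    mpath.write_text(json.dumps(mixture_payload, indent=2, sort_keys=True))
    paths["mixture"] = mpath
    return paths


def run_bursts(cfg: RunConfig, ms2_table_path: str | Path,
               interactions_path: str | Path,
               out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    ms2_table = pd.read_csv(ms2_table_path)
    inter_table = pd.read_csv(interactions_path)
    dt_min = cfg.frame_interval_min

    all_bursts: List[bursts_mod.Burst] = []
    all_links: List[bursts_mod.BurstHubLink] = []
    cc_rows = []
    stats_payload: Dict[str, dict] = {}
    for (nid,), grp in ms2_table.groupby(["nucleus_id"]):
        grp = grp.sort_values("frame")
        col = "intensity_corrected" if "intensity_corrected" in grp.columns else "intensity"
        trace = grp[col].fillna(0.0).clip(lower=0.0).to_numpy()
        if len(trace) < 5:
            continue
        found = bursts_mod.call_bursts(trace, dt_min, cfg.burst, nucleus_id=int(nid))
        # burst frames index into the trace; map back to movie frames
        frame_offset = int(grp["frame"].iloc[0])
        found = [
            dataclasses.replace(
                b,
                start_frame=b.start_frame + frame_offset,
                peak_frame=b.peak_frame + frame_offset,
                end_frame=b.end_frame + frame_offset,
                start_min=(b.start_frame + frame_offset) * dt_min,
                end_min=(b.end_frame + frame_offset) * dt_min,
            )
            for b in found
        ]
        all_bursts.extend(found)

        recs = _records_from_table(inter_table, int(nid), dt_min)
        if recs and found:
            all_links.extend(
                bursts_mod.link_bursts_to_hubs(found, recs, dt_min, mode="any")
            )
        # cross-correlation between MS2 and sphere mean intensity
        if recs:
            rec_frames = {r.frame: r for r in recs}
            common = [f for f in grp["frame"] if f in rec_frames]
            if len(common) >= 10:
                ms2_v = grp.set_index("frame").loc[common, "intensity"].fillna(0.0)
                hub_v = np.array(
                    [rec_frames[f].sphere_mean_intensity for f in common]
                )
                res = bursts_mod.cross_correlate(
                    ms2_v.to_numpy(), hub_v, dt_min,
                    max_lag_min=cfg.burst.max_lag_min,
                    smooth_sigma_frames=cfg.burst.cc_smooth_sigma_frames,
                )
                if res is not None:
                    for lag, val in zip(res.lags_min, res.values):
                        cc_rows.append(
                            dict(nucleus_id=int(nid), lag_min=lag, value=val,
                                 peak_lag_min=res.peak_lag_min)
                        )

    bursts_df = records_to_frame(all_bursts)
    links_df = records_to_frame(all_links)
    if len(bursts_df) and len(links_df):
        joined = bursts_df.merge(
            links_df, left_on=["nucleus_id", "index"],
            right_on=["nucleus_id", "burst_index"],
        )
        present = joined[joined["hub_present_at_start"]]
        absent = joined[~joined["hub_present_at_start"]]
        if len(present) >= 2 and len(absent) >= 2:
            for param in ("amplitude", "loading_rate_per_min", "output",
                          "duration_min"):
                gs = bursts_mod.group_compare(present[param], absent[param])
                stats_payload[f"{param}_by_hub_presence"] = dataclasses.asdict(gs)
        if len(present) >= 3:
            for pred in ("dwell_after_min", "pre_burst_intensity"):
                fits = bursts_mod.correlate_burst_params(present, pred)
                for param, fit in fits.items():
                    stats_payload[f"{param}_vs_{pred}"] = dataclasses.asdict(fit)

    paths = write_tables(
        {
            "bursts": bursts_df,
            "burst_hub_links": links_df,
            "cross_correlation": pd.DataFrame(cc_rows),
        },
        out_dir,
    )
    spath = Path(out_dir) / "stats.json"
    spath.write_text(json.dumps(stats_payload, indent=2, sort_keys=True))
    paths["stats"] = spath
    return paths


def _records_from_table(table: pd.DataFrame, nucleus_id: int, dt_min: float):
    recs = []
    sel = table[table["nucleus_id"] == nucleus_id] if len(table) else table
    for _, row in sel.iterrows():
        recs.append(
            inter_mod.InteractionRecord(
                nucleus_id=nucleus_id,
                frame=int(row["frame"]),
                time_min=float(row["time_min"]),
                sphere_mean_intensity=float(row["sphere_mean_intensity"]),
                overlap_volume_um3=float(row["overlap_volume_um3"]),
                overlap_mean_intensity=float(row["overlap_mean_intensity"]),
                hub_present=bool(row["hub_present"]),
                high_hub_present=bool(row.get("high_hub_present", False)),
                truncated=bool(row.get("truncated", False)),
            )
        )
    return sorted(recs, key=lambda r: r.frame)


def run_report(cfg: RunConfig, tables_dir: str | Path,
               out_dir: str | Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    _echo_config(cfg, out_dir)
    tables_dir = Path(tables_dir)
    tables: Dict[str, pd.DataFrame] = {}
    survival = None

    runs_path = tables_dir / "runs.csv"
    if runs_path.exists():
        runs = pd.read_csv(runs_path)
        if len(runs):
            grid, surv = inter_mod.survival_curve(runs["duration_min"])
            survival = (grid, surv)
            tables["runs_summary"] = (
                runs.groupby("dwell_class")["duration_min"]
                .agg(["mean", "std", "count"])
                .reset_index()
                if "dwell_class" in runs.columns
                else pd.DataFrame()
            )
    inter_path = tables_dir / "interactions.csv"
    if inter_path.exists():
        inter = pd.read_csv(inter_path)
        if len(inter):
            tables["interaction_timecourse"] = report_mod.aggregate(
                inter.assign(embryo_id=0),
                value_cols=["sphere_mean_intensity", "overlap_volume_um3"],
                group_cols=("frame",),
            )
    bursts_path = tables_dir / "bursts.csv"
    if bursts_path.exists():
        tables["bursts"] = pd.read_csv(bursts_path)

    return report_mod.render_report(
        tables, out_dir, cfg_hash=report_mod.config_hash(cfg), survival=survival
    )
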