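"""End-to-end pipeline runs: simulate -> track -> analyze.

Every run is driven by a :class:`centrotrack.config.RunConfig`; outputs carry
the config checksum in a manifest (with per-file SHA-256 checksums) so two
runs with the same config and seed are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from centrotrack import io as ctio
from centrotrack import kinematics, linker, simgen, spots
from centrotrack.config import RunConfig

log = logging.getLogger("centrotrack")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, files: list[Path]) -> Path:
    manifest = {
        "config_checksum": cfg.checksum(),
        "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _pair_params(cfg: RunConfig, i: int, cluster: bool) -> simgen.MotionParams:
    sim = cfg.simulate
    return simgen.MotionParams(
        mean_separation_search=(sim.mean_separation_clustering if cluster
                                else sim.mean_separation_search),
        sd_search=sim.sd_search,
        reversion_time=sim.reversion_time,
        onset_separation=sim.onset_separation,
        motorized_duration=sim.motorized_duration,
        final_separation=sim.final_separation,
        frame_interval=sim.frame_interval,
        n_frames=sim.n_frames,
        cluster=cluster,
        seed=cfg.seed * 100003 + i)


def run_simulate(cfg: RunConfig) -> dict:
    """Generate pair trajectories (and optionally image stacks) with truth."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulate
    files: list[Path] = []
    n_clustering = int(round(sim.n_pairs * sim.fraction_clustering))
    truths = {}
    for i in range(sim.n_pairs):
        cluster = i < n_clustering
        params = _pair_params(cfg, i, cluster)
        truth = simgen.simulate_pair(params)
        pid = f"pair{i:03d}"
        truths[pid] = truth
        csv = out / f"{pid}_truth.csv"
        side = out / f"{pid}_truth.json"
        ctio.write_truth_csv(csv, truth)
        ctio.write_truth_sidecar(side, truth)
        files += [csv, side]
        if sim.render_images:
            optics = simgen.OpticsParams(
                pixel_size_xy=sim.pixel_size_xy, z_spacing=sim.z_spacing,
                n_z=sim.n_z, n_y=sim.n_y, n_x=sim.n_x,
                noise_model=sim.noise_model,
                spot_amplitude=sim.spot_amplitude, background=sim.background,
                seed=cfg.seed * 100003 + i)
            stack = simgen.render_stack(truth, optics)
            tif = out / f"{pid}.ome.tif"
            ctio.write_stack(tif, stack)
            files.append(tif)
    manifest = _write_manifest(out, cfg, files)
    log.info("simulated %d pairs into %s", sim.n_pairs, out)
    return {"truths": truths, "manifest": manifest, "files": files}


def track_stack(stack: spots.ImageStack, cfg: RunConfig,
                seeds_by_frame: dict | None = None) -> list[linker.Trajectory]:
    """Detect, propagate and link one stack into trajectories."""
    tc = cfg.track
    gate = linker.mask_radius(stack.frame_interval, tc.mean_speed_um_s)
    log.info("gate radius: %.3f µm", gate)
    anchors = list(range(0, stack.n_frames, tc.anchor_spacing))
    plan = linker.build_plan(anchors, stack.n_frames)
    spots_by_frame: dict[int, list[spots.SpotObservation]] = {}
    # anchor detections
    for a in anchors:
        if seeds_by_frame and a in seeds_by_frame:
            centers = spots.seed_anchor(stack, a, mode="provided",
                                        seeds=seeds_by_frame[a])
        else:
            centers = spots.seed_anchor(stack, a, mode="auto")
        spots_by_frame[a] = [
            spots.fit_gaussian_3d(stack, a, c, source="anchor-seed")
            for c in centers]
    # propagated detections, in plan order
    for frame in plan.processing_order():
        if frame in anchors:
            continue
        src = plan.source_of[frame]
        found = []
        for o in spots_by_frame.get(src, []):
            c = spots.detect_in_mask(stack, frame, o.center, gate)
            if c is not None:
                found.append(spots.fit_gaussian_3d(stack, frame, c))
        spots_by_frame[frame] = found
    return linker.link(spots_by_frame, plan, gate, max_gap=tc.max_gap)


def run_track(cfg: RunConfig, stack_paths=None) -> dict:
    """Track every stack in the run directory into trajectory CSVs."""
    out = Path(cfg.out_dir)
    if stack_paths is None:
        stack_paths = sorted(out.glob("*.ome.tif"))
    files = []
    results = {}
    for path in stack_paths:
        stack = ctio.read_stack(path)
        seeds_csv = path.with_suffix("").with_suffix(".seeds.csv")
        seeds = ctio.read_seeds_csv(seeds_csv) if seeds_csv.exists() else None
        tracks = track_stack(stack, cfg, seeds)
        name = path.name.replace(".ome.tif", "")
        traj_csv = out / f"{name}_trajectories.csv"
        ctio.write_trajectories_csv(traj_csv, tracks, stack.frame_interval)
        files.append(traj_csv)
        results[name] = tracks
        if not tracks:
            log.warning("no trajectories in %s", path.name)
    plan_json = out / "track_plan.json"
    gate = linker.mask_radius(cfg.track.frame_interval,
                              cfg.track.mean_speed_um_s)
    plan_json.write_text(json.dumps({
        "gate_radius_um": gate,
        "anchor_spacing": cfg.track.anchor_spacing,
        "config_checksum": cfg.checksum()}, indent=2))
    files.append(plan_json)
    return {"trajectories": results, "files": files}


def analyze_pairs(series_list, cfg: RunConfig, out: Path) -> dict:
    """Completion, segmentation, MSD, aligned stats and histograms."""
    ac = cfg.analyze
    labels, summary = kinematics.classify_pairs(
        series_list, ac.d_clustered, ac.stability_window, ac.stability_sd)
    segs = []
    for s in series_list:
        c = summary["completions"][s.pair_id]
        if c is None or c < 3:
            segs.append(None)
            continue
        try:
            segs.append(kinematics.segment_phases(s, c))
        except ValueError:
            segs.append(None)
    rows = []
    for s, seg in zip(series_list, segs):
        c = summary["completions"][s.pair_id]
        rows.append({
            "pair_id": s.pair_id,
            "label": labels[s.pair_id],
            "completion_frame": c,
            "motorized_onset_frame": (seg.motorized_onset_frame
                                      if seg else None),
            "motorized_speed_um_s": (seg.motorized_speed_um_s if seg else None),
            "onset_separation_um": (seg.onset_separation_um if seg else None),
        })
    seg_csv = out / "segmentation.csv"
    pd.DataFrame(rows).to_csv(seg_csv, index=False)

    curve = kinematics.msd(series_list,
                           phase=("search" if ac.msd_phase == "search" else "all"),
                           segmentations=segs)
    msd_csv = out / "msd.csv"
    pd.DataFrame({"lag_s": curve.lag_s, "msd_um2": curve.msd,
                  "n": curve.n_contributing}).to_csv(msd_csv, index=False)

    aligned_csv = out / "aligned_stats.csv"
    with_event = [s for s in series_list if s.anaphase_onset_frame is not None]
    if with_event:
        stats = kinematics.align_population(with_event, "anaphase_onset")
        pd.DataFrame({"aligned_time_s": stats.aligned_time_s,
                      "mean_d_um": stats.mean_d, "sd_d_um": stats.sd_d,
                      "n": stats.n}).to_csv(aligned_csv, index=False)

    edges, counts, median, sem = kinematics.phase_histogram(
        series_list, segs, bin_width=ac.histogram_bin_um,
        n_boot=ac.bootstrap_resamples, seed=cfg.seed)
    hist_csv = out / "search_histogram.csv"
    pd.DataFrame({"bin_left_um": edges[:-1], "bin_right_um": edges[1:],
                  "count": counts}).to_csv(hist_csv, index=False)
    return {
        "labels": labels, "summary": summary, "segmentations": segs,
        "median_search_d_um": median, "sem_median_um": sem,
        "files": [seg_csv, msd_csv, aligned_csv, hist_csv],
    }


def run_analyze(cfg: RunConfig) -> dict:
    """Analyze the tracked/simulated pairs found in the run directory."""
    out = Path(cfg.out_dir)
    series_list = []
    for side in sorted(out.glob("pair*_truth.json")):
        meta = json.loads(side.read_text())
        csv = side.with_name(side.name.replace(".json", ".csv"))
        df = pd.read_csv(csv)
        pid = side.name.split("_")[0]
        pos = df.pivot_table(index="frame", columns="centrosome_id",
                             values=["x_um", "y_um", "z_um"]).to_numpy()
        a, b = pos[:, ::2], pos[:, 1::2]
        d = np.linalg.norm(a - b, axis=1)
        series_list.append(kinematics.SeparationSeries(
            pair_id=pid,
            time_s=np.arange(len(d)) * meta["frame_interval_s"],
            d=d,
            anaphase_onset_frame=meta["anaphase_onset_frame"]))
    if not series_list:
        log.warning("no pair tables found in %s; nothing to analyze", out)
        return {"files": []}
    result = analyze_pairs(series_list, cfg, out)
    audit = out / "analyze_audit.json"
    audit.write_text(json.dumps({
        "config_checksum": cfg.checksum(),
        "parameters": cfg.analyze.model_dump(),
        "n_pairs": len(series_list)}, indent=2))
    result["files"].append(audit)
    return result
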