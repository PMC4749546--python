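"""End-to-end orchestration: simulate → render → segment → track → classify,
plus spatial and activity stages, under one seeded configuration.

A run is a pure function of its configuration: every stochastic stage
receives a seed derived deterministically from the global seed, and the
report is serialized with sorted keys so identical configs give bit-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .activity import (compute_dff, detect_events, event_frequency,
                       peri_event_motility, delta_speed)
from .motility import classify_motility, link_tracks, segment_runs_pauses, LinkParams
from .segmentation import make_dendrite_mask, skeletonize_mask
from .skeleton import write_swc
from .spatial import (monte_carlo_null, branch_distance_profile,
                      enrichment_at_branch)
from .synthetic import (ArborParams, PlacementParams, MotilityParams,
                        CalciumParams, RenderParams, generate_arbor,
                        place_organelles, simulate_tracks, simulate_calcium,
                        render_movie)
from .synthetic.render import render_path_still
from .tracks import TrackSet

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str, name: str = "") -> int:
    """Deterministic per-stage seed below 2**31."""
    tag = zlib.crc32(f"{stage}/{name}".encode())
    return int((global_seed * 2654435761 + tag) % (2 ** 31 - 1))


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages in dependency order.

    Configuration sections (all optional except ``seed``): ``simulate``
    (arbor/placement/motility conditions/render), ``segment``, ``track``,
    ``motility``, ``spatial``, ``activity``.  Writes intermediate artifacts
    and ``report.json`` to ``out_dir``; returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"version": __version__, "config_hash": config_hash(config),
                    "seed": seed, "stages": {}}

    state: dict = {}

    # ------------------------------------------------------------- simulate
    if "simulate" in config:
        sim = config["simulate"] or {}
        arbor_params = ArborParams(**{**sim.get("arbor", {}),
                                      "seed": stage_seed(seed, "arbor")})
        skeleton = generate_arbor(arbor_params)
        write_swc(skeleton, out / "skeleton.swc")
        placement = PlacementParams(**{**sim.get("placement", {}),
                                       "seed": stage_seed(seed, "placement")})
        truth = place_organelles(skeleton, placement)
        state["skeleton"] = skeleton
        state["placement_truth"] = truth
        pd.DataFrame({"segment": truth.synapses.segment,
                      "offset_um": truth.synapses.offset}).to_csv(
            out / "synapses.csv", index=False)
        pd.DataFrame({"segment": truth.mitochondria.segment,
                      "offset_um": truth.mitochondria.offset}).to_csv(
            out / "mitochondria.csv", index=False)

        path_length = float(sim.get("path_length_um", 50.0))
        n_org = int(sim.get("n_organelles", 8))
        conditions = sim.get("conditions", {"default": {}})
        state["conditions"] = {}
        for name, overrides in conditions.items():
            mp = MotilityParams(**{**sim.get("motility", {}), **overrides,
                                   "seed": stage_seed(seed, "motility", name)})
            tracks, mtruth = simulate_tracks(path_length, mp, n_organelles=n_org)
            tracks.to_csv(out / f"tracks_truth_{name}.csv")
            cond = {"tracks_truth": tracks, "motility_truth": mtruth,
                    "params": mp}
            if sim.get("render") is not None:
                rcfg = {k: tuple(v) if isinstance(v, list) else v
                        for k, v in (sim.get("render") or {}).items()}
                rp = RenderParams(**{**rcfg, "seed": stage_seed(seed, "render", name)})
                polyline = np.array([[0.0, 0.0], [path_length, 0.0]])
                movie, rel_path = render_movie(tracks, polyline, rp)
                io.save_movie(movie, out / f"movie_{name}.tif")
                still = render_path_still(polyline, rp)
                io.save_stack(still, out / f"path_still_{name}.tif")
                np.savetxt(out / f"path_{name}.csv", rel_path, delimiter=",",
                           header="x_um,y_um", comments="")
                cond.update(movie=movie, still=still, rel_path=rel_path)
            state["conditions"][name] = cond
        report["stages"]["simulate"] = {
            "total_length_um": skeleton.total_length,
            "n_branch_points": int(len(skeleton.branch_points)),
            "n_synapses": int(len(truth.synapses)),
            "n_mitochondria": int(len(truth.mitochondria)),
            "conditions": sorted(conditions)}

    # -------------------------------------------------------------- segment
    if "segment" in config:
        if "conditions" not in state or not any(
                "movie" in c for c in state["conditions"].values()):
            raise PipelineError("segment stage needs rendered movies: "
                                "enable simulate.render (producer: simulate)")
        seg_summary = {}
        for name, cond in state["conditions"].items():
            if "still" not in cond:
                continue
            mask = make_dendrite_mask(cond["still"],
                                      **(config.get("segment") or {}))
            sk = skeletonize_mask(mask)
            cond["segmented_skeleton"] = sk
            seg_summary[name] = {"mask_voxels": mask.n_voxels,
                                 "skeleton_length_um": sk.total_length}
        report["stages"]["segment"] = seg_summary

    # ---------------------------------------------------------------- track
    if "track" in config:
        if "conditions" not in state:
            raise PipelineError("track stage needs movies (producer: simulate)")
        link = LinkParams(**(config.get("track") or {}))
        for name, cond in state["conditions"].items():
            if "movie" not in cond:
                raise PipelineError(
                    f"track stage: no movie for condition {name!r} "
                    "(producer: simulate.render)")
            sk = cond.get("segmented_skeleton")
            if sk is not None:
                nodes = sk.longest_path()
                path = sk.positions[nodes][:, :2]
            else:
                path = cond["rel_path"]
            cond["tracks_linked"] = link_tracks(cond["movie"], path, link)
            cond["tracks_linked"].to_csv(out / f"tracks_linked_{name}.csv")
        report["stages"]["track"] = {
            name: {"n_tracks": cond["tracks_linked"].n_organelles}
            for name, cond in state["conditions"].items()}

    # ------------------------------------------------------------- motility
    if "motility" in config:
        if "conditions" not in state:
            raise PipelineError("motility stage needs tracks (producer: simulate)")
        mcfg = config.get("motility") or {}
        source = mcfg.get("source", "truth")
        window = float(mcfg.get("window", 60.0))
        thr = float(mcfg.get("move_threshold", 0.4))
        mot_summary = {}
        for name, cond in state["conditions"].items():
            key = "tracks_linked" if source == "linker" else "tracks_truth"
            if key not in cond:
                raise PipelineError(f"motility stage: missing {key} for "
                                    f"{name!r} (producer: track)")
            tracks: TrackSet = cond[key]
            stats = classify_motility(tracks, window=window, move_threshold=thr)
            runs, pauses, spds = [], [], []
            for i in range(tracks.n_organelles):
                rp = segment_runs_pauses(tracks.positions[i], tracks.frame_interval)
                if len(rp.run_durations):
                    runs.extend(rp.run_durations)
                    pauses.extend(rp.pause_durations)
                    spds.extend(rp.run_speeds)
            mot_summary[name] = _round({
                **stats.summary(), "source": source,
                "mean_run_duration_s": float(np.mean(runs)) if runs else None,
                "mean_pause_duration_s": float(np.mean(pauses)) if pauses else None,
                "mean_run_speed_um_s": float(np.mean(spds)) if spds else None})
        report["stages"]["motility"] = mot_summary

    # -------------------------------------------------------------- spatial
    if "spatial" in config:
        if "placement_truth" not in state:
            raise PipelineError("spatial stage needs a skeleton and point sets "
                                "(producer: simulate)")
        scfg = config.get("spatial") or {}
        truth = state["placement_truth"]
        res = monte_carlo_null(truth.synapses, truth.mitochondria,
                               state["skeleton"],
                               n_iterations=int(scfg.get("n_iterations", 1000)),
                               seed=stage_seed(seed, "spatial"))
        io.nnd_to_json(res, out / "nnd.json")
        prof = branch_distance_profile(truth.mitochondria, state["skeleton"],
                                       bin_width=float(scfg.get("bin_width", 1.0)),
                                       max_distance=float(scfg.get("max_distance", 10.0)))
        io.profile_to_csv(prof, out / "branch_profile.csv")
        report["stages"]["spatial"] = _round({
            **res.summary(), "branch_enrichment_fold": enrichment_at_branch(prof)})

    # ------------------------------------------------------------- activity
    if "activity" in config:
        if "conditions" not in state:
            raise PipelineError("activity stage needs tracks (producer: simulate)")
        acfg = config.get("activity") or {}
        name = sorted(state["conditions"])[0]
        tracks = state["conditions"][name]["tracks_truth"]
        cp = CalciumParams(**{**acfg.get("calcium", {}),
                              "seed": stage_seed(seed, "calcium")})
        traces, mod_tracks, ca_truth = simulate_calcium(cp, tracks)
        dffs = [compute_dff(t) for t in traces]
        events = [detect_events(t) for t in dffs]
        freqs = [event_frequency(e, t.duration) for e, t in zip(events, dffs)]
        onsets = np.unique(np.concatenate([e.onset_times for e in events]))
        act_summary = {"n_windows": len(traces),
                       "mean_event_frequency_per_s": float(np.mean(freqs)),
                       "percent_time_above": float(np.mean(
                           [e.percent_time_above for e in events]))}
        if len(onsets):
            prof = peri_event_motility(mod_tracks, onsets,
                                       half_window=float(acfg.get("half_window", 10.0)))
            diff, ci = prof.pre_post_difference()
            ds = delta_speed(mod_tracks, onsets)
            act_summary.update(peri_event_diff=diff, peri_event_diff_ci=list(ci),
                               delta_speed_um_s=ds.mean,
                               delta_speed_p=ds.p_value)
        report["stages"]["activity"] = _round(act_summary)

    report_json = json.dumps(_round(report), sort_keys=True, indent=2)
    (out / "report.json").write_text(report_json)
    report["report_sha256"] = hashlib.sha256(report_json.encode()).hexdigest()
    return report


def developmental_contrast_config(seed: int = 0) -> dict:
    """Demo configuration: two simulated conditions differing only in the
    fraction of motile organelles (0.3, emulating an immature stage, vs 0.0,
    a mature stage), run through render → segment → track → classify."""
    return {
        "seed": seed,
        "simulate": {
            "arbor": {"n_branch_events": 10, "field_extent": [80.0, 80.0, 8.0]},
            "placement": {"synapse_density": 0.4, "mito_volume_fraction": 0.1},
            "path_length_um": 40.0,
            "n_organelles": 8,
            "motility": {"duration": 90.0},
            "conditions": {"immature": {"motile_prob": 0.3},
                           "mature": {"motile_prob": 0.0}},
            "render": {"voxel_size": [0.4, 0.2, 0.2]},
        },
        "segment": {},
        "track": {},
        "motility": {"source": "linker", "window": 60.0},
        "spatial": {"n_iterations": 200},
    }


def make_demo_datasets(out_dir, seed: int = 0) -> dict:
    """Write a small fixture bundle (SWC, CSVs, TIFFs) with known truth.

    Regenerating with the same seed gives identical files; every fixture
    loads through its module reader.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arbor = generate_arbor(ArborParams(n_branch_events=8,
                                       field_extent=(80.0, 80.0, 8.0),
                                       seed=stage_seed(seed, "demo-arbor")))
    write_swc(arbor, out / "arbor.swc")
    truth = place_organelles(arbor, PlacementParams(
        synapse_density=0.4, mito_volume_fraction=0.1, synapse_affinity=0.5,
        seed=stage_seed(seed, "demo-place")))
    pd.DataFrame({"segment": truth.synapses.segment,
                  "offset_um": truth.synapses.offset}).to_csv(
        out / "synapses.csv", index=False)
    tracks, _ = simulate_tracks(40.0, MotilityParams(
        duration=90.0, seed=stage_seed(seed, "demo-tracks")), n_organelles=6)
    tracks.to_csv(out / "tracks.csv")
    rp = RenderParams(seed=stage_seed(seed, "demo-render"))
    polyline = np.array([[0.0, 0.0], [40.0, 0.0]])
    movie, rel = render_movie(tracks, polyline, rp)
    io.save_movie(movie, out / "movie.tif")
    io.save_stack(render_path_still(polyline, rp), out / "path_still.tif")
    traces, _, ca_truth = simulate_calcium(
        CalciumParams(seed=stage_seed(seed, "demo-calcium")), tracks)
    pd.DataFrame({"frame": np.arange(traces[0].n_frames),
                  **{f"window_{i}": t.values for i, t in enumerate(traces)}}
                 ).to_csv(out / "traces.csv", index=False)
    ca_truth.events_dataframe().to_csv(out / "events.csv", index=False)
    return {"out_dir": str(out),
            "files": sorted(p.name for p in out.iterdir())}
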