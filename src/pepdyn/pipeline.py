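"""Pipeline orchestration: simulate/load trajectories, run the selected
analyses, write TSV tables and a run-metadata JSON.

The report bundle is a pure function of (inputs, config, seed): every random
stream derives from the single master seed and all parameter values are
logged into the metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import aggregates as agg
from . import ecd, hbonds, sasa, secstruct
from .io import read_structure, read_trajectory, write_structure, write_trajectory
from .model import Species, Trajectory
from .summaries import parse_window
from .synthetic import (
    AggregationSchedule,
    LatentModeSpec,
    MergeEvent,
    build_mixture,
    simulate,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "simulate_from_config"]

DEFAULT_ANALYSES = ("hbonds", "ss", "sasa", "aggregates", "ecd")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def simulate_from_config(cfg: dict, seed: int) -> Trajectory:
    """Build a mixture and simulate it according to the ``simulate`` block."""
    sim = cfg
    system = build_mixture(
        n_abeta=sim.get("n_abeta", 8),
        abeta_species=Species[sim.get("abeta_species", "ABETA42")],
        n_scp=sim.get("n_scp", 8),
        scp_species=Species[sim.get("scp_species", "SST14")],
        box=sim.get("box_nm"),
        min_gap=sim.get("min_gap_nm", 0.4),
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    modes = []
    for k, mspec in enumerate(sim.get("modes", [])):
        chains = mspec.get("chains", system.chain_labels)
        atoms = np.concatenate([system.chain_atom_indices(c) for c in chains])
        modes.append(
            LatentModeSpec.random_for_atoms(
                f"mode{k}", atoms, mspec.get("sigma_nm", 0.05), mspec.get("tau_ps", 10.0), rng
            )
        )
    merges = [
        MergeEvent.of(m["time_ps"], m["a"], m["b"]) for m in sim.get("merges", [])
    ]
    schedule = AggregationSchedule(
        merges=merges,
        step_sd=sim.get("step_sd_nm", 0.0),
        rot_sd_deg=sim.get("rot_sd_deg", 0.0),
        drift_rate=sim.get("drift_rate_nm_ps", 0.05),
        contact_dist=sim.get("contact_dist_nm", 0.35),
    )
    traj, gt = simulate(
        system,
        modes=modes,
        schedule=schedule,
        noise_sd=sim.get("noise_sd_nm", 0.01),
        n_frames=sim.get("n_frames", 200),
        dt=sim.get("dt_ps", 1.0),
        seed=seed,
    )
    traj.ground_truth = gt  # attached for callers that want it
    return traj


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Execute the configured analyses and write the report bundle.

    Returns a dict of output paths.  Raises before any computation when a
    named input path is missing.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    analyses = cfg.get("analyses", list(DEFAULT_ANALYSES))

    # Validate inputs up front.
    if "trajectory" in cfg:
        for key in ("structure", "trajectory"):
            if key in cfg and not Path(cfg[key]).exists():
                raise FileNotFoundError(f"input path {cfg[key]!r} ({key}) not found")

    if "simulate" in cfg:
        traj = simulate_from_config(cfg["simulate"], seed)
        write_structure(traj.system, out / "system.pdb")
        if cfg.get("write_trajectory", False):
            write_trajectory(traj, out / "trajectory.pdb")
        gt = getattr(traj, "ground_truth", None)
        if gt is not None:
            (out / "ground_truth.json").write_text(gt.to_json())
    else:
        system = read_structure(cfg["structure"])
        traj = read_trajectory(cfg["trajectory"], system, dt=cfg.get("dt_ps"))

    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    first_w = parse_window(cfg.get("first_window", "first:10%"), t0, t1) \
        if "first_window" in cfg else (t0, t0 + 0.1 * (t1 - t0))
    last_w = parse_window(cfg.get("last_window", "last:10%"), t0, t1) \
        if "last_window" in cfg else (t1 - 0.1 * (t1 - t0), t1)

    outputs: dict[str, str] = {}
    if "hbonds" in analyses:
        series = hbonds.census(traj)
        series.to_tsv(out / "hbonds.tsv")
        means = {
            "first": hbonds.window_means(series, first_w),
            "last": hbonds.window_means(series, last_w),
        }
        (out / "hbonds_windows.json").write_text(json.dumps(means, indent=2))
        outputs["hbonds"] = str(out / "hbonds.tsv")
    if "ss" in analyses:
        stride = int(cfg.get("ss_stride", 1))
        content = secstruct.ss_content_series(traj, stride=stride)
        content.to_csv(out / "ss_content.tsv", sep="\t", index=False)
        outputs["ss"] = str(out / "ss_content.tsv")
    if "sasa" in analyses:
        stride = int(cfg.get("sasa_stride", max(1, traj.n_frames // 50)))
        groups = {
            "abeta": [c.label for c in traj.system.chains if c.species.is_abeta],
            "scp": [c.label for c in traj.system.chains if c.species.is_scp],
        }
        groups = {k: v for k, v in groups.items() if v}
        series, summary = sasa.sasa_timeseries(
            traj, groups=groups, first_window=first_w, last_window=last_w,
            stride=stride, n_points=int(cfg.get("sasa_points", 240)),
        )
        series.to_csv(out / "sasa.tsv", sep="\t", index=False)
        if summary is not None:
            summary.to_csv(out / "sasa_summary.tsv", sep="\t", index=False)
        outputs["sasa"] = str(out / "sasa.tsv")
    if "aggregates" in analyses:
        window_frames = int(cfg.get("aggregate_window_frames", max(2, traj.n_frames // 10)))
        states = agg.timeline(traj, window_frames=window_frames)
        agg.timeline_table(states).to_csv(out / "aggregates.tsv", sep="\t", index=False)
        (out / "final_status.txt").write_text(states[-1].composition_text() + "\n")
        outputs["aggregates"] = str(out / "aggregates.tsv")
    if "ecd" in analyses:
        sel = traj.system.ca_selection()
        seg_len = float(cfg.get("ecd_segment_ps", 200.0))
        # clamp the segment length so the analysis window holds >= 1 segment
        window_span = last_w[1] - last_w[0]
        seg_len = max(min(seg_len, window_span, (traj.n_frames - 1) * traj.dt), 2 * traj.dt)
        images = ecd.segment_images(traj, sel, seg_len_ps=seg_len, window=last_w,
                                    d=int(cfg.get("ecd_modes", 10)))
        pcm = ecd.pair_correlation(images)
        pcm.to_tsv(out / "ecd_pair_correlation.tsv")
        labels = [str(traj.system.chain_ids[i]) for i in sel.indices]
        rids = np.array([int(traj.system.res_ids[i]) for i in sel.indices])
        prof = ecd.flexibility(images, labels, rids)
        prof.to_frame().to_csv(out / "ecd_flexibility.tsv", sep="\t", index=False)
        mean_rho = ecd.pair_correlation(images).rho
        dom = ecd.domains(mean_rho, threshold=float(cfg.get("ecd_threshold", ecd.detect_threshold(mean_rho))),
                          min_size=int(cfg.get("ecd_min_domain", 20)))
        dom_df = {"atom": dom.atom_indices.tolist(), "domain": dom.domain_id.tolist()}
        (out / "ecd_domains.json").write_text(json.dumps(dom_df))
        outputs["ecd"] = str(out / "ecd_flexibility.tsv")

    meta = {
        "pepdyn_version": __version__,
        "seed": seed,
        "config": cfg,
        "n_frames": traj.n_frames,
        "dt_ps": traj.dt,
        "first_window_ps": list(first_w),
        "last_window_ps": list(last_w),
        "outputs": outputs,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    outputs["metadata"] = str(out / "run_metadata.json")
    return outputs
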