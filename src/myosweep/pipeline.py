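"""End-to-end pipeline: simulate -> preprocess -> EMD features -> proportion
sweep -> class-distance comparison, with every artifact written as plain
CSV/TSV/JSON and every random stream derived from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import distance as dist
from . import io as mio
from .classifier import GAConfig
from .config import (EMDConfig, FeatureConfig, PipelineConfig, config_to_dict)
from .emd import emd
from .features import (build_channel_feature, build_trial_feature,
                       feature_frame, select_imfs)
from .preprocess import (ActiveSegment, FilterSpec, bandpass_and_notch,
                         default_onset_threshold, detect_onset, extract_active)
from .sweep import (SplitSpec, default_schedule, find_peak, run_sweep,
                    sweep_frame, uniform_assignment)
from .synth import (SimulationConfig, Trial, make_similar_gesture_group,
                    simulate_dataset)


def preprocess_dataset(
    trials: Sequence[Trial],
    filter_spec: FilterSpec,
    active_duration: float,
    rest_duration: float,
    threshold: float | None = None,
    window_ms: float = 256.0,
    overlap_ms: float = 50.0,
) -> tuple[list[ActiveSegment], float]:
    """Filter all trials, derive the dataset onset threshold from the rest
    bookends (unless given), and extract the active segments.

    Returns the segments and the threshold actually used.
    """
    filtered = [bandpass_and_notch(t, filter_spec) for t in trials]
    if threshold is None:
        threshold = default_onset_threshold(filtered, rest_duration,
                                            window_ms=window_ms)
    segments = []
    for trial in filtered:
        onset = detect_onset(trial, threshold, window_ms=window_ms,
                             overlap_ms=overlap_ms,
                             segment_duration_s=active_duration)
        segments.append(extract_active(trial, onset,
                                       duration_s=active_duration))
    return segments, threshold


def features_from_segments(
    segments: Sequence[ActiveSegment],
    emd_cfg: EMDConfig = EMDConfig(),
    feat_cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Per-channel EMD + ZC/WAMP features, assembled into a labeled table."""
    selected = select_imfs([], fixed_k=feat_cfg.fixed_k)
    trial_feats = []
    for seg in segments:
        blocks = []
        for c in range(seg.signal.shape[0]):
            decomp = emd(seg.signal[c], max_imfs=emd_cfg.max_imfs,
                         stop_sd=emd_cfg.stop_sd,
                         max_sift_iters=emd_cfg.max_sift_iters)
            blocks.append(build_channel_feature(
                decomp, selected,
                feature_window_samples=feat_cfg.feature_window_samples,
                deadband=feat_cfg.deadband, offset=feat_cfg.offset,
                channel_index=c + 1,
                wamp_threshold=feat_cfg.wamp_threshold))
        trial_feats.append(build_trial_feature(blocks, seg.trial_id,
                                               seg.gesture))
    return feature_frame(trial_feats)


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> str:
    df.to_csv(path, sep="\t", index=index)
    return str(path)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts plus a run manifest.

    Rerunning with the same config reproduces every numeric output
    byte-for-byte (the manifest's timestamps excepted).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.master_seed)
    seeds = [int(s) for s in master.generate_state(4) % (2 ** 31)]
    sim_seed, split_seed, sweep_seed, dist_seed = seeds
    stages = []
    t0 = time.time()

    # 1. simulate
    specs = make_similar_gesture_group(
        config.gestures.base_weights, list(config.gestures.names),
        config.simulation.similarity, rng_seed=sim_seed,
        group=config.gestures.group,
        difficulty_scales=config.gestures.difficulty_scales)
    sim_cfg = dataclasses.replace(config.simulation, seed=sim_seed)
    trials, manifest = simulate_dataset(specs, sim_cfg)
    manifest_path = mio.write_dataset(trials, manifest, out_dir)
    stages.append({"stage": "simulate", "outputs": [str(manifest_path)],
                   "seed": sim_seed, "n_trials": len(trials)})

    # 2. preprocess
    segments, threshold = preprocess_dataset(
        trials, config.filter, active_duration=sim_cfg.active_duration,
        rest_duration=sim_cfg.pre_rest)
    seg_dir = out_dir / "segments"
    seg_dir.mkdir(exist_ok=True)
    onset_rows = []
    for seg in segments:
        seg_trial = Trial(seg.trial_id, seg.gesture, seg.signal,
                          seg.sampling_rate)
        mio.write_trial_csv(seg_trial, seg_dir / f"{seg.trial_id}.csv")
        onset_rows.append({"trial_id": seg.trial_id,
                           "onset_index": seg.onset_index})
    onsets = manifest.merge(pd.DataFrame(onset_rows), on="trial_id")
    onsets["path"] = onsets["trial_id"].map(lambda t: f"segments/{t}.csv")
    extract_manifest = _write_tsv(onsets, out_dir / "segments_manifest.tsv")
    stages.append({"stage": "preprocess", "outputs": [extract_manifest],
                   "onset_threshold": threshold})

    # 3. features
    feats = features_from_segments(segments, config.emd, config.features)
    feats_path = out_dir / "features.tsv"
    mio.write_feature_table(feats, feats_path)
    stages.append({"stage": "features", "outputs": [str(feats_path)],
                   "n_features": len(feats.columns) - 2})

    # 4. sweep
    interest = config.sweep.interest or config.gestures.names[0]
    names = list(config.gestures.names)
    ordered = tuple([interest] + [n for n in names if n != interest])
    if config.sweep.steps is not None:
        from .sweep import AssignmentSchedule
        steps = tuple(tuple(int(c) for c in s) for s in config.sweep.steps)
        schedule = AssignmentSchedule(ordered, steps, config.sweep.total)
    else:
        schedule = default_schedule(ordered, total=config.sweep.total)
    split_spec = SplitSpec(config.sweep.candidate_per_gesture,
                           config.sweep.test_per_gesture, seed=split_seed)
    ga_cfg = config.ga
    result = run_sweep(feats, schedule, split_spec, ga_cfg,
                       repeats=config.sweep.repeats, master_seed=sweep_seed,
                       retune=config.sweep.retune,
                       uniform_per_gesture=config.sweep.uniform_per_gesture)
    sweep_path = _write_tsv(sweep_frame(result), out_dir / "sweep_result.tsv")
    peak_idx, peak_counts = find_peak(result)
    stages.append({"stage": "sweep", "outputs": [sweep_path],
                   "seed": sweep_seed, "peak_step": peak_idx + 1,
                   "peak_counts": peak_counts})

    # 5. distance: peak assignment vs uniform baseline
    from .sweep import split_candidates
    pool, _ = split_candidates(feats, split_spec)
    ridge = dist.default_ridge(pool, rel=config.distance.ridge_rel)
    uniform_counts = dict(zip(
        ordered, uniform_assignment(config.sweep.uniform_per_gesture,
                                    len(ordered))))
    comparison = dist.compare_assignments(
        pool, list(ordered), uniform_counts, peak_counts,
        repeats=config.distance.repeats, seed=dist_seed, ridge=ridge,
        sqrt=config.distance.sqrt, label_a="uniform", label_b="peak")
    dist_summary = _write_tsv(comparison.summary(),
                              out_dir / "distance_deltas.tsv")
    douts = pd.DataFrame({"repeat": np.arange(comparison.repeats) + 1,
                          "d_out_uniform": comparison.d_out_a,
                          "d_out_peak": comparison.d_out_b})
    dout_path = _write_tsv(douts, out_dir / "distance_d_out.tsv")
    stages.append({"stage": "distance", "outputs": [dist_summary, dout_path],
                   "seed": dist_seed, "ridge": ridge})

    cfg_dict = config_to_dict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    run_manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "master_seed": config.master_seed,
        "derived_seeds": {"simulate": sim_seed, "split": split_seed,
                          "sweep": sweep_seed, "distance": dist_seed},
        "stages": stages,
        "elapsed_s": time.time() - t0,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=str)
    return run_manifest
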