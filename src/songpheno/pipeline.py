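"""End-to-end orchestration: segment -> label -> features, with config snapshots.

``run_pipeline`` executes the stages in order on a directory of WAV files,
writes per-stage artifacts (segment CSV, label CSV, feature CSV) plus a
JSON snapshot of the effective configuration, and logs stage timings and
record counts.  Completed stages are detected by their output files, so an
interrupted run resumes from the last finished stage.  Per-file warnings
(files too short for rhythm analysis, single-rendition types) never abort
a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import acoustics, labeling, segmentation, syntax, timing
from .audio_core import InputError, bandpass, compute_rmse_trace, load_wav
from .segmentation import SegThresholds

log = logging.getLogger("songpheno")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline knobs in one serializable record."""

    wav_dir: str
    out_dir: str
    onset_thr: float = 0.05
    offset_thr: float = 0.05
    seg_table: str | None = None  # external segmenter output; skips segmentation
    seed: int = 42
    min_cluster_size: int | None = None
    bandpass_lo: float = 200.0
    bandpass_hi: float = 9000.0
    resume: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_recordings(wav_dir: str) -> dict:
    if not os.path.isdir(wav_dir):
        raise InputError(f"WAV directory not found: {wav_dir!r}")
    recs = {}
    for name in sorted(os.listdir(wav_dir)):
        if name.lower().endswith(".wav"):
            recs[name] = load_wav(os.path.join(wav_dir, name))
    if not recs:
        raise InputError(f"no WAV files in {wav_dir!r}")
    return recs


def _stage(name: str, out_path: str, resume: bool):
    done = resume and os.path.exists(out_path)
    if done:
        log.info("stage %s: found %s, resuming past it", name, out_path)
    return done


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run segment -> label -> features; returns the one-row feature table."""
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "config_snapshot.json"), "w") as fh:
        fh.write(config.to_json())
    recs = _load_recordings(config.wav_dir)
    log.info("loaded %d recordings from %s", len(recs), config.wav_dir)

    seg_path = os.path.join(config.out_dir, "segments.csv")
    if config.seg_table is not None:
        segs = segmentation.read_segment_table(config.seg_table)
        log.info("stage segment: ingested %d external segments", len(segs))
    elif _stage("segment", seg_path, config.resume):
        segs = segmentation.read_segment_table(seg_path)
    else:
        t0 = time.perf_counter()
        thr = SegThresholds(config.onset_thr, config.offset_thr)
        parts = []
        for name, rec in recs.items():
            try:
                filtered = bandpass(rec, config.bandpass_lo, min(config.bandpass_hi, 0.99 * rec.rate / 2))
                trace = compute_rmse_trace(filtered)
            except InputError as exc:
                log.warning("stage segment: skipping %s (%s)", name, exc)
                continue
            parts.append(segmentation.segment_amplitude(trace, thr))
        segs = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=segmentation.SEGMENT_COLUMNS
        )
        segmentation.write_segment_table(segs, seg_path)
        log.info(
            "stage segment: %d segments in %.1fs", len(segs), time.perf_counter() - t0
        )

    label_path = os.path.join(config.out_dir, "labels.csv")
    if _stage("label", label_path, config.resume):
        labeled = segmentation.read_segment_table(label_path)
    else:
        t0 = time.perf_counter()
        try:
            labeled = labeling.label_syllables(
                recs, segs, seed=config.seed, min_cluster_size=config.min_cluster_size
            )
        except InputError as exc:
            raise InputError(f"stage label failed: {exc}") from exc
        segmentation.write_segment_table(labeled, label_path)
        log.info(
            "stage label: %d labeled syllables in %.1fs",
            len(labeled),
            time.perf_counter() - t0,
        )

    feat_path = os.path.join(config.out_dir, "features.csv")
    t0 = time.perf_counter()
    syn = syntax.syntax_features(labeled, {f: r.duration for f, r in recs.items()})
    tim = timing.timing_features(recs.values(), labeled)
    aco = acoustics.acoustic_features_for_bird(recs, labeled)
    vec = acoustics.assemble_feature_vector(aco, syn, tim)
    features = vec.to_frame().T
    features.insert(0, "bird", os.path.basename(os.path.normpath(config.wav_dir)))
    features.to_csv(feat_path, index=False)
    log.info(
        "stage features: %d features in %.1fs", len(vec), time.perf_counter() - t0
    )
    return features
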