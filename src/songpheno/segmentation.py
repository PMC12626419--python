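"""Amplitude-derivative syllable segmentation and segmentation evaluation.

The segmenter thresholds the first derivative of the normalized per-file
RMSE trace: a syllable onset is a positive crossing of the onset threshold.
Offsets are hard to place consistently from amplitude alone, so segmentation
is onset-to-onset — each segment spans from its onset to the next onset,
covering the syllable plus its trailing silent gap.  Only when no further
onset follows within 300 ms (end of a bout) is the offset placed at the
first negative crossing of the offset threshold by the normalized RMSE.

Evaluation matches predicted event times to reference times one-to-one
(greedy over increasing |delta| within tolerance: 10 ms for onsets, 20 ms
for offsets) and reports precision, recall and F1 with
F1 = TP / (TP + (FP + FN)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio_core import AmplitudeTrace, InputError, ParameterError

__all__ = [
    "SegThresholds",
    "MatchResult",
    "SegMetrics",
    "SEGMENT_COLUMNS",
    "ONSET_TOL",
    "OFFSET_TOL",
    "validate_segments",
    "segment_amplitude",
    "match_events",
    "seg_f1",
    "time_deltas",
    "evaluate_segmentation",
    "optimize_thresholds",
    "default_threshold_grid",
    "read_segment_table",
    "write_segment_table",
]

#: canonical column order for segment tables
SEGMENT_COLUMNS = ["file", "onset", "offset", "label"]
#: matching tolerance for syllable onsets (s)
ONSET_TOL = 0.010
#: matching tolerance for syllable offsets (s)
OFFSET_TOL = 0.020
#: an onset not followed by another within this window ends the bout (s)
BOUT_END_WINDOW = 0.300
#: segments shorter than this many trace frames are discarded as artifacts
MIN_SEGMENT_FRAMES = 2


@dataclass(frozen=True)
class SegThresholds:
    """Global thresholds shared across all birds.

    ``onset_thr`` applies to the first derivative of the normalized RMSE
    (units: normalized RMSE per frame); ``offset_thr`` applies to the
    normalized RMSE itself.
    """

    onset_thr: float
    offset_thr: float


@dataclass
class MatchResult:
    """One-to-one event matching outcome within a tolerance."""

    pairs: list  # (ref_time, pred_time) tuples
    tp: int
    fp: int
    fn: int
    tol: float

    @property
    def deltas(self) -> np.ndarray:
        """Signed pred - ref differences (s) for matched pairs."""
        return np.array([p - r for r, p in self.pairs], dtype=float)


@dataclass
class SegMetrics:
    precision: float
    recall: float
    f1: float


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS)


def validate_segments(df: pd.DataFrame, allow_overlap: bool = True) -> pd.DataFrame:
    """Validate and canonicalize a segment table.

    Requires onset < offset per row; sorts by (file, onset); fills missing
    labels with "".  With ``allow_overlap=False``, overlapping segments
    within a file raise (amplitude-segmenter output is non-overlapping by
    construction).
    """
    df = df.copy()
    for col in ("file", "onset", "offset"):
        if col not in df.columns:
            raise InputError(f"segment table missing column {col!r}")
    if "label" not in df.columns:
        df["label"] = ""
    df["label"] = df["label"].fillna("").astype(str)
    bad = df.index[df["onset"] >= df["offset"]]
    if len(bad):
        raise InputError(f"onset >= offset at row(s) {list(bad[:5])}")
    df = df.sort_values(["file", "onset"], kind="stable").reset_index(drop=True)
    if not allow_overlap:
        for _, grp in df.groupby("file", sort=False):
            if (grp["onset"].values[1:] < grp["offset"].values[:-1] - 1e-9).any():
                raise InputError(f"overlapping segments in file {grp['file'].iloc[0]!r}")
    return df[SEGMENT_COLUMNS]


def segment_amplitude(
    trace: AmplitudeTrace, thr: SegThresholds, center_correction: bool = True
) -> pd.DataFrame:
    """Segment one normalized RMSE trace into syllables.

    Returns a segment table (onset/offset seconds, empty labels) for the
    trace's source file.  Degenerate segments shorter than two trace frames
    are discarded.

    Because RMSE frames are centered, energy from a sharp onset first
    enters the analysis window half a frame (``frame_len/2`` samples)
    before the onset itself, and the derivative threshold crossing fires at
    that leading edge.  With ``center_correction`` (default) all reported
    times are shifted forward by ``frame_len/2 / rate`` so they land on the
    acoustic event rather than the window edge.
    """
    rmse = np.asarray(trace.rmse, dtype=float)
    if rmse.size < 2:
        return _empty_segments()
    deriv = np.diff(rmse)  # deriv[i] = rmse[i+1] - rmse[i], per-frame units
    # positive crossing: derivative rises through onset_thr
    above = deriv > thr.onset_thr
    onset_frames = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onset_frames = np.insert(onset_frames, 0, 0)
    if onset_frames.size == 0:
        return _empty_segments()

    frame_dt = trace.hop / trace.rate
    shift = (trace.frame_len / 2) / trace.rate if center_correction else 0.0
    window_frames = int(round(BOUT_END_WINDOW / frame_dt))
    rows = []
    for j, on in enumerate(onset_frames):
        nxt = onset_frames[j + 1] if j + 1 < onset_frames.size else None
        if nxt is not None and (nxt - on) <= window_frames:
            off = nxt
        else:
            # bout end: first negative crossing of offset_thr by the RMSE
            seg = rmse[on + 1 :]
            below = np.flatnonzero((seg < thr.offset_thr) & (rmse[on:-1] >= thr.offset_thr))
            off = (on + 1 + below[0]) if below.size else rmse.size - 1
            if nxt is not None:
                off = min(off, nxt)
        if off - on < MIN_SEGMENT_FRAMES:
            continue
        rows.append((trace.source_id, on * frame_dt + shift, off * frame_dt + shift, ""))
    if not rows:
        return _empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def match_events(ref: Sequence[float], pred: Sequence[float], tol: float) -> MatchResult:
    """Greedy one-to-one matching of event times by increasing |delta|.

    Each reference event pairs with at most one prediction (and vice versa)
    within ``tol`` seconds.  For 1-D events at these tolerances the greedy
    pairing coincides with the optimal assignment.
    """
    ref = np.asarray(sorted(ref), dtype=float)
    pred = np.asarray(sorted(pred), dtype=float)
    cands = []
    for i, r in enumerate(ref):
        lo = np.searchsorted(pred, r - tol)
        hi = np.searchsorted(pred, r + tol, side="right")
        for j in range(lo, hi):
            cands.append((abs(pred[j] - r), i, j))
    cands.sort()
    used_r: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        pairs.append((ref[i], pred[j]))
    pairs.sort()
    tp = len(pairs)
    return MatchResult(pairs, tp=tp, fp=pred.size - tp, fn=ref.size - tp, tol=tol)


def seg_f1(match: MatchResult) -> SegMetrics:
    """Precision/recall/F1 from a match result; 0/0 cases defined as 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    denom = tp + 0.5 * (fp + fn)
    f1 = tp / denom if denom else 0.0
    return SegMetrics(precision, recall, f1)


def time_deltas(match: MatchResult) -> dict:
    """Signed matched-pair deltas with a median-|delta| summary (seconds)."""
    d = match.deltas
    return {
        "deltas": d,
        "median_abs": float(np.median(np.abs(d))) if d.size else float("nan"),
    }


def evaluate_segmentation(
    ref: pd.DataFrame,
    pred: pd.DataFrame,
    onset_tol: float = ONSET_TOL,
    offset_tol: float = OFFSET_TOL,
) -> dict:
    """Per-file onset and offset matching pooled into overall metrics."""
    ref = validate_segments(ref)
    pred = validate_segments(pred)
    out = {}
    for kind, tol in (("onset", onset_tol), ("offset", offset_tol)):
        tp = fp = fn = 0
        deltas = []
        files = sorted(set(ref["file"]) | set(pred["file"]))
        for f in files:
            m = match_events(
                ref.loc[ref["file"] == f, kind].values,
                pred.loc[pred["file"] == f, kind].values,
                tol,
            )
            tp += m.tp
            fp += m.fp
            fn += m.fn
            deltas.extend(m.deltas)
        metrics = seg_f1(MatchResult([], tp, fp, fn, tol))
        out[kind] = {
            "precision": metrics.precision,
            "recall": metrics.recall,
            "f1": metrics.f1,
            "median_abs_delta": float(np.median(np.abs(deltas))) if deltas else float("nan"),
        }
    return out


def default_threshold_grid(
    traces: Iterable[AmplitudeTrace], n: int = 10
) -> list[SegThresholds]:
    """Linspace of onset thresholds over (0, max derivative) with a fixed
    offset threshold at the trace midpoint (0.5 of normalized RMSE range)."""
    max_d = max(float(np.diff(t.rmse).max()) for t in traces)
    return [SegThresholds(x, 0.1) for x in np.linspace(0.01, max_d, n, endpoint=False)]


def optimize_thresholds(
    traces: Mapping[str, Sequence[AmplitudeTrace]],
    refs: Mapping[str, pd.DataFrame],
    grid: Sequence[SegThresholds],
    onset_tol: float = ONSET_TOL,
) -> SegThresholds:
    """Pick the grid point maximizing mean onset-F1 across birds.

    ``traces`` maps bird id -> that bird's traces; ``refs`` maps bird id ->
    reference segment table.  Ties break toward the lower onset threshold.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("threshold grid is empty")
    if not traces:
        raise ParameterError("need at least one bird with traces")
    best = None
    for thr in grid:
        f1s = []
        for bird, bird_traces in traces.items():
            pred = pd.concat(
                [segment_amplitude(t, thr) for t in bird_traces], ignore_index=True
            )
            if pred.empty:
                pred = _empty_segments()
            ref = refs[bird]
            tp = fp = fn = 0
            for f in sorted(set(ref["file"]) | set(pred["file"])):
                m = match_events(
                    ref.loc[ref["file"] == f, "onset"].values,
                    pred.loc[pred["file"] == f, "onset"].values,
                    onset_tol,
                )
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            f1s.append(seg_f1(MatchResult([], tp, fp, fn, onset_tol)).f1)
        mean_f1 = float(np.mean(f1s))
        key = (mean_f1, -thr.onset_thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return best[1]


def write_segment_table(table: pd.DataFrame, path) -> None:
    """CSV with header onset,offset,label,file; 6-decimal seconds."""
    df = validate_segments(table)
    out = df[["onset", "offset", "label", "file"]].copy()
    out["onset"] = out["onset"].map(lambda v: f"{v:.6f}")
    out["offset"] = out["offset"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_segment_table(path) -> pd.DataFrame:
    """Read a segment CSV; malformed rows raise with their row number."""
    df = pd.read_csv(path, dtype={"label": str})
    for col in ("onset", "offset"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    if "file" not in df.columns:
        df["file"] = ""
    if "label" not in df.columns:
        df["label"] = ""
    for idx, row in df.iterrows():
        if not np.isfinite(row["onset"]) or not np.isfinite(row["offset"]):
            raise InputError(f"{path}: non-numeric time at row {idx + 1}")
        if row["onset"] >= row["offset"]:
            raise InputError(f"{path}: onset >= offset at row {idx + 1}")
    return validate_segments(df)
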