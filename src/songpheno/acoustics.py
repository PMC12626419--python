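"""Frame-level acoustic features and the 55-feature phenotype vector.

Seven frame-level features in the Sound Analysis tradition — goodness of
pitch, mean frequency, Wiener entropy, amplitude, amplitude modulation,
frequency modulation, pitch — are computed per spectrogram frame with the
operational definitions below (frozen by regression tests; bit-parity with
the original MATLAB tools is not claimed):

* amplitude            dB of total frame power
* wiener_entropy       mean(ln power) - ln(mean power)  (<= 0; 0 = flat)
* mean_frequency       power-weighted spectral centroid (Hz)
* pitch                frequency of the largest cepstral peak in the
                       configured pitch range (Hz)
* goodness_of_pitch    height of that cepstral peak
* amplitude_modulation frame-to-frame derivative of total power
* frequency_modulation arctan of the ratio of summed squared time- to
                       frequency-derivatives of the dB spectrogram

Per-syllable means are summarized per type (mean and CV across renditions,
population s.d.), syllable duration joins as the eighth base feature, and
the bird-level vector takes min/median/max across types of each (feature,
statistic) pair: 8 x 2 x 3 = 48 acoustic values, plus 3 syntax and 4 timing
features = 55.

Amplitude and amplitude-modulation columns are flagged recording-sensitive:
they depend on gain and microphone placement, not only on the bird.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_core import AudioRecording, InputError, _frame
from .syntax import SyntaxFeatures
from .timing import TimingFeatures

__all__ = [
    "BASE_FEATURES",
    "FEATURE_NAMES_55",
    "RECORDING_SENSITIVE",
    "frame_features",
    "summarize_by_type",
    "assemble_feature_vector",
    "acoustic_features_for_bird",
]

#: per-frame acoustic features (order fixed)
FRAME_FEATURES = (
    "goodness_of_pitch",
    "mean_frequency",
    "wiener_entropy",
    "amplitude",
    "amplitude_modulation",
    "frequency_modulation",
    "pitch",
)
#: the 8 base features summarized per type (7 acoustic + duration)
BASE_FEATURES = FRAME_FEATURES + ("duration",)
#: features whose absolute values depend on recording conditions
RECORDING_SENSITIVE = frozenset({"amplitude", "amplitude_modulation"})

#: cepstral pitch search range (Hz)
PITCH_RANGE = (300.0, 3000.0)
#: analysis window/hop (samples); documented default, shared with labeling
ACOUSTIC_WINDOW = 512
ACOUSTIC_HOP = 128

_POWER_FLOOR = 1e-12

SYNTAX_NAMES = ("entropy_rate_norm", "mean_rep_bout_len", "cv_rep_bout_len")
TIMING_NAMES = (
    "syll_duration_entropy",
    "gap_duration_entropy",
    "rhythm_spectrum_entropy",
    "peak_freq_cv",
)


def _acoustic_summary_names() -> list:
    names = []
    for feat in BASE_FEATURES:
        for stat in ("mean", "cv"):
            for agg in ("min", "median", "max"):
                names.append(f"{feat}_{stat}_{agg}")
    return names


#: fixed 55-name ordering of the full phenotype vector
FEATURE_NAMES_55 = tuple(_acoustic_summary_names()) + SYNTAX_NAMES + TIMING_NAMES
assert len(FEATURE_NAMES_55) == 55


def frame_features(
    rec: AudioRecording,
    window: int = ACOUSTIC_WINDOW,
    hop: int = ACOUSTIC_HOP,
) -> pd.DataFrame:
    """Per-frame acoustic feature table (one row per frame, plus ``time``)."""
    frames = _frame(rec.samples, window, hop)
    win = np.hanning(window)
    spec = np.fft.rfft(frames * win, axis=1)
    power = np.abs(spec) ** 2  # (n_frames, n_bins)
    freqs = np.fft.rfftfreq(window, d=1.0 / rec.rate)
    total = power.sum(axis=1)
    safe_total = np.clip(total, _POWER_FLOOR, None)

    amplitude = 10.0 * np.log10(safe_total)
    # spectral floors are relative to each frame's peak so every feature
    # except amplitude/AM is invariant to overall gain
    frame_floor = np.maximum(power.max(axis=1, keepdims=True) * 1e-10, _POWER_FLOOR)
    logp = np.log(np.maximum(power, frame_floor))
    wiener = logp.mean(axis=1) - np.log(np.maximum(power.mean(axis=1), frame_floor[:, 0]))
    mean_freq = (power * freqs).sum(axis=1) / safe_total

    # cepstral pitch: peak of real cepstrum within the configured range
    cep = np.fft.irfft(logp, axis=1)
    quef = np.arange(cep.shape[1]) / rec.rate  # seconds
    qlo = max(int(np.floor(rec.rate / PITCH_RANGE[1])), 1)
    qhi = min(int(np.ceil(rec.rate / PITCH_RANGE[0])), cep.shape[1] // 2)
    band = cep[:, qlo : qhi + 1]
    peak_idx = band.argmax(axis=1) + qlo
    pitch = rec.rate / peak_idx
    goodness = np.clip(band.max(axis=1), 0.0, None)

    # modulation features from spectrogram derivatives (frame-relative floor
    # keeps FM gain-invariant)
    db_spec = (10.0 / np.log(10.0)) * logp
    if db_spec.shape[0] > 1:
        d_t = np.gradient(db_spec, axis=0)
        d_f = np.gradient(db_spec, axis=1)
        fm = np.arctan((d_t**2).sum(axis=1) / np.clip((d_f**2).sum(axis=1), _POWER_FLOOR, None))
        am = np.gradient(total)
    else:
        fm = np.zeros(1)
        am = np.zeros(1)

    out = pd.DataFrame(
        {
            "time": np.arange(frames.shape[0]) * hop / rec.rate,
            "goodness_of_pitch": goodness,
            "mean_frequency": mean_freq,
            "wiener_entropy": wiener,
            "amplitude": amplitude,
            "amplitude_modulation": am,
            "frequency_modulation": fm,
            "pitch": pitch,
        }
    )
    if not np.isfinite(out.drop(columns="time").values).all():
        raise AssertionError("non-finite acoustic feature values")
    return out


def summarize_by_type(frames_by_file: dict, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean and CV of rendition-mean features.

    ``frames_by_file`` maps file -> frame-feature table for that recording.
    Each syllable rendition is summarized by the mean of the frames whose
    center time falls inside [onset, offset); per type, the mean and the
    population CV of those rendition means are returned (CV is NaN for
    types with a single rendition).  Duration joins as the eighth feature.
    Returns a DataFrame indexed by type with columns
    ``{feature}_{mean|cv}`` and ``n_renditions``.
    """
    from .segmentation import validate_segments

    labels = validate_segments(labels)
    rendition_rows = []
    for idx, row in labels.iterrows():
        ff = frames_by_file.get(row["file"])
        if ff is None:
            raise InputError(f"no frame features for file {row['file']!r}")
        sel = ff[(ff["time"] >= row["onset"]) & (ff["time"] < row["offset"])]
        if sel.empty:  # syllable shorter than one hop: take nearest frame
            j = (ff["time"] - row["onset"]).abs().idxmin()
            sel = ff.loc[[j]]
        means = sel[list(FRAME_FEATURES)].mean()
        means["duration"] = row["offset"] - row["onset"]
        means["type"] = row["label"]
        rendition_rows.append(means)
    rend = pd.DataFrame(rendition_rows)
    out = {}
    for tok, grp in rend.groupby("type", sort=True):
        vals = {}
        for feat in BASE_FEATURES:
            x = grp[feat].values.astype(float)
            vals[f"{feat}_mean"] = x.mean()
            if len(x) >= 2:
                m = np.abs(x.mean())
                vals[f"{feat}_cv"] = x.std(ddof=0) / m if m else np.nan
            else:
                vals[f"{feat}_cv"] = np.nan
        vals["n_renditions"] = len(grp)
        out[tok] = vals
    return pd.DataFrame(out).T


def assemble_feature_vector(
    acoustic: pd.DataFrame | None,
    syntax: SyntaxFeatures | None = None,
    timing: TimingFeatures | None = None,
) -> pd.Series:
    """Assemble the bird-level phenotype vector.

    With all three blocks present the result has exactly 55 named values;
    the acoustic block alone yields 48.  Missing components or per-type NaN
    statistics propagate as NaN, never silently imputed.  Median over an
    even number of types is the lower median.
    """

    def lower_median(x: np.ndarray) -> float:
        x = np.sort(x[~np.isnan(x)])
        if x.size == 0:
            return float("nan")
        return float(x[(x.size - 1) // 2])

    vals = {}
    if acoustic is not None and len(acoustic):
        for feat in BASE_FEATURES:
            for stat in ("mean", "cv"):
                col = acoustic[f"{feat}_{stat}"].values.astype(float)
                finite = col[~np.isnan(col)]
                vals[f"{feat}_{stat}_min"] = finite.min() if finite.size else float("nan")
                vals[f"{feat}_{stat}_median"] = lower_median(col)
                vals[f"{feat}_{stat}_max"] = finite.max() if finite.size else float("nan")
    else:
        for name in _acoustic_summary_names():
            vals[name] = float("nan")
    if syntax is None and timing is None and acoustic is not None:
        return pd.Series(vals, index=_acoustic_summary_names(), dtype=float)
    s = syntax
    vals["entropy_rate_norm"] = s.entropy_rate_norm if s else float("nan")
    vals["mean_rep_bout_len"] = s.mean_rep_bout_len if s else float("nan")
    vals["cv_rep_bout_len"] = s.cv_rep_bout_len if s else float("nan")
    t = timing
    vals["syll_duration_entropy"] = t.syll_duration_entropy if t else float("nan")
    vals["gap_duration_entropy"] = t.gap_duration_entropy if t else float("nan")
    vals["rhythm_spectrum_entropy"] = t.rhythm_spectrum_entropy if t else float("nan")
    vals["peak_freq_cv"] = t.peak_freq_cv if t else float("nan")
    return pd.Series(vals, index=list(FEATURE_NAMES_55), dtype=float)


def acoustic_features_for_bird(recs, labels: pd.DataFrame) -> pd.DataFrame:
    """Convenience: frame features per file then per-type summary."""
    if not isinstance(recs, dict):
        recs = {r.source_id: r for r in recs}
    frames = {fid: frame_features(rec) for fid, rec in recs.items()}
    return summarize_by_type(frames, labels)
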