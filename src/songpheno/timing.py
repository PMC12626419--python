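"""Song timing features: duration-distribution entropies and rhythm analysis.

Duration entropy summarizes how predictable syllable (or gap) durations
are.  Syllable durations are log10-transformed and histogrammed into 50
bins over [-2.5, 0] (3 ms to 1 s); gap durations are histogrammed raw into
20 bins of 10 ms up to the 200 ms bout threshold.  The normalized entropy

    -sum_i p_i ln p_i / ln N

ranges from 0 (all mass in one bin) to 1 (uniform across all N bins).

Rhythm analysis works directly on audio, independent of segmentation.  A
file's rhythm spectrum is the low-frequency spectrum of the first
derivative of its amplitude envelope: files are cut into 3 s windows with a
0.2 s hop, the three highest-energy windows are mean-centered, Hann
windowed, zero-padded to 100000 points, band-limited to 1-500 Hz, Fourier
transformed, and averaged; only 0-30 Hz is kept.  Harmonic banding in this
band indicates a consistent motif rhythm.  Summary features: Wiener entropy
of the mean rhythm spectrum (0 flat, more negative = stronger rhythm) and
the CV of the per-file peak frequency within a 3 Hz band around the median
peak (rhythm stereotypy across renditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import AudioRecording, InputError, ParameterError, compute_rmse_trace

__all__ = [
    "DurationDistribution",
    "RhythmSpectrogram",
    "TimingFeatures",
    "duration_entropy",
    "rhythm_spectrum",
    "rhythm_spectrogram",
    "rhythm_entropy",
    "peak_freq_cv",
    "timing_features",
]

#: syllable-duration histogram: 50 bins over log10(seconds) in [-2.5, 0]
SYLL_BINS = np.linspace(-2.5, 0.0, 51)
#: gap-duration histogram: 20 bins of 10 ms up to 200 ms
GAP_BINS = np.linspace(0.0, 0.2, 21)
#: rhythm analysis window (s) and hop (s)
RHYTHM_WINDOW = 3.0
RHYTHM_HOP = 0.2
#: minimum eligible file duration: window + 3 hops
RHYTHM_MIN_DURATION = RHYTHM_WINDOW + 3 * RHYTHM_HOP
#: zero-padded FFT length for rhythm spectra
RHYTHM_NFFT = 100_000
#: band kept before the transform (Hz)
RHYTHM_BAND = (1.0, 500.0)
#: band retained for features and display (Hz)
RHYTHM_KEEP = (0.0, 30.0)
#: half-width of the peak-frequency constraint band (Hz)
PEAK_BAND_HALF_WIDTH = 1.5


@dataclass
class DurationDistribution:
    bin_edges: np.ndarray
    probs: np.ndarray  # probabilities summing to 1
    entropy_norm: float


@dataclass
class RhythmSpectrogram:
    """Per-file rhythm spectra stacked as columns (freq x file)."""

    freqs: np.ndarray
    spectra: np.ndarray  # shape (n_freqs, n_files)
    source_ids: list
    skipped: list  # source ids of files too short for rhythm analysis

    def smoothed(self, window: int = 10) -> np.ndarray:
        """Rolling mean across files for display; raw spectra drive features."""
        n = self.spectra.shape[1]
        out = np.empty_like(self.spectra)
        for j in range(n):
            lo = max(0, j - window + 1)
            out[:, j] = self.spectra[:, lo : j + 1].mean(axis=1)
        return out


@dataclass
class TimingFeatures:
    syll_duration_entropy: float
    gap_duration_entropy: float
    rhythm_spectrum_entropy: float
    peak_freq_cv: float


def duration_entropy(durations, kind: str) -> DurationDistribution:
    """Normalized entropy of a syllable or gap duration distribution.

    ``kind="syllable"``: log10-transform then 50 bins over [-2.5, 0].
    ``kind="gap"``: raw durations, 20 bins of 10 ms up to 200 ms (longer
    gaps are bout boundaries and must be excluded upstream).
    """
    durations = np.asarray(list(durations), dtype=float)
    if durations.size == 0:
        raise InputError("duration entropy needs at least one duration")
    if kind == "syllable":
        edges = SYLL_BINS
        values = np.log10(np.clip(durations, 10 ** edges[0], 10 ** edges[-1]))
    elif kind == "gap":
        edges = GAP_BINS
        values = np.clip(durations, edges[0], edges[-1])
    else:
        raise ParameterError(f"kind must be 'syllable' or 'gap', got {kind!r}")
    counts, _ = np.histogram(values, bins=edges)
    p = counts / counts.sum()
    n_bins = len(edges) - 1
    nz = p[p > 0]
    ent = float(-(nz * np.log(nz)).sum() / np.log(n_bins))
    return DurationDistribution(edges, p, ent)


def rhythm_spectrum(
    rec: AudioRecording, use_real_part: bool = False
) -> tuple[np.ndarray, np.ndarray] | None:
    """Rhythm spectrum of one file, or None if the file is too short.

    Returns ``(freqs, spectrum)`` restricted to 0-30 Hz.  The amplitude
    envelope is the min-max-normalized RMSE trace (hop 512), which makes the
    spectrum invariant to overall audio gain.  With ``use_real_part`` the
    literal real component of the transform is taken instead of the
    magnitude.
    """
    if rec.duration < RHYTHM_MIN_DURATION:
        return None
    # max-normalization keeps the spectrum gain-invariant without blowing up
    # the numerical ripple of near-constant envelopes (min-max would)
    trace = compute_rmse_trace(rec, normalize=False)
    env_rate = rec.rate / trace.hop  # envelope samples per second
    win = int(round(RHYTHM_WINDOW * env_rate))
    hop = max(int(round(RHYTHM_HOP * env_rate)), 1)
    env = trace.rmse / trace.rmse.max() if trace.rmse.max() > 0 else trace.rmse
    starts = np.arange(0, env.size - win + 1, hop)
    if starts.size == 0:
        return None
    energies = np.array([env[s : s + win].sum() for s in starts])
    best = starts[np.argsort(energies)[::-1][:3]]
    freqs_full = np.fft.rfftfreq(RHYTHM_NFFT, d=1.0 / env_rate)
    spectra = []
    for s in best:
        d = np.diff(env[s : s + win])
        d = d - d.mean()
        d = d * np.hanning(d.size)
        spec = np.fft.rfft(d, n=RHYTHM_NFFT)
        vals = spec.real if use_real_part else np.abs(spec)
        # band-limit by bin masking (exact; no filter design)
        vals = np.where(
            (freqs_full >= RHYTHM_BAND[0]) & (freqs_full <= RHYTHM_BAND[1]), vals, 0.0
        )
        spectra.append(vals)
    mean_spec = np.mean(spectra, axis=0)
    keep = (freqs_full >= RHYTHM_KEEP[0]) & (freqs_full <= RHYTHM_KEEP[1])
    return freqs_full[keep], mean_spec[keep]


def rhythm_spectrogram(recs, use_real_part: bool = False) -> RhythmSpectrogram:
    """Stack per-file rhythm spectra; too-short files are skipped, not fatal."""
    cols, ids, skipped = [], [], []
    freqs = None
    for rec in recs:
        out = rhythm_spectrum(rec, use_real_part)
        if out is None:
            skipped.append(rec.source_id)
            continue
        freqs, spec = out
        cols.append(spec)
        ids.append(rec.source_id)
    if not cols:
        raise InputError("no file long enough for rhythm analysis")
    return RhythmSpectrogram(freqs, np.column_stack(cols), ids, skipped)


def rhythm_entropy(rs: RhythmSpectrogram) -> float:
    """Wiener entropy of the mean rhythm spectrum's power (<= 0).

    mean(ln power) - ln(mean power): 0 for a flat spectrum, increasingly
    negative as energy concentrates into harmonic bands.  Evaluated over
    the bins the band-limit actually kept (>= 1 Hz); the zeroed sub-1 Hz
    bins carry no signal and would otherwise dominate the geometric mean.
    """
    mask = rs.freqs >= RHYTHM_BAND[0]
    if not mask.any():
        mask = np.ones_like(rs.freqs, dtype=bool)
    mean_spec = rs.spectra[mask].mean(axis=1)
    power = mean_spec**2
    power = np.clip(power, 1e-300, None)
    return float(np.mean(np.log(power)) - np.log(np.mean(power)))


def peak_freq_cv(rs: RhythmSpectrogram, band_half_width: float = PEAK_BAND_HALF_WIDTH) -> float:
    """CV of per-file rhythm peak frequency within a 3 Hz band.

    The peak frequency of each file is first taken over the full 0-30 Hz
    band to locate the median peak; each file's peak is then re-estimated
    within median +/- ``band_half_width`` Hz so jumps between harmonic bands
    do not inflate the variability.  Population s.d. / mean.
    """
    if rs.spectra.shape[1] < 2:
        raise InputError("peak frequency CV needs at least two files")
    raw_peaks = rs.freqs[np.argmax(rs.spectra, axis=0)]
    med = float(np.median(raw_peaks))
    mask = (rs.freqs >= med - band_half_width) & (rs.freqs <= med + band_half_width)
    if not mask.any():
        mask = np.ones_like(rs.freqs, dtype=bool)
    sub = rs.spectra[mask]
    peaks = rs.freqs[mask][np.argmax(sub, axis=0)]
    mean = peaks.mean()
    return float(peaks.std(ddof=0) / mean) if mean else 0.0


def plot_rhythm_spectrogram(rs: RhythmSpectrogram, smoothed: bool = True, ax=None):
    """Display the rhythm spectrogram (rolling 10-file mean by default).

    Convenience view; features always use the raw spectra.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    data = rs.smoothed() if smoothed else rs.spectra
    ax.imshow(
        data,
        aspect="auto",
        origin="lower",
        extent=(0, data.shape[1], rs.freqs[0], rs.freqs[-1]),
        cmap="magma",
    )
    ax.set_xlabel("file index")
    ax.set_ylabel("rhythm frequency (Hz)")
    return ax


def timing_features(recs, segments=None) -> TimingFeatures:
    """Bird-level timing summary from recordings (+ optional segment table).

    Duration entropies need segment durations; when ``segments`` is None
    they are NaN and only the rhythm features are computed.
    """
    import pandas as pd

    if segments is not None and len(segments):
        segs = segments
        durs = (segs["offset"] - segs["onset"]).values
        se = duration_entropy(durs, "syllable").entropy_norm
        gaps = []
        for _, grp in segs.groupby("file", sort=False):
            grp = grp.sort_values("onset")
            g = grp["onset"].values[1:] - grp["offset"].values[:-1]
            gaps.extend(g[(g > 0) & (g <= 0.2)])
        ge = duration_entropy(gaps, "gap").entropy_norm if gaps else float("nan")
    else:
        se = ge = float("nan")
    rs = rhythm_spectrogram(recs)
    re_ = rhythm_entropy(rs)
    pf = peak_freq_cv(rs) if rs.spectra.shape[1] >= 2 else float("nan")
    return TimingFeatures(se, ge, re_, pf)
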