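"""Shared audio primitives: WAV I/O, bandpass filtering, RMSE traces, spectrograms.

Conventions fixed here and relied on by every downstream stage:

* Frames are **centered**: the signal is reflect-padded by half a frame on
  each side, so frame ``k`` is centered on sample ``k * hop`` and its
  timestamp is ``k * hop / rate`` seconds.
* dB scaling is referenced to the maximum magnitude in the array, with a
  small epsilon (``DB_EPS``) added before the log so silent input produces a
  finite uniform floor rather than ``-inf``.
* The per-file RMSE trace is min-max normalized to [0, 1], which makes a
  single global segmentation threshold meaningful across recordings.
* Bandpass filtering is zero-phase (forward-backward 4th-order Butterworth),
  so filtering never shifts segment timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "AudioRecording",
    "AmplitudeTrace",
    "Spectrogram",
    "InputError",
    "ParameterError",
    "load_wav",
    "write_wav",
    "bandpass",
    "compute_rmse_trace",
    "make_spectrogram",
    "DEFAULT_HOP",
    "DEFAULT_FRAME_LEN",
    "SPEC_WINDOW",
    "SPEC_HOP",
    "DB_EPS",
]

#: hop length (samples) for amplitude/RMSE traces
DEFAULT_HOP = 512
#: frame length (samples) for amplitude/RMSE traces
DEFAULT_FRAME_LEN = 2048
#: STFT window length (samples) for syllable spectrograms
SPEC_WINDOW = 512
#: STFT hop length (samples) for syllable spectrograms
SPEC_HOP = 128
#: epsilon added to magnitudes before log scaling
DB_EPS = 1e-10

#: Butterworth order used for all bandpass filters (applied forward-backward)
BANDPASS_ORDER = 4


class InputError(ValueError):
    """Raised for unreadable or structurally invalid input data."""


class ParameterError(ValueError):
    """Raised for out-of-range analysis parameters."""


@dataclass
class AudioRecording:
    """Mono audio with its sample rate and an opaque source identifier."""

    samples: np.ndarray
    rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError("AudioRecording requires mono (1-D) samples")
        if self.samples.size == 0:
            raise InputError("AudioRecording requires non-empty samples")
        if self.rate <= 0:
            raise InputError("AudioRecording requires rate > 0")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate


@dataclass
class AmplitudeTrace:
    """Per-frame RMSE of a recording, min-max normalized to [0, 1]."""

    rmse: np.ndarray
    hop: int
    frame_len: int
    rate: int
    source_id: str = ""

    @property
    def times(self) -> np.ndarray:
        """Timestamp of each frame center in seconds (k * hop / rate)."""
        return np.arange(self.rmse.size) * self.hop / self.rate


@dataclass
class Spectrogram:
    """dB-scaled magnitude spectrogram (freq rows x time columns)."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_len: int
    hop: int


def load_wav(path) -> AudioRecording:
    """Read a WAV file as mono float samples at its native rate.

    Integer PCM is rescaled to [-1, 1]; multi-channel audio is averaged
    across channels.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises assorted ValueError subtypes
        raise InputError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM is offset-binary
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.size == 0:
        raise InputError(f"WAV file {path!r} contains no samples")
    import os

    return AudioRecording(data, int(rate), source_id=os.path.basename(str(path)))


def write_wav(path, rec: AudioRecording) -> None:
    """Write a recording as 32-bit float WAV."""
    wavfile.write(path, rec.rate, rec.samples.astype(np.float32))


def bandpass(rec: AudioRecording, lo: float, hi: float) -> AudioRecording:
    """Zero-phase Butterworth bandpass; preserves length, rate and timing."""
    nyq = rec.rate / 2
    if not (0 < lo < hi):
        raise ParameterError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ParameterError(f"hi={hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = butter(BANDPASS_ORDER, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sosfiltfilt(sos, rec.samples)
    return AudioRecording(filtered, rec.rate, rec.source_id)


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Centered framing with reflect padding; returns (n_frames, frame_len)."""
    pad = frame_len // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + len(x) // hop  # centered convention: frame k at sample k*hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    if idx.max() >= xp.size:  # last frame can overrun when hop ∤ len(x)
        xp = np.pad(xp, (0, idx.max() - xp.size + 1), mode="reflect")
    return xp[idx]


def compute_rmse_trace(
    rec: AudioRecording,
    hop: int = DEFAULT_HOP,
    frame_len: int = DEFAULT_FRAME_LEN,
    normalize: bool = True,
) -> AmplitudeTrace:
    """Per-frame root-mean-square energy, min-max normalized per file.

    Frames are centered with reflect padding; frame ``k`` sits at
    ``k*hop/rate`` seconds. With ``normalize=True`` (default) the trace is
    scaled to [0, 1]; a constant trace maps to all zeros.
    """
    if rec.samples.size < frame_len:
        raise InputError(
            f"recording of {rec.samples.size} samples shorter than frame_len={frame_len}"
        )
    frames = _frame(rec.samples, frame_len, hop)
    rmse = np.sqrt(np.mean(frames**2, axis=1))
    if normalize:
        lo, hi = rmse.min(), rmse.max()
        rmse = (rmse - lo) / (hi - lo) if hi > lo else np.zeros_like(rmse)
    return AmplitudeTrace(rmse, hop, frame_len, rec.rate, rec.source_id)


def make_spectrogram(
    rec: AudioRecording,
    window_len: int = SPEC_WINDOW,
    hop: int = SPEC_HOP,
    top_db: float | None = 80.0,
) -> Spectrogram:
    """dB-scaled magnitude STFT referenced to the file's maximum magnitude.

    Hann-windowed centered frames; dB values are
    ``20 log10((|S| + eps) / (max|S| + eps))`` so the peak sits at 0 dB and
    an all-zero signal yields a uniform 0 dB floor with no NaN/-inf.
    ``top_db`` clips the dynamic range at that many dB below the peak
    (pass None to disable).
    """
    if hop <= 0:
        raise ParameterError(f"hop must be positive, got {hop}")
    if window_len > rec.samples.size:
        raise InputError(
            f"window_len={window_len} exceeds recording length {rec.samples.size}"
        )
    frames = _frame(rec.samples, window_len, hop)
    win = np.hanning(window_len)
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T  # freq x time
    ref = mag.max()
    db = 20.0 * np.log10((mag + DB_EPS) / (ref + DB_EPS))
    if top_db is not None:
        db = np.maximum(db, -top_db)
    freqs = np.fft.rfftfreq(window_len, d=1.0 / rec.rate)
    times = np.arange(mag.shape[1]) * hop / rec.rate
    return Spectrogram(db, freqs, times, window_len, hop)
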