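"""Deterministic synthetic zebra finch song generator.

Produces WAV-writable audio plus ground-truth segment/label tables for
exercising the whole analysis pipeline.  Syllables are additive harmonic
stacks (fundamental + rolled-off harmonics) with optional linear frequency
sweep and a noise admixture — the simplest signal family that gives every
acoustic feature (pitch, goodness of pitch, Wiener entropy, FM, mean
frequency) something to measure.  Song structure follows a first-order
Markov grammar: a variable number of introductory notes, then a motif, with
a transition-noise knob ``epsilon`` that replaces motif transitions with
random jumps.

Presets encode the study regimes:

* ``adult``     — stereotyped song: tight duration jitter, epsilon 0.01.
* ``juvenile``  — variable song: 3x duration jitter, heavy amplitude
  wander, epsilon 0.5.
* ``isolate_like`` — few types, long variable syllables, loose grammar.
* ``repeater``  — one motif syllable repeats with geometric run lengths,
  exercising repetition-bout statistics (expected mean run length 1/(1-q)).

All randomness flows from a single seed; per-file substreams are derived
deterministically, so a spec renders byte-identical audio on every run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio_core import AudioRecording, InputError
from .segmentation import SEGMENT_COLUMNS, validate_segments

__all__ = [
    "SyllableArchetype",
    "SongGrammar",
    "SynthSongSpec",
    "render_song",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SyllableArchetype:
    """Parametric description of one syllable type."""

    fundamental: float  # Hz
    n_harmonics: int = 5
    rolloff: float = 0.6  # amplitude ratio between successive harmonics
    dur_mean: float = 0.08  # s
    dur_jitter: float = 0.004  # s.d. of duration (s)
    sweep: float = 0.0  # linear fundamental sweep (Hz/s)
    noisiness: float = 0.05  # in [0,1]: fraction of noise mixed in
    f0_jitter: float = 0.02  # per-rendition fractional s.d. of the fundamental
    amp_jitter: float = 0.1  # s.d. of slow random within-syllable gain modulation

    def __post_init__(self):
        if self.dur_mean <= 0:
            raise InputError("archetype duration mean must be positive")


@dataclass(frozen=True)
class SongGrammar:
    """First-order syllable grammar: intro notes then a motif."""

    motif: tuple  # ordered syllable tokens, e.g. ("a","b","c")
    intro_token: str = "i"
    intro_min: int = 1
    intro_max: int = 4
    epsilon: float = 0.0  # probability of a random off-motif transition
    motif_repeats: int = 1  # motif passes per bout (adults chain several)
    gap_mean: float = 0.06  # intra-bout silent gap (s)
    gap_jitter: float = 0.01
    repeat_token: str | None = None  # token with geometric self-repeats
    repeat_q: float = 0.0  # P(continue repeating); mean run 1/(1-q)

    @property
    def tokens(self) -> tuple:
        return tuple(dict.fromkeys((self.intro_token,) + tuple(self.motif)))


@dataclass(frozen=True)
class SynthSongSpec:
    """Full recipe for a synthetic song dataset."""

    grammar: SongGrammar
    archetypes: dict  # token -> SyllableArchetype
    bouts_per_file: int = 3
    n_files: int = 4
    rate: int = 44100  # typical colony recording rate; resolves 10 ms onsets
    noise_floor: float = 1e-3  # s.d. of background Gaussian noise
    cage_noise_rate: float = 0.0  # expected broadband noise events per file
    inter_bout_gap: float = 0.5  # s, must exceed the 200 ms bout rule
    seed: int = 0

    def __post_init__(self):
        g = self.grammar
        if g.gap_mean - 4 * g.gap_jitter < 0:
            raise InputError("gap jitter can produce negative gaps")
        if g.gap_mean + 4 * g.gap_jitter > 0.2:
            raise InputError("intra-bout gaps must stay below 200 ms")
        for tok in g.tokens:
            if tok not in self.archetypes:
                raise InputError(f"grammar token {tok!r} has no archetype")
            a = self.archetypes[tok]
            if a.fundamental * a.n_harmonics >= self.rate / 2:
                raise InputError(f"archetype {tok!r} aliases above Nyquist")


def _syllable_wave(arch: SyllableArchetype, dur: float, rate: int, rng) -> np.ndarray:
    n = max(int(round(dur * rate)), 8)
    t = np.arange(n) / rate
    f0_base = arch.fundamental * (1.0 + arch.f0_jitter * rng.standard_normal())
    f0 = f0_base + arch.sweep * t
    phase = 2 * np.pi * np.cumsum(f0) / rate
    wave = np.zeros(n)
    for h in range(1, arch.n_harmonics + 1):
        wave += arch.rolloff ** (h - 1) * np.sin(h * phase)
    wave /= np.max(np.abs(wave))
    if arch.noisiness > 0:
        wave = (1 - arch.noisiness) * wave + arch.noisiness * rng.standard_normal(n)
    if arch.amp_jitter > 0:  # slow (~20 ms) random gain wander within the syllable
        knots = max(int(np.ceil(dur / 0.02)) + 2, 2)
        gains = np.clip(1.0 + arch.amp_jitter * rng.standard_normal(knots), 0.1, None)
        wave = wave * np.interp(np.arange(n), np.linspace(0, n - 1, knots), gains)
    # 5 ms cosine ramps avoid onset/offset clicks
    ramp = min(int(0.005 * rate), n // 4)
    env = np.ones(n)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    return 0.7 * wave * env


def _sample_bout_tokens(g: SongGrammar, rng) -> list:
    tokens = [g.intro_token] * int(rng.integers(g.intro_min, g.intro_max + 1))
    motif = list(g.motif)
    for _ in range(g.motif_repeats):
        pos = 0
        steps = 0
        while steps < 3 * len(motif):  # one motif pass, with epsilon detours
            if rng.random() < g.epsilon:
                tok = motif[int(rng.integers(len(motif)))]
            else:
                tok = motif[pos]
                pos += 1
            tokens.append(tok)
            if g.repeat_token is not None and tok == g.repeat_token:
                while rng.random() < g.repeat_q:
                    tokens.append(tok)
            steps += 1
            if pos >= len(motif):
                break
    return tokens


def render_song(spec: SynthSongSpec):
    """Render the dataset.

    Returns ``(recordings, truth)`` where ``recordings`` is a list of
    :class:`AudioRecording` (source ids ``synth_000.wav`` ...) and ``truth``
    a validated segment table with ground-truth labels (cage-noise events,
    if any, labeled ``"noise"``).
    """
    master = np.random.default_rng(spec.seed)
    file_seeds = master.integers(0, 2**31 - 1, size=spec.n_files)
    recordings = []
    rows = []
    for fi in range(spec.n_files):
        rng = np.random.default_rng(file_seeds[fi])
        fname = f"synth_{fi:03d}.wav"
        chunks = [np.zeros(int(0.3 * spec.rate))]
        cursor = 0.3
        for _ in range(spec.bouts_per_file):
            for tok in _sample_bout_tokens(spec.grammar, rng):
                arch = spec.archetypes[tok]
                dur = max(float(rng.normal(arch.dur_mean, arch.dur_jitter)), 0.015)
                wave = _syllable_wave(arch, dur, spec.rate, rng)
                rows.append((fname, cursor, cursor + len(wave) / spec.rate, tok))
                chunks.append(wave)
                cursor += len(wave) / spec.rate
                gap = float(rng.normal(spec.grammar.gap_mean, spec.grammar.gap_jitter))
                gap = float(np.clip(gap, 0.02, 0.19))
                chunks.append(np.zeros(int(gap * spec.rate)))
                cursor += int(gap * spec.rate) / spec.rate
            chunks.append(np.zeros(int(spec.inter_bout_gap * spec.rate)))
            cursor += int(spec.inter_bout_gap * spec.rate) / spec.rate
        samples = np.concatenate(chunks)
        n_noise = rng.poisson(spec.cage_noise_rate)
        for _ in range(n_noise):
            ndur = float(rng.uniform(0.03, 0.12))
            nlen = int(ndur * spec.rate)
            start = int(rng.uniform(0, max(len(samples) - nlen, 1)))
            burst = 0.4 * rng.standard_normal(nlen) * np.hanning(nlen)
            samples[start : start + nlen] += burst
            rows.append((fname, start / spec.rate, (start + nlen) / spec.rate, "noise"))
        if spec.noise_floor > 0:
            samples = samples + spec.noise_floor * rng.standard_normal(len(samples))
        recordings.append(AudioRecording(samples, spec.rate, source_id=fname))
    truth = validate_segments(pd.DataFrame(rows, columns=SEGMENT_COLUMNS))
    return recordings, truth


def _default_archetypes(
    dur_jitter: float = 0.006,
    noisiness: float = 0.08,
    f0_jitter: float = 0.02,
    amp_jitter: float = 0.05,
) -> dict:
    args = (noisiness, f0_jitter, amp_jitter)
    return {
        "i": SyllableArchetype(2200, 3, 0.5, 0.045, dur_jitter * 0.8, 0.0, *args),
        "a": SyllableArchetype(700, 7, 0.7, 0.090, dur_jitter, 9000.0, *args),
        "b": SyllableArchetype(1400, 5, 0.6, 0.070, dur_jitter, -5000.0, *args),
        "c": SyllableArchetype(950, 6, 0.65, 0.110, dur_jitter, 2500.0, *args),
    }


PRESET_NAMES = ("adult", "juvenile", "isolate_like", "repeater")


def preset(name: str, seed: int = 0, n_files: int = 4, bouts_per_file: int = 3) -> SynthSongSpec:
    """Documented parameter bundles for the study regimes."""
    if name == "adult":
        return SynthSongSpec(
            grammar=SongGrammar(
                motif=("a", "b", "c"), epsilon=0.005, intro_min=2, intro_max=3,
                motif_repeats=2, gap_jitter=0.005,
            ),
            archetypes=_default_archetypes(),
            n_files=n_files,
            bouts_per_file=bouts_per_file,
            seed=seed,
        )
    if name == "juvenile":
        return SynthSongSpec(
            grammar=SongGrammar(
                motif=("a", "b", "c"), epsilon=0.5, gap_mean=0.08, gap_jitter=0.02,
                motif_repeats=2,
            ),
            archetypes=_default_archetypes(dur_jitter=0.020, noisiness=0.15, f0_jitter=0.05, amp_jitter=0.8),
            n_files=n_files,
            bouts_per_file=bouts_per_file,
            seed=seed,
        )
    if name == "isolate_like":
        arche = {
            "i": SyllableArchetype(2000, 3, 0.5, 0.05, 0.004, 0.0, 0.08, 0.03, 0.3),
            "a": SyllableArchetype(800, 6, 0.7, 0.180, 0.030, 3000.0, 0.10, 0.03, 0.3),
            "b": SyllableArchetype(1100, 5, 0.6, 0.140, 0.025, -2000.0, 0.10, 0.03, 0.3),
        }
        return SynthSongSpec(
            grammar=SongGrammar(motif=("a", "b"), epsilon=0.3),
            archetypes=arche,
            n_files=n_files,
            bouts_per_file=bouts_per_file,
            seed=seed,
        )
    if name == "repeater":
        return SynthSongSpec(
            grammar=SongGrammar(
                motif=("a", "b", "c"), epsilon=0.02, repeat_token="b", repeat_q=0.6
            ),
            archetypes=_default_archetypes(),
            n_files=n_files,
            bouts_per_file=bouts_per_file,
            seed=seed,
        )
    raise InputError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")


def variant(spec: SynthSongSpec, **kwargs) -> SynthSongSpec:
    """Return a copy of ``spec`` with top-level fields replaced."""
    return replace(spec, **kwargs)
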