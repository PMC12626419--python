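# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind `songpheno`, and what the synthetic-data validation does and
does not establish about real recordings.

## Audio conventions

All analyses share one framing convention: frames are centered, the signal
is reflect-padded by half a frame, and frame *k* carries timestamp
`k·hop/rate`. dB scaling is referenced to the maximum magnitude of the
array at hand, with an epsilon of 1e-10 inside the log so silent input
yields a finite uniform floor. Spectrogram dynamic range is clipped at
80 dB below peak by default (40 dB for labeling spectrograms, see below).
Bandpass filtering is a 4th-order Butterworth applied forward-backward
(zero phase), so filtering never shifts event timestamps. The per-file
RMSE trace (hop 512, frame 2048) is min-max normalized to [0, 1], which is
what makes a single global segmentation threshold meaningful across
recordings of different gain.

## Segmentation

A syllable onset is a positive crossing of the onset threshold by the
first difference of the normalized RMSE; segmentation is onset-to-onset,
with bout-final offsets placed at the first negative crossing of the
offset threshold within the RMSE itself when no further onset follows
within 300 ms. Segments shorter than two trace frames are discarded as
degenerate crossings.

One subtlety matters for timing accuracy: because RMSE frames are
centered, energy from a sharp onset starts entering the analysis window
`frame_len/2` samples *before* the onset, and for an RMS-shaped rise the
first derivative crossing fires essentially at that leading edge. Reported
times are therefore shifted forward by `frame_len/2 / rate` (≈23 ms at
44.1 kHz). This correction is on by default and can be disabled
(`center_correction=False`); with it, onsets on clean synthetic song are
recovered with a median error of ~3 ms, within the 10 ms evaluation
tolerance.

Event matching for evaluation is greedy over increasing |Δt| with
one-to-one use of events. For reference events separated by at least twice
the tolerance — which syllable onsets always are at the 10 ms tolerance —
the candidate graph is a union of stars and the greedy pairing attains the
maximum-cardinality assignment; the test suite verifies this against a
brute-force bipartite-matching oracle. Threshold optimization evaluates a
candidate grid and keeps the setting with the highest mean onset-F1 across
birds, breaking ties toward the lower onset threshold.

## Labeling

Syllable spectrograms for clustering are bandpassed 500 Hz–15 kHz,
amplitude-normalized per rendition, STFT'd (window 512, hop 128), dB
scaled with a 40 dB dynamic-range clip, padded to the longest syllable in
the bird's set (clipped at 870 ms), and flattened. The 40 dB clip (vs the
80 dB elsewhere) bounds the contrast between pad columns and signal
columns, so small duration differences between renditions do not dominate
Euclidean distances.

UMAP runs with 2 output dimensions, `n_neighbors=10`, `min_dist=0.0`
(dense local packing is what a density-based clusterer wants), fixed seed.
HDBSCAN uses `min_cluster_size = max(5, 0.1·n)` and
`allow_single_cluster=True`; the fraction rule reflects that a zebra finch
sings each of its handful of types many times per day, so genuine types
are never a sliver of the pool, and `allow_single_cluster` is required for
the degenerate one-type repertoire. Every value is overridable, but the
contract is one shared set across birds — never per-bird tuning. Points
HDBSCAN declines carry the reserved noise token `-1` and are retained
downstream as their own category.

Evaluation aligns predictions to references by onset within 100 ms;
unmatched predictions get reference category `x`, unmatched references get
cluster `1000`. Homogeneity and completeness are the standard
`1 − H(·|·)/H(·)` forms with natural logs (the base cancels); degenerate
0/0 cases are defined as 1. The implementation is verified against both a
first-principles entropy computation and scikit-learn's independent
implementation.

## Syntax

Bout extraction, the transition matrix, and the entropy rate follow the
rules stated in the README. Details fixed here:

* Syllables isolated by >200 ms of silence on both sides are dropped as
  putative calls before syntax analysis; file bounds count as long
  silence for this rule.
* The transition matrix inserts a silence state at intra-file gaps
  >200 ms. Transitions across file bounds are never counted. Leading and
  trailing silences can only be represented when file durations are
  supplied (optional argument); without them the first and last syllables
  of a file simply have no silence-side transitions.
* Occupancy π includes the silence state by default (configurable).
* Terminal-only states (no outgoing transitions) contribute nothing to the
  entropy sum. The normalized score is clipped to [0, 1].
* Repetition-bout CV uses the population standard deviation (ddof=0), as
  do all CVs in the package.
* Introductory-note criterion: a type qualifies if its probability of
  being entered from silence is within 0.05 (absolute) of the most
  silence-entered type, **and** its outgoing distribution — renormalized
  over targets other than itself and silence — has a dominant target above
  0.5. The renormalization is deliberate: intro notes repeat, so their raw
  row probability is dominated by the self-transition, and the "dominant
  following syllable" reading only makes sense among non-self targets.
* Call criterion: a non-intro type produced in an isolated run of one or
  two syllables in more than ⅓ of its utterances.
* The bird-level repetition features report the non-intro, non-call type
  with the highest mean repetition-bout length; if every type is excluded
  the features are NaN.

## Timing

Duration entropies use fixed histograms (syllables: 50 bins over
log₁₀ s ∈ [−2.5, 0]; gaps: 20 × 10 ms bins, gaps above 200 ms excluded
upstream as bout boundaries) and normalized entropy −Σ p ln p / ln N with
0·ln 0 := 0.

Rhythm analysis uses the RMSE trace (hop 512) as the amplitude envelope,
max-normalized per file. Max (rather than min-max) normalization keeps the
spectrum invariant to overall gain without amplifying the numerical ripple
of near-constant envelopes. Files shorter than 3.6 s (one 3 s window plus
three 0.2 s hops) are skipped with a marker, not an error. Band-limiting
to 1–500 Hz is applied by masking FFT bins (exact; no filter design), and
the "real component" of the transform is implemented as the magnitude of
the real-input FFT, with the literal real part available by flag. The
Wiener entropy of the mean rhythm spectrum is evaluated over the retained
1–30 Hz bins only: the sub-1 Hz bins are zeroed by the band-limit and
would otherwise contribute a large constant to the geometric mean that
carries no information about the song. The peak-frequency CV re-estimates
each file's peak inside a 3 Hz band (median ± 1.5 Hz) so jumps between
harmonic bands do not masquerade as rhythm variability.

## Acoustic features

The seven frame-level features use these operational definitions (window
512, hop 128, Hann):

| feature | definition |
|---|---|
| amplitude | 10 log₁₀ of total frame power (gain-sensitive by design) |
| Wiener entropy | mean(ln power) − ln(mean power) per frame |
| mean frequency | power-weighted spectral centroid |
| pitch | frequency of the largest real-cepstrum peak, search range 300–3000 Hz |
| goodness of pitch | height of that cepstral peak |
| amplitude modulation | frame-to-frame derivative of total power |
| frequency modulation | arctan of Σ(∂S/∂t)² / Σ(∂S/∂f)² on the dB spectrogram |

Spectral floors are relative to each frame's peak power, which makes every
feature except amplitude and AM exactly invariant to gain; those two are
flagged recording-sensitive in the package metadata because they track the
microphone, not the bird. These definitions are frozen by regression tests;
numerical parity with the original MATLAB analysis tools is not claimed.
One practical consequence: the cepstral-peak goodness of pitch separates
harmonic stacks from white noise by roughly a factor of 2–3 (the noise
score is the extreme value of the log-periodogram cepstrum, ≈0.17 for
512-sample frames), not by an order of magnitude.

Summarization: rendition mean over frames whose center lies in
[onset, offset); per-type mean and population CV over renditions (CV is
NaN for single-rendition types); min / lower-median / max across types.
8 base features × {mean, CV} × {min, median, max} = 48 values, plus
entropy rate, mean and CV of repetition-bout length, syllable- and
gap-duration entropy, rhythm-spectrum entropy, and peak-frequency CV = 55,
in a fixed documented order. Missing components propagate as NaN, never
imputed.

## Similarity scoring

Input spectrograms are amplitude-normalized, clipped or zero-padded to
180 ms, and restricted to 2–6 kHz. The published architecture — conv
(32×3×3), then four repetitions of [multiscale analysis module → conv
64×3×3 with stride 2 on the frequency axis], where each MAM runs four
parallel strands (1×1; 1×1→3×3; 1×1→5×5; 1×1→7×7; 32 kernels each)
concatenated to 128 channels, ReLU throughout, global average pooling, and
three dense layers to an L2-normalized 8-D output — is implemented
directly in numpy with hand-written backward passes and AdamW
(weight decay 1e-4). A desk-scale preset (16×16 pooled inputs, 2 conv
layers + 1 MAM at reduced widths by default; the tests' family experiment
uses 3 conv + 2 MAM with 16/32-channel widths) is what the test suite and
acceptance script train; the full architecture is constructible from the
same builder and verified by a forward-pass test.

Training mines all valid triplets per mini-batch (anchor and positive
share a type label from the same bird; the negative differs in type),
classifies them as hard (d(A,P) > d(A,N)), semi-hard
(0 < d(A,N) − d(A,P) < α) or zero, and samples 75:25 semi-hard:hard. The
margin starts at 0.1 and steps by 0.2 (cap 0.7) after any epoch whose
average count of informative triplets per batch falls below a threshold —
2500 at published scale; the desk default is 40, scaled to the toy batch
sizes. Distances in the loss are plain (unsquared) Euclidean norms; a
config flag enables the squared variant. Training is deterministic given
the seed.

EMD is exact optimal transport with uniform weights and Euclidean ground
metric: equal-size pools reduce to a linear-sum assignment, unequal sizes
solve the transport LP. On the unit 8-sphere the distance between two
point masses at orthogonal positions is √2 ≈ 1.41, the space's practical
maximum. MMD uses a Gaussian RBF kernel with σ = half the median pairwise
distance among ≤1000 sampled reference embeddings, the biased estimator
with diagonal terms (so identical sets score exactly 0), reported as
√max(MMD², 0).

Comparison protocols: a self-comparison splits pools under 4000 syllables
into disjoint halves and samples two disjoint 2000-syllable sets
otherwise; all other comparisons subsample up to 4000 per bird. Sampling
seeds are recorded in every report. The contrast index is the absolute
value of (self − cross)/(self + cross) with cross the mean over three
unrelated-bird comparisons; the tutor contrast index substitutes the
tutor comparison.

At desk scale the self-comparison EMD carries a finite-sample floor
(~0.05–0.2): splitting a few hundred embeddings in half leaves
cluster-proportion mismatch and nearest-neighbor bias that vanish only at
the thousands-of-syllables scale. The contrast index on the fixed
validation fixtures exceeds 0.8, but it varies noticeably with the
generator and training seeds; the acceptance script reports whatever the
supplied seed produces.

## Synthetic song generator

The generator is the statistical ground truth for every parameter-recovery
claim. Syllables are additive harmonic stacks (fundamental, harmonic count,
rolloff) with optional linear frequency sweep, noise admixture, 5 ms
onset/offset ramps, and per-rendition jitter in duration (Gaussian),
fundamental (fractional Gaussian), and a slow (~20 ms knot spacing) random
within-syllable gain wander. Song structure is a first-order grammar:
a variable number of introductory notes, then one or more motif passes,
with probability ε of an off-motif jump at each step and optional
geometric self-repeats for one token. Intra-bout gaps are jittered below
200 ms; inter-bout silences are 0.5 s. Optional broadband cage-noise
bursts are labeled `noise` in the truth table. All randomness derives from
one seed with per-file substreams, so output is bit-reproducible.

Default rate is 44.1 kHz — the usual colony recording rate — which also
makes the RMSE frame grid (11.6 ms) fine enough to resolve the 10 ms onset
tolerance. Regime presets: `adult` (duration jitter 6 ms, f0 jitter 2%,
amplitude wander 0.05, ε = 0.005, two motif passes, intro count 2–3),
`juvenile` (duration jitter 20 ms, f0 jitter 5%, amplitude wander 0.8,
ε = 0.5 — the heavy amplitude wander is the defining envelope instability
of subsong), `isolate_like` (fewer, longer, more variable types), and
`repeater` (one motif syllable with geometric repeats, mean run length
1/(1−q) = 2.5).

What the generator does *not* emulate: realistic syrinx acoustics,
reverberation, overlapping cage noise during syllables, calls interleaved
with song, long-range syntax dependencies, or recording-chain variation.
Passing the validation suite therefore demonstrates correctness of the
algorithms under controlled conditions — thresholds transfer across
gain and file boundaries, clustering recovers well-separated types,
entropy features order regimes correctly — not field performance on
colony recordings, which depends on segmentation and annotation quality
the synthetic fixtures idealize.

A realism note: perfectly identical renditions (zero acoustic jitter)
produce a pathological clustering geometry — renditions quantize onto
discrete spectrogram frame counts and every type shatters into
frame-count islands. No real bird produces identical renditions; the
default jitters are chosen at the low end of natural variability.

## Numerical choices and degenerate inputs

* 0/0 conventions: precision/recall/F1 → 0; homogeneity/completeness → 1
  (single-class); CV of a single rendition → NaN.
* All-zero audio yields finite floor spectrograms and features, never NaN.
* Entropy computations use 0·ln 0 := 0 and clip normalized scores to
  their stated ranges.
* Even type counts use the lower median.
* Ties in threshold optimization break toward the lower onset threshold.
* The EMD transport LP is solved with HiGHS; equal-size pools bypass it
  via the assignment solver.

## Known limitations

* Amplitude segmentation cannot place offsets of non-final syllables
  (onset-to-onset design); offset F1 is only meaningful for external
  segmenters ingested as tables.
* The desk-scale embedder demonstrates the training dynamics and the
  metric pipeline, not the published model's representational capacity;
  contrast indices at this scale are seed-dependent.
* Goodness of pitch, AM, and FM are operational definitions, not
  re-implementations of the original MATLAB tools; absolute values are not
  comparable across software.
* UMAP determinism holds per seed, platform, and library version; labels
  are stable only in distribution across seeds (the stability helper
  quantifies this).
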