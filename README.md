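# songpheno

Automated, interpretable phenotyping of zebra finch song.

Birdsong researchers quantify vocal learning by segmenting song recordings
into syllables, grouping the syllables into a bird's repertoire of types,
and summarizing syntax (the order of types), timing, and acoustics into
features that can be compared across birds, ages, and experimental
manipulations. `songpheno` implements that pipeline end to end on plain WAV
files, plus a metric-learning similarity scorer for comparing whole
repertoires, and a deterministic synthetic-song generator used to validate
every stage against known ground truth.

## What it computes

**Segmentation.** Syllable onsets are positive threshold crossings of the
first derivative of the per-file normalized RMSE trace (hop 512, frame
2048, audio bandpassed 200 Hz–9 kHz). Segmentation is onset-to-onset: a
segment spans a syllable and its trailing gap; a bout-final offset is the
first negative crossing of an offset threshold. External segmenter output
(e.g. from a pretrained neural segmenter) can be ingested as a CSV instead.
Evaluation matches events one-to-one within 10 ms (onsets) / 20 ms
(offsets) and reports precision, recall, and
F1 = TP / (TP + ½(FP + FN)).

**Labeling.** Per-syllable dB spectrograms (bandpass 500 Hz–15 kHz,
amplitude-normalized per rendition, STFT 512/128, padded to the longest
syllable, clipped at 870 ms) are embedded into 2-D with UMAP and clustered
with HDBSCAN under one shared hyperparameter set for all birds. Agreement
with reference annotations is scored by homogeneity, completeness and
v-measure:

    h = 1 − H(ref | cluster)/H(ref),  c = 1 − H(cluster | ref)/H(cluster),
    v = 2hc/(h + c)

**Syntax.** Bouts are runs of ≥2 syllables with gaps ≤200 ms. The
transition matrix over syllable types plus a silence state gives the
normalized entropy rate

    −Σᵢ πᵢ Σₖ p(k|i) log₂ p(k|i) / log₂ N,   N = #types + 1,

0 for fully stereotyped syntax, 1 for uniform transitions. Repetition
bouts (maximal runs of one type), putative introductory notes and putative
calls are identified by the printed transition-probability heuristics.

**Timing.** Normalized duration-distribution entropies (syllables: 50 bins
over log₁₀ duration ∈ [−2.5, 0]; gaps: 20 × 10 ms bins) and rhythm
analysis: each file's rhythm spectrum is the 0–30 Hz spectrum of the
amplitude-envelope derivative (3 s windows, 0.2 s hop, three
highest-energy windows, Hann, zero-padded to 100 000 points, band-limited
1–500 Hz). The Wiener entropy of the mean rhythm spectrum measures rhythm
strength; the CV of the per-file peak frequency inside a 3 Hz band around
the median measures rhythm stereotypy.

**Acoustics.** Seven frame-level features in the Sound Analysis tradition
(goodness of pitch, mean frequency, Wiener entropy, amplitude, amplitude
modulation, frequency modulation, pitch), summarized per rendition, then
per type (mean and CV), then across types (min/median/max), with syllable
duration as the eighth base feature: 8 × 2 × 3 = 48 acoustic values. With
3 syntax and 4 timing features the bird-level phenotype has exactly 55
named features.

**Similarity.** A convolutional triplet-loss network (five conv layers
alternating with four multiscale analysis modules, global pooling, three
dense layers) maps 180 ms, 2–6 kHz syllable spectrograms to unit 8-D
embeddings; training mines semi-hard and hard triplets 75:25 with a
dynamic margin (0.1 → 0.7 in steps of 0.2). Repertoires are compared as
embedding clouds with exact Earth Mover's Distance and Gaussian-kernel MMD
(bandwidth = half the median pairwise distance of ≤1000 reference
embeddings), and separability is summarized by the contrast index
|self − cross| / (self + cross).

## Worked example

Generate four files of stereotyped adult-regime song, segment them, label
the syllables, and compute features — no manual annotation involved:

```python
import pandas as pd
from songpheno import synthsong, segmentation, labeling, syntax, timing
from songpheno.audio_core import bandpass, compute_rmse_trace

spec = synthsong.preset("adult", seed=1, n_files=4, bouts_per_file=3)
recs, truth = synthsong.render_song(spec)

thr = segmentation.SegThresholds(0.05, 0.05)
pred = pd.concat(
    [segmentation.segment_amplitude(compute_rmse_trace(bandpass(r, 200, 9000)), thr)
     for r in recs],
    ignore_index=True,
)
ev = segmentation.evaluate_segmentation(truth, pred)
print(f"onset F1: {ev['onset']['f1']:.3f}")

labeled = labeling.label_syllables(recs, pred, seed=42)
print(f"clusters found: {sorted(set(labeled['label']))}")
lab_ev = labeling.cluster_eval(labeling.align_labels(truth, labeled))
print(f"v-measure vs truth: {lab_ev.v_measure:.3f}")

feats = syntax.syntax_features(labeled)
print(f"entropy rate: {feats.entropy_rate_norm:.3f}")
print(f"intro notes: {sorted(feats.intro_notes)}")
tf = timing.timing_features(recs, labeled)
print(f"syllable duration entropy: {tf.syll_duration_entropy:.3f}")
print(f"rhythm spectrum entropy: {tf.rhythm_spectrum_entropy:.3f}")
```

Output:

```
onset F1: 1.000
clusters found: ['0', '1', '2', '3']
v-measure vs truth: 1.000
entropy rate: 0.207
intro notes: ['1']
syllable duration entropy: 0.436
rhythm spectrum entropy: -0.804
```

Every generator onset is recovered within the 10 ms tolerance; the four
syllable archetypes come back as four clusters in perfect agreement with
the ground truth (v-measure 1.0); the low entropy rate reflects the
stereotyped adult grammar, and cluster `1` is flagged as the introductory
note. The same stages are available from the shell
(`songpheno synth / segment / seg-eval / label / label-eval / syntax /
timing / run`).

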