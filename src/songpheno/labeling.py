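"""Unsupervised syllable labeling: spectrogram prep, UMAP, HDBSCAN, evaluation.

Each segmented syllable is turned into a flattened dB spectrogram vector
(audio bandpassed 500 Hz - 15 kHz, amplitude-normalized per rendition, STFT
window 512 / hop 128, padded to the longest syllable or clipped at 870 ms).
The vectors are embedded into 2-D with UMAP and clustered with HDBSCAN; the
cluster tokens are the bird's automatic syllable labels, with ``-1``
reserved for points HDBSCAN declines to assign (noise).

One shared UMAP/HDBSCAN hyperparameter set is used for all birds; every
value is overridable but the contract is a single set per study, never
per-bird tuning.

Evaluation aligns predicted to reference segments by onset (100 ms
tolerance), assigns unmatched predictions the reference category ``"x"``
and unmatched references the cluster ``"1000"``, builds the confusion
matrix, and scores homogeneity = 1 - H(ref|cluster)/H(ref), completeness =
1 - H(cluster|ref)/H(cluster), and their harmonic mean (v-measure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_core import AudioRecording, InputError, bandpass, make_spectrogram
from .segmentation import match_events, validate_segments

__all__ = [
    "SyllableSpectrogramSet",
    "ClusterEval",
    "NOISE_LABEL",
    "UNMATCHED_REF_CLUSTER",
    "UNMATCHED_PRED_CATEGORY",
    "prepare_syllable_spectrograms",
    "embed_umap",
    "cluster_hdbscan",
    "label_syllables",
    "align_labels",
    "cluster_eval",
    "stability_over_seeds",
]

#: reserved cluster token for HDBSCAN noise points
NOISE_LABEL = "-1"
#: cluster assigned to reference syllables with no predicted counterpart
UNMATCHED_REF_CLUSTER = "1000"
#: reference category assigned to predictions with no reference counterpart
UNMATCHED_PRED_CATEGORY = "x"
#: onset-matching tolerance for label alignment (s)
ALIGN_TOL = 0.100
#: maximum represented syllable duration (s)
MAX_SYLLABLE_DURATION = 0.870
#: labeling bandpass (Hz); upper edge clipped below Nyquist when needed
LABEL_BAND = (500.0, 15000.0)
#: dynamic range (dB below peak) kept in labeling spectrograms; bounding the
#: floor keeps pad columns from dominating distances between renditions
LABEL_TOP_DB = 40.0

#: shared UMAP defaults (2-D output for clustering; dense local structure)
UMAP_DEFAULTS = dict(n_components=2, n_neighbors=10, min_dist=0.0, metric="euclidean")
#: shared HDBSCAN defaults; min cluster size scales with repertoire size.
#: a zebra finch sings every type many times a day, so any real cluster
#: holds a sizable fraction of the rendition pool
HDBSCAN_MIN_CLUSTER_FRACTION = 0.1
HDBSCAN_MIN_CLUSTER_FLOOR = 5


@dataclass
class SyllableSpectrogramSet:
    """Per-syllable flattened dB spectrogram vectors of identical length."""

    vectors: np.ndarray  # (n_syllables, n_pixels)
    segments: pd.DataFrame  # source rows
    shape: tuple  # (n_freqs, n_frames) before flattening
    clipped: int  # syllables clipped at the duration cap

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ClusterEval:
    confusion: pd.DataFrame  # clusters x reference labels
    homogeneity: float
    completeness: float
    v_measure: float


def prepare_syllable_spectrograms(
    recs, segs: pd.DataFrame, band: tuple = LABEL_BAND
) -> SyllableSpectrogramSet:
    """Standardize per-syllable spectrograms for embedding.

    ``recs`` is an iterable (or mapping file -> recording) of
    :class:`AudioRecording`.  Audio is bandpassed, each rendition amplitude
    normalized independently, STFT'd (512/128), dB scaled, padded to the
    longest syllable (clipped at 870 ms), and flattened.
    """
    if not isinstance(recs, dict):
        recs = {r.source_id: r for r in recs}
    segs = validate_segments(segs)
    specs, kept_rows = [], []
    clipped = 0
    filtered: dict[str, AudioRecording] = {}
    for idx, row in segs.iterrows():
        rec = recs.get(row["file"])
        if rec is None:
            raise InputError(f"segment row {idx}: no recording for file {row['file']!r}")
        if row["file"] not in filtered:
            hi = min(band[1], 0.99 * rec.rate / 2)
            filtered[row["file"]] = bandpass(rec, band[0], hi)
        frec = filtered[row["file"]]
        i0 = int(round(row["onset"] * frec.rate))
        i1 = int(round(row["offset"] * frec.rate))
        if i0 < 0 or i1 > frec.samples.size:
            raise InputError(f"segment row {idx} lies outside audio bounds")
        cap = int(MAX_SYLLABLE_DURATION * frec.rate)
        if i1 - i0 > cap:
            i1 = i0 + cap
            clipped += 1
        chunk = frec.samples[i0:i1]
        peak = np.max(np.abs(chunk))
        if peak > 0:
            chunk = chunk / peak
        if chunk.size < 512:  # short syllables: zero-pad to one window
            chunk = np.pad(chunk, (0, 512 - chunk.size))
        spec = make_spectrogram(
            AudioRecording(chunk, frec.rate, row["file"]), top_db=LABEL_TOP_DB
        )
        specs.append(spec.values)
        kept_rows.append(row)
    if not specs:
        raise InputError("no syllables to prepare")
    n_freqs = specs[0].shape[0]
    width = max(s.shape[1] for s in specs)
    floor = min(s.min() for s in specs)
    vecs = np.full((len(specs), n_freqs * width), floor, dtype=np.float32)
    for i, s in enumerate(specs):
        padded = np.full((n_freqs, width), floor, dtype=np.float32)
        padded[:, : s.shape[1]] = s
        vecs[i] = padded.ravel()
    return SyllableSpectrogramSet(
        vecs, pd.DataFrame(kept_rows).reset_index(drop=True), (n_freqs, width), clipped
    )


def embed_umap(specs: SyllableSpectrogramSet, seed: int, **overrides) -> np.ndarray:
    """2-D UMAP embedding of the syllable spectrogram set (deterministic per seed)."""
    if len(specs) < 10:
        raise InputError(f"need at least 10 syllables for UMAP, got {len(specs)}")
    import umap

    params = {**UMAP_DEFAULTS, **overrides}
    params["n_neighbors"] = min(params["n_neighbors"], len(specs) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(random_state=seed, **params)
        return np.asarray(reducer.fit_transform(specs.vectors), dtype=float)


def cluster_hdbscan(emb: np.ndarray, min_cluster_size: int | None = None) -> np.ndarray:
    """HDBSCAN labels on a UMAP embedding; noise points get NOISE_LABEL.

    Returns an array of string tokens ("0", "1", ..., "-1").  The default
    minimum cluster size is max(floor, fraction * n), one shared rule for
    all birds.
    """
    from sklearn.cluster import HDBSCAN

    n = emb.shape[0]
    if min_cluster_size is None:
        min_cluster_size = max(
            HDBSCAN_MIN_CLUSTER_FLOOR, int(HDBSCAN_MIN_CLUSTER_FRACTION * n)
        )
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size, allow_single_cluster=True, copy=True
    ).fit_predict(emb)
    return labels.astype(int).astype(str)


def label_syllables(
    recs, segs: pd.DataFrame, seed: int = 0, min_cluster_size: int | None = None
) -> pd.DataFrame:
    """End-to-end labeling: prepare -> UMAP -> HDBSCAN.

    Returns the segment table with the ``label`` column replaced by cluster
    tokens.
    """
    specs = prepare_syllable_spectrograms(recs, segs)
    emb = embed_umap(specs, seed)
    labels = cluster_hdbscan(emb, min_cluster_size)
    out = specs.segments.copy()
    out["label"] = labels
    return validate_segments(out)


def align_labels(ref: pd.DataFrame, pred: pd.DataFrame, tol: float = ALIGN_TOL) -> pd.DataFrame:
    """Pair reference and predicted labels by onset matching (100 ms).

    Returns a DataFrame with columns ``ref`` and ``cluster``; unmatched
    predictions get reference category "x", unmatched references get
    cluster "1000".
    """
    ref = validate_segments(ref)
    pred = validate_segments(pred)
    pairs = []
    for f in sorted(set(ref["file"]) | set(pred["file"])):
        r = ref[ref["file"] == f].reset_index(drop=True)
        p = pred[pred["file"] == f].reset_index(drop=True)
        m = match_events(r["onset"].values, p["onset"].values, tol)
        r_used, p_used = set(), set()
        r_on = list(r["onset"].values)
        p_on = list(p["onset"].values)
        for rt, pt in m.pairs:
            ri = min(i for i, v in enumerate(r_on) if v == rt and i not in r_used)
            pi = min(i for i, v in enumerate(p_on) if v == pt and i not in p_used)
            r_used.add(ri)
            p_used.add(pi)
            pairs.append((r.loc[ri, "label"], p.loc[pi, "label"]))
        for ri in range(len(r)):
            if ri not in r_used:
                pairs.append((r.loc[ri, "label"], UNMATCHED_REF_CLUSTER))
        for pi in range(len(p)):
            if pi not in p_used:
                pairs.append((UNMATCHED_PRED_CATEGORY, p.loc[pi, "label"]))
    return pd.DataFrame(pairs, columns=["ref", "cluster"])


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def cluster_eval(pairs: pd.DataFrame) -> ClusterEval:
    """Homogeneity, completeness and v-measure from aligned label pairs.

    All entropies are natural-log entropies of the confusion matrix.
    Degenerate 0/0 cases (single reference class or single cluster with
    zero conditional entropy) are defined as 1.
    """
    if pairs.empty:
        raise InputError("cluster_eval needs at least one aligned pair")
    conf = pd.crosstab(pairs["cluster"], pairs["ref"])
    m = conf.values.astype(float)
    total = m.sum()
    h_ref = _entropy(m.sum(axis=0))
    h_clu = _entropy(m.sum(axis=1))
    # conditional entropies from joint counts
    h_ref_given_clu = 0.0
    h_clu_given_ref = 0.0
    for i in range(m.shape[0]):
        row = m[i]
        if row.sum():
            h_ref_given_clu += row.sum() / total * _entropy(row)
    for j in range(m.shape[1]):
        col = m[:, j]
        if col.sum():
            h_clu_given_ref += col.sum() / total * _entropy(col)
    hom = 1.0 if h_ref == 0 else 1.0 - h_ref_given_clu / h_ref
    com = 1.0 if h_clu == 0 else 1.0 - h_clu_given_ref / h_clu
    v = 0.0 if hom + com == 0 else 2 * hom * com / (hom + com)
    return ClusterEval(conf, hom, com, v)


def stability_over_seeds(specs: SyllableSpectrogramSet, seeds, ref_labels) -> dict:
    """v-measure per UMAP seed and the dispersion across seeds.

    ``ref_labels`` is a sequence of reference labels aligned 1:1 with the
    rows of ``specs`` (already matched; alignment noise is not re-simulated
    here).  Returns ``{"per_seed": {...}, "std": float}``.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise InputError("stability analysis needs at least two seeds")
    ref_labels = list(ref_labels)
    scores = {}
    for s in seeds:
        emb = embed_umap(specs, s)
        labels = cluster_hdbscan(emb)
        pairs = pd.DataFrame({"ref": ref_labels, "cluster": labels})
        scores[s] = cluster_eval(pairs).v_measure
    vals = np.array(list(scores.values()))
    return {"per_seed": scores, "std": float(vals.std(ddof=0))}
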