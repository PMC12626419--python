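"""Song syntax analysis: bouts, transition matrices, entropy rate, repetition.

A *bout* is a sequence of at least two syllables separated by silent gaps of
at most 200 ms.  Syllables isolated by more than 200 ms of silence on both
sides are treated as putative calls and dropped before syntax analysis.
The transition matrix counts adjacent-state transitions over syllable labels
plus a silence state (gaps longer than 200 ms); transitions to and from file
bounds are ignored as recording artifacts.  The entropy rate

    H = -sum_i pi_i sum_k p_ik log2 p_ik

is normalized by log2(N) with N = number of syllable types + 1 (silence),
giving a [0, 1] stereotypy score: 0 for fully deterministic syntax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_core import InputError, ParameterError
from .segmentation import validate_segments

__all__ = [
    "SILENCE",
    "BoutSet",
    "TransitionMatrix",
    "SyntaxFeatures",
    "extract_bouts",
    "make_syntax_raster",
    "make_transition_matrix",
    "entropy_rate",
    "repetition_stats",
    "find_intro_notes",
    "find_calls",
    "syntax_features",
]

#: reserved token for the silence state in transition matrices
SILENCE = "silence"
#: silent gap (s) separating bouts / marking silence states
GAP_THRESHOLD = 0.200
#: probability margin for the intro-note "most likely from silence" criterion
INTRO_SILENCE_MARGIN = 0.05
#: dominance threshold for the intro-note "single dominant transition" rule
INTRO_DOMINANCE = 0.5
#: fraction of short isolated utterances above which a type is a putative call
CALL_FRACTION = 1.0 / 3.0


@dataclass
class BoutSet:
    """Ordered label sequences, one per bout, with provenance."""

    bouts: list  # list of list[str]
    provenance: list = field(default_factory=list)  # (file, [onsets]) per bout

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)


@dataclass
class TransitionMatrix:
    """Conditional transition probabilities over syllable + silence states."""

    states: list
    counts: pd.DataFrame  # counts[i, k]
    probs: pd.DataFrame  # row-normalized (zero-count rows stay zero)
    occupancy: pd.Series  # empirical state frequency pi_i

    @property
    def syllable_states(self) -> list:
        return [s for s in self.states if s != SILENCE]


@dataclass
class SyntaxFeatures:
    entropy_rate_norm: float
    mean_rep_bout_len: float
    cv_rep_bout_len: float
    selected_type: str | None
    per_type_repetition: pd.DataFrame
    intro_notes: set
    calls: set


def _file_sequences(labels: pd.DataFrame):
    """Yield (file, sub-DataFrame sorted by onset) per source file."""
    labels = validate_segments(labels)
    for f, grp in labels.groupby("file", sort=True):
        yield f, grp.reset_index(drop=True)


def _gap_flags(grp: pd.DataFrame):
    """Leading/trailing gap per syllable; file bounds count as long silence."""
    n = len(grp)
    pre = np.full(n, np.inf)
    post = np.full(n, np.inf)
    onsets = grp["onset"].values
    offsets = grp["offset"].values
    pre[1:] = onsets[1:] - offsets[:-1]
    post[:-1] = onsets[1:] - offsets[:-1]
    return pre, post


def drop_isolated_calls(labels: pd.DataFrame) -> pd.DataFrame:
    """Remove syllables isolated by >200 ms silence on both sides."""
    keep = []
    for f, grp in _file_sequences(labels):
        pre, post = _gap_flags(grp)
        mask = ~((pre > GAP_THRESHOLD) & (post > GAP_THRESHOLD))
        keep.append(grp[mask])
    if not keep:
        return validate_segments(labels)
    return pd.concat(keep, ignore_index=True)


def extract_bouts(labels: pd.DataFrame) -> BoutSet:
    """Split labeled syllables into bouts (>=2 syllables, gaps <= 200 ms)."""
    bouts, prov = [], []
    for f, grp in _file_sequences(labels):
        onsets = grp["onset"].values
        offsets = grp["offset"].values
        toks = grp["label"].tolist()
        start = 0
        for i in range(1, len(grp) + 1):
            boundary = i == len(grp) or onsets[i] - offsets[i - 1] > GAP_THRESHOLD
            if boundary:
                if i - start >= 2:
                    bouts.append(toks[start:i])
                    prov.append((f, list(onsets[start:i])))
                start = i
    return BoutSet(bouts, prov)


def make_syntax_raster(bouts: BoutSet, align_label: str, pad: str = "") -> list:
    """Bout-by-position label grid aligned on the first ``align_label``.

    Rows are left-padded so the first occurrence of the alignment syllable
    shares a column, then ordered lexicographically on their post-alignment
    sequence so similar bouts sit together.  Returns a list of equal-length
    label rows.
    """
    hits = [b for b in bouts if align_label in b]
    if not hits:
        raise ParameterError(f"alignment label {align_label!r} occurs in no bout")
    firsts = [b.index(align_label) for b in hits]
    col = max(firsts)
    padded = [[pad] * (col - k) + list(b) for b, k in zip(hits, firsts)]
    width = max(len(r) for r in padded)
    padded = [r + [pad] * (width - len(r)) for r in padded]
    padded.sort(key=lambda r: r[col:])
    return padded


def make_transition_matrix(
    labels: pd.DataFrame, file_durations: dict | None = None
) -> TransitionMatrix:
    """Count adjacent-state transitions including silence entries/exits.

    Putative-call syllables (isolated by >200 ms on both sides) are dropped
    first.  A silence state is inserted at every intra-file gap longer than
    200 ms; with ``file_durations`` (file -> seconds) provided, leading and
    trailing >200 ms silences are also represented.  Transitions across file
    bounds are never counted.
    """
    labels = drop_isolated_calls(labels)
    sequences = []
    for f, grp in _file_sequences(labels):
        seq = []
        onsets, offsets = grp["onset"].values, grp["offset"].values
        if file_durations is not None and len(grp) and onsets[0] > GAP_THRESHOLD:
            seq.append(SILENCE)
        for i, tok in enumerate(grp["label"]):
            if i > 0 and onsets[i] - offsets[i - 1] > GAP_THRESHOLD:
                seq.append(SILENCE)
            seq.append(tok)
        if (
            file_durations is not None
            and len(grp)
            and file_durations.get(f, offsets[-1]) - offsets[-1] > GAP_THRESHOLD
        ):
            seq.append(SILENCE)
        sequences.append(seq)

    tokens = sorted({t for seq in sequences for t in seq if t != SILENCE})
    states = tokens + [SILENCE]
    counts = pd.DataFrame(0, index=states, columns=states, dtype=float)
    occ = pd.Series(0.0, index=states)
    for seq in sequences:
        for t in seq:
            occ[t] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            counts.loc[a, b] += 1
    probs = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    occupancy = occ / occ.sum() if occ.sum() else occ
    return TransitionMatrix(states, counts, probs, occupancy)


def entropy_rate(tm: TransitionMatrix, include_silence_in_occupancy: bool = True) -> float:
    """Normalized Markov entropy rate in [0, 1].

    N counts syllable types plus one for silence.  Rows with no outgoing
    transitions contribute nothing.  With
    ``include_silence_in_occupancy=False`` the occupancy is renormalized
    over syllable states only.
    """
    n_states = len(tm.syllable_states) + 1
    if n_states <= 1:
        raise ParameterError("entropy rate undefined for a single state")
    occ = tm.occupancy.copy()
    if not include_silence_in_occupancy:
        occ[SILENCE] = 0.0
        occ = occ / occ.sum() if occ.sum() else occ
    p = tm.probs.values
    pi = occ.reindex(tm.probs.index).values
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    raw = -np.sum(pi[:, None] * p * logp)
    return float(np.clip(raw / np.log2(n_states), 0.0, 1.0))


def repetition_stats(bouts: BoutSet) -> pd.DataFrame:
    """Per-type repetition-bout statistics.

    A repetition bout is a maximal run of one label within a bout.  Returns
    a DataFrame indexed by type with columns ``n_bouts``, ``mean_len``,
    ``cv_len`` (population s.d. / mean).
    """
    runs: dict[str, list[int]] = {}
    for bout in bouts:
        i = 0
        while i < len(bout):
            j = i
            while j < len(bout) and bout[j] == bout[i]:
                j += 1
            runs.setdefault(bout[i], []).append(j - i)
            i = j
    rows = []
    for tok in sorted(runs):
        lens = np.array(runs[tok], dtype=float)
        mean = lens.mean()
        cv = lens.std(ddof=0) / mean if mean else np.nan
        rows.append((tok, len(lens), mean, cv))
    return pd.DataFrame(
        rows, columns=["type", "n_bouts", "mean_len", "cv_len"]
    ).set_index("type")


def find_intro_notes(
    tm: TransitionMatrix,
    silence_margin: float = INTRO_SILENCE_MARGIN,
    dominance: float = INTRO_DOMINANCE,
) -> set:
    """Putative introductory notes from the transition matrix.

    A type qualifies if (1) its probability of being transitioned to from
    silence is within ``silence_margin`` of the most silence-followed type,
    and (2) among its outgoing transitions to other syllable types
    (excluding itself and silence) one target dominates with renormalized
    probability above ``dominance``.
    """
    if SILENCE not in tm.probs.index:
        return set()
    from_sil = tm.probs.loc[SILENCE, tm.syllable_states]
    if from_sil.empty or from_sil.max() == 0:
        return set()
    top = from_sil.max()
    out = set()
    for tok in tm.syllable_states:
        if from_sil[tok] < top - silence_margin:
            continue
        targets = [s for s in tm.syllable_states if s != tok]
        if not targets:
            continue
        row = tm.probs.loc[tok, targets]
        total = row.sum()
        if total > 0 and (row / total).max() > dominance:
            out.add(tok)
    return out


def find_calls(labels: pd.DataFrame, intro: set | frozenset = frozenset()) -> set:
    """Putative calls: non-intro types mostly produced in short isolated bouts.

    A rendition counts as "short isolated" if it belongs to a run of one or
    two syllables bounded by >200 ms of silence (file bounds count).  Types
    whose short-isolated fraction exceeds 1/3 qualify.
    """
    iso_counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for f, grp in _file_sequences(labels):
        onsets, offsets = grp["onset"].values, grp["offset"].values
        toks = grp["label"].tolist()
        # split into silence-bounded groups
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or onsets[i] - offsets[i - 1] > GAP_THRESHOLD:
                short_iso = (i - start) <= 2
                for tok in toks[start:i]:
                    totals[tok] = totals.get(tok, 0) + 1
                    if short_iso:
                        iso_counts[tok] = iso_counts.get(tok, 0) + 1
                start = i
    return {
        tok
        for tok in totals
        if tok not in intro and iso_counts.get(tok, 0) / totals[tok] > CALL_FRACTION
    }


def plot_syntax_raster(bouts: BoutSet, align_label: str, ax=None):
    """Minimal raster display: one row per bout, colored by syllable type.

    A convenience view over :func:`make_syntax_raster`; not part of the
    tested numerical contract.
    """
    import matplotlib.pyplot as plt

    grid = make_syntax_raster(bouts, align_label)
    tokens = sorted({t for row in grid for t in row if t})
    index = {t: i + 1 for i, t in enumerate(tokens)}
    mat = np.array([[index.get(t, 0) for t in row] for row in grid])
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.25 * len(grid) + 1))
    ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="tab10")
    ax.set_xlabel("position (aligned)")
    ax.set_ylabel("bout")
    return ax


def syntax_features(labels: pd.DataFrame, file_durations: dict | None = None) -> SyntaxFeatures:
    """Bird-level syntax summary.

    Entropy rate plus the repetition statistics of the non-intro, non-call
    syllable type with the highest mean repetition-bout length.  If every
    type is excluded, the repetition features are NaN and
    ``selected_type`` is None.
    """
    labels = validate_segments(labels)
    tm = make_transition_matrix(labels, file_durations)
    er = entropy_rate(tm)
    intro = find_intro_notes(tm)
    calls = find_calls(labels, intro)
    bouts = extract_bouts(drop_isolated_calls(labels))
    reps = repetition_stats(bouts)
    eligible = reps.drop(index=[t for t in reps.index if t in intro or t in calls], errors="ignore")
    if eligible.empty:
        return SyntaxFeatures(er, np.nan, np.nan, None, reps, intro, calls)
    sel = eligible["mean_len"].idxmax()
    return SyntaxFeatures(
        er,
        float(eligible.loc[sel, "mean_len"]),
        float(eligible.loc[sel, "cv_len"]),
        sel,
        reps,
        intro,
        calls,
    )
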