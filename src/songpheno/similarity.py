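"""Distribution-based song similarity: triplet embedder, EMD/MMD, contrast.

A convolutional metric-learning network maps 180 ms, 2-6 kHz syllable
spectrograms onto a unit 8-D hypersphere, trained with *dynamic* triplet
loss:

    L = sum_i max(||f(A_i)-f(P_i)||_2 - ||f(A_i)-f(N_i)||_2 + alpha, 0)

where anchors/positives share a type label from one bird and negatives
differ.  Distances are plain (unsquared) Euclidean norms; a config flag
enables the squared-distance variant.  Triplets are mined per mini-batch
(75 semi-hard : 25 hard) and the margin alpha grows stepwise
0.1 -> 0.3 -> 0.5 -> 0.7 whenever an epoch averages fewer informative
triplets per batch than a threshold.

The full architecture is five 3x3 convolutional layers (32 then 64
kernels, stride 2 on the frequency axis from the second conv onward)
alternating with four Multiscale Analysis Modules (four parallel strands —
1x1, 1x1->3x3, 1x1->5x5, 1x1->7x7, 32 kernels each — concatenated to 128
channels), ReLU throughout, global average pooling and three fully
connected layers to an L2-normalized 8-D embedding.  The network is
implemented directly in numpy (forward and backward passes, AdamW with
weight decay 1e-4); a reduced desk-scale preset with the same layer types
but smaller depth/width is what tests and examples exercise.

Repertoires are compared as point clouds of embeddings: exact Earth
Mover's Distance (optimal transport, Euclidean ground metric, uniform
weights; maximum 2**0.5 ~ 1.41 between point masses at orthogonal unit
vectors) and Maximum Mean Discrepancy (Gaussian RBF kernel, bandwidth =
half the median pairwise distance of <=1000 sampled reference embeddings,
biased estimator including diagonal terms, reported as sqrt(MMD^2)).
Contrast indices |(self - cross)/(self + cross)| quantify how cleanly the
scorer separates same-bird from unrelated-bird comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .audio_core import AudioRecording, InputError, ParameterError, bandpass, make_spectrogram
from .segmentation import validate_segments

__all__ = [
    "EmbedderConfig",
    "TrainState",
    "SimilarityReport",
    "prep_similarity_spectrograms",
    "build_embedder",
    "desk_config",
    "paper_config",
    "triplet_loss",
    "classify_triplet",
    "train_embedder",
    "embed",
    "emd",
    "mmd",
    "median_heuristic_bandwidth",
    "compare_birds",
    "contrast_index",
    "tutor_contrast_index",
]

#: uniform syllable duration for similarity spectrograms (s)
SIM_DURATION = 0.180
#: retained frequency band (Hz)
SIM_BAND = (2000.0, 6000.0)
#: margin schedule
MARGIN_START = 0.1
MARGIN_STEP = 0.2
MARGIN_MAX = 0.7
MARGIN_VALUES = (0.1, 0.3, 0.5, 0.7)
#: semi-hard : hard mining ratio
MINING_RATIO = (75, 25)


# --------------------------------------------------------------------------
# Data preparation
# --------------------------------------------------------------------------

def prep_similarity_spectrograms(
    recs, segs: pd.DataFrame, target_shape: tuple | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fixed-size syllable spectrograms for the embedder.

    Every syllable is amplitude-normalized, clipped or zero-padded to a
    uniform 180 ms, STFT'd (512/128) and restricted to 2-6 kHz.  With
    ``target_shape`` the spectrogram is additionally average-pooled to that
    (freq, time) shape (the desk-scale preset input).  Returns
    ``(array (n, F, T), segments)``.
    """
    if not isinstance(recs, dict):
        recs = {r.source_id: r for r in recs}
    segs = validate_segments(segs)
    out = []
    for idx, row in segs.iterrows():
        rec = recs.get(row["file"])
        if rec is None:
            raise InputError(f"segment row {idx}: no recording for {row['file']!r}")
        n_target = int(SIM_DURATION * rec.rate)
        i0 = int(round(row["onset"] * rec.rate))
        i1 = min(int(round(row["offset"] * rec.rate)), i0 + n_target)
        chunk = rec.samples[i0:i1]
        peak = np.max(np.abs(chunk)) if chunk.size else 0.0
        if peak > 0:
            chunk = chunk / peak
        if chunk.size < n_target:
            chunk = np.pad(chunk, (0, n_target - chunk.size))
        spec = make_spectrogram(AudioRecording(chunk, rec.rate, row["file"]))
        keep = (spec.freqs >= SIM_BAND[0]) & (spec.freqs <= SIM_BAND[1])
        img = spec.values[keep]
        if target_shape is not None:
            img = _avg_pool_to(img, target_shape)
        out.append(img.astype(np.float32))
    arr = np.stack(out)
    # standardize globally so network inputs are O(1)
    arr = (arr - arr.mean()) / (arr.std() + 1e-8)
    return arr, segs


def _avg_pool_to(img: np.ndarray, shape: tuple) -> np.ndarray:
    """Average-pool a 2-D array to an exact target shape via bin edges."""
    fh, fw = shape
    h, w = img.shape
    re = np.linspace(0, h, fh + 1).astype(int)
    ce = np.linspace(0, w, fw + 1).astype(int)
    out = np.empty((fh, fw), dtype=img.dtype)
    for i in range(fh):
        for j in range(fw):
            block = img[re[i] : max(re[i + 1], re[i] + 1), ce[j] : max(ce[j + 1], ce[j] + 1)]
            out[i, j] = block.mean()
    return out


# --------------------------------------------------------------------------
# numpy layers
# --------------------------------------------------------------------------

class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv2d(_Layer):
    """Same-padded 2-D convolution with (freq, time) stride support."""

    def __init__(self, c_in, c_out, k, stride=(1, 1), rng=None):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self.k, self.stride = k, stride
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        k, (s1, s2) = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        from numpy.lib.stride_tricks import sliding_window_view

        wins = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s1, ::s2]
        self._cache = (x.shape, wins) if train else (x.shape, None)
        out = np.einsum("bchwij,ocij->bohw", wins, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, g):
        (bshape, wins) = self._cache
        k, (s1, s2) = self.k, self.stride
        p = k // 2
        self.grads[0][...] = np.einsum("bohw,bchwij->ocij", g, wins, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        b, c, h, w = bshape
        gx = np.zeros((b, c, h + 2 * p, w + 2 * p))
        oh, ow = g.shape[2], g.shape[3]
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + s1 * oh : s1, j : j + s2 * ow : s2] += np.einsum(
                    "bohw,oc->bchw", g, self.w[:, :, i, j], optimize=True
                )
        return gx[:, :, p : p + h, p : p + w]


class _ReLU(_Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MAM(_Layer):
    """Multiscale Analysis Module: four parallel strands concatenated."""

    def __init__(self, c_in, strand_channels, rng):
        super().__init__()
        sc = strand_channels
        self.strands = [
            [_Conv2d(c_in, sc, 1, rng=rng), _ReLU()],
            [_Conv2d(c_in, sc, 1, rng=rng), _ReLU(), _Conv2d(sc, sc, 3, rng=rng), _ReLU()],
            [_Conv2d(c_in, sc, 1, rng=rng), _ReLU(), _Conv2d(sc, sc, 5, rng=rng), _ReLU()],
            [_Conv2d(c_in, sc, 1, rng=rng), _ReLU(), _Conv2d(sc, sc, 7, rng=rng), _ReLU()],
        ]
        self.out_channels = 4 * sc
        for strand in self.strands:
            for layer in strand:
                self.params += layer.params
                self.grads += layer.grads

    def forward(self, x, train=True):
        outs = []
        for strand in self.strands:
            h = x
            for layer in strand:
                h = layer.forward(h, train)
            outs.append(h)
        self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, g):
        gx = 0.0
        start = 0
        for strand, width in zip(self.strands, self._splits):
            gs = g[:, start : start + width]
            start += width
            for layer in reversed(strand):
                gs = layer.backward(gs)
            gx = gx + gs
        return gx


class _GlobalAvgPool(_Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        b, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float64)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class _L2Norm(_Layer):
    def forward(self, x, train=True):
        self._x = x
        self._norm = np.linalg.norm(x, axis=1, keepdims=True).clip(1e-12)
        return x / self._norm

    def backward(self, g):
        x, n = self._x, self._norm
        return g / n - x * ((x * g).sum(axis=1, keepdims=True)) / n**3


@dataclass
class EmbedderConfig:
    """Architecture hyperparameters.

    ``paper_config()`` reproduces the published layer plan; ``desk_config()``
    is the reduced preset (same layer types, smaller depth and width) used
    throughout tests and examples.
    """

    input_shape: tuple = (16, 16)  # (freq bins, time frames)
    conv1_channels: int = 8
    conv_channels: int = 16
    mam_strand_channels: int = 4
    n_conv: int = 3  # total conv layers; MAMs fill the gaps (n_conv - 1)
    dense_sizes: tuple = (32, 16)
    embed_dim: int = 8
    squared_distances: bool = False


def desk_config(**overrides) -> EmbedderConfig:
    return EmbedderConfig(**overrides)


def paper_config(input_shape=(46, 31)) -> EmbedderConfig:
    """The full published architecture: 5 convs, 4 MAMs, 128-channel MAM output."""
    return EmbedderConfig(
        input_shape=input_shape,
        conv1_channels=32,
        conv_channels=64,
        mam_strand_channels=32,
        n_conv=5,
        dense_sizes=(64, 32),
    )


class Embedder:
    """Sequential numpy network mapping spectrograms to unit 8-D vectors."""

    def __init__(self, config: EmbedderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        layers: list[_Layer] = [_Conv2d(1, c.conv1_channels, 3, rng=rng), _ReLU()]
        ch = c.conv1_channels
        h = c.input_shape[0]
        for i in range(c.n_conv - 1):
            if h < 2:
                raise ParameterError(
                    "frequency axis collapsed; shrink n_conv or grow input"
                )
            mam = _MAM(ch, c.mam_strand_channels, rng)
            layers += [mam]
            ch = mam.out_channels
            layers += [_Conv2d(ch, c.conv_channels, 3, stride=(2, 1), rng=rng), _ReLU()]
            ch = c.conv_channels
            h = (h + 2 * 1 - 3) // 2 + 1
        layers += [_GlobalAvgPool()]
        n = ch
        for d in c.dense_sizes:
            layers += [_Dense(n, d, rng), _ReLU()]
            n = d
        layers += [_Dense(n, c.embed_dim, rng), _L2Norm()]
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        h = x[:, None, :, :].astype(np.float64)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, g_emb: np.ndarray) -> None:
        g = g_emb
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def __call__(self, x):
        return self.forward(x, train=False)


def build_embedder(config: EmbedderConfig, seed: int = 0) -> Embedder:
    """Construct the network; raises on shape-inconsistent configs."""
    return Embedder(config, seed)


def embed(embedder: Embedder, specs: np.ndarray, batch: int = 128) -> np.ndarray:
    """Forward pass in batches -> (n, 8) unit-norm embeddings."""
    outs = [embedder(specs[i : i + batch]) for i in range(0, len(specs), batch)]
    return np.concatenate(outs)


# --------------------------------------------------------------------------
# Triplet loss and training
# --------------------------------------------------------------------------

def triplet_loss(dAP: float, dAN: float, alpha: float, squared: bool = False):
    """max(d(A,P) - d(A,N) + alpha, 0) on plain (or squared) L2 distances."""
    if squared:
        dAP, dAN = dAP**2, dAN**2
    return np.maximum(dAP - dAN + alpha, 0.0)


def classify_triplet(dAP: float, dAN: float, alpha: float) -> str:
    """Triplet hardness: 'hard' (positive farther than negative),
    'semi_hard' (margin violated but ordering correct), or 'zero'."""
    if dAP > dAN:
        return "hard"
    if dAP < dAN and dAN - dAP < alpha:
        return "semi_hard"
    return "zero"


@dataclass
class TrainState:
    """Margin schedule and mining bookkeeping across training."""

    margin: float = MARGIN_START
    epoch: int = 0
    nonzero_per_epoch: list = field(default_factory=list)
    margin_history: list = field(default_factory=list)
    mining_ratio: tuple = MINING_RATIO


class _AdamW:
    def __init__(self, params, grads, lr=1e-3, weight_decay=1e-4):
        self.params, self.grads = params, grads
        self.lr, self.wd = lr, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * (mh / (np.sqrt(vh) + eps) + self.wd * p)


def _mine_triplets(emb, labels, birds, margin, rng, max_triplets, squared):
    """Classify all valid triplets in a batch and sample 75:25 semi:hard."""
    n = emb.shape[0]
    d = cdist(emb, emb)
    if squared:
        d = d**2
    semi, hard = [], []
    for a in range(n):
        pos = np.flatnonzero((labels == labels[a]) & (birds == birds[a]))
        neg = np.flatnonzero(labels != labels[a])
        for p in pos:
            if p == a:
                continue
            dap = d[a, p]
            for q in neg:
                dan = d[a, q]
                if dap > dan:
                    hard.append((a, p, q))
                elif dap < dan and dan - dap < margin:
                    semi.append((a, p, q))
    n_nonzero = len(semi) + len(hard)
    if n_nonzero == 0:
        return [], 0
    r_semi, r_hard = MINING_RATIO
    want = min(max_triplets, n_nonzero)
    n_semi = min(len(semi), int(round(want * r_semi / (r_semi + r_hard))))
    n_hard = min(len(hard), want - n_semi)
    chosen = []
    if semi:
        chosen += [semi[i] for i in rng.choice(len(semi), size=n_semi, replace=False)]
    if hard:
        chosen += [hard[i] for i in rng.choice(len(hard), size=n_hard, replace=False)]
    return chosen, n_nonzero


def train_embedder(
    specs: np.ndarray,
    labels,
    birds,
    config: EmbedderConfig | None = None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 1e-3,
    max_triplets_per_batch: int = 128,
    nonzero_threshold: int = 40,
    weight_decay: float = 1e-4,
):
    """Train the embedder with dynamic triplet loss.

    ``specs`` is (n, F, T); ``labels`` are syllable-type tokens; ``birds``
    identifies the source bird (anchors and positives must share both).
    The margin starts at 0.1 and steps by 0.2 (to at most 0.7) after any
    epoch averaging fewer than ``nonzero_threshold`` informative (semi-hard
    or hard) triplets per batch — the desk-scale analog of the published
    2500-per-batch rule, scaled to dataset size.  Deterministic per seed.

    Returns ``(embedder, TrainState)``.
    """
    labels = np.asarray(labels)
    birds = np.asarray(birds)
    if len(set(map(tuple, zip(birds, labels)))) < 2 or len(set(labels)) < 2:
        raise InputError("triplet training needs at least two syllable types")
    if config is None:
        config = desk_config(input_shape=specs.shape[1:])
    net = build_embedder(config, seed)
    opt = _AdamW(net.params, net.grads, lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed + 1)
    state = TrainState()
    n = specs.shape[0]
    sq = config.squared_distances
    for epoch in range(epochs):
        order = rng.permutation(n)
        nonzero_counts = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 3:
                continue
            emb = net.forward(specs[idx], train=True)
            triplets, n_nonzero = _mine_triplets(
                emb, labels[idx], birds[idx], state.margin, rng, max_triplets_per_batch, sq
            )
            nonzero_counts.append(n_nonzero)
            if not triplets:
                continue
            g = np.zeros_like(emb)
            eps = 1e-12
            n_active = 0
            for a, p, q in triplets:
                ea, ep, eq = emb[a], emb[p], emb[q]
                dap = max(np.linalg.norm(ea - ep), eps)
                dan = max(np.linalg.norm(ea - eq), eps)
                if triplet_loss(dap, dan, state.margin, sq) <= 0:
                    continue
                n_active += 1
                if sq:
                    g[a] += 2 * (eq - ep)
                    g[p] += 2 * (ep - ea)
                    g[q] += 2 * (ea - eq)
                else:
                    uap = (ea - ep) / dap
                    uan = (ea - eq) / dan
                    g[a] += uap - uan
                    g[p] += -uap
                    g[q] += uan
            if n_active == 0:
                continue
            g /= n_active
            net.backward(g)
            opt.step()
        state.epoch = epoch + 1
        mean_nonzero = float(np.mean(nonzero_counts)) if nonzero_counts else 0.0
        state.nonzero_per_epoch.append(mean_nonzero)
        state.margin_history.append(state.margin)
        if mean_nonzero < nonzero_threshold and state.margin < MARGIN_MAX - 1e-9:
            state.margin = round(state.margin + MARGIN_STEP, 10)
    return net, state


# --------------------------------------------------------------------------
# Distribution distances
# --------------------------------------------------------------------------

def emd(a: np.ndarray, b: np.ndarray) -> float:
    """Exact Earth Mover's Distance between uniform-weight point clouds.

    Euclidean ground metric.  Equal-size pools reduce to an optimal
    assignment; unequal sizes solve the transport linear program exactly.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InputError("EMD needs non-empty embedding sets")
    cost = cdist(a, b)
    m, n = cost.shape
    if m == n:
        ri, ci = linear_sum_assignment(cost)
        return float(cost[ri, ci].mean())
    # transport LP: x >= 0, row sums 1/m, col sums 1/n
    from scipy.sparse import lil_matrix

    A = lil_matrix((m + n, m * n))
    for i in range(m):
        A[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        A[m + j, j::n] = 1.0
    rhs = np.concatenate([np.full(m, 1.0 / m), np.full(n, 1.0 / n)])
    res = linprog(cost.ravel(), A_eq=A.tocsr(), b_eq=rhs, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible OT
        raise RuntimeError(f"EMD transport LP failed: {res.message}")
    return float(res.fun)


def median_heuristic_bandwidth(ref: np.ndarray, rng=None, max_points: int = 1000) -> float:
    """Half the median pairwise distance of <=1000 sampled reference points."""
    ref = np.atleast_2d(ref)
    if ref.shape[0] < 2:
        raise InputError("bandwidth reference needs at least two points")
    if rng is None:
        rng = np.random.default_rng(0)
    if ref.shape[0] > max_points:
        ref = ref[rng.choice(ref.shape[0], size=max_points, replace=False)]
    d = cdist(ref, ref)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return 0.5 * med


def mmd(a: np.ndarray, b: np.ndarray, bandwidth_ref: np.ndarray | None = None,
        sigma: float | None = None, rng=None) -> float:
    """Gaussian-kernel Maximum Mean Discrepancy, sqrt of the biased estimator.

    The kernel bandwidth is ``sigma`` if given, otherwise half the median
    pairwise distance among <=1000 reference embeddings (``bandwidth_ref``;
    defaults to the pooled inputs).  The biased estimator keeps diagonal
    terms, so identical sets score exactly 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InputError("MMD needs non-empty embedding sets")
    if sigma is None:
        if bandwidth_ref is None:
            bandwidth_ref = np.vstack([a, b])
        sigma = median_heuristic_bandwidth(bandwidth_ref, rng)
    if sigma <= 0:
        raise ParameterError(
            "degenerate bandwidth sigma=0 (all reference points identical); "
            "pass an explicit sigma"
        )
    gamma = 1.0 / (2 * sigma**2)

    def kmean(x, y):
        return float(np.exp(-gamma * cdist(x, y) ** 2).mean())

    mmd2 = kmean(a, a) + kmean(b, b) - 2 * kmean(a, b)
    return float(np.sqrt(max(mmd2, 0.0)))


# --------------------------------------------------------------------------
# Comparison protocols and contrast indices
# --------------------------------------------------------------------------

#: pools at or above this size are subsampled rather than split
SELF_SPLIT_LIMIT = 4000
SELF_SAMPLE_SIZE = 2000
CROSS_SAMPLE_MAX = 4000

COMPARISON_KINDS = ("self", "tutor", "sibling", "unrelated", "developmental")


@dataclass
class SimilarityReport:
    kind: str
    emd: float
    mmd: float
    n_a: int
    n_b: int
    seed: int


def compare_birds(
    a: np.ndarray,
    b: np.ndarray | None = None,
    kind: str = "unrelated",
    seed: int = 0,
    bandwidth_ref: np.ndarray | None = None,
) -> SimilarityReport:
    """EMD and MMD between two syllable-embedding pools.

    ``kind="self"`` compares bird ``a`` with itself: pools under 4000
    syllables are split into two disjoint halves, larger pools yield two
    disjoint random samples of 2000.  All other kinds subsample up to 4000
    embeddings per bird.  The sampling seed is recorded in the report.
    """
    if kind not in COMPARISON_KINDS:
        raise ParameterError(f"kind must be one of {COMPARISON_KINDS}")
    rng = np.random.default_rng(seed)
    a = np.atleast_2d(a)
    if kind == "self":
        n = a.shape[0]
        perm = rng.permutation(n)
        if n < SELF_SPLIT_LIMIT:
            half = n // 2
            x, y = a[perm[:half]], a[perm[half : 2 * half]]
        else:
            x = a[perm[:SELF_SAMPLE_SIZE]]
            y = a[perm[SELF_SAMPLE_SIZE : 2 * SELF_SAMPLE_SIZE]]
    else:
        if b is None:
            raise InputError(f"comparison kind {kind!r} needs a second pool")
        b = np.atleast_2d(b)
        x = a if a.shape[0] <= CROSS_SAMPLE_MAX else a[
            rng.choice(a.shape[0], CROSS_SAMPLE_MAX, replace=False)
        ]
        y = b if b.shape[0] <= CROSS_SAMPLE_MAX else b[
            rng.choice(b.shape[0], CROSS_SAMPLE_MAX, replace=False)
        ]
    return SimilarityReport(
        kind=kind,
        emd=emd(x, y),
        mmd=mmd(x, y, bandwidth_ref=bandwidth_ref, rng=rng),
        n_a=x.shape[0],
        n_b=y.shape[0],
        seed=seed,
    )


def contrast_index(self_d: float, cross_d: float) -> float:
    """|self - cross| / (self + cross); cross is a mean over 3 unrelated birds."""
    denom = self_d + cross_d
    if denom <= 0:
        raise ParameterError("contrast index undefined for zero denominator")
    return float(abs((self_d - cross_d) / denom))


def tutor_contrast_index(tutor_d: float, cross_d: float) -> float:
    """|tutor - cross| / (tutor + cross); cross as in :func:`contrast_index`."""
    return contrast_index(tutor_d, cross_d)
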