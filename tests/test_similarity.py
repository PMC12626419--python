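"""Similarity scoring: prep, triplet embedder, EMD/MMD, comparison protocols."""

import numpy as np
import pandas as pd
import pytest

from songpheno import synthsong
from songpheno.audio_core import InputError, ParameterError
from songpheno.similarity import (
    MARGIN_VALUES,
    SimilarityReport,
    build_embedder,
    classify_triplet,
    compare_birds,
    contrast_index,
    desk_config,
    embed,
    emd,
    median_heuristic_bandwidth,
    mmd,
    paper_config,
    prep_similarity_spectrograms,
    train_embedder,
    triplet_loss,
    tutor_contrast_index,
)


@pytest.fixture(scope="module")
def toy_training_set():
    """Two synthetic birds, four syllable types each, pooled spectrograms."""
    parts, labels, birds = [], [], []
    for bird_seed, bird in ((1, "b1"), (2, "b2")):
        spec = synthsong.preset("adult", seed=bird_seed, n_files=3, bouts_per_file=3)
        recs, truth = synthsong.render_song(spec)
        s, segs = prep_similarity_spectrograms(recs, truth, target_shape=(16, 16))
        parts.append(s)
        labels += [f"{bird}_{t}" for t in segs["label"]]
        birds += [bird] * len(segs)
    return np.concatenate(parts), np.array(labels), np.array(birds)


@pytest.fixture(scope="module")
def trained(toy_training_set):
    specs, labels, birds = toy_training_set
    net, state = train_embedder(specs, labels, birds, seed=0, epochs=15)
    return net, state, specs, labels, birds


class TestPrep:
    def test_long_syllable_clipped_to_180ms(self, adult_dataset):
        recs, _ = adult_dataset
        rate = recs[0].rate
        segs = pd.DataFrame(
            {"file": recs[0].source_id, "onset": [0.0], "offset": [0.25], "label": ["x"]}
        )
        arr, _ = prep_similarity_spectrograms(recs, segs)
        assert arr.shape[2] == 1 + int(0.180 * rate) // 128

    def test_short_syllable_padded_to_180ms(self, adult_dataset):
        recs, _ = adult_dataset
        segs = pd.DataFrame(
            {"file": recs[0].source_id, "onset": [0.3], "offset": [0.35], "label": ["x"]}
        )
        long_segs = segs.assign(offset=0.48)
        a, _ = prep_similarity_spectrograms(recs, segs)
        b, _ = prep_similarity_spectrograms(recs, long_segs)
        assert a.shape == b.shape

    def test_band_restricted_to_2_6_khz(self, adult_dataset):
        recs, truth = adult_dataset
        rate = recs[0].rate
        freqs = np.fft.rfftfreq(512, d=1.0 / rate)
        expected_rows = int(((freqs >= 2000) & (freqs <= 6000)).sum())
        arr, _ = prep_similarity_spectrograms(recs, truth.head(3))
        assert arr.shape[1] == expected_rows

    def test_target_shape_pooling(self, adult_dataset):
        recs, truth = adult_dataset
        arr, _ = prep_similarity_spectrograms(recs, truth.head(3), target_shape=(16, 16))
        assert arr.shape == (3, 16, 16)


class TestEmbedderArchitecture:
    def test_forward_unit_norm_batch(self):
        net = build_embedder(desk_config(), seed=0)
        x = np.random.default_rng(0).standard_normal((5, 16, 16))
        e = net(x)
        assert e.shape == (5, 8)
        np.testing.assert_allclose(np.linalg.norm(e, axis=1), 1.0, atol=1e-5)

    def test_paper_architecture_builds_and_runs(self):
        net = build_embedder(paper_config(), seed=0)
        e = net(np.random.default_rng(1).standard_normal((1, 46, 31)))
        assert e.shape == (1, 8)
        np.testing.assert_allclose(np.linalg.norm(e, axis=1), 1.0, atol=1e-5)

    def test_amplitude_scaling_after_normalization_is_identity(self, adult_dataset):
        # per-syllable amplitude normalization happens in prep: doubling the
        # raw audio produces identical network inputs, hence embeddings
        recs, truth = adult_dataset
        from songpheno.audio_core import AudioRecording

        doubled = [AudioRecording(r.samples * 2, r.rate, r.source_id) for r in recs]
        a, _ = prep_similarity_spectrograms(recs, truth.head(4), target_shape=(16, 16))
        b, _ = prep_similarity_spectrograms(doubled, truth.head(4), target_shape=(16, 16))
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_collapsed_frequency_axis_rejected(self):
        with pytest.raises(ParameterError):
            build_embedder(desk_config(input_shape=(2, 16), n_conv=5), seed=0)


class TestTripletLoss:
    def test_boundary_zero(self):
        assert triplet_loss(0.0, 0.1, 0.1) == 0.0

    def test_arithmetic(self):
        assert triplet_loss(0.5, 0.3, 0.1) == pytest.approx(0.3)

    def test_equal_distances_zero_margin(self):
        assert triplet_loss(0.4, 0.4, 0.0) == 0.0

    def test_classification_hard(self):
        assert classify_triplet(0.5, 0.3, 0.1) == "hard"

    def test_classification_semi_hard(self):
        assert classify_triplet(0.40, 0.45, 0.1) == "semi_hard"

    def test_classification_zero(self):
        assert classify_triplet(0.1, 0.9, 0.1) == "zero"


class TestTraining:
    def test_intra_type_distances_below_inter(self, trained):
        from scipy.spatial.distance import cdist

        net, state, specs, labels, birds = trained
        e = embed(net, specs)
        d = cdist(e, e)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        assert d[same].mean() < d[~same].mean()

    def test_margin_schedule_confined_and_monotone(self, trained):
        _, state, *_ = trained
        hist = state.margin_history
        assert set(hist) <= set(MARGIN_VALUES)
        assert all(a <= b for a, b in zip(hist, hist[1:]))

    def test_margin_steps_when_triplets_exhaust(self, toy_training_set):
        specs, labels, birds = toy_training_set
        # high threshold: every epoch looks starved, margin must climb to cap
        _, state = train_embedder(
            specs, labels, birds, seed=0, epochs=5, nonzero_threshold=10**6
        )
        assert state.margin_history == [0.1, 0.3, 0.5, 0.7, 0.7]

    def test_deterministic_given_seed(self, toy_training_set):
        specs, labels, birds = toy_training_set
        sub = slice(0, 60)
        n1, _ = train_embedder(specs[sub], labels[sub], birds[sub], seed=3, epochs=2)
        n2, _ = train_embedder(specs[sub], labels[sub], birds[sub], seed=3, epochs=2)
        np.testing.assert_allclose(embed(n1, specs[sub]), embed(n2, specs[sub]))

    def test_single_type_rejected(self, toy_training_set):
        specs, labels, birds = toy_training_set
        ones = np.full(len(labels), "only")
        with pytest.raises(InputError):
            train_embedder(specs, ones, birds, seed=0, epochs=1)


class TestEmd:
    def test_identical_sets_zero(self, rng):
        a = rng.standard_normal((20, 8))
        assert emd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_point_masses(self):
        a = np.tile(np.eye(8)[0], (10, 1))
        b = np.tile(np.eye(8)[1], (10, 1))
        assert emd(a, b) == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_point_masses_at_distance_d(self):
        a = np.zeros((5, 8))
        b = np.zeros((7, 8))
        b[:, 0] = 0.73  # unequal sizes: exercises the transport LP
        assert emd(a, b) == pytest.approx(0.73, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.standard_normal((15, 8))
        b = rng.standard_normal((15, 8))
        assert emd(a, b) == pytest.approx(emd(b, a), abs=1e-9)

    def test_triangle_inequality_on_point_masses(self):
        pts = [np.zeros(8), np.eye(8)[0] * 2, np.eye(8)[1] * 3]
        sets = [np.tile(p, (4, 1)) for p in pts]
        ab = emd(sets[0], sets[1])
        bc = emd(sets[1], sets[2])
        ac = emd(sets[0], sets[2])
        assert ac <= ab + bc + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            emd(np.empty((0, 8)), np.ones((3, 8)))


class TestMmd:
    def test_identical_sets_zero(self, rng):
        a = rng.standard_normal((30, 8))
        assert mmd(a, a, sigma=1.0) == pytest.approx(0.0, abs=1e-7)

    def test_two_point_closed_form(self):
        # point masses at distance sigma: MMD^2 = 2 - 2 e^{-1/2}
        a = np.zeros((6, 8))
        b = np.zeros((6, 8))
        b[:, 0] = 1.0
        expected = np.sqrt(2 - 2 * np.exp(-0.5))
        assert mmd(a, b, sigma=1.0) == pytest.approx(expected, abs=1e-9)

    def test_far_apart_approaches_sqrt2(self):
        a = np.zeros((6, 8))
        b = np.zeros((6, 8))
        b[:, 0] = 1e3
        assert mmd(a, b, sigma=1.0) == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_monotone_in_separation(self, rng):
        base = rng.standard_normal((80, 8))
        other = rng.standard_normal((80, 8))
        vals = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            shifted = other + shift * np.eye(8)[0]
            vals.append(mmd(base, shifted, sigma=1.0))
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_bandwidth_median_heuristic(self):
        ref = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        # pairwise distances: 0 (within) and sqrt(2) (across); median of the
        # 45 pairs is sqrt(2) at these counts -> sigma = sqrt(2)/2
        sigma = median_heuristic_bandwidth(ref)
        assert sigma == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_degenerate_bandwidth_rejected(self):
        a = np.zeros((5, 8))
        with pytest.raises(ParameterError, match="bandwidth"):
            mmd(a, a)


class TestComparisons:
    def test_self_comparison_splits_small_pool_in_half(self, rng):
        pool = rng.standard_normal((300, 8))
        rep = compare_birds(pool, kind="self", seed=1)
        assert rep.n_a == rep.n_b == 150
        assert rep.emd > 0  # disjoint halves of a continuous cloud

    def test_large_pool_sampled_at_2000(self, rng):
        pool = rng.standard_normal((4500, 4))
        rep = compare_birds(pool, kind="self", seed=1)
        assert rep.n_a == rep.n_b == 2000

    def test_identical_pools_score_zero_emd(self, rng):
        pool = rng.standard_normal((60, 8))
        rep = compare_birds(pool, pool, kind="tutor", seed=5)
        assert rep.emd == pytest.approx(0.0, abs=1e-9)
        assert rep.kind == "tutor"
        assert rep.seed == 5

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ParameterError):
            compare_birds(rng.standard_normal((10, 8)), kind="cousin")

    def test_contrast_index_arithmetic(self):
        assert contrast_index(0.0, 0.5) == 1.0
        assert contrast_index(0.4, 0.4) == 0.0
        assert contrast_index(0.2, 0.6) == pytest.approx(0.5)
        assert tutor_contrast_index(0.2, 0.6) == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            contrast_index(0.0, 0.0)


class TestFamilyOrdering:
    def test_self_tutor_unrelated_ordering(self, family_reports):
        """Pools sharing archetypes score lower than disjoint-archetype
        pools, for both EMD and MMD: self < tutor < unrelated."""
        fr = family_reports
        assert fr["self"].emd < fr["tutor"].emd < fr["cross_emd"]
        assert fr["self"].mmd < fr["tutor"].mmd < fr["cross_mmd"]

    def test_contrast_index_separates_families(self, family_reports):
        """|self - cross|/(self + cross) on the trained toy embedder."""
        fr = family_reports
        assert contrast_index(fr["self"].emd, fr["cross_emd"]) > 0.8

    def test_tutor_contrast_index_positive(self, family_reports):
        fr = family_reports
        tci = tutor_contrast_index(fr["tutor"].emd, fr["cross_emd"])
        assert 0.0 < tci < 1.0
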