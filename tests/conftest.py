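"""Shared fixtures: synthetic song datasets generated once per session."""

import warnings

import numpy as np
import pytest

from songpheno import synthsong

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def adult_dataset():
    """Stereotyped adult-regime songs with ground truth (4 files, 3 bouts)."""
    spec = synthsong.preset("adult", seed=1, n_files=4, bouts_per_file=3)
    recs, truth = synthsong.render_song(spec)
    return recs, truth


@pytest.fixture(scope="session")
def adult_dataset_large():
    """Bigger adult dataset for timing/feature statistics (8 files)."""
    spec = synthsong.preset("adult", seed=1, n_files=8, bouts_per_file=3)
    recs, truth = synthsong.render_song(spec)
    return recs, truth


@pytest.fixture(scope="session")
def juvenile_dataset_large():
    """Juvenile-regime twin of adult_dataset_large (same seed family)."""
    spec = synthsong.preset("juvenile", seed=1, n_files=8, bouts_per_file=3)
    recs, truth = synthsong.render_song(spec)
    return recs, truth


@pytest.fixture(scope="session")
def labeled_adult(adult_dataset):
    """Adult dataset run through the full labeling pipeline once."""
    from songpheno import labeling

    recs, truth = adult_dataset
    labeled = labeling.label_syllables(recs, truth, seed=42)
    return recs, truth, labeled


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def family_reports():
    """Train the desk-scale embedder on three synthetic birds and score the
    paper-style comparison types for one pupil.

    Returns a dict with the self/tutor reports, the per-unrelated-bird
    reports, and the mean cross distances.
    """
    import dataclasses

    from songpheno import similarity as sim

    def bird(preset_name, seed, nf, tag, f0m=1.0, durm=1.0):
        spec = synthsong.preset(preset_name, seed=seed, n_files=nf, bouts_per_file=3)
        if f0m != 1.0 or durm != 1.0:
            arche = {
                k: dataclasses.replace(
                    a, fundamental=a.fundamental * f0m, dur_mean=a.dur_mean * durm
                )
                for k, a in spec.archetypes.items()
            }
            spec = dataclasses.replace(spec, archetypes=arche)
        recs, truth = synthsong.render_song(spec)
        s, segs = sim.prep_similarity_spectrograms(recs, truth, target_shape=(16, 16))
        return (
            s,
            np.array([f"{tag}_{x}" for x in segs["label"]]),
            np.array([tag] * len(segs)),
        )

    pupil = bird("adult", 1, 6, "b1")
    train_parts = [pupil, bird("adult", 2, 3, "b2"), bird("isolate_like", 5, 3, "b5")]
    specs = np.concatenate([p[0] for p in train_parts])
    labels = np.concatenate([p[1] for p in train_parts])
    birds = np.concatenate([p[2] for p in train_parts])
    cfg = sim.desk_config(
        input_shape=(16, 16),
        conv1_channels=16,
        conv_channels=32,
        mam_strand_channels=8,
        dense_sizes=(64, 32),
    )
    net, state = sim.train_embedder(
        specs, labels, birds, config=cfg, seed=0, epochs=45, nonzero_threshold=5
    )
    # tutor: imperfect imitation (f0 ~10% sharp, durations ~15% long);
    # unrelated: three isolate-family birds the pupil shares nothing with
    tutor = bird("adult", 3, 2, "b3", f0m=1.10, durm=1.15)
    unrelated = [bird("isolate_like", s, 2, f"u{s}") for s in (4, 6, 8)]

    e_pupil = sim.embed(net, pupil[0])
    self_rep = sim.compare_birds(e_pupil, kind="self", seed=0)
    tutor_rep = sim.compare_birds(e_pupil, sim.embed(net, tutor[0]), kind="tutor", seed=0)
    unrel_reps = [
        sim.compare_birds(e_pupil, sim.embed(net, u[0]), kind="unrelated", seed=0)
        for u in unrelated
    ]
    return {
        "net": net,
        "state": state,
        "train": (specs, labels, birds),
        "self": self_rep,
        "tutor": tutor_rep,
        "unrelated": unrel_reps,
        "cross_emd": float(np.mean([r.emd for r in unrel_reps])),
        "cross_mmd": float(np.mean([r.mmd for r in unrel_reps])),
    }
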