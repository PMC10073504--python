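import numpy as np
import pytest

import transfeat as tf
from transfeat.simulate import SessionTimeline, StateEffect, default_state_effects


def short_timeline() -> SessionTimeline:
    """Halved protocol used where the full 21-minute session is unnecessary."""
    layout = [("relax", 60.0), ("neutral", 120.0), ("relax", 60.0),
              ("negative", 120.0), ("relax", 60.0), ("positive", 120.0)]
    segs, t = [], 0.0
    for label, dur in layout:
        segs.append((label, t, t + dur))
        t += dur
    return SessionTimeline(segs)


def noise_free_config(n_subjects: int = 1, seed: int = 0) -> tf.CohortSimConfig:
    """Deterministic cohort with grid-aligned landmarks for exact recovery.

    RR fixed at 0.8 s; BVP sampled at 200 Hz so pulse onset/peak times fall
    exactly on the sampling grid; no modulation, noise or sudomotor events.
    """
    effects = {}
    for label in ("relax", "neutral", "negative", "positive"):
        effects[label] = StateEffect(
            mean_rr_s=0.8, rr_sd_s=0.0, rr_lf_amp_s=0.0, rr_hf_amp_s=0.0,
            pulse_amp_mean=0.72, pulse_amp_sd=0.0,
            scr_rate_per_min=0.0, scr_amp_mean=0.0,
            tonic_level=6.0, tonic_drift_per_min=0.0)
    return tf.CohortSimConfig(
        n_subjects=n_subjects, seed=seed, bvp_rate_hz=200.0,
        state_effects=effects, timeline=short_timeline(),
        ecg_noise_sd=0.0, bvp_noise_sd=0.0, gsr_noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort3():
    """Three default-condition subjects over the full protocol."""
    return tf.simulate_cohort(tf.CohortSimConfig(n_subjects=3, seed=101))


@pytest.fixture(scope="session")
def fm3(cohort3):
    """Feature matrix of the three-subject cohort."""
    return tf.extract_feature_matrix(cohort3)


@pytest.fixture(scope="session")
def short_cohort():
    """Eight subjects over the halved protocol, default state effects."""
    cfg = tf.CohortSimConfig(n_subjects=8, seed=55, timeline=short_timeline())
    return tf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def short_fm(short_cohort):
    return tf.extract_feature_matrix(short_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
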