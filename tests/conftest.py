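import numpy as np
import pandas as pd
import pytest

import pitchmimic as pm
from pitchmimic.performer import MODALITIES


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_comp_config():
    return pm.CompositionConfig(seed=7)


@pytest.fixture(scope="session")
def melody_sets():
    """Two small stimulus sets, one per modality."""
    sets = {}
    for i, m in enumerate(MODALITIES):
        cfg = pm.CompositionConfig(n_melodies=12, seed=100 + i)
        sets[m] = [pm.Melody(mel.notes, f"{m}-{mel.id}")
                   for mel in pm.compose_set(cfg)]
    return sets


def make_profile(participant_id="p000", sex="F", perceptual_sd=0.0,
                 motor_sd=(0.0, 0.0), bias=(0.0, 0.0), gamma=(0.0, 0.0),
                 habitual=(300.0, 900.0), prange=((-600.0, 1800.0),) * 2,
                 **kw):
    """A profile with explicit (sing, whistle) parameter pairs."""
    pair = lambda v: dict(zip(MODALITIES, v))
    return pm.PerformerProfile(
        participant_id=participant_id, sex=sex,
        habitual_pitch=pair(habitual), producible_range=pair(prange),
        motor_noise_sd=pair(motor_sd), bias=pair(bias),
        compression=pair(gamma), perceptual_noise_sd=perceptual_sd, **kw)


@pytest.fixture()
def noiseless_profile():
    return make_profile()


@pytest.fixture(scope="session")
def small_study(melody_sets):
    """A small simulated cohort, scored with default policies."""
    cohort = pm.CohortConfig(n_participants=8, seed=42)
    trials, participants = pm.simulate_study(cohort, melody_sets, seed=42)
    kept, excluded = pm.filter_trials(trials, participants)
    errs = pm.note_errors(kept, participants)
    scores = pm.score_participants(errs, participants, excluded)
    return {"trials": trials, "participants": participants, "kept": kept,
            "excluded": excluded, "note_errors": errs, "scores": scores}
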