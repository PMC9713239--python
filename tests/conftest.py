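"""Shared fixtures: one synthetic subject and pre-built set families.

The expensive artifacts (TMCMC families, the trained surrogate) are built
once per session and shared across test modules.
"""

import numpy as np
import pytest

from kneeplan import bpe, knee_core as kc, safe_zones as sz, surrogate as sg

SUBJECT_SEED = 0


@pytest.fixture(scope="session")
def subject():
    geometry, props = kc.make_synthetic_subject(SUBJECT_SEED)
    return geometry, props


@pytest.fixture(scope="session")
def family_d(subject):
    geometry, _ = subject
    return bpe.build_family(geometry, sz.SafeZoneSpec("damage"), 200,
                            bpe.TmcmcConfig(chain_size=300, seed=5))


@pytest.fixture(scope="session")
def family_ds(subject):
    geometry, _ = subject
    return bpe.build_family(geometry, sz.SafeZoneSpec("damage_stability"), 150,
                            bpe.TmcmcConfig(chain_size=300, seed=6))


@pytest.fixture(scope="session")
def family_dk(subject):
    geometry, props = subject
    states = kc.simulate_squat(geometry, props, None)
    target = sz.KinematicsTarget.from_states(states)
    zone = sz.SafeZoneSpec("damage_kinematics", kinematics_target=target)
    return bpe.build_family(geometry, zone, 250,
                            bpe.TmcmcConfig(chain_size=300, seed=7))


@pytest.fixture(scope="session")
def postka_surrogate(subject, family_d):
    """Gate-checked post-TKA surrogate trained on the damage family."""
    geometry, _ = subject
    train = sg.generate_training_set(geometry, family_d, n=4096, seed=2)
    model, report = sg.train_and_validate(
        train, sg.SurrogateSpec.post_tka(hidden=(96, 96), seed=3),
        geometry=geometry, epochs=250)
    return model, report
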