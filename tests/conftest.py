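import dataclasses

import pytest

import strokevalnet as sv

from _toydb import build_toy_database


@pytest.fixture(scope="session")
def registry():
    return sv.builtin_concept_sets()


@pytest.fixture(scope="session")
def toy_db():
    return build_toy_database()


@pytest.fixture(scope="session")
def definitions():
    return sv.builtin_score_definitions()


@pytest.fixture(scope="session")
def gen_db():
    """One moderately sized synthetic Medicare-style database with ground truth."""
    profile = sv.make_profile("medicare_65plus", n_persons=8000)
    return sv.generate_database(profile, seed=11)


@pytest.fixture(scope="session")
def gen_db_untreated():
    """Same profile with treatment switched off (pure-risk outcome process)."""
    profile = sv.make_profile("medicare_65plus", n_persons=8000)
    profile = dataclasses.replace(
        profile,
        treatment_policy=dataclasses.replace(profile.treatment_policy, efficacy=0.0),
    )
    return sv.generate_database(profile, seed=11)
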