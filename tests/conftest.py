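"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import warnings

import pytest

import latemp

# every cluster test warns once about the always-degenerate first time point
# (baseline correction forces zero variance there); keep test output readable
warnings.filterwarnings(
    "ignore", message=r".*zero-variance paired differences.*"
)
warnings.filterwarnings("ignore", message=r".*zero residual variance.*")


@pytest.fixture(scope="session")
def default_design() -> latemp.StudyDesign:
    return latemp.StudyDesign()


@pytest.fixture(scope="session")
def one_experiment_design() -> latemp.StudyDesign:
    return latemp.StudyDesign(experiments=("exp1",))


@pytest.fixture(scope="session")
def default_dataset(default_design):
    """Full two-experiment dataset under the default study conditions."""
    return latemp.generate_experiment(default_design, latemp.EffectSpec(), seed=7)


@pytest.fixture(scope="session")
def clean_dataset(one_experiment_design):
    """One-experiment dataset with no artifacts (all other noise at defaults)."""
    return latemp.generate_experiment(
        one_experiment_design, latemp.EffectSpec(artifact_rate=0.0), seed=7
    )


@pytest.fixture(scope="session")
def clean_samples(clean_dataset):
    recordings, trials, _ = clean_dataset
    return latemp.preprocess_dataset(recordings, trials)


@pytest.fixture(scope="session")
def tympanic_samples(clean_samples):
    return [s for s in clean_samples if s.site == "tympanic"]


@pytest.fixture(scope="session")
def wrist_samples(clean_samples):
    return [s for s in clean_samples if s.site == "wrist"]


@pytest.fixture(scope="session")
def tympanic_vectors(tympanic_samples):
    vectors = [latemp.build_feature_vector(s) for s in tympanic_samples]
    return latemp.normalize_within_participant(vectors)
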