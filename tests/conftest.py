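import numpy as np
import pytest

from swaylearn import (
    FeatureConfig,
    ParticipantProfile,
    SimulationConfig,
    simulate_features,
)


def make_profile(group="ASD", severity=1.0, age=13.0, pid=None):
    return ParticipantProfile(
        participant_id=pid or f"{group.lower()}001",
        group=group,
        age_years=age,
        latent_severity=severity,
        bot2_percentile=20.0,
        srs2_score=80.0,
        rbsr_score=30.0,
        iq=105.0,
        sex="M",
    )


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small, fast cohort: 6+6 participants, 3 poses, one session."""
    return SimulationConfig(
        n_asd=6,
        n_td=6,
        n_poses=3,
        sessions=(2,),
        frames_min=640,
        frames_max=704,
        p_corrupt_file=0.0,
        p_missing=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_features(tiny_sim_config):
    """Cleaned + featurized tiny synthetic cohort (shared, read-only)."""
    return simulate_features(tiny_sim_config, feature_config=FeatureConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
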