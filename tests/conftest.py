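import numpy as np
import pytest

from gaitimpress.features import extract_features
from gaitimpress.joint_centers import compute_joint_centers
from gaitimpress.gait_cycle import detect_gait_events, segment_cycles
from gaitimpress.synthetic import WalkerParams, generate_walker_trajectories


@pytest.fixture(scope="session")
def clean_params():
    """A deterministic walker: no noise, no stride variability, symmetric."""
    return WalkerParams(
        stride_time_cv=0.0, swing_time_asymmetry=1.0, noise_sd_m=0.0, seed=1
    )


@pytest.fixture(scope="session")
def clean_trial(clean_params):
    return generate_walker_trajectories(clean_params, duration=12.0, rate=100.0)


@pytest.fixture(scope="session")
def noisy_trial():
    p = WalkerParams(
        stride_time_cv=0.02, swing_time_asymmetry=1.02, noise_sd_m=0.001, seed=7
    )
    return generate_walker_trajectories(p, duration=12.0, rate=100.0)


@pytest.fixture(scope="session")
def clean_pipeline(clean_trial):
    """Joint centers, events, and cycles of the clean trial."""
    jc = compute_joint_centers(clean_trial.trajectories)
    events = detect_gait_events(jc, clean_trial.trajectories)
    cycles = segment_cycles(events)
    return jc, events, cycles


@pytest.fixture(scope="session")
def clean_features(clean_trial, clean_params):
    return extract_features(
        clean_trial.trajectories,
        height_m=clean_params.height_m,
        weight_kg=clean_params.weight_kg,
    )


def relative_error(est: float, truth: float, floor: float = 1e-9) -> float:
    """|est - truth| / |truth|, falling back to absolute error near zero."""
    if abs(truth) > floor:
        return abs(est - truth) / abs(truth)
    return abs(est - truth)
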