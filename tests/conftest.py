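import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model():
    from neuroarm.kinematics import RobotModel

    return RobotModel()


def random_reachable_targets(model, rng, n):
    """Uniformly sampled targets inside the arm's working envelope."""
    out = []
    from neuroarm.kinematics import inverse_kinematics

    while len(out) < n:
        az = rng.uniform(-np.pi, np.pi)
        rho = rng.uniform(30.0, 340.0)
        z = rng.uniform(-model.base_height - 40.0, 340.0)
        xe = np.array([rho * np.cos(az), rho * np.sin(az), z])
        if inverse_kinematics(xe, model).reachable:
            out.append(xe)
    return out


@pytest.fixture(scope="session")
def default_scene():
    """One rendered noise-free scene plus its ground truth."""
    from neuroarm.synth import gen_scene

    return gen_scene(disk_table=(180.0, 220.0),
                     targets_table={"green": (120.0, 150.0), "red": (290.0, 170.0)})


@pytest.fixture(scope="session")
def trained_session():
    """A trained consensus classifier on a 2-repetition synthetic session."""
    from neuroarm.app import run_training_session
    from neuroarm.bci import ConsensusClassifier
    from neuroarm.synth import SubjectParams

    params = SubjectParams(erd_depth=0.6, noise_sd_uv=4.0,
                           p300_amp_slope_uv=-0.4, p300_lat_slope_ms=12.0)
    report = run_training_session(params, seed=42, n_trials=2)
    clf = ConsensusClassifier.from_json_dict(report.extras["classifier"])
    return params, report, clf
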