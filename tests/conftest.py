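import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "homecage",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("homecage")

from homecage.archive import merge_sessions, write_archive
from homecage.synth import ExperimentConfig, FailureSpec, PhaseSpec, generate_experiment


def small_config(**overrides) -> ExperimentConfig:
    """A 3-mouse, 2-phase experiment small enough for per-test generation."""
    base = dict(
        n_mice=3,
        mouse_names=("Jerry", "Tom", "Spike"),
        groups={"C57A": ("Jerry", "Tom", "Spike")},
        phases=(
            PhaseSpec(name="NPA 1 dark", duration_hours=2.0, p_corner=0.25),
            PhaseSpec(name="PP 1 dark", duration_hours=2.0, p_corner=0.7,
                      p_side=0.7),
        ),
        visit_rate=8.0,
        seed=7,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@pytest.fixture(scope="session")
def small_experiment():
    sessions, timeline, truth = generate_experiment(small_config())
    return sessions, timeline, truth


@pytest.fixture(scope="session")
def small_data(small_experiment):
    sessions, _, _ = small_experiment
    return merge_sessions(sessions)


@pytest.fixture(scope="session")
def small_archive(small_experiment, tmp_path_factory):
    sessions, _, _ = small_experiment
    path = tmp_path_factory.mktemp("archives") / "small.zip"
    write_archive(sessions[0], path)
    return path


@pytest.fixture(scope="session")
def failure_experiment():
    """Small experiment with one presence and one lickometer failure injected."""
    config = small_config(
        seed=11,
        failures=(
            FailureSpec(kind="presence", cage=1, corner=3, at_hours=1.0),
            FailureSpec(kind="lickometer", cage=1, corner=1, side=1,
                        at_hours=2.5),
        ),
    )
    sessions, timeline, truth = generate_experiment(config)
    return sessions, timeline, truth
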