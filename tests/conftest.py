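import numpy as np
import pytest

from coprqa.types import CopTrajectory, TrialMeta


@pytest.fixture
def circle_segment():
    """COP segment factory tracing a circle: (radius_cm, period_s, n, rate)."""

    def make(radius=1.0, period_s=2.0, n=1000, rate_hz=None, center=(0.0, 0.0)):
        if rate_hz is None:
            rate_hz = (n - 1) / period_s  # exactly one revolution over the segment
        theta = np.linspace(0.0, 2.0 * np.pi, n)
        return CopTrajectory(
            ml=center[0] + radius * np.cos(theta),
            ap=center[1] + radius * np.sin(theta),
            rate_hz=rate_hz,
        )

    return make


@pytest.fixture(scope="session")
def free_trial():
    """One seeded Free-condition synthetic trial at desk-scale rates."""
    from coprqa.synth import DEFAULT_PRESETS, generate_trial

    return generate_trial(
        DEFAULT_PRESETS["Free"],
        seed=7,
        meta=TrialMeta(participant="P01", condition="Free", trial=0),
        rate_plates=100.0,
        rate_kin=50.0,
    )


@pytest.fixture(scope="session")
def free_trial_cop(free_trial):
    from coprqa.pipeline import cop_from_trial

    return cop_from_trial(free_trial)


@pytest.fixture(scope="session")
def free_trial_cycles(free_trial):
    from coprqa.segmentation import segment_trial

    return segment_trial(free_trial.wrist)
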