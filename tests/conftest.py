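import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def freqs():
    return np.arange(3.0, 51.0, 1.0)


@pytest.fixture(scope="session")
def small_epochs():
    """Tiny but complete dataset: 2 subjects x 2 conditions, all components."""
    from specdyn.synth import default_spec, simulate_epochs

    spec = default_spec(
        n_subjects=2,
        trials_per_condition=6,
        n_channels=4,
        condition_labels=[
            ("verbal", "0back", "nontarget"),
            ("verbal", "0back", "target"),
        ],
        sampling_rate=200.0,
        epoch_window=(-1.0, 2.0),
        seed=11,
    )
    return spec, simulate_epochs(spec)


@pytest.fixture(scope="session")
def exponent_shift_tfr():
    """Trial-averaged superlet TFR of data whose only change is an
    exponent increase of 0.3 between 0.2 and 0.8 s (4 subjects)."""
    from specdyn.synth import ExponentEvent, GroundTruthSpec, simulate_epochs
    from specdyn.tfr import tfr_epochs

    spec = GroundTruthSpec(
        n_subjects=4,
        condition_labels=[("verbal", "0back", "nontarget")],
        trials_per_condition=12,
        n_channels=2,
        channel_groups={},
        sampling_rate=200.0,
        epoch_window=(-1.5, 2.8),
        exponent_events=[ExponentEvent(0.2, 0.6, 0.3, shape="plateau")],
        oscillations=[],
        erp_template=None,
        sensor_noise_sd=0.05,
        seed=21,
    )
    return spec, tfr_epochs(simulate_epochs(spec))
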