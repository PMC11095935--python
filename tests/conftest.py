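import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retrogaze.io import GazeRecording, TrialMeta

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(x, y, participant="P01", session="S1", t0=0.0):
    x = np.asarray(x, dtype=float)
    return GazeRecording(
        participant_id=participant,
        session_id=session,
        time=np.arange(len(x), dtype=float) + t0,
        x=x,
        y=np.asarray(y, dtype=float),
    )


def make_trial(trial_id=0, rule_id=1, cue_onset=1000.0, past=(0.0, 4.0), future=(4.0, 0.0)):
    return TrialMeta(
        trial_id=trial_id,
        rule_id=rule_id,
        cue_onset=cue_onset,
        past_location=np.asarray(past, dtype=float),
        future_location=np.asarray(future, dtype=float),
    )


@pytest.fixture
def quiet_epoch_factory(rng):
    """Epochs of band-limited low-amplitude noise with optional injected steps."""
    from retrogaze.io import GazeEpoch
    from retrogaze.simulate import SimulationParams, simulate_trial

    def factory(events=(), noise_sd=0.002, seed=0, **param_kw):
        params = SimulationParams(
            noise_sd=noise_sd,
            drift_sd=0.0,
            blink_rate=0.0,
            base_saccade_rate=0.0,
            response_prob=0.0,
            return_saccades=False,
            seed=seed,
            **param_kw,
        )
        local_rng = np.random.default_rng(seed)
        meta = make_trial()
        epoch, truth, blinks = simulate_trial(
            meta, params, local_rng, events=list(events) or None
        )
        return epoch, truth

    return factory
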