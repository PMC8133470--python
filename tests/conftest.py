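import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazexpert.cleaning import clean_dataset, filter_trials
from gazexpert.events import GazeTrial, segment_trial
from gazexpert.features import feature_matrix
from gazexpert.simulate import SimConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trial(x, y, valid=None, rate_hz=250.0, frame=(3840, 1920), **ids):
    """Hand-built trace with exact 4 ms spacing at 250 Hz."""
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) * (1000.0 / rate_hz)
    return GazeTrial(
        participant_id=ids.get("participant_id", "P01"),
        class_label=ids.get("class_label", "novice"),
        trial_id=ids.get("trial_id", "T00"),
        block=ids.get("block", 0),
        t_ms=t,
        x=x,
        y=np.asarray(y, dtype=float),
        valid=np.ones(x.size, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        rate_hz=rate_hz,
        frame=frame,
    )


def pipeline_matrix(sim_config: SimConfig, profiles=None):
    """generate -> filter -> segment -> clean -> featurize."""
    trials = generate_dataset(sim_config, profiles=profiles)
    kept, _ = filter_trials(trials)
    streams = [segment_trial(tr) for tr in kept]
    cleaned, _ = clean_dataset(streams)
    matrix, _ = feature_matrix(cleaned)
    return matrix


@pytest.fixture(scope="session")
def calibrated_matrix():
    """Feature matrix from the full study-condition dataset.

    12/10/13 participants x 52 trials with small idiosyncrasy and default
    device errors; 8 s trials keep the build tractable while leaving ~20
    events per trial.
    """
    cfg = SimConfig(trial_duration_s=8.0, idiosyncrasy_spread=0.05, seed=20240)
    return pipeline_matrix(cfg)


@pytest.fixture(scope="session")
def clean_streams_small():
    """Segmented, error-free trials with ground truth attached."""
    cfg = SimConfig(
        participants_per_class={"expert": 2, "intermediate": 2, "novice": 2},
        trials_per_participant=4, trial_duration_s=10.0,
        dropout_rate=0.0, spike_rate=0.0, low_track_fraction=0.0,
        idiosyncrasy_spread=0.0, seed=7,
    )
    trials = generate_dataset(cfg)
    streams = [segment_trial(tr) for tr in trials]
    cleaned, _ = clean_dataset(streams)
    return cleaned
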