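import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from motioncue.synthetic_data import (
    DEFAULT_CATEGORY_MIX,
    NeuronModel,
    Session,
    TaskConfig,
    plant_population,
    simulate_session,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    return TaskConfig(
        blocks=2,
        trials_per_block=60,
        passive_clarity_reps=12,
        passive_motion_reps=8,
        abort_prob=0.05,
    )


@pytest.fixture(scope="session")
def planted_neurons() -> list[NeuronModel]:
    return plant_population(DEFAULT_CATEGORY_MIX, 6, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config, planted_neurons) -> Session:
    return simulate_session(small_config, planted_neurons, seed=5)


def build_session(
    spike_times: dict[int, dict[int, list[float]]],
    trials: pd.DataFrame,
    config: TaskConfig | None = None,
    neurons: list[NeuronModel] | None = None,
) -> Session:
    """Assemble a Session by hand for oracle tests with known spike trains."""
    config = config or TaskConfig()
    nids = sorted(spike_times)
    neurons = neurons or [NeuronModel(neuron_id=i) for i in nids]
    spikes = {
        nid: {
            int(t): np.asarray(sorted(spike_times[nid].get(int(t), [])),
                               dtype=float)
            for t in trials["trial_id"]
        }
        for nid in nids
    }
    return Session(
        session_id=0, monkey_label="Y", config=config, neurons=neurons,
        trials=trials, spikes=spikes, eye={},
    )


def passive_clarity_trials(
    clarity_levels, shapes=("blob", "spikey"), reps=1
) -> pd.DataFrame:
    rows = []
    tid = 0
    for _ in range(reps):
        for shape in shapes:
            for c in clarity_levels:
                rows.append(dict(
                    trial_id=tid, phase="passive_clarity", block=-1,
                    shape_category=shape, pair_id=0, clarity=c,
                    motion_kind="static", motion_role="passive",
                    correct_side="none", response_side="none",
                    correct=np.nan, rewarded=np.nan, reaction_ms=np.nan,
                    aborted=False,
                ))
                tid += 1
    return pd.DataFrame(rows)
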