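import numpy as np
import pytest

from metaprob.agent_sim import SimulationSpec, simulate_study
from metaprob.pipeline import pooled_followup
from metaprob.task_core import TrialRecord


def make_trial(
    coherence=0.12,
    p_external=0.5,
    chose_internal=True,
    correct=True,
    rewarded=None,
    true_direction="left",
    trial_index=1,
    session_id="t",
):
    """Concise TrialRecord factory with self-consistent directions."""
    response = true_direction if correct else (
        "right" if true_direction == "left" else "left"
    )
    if rewarded is None:
        rewarded = correct and chose_internal
    return TrialRecord(
        session_id=session_id,
        trial_index=trial_index,
        coherence=coherence,
        p_external=p_external,
        chose_internal=chose_internal,
        true_direction=true_direction,
        response_direction=response,
        perceptual_correct=correct,
        rewarded=rewarded,
    )


@pytest.fixture(scope="session")
def small_study():
    """Two simulated sessions with follow-up, pooled for reuse."""
    spec = SimulationSpec(n_sessions=4)
    sessions = simulate_study(spec, seed=11)
    trials = [t for main, _ in sessions for t in main.trials]
    followup = pooled_followup([f for _, f in sessions])
    return {"sessions": sessions, "trials": trials, "followup": followup}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
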