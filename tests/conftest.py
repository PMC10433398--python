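import numpy as np
import pytest

from twostep.agents import AgentParams, HybridAgent
from twostep.stay_switch import features_from_logs
from twostep.task import TaskConfig, run_session


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


def simulate_prototype_logs(w: float, seed: int, n_subjects: int = 30,
                            config: TaskConfig | None = None):
    """Single-session cohort of identical-w hybrid agents (no design factors)."""
    config = config or TaskConfig()
    root = np.random.SeedSequence(seed)
    logs = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        agent = HybridAgent(AgentParams(w=w), p_common=config.p_common, rng=rng)
        logs.append(run_session(agent, config, seed=rng, subject_id=f"S{i:02d}"))
    return logs


@pytest.fixture(scope="session")
def prototype_features():
    """Lagged stay features for pure-MF (w=0) and pure-MB (w=1) cohorts."""
    return {
        w: features_from_logs(simulate_prototype_logs(w, seed=0)) for w in (0.0, 1.0)
    }
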