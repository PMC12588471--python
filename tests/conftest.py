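import numpy as np
import pandas as pd
import pytest

from guesslab import BiasSpec, StudyConfig, simulate_study
from guesslab.simulate import TRIAL_COLUMNS


@pytest.fixture(scope="session")
def mixed_null_table() -> pd.DataFrame:
    """Small mixed-session human study at exactly chance, no heterogeneity."""
    cfg = StudyConfig(
        n_participants=40,
        session_type="mixed",
        incomplete_session_prob=0.0,
        overrun_prob=0.0,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def reg_null_table() -> pd.DataFrame:
    """Pure-session REG arm at chance."""
    cfg = StudyConfig(
        n_participants=60,
        session_type="pure",
        arm="reg",
        incomplete_session_prob=0.0,
        overrun_prob=0.0,
        seed=12,
    )
    return simulate_study(cfg)


def synthetic_condition_table(
    n: int,
    p: float,
    seed: int,
    condition: str = "X",
    arm: str = "reg",
    participant_id: str = "REG",
) -> pd.DataFrame:
    """Fabricate a minimal single-condition trial table from Bernoulli draws.

    Used where only the hit column matters and full paradigm simulation
    would be wastefully slow.
    """
    rng = np.random.default_rng(seed)
    hits = rng.random(n) < p
    target = np.where(rng.random(n) < 0.5, "left", "right")
    guess = np.where(hits, target, np.where(target == "left", "right", "left"))
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "session_id": "S1",
            "session_type": "pure",
            "arm": arm,
            "condition": condition,
            "trial_index": (np.arange(n) % 36) + 1,
            "guess_side": guess,
            "target_side": target,
            "hit": hits,
            "reward_shown": hits & (condition in ("X", "O")),
        },
        columns=TRIAL_COLUMNS,
    )
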