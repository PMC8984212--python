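import numpy as np
import pandas as pd
import pytest

from triarm import SimConfig, synth


@pytest.fixture(scope="session")
def trial_and_config():
    """A moderate full trial (morbidity, adherence, registry included)."""
    cfg = SimConfig(n_per_arm=150, seed=11)
    return synth.simulate_trial(cfg), cfg


@pytest.fixture(scope="session")
def trial(trial_and_config):
    return trial_and_config[0]


@pytest.fixture(scope="session")
def two_visit_complete():
    """60 children, baseline + month 3, complete data, no covariates.

    Single union and sex so the constrained longitudinal fit carries no
    stratification dummies — the clean setting for the ANCOVA identity.
    """
    rng = np.random.default_rng(5)
    n = 60
    arm = np.repeat(["iron", "mnp", "placebo"], n // 3)
    y0 = rng.normal(100, 15, n)
    y1 = 60 + 0.4 * y0 + 2.0 * (arm == "iron") + rng.normal(0, 12, n)
    tab = pd.DataFrame({
        "child_id": np.repeat([f"c{i:02d}" for i in range(n)], 2),
        "visit": np.tile([0, 1], n),
        "arm": np.repeat(arm, 2),
        "union": "Bhulta", "sex": "female",
        "y": np.column_stack([y0, y1]).ravel(),
    })
    return tab, arm, y0, y1


@pytest.fixture(scope="session")
def three_visit_complete():
    """90 children, three visits, two strata; complete data."""
    cfg = SimConfig(n_per_arm=30, seed=17, light=True,
                    effects={"cognitive": {"iron": (2.0, 3.0)}})
    data = synth.simulate_trial(cfg)
    return data.analysis_table()
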