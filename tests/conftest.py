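import numpy as np
import pandas as pd
import pytest

from exposcan import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted effects, shared by read-only tests."""
    cfg = syn.GeneratorConfig(
        n_participants=4000,
        n_variables_per_domain={d: 3 for d in syn.DOMAINS},
        true_log_hr={
            "medical_history_v1": 0.5,
            "psychosocial_v1": 0.45,
            "lifestyle_v0": -0.35,
        },
        baseline_hazard_scale=0.006,
        missing_rate=0.02,
        special_code_rate=0.01,
        seed=42,
    )
    cohort, catalog, truth = syn.generate_cohort(cfg)
    return cfg, cohort, catalog, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def survival_frame(rng, n, log_hr=0.0, scale=0.05, followup=12.0, binary=True):
    """Simple single-covariate survival data for solver tests."""
    x = rng.binomial(1, 0.5, n).astype(float) if binary else rng.standard_normal(n)
    t_event = rng.exponential(1.0 / (scale * np.exp(log_hr * x)))
    time = np.minimum(t_event, followup)
    event = (t_event <= followup).astype(int)
    return pd.DataFrame({"time": time, "event": event, "x": x})
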