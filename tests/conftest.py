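import numpy as np
import pandas as pd
import pytest

from irgp_surv import ExpressionCohort, SimulationConfig, simulate_cohorts


def make_cohort(n_genes=8, n_samples=20, seed=0, platform="test", log_scale=True):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    vals = rng.normal(5.0, 2.0, size=(n_genes, n_samples))
    return ExpressionCohort(
        values=pd.DataFrame(vals, index=genes, columns=samples),
        platform=platform,
        log_scale=log_scale,
    )


def make_clinical(sample_ids, seed=0, rate=0.3, censor_upper=4.0):
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    t_event = rng.exponential(1.0 / rate, size=n)
    t_cens = rng.uniform(0, censor_upper, size=n)
    return pd.DataFrame(
        {
            "age": rng.integers(40, 80, n),
            "gender": rng.choice(["male", "female"], n),
            "grade": rng.integers(1, 5, n),
            "stage": rng.integers(1, 5, n),
            "os_time": np.minimum(t_event, t_cens),
            "os_event": (t_event <= t_cens).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small two-platform simulated study with 5 true pairs."""
    cfg = SimulationConfig(
        n_samples=(260, 120),
        n_genes=80,
        n_immune_genes=60,
        n_true_pairs=5,
        true_log_hazard_ratios=(0.7,) * 5,
        censoring_rate=0.3,
        seed=42,
    )
    cohorts, clinicals, truth = simulate_cohorts(cfg)
    return cfg, cohorts, clinicals, truth
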