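import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def sumstats_frame():
    """A small, clean summary-statistics frame in internal columns."""
    def make(n=5, seed=0):
        r = np.random.default_rng(seed)
        beta = r.normal(0, 0.1, n)
        se = r.uniform(0.01, 0.05, n)
        return pd.DataFrame({
            "snp": [f"rs{i+1}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 100_000,
            "ea": "A", "oa": "G",
            "eaf": r.uniform(0.1, 0.9, n),
            "beta": beta, "se": se, "z": beta / se,
            "p": 2 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(np.abs(beta / se)),
            "n": 10_000.0, "info": 0.99, "hwe_p": 0.5,
        })
    return make
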