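import logging

import numpy as np
import pandas as pd
import pytest

from munet.synthdata import simulate_cohort

# keep per-mu failure warnings out of test output; they are expected in
# degenerate grid points
logging.getLogger("munet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-condition cohort shared by read-only tests."""
    return simulate_cohort(n_samples=120, n_modules=3, genes_per_module=12,
                           n_noise_genes=12, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival(n, seed=0, b1=1.0, scale=0.5, censor_frac=0.3):
    """Small Weibull AFT survival table plus its driving latent."""
    r = np.random.default_rng(seed)
    z = r.standard_normal(n)
    log_t = 6.5 + b1 * z + scale * np.log(-np.log(r.uniform(size=n)))
    t = np.exp(log_t)
    c = r.uniform(0, np.quantile(t, 1 - censor_frac) * 1.5, size=n)
    ids = [f"P{i:03d}" for i in range(n)]
    surv = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)},
                        index=pd.Index(ids, name="id"))
    return surv, pd.Series(z, index=ids)
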