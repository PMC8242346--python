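import numpy as np
import pandas as pd
import pytest

from panitg.cohort import NORMAL, TUMOR, OmicsCohort
from panitg.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with one planted signal of every kind."""
    cfg = CohortConfig(
        cancer_code="FIX",
        n_tumor=100,
        n_normal=50,
        n_genes=120,
        seed=42,
        planted_up={"ITGA11": 2.0},
        planted_down={"ITGA8": 1.5},
        planted_cnv_drivers={"ITGB8": ("gain", 0.6, 0.5, 0.7)},
        planted_meth_drivers={"ITGA4": ("hyper", 0.2, 0.7)},
        planted_prognostic={"ITGA11": 0.8, "ITGA9": -0.6},
        mutation_rate_per_gene={"ITGAV": 0.10, "ITGB4": 0.05},
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 3-gene cohort for exact-arithmetic checks."""
    genes = ["G1", "G2", "G3"]
    samples = [f"T{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.normal(6, 1, (3, 10)), index=genes, columns=samples)
    st = pd.Series([TUMOR] * 5 + [NORMAL] * 5, index=samples)
    return OmicsCohort(cancer_code="TINY", expression=expr, sample_type=st)


def weibull_ph_data(rng, n, beta, shape=1.2, scale=60.0, censor_frac=0.2):
    """Direct Weibull proportional-hazards simulation for survival tests."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = rng.normal(size=(n, beta.size))
    lp = x @ beta
    t = scale * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1 / shape)
    if censor_frac > 0:
        c = rng.exponential(np.quantile(t, 1 - censor_frac) * 2.0, size=n)
    else:
        c = np.full(n, np.inf)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return x, times, events
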