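"""Shared fixtures: one default synthetic cohort reused across modules."""
import numpy as np
import pandas as pd
import pytest

from callsig import diffexp
from callsig.expression import log_cpm, upper_quartile_factors
from callsig.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (study-sized groups, planted truth)."""
    return simulate_counts(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(default_cohort):
    counts, samples, genes, truth = default_cohort
    return diffexp.fit_nb_glm(counts, samples)


@pytest.fixture(scope="session")
def de_table(fitted):
    return diffexp.de_table(fitted)


@pytest.fixture(scope="session")
def tumor_expression(default_cohort):
    """logCPM over tumour samples only, with labels."""
    counts, samples, genes, truth = default_cohort
    expr = log_cpm(counts, upper_quartile_factors(counts), 1.0)
    tumor = samples.index[samples["group"] != "Control"]
    return expr[list(tumor)], samples.loc[tumor, "group"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_group_counts(seed=11, n_genes=1500, n_per_group=15, phi=0.1,
                     lfc=None, libsize=8e5):
    """Small two-group NB cohort for calibration checks.

    ``lfc`` is an optional per-gene log2 fold-change vector applied to
    the second group.
    """
    rng = np.random.default_rng(seed)
    q = rng.lognormal(0, 1.0, n_genes)
    q /= q.sum()
    lib = rng.lognormal(np.log(libsize), 0.2, 2 * n_per_group)
    mu = np.outer(q, lib)
    if lfc is not None:
        mu[:, n_per_group:] = mu[:, n_per_group:] * np.exp2(lfc)[:, None]
    if phi > 0:
        counts = rng.poisson(rng.gamma(1.0 / phi, mu * phi))
    else:
        counts = rng.poisson(mu)
    counts = pd.DataFrame(
        counts, index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(2 * n_per_group)])
    samples = pd.DataFrame(
        {"group": ["Control"] * n_per_group + ["HeH"] * n_per_group,
         "batch": "B1"}, index=counts.columns)
    return counts, samples
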