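import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")

from ltcincidence import (
    PrevalenceTable,
    default_truths,
    synthesize_tables,
)


@pytest.fixture(scope="session")
def gompertz_truths():
    return default_truths()


@pytest.fixture(scope="session")
def gompertz_tables(gompertz_truths):
    """Default synthetic study tables (biennial 2011-2019, registry groups)."""
    prev, mort, surfaces = synthesize_tables(gompertz_truths)
    return prev, mort, surfaces


def make_logitlinear_prevalence(
    beta0=-10.0,
    beta_t=0.01,
    beta_a=0.09,
    t_ref=2015.0,
    years=(2011, 2013, 2015, 2017, 2019),
    ages=(52.5, 57.5, 62.5, 67.5, 72.5, 77.5, 82.5, 87.5),
    sex="female",
    n_pop=10**9,
    noise_sd=0.0,
    rng=None,
):
    """Grouped table whose prevalences lie exactly on a logit-linear surface.

    Ages are 5-year group midpoints; with noise_sd > 0, independent Gaussian
    noise is added on the logit scale.
    """
    from scipy.special import expit

    rows = []
    for year in years:
        for a in ages:
            eta = beta0 + beta_t * (year - t_ref) + beta_a * a
            if noise_sd > 0:
                eta = eta + rng.normal(0.0, noise_sd)
            p = float(expit(eta))
            lo = int(a - 2.5)
            # exact fractional counts: the table then carries the surface
            # values to machine precision (counts need not be integers)
            rows.append((year, sex, lo, lo + 5.0, p * n_pop, n_pop))
    df = pd.DataFrame(rows, columns=["year", "sex", "age_lo", "age_hi", "n_care", "n_pop"])
    return PrevalenceTable.from_records(df)
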