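import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import patternmix as pm

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def empirical_ds():
    """Illness-severity-like fixture at the reference size (437 subjects),
    reproducing the reference pattern-by-group table exactly."""
    return pm.generate_empirical_like(437, seed=1)


@pytest.fixture(scope="session")
def empirical_patterns(empirical_ds):
    return pm.classify_patterns(empirical_ds)


@pytest.fixture(scope="session")
def empirical_dropout(empirical_ds, empirical_patterns):
    return pm.dropout_summary(empirical_ds, empirical_patterns)


@pytest.fixture
def fast_cfg():
    return pm.McmcConfig(n_iterations=3000, n_burnin=1000, thin=2, seed=7)


@pytest.fixture
def med_cfg():
    return pm.McmcConfig(n_iterations=12000, n_burnin=3000, thin=9, seed=42)


@pytest.fixture
def toy_dataset_factory():
    """Build a small dataset from (subject, mask, group) triples over the
    standard key weeks; responses are filled deterministically."""

    def make(mask_group, key_weeks=(0, 1, 3, 6)):
        rows, cov = [], {}
        for i, (mask, g) in enumerate(mask_group):
            sid = f"T{i:03d}"
            cov[sid] = g
            for w, bit in zip(key_weeks, mask):
                if bit == "1":
                    rows.append((sid, w, 4.0 + 0.1 * i - 0.2 * w))
        records = pd.DataFrame(rows, columns=["subject", "week", "y"])
        covariates = pd.DataFrame(
            {"drug": pd.Series(cov)}, index=pd.Index(list(cov), name="subject")
        )
        return pm.LongitudinalDataset(
            records, covariates, planned_weeks=key_weeks, key_weeks=key_weeks
        )

    return make


@pytest.fixture
def conjugate_toy():
    """Known-variance normal-mean problem cast as a degenerate growth model:
    one observation per subject at week 0, no random effects, fixed residual
    variance, unbounded flat-ish prior on the intercept."""
    rng = np.random.default_rng(7)
    n, sigma2, mu_true = 50, 4.0, 3.0
    y = mu_true + rng.standard_normal(n) * np.sqrt(sigma2)
    rec = pd.DataFrame({"subject": np.arange(n), "week": 0, "y": y})
    cov = pd.DataFrame(index=pd.RangeIndex(n, name="subject"))
    ds = pm.LongitudinalDataset(rec, cov, planned_weeks=(0,), key_weeks=(0,))
    spec = pm.build_model(
        "ignorable", "linear", (),
        variance_covariates=(),
        priors=pm.PriorSpec(intercept_bounds=None),
        random_effects=False,
        fixed_tau=(np.log(sigma2),),
    )
    prior_var = spec.priors.fixed_effect_var
    post_var = 1.0 / (n / sigma2 + 1.0 / prior_var)
    post_mean = post_var * y.sum() / sigma2
    return ds, spec, post_mean, post_var
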