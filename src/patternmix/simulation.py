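"""Synthetic data generation and the missingness bias experiment.

Two generators live here.

``simulate_*`` implements the bias-study data-generating mechanism: a linear
random-effects growth model for 400 subjects over waves 1..6 with a binary
covariate X1 (a dichotomized standard-normal latent) and a continuous
covariate X2 ~ N(0,1) that is *withheld from the fitted models*, emulating an
unmeasured confounder.  X1 is linked to X2 through the latent variable
(latent = 0.5 X2 + e_x, Var(e_x) = 0.75, cut at 0, so the latent has unit
variance and correlation 0.5 with X2).  Missingness at waves 2..6 follows
per-wave logistic models in X1 and X2 whose coefficients double from wave to
wave, producing both monotone and intermittent missingness; wave 1 is always
observed.

``generate_empirical_like`` builds an illness-severity-like fixture: square
root-of-week growth on a bounded 1..7 rating scale for two treatment groups,
with observation occasions {0,1,3,6} plus rarely assessed mid-weeks and a
missing-data pattern catalogue drawn from the reference pattern frequency
table of the motivating schizophrenia trial (quota assignment, so at the
reference size of 437 subjects the pattern-by-group table is reproduced
exactly).  Pattern assignment is independent of the responses, so the
fixture's missingness is ignorable by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    ConfigurationError,
    DataError,
    DropoutSummary,
    LongitudinalDataset,
    classify_patterns,
    dropout_summary,
)
from .models import PriorSpec, build_model
from .mcmc import McmcConfig, hpdi, sample_posterior

logger = logging.getLogger("patternmix")

# ---------------------------------------------------------------------------
# the bias-study DGM
# ---------------------------------------------------------------------------

DEFAULT_MISSING_LOGITS: Mapping[int, tuple] = {
    2: (-1.0, 0.2, 0.3),
    3: (-1.0, 0.4, 0.6),
    4: (-1.0, 0.8, 1.2),
    5: (-1.0, 1.6, 2.4),
    6: (-1.0, 3.2, 4.8),
}


@dataclass
class SimulationConfig:
    """The bias-study data-generating mechanism."""

    n_subjects: int = 400
    n_waves: int = 6
    gamma_00: float = 1.0
    gamma_01: float = 0.5
    gamma_02: float = 1.0
    gamma_10: float = 2.0
    gamma_11: float = 0.2
    gamma_12: float = 0.5
    sigma_e2: float = 0.3
    phi_u0: float = 1.0
    phi_u1: float = 0.5
    phi_u1u0: float = 0.1
    covariate_link: float = 0.5
    missing_logits: Mapping[int, tuple] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_LOGITS)
    )

    @property
    def phi_matrix(self) -> np.ndarray:
        return np.array(
            [[self.phi_u0, self.phi_u1u0], [self.phi_u1u0, self.phi_u1]]
        )

    def true_values(self) -> dict:
        """DGM values keyed by the fitted-model parameter names (covariate
        order: intercept, x1)."""
        return {
            "gamma_00": self.gamma_00,
            "gamma_01": self.gamma_01,
            "gamma_10": self.gamma_10,
            "gamma_11": self.gamma_11,
            "tau_0": math.log(self.sigma_e2),
            "phi_u0": self.phi_u0,
            "phi_u1u0": self.phi_u1u0,
            "phi_u1": self.phi_u1,
        }


def _psd_factor(m: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(np.asarray(m, dtype=float))
    if (vals < -1e-10).any():
        raise DataError("covariance matrix is not positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_covariates(n: int, seed: int, link: float = 0.5):
    """Binary X1 and continuous X2.

    X2 ~ N(0,1); the latent X1* = link*X2 + e_x with Var(e_x) = 1 - link^2
    has unit variance and correlation ``link`` with X2; X1 = 1{X1* > 0}.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x2 = rng.standard_normal(n)
    e = rng.standard_normal(n) * math.sqrt(1.0 - link ** 2)
    latent = link * x2 + e
    x1 = (latent > 0).astype(int)
    return x1, x2


def simulate_outcomes(
    cfg: SimulationConfig, x1, x2, seed: int
) -> LongitudinalDataset:
    """Complete responses at waves 1..cfg.n_waves (week = wave - 1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = len(x1)
    if len(x2) != n:
        raise ConfigurationError("x1 and x2 must have equal length")
    rng = np.random.default_rng(seed)
    L = _psd_factor(cfg.phi_matrix)
    u = rng.standard_normal((n, 2)) @ L.T
    b0 = cfg.gamma_00 + cfg.gamma_01 * x1 + cfg.gamma_02 * x2 + u[:, 0]
    b1 = cfg.gamma_10 + cfg.gamma_11 * x1 + cfg.gamma_12 * x2 + u[:, 1]
    weeks = np.arange(cfg.n_waves)          # wave - 1
    mu = b0[:, None] + b1[:, None] * weeks[None, :]
    y = mu + rng.standard_normal((n, cfg.n_waves)) * math.sqrt(cfg.sigma_e2)
    records = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), cfg.n_waves),
            "week": np.tile(weeks, n),
            "y": y.ravel(),
        }
    )
    covariates = pd.DataFrame({"x1": x1.astype(int), "x2": x2},
                              index=pd.RangeIndex(n, name="subject"))
    return LongitudinalDataset(
        records=records,
        covariates=covariates,
        planned_weeks=tuple(weeks),
        key_weeks=tuple(weeks),
    )


def missingness_probability(wave: int, x1, x2, cfg: SimulationConfig):
    """Probability that the response at ``wave`` is missing."""
    if wave == 1:
        raise ConfigurationError("wave 1 is always observed")
    if wave not in cfg.missing_logits:
        raise ConfigurationError(f"no missingness model for wave {wave}")
    c0, c1, c2 = cfg.missing_logits[wave]
    eta = c0 + c1 * np.asarray(x1, dtype=float) + c2 * np.asarray(x2, dtype=float)
    out = expit(eta)
    return out if np.ndim(out) else float(out)


def apply_missingness(
    ds: LongitudinalDataset, cfg: SimulationConfig, seed: int
) -> LongitudinalDataset:
    """Delete wave-2..6 records independently with their configured
    missingness probabilities; wave-1 records are always retained."""
    rng = np.random.default_rng(seed)
    rec = ds.records
    x1 = ds.covariates["x1"].reindex(rec["subject"]).to_numpy(dtype=float)
    x2 = ds.covariates["x2"].reindex(rec["subject"]).to_numpy(dtype=float)
    wave = rec["week"].to_numpy() + 1
    p = np.zeros(len(rec))
    for w, coefs in cfg.missing_logits.items():
        m = wave == w
        p[m] = expit(coefs[0] + coefs[1] * x1[m] + coefs[2] * x2[m])
    keep = rng.uniform(size=len(rec)) >= p
    keep |= wave == 1
    return replace(ds, records=rec.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# derived missingness covariates for the fitted models
# ---------------------------------------------------------------------------

def derive_missingness_covariates(ds: LongitudinalDataset) -> pd.DataFrame:
    """Per-subject drop indicator, dropout timing and pattern cluster label.

    ``drop`` flags a strictly monotone dropout pattern (a prefix of observed
    waves followed only by missing waves).  ``timing`` counts the trailing
    missing waves of a monotone dropout (how early the subject left: 0 for
    completers and purely intermittent patterns, up to n_waves - 1 for a
    first-wave-only subject), so the completer stratum is the covariate
    reference in both the drop and the timing models.  ``pattern`` is the
    observation mask used to cluster subjects in the random pattern-mixture
    fit; in this experiment every subject is clustered, completers forming
    their own pattern, so the fixed intercept is a population-of-patterns
    mean rather than being anchored by the completer stratum.
    """
    pa = classify_patterns(ds)
    n_waves = len(ds.key_weeks)
    masks = pa.masks

    def is_monotone(m: str) -> bool:
        first_zero = m.find("0")
        return first_zero >= 0 and "1" not in m[first_zero:]

    drop = masks.map(is_monotone).astype(int).rename("drop")
    timing = masks.map(
        lambda m: (n_waves - 1 - m.rfind("1")) if is_monotone(m) else 0
    ).astype(float).rename("timing")
    pattern = masks.rename("pattern")
    return pd.concat([drop, timing, pattern], axis=1)


# ---------------------------------------------------------------------------
# the bias experiment
# ---------------------------------------------------------------------------

STUDY_MODELS = ("ignorable", "single_dropout", "timing_of_dropout", "random_pmm")


@dataclass
class BiasTable:
    """Average posterior estimates, bias and interval widths per fitted
    model and parameter, across simulation replicates."""

    table: pd.DataFrame
    n_reps: int
    replicate_seeds: list

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _study_spec(model: str, pattern: Optional[pd.Series]):
    priors = PriorSpec(intercept_bounds=None)
    common = dict(covariates=("x1",), variance_covariates=(), priors=priors)
    if model == "ignorable":
        return build_model("ignorable", "linear", **common)
    if model == "single_dropout":
        return build_model("fixed_pmm", "linear",
                           extra_level2_terms=("drop",), **common)
    if model == "timing_of_dropout":
        return build_model("fixed_pmm", "linear",
                           extra_level2_terms=("timing",), **common)
    if model == "random_pmm":
        return build_model("random_pmm", "linear",
                           pattern_set=pattern, **common)
    raise ConfigurationError(f"unknown study model {model!r}")


def run_simulation_study(
    cfg: SimulationConfig,
    n_reps: int,
    mcmc_cfg: McmcConfig,
    seed: int,
    models: Sequence[str] = STUDY_MODELS,
    prob: float = 0.95,
) -> BiasTable:
    """Replicate the missingness bias experiment.

    Per replicate, data are generated under the full DGM (X2 an unmeasured
    confounder of both the trajectory and the missingness), missingness is
    applied, and each requested model is fitted with X1 as the only measured
    covariate.  Posterior means and HPDI widths are averaged across
    replicates; bias = average estimate - generating value, exactly.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    true_vals = cfg.true_values()
    sums: dict = {}
    widths: dict = {}
    counts: dict = {}
    failures = 0
    rep_seeds = []
    for rep in range(n_reps):
        data_seed = seed + rep
        rep_seeds.append(data_seed)
        x1, x2 = simulate_covariates(cfg.n_subjects, data_seed, cfg.covariate_link)
        full = simulate_outcomes(cfg, x1, x2, seed + 1_000_000 + rep)
        obs = apply_missingness(full, cfg, seed + 2_000_000 + rep)
        extra = derive_missingness_covariates(obs)
        obs = obs.with_covariates(extra[["drop", "timing"]])
        pattern = extra["pattern"]
        rep_ok = True
        rep_results = {}
        for model in models:
            try:
                spec = _study_spec(model, pattern)
                fit_cfg = replace(mcmc_cfg, seed=mcmc_cfg.seed + 10 * rep)
                draws = sample_posterior(spec, obs, None, fit_cfg)
                res = {}
                for name in draws.params.columns:
                    x = draws.params[name].to_numpy()
                    lo, hi = hpdi(x, prob)
                    res[name] = (float(x.mean()), hi - lo)
                rep_results[model] = res
            except Exception as exc:  # pragma: no cover - failure path
                logger.warning("replicate %d model %s failed: %s", rep, model, exc)
                rep_ok = False
                break
        if not rep_ok:
            failures += 1
            continue
        for model, res in rep_results.items():
            for name, (est, width) in res.items():
                key = (model, name)
                sums[key] = sums.get(key, 0.0) + est
                widths[key] = widths.get(key, 0.0) + width
                counts[key] = counts.get(key, 0) + 1
    if failures > 0.2 * n_reps:
        raise RuntimeError(
            f"{failures}/{n_reps} replicates failed; simulation study aborted"
        )
    rows = []
    for (model, name), c in counts.items():
        avg = sums[(model, name)] / c
        true = true_vals.get(name, float("nan"))
        rows.append(
            {
                "model": model,
                "parameter": name,
                "true_value": true,
                "avg_estimate": avg,
                "bias": avg - true,
                "avg_interval_width": widths[(model, name)] / c,
                "n_reps": c,
            }
        )
    table = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(models)}
    table = table.sort_values(
        ["model", "parameter"], key=lambda s: s.map(order).fillna(s) if s.name == "model" else s
    ).reset_index(drop=True)
    return BiasTable(table=table, n_reps=n_reps - failures, replicate_seeds=rep_seeds)


# ---------------------------------------------------------------------------
# illness-severity-like fixture
# ---------------------------------------------------------------------------

#: Reference pattern-by-group frequencies (masks over key weeks 0,1,3,6) of
#: the motivating schizophrenia trial: 437 patients, 108 placebo / 329 drug.
REFERENCE_PATTERN_TABLE = pd.DataFrame(
    {
        "mask": ["1111", "1110", "1100", "1101", "1011",
                 "0111", "1000", "1001", "1010"],
        "placebo": [64, 19, 18, 3, 2, 1, 0, 0, 1],
        "drug": [248, 34, 27, 10, 3, 2, 3, 2, 0],
    }
).set_index("mask")

#: Generating values of the fixture's square-root-of-week growth model
#: (posterior point estimates of the reference analysis).
EMPIRICAL_GROWTH_PARAMS = {
    "gamma_00": 5.34,   # placebo baseline level
    "gamma_01": 0.05,   # drug effect on baseline
    "gamma_10": -0.33,  # placebo sqrt(week) slope
    "gamma_11": -0.65,  # drug effect on the slope
    "tau_0": -0.81,     # log residual variance, placebo
    "tau_1": 0.28,      # drug offset on the log residual variance
    "phi_u0": 0.47,
    "phi_u1u0": -0.03,
    "phi_u1": 0.32,
}


def _quota(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n into len(weights) cells."""
    w = np.asarray(weights, dtype=float)
    exact = w / w.sum() * n
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def generate_empirical_like(
    n: int = 437,
    seed: int = 0,
    mid_week_prob: float = 0.03,
    params: Optional[Mapping[str, float]] = None,
) -> LongitudinalDataset:
    """Illness-severity-like fixture with the reference missingness patterns.

    Subjects are apportioned to treatment groups and missing-data patterns by
    largest-remainder quotas on the reference frequency table, so at n = 437
    the reference pattern-by-group table is reproduced exactly.  Responses
    follow the square-root-of-week growth model with the reference point
    estimates as generating values, clipped to the 1..7 rating scale.
    Mid-weeks 2, 4, 5 are observed with small probability, only before the
    subject's last key-week observation so the last-observed week stays
    pattern-determined.  Pattern assignment is independent of the responses:
    the fixture's missingness is ignorable by construction.
    """
    if n < 20:
        raise ConfigurationError("n must be >= 20")
    p = dict(EMPIRICAL_GROWTH_PARAMS)
    p.update(params or {})
    rng = np.random.default_rng(seed)
    ref = REFERENCE_PATTERN_TABLE
    group_sizes = _quota(ref.sum(axis=0).to_numpy(), n)  # placebo, drug
    key_weeks = (0, 1, 3, 6)
    mid_weeks = (2, 4, 5)

    subjects, drugs, masks = [], [], []
    sid = 0
    for g, gname in enumerate(("placebo", "drug")):
        quotas = _quota(ref[gname].to_numpy(), int(group_sizes[g]))
        for mask, q in zip(ref.index, quotas):
            for _ in range(q):
                subjects.append(f"S{sid:04d}")
                drugs.append(g)
                masks.append(mask)
                sid += 1
    drugs = np.array(drugs)
    n_sub = len(subjects)

    phi = np.array([[p["phi_u0"], p["phi_u1u0"]], [p["phi_u1u0"], p["phi_u1"]]])
    u = rng.standard_normal((n_sub, 2)) @ _psd_factor(phi).T
    b0 = p["gamma_00"] + p["gamma_01"] * drugs + u[:, 0]
    b1 = p["gamma_10"] + p["gamma_11"] * drugs + u[:, 1]
    sd = np.sqrt(np.exp(p["tau_0"] + p["tau_1"] * drugs))

    rows = []
    for i in range(n_sub):
        mask = masks[i]
        weeks = [w for w, b in zip(key_weeks, mask) if b == "1"]
        last_key = max(weeks) if weeks else 0
        for w in mid_weeks:
            if w < last_key and rng.uniform() < mid_week_prob:
                weeks.append(w)
        for w in sorted(weeks):
            y = b0[i] + b1[i] * math.sqrt(w) + sd[i] * rng.standard_normal()
            rows.append((subjects[i], w, float(np.clip(y, 1.0, 7.0))))
    records = pd.DataFrame(rows, columns=["subject", "week", "y"])
    covariates = pd.DataFrame(
        {"drug": drugs}, index=pd.Index(subjects, name="subject")
    )
    return LongitudinalDataset(
        records=records,
        covariates=covariates,
        planned_weeks=(0, 1, 2, 3, 4, 5, 6),
        key_weeks=key_weeks,
    )
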