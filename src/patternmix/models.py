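"""Growth-model specifications and their missingness extensions.

The core data model is a two-level random-effects growth curve for a
longitudinal response y_ti,

    level 1:  y_ti = f(beta_i, week_ti) + e_ti,      e_ti ~ N(0, sigma2_e(i))
    level 2:  beta_ji = x_i' gamma_j + u_ji,         (u_0i, u_1i) ~ N2(0, Phi_u)

with four growth forms f (linear, linear in sqrt(week), quadratic,
exponential with a lower asymptote) and a log-linear model for the residual
variance, sigma2_e(i) = exp(tau' x_var,i), so variances may differ between
covariate groups.

Five treatments of the missing-data mechanism share this core:

ignorable
    the growth model alone (missingness independent of the missing values
    given covariates).
fixed_pmm
    a fixed pattern-mixture model: a subject-level dropout indicator (and
    its interaction with the covariate) enters every level-2 regression;
    population-averaged effects are recovered by weighting the pattern
    strata by their proportions (see :func:`pattern_average`).
random_pmm
    a random pattern-mixture model: subjects with incomplete data are
    clustered by missing-data pattern, and the cluster contributes random
    intercept/slope deviations (v_0k, v_1k) ~ N2(0, Phi_v) — a three-level
    hierarchy, subjects within patterns.  Complete-data subjects carry no
    pattern-level effect.
joint_dropout
    the growth model fitted jointly with a normal regression of the
    log last-observed week on the group covariate,
    ln(MaxWeek)_i = alpha_0 + alpha_1 group_i + eps_i,
    Var(eps_i) = exp(kappa' x_var,i); the two processes are independent.
shared_parameter
    the joint model with the subject's growth coefficients entering the
    dropout-time regression: ... + alpha_2 beta_0i + alpha_3 beta_1i, so
    dropout time may depend on the (observed and unobserved) trajectory
    through the shared random coefficients.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    ConfigurationError,
    DataError,
    DropoutSummary,
    LongitudinalDataset,
)

GROWTH_FORMS = ("linear", "sqrt_linear", "quadratic", "exponential")
TREATMENTS = ("ignorable", "fixed_pmm", "random_pmm", "joint_dropout", "shared_parameter")

#: growth forms with a third subject coefficient (curvature / rate)
THREE_COEF_FORMS = ("quadratic", "exponential")


def n_growth_coefs(form: str) -> int:
    if form not in GROWTH_FORMS:
        raise ConfigurationError(f"unknown growth form {form!r}")
    return 3 if form in THREE_COEF_FORMS else 2


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Weakly informative priors.

    Fixed effects, variance-model and dropout-time coefficients are
    N(0, fixed_effect_var).  The growth intercept gamma_00 may be truncated
    to the response scale (the illness-rating scale is bounded 1..7).
    Covariance matrices are inverse-Wishart with small degrees of freedom
    (dimension + 1 by default) and identity scale.  ``pattern_sd_half_t_df``
    is a configuration stub for a half-t prior on a single pattern-level
    standard deviation (useful with very few patterns); it is carried but
    not implemented by the sampler.
    """

    fixed_effect_var: float = 1000.0
    intercept_bounds: Optional[tuple] = (1.0, 7.0)
    iw_df: int = 3
    iw_scale: float = 1.0
    pattern_sd_half_t_df: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intercept_bounds is not None:
            lo, hi = self.intercept_bounds
            if not lo < hi:
                raise ConfigurationError("intercept_bounds must satisfy lower < upper")
        if self.iw_df <= 1:  # dim - 1 with dim = 2
            raise ConfigurationError("inverse-Wishart df must exceed dimension - 1")


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A fully described candidate model: growth form, level-2 regressions,
    variance models, missingness treatment and priors."""

    treatment: str
    form: str
    covariates: tuple = ("drug",)
    extra_level2_terms: tuple = ()
    variance_covariates: tuple = ("drug",)
    dropout_group: Optional[str] = "drug"
    pattern_set: Optional[pd.Series] = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    random_effects: bool = True
    fixed_tau: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        if self.form not in GROWTH_FORMS:
            raise ConfigurationError(f"unknown growth form {self.form!r}")
        self.covariates = tuple(self.covariates)
        self.extra_level2_terms = tuple(self.extra_level2_terms)
        self.variance_covariates = tuple(self.variance_covariates)
        if self.treatment == "random_pmm":
            if self.pattern_set is None:
                raise ConfigurationError("random_pmm requires a pattern_set")
            clusters = pd.Series(self.pattern_set).dropna().unique()
            if len(clusters) < 2:
                raise ConfigurationError(
                    "random_pmm requires at least 2 clusters among incomplete subjects"
                )

    # -- structure --------------------------------------------------------

    @property
    def level2_terms(self) -> tuple:
        return ("intercept",) + self.covariates + self.extra_level2_terms

    @property
    def curvature_terms(self) -> tuple:
        if n_growth_coefs(self.form) == 3:
            return ("intercept",) + self.covariates
        return ()

    @property
    def variance_terms(self) -> tuple:
        return ("intercept",) + self.variance_covariates

    @property
    def has_dropout_model(self) -> bool:
        return self.treatment in ("joint_dropout", "shared_parameter")

    @property
    def n_alpha(self) -> int:
        if not self.has_dropout_model:
            return 0
        return 4 if self.treatment == "shared_parameter" else 2

    def parameter_names(self) -> list:
        """Names of every sampled scalar quantity (covariance matrices are
        reported entry-wise)."""
        names = [f"gamma_0{m}" for m in range(len(self.level2_terms))]
        names += [f"gamma_1{m}" for m in range(len(self.level2_terms))]
        names += [f"gamma_2{m}" for m in range(len(self.curvature_terms))]
        if self.fixed_tau is None:
            names += [f"tau_{m}" for m in range(len(self.variance_terms))]
        if self.has_dropout_model:
            names += [f"alpha_{m}" for m in range(self.n_alpha)]
            names += [f"kappa_{m}" for m in range(len(self.variance_terms))]
        if self.random_effects:
            names += ["phi_u0", "phi_u1u0", "phi_u1"]
        if self.treatment == "random_pmm":
            names += ["phi_v0", "phi_v1v0", "phi_v1"]
        return names

    @property
    def q(self) -> int:
        """Parameter count as conventionally reported: scalar level-2 fixed
        effects plus variance-model coefficients, with each covariance matrix
        and each additional coefficient block (curvature regression,
        dropout-time regression) counted once."""
        q = 2 * len(self.level2_terms)
        if self.fixed_tau is None:
            q += len(self.variance_terms)
        if self.random_effects:
            q += 1  # Phi_u
        if self.curvature_terms:
            q += 1  # beta_2 regression block
        if self.has_dropout_model:
            q += 1  # alpha block
            q += len(self.variance_terms)  # kappa coefficients
        if self.treatment == "random_pmm":
            q += 1  # Phi_v
        return q


def build_model(
    treatment: str,
    form: str,
    covariates: Sequence[str] = ("drug",),
    *,
    pattern_set: Optional[pd.Series] = None,
    priors: Optional[PriorSpec] = None,
    variance_covariates: Optional[Sequence[str]] = None,
    extra_level2_terms: Optional[Sequence[str]] = None,
    dropout_group: Optional[str] = None,
    random_effects: bool = True,
    fixed_tau: Optional[tuple] = None,
) -> ModelSpec:
    """Validate and assemble a :class:`ModelSpec`.

    For ``fixed_pmm`` the default level-2 extension is the dropout indicator
    plus its interaction with each covariate (``drop``, ``cov*drop``); pass
    ``extra_level2_terms`` to override (e.g. a dropout-timing covariate).
    """
    covariates = tuple(covariates)
    if extra_level2_terms is None:
        if treatment == "fixed_pmm":
            extra_level2_terms = ("drop",) + tuple(f"{c}*drop" for c in covariates)
        else:
            extra_level2_terms = ()
    if variance_covariates is None:
        variance_covariates = covariates
    if dropout_group is None:
        dropout_group = covariates[0] if covariates else None
    return ModelSpec(
        treatment=treatment,
        form=form,
        covariates=covariates,
        extra_level2_terms=tuple(extra_level2_terms),
        variance_covariates=tuple(variance_covariates),
        dropout_group=dropout_group,
        pattern_set=pattern_set,
        priors=priors or PriorSpec(),
        random_effects=random_effects,
        fixed_tau=fixed_tau,
    )


# ---------------------------------------------------------------------------
# evaluation primitives
# ---------------------------------------------------------------------------

def growth_mean(form: str, beta: Sequence[float], week) -> np.ndarray | float:
    """Deterministic mean trajectory value at ``week`` for coefficient
    vector ``beta``.

    linear: b0 + b1 w;  sqrt_linear: b0 + b1 sqrt(w);
    quadratic: b0 + b1 w + b2 w^2;
    exponential: b1 - (b1 - b0) exp(-b2 w) with rate b2 > 0 (b0 is the
    baseline level, b1 the asymptote).
    """
    beta = np.asarray(beta, dtype=float)
    w = np.asarray(week, dtype=float)
    if (w < 0).any() if w.ndim else w < 0:
        raise DataError("week must be non-negative")
    if len(beta) != n_growth_coefs(form):
        raise ConfigurationError(
            f"{form} needs {n_growth_coefs(form)} coefficients, got {len(beta)}"
        )
    if form == "linear":
        out = beta[0] + beta[1] * w
    elif form == "sqrt_linear":
        out = beta[0] + beta[1] * np.sqrt(w)
    elif form == "quadratic":
        out = beta[0] + beta[1] * w + beta[2] * w ** 2
    else:
        if beta[2] <= 0:
            raise DataError("exponential rate beta2 must be strictly positive")
        out = beta[1] - (beta[1] - beta[0]) * np.exp(-beta[2] * w)
    return out if np.ndim(out) else float(out)


def mean_records(
    form: str,
    b0: np.ndarray,
    b1: np.ndarray,
    b2: Optional[np.ndarray],
    week: np.ndarray,
    tweek: np.ndarray,
) -> np.ndarray:
    """Record-level mean given per-record subject coefficients.  ``tweek``
    is the precomputed time transform (week, sqrt(week) or week again)."""
    if form in ("linear", "sqrt_linear"):
        return b0 + b1 * tweek
    if form == "quadratic":
        return b0 + b1 * week + b2 * week ** 2
    return b1 - (b1 - b0) * np.exp(-b2 * week)


def residual_variance(tau: Sequence[float], drug) -> np.ndarray | float:
    """Within-subject residual variance exp{tau_0 + tau_1 * group}."""
    tau = np.asarray(tau, dtype=float)
    x = np.asarray(drug, dtype=float)
    out = np.exp(tau[0] + (tau[1] * x if len(tau) > 1 else 0.0))
    return out if np.ndim(out) else float(out)


def pattern_average(gamma_complete, gamma_drop_delta, pi_drop: float):
    """Population-averaged coefficients of a fixed pattern-mixture model.

    With the dropout stratum's coefficients parameterized as offsets Delta
    from the completer stratum, the average over strata weighted by the
    dropout proportion pi is

        (1 - pi) gamma + pi (gamma + Delta) = gamma + pi * Delta.

    Applied per posterior draw this yields full posterior summaries (HPDIs)
    of the averaged effects.
    """
    if not 0.0 <= pi_drop <= 1.0:
        raise ConfigurationError("pi_drop must lie in [0, 1]")
    g = np.asarray(gamma_complete, dtype=float)
    d = np.asarray(gamma_drop_delta, dtype=float)
    out = g + pi_drop * d
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

class ModelMatrices:
    """Precomputed arrays binding a :class:`ModelSpec` to a dataset.

    Used by both the standalone log-likelihood and the MCMC engine so the
    two never disagree about the design.
    """

    def __init__(
        self,
        spec: ModelSpec,
        ds: LongitudinalDataset,
        dropout: Optional[DropoutSummary] = None,
    ):
        self.spec = spec
        self.subjects = ds.subjects
        self.n_subjects = ds.n_subjects
        pos = {s: i for i, s in enumerate(self.subjects)}

        rec = ds.records
        self.subj_idx = rec["subject"].map(pos).to_numpy(dtype=np.intp)
        self.week = rec["week"].to_numpy(dtype=float)
        self.y = rec["y"].to_numpy(dtype=float)
        self.n_records = len(rec)
        if self.n_records == 0:
            raise DataError("dataset has no records")
        if spec.form == "sqrt_linear":
            self.tweek = np.sqrt(self.week)
        else:
            self.tweek = self.week

        table = ds.covariates.copy()
        if dropout is not None:
            table = table.join(dropout.drop.rename("drop"), how="left") \
                if "drop" not in table.columns else table
        self._table = table

        self.X2 = self._design(spec.level2_terms)          # N x p2
        self.Xc = (
            self._design(spec.curvature_terms) if spec.curvature_terms else None
        )
        self.Xvar = self._design(spec.variance_terms)      # N x pv

        if spec.has_dropout_model:
            if dropout is None:
                raise ConfigurationError(
                    f"{spec.treatment} requires a DropoutSummary"
                )
            self.lnmw = dropout.ln_max_week.reindex(self.subjects).to_numpy(dtype=float)
            terms = ("intercept",) + ((spec.dropout_group,) if spec.dropout_group else ())
            self.Xdrop = self._design(terms)
        else:
            self.lnmw = None
            self.Xdrop = None

        if spec.treatment == "random_pmm":
            ps = pd.Series(spec.pattern_set).reindex(self.subjects)
            labels = sorted(ps.dropna().unique().tolist(), key=str)
            lab_pos = {c: i for i, c in enumerate(labels)}
            self.cluster_labels = labels
            self.n_clusters = len(labels)
            self.cluster_idx = ps.map(lab_pos).fillna(-1).to_numpy(dtype=np.intp)
        else:
            self.cluster_labels = []
            self.n_clusters = 0
            self.cluster_idx = None

    def _design(self, terms: Sequence[str]) -> np.ndarray:
        cols = []
        for t in terms:
            if t == "intercept":
                cols.append(np.ones(self.n_subjects))
            elif "*" in t:
                a, b = t.split("*")
                cols.append(self._col(a) * self._col(b))
            else:
                cols.append(self._col(t))
        return np.column_stack(cols)

    def _col(self, name: str) -> np.ndarray:
        if name not in self._table.columns:
            raise ConfigurationError(f"covariate column {name!r} not available")
        return self._table[name].to_numpy(dtype=float)

    # -- state evaluation -------------------------------------------------

    def subject_coefs(self, gamma01: np.ndarray, gamma2: Optional[np.ndarray],
                      u: np.ndarray, v: Optional[np.ndarray]):
        """Per-subject (b0, b1, b2) given fixed effects and random effects.

        ``gamma01`` is (p2, 2); for the exponential form the curvature
        linear predictor is exponentiated so the rate is always positive.
        """
        b01 = self.X2 @ gamma01
        if self.spec.random_effects and u is not None:
            b01 = b01 + u
        if v is not None and self.cluster_idx is not None:
            incomplete = self.cluster_idx >= 0
            b01 = b01.copy()
            b01[incomplete] += v[self.cluster_idx[incomplete]]
        b2 = None
        if self.Xc is not None:
            eta2 = self.Xc @ gamma2
            b2 = np.exp(eta2) if self.spec.form == "exponential" else eta2
        return b01[:, 0], b01[:, 1], b2

    def record_means(self, b0, b1, b2) -> np.ndarray:
        s = self.subj_idx
        return mean_records(
            self.spec.form,
            b0[s],
            b1[s],
            None if b2 is None else b2[s],
            self.week,
            self.tweek,
        )

    def record_logvar(self, tau: np.ndarray) -> np.ndarray:
        return (self.Xvar @ tau)[self.subj_idx]

    def response_loglik_records(self, mu, logvar) -> np.ndarray:
        return -0.5 * (np.log(2 * np.pi) + logvar + (self.y - mu) ** 2 * np.exp(-logvar))

    def dropout_loglik_subjects(self, alpha, kappa, b0, b1) -> np.ndarray:
        m = self.Xdrop @ alpha[: self.Xdrop.shape[1]]
        if self.spec.treatment == "shared_parameter":
            m = m + alpha[-2] * b0 + alpha[-1] * b1
        logv = self.Xvar @ kappa
        return -0.5 * (np.log(2 * np.pi) + logv + (self.lnmw - m) ** 2 * np.exp(-logv))


def _gamma_matrix(spec: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
    p2 = len(spec.level2_terms)
    return np.array(
        [[float(params[f"gamma_{j}{m}"]) for j in (0, 1)] for m in range(p2)]
    )


def log_likelihood(
    spec: ModelSpec,
    params: Mapping,
    ds: LongitudinalDataset,
    dropout: Optional[DropoutSummary] = None,
) -> float:
    """Conditional log-likelihood of the data given the full parameter state.

    Sums normal log-densities of the observed responses with mean
    ``growth_mean`` and variance ``residual_variance``, plus — for the joint
    and shared-parameter treatments — the normal log-density of
    ln(MaxWeek).  Conditional on the random effects ``u`` (and ``v``): their
    distributions are priors handled by the sampler, not part of this value.

    ``params`` maps parameter names (see ``spec.parameter_names()``) to
    values, plus ``u`` (n_subjects x 2) and, for random_pmm, ``v``
    (n_clusters x 2, ordered by ``ModelMatrices.cluster_labels``).
    """
    mm = ModelMatrices(spec, ds, dropout)
    for name in spec.parameter_names():
        if name.startswith("phi"):
            continue
        if name not in params:
            raise ConfigurationError(f"missing parameter {name!r}")
        if not math.isfinite(float(params[name])):
            raise DataError(f"non-finite value for parameter {name!r}")
    gamma01 = _gamma_matrix(spec, params)
    gamma2 = None
    if spec.curvature_terms:
        gamma2 = np.array(
            [float(params[f"gamma_2{m}"]) for m in range(len(spec.curvature_terms))]
        )
    if spec.fixed_tau is not None:
        tau = np.asarray(spec.fixed_tau, dtype=float)
    else:
        tau = np.array(
            [float(params[f"tau_{m}"]) for m in range(len(spec.variance_terms))]
        )
    u = np.asarray(params.get("u", np.zeros((mm.n_subjects, 2))), dtype=float)
    v = None
    if spec.treatment == "random_pmm":
        v = np.asarray(params.get("v", np.zeros((mm.n_clusters, 2))), dtype=float)
    b0, b1, b2 = mm.subject_coefs(gamma01, gamma2, u, v)
    mu = mm.record_means(b0, b1, b2)
    ll = float(mm.response_loglik_records(mu, mm.record_logvar(tau)).sum())
    if spec.has_dropout_model:
        alpha = np.array([float(params[f"alpha_{m}"]) for m in range(spec.n_alpha)])
        kappa = np.array(
            [float(params[f"kappa_{m}"]) for m in range(len(spec.variance_terms))]
        )
        ll += float(mm.dropout_loglik_subjects(alpha, kappa, b0, b1).sum())
    return ll


# ---------------------------------------------------------------------------
# flat TOML-dialect (de)serialization
# ---------------------------------------------------------------------------

def spec_to_toml(spec: ModelSpec, pattern_rule: str = "") -> str:
    """Serialize a ModelSpec to a flat key-value TOML document.  The pattern
    set itself is data-dependent; only its derivation rule tag is stored."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (tuple, list)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(type(v))

    buf = io.StringIO()
    pairs = [
        ("treatment", spec.treatment),
        ("form", spec.form),
        ("covariates", list(spec.covariates)),
        ("extra_level2_terms", list(spec.extra_level2_terms)),
        ("variance_covariates", list(spec.variance_covariates)),
        ("dropout_group", spec.dropout_group or ""),
        ("pattern_rule", pattern_rule),
        ("random_effects", spec.random_effects),
        ("prior_fixed_effect_var", spec.priors.fixed_effect_var),
        ("prior_iw_df", spec.priors.iw_df),
        ("prior_iw_scale", spec.priors.iw_scale),
    ]
    if spec.priors.intercept_bounds is not None:
        pairs.append(("prior_intercept_bounds", list(spec.priors.intercept_bounds)))
    for k, v in pairs:
        buf.write(f"{k} = {fmt(v)}\n")
    return buf.getvalue()


def spec_from_toml(text: str, pattern_set: Optional[pd.Series] = None) -> ModelSpec:
    import tomllib

    d = tomllib.loads(text)
    priors = PriorSpec(
        fixed_effect_var=d.get("prior_fixed_effect_var", 1000.0),
        intercept_bounds=tuple(d["prior_intercept_bounds"])
        if "prior_intercept_bounds" in d
        else None,
        iw_df=d.get("prior_iw_df", 3),
        iw_scale=d.get("prior_iw_scale", 1.0),
    )
    return build_model(
        d["treatment"],
        d["form"],
        tuple(d.get("covariates", ())),
        pattern_set=pattern_set,
        priors=priors,
        variance_covariates=tuple(d.get("variance_covariates", ())),
        extra_level2_terms=tuple(d.get("extra_level2_terms", ())),
        dropout_group=d.get("dropout_group") or None,
        random_effects=d.get("random_effects", True),
    )
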