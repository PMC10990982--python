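"""Self-tuned random-walk Metropolis-within-Gibbs sampler and diagnostics.

Sampling scheme, per sweep:

* every scalar fixed effect (level-2 gammas, curvature coefficients,
  variance-model taus, dropout-time alphas and kappas) is updated by an
  adaptive random-walk Metropolis step whose proposal scale is tuned toward
  a 0.44 acceptance rate during burn-in and frozen afterwards (freezing
  preserves detailed balance of the post-burn-in chain);
* subject random effects u_i (2-vectors) are updated by per-subject
  Metropolis steps, vectorized across subjects, tuned toward 0.234;
* pattern random effects v_k likewise, per cluster;
* the random-effect covariance matrices Phi_u (and Phi_v) are drawn from
  their exact inverse-Wishart full conditionals given the current random
  effects (conjugate Gibbs), which mixes better than Metropolis on
  covariance entries while targeting the same posterior.

Posterior summaries follow the reporting conventions of Bayesian growth
modelling: mean/median, a kernel-density posterior mode (Silverman
bandwidth), the 95% highest posterior density interval (shortest contiguous
interval), a batch-means effective sample size, the published minimum-ESS
bound, and the conditional-likelihood DIC (random effects in focus).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln as _gammaln
from scipy.stats import chi2, gaussian_kde, invwishart

from .data import ConfigurationError, DataError, DropoutSummary, LongitudinalDataset
from .models import ModelMatrices, ModelSpec, log_likelihood

logger = logging.getLogger("patternmix")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Chain settings.

    Defaults are desk-scale (200k iterations, 10k burn-in, thin 20); the
    published full-scale settings (10M/50k/1000) are reachable by config for
    long reference runs.
    """

    n_iterations: int = 200_000
    n_burnin: int = 10_000
    thin: int = 20
    seed: int = 0
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.234
    adapt_rate: float = 1.5
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iterations:
            raise ConfigurationError("n_burnin must be smaller than n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws plus bookkeeping needed for DIC."""

    params: pd.DataFrame
    deviance: np.ndarray
    u_mean: Optional[np.ndarray]
    v_mean: Optional[np.ndarray]
    accept_rates: dict
    spec: ModelSpec
    config: McmcConfig
    subjects: pd.Index
    cluster_labels: list
    chain_id: np.ndarray

    @property
    def n_draws(self) -> int:
        return len(self.params)


@dataclass
class PosteriorSummary:
    table: pd.DataFrame
    prob: float


@dataclass
class DiagnosticsReport:
    p: int
    alpha: float
    eps: float
    min_ess_bound: float
    observed_min_ess: float
    dic: float
    per_parameter: pd.DataFrame

    @property
    def all_pass(self) -> bool:
        return bool(self.per_parameter["ess_pass"].all())


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Sampler:
    def __init__(self, spec: ModelSpec, ds: LongitudinalDataset,
                 dropout: Optional[DropoutSummary], cfg: McmcConfig,
                 rng: np.random.Generator):
        self.spec = spec
        self.cfg = cfg
        self.rng = rng
        self.mm = ModelMatrices(spec, ds, dropout)
        mm = self.mm
        self.prior_var = spec.priors.fixed_effect_var
        self.bounds = spec.priors.intercept_bounds
        self.iw_df = spec.priors.iw_df
        self.iw_scale = spec.priors.iw_scale * np.eye(2)

        self.p2 = len(spec.level2_terms)
        self.pc = len(spec.curvature_terms)
        self.pv = len(spec.variance_terms)
        self.n_alpha = spec.n_alpha

        if mm.cluster_idx is not None:
            ci = mm.cluster_idx[mm.subj_idx]
            self.rec_cluster = ci  # -1 for complete subjects' records
        else:
            self.rec_cluster = None

        self._init_state()
        # adaptation state
        n_scalars = 2 * self.p2 + self.pc + (0 if spec.fixed_tau is not None else self.pv) \
            + self.n_alpha + (self.pv if spec.has_dropout_model else 0)
        self.ls_scalar = np.full(n_scalars, math.log(0.1))
        self.ls_trans = np.full(2 * self.p2, math.log(0.1))
        self.ls_u = np.full(mm.n_subjects, math.log(0.5))
        self.ls_v = np.full(max(mm.n_clusters, 1), math.log(0.2))
        self.adapt_count = 0
        self.adapting = True
        self.acc = {k: [0, 0] for k in ("gamma", "tau", "alpha_kappa", "u", "v")}

    # -- initialization ---------------------------------------------------

    def _init_state(self) -> None:
        mm, spec = self.mm, self.spec
        s = mm.subj_idx
        if spec.form == "exponential":
            g0 = np.exp(-mm.week)
            g1 = 1.0 - g0
        else:
            g0 = np.ones(mm.n_records)
            g1 = mm.tweek
        cols = [mm.X2[s, m] * g0 for m in range(self.p2)]
        cols += [mm.X2[s, m] * g1 for m in range(self.p2)]
        if spec.form == "quadratic":
            cols += [mm.Xc[s, m] * mm.week ** 2 for m in range(self.pc)]
        D = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(D, mm.y, rcond=None)
        self.gamma01 = np.column_stack([coef[: self.p2], coef[self.p2: 2 * self.p2]])
        if self.bounds is not None:
            lo, hi = self.bounds
            self.gamma01[0, 0] = float(np.clip(self.gamma01[0, 0], lo + 1e-3, hi - 1e-3))
        if spec.form == "quadratic":
            self.gamma2 = coef[2 * self.p2:]
        elif spec.form == "exponential":
            self.gamma2 = np.zeros(self.pc)  # rate exp(0) = 1
        else:
            self.gamma2 = None
        resid = mm.y - D @ coef
        rvar = max(float(np.var(resid)), 1e-3)
        if spec.fixed_tau is not None:
            self.tau = np.asarray(spec.fixed_tau, dtype=float)
        else:
            self.tau = np.zeros(self.pv)
            self.tau[0] = math.log(rvar)
        self.u = np.zeros((mm.n_subjects, 2))
        self.Phi_u = 0.1 * np.eye(2)
        self.v = np.zeros((max(mm.n_clusters, 1), 2)) if spec.treatment == "random_pmm" else None
        self.Phi_v = 0.01 * np.eye(2) if spec.treatment == "random_pmm" else None
        if spec.has_dropout_model:
            a, *_ = np.linalg.lstsq(mm.Xdrop, mm.lnmw, rcond=None)
            self.alpha = np.zeros(self.n_alpha)
            self.alpha[: len(a)] = a
            dres = mm.lnmw - mm.Xdrop @ a
            self.kappa = np.zeros(self.pv)
            self.kappa[0] = math.log(max(float(np.var(dres)), 1e-3))
        else:
            self.alpha = None
            self.kappa = None
        self._refresh_caches()
        if not (math.isfinite(self.ll_y) and math.isfinite(self.ll_d)):
            raise DataError("non-finite initial log-likelihood; check the data")

    # -- cached quantities ------------------------------------------------

    def _coefs(self):
        return self.mm.subject_coefs(self.gamma01, self.gamma2, self.u, self.v)

    def _refresh_caches(self) -> None:
        mm = self.mm
        self.b0, self.b1, self.b2 = self._coefs()
        self.mu = mm.record_means(self.b0, self.b1, self.b2)
        self.logvar = mm.record_logvar(self.tau)
        self.ll_rec = mm.response_loglik_records(self.mu, self.logvar)
        self.ll_y = float(self.ll_rec.sum())
        if self.spec.has_dropout_model:
            self.ll_d_sub = mm.dropout_loglik_subjects(
                self.alpha, self.kappa, self.b0, self.b1
            )
            self.ll_d = float(self.ll_d_sub.sum())
        else:
            self.ll_d_sub = None
            self.ll_d = 0.0

    # -- adaptation -------------------------------------------------------

    def _adapt(self, ls: np.ndarray, idx, acc_prob, target: float) -> None:
        if not self.adapting:
            return
        step = self.cfg.adapt_rate / (1.0 + self.adapt_count) ** 0.6
        ls[idx] = np.clip(ls[idx] + step * (acc_prob - target), -12.0, 6.0)

    def _tally(self, key: str, accepted: float, total: float) -> None:
        if not self.adapting:
            self.acc[key][0] += accepted
            self.acc[key][1] += total

    # -- scalar Metropolis blocks -----------------------------------------

    def _scalar_update(self, slot: int, get, set_, logprior, affects_dropout: bool,
                       tally_key: str, bounds=None) -> None:
        old = get()
        scale = math.exp(self.ls_scalar[slot])
        prop = old + scale * self.rng.standard_normal()
        if bounds is not None and not (bounds[0] <= prop <= bounds[1]):
            self._adapt(self.ls_scalar, slot, 0.0, self.cfg.target_accept_scalar)
            self._tally(tally_key, 0.0, 1.0)
            return
        set_(prop)
        mm = self.mm
        b0, b1, b2 = self._coefs()
        mu = mm.record_means(b0, b1, b2)
        logvar = mm.record_logvar(self.tau)
        ll_rec = mm.response_loglik_records(mu, logvar)
        ll_y = float(ll_rec.sum())
        if self.spec.has_dropout_model:
            ll_d_sub = mm.dropout_loglik_subjects(self.alpha, self.kappa, b0, b1)
            ll_d = float(ll_d_sub.sum())
        else:
            ll_d_sub, ll_d = None, 0.0
        delta = (ll_y + ll_d) - (self.ll_y + self.ll_d) + logprior(prop) - logprior(old)
        if not math.isfinite(delta):
            acc_prob = 0.0
        else:
            acc_prob = 1.0 if delta >= 0 else math.exp(delta)
        if math.isfinite(delta) and math.log(self.rng.uniform()) < delta:
            self.b0, self.b1, self.b2 = b0, b1, b2
            self.mu, self.logvar, self.ll_rec, self.ll_y = mu, logvar, ll_rec, ll_y
            self.ll_d_sub, self.ll_d = ll_d_sub, ll_d
            accepted = 1.0
        else:
            set_(old)
            accepted = 0.0
        self._adapt(self.ls_scalar, slot, acc_prob, self.cfg.target_accept_scalar)
        self._tally(tally_key, accepted, 1.0)

    def _normal_logprior(self, x: float) -> float:
        return -0.5 * x * x / self.prior_var

    def _update_fixed_effects(self) -> None:
        slot = 0
        for j in (0, 1):
            for m in range(self.p2):
                bounds = self.bounds if (j == 0 and m == 0) else None

                def get(j=j, m=m):
                    return self.gamma01[m, j]

                def set_(val, j=j, m=m):
                    self.gamma01[m, j] = val

                self._scalar_update(slot, get, set_, self._normal_logprior,
                                    False, "gamma", bounds)
                slot += 1
        for m in range(self.pc):
            def get(m=m):
                return self.gamma2[m]

            def set_(val, m=m):
                self.gamma2[m] = val

            self._scalar_update(slot, get, set_, self._normal_logprior, False, "gamma")
            slot += 1
        if self.spec.fixed_tau is None:
            for m in range(self.pv):
                def get(m=m):
                    return self.tau[m]

                def set_(val, m=m):
                    self.tau[m] = val

                self._scalar_update(slot, get, set_, self._normal_logprior, False, "tau")
                slot += 1
        if self.spec.has_dropout_model:
            for m in range(self.n_alpha):
                def get(m=m):
                    return self.alpha[m]

                def set_(val, m=m):
                    self.alpha[m] = val

                self._scalar_update(slot, get, set_, self._normal_logprior,
                                    True, "alpha_kappa")
                slot += 1
            for m in range(self.pv):
                def get(m=m):
                    return self.kappa[m]

                def set_(val, m=m):
                    self.kappa[m] = val

                self._scalar_update(slot, get, set_, self._normal_logprior,
                                    True, "alpha_kappa")
                slot += 1

    # -- random effect blocks ---------------------------------------------

    def _update_u(self) -> None:
        mm, rng = self.mm, self.rng
        n = mm.n_subjects
        scales = np.exp(self.ls_u)
        u_prop = self.u + scales[:, None] * rng.standard_normal((n, 2))
        b0p = self.b0 + (u_prop[:, 0] - self.u[:, 0])
        b1p = self.b1 + (u_prop[:, 1] - self.u[:, 1])
        mu_p = mm.record_means(b0p, b1p, self.b2)
        ll_rec_p = mm.response_loglik_records(mu_p, self.logvar)
        d_rec = ll_rec_p - self.ll_rec
        delta = np.bincount(mm.subj_idx, weights=d_rec, minlength=n)
        Pinv = np.linalg.inv(self.Phi_u)
        def qf(x):
            return np.einsum("ni,ij,nj->n", x, Pinv, x)
        delta += -0.5 * (qf(u_prop) - qf(self.u))
        if self.spec.has_dropout_model:
            ll_d_p = mm.dropout_loglik_subjects(self.alpha, self.kappa, b0p, b1p)
            delta += ll_d_p - self.ll_d_sub
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        accept = np.log(rng.uniform(size=n)) < delta
        self.u[accept] = u_prop[accept]
        acc_prob = np.exp(np.minimum(delta, 0.0))
        self._adapt(self.ls_u, slice(None), acc_prob, self.cfg.target_accept_vector)
        self._tally("u", float(accept.sum()), float(n))
        self._refresh_caches()

    def _update_v(self) -> None:
        mm, rng = self.mm, self.rng
        K = mm.n_clusters
        scales = np.exp(self.ls_v)
        v_prop = self.v + scales[:, None] * rng.standard_normal((K, 2))
        dv = v_prop - self.v
        incomplete = mm.cluster_idx >= 0
        b0p = self.b0.copy()
        b1p = self.b1.copy()
        b0p[incomplete] += dv[mm.cluster_idx[incomplete], 0]
        b1p[incomplete] += dv[mm.cluster_idx[incomplete], 1]
        mu_p = mm.record_means(b0p, b1p, self.b2)
        d_rec = mm.response_loglik_records(mu_p, self.logvar) - self.ll_rec
        rc = self.rec_cluster
        delta = np.bincount(rc[rc >= 0], weights=d_rec[rc >= 0], minlength=K)
        Pinv = np.linalg.inv(self.Phi_v)
        def qf(x):
            return np.einsum("ki,ij,kj->k", x, Pinv, x)
        delta += -0.5 * (qf(v_prop) - qf(self.v))
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        accept = np.log(rng.uniform(size=K)) < delta
        self.v[accept] = v_prop[accept]
        acc_prob = np.exp(np.minimum(delta, 0.0))
        self._adapt(self.ls_v, slice(None), acc_prob, self.cfg.target_accept_vector)
        self._tally("v", float(accept.sum()), float(K))
        self._refresh_caches()

    def _update_translations(self) -> None:
        """Joint moves along the fixed-effect/random-effect ridge.

        Shifting a level-2 coefficient by delta while shifting every
        subject's random effect by -delta * (its design value) leaves all
        subject coefficients — hence the entire likelihood — invariant, so
        the acceptance ratio involves only the priors.  These moves let the
        fixed effects traverse their marginal posterior instead of the much
        narrower conditional-given-u slice, which is what limits mixing of
        scalar random-walk updates in hierarchical models.
        """
        mm, rng = self.mm, self.rng
        Pinv = np.linalg.inv(self.Phi_u)
        slot = 0
        for j in (0, 1):
            for m in range(self.p2):
                delta = math.exp(self.ls_trans[slot]) * rng.standard_normal()
                old_g = self.gamma01[m, j]
                new_g = old_g + delta
                if j == 0 and m == 0 and self.bounds is not None and not (
                    self.bounds[0] <= new_g <= self.bounds[1]
                ):
                    self._adapt(self.ls_trans, slot, 0.0,
                                self.cfg.target_accept_scalar)
                    slot += 1
                    continue
                shift = delta * mm.X2[:, m]
                u_col = self.u[:, j] - shift
                other = self.u[:, 1 - j]
                # change in the bivariate-normal log prior of u, column j only
                d_quad = (
                    Pinv[j, j] * (u_col ** 2 - self.u[:, j] ** 2)
                    + 2.0 * Pinv[j, 1 - j] * other * (u_col - self.u[:, j])
                ).sum()
                dlp = -0.5 * d_quad + self._normal_logprior(new_g) \
                    - self._normal_logprior(old_g)
                acc_prob = 1.0 if dlp >= 0 else (
                    math.exp(dlp) if math.isfinite(dlp) else 0.0
                )
                if math.isfinite(dlp) and math.log(rng.uniform()) < dlp:
                    self.gamma01[m, j] = new_g
                    self.u[:, j] = u_col
                    # subject coefficients and likelihood caches are invariant
                self._adapt(self.ls_trans, slot, acc_prob,
                            self.cfg.target_accept_scalar)
                slot += 1

    def _update_phi(self, x: np.ndarray) -> np.ndarray:
        n = len(x)
        scale = self.iw_scale + x.T @ x
        df = self.iw_df + n
        draw = invwishart.rvs(df=df, scale=scale, random_state=self.rng)
        return np.asarray(draw).reshape(2, 2)

    # -- sweep ------------------------------------------------------------

    def sweep(self) -> None:
        self._update_fixed_effects()
        if self.spec.random_effects:
            self._update_u()
            self._update_translations()
            self.Phi_u = self._update_phi(self.u)
        if self.spec.treatment == "random_pmm":
            self._update_v()
            self.Phi_v = self._update_phi(self.v)
        self.adapt_count += 1

    # -- output -----------------------------------------------------------

    def current_row(self) -> list:
        row = list(self.gamma01[:, 0]) + list(self.gamma01[:, 1])
        if self.gamma2 is not None:
            row += list(self.gamma2)
        if self.spec.fixed_tau is None:
            row += list(self.tau)
        if self.spec.has_dropout_model:
            row += list(self.alpha) + list(self.kappa)
        if self.spec.random_effects:
            row += [self.Phi_u[0, 0], self.Phi_u[1, 0], self.Phi_u[1, 1]]
        if self.spec.treatment == "random_pmm":
            row += [self.Phi_v[0, 0], self.Phi_v[1, 0], self.Phi_v[1, 1]]
        return row

    @property
    def deviance(self) -> float:
        return -2.0 * (self.ll_y + self.ll_d)


def sample_posterior(
    spec: ModelSpec,
    ds: LongitudinalDataset,
    dropout: Optional[DropoutSummary],
    cfg: McmcConfig,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler for ``spec`` on ``ds``.

    Returns thinned post-burn-in draws; reproducible bit-for-bit given the
    same (spec, data, config, seed).
    """
    if spec.priors.pattern_sd_half_t_df is not None:
        raise NotImplementedError(
            "half-t prior on the pattern-level standard deviation is a "
            "configuration stub and is not implemented by this sampler"
        )
    names = spec.parameter_names()
    all_rows, all_dev, all_chain = [], [], []
    u_sum = None
    v_sum = None
    subjects = None
    cluster_labels: list = []
    accept_rates: dict = {}
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([int(cfg.seed), chain])
        smp = _Sampler(spec, ds, dropout, cfg, rng)
        subjects = smp.mm.subjects
        cluster_labels = smp.mm.cluster_labels
        if u_sum is None:
            u_sum = np.zeros_like(smp.u)
            if smp.v is not None:
                v_sum = np.zeros_like(smp.v)
        for it in range(cfg.n_iterations):
            if it == cfg.n_burnin:
                smp.adapting = False
            smp.sweep()
            if it >= cfg.n_burnin and (it - cfg.n_burnin + 1) % cfg.thin == 0:
                all_rows.append(smp.current_row())
                all_dev.append(smp.deviance)
                all_chain.append(chain)
                u_sum += smp.u
                if v_sum is not None:
                    v_sum += smp.v
        for k, (a, t) in smp.acc.items():
            if t > 0:
                accept_rates[f"chain{chain}_{k}"] = a / t
    params = pd.DataFrame(all_rows, columns=names)
    n = len(params)
    if not np.isfinite(params.to_numpy()).all():
        raise RuntimeError("non-finite posterior draws; sampler diverged")
    return PosteriorDraws(
        params=params,
        deviance=np.asarray(all_dev),
        u_mean=u_sum / n if (u_sum is not None and spec.random_effects) else None,
        v_mean=v_sum / n if v_sum is not None else None,
        accept_rates=accept_rates,
        spec=spec,
        config=cfg,
        subjects=subjects,
        cluster_labels=cluster_labels,
        chain_id=np.asarray(all_chain),
    )


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def hpdi(samples, prob: float = 0.95) -> tuple:
    """Highest posterior density interval: the shortest contiguous interval
    containing ``ceil(prob * n)`` of the sorted draws (leftmost on ties)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise DataError(f"hpdi needs at least 100 draws, got {n}")
    if not 0.0 < prob < 1.0:
        raise ConfigurationError("prob must lie strictly between 0 and 1")
    m = int(math.ceil(prob * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(chain) -> float:
    """Batch-means ESS: n * (marginal variance) / (batch-means long-run
    variance estimate), batch size floor(sqrt(n))."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise DataError(f"effective_sample_size needs at least 100 draws, got {n}")
    s2 = float(np.var(x, ddof=1))
    if s2 == 0.0:
        logger.warning("constant chain; reporting ESS = n")
        return float(n)
    b = int(math.floor(math.sqrt(n)))
    a = n // b
    means = x[: a * b].reshape(a, b).mean(axis=1)
    sigma2 = b * float(np.var(means, ddof=1))
    if sigma2 == 0.0:
        return float(n)
    return n * s2 / sigma2


def min_ess_bound(p: int, alpha: float = 0.05, eps: float = 0.05) -> float:
    """Minimum effective sample size needed to estimate a p-dimensional
    posterior mean to relative precision eps at confidence 1 - alpha:

        minESS = 2^(2/p) * pi / (p * Gamma(p/2))^(2/p) * chi2(1-alpha, p) / eps^2
    """
    if p < 1:
        raise ConfigurationError("p must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if eps <= 0.0:
        raise ConfigurationError("eps must be positive")
    log_lead = (2.0 / p) * math.log(2.0) + math.log(math.pi) \
        - (2.0 / p) * (math.log(p) + float(_gammaln(p / 2.0)))
    return math.exp(log_lead) * float(chi2.ppf(1.0 - alpha, p)) / eps ** 2


def _kde_mode(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def summarize(draws, prob: float = 0.95) -> PosteriorSummary:
    """Per-parameter posterior mean, median, KDE mode, HPDI and ESS."""
    params = draws.params if isinstance(draws, PosteriorDraws) else pd.DataFrame(draws)
    if params.empty:
        raise DataError("no draws to summarize")
    rows = {}
    for name in params.columns:
        x = params[name].to_numpy(dtype=float)
        lo, hi = hpdi(x, prob)
        rows[name] = {
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "mode": _kde_mode(x),
            "hpdi_low": lo,
            "hpdi_high": hi,
            "ess": effective_sample_size(x),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(params.columns)
    return PosteriorSummary(table=table, prob=prob)


def dic_components(
    draws: PosteriorDraws,
    spec: ModelSpec,
    ds: LongitudinalDataset,
    dropout: Optional[DropoutSummary] = None,
) -> tuple:
    """(DIC, mean deviance, p_D) under the conditional likelihood (random
    effects in focus): p_D = Dbar - D(posterior means of all quantities in
    the likelihood, random effects included)."""
    dbar = float(draws.deviance.mean())
    point = {k: float(draws.params[k].mean()) for k in draws.params.columns}
    point["u"] = draws.u_mean if draws.u_mean is not None else np.zeros((ds.n_subjects, 2))
    if draws.v_mean is not None:
        point["v"] = draws.v_mean
    dhat = -2.0 * log_likelihood(spec, point, ds, dropout)
    p_d = dbar - dhat
    return dbar + p_d, dbar, p_d


def dic(
    draws: PosteriorDraws,
    spec: ModelSpec,
    ds: LongitudinalDataset,
    dropout: Optional[DropoutSummary] = None,
) -> float:
    return dic_components(draws, spec, ds, dropout)[0]


def diagnostics(
    draws: PosteriorDraws,
    spec: ModelSpec,
    ds: LongitudinalDataset,
    dropout: Optional[DropoutSummary] = None,
    alpha: float = 0.05,
    eps: float = 0.05,
) -> DiagnosticsReport:
    """Min-ESS bound at p = spec.q, observed ESS per parameter, DIC."""
    bound = min_ess_bound(spec.q, alpha, eps)
    ess = {
        name: effective_sample_size(draws.params[name].to_numpy())
        for name in draws.params.columns
    }
    per = pd.DataFrame({"ess": pd.Series(ess)})
    per["ess_pass"] = per["ess"] >= bound
    return DiagnosticsReport(
        p=spec.q,
        alpha=alpha,
        eps=eps,
        min_ess_bound=bound,
        observed_min_ess=float(per["ess"].min()),
        dic=dic(draws, spec, ds, dropout),
        per_parameter=per,
    )
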