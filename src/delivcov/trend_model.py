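"""Bayesian hierarchical logit model for coverage trends and 2030 projection.

The observation model for one survey point ``s`` from country ``i`` in year
``t`` is binomial on the effective sample size::

    successes_s ~ Binomial(n_effective_s, p_it)
    logit(p_it) = alpha_i + beta_i * (t - 2000) / 10
                  + gamma_sdi * SDI_it + gamma_hrh * HRH_it

with country intercepts and slopes partially pooled::

    alpha_i ~ Normal(mu_alpha, sigma_alpha^2)
    beta_i  ~ Normal(mu_beta,  sigma_beta^2)

Time is centred at 2000 and scaled per decade, so ``beta_i`` is a
country's change in the log-odds of coverage per ten years.  SDI and HRH
enter z-scored against the fitting set; the stored back-transform keeps the
reported coefficients interpretable on natural scales.

Hyper-means and covariate effects carry wide Normal priors; the hyper
standard deviations carry a half-Cauchy prior by default, with uniform and
half-normal alternatives used by the prior-sensitivity protocol.  Posterior
sampling is an adaptive Metropolis-within-Gibbs scheme: conjugate Gibbs
updates for the hyper-means and random-walk Metropolis updates (with
proposal scales adapted during burn-in and frozen thereafter) for
everything else.  All chains advance in lock-step through one seeded
generator, so draws are bit-reproducible given (seed, config, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .registry_io import CovariateRow, SurveyPoint

__all__ = [
    "McmcConfig",
    "TrendParameters",
    "PosteriorDraws",
    "SensitivityResult",
    "logit_transform",
    "inverse_logit",
    "log_posterior",
    "fit",
    "project",
    "sensitivity_refit",
    "median_absolute_difference",
    "filter_points",
]

_PRIOR_FAMILIES = ("half_cauchy", "uniform", "half_normal")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler and prior configuration.

    Defaults follow the production run: 10,000 iterations, three chains,
    thinning 10, burn-in 500.
    """

    n_iter: int = 10_000
    n_chains: int = 3
    thin: int = 10
    burn_in: int = 500
    seed: int = 0
    prior_scale_fixed: float = 100.0
    prior_family_sd: str = "half_cauchy"
    prior_scale_sd: float = 2.5
    use_covariates: bool = True
    region_hierarchy: bool = False

    def validate(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.prior_scale_fixed <= 0 or self.prior_scale_sd <= 0:
            raise ValueError("prior scales must be positive")
        if self.prior_family_sd not in _PRIOR_FAMILIES:
            raise ValueError(f"prior_family_sd must be one of {_PRIOR_FAMILIES}")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def from_yaml(cls, path) -> "McmcConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=True)


@dataclass
class TrendParameters:
    """One point in parameter space, aligned to an ordered country list."""

    countries: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    mu_alpha: float
    mu_beta: float
    sigma_alpha: float
    sigma_beta: float
    gamma_sdi: float = 0.0
    gamma_hrh: float = 0.0

    def validate(self) -> None:
        k = len(self.countries)
        if len(self.alpha) != k or len(self.beta) != k:
            raise ValueError("alpha/beta must have one entry per country")
        if not (self.sigma_alpha > 0 and self.sigma_beta > 0):
            raise ValueError("hyper-SDs must be positive")


def logit_transform(p):
    """log(p / (1 - p)); rejects the boundary values 0 and 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit requires 0 < p < 1; clamp boundary coverages first")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return float(out) if out.ndim == 0 else out


def _clamp_coverage(y: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    lo = 0.5 / n_eff
    return np.clip(y, lo, 1.0 - lo)


def filter_points(
    points: Iterable[SurveyPoint], outcome: str, stratum: str = "national"
) -> list[SurveyPoint]:
    """Select the single outcome/stratum slice the trend model fits."""
    return [p for p in points if p.outcome == outcome and p.stratum == stratum]


# ---------------------------------------------------------------------------
# data assembly


class _FitData:
    """Design arrays for one outcome/stratum slice."""

    def __init__(
        self,
        points: Sequence[SurveyPoint],
        covariates: Sequence[CovariateRow] | None,
        use_covariates: bool,
        countries: Sequence[str] | None = None,
    ):
        outs = {p.outcome for p in points}
        strata = {p.stratum for p in points}
        if len(outs) > 1 or len(strata) > 1:
            raise ValueError(
                "fit() expects a single outcome and stratum; use filter_points()"
            )
        self.outcome = next(iter(outs)) if outs else "INSD"
        self.stratum = next(iter(strata)) if strata else "national"
        data_countries = sorted({p.country_iso for p in points})
        self.countries = sorted(set(data_countries) | set(countries or ()))
        self.regions = {p.country_iso: p.region for p in points}
        idx = {c: k for k, c in enumerate(self.countries)}

        self.y = np.array([p.coverage for p in points])
        self.n_eff = np.array([p.n_effective for p in points])
        self.t = np.array([(p.survey_year - 2000) / 10.0 for p in points])
        self.country_idx = np.array([idx[p.country_iso] for p in points], dtype=int)
        self.n_obs = len(points)
        k = len(self.countries)
        # obs -> country indicator for per-country likelihood sums
        self.ind = np.zeros((self.n_obs, k))
        self.ind[np.arange(self.n_obs), self.country_idx] = 1.0

        self.use_covariates = use_covariates
        self.cov_mean = np.zeros(2)
        self.cov_sd = np.ones(2)
        if use_covariates:
            if covariates is None:
                raise ValueError("use_covariates is on but no covariate series given")
            lookup = {(r.country_iso, r.year): (r.sdi, r.hrh) for r in covariates}
            vals = []
            for p in points:
                key = (p.country_iso, p.survey_year)
                if key not in lookup:
                    raise ValueError(f"missing covariate row for {key}")
                vals.append(lookup[key])
            raw = np.array(vals) if vals else np.zeros((0, 2))
            if len(raw):
                self.cov_mean = raw.mean(axis=0)
                sd = raw.std(axis=0)
                self.cov_sd = np.where(sd > 0, sd, 1.0)
            self.x = (raw - self.cov_mean) / self.cov_sd
        else:
            self.x = np.zeros((self.n_obs, 2))


def _binom_loglik_obs(eta: np.ndarray, y: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    # binomial log-likelihood kernel with real-valued effective n
    return n_eff * (y * eta - np.logaddexp(0.0, eta))


def _log_prior_sd(sigma: float, config: McmcConfig) -> float:
    s = config.prior_scale_sd
    if sigma <= 0:
        return -np.inf
    if config.prior_family_sd == "half_cauchy":
        return -np.log1p((sigma / s) ** 2)
    if config.prior_family_sd == "half_normal":
        return -0.5 * (sigma / s) ** 2
    # uniform(0, 10 * prior_scale_sd / 2.5): flat with a hard ceiling
    upper = 10.0 * s / 2.5
    return 0.0 if sigma < upper else -np.inf


def log_posterior(
    params: TrendParameters,
    data: Sequence[SurveyPoint],
    covariates: Sequence[CovariateRow] | None = None,
    config: McmcConfig | None = None,
) -> float:
    """Log prior + log likelihood, up to an additive constant."""
    config = config or McmcConfig()
    params.validate()
    vals = np.concatenate([
        params.alpha, params.beta,
        [params.mu_alpha, params.mu_beta, params.gamma_sdi, params.gamma_hrh],
    ])
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite parameter values")

    fd = _FitData(list(data), covariates, config.use_covariates, params.countries)
    if fd.countries != list(params.countries):
        raise ValueError("parameter country list does not match the data")

    lp = 0.0
    s0 = config.prior_scale_fixed
    for v in (params.mu_alpha, params.mu_beta):
        lp += -0.5 * (v / s0) ** 2
    if config.use_covariates:
        for v in (params.gamma_sdi, params.gamma_hrh):
            lp += -0.5 * (v / s0) ** 2
    lp += _log_prior_sd(params.sigma_alpha, config)
    lp += _log_prior_sd(params.sigma_beta, config)
    lp += float(
        -len(params.countries) * np.log(params.sigma_alpha)
        - 0.5 * np.sum(((params.alpha - params.mu_alpha) / params.sigma_alpha) ** 2)
    )
    lp += float(
        -len(params.countries) * np.log(params.sigma_beta)
        - 0.5 * np.sum(((params.beta - params.mu_beta) / params.sigma_beta) ** 2)
    )
    if fd.n_obs:
        eta = (
            params.alpha[fd.country_idx]
            + params.beta[fd.country_idx] * fd.t
            + fd.x @ np.array([params.gamma_sdi, params.gamma_hrh])
        )
        lp += float(np.sum(_binom_loglik_obs(eta, fd.y, fd.n_eff)))
    return lp


# ---------------------------------------------------------------------------
# sampler


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned draws per chain, keyed by parameter name.

    Array shapes are ``(n_chains, n_draws)`` for scalars and
    ``(n_chains, n_draws, n_countries)`` for country vectors.
    """

    params: dict[str, np.ndarray]
    countries: list[str]
    outcome: str
    stratum: str
    config: McmcConfig
    cov_mean: np.ndarray
    cov_sd: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def chains(self, name: str, index: int | None = None) -> np.ndarray:
        arr = self.params[name]
        return arr if index is None else arr[:, :, index]

    def flat(self, name: str, index: int | None = None) -> np.ndarray:
        return self.chains(name, index).reshape(-1)

    def monitored(self) -> dict[str, np.ndarray]:
        """Scalar chain matrix per monitored parameter (for diagnostics)."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                for k, c in enumerate(self.countries):
                    out[f"{name}[{c}]"] = arr[:, :, k]
        return out

    def coverage_draws(
        self, country: str, year: int, sdi: float = 0.0, hrh: float = 0.0
    ) -> np.ndarray:
        """Flattened posterior draws of coverage p for a country-year."""
        k = self.countries.index(country)
        t = (year - 2000) / 10.0
        eta = self.flat("alpha", k) + self.flat("beta", k) * t
        if self.config.use_covariates:
            z = (np.array([sdi, hrh]) - self.cov_mean) / self.cov_sd
            eta = eta + self.flat("gamma_sdi") * z[0] + self.flat("gamma_hrh") * z[1]
        return inverse_logit(eta)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (parameter, chain, draw, value) for persistence."""
        frames = []
        for name, arr in self.monitored().items():
            nc, nd = arr.shape
            frames.append(pd.DataFrame({
                "parameter": name,
                "chain": np.repeat(np.arange(nc), nd),
                "draw": np.tile(np.arange(nd), nc),
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


class SamplerError(RuntimeError):
    pass


_ADAPT_INTERVAL = 50
_TARGET_ACC = 0.44
_TARGET_ACC_JOINT = 0.30


def _empirical_init(fd: _FitData) -> tuple[np.ndarray, np.ndarray]:
    """Per-country least-squares on the empirical logit; pooled fallback."""
    k = len(fd.countries)
    y_cl = _clamp_coverage(fd.y, fd.n_eff) if fd.n_obs else np.array([])
    el = logit_transform(y_cl) if fd.n_obs else np.array([])
    if fd.n_obs >= 2 and np.ptp(fd.t) > 0:
        g_slope, g_int = np.polyfit(fd.t, el, 1)
    elif fd.n_obs:
        g_slope, g_int = 0.0, float(np.mean(el))
    else:
        g_slope, g_int = 0.0, 0.0
    alpha0 = np.full(k, g_int)
    beta0 = np.full(k, g_slope)
    for j in range(k):
        m = fd.country_idx == j
        if m.sum() >= 2 and np.ptp(fd.t[m]) > 0:
            b, a = np.polyfit(fd.t[m], el[m], 1)
            alpha0[j], beta0[j] = a, b
        elif m.sum() == 1:
            alpha0[j] = el[m][0] - g_slope * fd.t[m][0]
    return alpha0, beta0


def fit(
    data: Sequence[SurveyPoint],
    covariates: Sequence[CovariateRow] | None = None,
    config: McmcConfig | None = None,
    countries: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the hierarchical trend model.

    ``countries`` may extend the country set beyond those observed (such a
    country's intercept and slope then shrink to the hyper-means).  All
    chains are advanced together; proposal scales adapt only during
    burn-in.
    """
    config = config or McmcConfig()
    config.validate()
    data = list(data)
    if not data:
        raise ValueError("need at least one survey point")
    fd = _FitData(data, covariates, config.use_covariates, countries)
    k = len(fd.countries)
    nc = config.n_chains
    rng = np.random.Generator(np.random.PCG64(config.seed))

    region_names = sorted({fd.regions.get(c, "_none") for c in fd.countries})
    region_idx = np.array(
        [region_names.index(fd.regions.get(c, "_none")) for c in fd.countries]
    )
    n_regions = len(region_names)
    use_regions = config.region_hierarchy and n_regions > 1

    # data-informed start, jittered per chain with growing spread
    alpha0, beta0 = _empirical_init(fd)
    jit = np.array([0.1 * (c + 1) for c in range(nc)])[:, None]
    alpha = alpha0[None, :] + rng.standard_normal((nc, k)) * jit
    beta = beta0[None, :] + rng.standard_normal((nc, k)) * jit
    gamma = rng.standard_normal((nc, 2)) * 0.01
    mu_alpha = alpha.mean(axis=1)
    mu_beta = beta.mean(axis=1)
    mu_region_a = np.tile(mu_alpha[:, None], (1, n_regions))
    log_sig_a = np.log(np.maximum(alpha.std(axis=1), 0.1))
    log_sig_b = np.log(np.maximum(beta.std(axis=1), 0.1))

    # adaptive proposal log-scales
    ls_alpha = np.full((nc, k), np.log(0.2))
    ls_beta = np.full((nc, k), np.log(0.2))
    ls_gamma = np.full(nc, np.log(0.1))
    ls_siga = np.full(nc, np.log(0.3))
    ls_sigb = np.full(nc, np.log(0.3))
    acc = {key: np.zeros((nc,) + shp) for key, shp in
           (("alpha", (k,)), ("beta", (k,)), ("gamma", ()), ("sigma_alpha", ()),
            ("sigma_beta", ()))}
    trials = {key: 0 for key in acc}

    xg = fd.x  # (M, 2)
    s0 = config.prior_scale_fixed

    def country_loglik(a, b, g):
        eta = a[:, fd.country_idx] + b[:, fd.country_idx] * fd.t + (g @ xg.T)
        return _binom_loglik_obs(eta, fd.y, fd.n_eff) @ fd.ind  # (nc, k)

    def total_loglik(a, b, g):
        eta = a[:, fd.country_idx] + b[:, fd.country_idx] * fd.t + (g @ xg.T)
        return _binom_loglik_obs(eta, fd.y, fd.n_eff).sum(axis=1)  # (nc,)

    def sd_logprior(sig):
        s = config.prior_scale_sd
        if config.prior_family_sd == "half_cauchy":
            return -np.log1p((sig / s) ** 2)
        if config.prior_family_sd == "half_normal":
            return -0.5 * (sig / s) ** 2
        upper = 10.0 * s / 2.5
        return np.where(sig < upper, 0.0, -np.inf)

    n_draws = config.draws_per_chain
    store = {
        "alpha": np.empty((nc, n_draws, k)),
        "beta": np.empty((nc, n_draws, k)),
        "mu_alpha": np.empty((nc, n_draws)),
        "mu_beta": np.empty((nc, n_draws)),
        "sigma_alpha": np.empty((nc, n_draws)),
        "sigma_beta": np.empty((nc, n_draws)),
    }
    if config.use_covariates:
        store["gamma_sdi"] = np.empty((nc, n_draws))
        store["gamma_hrh"] = np.empty((nc, n_draws))

    d = 0
    for it in range(config.n_iter):
        adapting = it < config.burn_in
        sig_a = np.exp(log_sig_a)
        sig_b = np.exp(log_sig_b)
        mu_a_country = mu_region_a[np.arange(nc)[:, None], region_idx] if use_regions \
            else mu_alpha[:, None]

        # --- alpha block: independent per-country RW Metropolis
        cur = country_loglik(alpha, beta, gamma)
        prop = alpha + rng.standard_normal((nc, k)) * np.exp(ls_alpha)
        new = country_loglik(prop, beta, gamma)
        dprior = (
            -0.5 * ((prop - mu_a_country) / sig_a[:, None]) ** 2
            + 0.5 * ((alpha - mu_a_country) / sig_a[:, None]) ** 2
        )
        ok = np.log(rng.uniform(size=(nc, k))) < new - cur + dprior
        alpha = np.where(ok, prop, alpha)
        acc["alpha"] += ok
        trials["alpha"] += 1

        # --- beta block
        cur = country_loglik(alpha, beta, gamma)
        prop = beta + rng.standard_normal((nc, k)) * np.exp(ls_beta)
        new = country_loglik(alpha, prop, gamma)
        dprior = (
            -0.5 * ((prop - mu_beta[:, None]) / sig_b[:, None]) ** 2
            + 0.5 * ((beta - mu_beta[:, None]) / sig_b[:, None]) ** 2
        )
        ok = np.log(rng.uniform(size=(nc, k))) < new - cur + dprior
        beta = np.where(ok, prop, beta)
        acc["beta"] += ok
        trials["beta"] += 1

        # --- covariate effects: joint 2-d RW per chain
        if config.use_covariates:
            cur = total_loglik(alpha, beta, gamma)
            prop = gamma + rng.standard_normal((nc, 2)) * np.exp(ls_gamma)[:, None]
            new = total_loglik(alpha, beta, prop)
            dprior = (-0.5 * (prop / s0) ** 2 + 0.5 * (gamma / s0) ** 2).sum(axis=1)
            ok = np.log(rng.uniform(size=nc)) < new - cur + dprior
            gamma = np.where(ok[:, None], prop, gamma)
            acc["gamma"] += ok
            trials["gamma"] += 1

        # --- hyper-means: conjugate Gibbs
        if use_regions:
            # region means around global mu_alpha, then global around regions
            tau = sig_a  # share the country-level SD for the region level
            for r in range(n_regions):
                m = region_idx == r
                kr = int(m.sum())
                prec = kr / sig_a**2 + 1.0 / tau**2
                mean = (alpha[:, m].sum(axis=1) / sig_a**2 + mu_alpha / tau**2) / prec
                mu_region_a[:, r] = mean + rng.standard_normal(nc) / np.sqrt(prec)
            prec = n_regions / tau**2 + 1.0 / s0**2
            mean = (mu_region_a.sum(axis=1) / tau**2) / prec
            mu_alpha = mean + rng.standard_normal(nc) / np.sqrt(prec)
        else:
            prec = k / sig_a**2 + 1.0 / s0**2
            mean = (alpha.sum(axis=1) / sig_a**2) / prec
            mu_alpha = mean + rng.standard_normal(nc) / np.sqrt(prec)
        prec = k / sig_b**2 + 1.0 / s0**2
        mean = (beta.sum(axis=1) / sig_b**2) / prec
        mu_beta = mean + rng.standard_normal(nc) / np.sqrt(prec)

        # --- hyper-SDs: RW Metropolis on the log scale (with Jacobian)
        center_a = mu_region_a[np.arange(nc)[:, None], region_idx] if use_regions \
            else mu_alpha[:, None]
        ssq_a = ((alpha - center_a) ** 2).sum(axis=1)
        prop_ls = log_sig_a + rng.standard_normal(nc) * np.exp(ls_siga)
        cur_sig, prop_sig = np.exp(log_sig_a), np.exp(prop_ls)
        logp_cur = (-k * log_sig_a - 0.5 * ssq_a / cur_sig**2
                    + sd_logprior(cur_sig) + log_sig_a)
        logp_new = (-k * prop_ls - 0.5 * ssq_a / prop_sig**2
                    + sd_logprior(prop_sig) + prop_ls)
        ok = np.log(rng.uniform(size=nc)) < logp_new - logp_cur
        log_sig_a = np.where(ok, prop_ls, log_sig_a)
        acc["sigma_alpha"] += ok
        trials["sigma_alpha"] += 1

        ssq_b = ((beta - mu_beta[:, None]) ** 2).sum(axis=1)
        prop_ls = log_sig_b + rng.standard_normal(nc) * np.exp(ls_sigb)
        cur_sig, prop_sig = np.exp(log_sig_b), np.exp(prop_ls)
        logp_cur = (-k * log_sig_b - 0.5 * ssq_b / cur_sig**2
                    + sd_logprior(cur_sig) + log_sig_b)
        logp_new = (-k * prop_ls - 0.5 * ssq_b / prop_sig**2
                    + sd_logprior(prop_sig) + prop_ls)
        ok = np.log(rng.uniform(size=nc)) < logp_new - logp_cur
        log_sig_b = np.where(ok, prop_ls, log_sig_b)
        acc["sigma_beta"] += ok
        trials["sigma_beta"] += 1

        # --- adapt proposal scales during burn-in only
        if adapting and (it + 1) % _ADAPT_INTERVAL == 0:
            n = _ADAPT_INTERVAL
            ls_alpha += 0.5 * (acc["alpha"] / n - _TARGET_ACC)
            ls_beta += 0.5 * (acc["beta"] / n - _TARGET_ACC)
            ls_gamma += 0.5 * (acc["gamma"] / n - _TARGET_ACC_JOINT)
            ls_siga += 0.5 * (acc["sigma_alpha"] / n - _TARGET_ACC)
            ls_sigb += 0.5 * (acc["sigma_beta"] / n - _TARGET_ACC)
            for key in acc:
                acc[key][...] = 0.0
                trials[key] = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and d < n_draws:
            store["alpha"][:, d] = alpha
            store["beta"][:, d] = beta
            store["mu_alpha"][:, d] = mu_alpha
            store["mu_beta"][:, d] = mu_beta
            store["sigma_alpha"][:, d] = np.exp(log_sig_a)
            store["sigma_beta"][:, d] = np.exp(log_sig_b)
            if config.use_covariates:
                store["gamma_sdi"][:, d] = gamma[:, 0]
                store["gamma_hrh"][:, d] = gamma[:, 1]
            d += 1

    if not np.all([np.isfinite(v).all() for v in store.values()]):
        bad = [kk for kk, v in store.items() if not np.isfinite(v).all()]
        raise SamplerError(f"non-finite draws in parameter block(s): {bad}")

    acc_rates = {
        key: float(np.mean(a) / max(trials[key], 1)) for key, a in acc.items()
    }
    return PosteriorDraws(
        params=store,
        countries=fd.countries,
        outcome=fd.outcome,
        stratum=fd.stratum,
        config=config,
        cov_mean=fd.cov_mean,
        cov_sd=fd.cov_sd,
        acceptance=acc_rates,
    )


# ---------------------------------------------------------------------------
# projection


def _covariate_table(
    covariates: Sequence[CovariateRow],
    countries: Sequence[str],
    years: Sequence[int],
    extrapolate: bool,
) -> dict[tuple[str, int], tuple[float, float]]:
    lookup = {(r.country_iso, r.year): (r.sdi, r.hrh) for r in covariates}
    missing = [(c, y) for c in countries for y in years if (c, y) not in lookup]
    if missing and not extrapolate:
        raise ValueError(
            f"missing covariates for {missing[:5]}{'...' if len(missing) > 5 else ''}; "
            "enable extrapolation or extend the series"
        )
    if missing:
        for c in countries:
            have = sorted(y for (ci, y) in lookup if ci == c)
            if not have:
                raise ValueError(f"no covariate rows at all for {c}")
            recent = have[-10:]
            sdi_v = np.array([lookup[(c, y)][0] for y in recent])
            hrh_v = np.array([lookup[(c, y)][1] for y in recent])
            if len(recent) >= 2:
                ps = np.polyfit(recent, sdi_v, 1)
                ph = np.polyfit(recent, hrh_v, 1)
            else:
                ps = (0.0, sdi_v[0])
                ph = (0.0, hrh_v[0])
            for y in years:
                if (c, y) not in lookup:
                    lookup[(c, y)] = (
                        float(np.clip(np.polyval(ps, y), 0.0, 1.0)),
                        float(max(np.polyval(ph, y), 0.0)),
                    )
    return lookup


def project(
    draws: PosteriorDraws,
    covariates: Sequence[CovariateRow] | None = None,
    years: Sequence[int] = tuple(range(2000, 2031)),
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Posterior mean and 95% CrI of coverage (percent) per country-year.

    Returns a tidy frame with columns country_iso, stratum, outcome, year,
    mean, cri_low, cri_high.
    """
    years = list(years)
    need_cov = draws.config.use_covariates
    lookup = (
        _covariate_table(covariates or [], draws.countries, years, extrapolate)
        if need_cov else {}
    )
    t = (np.array(years) - 2000) / 10.0  # (Y,)
    alpha = np.concatenate(draws.params["alpha"], axis=0)  # (D, K)
    beta = np.concatenate(draws.params["beta"], axis=0)
    rows = []
    for kk, c in enumerate(draws.countries):
        eta = alpha[:, kk:kk + 1] + beta[:, kk:kk + 1] * t[None, :]  # (D, Y)
        if need_cov:
            z = np.array([
                ((np.array(lookup[(c, y)]) - draws.cov_mean) / draws.cov_sd)
                for y in years
            ])  # (Y, 2)
            eta = eta + draws.flat("gamma_sdi")[:, None] * z[:, 0][None, :]
            eta = eta + draws.flat("gamma_hrh")[:, None] * z[:, 1][None, :]
        p = inverse_logit(eta) * 100.0
        mean = p.mean(axis=0)
        lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
        for j, y in enumerate(years):
            rows.append((c, draws.stratum, draws.outcome, y, mean[j], lo[j], hi[j]))
    return pd.DataFrame(
        rows,
        columns=["country_iso", "stratum", "outcome", "year",
                 "mean", "cri_low", "cri_high"],
    )


# ---------------------------------------------------------------------------
# sensitivity protocol


def median_absolute_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-year median of |mean_a − mean_b| across countries (points)."""
    merged = a.merge(
        b, on=["country_iso", "stratum", "outcome", "year"], suffixes=("_a", "_b")
    )
    if len(merged) != len(a):
        raise ValueError("trajectory frames do not align")
    merged["absdiff"] = (merged["mean_a"] - merged["mean_b"]).abs()
    out = merged.groupby("year", as_index=False)["absdiff"].median()
    return out.rename(columns={"absdiff": "median_abs_diff"})


@dataclass
class SensitivityResult:
    base: pd.DataFrame
    no_covariates: pd.DataFrame
    alt_prior: pd.DataFrame
    diff_no_covariates: pd.DataFrame
    diff_alt_prior: pd.DataFrame


def sensitivity_refit(
    data: Sequence[SurveyPoint],
    covariates: Sequence[CovariateRow] | None,
    base_config: McmcConfig,
    years: Sequence[int] = tuple(range(2000, 2031)),
    extrapolate: bool = False,
) -> SensitivityResult:
    """Refit (a) without SDI/HRH and (b) with the alternate hyper-SD prior,
    and summarise each refit against the base as a per-year median absolute
    difference of posterior-mean coverage."""
    base = project(fit(data, covariates, base_config), covariates, years, extrapolate)
    cfg_nocov = replace(base_config, use_covariates=False)
    nocov = project(fit(data, covariates, cfg_nocov), covariates, years, extrapolate)
    alt_family = "uniform" if base_config.prior_family_sd != "uniform" else "half_normal"
    cfg_alt = replace(base_config, prior_family_sd=alt_family)
    alt = project(fit(data, covariates, cfg_alt), covariates, years, extrapolate)
    return SensitivityResult(
        base=base,
        no_covariates=nocov,
        alt_prior=alt,
        diff_no_covariates=median_absolute_difference(base, nocov),
        diff_alt_prior=median_absolute_difference(base, alt),
    )
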