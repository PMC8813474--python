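"""Individual-level determinants of delivery-care use.

Bayesian hierarchical logistic regression of a binary outcome (facility
delivery or skilled attendance at birth) on household and maternal
covariates, with a random intercept per country::

    y_j ~ Bernoulli(p_j),  logit(p_j) = b0 + x_j' b + u_0i(j)
    u_0i ~ Normal(0, sigma2_u0)

Covariates are dummy-coded against fixed reference levels (household head
aged <30 and male; no education; parity 1; no ANC visits; no mass-media
access; poorest quintile; urban residence), so each coefficient is a
log-odds ratio against its reference.  Priors are weakly informative:
Normal(0, 10^2) on fixed effects and half-Cauchy(0, 2.5) on the
random-intercept SD.

Sampling is Metropolis-within-Gibbs: a joint random-walk update of all
fixed effects using the ML covariance as proposal shape, vectorised
per-country updates of the random intercepts, and a log-scale update of
the intercept SD.  Proposal scales adapt during burn-in only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import registry_io as rio
from .registry_io import IndividualRecord
from .trend_model import McmcConfig

__all__ = [
    "DESIGN_FIELDS",
    "design_columns",
    "encode_design",
    "fit_determinants",
    "or_table",
    "DeterminantDraws",
    "SeparationError",
]

# field name -> ordered levels, reference first (the printed table's order)
DESIGN_FIELDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("hh_head_age", rio.HH_HEAD_AGE_LEVELS),
    ("hh_head_sex", rio.HH_HEAD_SEX_LEVELS),
    ("education", rio.EDUCATION_LEVELS),
    ("parity", rio.PARITY_LEVELS),
    ("anc_visits", rio.ANC_LEVELS),
    ("media", rio.MEDIA_LEVELS),
    ("wealth_quintile", rio.WEALTH_LEVELS),
    ("residence", rio.RESIDENCE_LEVELS),
)

_FIXED_PRIOR_SD = 10.0
_SD_PRIOR_SCALE = 2.5
_ADAPT_INTERVAL = 50


class SeparationError(RuntimeError):
    """A covariate level perfectly predicts the outcome."""


def design_columns() -> list[str]:
    """Stable "<field>:<level>" names of the 21 non-reference columns."""
    return [
        f"{fld}:{lvl}" for fld, levels in DESIGN_FIELDS for lvl in levels[1:]
    ]


def encode_design(
    records: Sequence[IndividualRecord], outcome: str = "INSD"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Dummy-code records against the reference levels.

    Returns (X, y, country_idx, countries, column_names) where X is the
    (n, 21) indicator matrix in the documented column order and y the
    requested outcome flag.
    """
    if not records:
        raise ValueError("no records to encode")
    if outcome not in rio.OUTCOMES:
        raise ValueError(f"outcome must be one of {rio.OUTCOMES}")
    attr = "outcome_insd" if outcome == "INSD" else "outcome_sba"
    for r in records:
        r.validate()
    cols = design_columns()
    n = len(records)
    x = np.zeros((n, len(cols)))
    pos = {name: j for j, name in enumerate(cols)}
    for i, r in enumerate(records):
        for fld, levels in DESIGN_FIELDS:
            val = getattr(r, fld)
            key = f"{fld}:{val}"
            if key in pos:
                x[i, pos[key]] = 1.0
    y = np.array([getattr(r, attr) for r in records], dtype=float)
    countries = sorted({r.country_iso for r in records})
    cidx = {c: k for k, c in enumerate(countries)}
    country_idx = np.array([cidx[r.country_iso] for r in records], dtype=int)
    return x, y, country_idx, countries, cols


def _check_separation(x: np.ndarray, y: np.ndarray, cols: list[str]) -> None:
    if y.min() == y.max():
        raise ValueError("outcomes are all identical; nothing to model")
    for j, name in enumerate(cols):
        mask = x[:, j] == 1.0
        if mask.any() and (y[mask].min() == y[mask].max()):
            raise SeparationError(
                f"level {name!r} perfectly predicts the outcome "
                f"(all y = {int(y[mask][0])} in that group)"
            )


@dataclass
class DeterminantDraws:
    """Posterior draws of the determinants model, per chain."""

    params: dict[str, np.ndarray]  # beta: (nc, nd, 22); u0: (nc, nd, K); ...
    columns: list[str]  # 21 design columns (beta[..., 0] is the intercept)
    countries: list[str]
    outcome: str
    config: McmcConfig
    acceptance: dict[str, float]

    def flat(self, name: str, index: int | None = None) -> np.ndarray:
        arr = self.params[name]
        if index is not None:
            arr = arr[:, :, index]
        return arr.reshape(-1, *arr.shape[3:]) if arr.ndim > 2 else arr.reshape(-1)

    def coefficient_draws(self, column: str) -> np.ndarray:
        """Flattened draws of one design coefficient (log-odds scale)."""
        j = self.columns.index(column) + 1  # offset for the intercept
        return self.params["beta"][:, :, j].reshape(-1)

    def monitored(self) -> dict[str, np.ndarray]:
        out = {"intercept": self.params["beta"][:, :, 0]}
        for j, c in enumerate(self.columns):
            out[c] = self.params["beta"][:, :, j + 1]
        if "sigma2_u0" in self.params:
            out["sigma2_u0"] = self.params["sigma2_u0"]
        return out


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def fit_determinants(
    records: Sequence[IndividualRecord],
    config: McmcConfig | None = None,
    outcome: str = "INSD",
    include_random_intercept: bool = True,
) -> DeterminantDraws:
    """Posterior draws for the random-intercept logistic model.

    With ``include_random_intercept=False`` the model collapses to plain
    Bayesian logistic regression (used for single-country analyses and as
    the bridge to the maximum-likelihood oracle).
    """
    config = config or McmcConfig()
    config.validate()
    x, y, country_idx, countries, cols = encode_design(records, outcome)
    _check_separation(x, y, cols)
    k = len(countries)
    if include_random_intercept and k < 2:
        raise ValueError("random intercept needs records from >= 2 countries")
    n, p = x.shape
    xd = np.column_stack([np.ones(n), x])  # intercept first

    # ML fit supplies the starting point and the joint-proposal shape
    try:
        ml = sm.Logit(y, xd).fit(disp=0, maxiter=200)
        theta_ml = np.asarray(ml.params)
        cov_ml = np.asarray(ml.cov_params())
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise SeparationError(f"ML initialisation failed: {exc}") from exc
    if not np.all(np.isfinite(cov_ml)):
        raise SeparationError("non-finite ML covariance; check for separation")
    chol = np.linalg.cholesky(cov_ml + 1e-10 * np.eye(p + 1))

    nc, nd = config.n_chains, config.draws_per_chain
    store: dict[str, np.ndarray] = {"beta": np.empty((nc, nd, p + 1))}
    if include_random_intercept:
        store["u0"] = np.empty((nc, nd, k))
        store["sigma2_u0"] = np.empty((nc, nd))
    acc_tot = {"beta": 0.0, "u0": 0.0, "sigma_u": 0.0}

    for chain in range(nc):
        rng = np.random.Generator(np.random.PCG64(config.seed + 1000 * (chain + 1)))
        theta = theta_ml + chol @ rng.standard_normal(p + 1) * (0.1 * (chain + 1))
        u = np.zeros(k)
        log_sig = np.log(0.5)
        ls_theta = np.log(1.0)  # multiplier on the ML-shaped proposal
        ls_u = np.full(k, np.log(0.3))
        ls_sig = np.log(0.3)
        acc = {"beta": 0.0, "u0": np.zeros(k), "sigma_u": 0.0}

        eta_fixed = xd @ theta
        u_obs = u[country_idx] if include_random_intercept else 0.0
        ll_cur = float(_bernoulli_loglik(eta_fixed + u_obs, y).sum())

        d = 0
        for it in range(config.n_iter):
            adapting = it < config.burn_in

            # --- joint fixed-effects update
            step = chol @ rng.standard_normal(p + 1) * np.exp(ls_theta)
            theta_prop = theta + step
            eta_prop = xd @ theta_prop
            ll_prop = float(_bernoulli_loglik(eta_prop + u_obs, y).sum())
            dprior = float(
                -0.5 * np.sum((theta_prop / _FIXED_PRIOR_SD) ** 2)
                + 0.5 * np.sum((theta / _FIXED_PRIOR_SD) ** 2)
            )
            if np.log(rng.uniform()) < ll_prop - ll_cur + dprior:
                theta, eta_fixed, ll_cur = theta_prop, eta_prop, ll_prop
                acc["beta"] += 1

            if include_random_intercept:
                # --- per-country random intercepts (vectorised MH)
                sig = np.exp(log_sig)
                u_prop = u + rng.standard_normal(k) * np.exp(ls_u)
                ll_rec_cur = _bernoulli_loglik(eta_fixed + u[country_idx], y)
                ll_rec_prop = _bernoulli_loglik(eta_fixed + u_prop[country_idx], y)
                ll_c_cur = np.bincount(country_idx, weights=ll_rec_cur, minlength=k)
                ll_c_prop = np.bincount(country_idx, weights=ll_rec_prop, minlength=k)
                dprior_u = -0.5 * (u_prop / sig) ** 2 + 0.5 * (u / sig) ** 2
                ok = np.log(rng.uniform(size=k)) < ll_c_prop - ll_c_cur + dprior_u
                u = np.where(ok, u_prop, u)
                acc["u0"] += ok
                u_obs = u[country_idx]
                ll_cur = float(_bernoulli_loglik(eta_fixed + u_obs, y).sum())

                # --- intercept SD on the log scale (half-Cauchy prior)
                prop_ls = log_sig + rng.standard_normal() * np.exp(ls_sig)
                ssq = float(np.sum(u**2))
                def _lp(lsig):
                    s = np.exp(lsig)
                    return (-k * lsig - 0.5 * ssq / s**2
                            - np.log1p((s / _SD_PRIOR_SCALE) ** 2) + lsig)
                if np.log(rng.uniform()) < _lp(prop_ls) - _lp(log_sig):
                    log_sig = prop_ls
                    acc["sigma_u"] += 1

            if adapting and (it + 1) % _ADAPT_INTERVAL == 0:
                m = _ADAPT_INTERVAL
                ls_theta += 0.5 * (acc["beta"] / m - 0.234)
                if include_random_intercept:
                    ls_u += 0.5 * (acc["u0"] / m - 0.44)
                    ls_sig += 0.5 * (acc["sigma_u"] / m - 0.44)
                acc = {"beta": 0.0, "u0": np.zeros(k), "sigma_u": 0.0}

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                    and d < nd:
                store["beta"][chain, d] = theta
                if include_random_intercept:
                    store["u0"][chain, d] = u
                    store["sigma2_u0"][chain, d] = np.exp(2 * log_sig)
                d += 1

        post = config.n_iter - config.burn_in
        acc_tot["beta"] += acc["beta"] / max(post, 1)
        if include_random_intercept:
            acc_tot["u0"] += float(np.mean(acc["u0"])) / max(post, 1)
            acc_tot["sigma_u"] += acc["sigma_u"] / max(post, 1)

    if not np.all([np.isfinite(v).all() for v in store.values()]):
        raise RuntimeError("non-finite posterior draws")
    acceptance = {kk: v / nc for kk, v in acc_tot.items()}
    return DeterminantDraws(
        params=store, columns=cols, countries=countries,
        outcome=outcome, config=config, acceptance=acceptance,
    )


def or_table(
    draws: DeterminantDraws, point: str = "median"
) -> pd.DataFrame:
    """Odds-ratio table mirroring the published layout.

    One row per covariate level (reference rows print OR 1.00 with no
    interval) plus the random-intercept-variance line; the point estimate
    is the posterior median by default (``point="mean"`` switches).
    """
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    rows = []
    for fld, levels in DESIGN_FIELDS:
        for li, lvl in enumerate(levels):
            if li == 0:
                rows.append((fld, lvl, 1.00, np.nan, np.nan, True))
                continue
            cd = np.exp(draws.coefficient_draws(f"{fld}:{lvl}"))
            est = float(np.median(cd) if point == "median" else np.mean(cd))
            lo, hi = np.percentile(cd, [2.5, 97.5])
            rows.append((fld, lvl, est, float(lo), float(hi), False))
    if "sigma2_u0" in draws.params:
        sd = draws.flat("sigma2_u0")
        est = float(np.median(sd) if point == "median" else np.mean(sd))
        lo, hi = np.percentile(sd, [2.5, 97.5])
        rows.append(("random_intercept", "sigma2_u0", est, float(lo), float(hi), False))
    return pd.DataFrame(
        rows,
        columns=["characteristic", "level", "estimate", "cri_low", "cri_high",
                 "reference"],
    )
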