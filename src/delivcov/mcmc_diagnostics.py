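"""Convergence diagnostics: Gelman-Rubin PSRF and trace summaries.

The potential scale reduction factor (PSRF) compares between-chain and
within-chain variance for each monitored parameter.  With ``m`` chains of
length ``n``, chain means ``x̄_j`` and within-chain sample variances
``s_j²``::

    W = mean_j s_j²                 (within-chain variance)
    B/n = var_j(x̄_j)                (variance of the chain means)
    V̂ = (n − 1)/n · W + B/n         (pooled variance estimate)
    PSRF = sqrt(V̂ / W)

Values near 1 indicate that the chains have mixed into a common
distribution.  The classic (non-split, non-rank-normalised) estimator is
the default, matching the JAGS-era workflow; a split-chain variant is
available behind a flag.  The upper limit is the 97.5th percentile of the
variance ratio under the standard F-approximation with moment-matched
degrees of freedom for W.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PsrfReport", "gelman_rubin", "diagnostics_table", "trace_summary"]

FLAG_THRESHOLD = 1.1


class DegenerateChainsError(ValueError):
    """All chains are (jointly) constant; the variance ratio is undefined."""


@dataclass(frozen=True)
class PsrfReport:
    parameter: str
    psrf_point: float
    psrf_upper: float
    flag: bool


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array-like (m chains x n draws)")
    m, n = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 4:
        raise ValueError("need chain length >= 4")
    return arr


def gelman_rubin(
    chains, parameter: str = "theta", split: bool = False
) -> PsrfReport:
    """Potential scale reduction factor for one monitored parameter.

    ``chains`` is an (m, n) array-like of m parallel chains.  With
    ``split=True`` each chain is halved first (2m half-chains), which also
    detects within-chain drift.
    """
    arr = _as_chain_matrix(chains)
    if split:
        half = arr.shape[1] // 2
        arr = np.vstack([arr[:, :half], arr[:, half:2 * half]])
    m, n = arr.shape

    s2 = arr.var(axis=1, ddof=1)
    w = float(s2.mean())
    if w == 0.0:
        raise DegenerateChainsError(
            f"within-chain variance is zero for {parameter!r}"
        )
    b_over_n = float(arr.mean(axis=1).var(ddof=1))  # B/n
    v_hat = (n - 1) / n * w + b_over_n
    psrf_point = float(np.sqrt(v_hat / w))

    # F-approximation to the 97.5th percentile of the variance ratio:
    # the B component has m-1 df; W's df are moment-matched from the
    # spread of the per-chain variances.
    var_s2 = float(s2.var(ddof=1)) if m > 1 else 0.0
    df_w = 2.0 * w**2 / var_s2 if var_s2 > 0 else np.inf
    if b_over_n == 0.0:
        psrf_upper = psrf_point
    else:
        f_q = stats.f.ppf(0.975, m - 1, df_w) if np.isfinite(df_w) else \
            stats.chi2.ppf(0.975, m - 1) / (m - 1)
        upper_var = (n - 1) / n * w + (m + 1) / m * b_over_n * f_q
        psrf_upper = float(np.sqrt(upper_var / w))
    psrf_upper = max(psrf_upper, psrf_point)
    return PsrfReport(
        parameter=parameter,
        psrf_point=psrf_point,
        psrf_upper=psrf_upper,
        flag=psrf_upper > FLAG_THRESHOLD,
    )


def diagnostics_table(
    monitored: Mapping[str, np.ndarray], split: bool = False
) -> pd.DataFrame:
    """PSRF report for every monitored parameter (chain matrices).

    Parameters whose chains are degenerate (zero within-chain variance)
    are reported with NaN PSRF and a raised flag rather than aborting the
    whole table.
    """
    rows = []
    for name, arr in monitored.items():
        try:
            r = gelman_rubin(arr, parameter=name, split=split)
            rows.append((name, r.psrf_point, r.psrf_upper, r.flag))
        except DegenerateChainsError:
            rows.append((name, np.nan, np.nan, True))
    return pd.DataFrame(
        rows, columns=["parameter", "psrf_point", "psrf_upper", "flag"]
    )


def trace_summary(
    chains, parameter: str = "theta", acceptance: float | None = None
) -> pd.DataFrame:
    """Numerical companion to a trace plot: per-chain running means.

    Returns a long frame (parameter, chain, draw, running_mean) with the
    pooled mean and, when supplied, the sampler acceptance rate attached
    as frame attributes.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("chains must be a non-empty 2-D array-like")
    m, n = arr.shape
    running = np.cumsum(arr, axis=1) / np.arange(1, n + 1)
    out = pd.DataFrame({
        "parameter": parameter,
        "chain": np.repeat(np.arange(m), n),
        "draw": np.tile(np.arange(n), m),
        "running_mean": running.reshape(-1),
    })
    out.attrs["pooled_mean"] = float(arr.mean())
    if acceptance is not None:
        if not 0.0 <= acceptance <= 1.0:
            raise ValueError("acceptance rate must be in [0, 1]")
        out.attrs["acceptance"] = float(acceptance)
    return out
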