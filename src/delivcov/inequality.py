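"""Wealth-based inequality metrics: slope index of inequality (SII),
urban-rural gaps, and percentage-change summaries.

The SII regresses subgroup coverage on the ridit score of each wealth
quintile — the midpoint of the group's interval on the cumulative
population-share axis, poorest (Q1) first — by weighted least squares with
the population shares as weights.  The fitted difference between the top
(rank 1) and bottom (rank 0) of the wealth distribution equals the
regression slope: positive SII means coverage concentrates among the rich
(pro-rich inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuintileCoverage",
    "SiiEstimate",
    "ridit_scores",
    "sii",
    "sii_from_draws",
    "percentage_change",
    "residence_gap",
    "sii_report",
]

WIDE_GAP_THRESHOLD = 30.0


@dataclass(frozen=True)
class QuintileCoverage:
    """Coverage (percent) per wealth quintile for one country-year-outcome."""

    country_iso: str
    outcome: str
    year: int
    coverage: tuple[float, float, float, float, float]  # Q1..Q5, percent
    shares: tuple[float, float, float, float, float] = (0.2,) * 5

    def validate(self) -> None:
        if len(self.coverage) != 5 or len(self.shares) != 5:
            raise ValueError("need exactly five quintile coverages and shares")
        if abs(sum(self.shares) - 1.0) > 1e-6:
            raise ValueError(f"shares sum to {sum(self.shares)}, expected 1")
        if any(not 0.0 <= c <= 100.0 for c in self.coverage):
            raise ValueError("quintile coverages must be in [0, 100]")


@dataclass(frozen=True)
class SiiEstimate:
    sii: float  # percentage points
    direction: str  # pro-rich / pro-poor / none
    cri_low: float | None = None
    cri_high: float | None = None


def ridit_scores(shares: Sequence[float]) -> np.ndarray:
    """Midpoints of the cumulative-share intervals, poorest group first."""
    shares = np.asarray(shares, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(shares)])
    return cum[:-1] + shares / 2.0


def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    return float(
        np.average((x - xbar) * (y - ybar), weights=w)
        / np.average((x - xbar) ** 2, weights=w)
    )


def _direction(value: float) -> str:
    if value > 0:
        return "pro-rich"
    if value < 0:
        return "pro-poor"
    return "none"


def sii(qc: QuintileCoverage) -> SiiEstimate:
    """Slope index of inequality for one set of quintile coverages.

    Weighted least squares of coverage on ridit scores; the slope is the
    fitted coverage difference between cumulative rank 1 and rank 0.
    """
    qc.validate()
    x = ridit_scores(qc.shares)
    slope = _wls_slope(x, np.asarray(qc.coverage, dtype=float),
                       np.asarray(qc.shares, dtype=float))
    return SiiEstimate(sii=slope, direction=_direction(slope))


def sii_from_draws(
    draws_by_quintile: Sequence[np.ndarray],
    shares: Sequence[float] = (0.2,) * 5,
) -> SiiEstimate:
    """Per-draw SII with a 95% credible interval.

    ``draws_by_quintile`` holds equal-length arrays of posterior coverage
    draws (percent) for Q1..Q5; the SII is computed draw by draw and
    summarised by its posterior mean and central 95% interval.
    """
    arrs = [np.asarray(a, dtype=float) for a in draws_by_quintile]
    if len(arrs) != 5 or len({a.shape for a in arrs}) != 1:
        raise ValueError("need five equal-length draw arrays (Q1..Q5)")
    x = ridit_scores(shares)
    w = np.asarray(shares, dtype=float)
    y = np.stack(arrs, axis=1)  # (D, 5)
    xbar = np.average(x, weights=w)
    xc = x - xbar
    denom = np.average(xc**2, weights=w)
    ybar = np.average(y, axis=1, weights=w)
    slopes = np.average(xc * (y - ybar[:, None]), axis=1, weights=w) / denom
    mean = float(slopes.mean())
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return SiiEstimate(sii=mean, direction=_direction(mean),
                       cri_low=float(lo), cri_high=float(hi))


def percentage_change(v_start: float, v_end: float, mode: str = "point") -> float:
    """Change between two coverage levels (percent scale).

    ``point`` mode is the difference in percentage points; ``relative``
    mode is 100 * (end − start) / start.
    """
    for v in (v_start, v_end):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"coverage {v} outside [0, 100]")
    if mode == "point":
        return v_end - v_start
    if mode == "relative":
        if v_start == 0:
            raise ValueError("relative change undefined for v_start = 0")
        return 100.0 * (v_end - v_start) / v_start
    raise ValueError(f"unknown mode {mode!r}")


def residence_gap(urban: float, rural: float) -> tuple[float, bool]:
    """Urban minus rural coverage (points) and the wide-disparity flag."""
    for v in (urban, rural):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"coverage {v} outside [0, 100]")
    gap = urban - rural
    return gap, gap >= WIDE_GAP_THRESHOLD


def sii_report(quintile_sets: Sequence[QuintileCoverage]) -> pd.DataFrame:
    """Tidy SII table (country, outcome, year, sii, direction)."""
    rows = []
    for qc in quintile_sets:
        est = sii(qc)
        rows.append((qc.country_iso, qc.outcome, qc.year, est.sii, est.direction))
    return pd.DataFrame(
        rows, columns=["country_iso", "outcome", "year", "sii", "direction"]
    )
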