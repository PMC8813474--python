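"""Threshold classification, country counting and table assembly.

The headline summaries of the projection exercise are counts of countries
whose predicted national coverage clears (or misses) a threshold — e.g.
how many of the 54 countries reach 80% coverage of both institutional
delivery and skilled birth attendance by 2030.  Comparisons are made on
the one-decimal printed values, matching the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .registry_io import PrintedPrediction, REGIONS

__all__ = [
    "ThresholdReport",
    "predictions_to_frame",
    "count_above_threshold",
    "count_below_threshold",
    "assemble_country_table",
    "format_cell",
]


@dataclass(frozen=True)
class ThresholdReport:
    year: int
    outcomes: tuple[str, ...]
    threshold: float
    countries_meeting: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.countries_meeting)


def predictions_to_frame(predictions) -> pd.DataFrame:
    """Normalise predictions to a tidy frame with one-decimal means.

    Accepts either a collection of printed-prediction cells or a
    trajectory frame (country_iso/stratum/outcome/year/mean/...).  Means
    are rounded to one decimal, the precision of the published tables.
    """
    if isinstance(predictions, pd.DataFrame):
        df = predictions.copy()
        if "stratum" in df.columns:
            df = df[df["stratum"] == "national"]
        if "country_name" not in df.columns:
            df["country_name"] = df["country_iso"]
        if "region" not in df.columns:
            df["region"] = ""
    else:
        df = pd.DataFrame([vars(p) for p in predictions])
    need = {"country_name", "country_iso", "outcome", "year",
            "mean", "cri_low", "cri_high"}
    if df.empty:
        return pd.DataFrame(columns=sorted(need) + ["region"])
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"predictions lack columns {sorted(missing)}")
    for c in ("mean", "cri_low", "cri_high"):
        df[c] = df[c].round(1)
    return df


def _cells(df: pd.DataFrame, year: int, outcomes: Sequence[str]) -> pd.DataFrame:
    sub = df[(df["year"] == year) & (df["outcome"].isin(list(outcomes)))]
    counts = sub.groupby("country_name")["outcome"].nunique()
    short = counts[counts < len(outcomes)]
    all_countries = df["country_name"].unique()
    absent = set(all_countries) - set(counts.index)
    if len(short) or absent:
        raise KeyError(
            f"missing cells for year {year}, outcomes {tuple(outcomes)}: "
            f"{sorted(set(short.index) | absent)}"
        )
    return sub


def count_above_threshold(
    predictions, year: int, outcomes: Sequence[str], threshold: float
) -> ThresholdReport:
    """Countries whose mean prediction is >= threshold for EVERY outcome."""
    df = predictions_to_frame(predictions)
    sub = _cells(df, year, outcomes)
    ok = sub.groupby("country_name")["mean"].agg(lambda v: bool((v >= threshold).all()))
    meeting = tuple(sorted(ok[ok].index))
    return ThresholdReport(year=year, outcomes=tuple(outcomes),
                           threshold=threshold, countries_meeting=meeting)


def count_below_threshold(
    predictions, year: int, outcome: str, threshold: float
) -> ThresholdReport:
    """Countries whose mean prediction is < threshold for one outcome."""
    df = predictions_to_frame(predictions)
    sub = _cells(df, year, [outcome])
    below = sub[sub["mean"] < threshold]
    return ThresholdReport(year=year, outcomes=(outcome,), threshold=threshold,
                           countries_meeting=tuple(sorted(below["country_name"])))


def format_cell(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.1f} ({lo:.1f}–{hi:.1f})"


def assemble_country_table(
    predictions, years: Sequence[int] = (2000, 2018, 2030)
) -> pd.DataFrame:
    """One row per country, grouped by region, "mean (low-high)" cells.

    Columns are <outcome>_<year> strings for both outcomes across the
    requested years; regions follow the canonical six-region order.
    """
    df = predictions_to_frame(predictions)
    if df.empty:
        cols = ["region", "country_name"] + [
            f"{o}_{y}" for o in ("INSD", "SBA") for y in years
        ]
        return pd.DataFrame(columns=cols)
    for y in years:
        _cells(df, y, sorted(df["outcome"].unique()))
    rows = []
    region_rank = {r: i for i, r in enumerate(REGIONS)}
    for (region, name), grp in df.groupby(["region", "country_name"]):
        row = {"region": region, "country_name": name}
        for o in sorted(df["outcome"].unique()):
            for y in years:
                cell = grp[(grp["outcome"] == o) & (grp["year"] == y)]
                r = cell.iloc[0]
                row[f"{o}_{y}"] = format_cell(r["mean"], r["cri_low"], r["cri_high"])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["_rank"] = out["region"].map(lambda r: region_rank.get(r, len(REGIONS)))
    out = out.sort_values(["_rank", "country_name"]).drop(columns="_rank")
    return out.reset_index(drop=True)
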