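"""Data model, validation and CSV I/O for the delivery-care coverage pipeline.

Three tabular inputs drive the analysis:

* survey coverage points — one observed proportion per
  country x year x stratum x outcome, with an effective sample size
  (the denominator after design-effect deflation);
* country-year covariate series — Sociodemographic Index (SDI, in [0, 1])
  and Human Resources for Health density (HRH, per 1,000 population);
* individual birth records for the determinants model, emulating the
  DHS/MICS recode structure.

A packaged fixture carries the printed national predictions (mean and 95%
credible interval for 2000, 2018 and 2030 for both outcomes in all 54
countries) used by the threshold-count reports.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, fields as _dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "REGIONS",
    "OUTCOMES",
    "STRATA",
    "SOURCES",
    "SurveyPoint",
    "CovariateRow",
    "PrintedPrediction",
    "IndividualRecord",
    "ValidationError",
    "FixtureError",
    "effective_sample_size",
    "load_survey_points",
    "write_survey_points",
    "load_covariates",
    "write_covariates",
    "covariate_gaps",
    "load_printed_predictions",
    "load_individuals",
    "write_individuals",
    "survey_points_to_frame",
]

REGIONS = (
    "South Asia",
    "East Asia and the Pacific",
    "Eastern and Southern Africa",
    "West and Central Africa",
    "Latin America and Caribbean",
    "Central and Eastern Europe",
)
OUTCOMES = ("INSD", "SBA")
STRATA = ("national", "urban", "rural", "Q1", "Q2", "Q3", "Q4", "Q5")
SOURCES = ("DHS", "MICS", "SYNTH")

HH_HEAD_AGE_LEVELS = ("<30", "30-45", "46-60", ">60")
HH_HEAD_SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
PARITY_LEVELS = ("1", "2", "3", ">=4")
ANC_LEVELS = ("0", "1", "2", "3", ">=4")
MEDIA_LEVELS = ("none", "<weekly", ">=weekly")
WEALTH_LEVELS = ("Q1", "Q2", "Q3", "Q4", "Q5")
RESIDENCE_LEVELS = ("urban", "rural")

_TABLE1_RESOURCE = "table1_predictions.csv"
_TABLE1_SHA256 = "62ffd456c611c620bf7e2fd0fbe254ae3329943778c4fb6ee97ce1fe404e69a8"


class ValidationError(ValueError):
    """A row failed schema validation; carries 1-based data-row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = tuple(rows)


class FixtureError(RuntimeError):
    """The packaged fixture is missing or corrupted."""


@dataclass(frozen=True)
class SurveyPoint:
    """One observed coverage estimate for a country-year-stratum-outcome."""

    country_iso: str
    region: str
    survey_year: int
    source: str
    stratum: str
    outcome: str
    coverage: float
    n_effective: float

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError(
                f"coverage {self.coverage} outside [0, 1] "
                f"({self.country_iso} {self.survey_year})"
            )
        if not self.n_effective > 0:
            raise ValidationError(
                f"n_effective must be positive, got {self.n_effective}"
            )


@dataclass(frozen=True)
class CovariateRow:
    """SDI and HRH for one country-year."""

    country_iso: str
    year: int
    sdi: float
    hrh: float

    def validate(self) -> None:
        if not 0.0 <= self.sdi <= 1.0:
            raise ValidationError(
                f"sdi {self.sdi} outside [0, 1] ({self.country_iso} {self.year})"
            )
        if self.hrh < 0:
            raise ValidationError(
                f"hrh must be non-negative, got {self.hrh} "
                f"({self.country_iso} {self.year})"
            )


@dataclass(frozen=True)
class PrintedPrediction:
    """One published national prediction cell (percent scale, as printed)."""

    country_name: str
    country_iso: str
    region: str
    outcome: str
    year: int
    mean: float
    cri_low: float
    cri_high: float


@dataclass(frozen=True)
class IndividualRecord:
    """One birth record in the DHS/MICS-style recode schema.

    Outcomes are binary flags; every covariate is categorical with the
    reference level listed first in the module-level ``*_LEVELS`` tuples.
    """

    country_iso: str
    outcome_insd: int
    outcome_sba: int
    hh_head_age: str
    hh_head_sex: str
    education: str
    parity: str
    anc_visits: str
    media: str
    wealth_quintile: str
    residence: str

    def validate(self) -> None:
        checks = (
            ("outcome_insd", self.outcome_insd, (0, 1)),
            ("outcome_sba", self.outcome_sba, (0, 1)),
            ("hh_head_age", self.hh_head_age, HH_HEAD_AGE_LEVELS),
            ("hh_head_sex", self.hh_head_sex, HH_HEAD_SEX_LEVELS),
            ("education", self.education, EDUCATION_LEVELS),
            ("parity", self.parity, PARITY_LEVELS),
            ("anc_visits", self.anc_visits, ANC_LEVELS),
            ("media", self.media, MEDIA_LEVELS),
            ("wealth_quintile", self.wealth_quintile, WEALTH_LEVELS),
            ("residence", self.residence, RESIDENCE_LEVELS),
        )
        for name, value, allowed in checks:
            if value not in allowed:
                raise ValidationError(f"{name}={value!r} not in {allowed}")


def effective_sample_size(raw_n: float, design_effect: float = 2.0) -> float:
    """Deflate a cluster-survey sample size to an effective SRS size.

    The default design effect of 2.0 is typical for two-stage cluster
    household surveys.
    """
    if raw_n <= 0:
        raise ValueError("raw_n must be positive")
    if design_effect <= 0:
        raise ValueError("design_effect must be positive")
    return raw_n / design_effect


def _read_rows(path: str | Path, expected_header: Sequence[str]) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(expected_header):
            raise ValidationError(
                f"header mismatch in {path}: expected {list(expected_header)}, "
                f"got {reader.fieldnames}"
            )
        return list(reader)


SURVEY_COLUMNS = (
    "country_iso", "region", "survey_year", "source",
    "stratum", "outcome", "coverage", "n_effective",
)


def load_survey_points(
    path: str | Path, schema_strict: bool = True
) -> list[SurveyPoint]:
    """Read survey coverage points from CSV, validating every row.

    In strict mode any invalid row aborts the load with a
    :class:`ValidationError` naming the offending data rows (1-based).  In
    lenient mode invalid rows are skipped and reported via ``warnings``.
    Duplicate (country, year, stratum, outcome, source) keys are always an
    error.
    """
    import warnings

    points: list[SurveyPoint] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(_read_rows(path, SURVEY_COLUMNS), start=1):
        try:
            sp = SurveyPoint(
                country_iso=row["country_iso"],
                region=row["region"],
                survey_year=int(row["survey_year"]),
                source=row["source"],
                stratum=row["stratum"],
                outcome=row["outcome"],
                coverage=float(row["coverage"]),
                n_effective=float(row["n_effective"]),
            )
            sp.validate()
        except (ValidationError, ValueError, KeyError) as exc:
            bad.append((i, str(exc)))
            continue
        points.append(sp)
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad)
        if schema_strict:
            raise ValidationError(f"invalid survey rows: {msg}", [i for i, _ in bad])
        warnings.warn(f"skipped invalid survey rows: {msg}", stacklevel=2)
    keys = [(p.country_iso, p.survey_year, p.stratum, p.outcome, p.source) for p in points]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate survey keys: {dupes}")
    return points


def write_survey_points(points: Iterable[SurveyPoint], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for p in points:
            writer.writerow([
                p.country_iso, p.region, p.survey_year, p.source,
                p.stratum, p.outcome, repr(p.coverage), repr(p.n_effective),
            ])


def survey_points_to_frame(points: Iterable[SurveyPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points], columns=[f.name for f in _dc_fields(SurveyPoint)])


COVARIATE_COLUMNS = ("country_iso", "year", "sdi", "hrh")


def load_covariates(path: str | Path) -> list[CovariateRow]:
    """Read and validate a country-year SDI/HRH series."""
    rows: list[CovariateRow] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(_read_rows(path, COVARIATE_COLUMNS), start=1):
        try:
            cr = CovariateRow(
                country_iso=row["country_iso"],
                year=int(row["year"]),
                sdi=float(row["sdi"]),
                hrh=float(row["hrh"]),
            )
            cr.validate()
        except (ValidationError, ValueError) as exc:
            bad.append((i, str(exc)))
            continue
        rows.append(cr)
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad)
        raise ValidationError(f"invalid covariate rows: {msg}", [i for i, _ in bad])
    keys = [(r.country_iso, r.year) for r in rows]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate country-year covariate rows: {dupes}")
    return rows


def write_covariates(rows: Iterable[CovariateRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COVARIATE_COLUMNS)
        for r in rows:
            writer.writerow([r.country_iso, r.year, repr(r.sdi), repr(r.hrh)])


def covariate_gaps(
    rows: Sequence[CovariateRow], years: Iterable[int]
) -> list[tuple[str, int]]:
    """List (country, year) pairs missing from the series over ``years``."""
    years = list(years)
    have = {(r.country_iso, r.year) for r in rows}
    countries = sorted({r.country_iso for r in rows})
    return [(c, y) for c in countries for y in years if (c, y) not in have]


def load_printed_predictions() -> list[PrintedPrediction]:
    """Load the packaged fixture of printed national predictions.

    The fixture holds 54 countries x 2 outcomes x 3 years (2000, 2018,
    2030) on the percent scale, exactly as printed, and is verified
    against a recorded SHA-256 checksum at load time.
    """
    ref = resources.files("delivcov.data").joinpath(_TABLE1_RESOURCE)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise FixtureError("printed-predictions fixture missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureError(
            f"printed-predictions fixture corrupted (sha256 {digest})"
        )
    reader = csv.DictReader(raw.decode("utf-8").splitlines())
    cells = [
        PrintedPrediction(
            country_name=row["country_name"],
            country_iso=row["country_iso"],
            region=row["region"],
            outcome=row["outcome"],
            year=int(row["year"]),
            mean=float(row["mean"]),
            cri_low=float(row["cri_low"]),
            cri_high=float(row["cri_high"]),
        )
        for row in reader
    ]
    if len(cells) != 324 or len({c.country_iso for c in cells}) != 54:
        raise FixtureError("printed-predictions fixture has wrong shape")
    return cells


INDIVIDUAL_COLUMNS = (
    "country_iso", "outcome_insd", "outcome_sba", "hh_head_age", "hh_head_sex",
    "education", "parity", "anc_visits", "media", "wealth_quintile", "residence",
)


def load_individuals(path: str | Path) -> list[IndividualRecord]:
    records: list[IndividualRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(_read_rows(path, INDIVIDUAL_COLUMNS), start=1):
        try:
            rec = IndividualRecord(
                country_iso=row["country_iso"],
                outcome_insd=int(row["outcome_insd"]),
                outcome_sba=int(row["outcome_sba"]),
                hh_head_age=row["hh_head_age"],
                hh_head_sex=row["hh_head_sex"],
                education=row["education"],
                parity=row["parity"],
                anc_visits=row["anc_visits"],
                media=row["media"],
                wealth_quintile=row["wealth_quintile"],
                residence=row["residence"],
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            bad.append((i, str(exc)))
            continue
        records.append(rec)
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad)
        raise ValidationError(f"invalid individual rows: {msg}", [i for i, _ in bad])
    return records


def write_individuals(records: Iterable[IndividualRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDIVIDUAL_COLUMNS)
        for r in records:
            writer.writerow([getattr(r, c) for c in INDIVIDUAL_COLUMNS])
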