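"""Synthetic-data generator with known ground truth.

Emulates the statistical structure the pipeline assumes in real DHS/MICS
inputs: 54 countries in 6 regions observed through roughly four surveys
each between 2000 and 2019, binomial sampling of adolescent births with a
cluster design effect, logistic-in-time national trajectories with
partially pooled country intercepts/slopes, urban > rural and rich > poor
gradients on the logit scale, and individual birth records whose outcome
follows a random-intercept logistic model.  Every output is reproducible
from the spec's seed, and truth objects carry the parameters the recovery
tests compare against.

No attempt is made to mimic any real country's values — only the assumed
data-generating structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import registry_io as rio
from .registry_io import CovariateRow, IndividualRecord, SurveyPoint
from .trend_model import inverse_logit

__all__ = [
    "GeneratorSpec",
    "DeterminantTruth",
    "TrendTruth",
    "generate_trajectories",
    "generate_surveys",
    "generate_individuals",
    "write_dataset",
]

_REGION_CYCLE = rio.REGIONS

# Documented covariate marginals for individual records (probabilities per
# level, reference level first).  Chosen as plausible LMIC adolescent-birth
# frequencies; recovery tests do not depend on them.
INDIVIDUAL_MARGINALS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "hh_head_age": (rio.HH_HEAD_AGE_LEVELS, (0.20, 0.40, 0.25, 0.15)),
    "hh_head_sex": (rio.HH_HEAD_SEX_LEVELS, (0.75, 0.25)),
    "education": (rio.EDUCATION_LEVELS, (0.25, 0.35, 0.30, 0.10)),
    "parity": (rio.PARITY_LEVELS, (0.55, 0.25, 0.12, 0.08)),
    "anc_visits": (rio.ANC_LEVELS, (0.15, 0.10, 0.15, 0.20, 0.40)),
    "media": (rio.MEDIA_LEVELS, (0.30, 0.25, 0.45)),
    "wealth_quintile": (rio.WEALTH_LEVELS, (0.2,) * 5),
    "residence": (rio.RESIDENCE_LEVELS, (0.35, 0.65)),
}


@dataclass(frozen=True)
class DeterminantTruth:
    """True log-odds for the individual-level model.

    ``coefficients`` maps "<field>:<level>" (non-reference levels only) to
    a log-odds effect; omitted levels default to zero effect.
    """

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    sigma2_u0: float = 1.71

    def validate(self) -> None:
        if self.sigma2_u0 <= 0:
            raise ValueError("sigma2_u0 must be positive")
        for key in self.coefficients:
            fld, _, level = key.partition(":")
            levels, _ = INDIVIDUAL_MARGINALS[fld]
            if level not in levels[1:]:
                raise ValueError(f"unknown non-reference level {key!r}")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-design and ground-truth parameters for the generator.

    Defaults emulate the multi-country survey setting the pipeline
    targets: 54 countries in 6 regions, ~4 surveys each over 2000-2019
    (~216 survey occasions), 2,000 respondents per survey deflated by a
    design effect of 2, country trajectories rising by about one logit per
    decade from a mid-low base, an urban-rural gap of one logit and a
    monotone wealth gradient.
    """

    n_countries: int = 54
    n_regions: int = 6
    years_observed: tuple[int, int] = (2000, 2019)
    surveys_per_country: int = 4
    mu_alpha: float = -0.4
    mu_beta: float = 1.0
    sigma_alpha: float = 1.0
    sigma_beta: float = 0.3
    gamma_sdi: float = 1.0
    gamma_hrh: float = 0.1
    design_effect: float = 2.0
    n_respondents: int = 2000
    urban_advantage: float = 1.0
    quintile_gradient: float = 0.4
    determinant_truth: DeterminantTruth = field(default_factory=DeterminantTruth)
    outcomes: tuple[str, ...] = ("INSD", "SBA")
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_alpha <= 0 or self.sigma_beta <= 0:
            raise ValueError("hyper-SDs must be positive")
        y0, y1 = self.years_observed
        if not 1900 < y0 <= y1 < 2100:
            raise ValueError("invalid years_observed range")
        if self.urban_advantage < 0:
            raise ValueError("urban_advantage must be >= 0")
        if self.n_countries < 1 or self.surveys_per_country < 1:
            raise ValueError("need at least one country and one survey")
        if self.design_effect <= 0 or self.n_respondents <= 0:
            raise ValueError("design_effect and n_respondents must be positive")
        self.determinant_truth.validate()


@dataclass
class TrendTruth:
    """Ground-truth coverage surface and the parameters that made it."""

    spec: GeneratorSpec
    countries: list[str]
    regions: dict[str, str]
    alpha: dict[str, np.ndarray]  # outcome -> (K,)
    beta: dict[str, np.ndarray]
    covariates: list[CovariateRow]
    _cov: dict[tuple[str, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._cov = {(r.country_iso, r.year): (r.sdi, r.hrh) for r in self.covariates}

    def eta(self, country: str, year: int, outcome: str = "INSD",
            stratum: str = "national") -> float:
        k = self.countries.index(country)
        t = (year - 2000) / 10.0
        sdi, hrh = self._cov[(country, year)]
        e = (self.alpha[outcome][k] + self.beta[outcome][k] * t
             + self.spec.gamma_sdi * sdi + self.spec.gamma_hrh * hrh)
        ua = self.spec.urban_advantage
        if stratum == "urban":
            e += ua / 2.0
        elif stratum == "rural":
            e -= ua / 2.0
        elif stratum in rio.WEALTH_LEVELS:
            j = int(stratum[1])
            e += self.spec.quintile_gradient * (j - 3)
        elif stratum != "national":
            raise ValueError(f"unknown stratum {stratum!r}")
        return float(e)

    def coverage(self, country: str, year: int, outcome: str = "INSD",
                 stratum: str = "national") -> float:
        return float(inverse_logit(self.eta(country, year, outcome, stratum)))


def _country_codes(n: int) -> list[str]:
    # synthetic ISO-like codes S00..S99, stable and disjoint from real ISO3
    return [f"S{i:02d}" for i in range(n)]


def generate_trajectories(spec: GeneratorSpec) -> TrendTruth:
    """Draw country parameters and covariate series; return the truth surface.

    SDI is a smooth increasing series clipped to [0, 1]; HRH a positive
    increasing series.  Country intercepts and slopes come from the stated
    hyper-distributions (degenerate when a hyper-SD is set to ~0).
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    countries = _country_codes(spec.n_countries)
    regions = {
        c: _REGION_CYCLE[i % spec.n_regions] for i, c in enumerate(countries)
    }
    alpha: dict[str, np.ndarray] = {}
    beta: dict[str, np.ndarray] = {}
    for outcome in spec.outcomes:
        alpha[outcome] = rng.normal(spec.mu_alpha, spec.sigma_alpha, spec.n_countries)
        beta[outcome] = rng.normal(spec.mu_beta, spec.sigma_beta, spec.n_countries)

    sdi_start = rng.uniform(0.25, 0.65, spec.n_countries)
    sdi_rate = rng.uniform(0.004, 0.012, spec.n_countries)
    hrh_start = rng.uniform(0.5, 3.0, spec.n_countries)
    hrh_rate = rng.uniform(0.02, 0.10, spec.n_countries)
    covariates = [
        CovariateRow(
            country_iso=c,
            year=y,
            sdi=float(np.clip(sdi_start[i] + sdi_rate[i] * (y - 2000), 0.0, 1.0)),
            hrh=float(hrh_start[i] + hrh_rate[i] * (y - 2000)),
        )
        for i, c in enumerate(countries)
        for y in range(2000, 2031)
    ]
    return TrendTruth(
        spec=spec, countries=countries, regions=regions,
        alpha=alpha, beta=beta, covariates=covariates,
    )


def _survey_years(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Evenly spaced survey occasions with seed-jitter (per country row)."""
    y0, y1 = spec.years_observed
    base = np.linspace(y0, y1, spec.surveys_per_country)
    years = np.empty((spec.n_countries, spec.surveys_per_country), dtype=int)
    for i in range(spec.n_countries):
        jit = rng.integers(-1, 2, spec.surveys_per_country) if y1 > y0 else 0
        yy = np.clip(np.round(base + jit), y0, y1).astype(int)
        # collapse accidental collisions back onto the even grid
        if len(np.unique(yy)) < len(yy):
            yy = np.clip(np.round(base), y0, y1).astype(int)
        years[i] = yy
    return years


def generate_surveys(
    truth: TrendTruth,
    strata: Sequence[str] = ("national",),
    outcomes: Sequence[str] | None = None,
) -> list[SurveyPoint]:
    """Binomial survey observations of the truth surface.

    Each scheduled country-year survey contributes one point per requested
    stratum and outcome, with successes ~ Binomial(n_effective, p*) and
    n_effective = n_respondents / design_effect.
    """
    spec = truth.spec
    outcomes = tuple(outcomes) if outcomes is not None else spec.outcomes
    rng = np.random.Generator(np.random.PCG64(spec.seed + 1))
    years = _survey_years(spec, rng)
    n_eff = max(int(round(spec.n_respondents / spec.design_effect)), 1)
    points: list[SurveyPoint] = []
    for i, c in enumerate(truth.countries):
        for y in years[i]:
            for stratum in strata:
                for outcome in outcomes:
                    p = truth.coverage(c, int(y), outcome, stratum)
                    successes = rng.binomial(n_eff, p)
                    points.append(SurveyPoint(
                        country_iso=c,
                        region=truth.regions[c],
                        survey_year=int(y),
                        source="SYNTH",
                        stratum=stratum,
                        outcome=outcome,
                        coverage=successes / n_eff,
                        n_effective=float(n_eff),
                    ))
    return points


def _design_keys() -> list[str]:
    keys = []
    for fld, (levels, _) in INDIVIDUAL_MARGINALS.items():
        keys.extend(f"{fld}:{lvl}" for lvl in levels[1:])
    return keys


def generate_individuals(
    spec: GeneratorSpec,
    n_per_country: int = 1000,
) -> list[IndividualRecord]:
    """DHS/MICS-style individual birth records with a known outcome model.

    Covariates follow the documented marginal frequency tables; both
    outcome flags are independent Bernoulli draws from the same linear
    predictor ``intercept + u_0i + x'beta`` with country intercepts
    u_0i ~ Normal(0, sigma2_u0).
    """
    spec.validate()
    truth = spec.determinant_truth
    rng = np.random.Generator(np.random.PCG64(spec.seed + 2))
    countries = _country_codes(spec.n_countries)
    u0 = rng.normal(0.0, np.sqrt(truth.sigma2_u0), spec.n_countries)

    records: list[IndividualRecord] = []
    for i, c in enumerate(countries):
        draws = {
            fld: np.asarray(levels)[rng.choice(
                len(levels), size=n_per_country, p=np.asarray(probs) / np.sum(probs)
            )]
            for fld, (levels, probs) in INDIVIDUAL_MARGINALS.items()
        }
        eta = np.full(n_per_country, truth.intercept + u0[i])
        for key, coef in truth.coefficients.items():
            fld, _, level = key.partition(":")
            eta += coef * (draws[fld] == level)
        p = inverse_logit(eta)
        y_insd = rng.binomial(1, p)
        y_sba = rng.binomial(1, p)
        for j in range(n_per_country):
            records.append(IndividualRecord(
                country_iso=c,
                outcome_insd=int(y_insd[j]),
                outcome_sba=int(y_sba[j]),
                hh_head_age=str(draws["hh_head_age"][j]),
                hh_head_sex=str(draws["hh_head_sex"][j]),
                education=str(draws["education"][j]),
                parity=str(draws["parity"][j]),
                anc_visits=str(draws["anc_visits"][j]),
                media=str(draws["media"][j]),
                wealth_quintile=str(draws["wealth_quintile"][j]),
                residence=str(draws["residence"][j]),
            ))
    return records


def write_dataset(
    spec: GeneratorSpec,
    out_dir: str | Path,
    strata: Sequence[str] = ("national",),
    n_individuals_per_country: int = 0,
) -> dict[str, Path]:
    """Generate and write the full CSV dataset plus a provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_trajectories(spec)
    points = generate_surveys(truth, strata=strata)
    paths = {
        "surveys": out / "survey_points.csv",
        "covariates": out / "covariates.csv",
        "metadata": out / "metadata.json",
    }
    rio.write_survey_points(points, paths["surveys"])
    rio.write_covariates(truth.covariates, paths["covariates"])
    if n_individuals_per_country > 0:
        paths["individuals"] = out / "individuals.csv"
        rio.write_individuals(
            generate_individuals(spec, n_individuals_per_country),
            paths["individuals"],
        )
    meta = asdict(spec)
    meta["strata"] = list(strata)
    with paths["metadata"].open("w") as fh:
        json.dump(meta, fh, indent=2, default=list)
    return paths
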