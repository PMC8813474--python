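import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from delivcov import synthetic_data as sd
from delivcov import determinants as det
from delivcov import trend_model as tm
from delivcov.registry_io import load_printed_predictions

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# reduced-but-realistic sampler settings used by the recovery tests
REDUCED = dict(n_iter=3000, n_chains=3, thin=5, burn_in=500)


@pytest.fixture(scope="session")
def printed_predictions():
    return load_printed_predictions()


@pytest.fixture(scope="session")
def recovery_setup():
    """10-country synthetic dataset with known trend parameters, fitted once."""
    spec = sd.GeneratorSpec(
        n_countries=10, surveys_per_country=4,
        gamma_sdi=0.0, gamma_hrh=0.0,
        outcomes=("INSD",), n_respondents=2000, design_effect=2.0, seed=7,
    )
    truth = sd.generate_trajectories(spec)
    points = sd.generate_surveys(truth)
    cfg = tm.McmcConfig(seed=11, use_covariates=False, **REDUCED)
    draws = tm.fit(points, None, cfg)
    return spec, truth, points, draws


@pytest.fixture(scope="session")
def determinant_setup():
    """20,000 synthetic records (10 countries) with known effects, fitted once."""
    truth = sd.DeterminantTruth(
        intercept=-0.5,
        coefficients={"residence:rural": float(np.log(2.0))},
        sigma2_u0=1.5,
    )
    spec = sd.GeneratorSpec(n_countries=10, determinant_truth=truth, seed=3)
    records = sd.generate_individuals(spec, n_per_country=2000)
    cfg = tm.McmcConfig(seed=9, **REDUCED)
    draws = det.fit_determinants(records, cfg)
    return truth, records, draws
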