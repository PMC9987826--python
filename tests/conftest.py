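import numpy as np
import pytest

from trophocc.data_model import (
    BeetleSurvey,
    DetectionRecord,
    Fire,
    PointCovariates,
    StudyDesign,
    SurveyDataset,
)
from trophocc.mcmc import MCMCConfig, PosteriorDraws, _FIXED_EFFECT_NAMES, _GAMMA_NAMES
from trophocc.model_core import ModelParameters
from trophocc.synthetic_data import field_study_params


@pytest.fixture(scope="session")
def study_params() -> ModelParameters:
    """Posterior-mean generating truths used across recovery tests."""
    return field_study_params()


@pytest.fixture()
def tiny_dataset() -> SurveyDataset:
    """Two fires, three points, two model years, handcrafted records."""
    design = StudyDesign(
        fires=(
            Fire("east", 2016, 2, (2017, 2018)),
            Fire("west", 2017, 1, (2018,)),
        ),
        reference_year=2018,
    )
    covariates = {
        "east-p00": PointCovariates(
            "east-p00", "east", 1500.0, 39.0, 0.4,
            {2017: ("6-15", "6-15", "<=5"), 2018: ("6-15", "<=5", "<=5")},
        ),
        "east-p01": PointCovariates(
            "east-p01", "east", 1700.0, 39.1, 0.8,
            {2017: ("16-30", "6-15", "<=5"), 2018: ("16-30", "6-15", "<=5")},
        ),
        "west-p00": PointCovariates(
            "west-p00", "west", 2100.0, 40.2, 0.1,
            {2018: ("31-50", "16-30", "6-15")},
        ),
    }
    detections = [
        # east-p00, 2017: passive non-detections then broadcast detection,
        # with the remaining broadcast intervals censored (removal design)
        DetectionRecord("east", "east-p00", 2017, 1, 0, 0),
        DetectionRecord("east", "east-p00", 2017, 2, 0, 0),
        DetectionRecord("east", "east-p00", 2017, 3, 0, 0),
        DetectionRecord("east", "east-p00", 2017, 4, 1, 1),
        DetectionRecord("east", "east-p00", 2017, 5, 1, None, censored=True),
        DetectionRecord("east", "east-p00", 2017, 6, 1, None, censored=True),
        # east-p00, 2018: all non-detections
        DetectionRecord("east", "east-p00", 2018, 1, 1, 0),
        DetectionRecord("east", "east-p00", 2018, 2, 1, 0),
        DetectionRecord("east", "east-p00", 2018, 3, 1, 0),
        # east-p01 surveyed only in 2018 (2017 missing)
        DetectionRecord("east", "east-p01", 2018, 1, 1, 0),
        DetectionRecord("east", "east-p01", 2018, 2, 1, 1),
        DetectionRecord("east", "east-p01", 2018, 3, 1, None, censored=True),
        # west-p00, 2018
        DetectionRecord("west", "west-p00", 2018, 1, 0, 0),
        DetectionRecord("west", "west-p00", 2018, 2, 0, 0),
        DetectionRecord("west", "west-p00", 2018, 3, 0, 0),
        DetectionRecord("west", "west-p00", 2018, 4, 1, 0),
        DetectionRecord("west", "west-p00", 2018, 5, 1, 0),
        DetectionRecord("west", "west-p00", 2018, 6, 1, 0),
    ]
    beetle = [
        BeetleSurvey("east-p00", 6, 20),
        BeetleSurvey("east-p01", 5, 31),
        BeetleSurvey("west-p00", 6, 12),
    ]
    return SurveyDataset(
        design=design, detections=detections, beetle=beetle, covariates=covariates
    ).validate()


def draws_from_params(params: ModelParameters, n: int = 1) -> PosteriorDraws:
    """A degenerate posterior whose every draw equals ``params``."""
    names = _FIXED_EFFECT_NAMES + ["tau_beta0"] + _GAMMA_NAMES
    values = {
        "alpha0": params.detection.alpha0,
        "alpha_type": params.detection.alpha_type,
        "beta_elev": params.occupancy.beta_elev,
        "beta_lat": params.occupancy.beta_lat,
        "beta_snag": params.occupancy.beta_snag,
        "beta_beetle": params.occupancy.beta_beetle,
        "beta_age_x_beetle": params.occupancy.beta_age_x_beetle,
        "phi": params.occupancy.phi,
        "mu_beta0": params.occupancy.mu_beta0,
        "tau_beta0": params.occupancy.tau_beta0,
        "gamma0": params.beetle.gamma0,
        "gamma_age": params.beetle.gamma_age,
        "gamma_pine": params.beetle.gamma_pine,
        "gamma_age_x_pine": params.beetle.gamma_age_x_pine,
    }
    row = np.array([values[name] for name in names])
    draws = np.tile(row, (1, n, 1))
    return PosteriorDraws(names=names, draws=draws, config=MCMCConfig(seed=0))
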