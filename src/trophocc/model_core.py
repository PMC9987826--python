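"""Deterministic skeleton of the multi-trophic occupancy model.

Three logit-linear components:

* detection:   logit(p) = alpha0 + alpha_type * type            (type: 0 passive, 1 broadcast)
* occupancy:   logit(psi_jt) = beta0_fire(j) + beta_elev*elev_j + beta_lat*lat_j
               + beta_snag*snag_jt + beta_beetle*intensity_jt
               + beta_ageXbeetle*age_jt*intensity_jt [+ phi*z_{j,t-1}]
* beetle sign: logit(intensity_jt) = gamma0 + gamma_age*age_jt
               + gamma_pine*pine_j + gamma_ageXpine*age_jt*pine_j

Beetle sign intensity is a deterministic function of the gamma parameters
and covariates (no residual noise); parameter uncertainty flows through the
gammas.  The autologistic phi term carries last year's true occurrence into
this year's occupancy logit and applies from each point's second post-fire
year onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "DetectionParams",
    "OccupancyParams",
    "BeetleParams",
    "ModelParameters",
    "inv_logit",
    "detection_prob",
    "beetle_intensity",
    "occupancy_logit",
    "occupancy_prob",
]


def inv_logit(x):
    """Numerically stable inverse logit (never exponentiates large args)."""
    return expit(x)


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class DetectionParams:
    """Logit-scale detection intercept and broadcast effect."""

    alpha0: float = 0.0
    alpha_type: float = 0.0

    def __post_init__(self):
        _check_finite("alpha0", self.alpha0)
        _check_finite("alpha_type", self.alpha_type)


@dataclass(frozen=True)
class OccupancyParams:
    """Occupancy slopes, autologistic term, and fire-level intercepts.

    ``beta0`` holds one intercept per fire (design order); ``mu_beta0`` and
    ``tau_beta0`` are the hyper-mean and hyper-precision of the normal the
    intercepts are drawn from.
    """

    beta0: np.ndarray = field(default_factory=lambda: np.zeros(1))
    mu_beta0: float = 0.0
    tau_beta0: float = 1.0
    beta_elev: float = 0.0
    beta_lat: float = 0.0
    beta_snag: float = 0.0
    beta_beetle: float = 0.0
    beta_age_x_beetle: float = 0.0
    phi: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "beta0", np.atleast_1d(np.asarray(self.beta0, dtype=float)))
        for name in ("mu_beta0", "beta_elev", "beta_lat", "beta_snag",
                     "beta_beetle", "beta_age_x_beetle", "phi"):
            _check_finite(name, getattr(self, name))
        _check_finite("beta0", self.beta0)
        if not self.tau_beta0 > 0:
            raise ValueError(f"tau_beta0 must be > 0, got {self.tau_beta0}")


@dataclass(frozen=True)
class BeetleParams:
    """Beetle sign-intensity submodel coefficients (logit scale)."""

    gamma0: float = 0.0
    gamma_age: float = 0.0
    gamma_pine: float = 0.0
    gamma_age_x_pine: float = 0.0

    def __post_init__(self):
        for name in ("gamma0", "gamma_age", "gamma_pine", "gamma_age_x_pine"):
            _check_finite(name, getattr(self, name))


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the joint model."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    occupancy: OccupancyParams = field(default_factory=OccupancyParams)
    beetle: BeetleParams = field(default_factory=BeetleParams)

    def with_beta0(self, beta0: np.ndarray) -> "ModelParameters":
        return replace(self, occupancy=replace(self.occupancy, beta0=beta0))


def detection_prob(params: DetectionParams, survey_type: int) -> float:
    """Per-interval detection probability given survey type (0/1)."""
    if survey_type not in (0, 1):
        raise ValueError(f"survey_type must be 0 or 1, got {survey_type}")
    return float(inv_logit(params.alpha0 + params.alpha_type * survey_type))


def beetle_intensity(params: BeetleParams, age, pine):
    """Latent beetle sign intensity in (0, 1).

    ``age`` is years since fire on the scale used at fitting time
    (standardized by default); ``pine`` is the proportion of sampled trees
    of genus *Pinus*, on [0, 1].
    """
    lp = (params.gamma0
          + params.gamma_age * np.asarray(age, dtype=float)
          + params.gamma_pine * np.asarray(pine, dtype=float)
          + params.gamma_age_x_pine * np.asarray(age, dtype=float) * np.asarray(pine, dtype=float))
    return inv_logit(lp)


def occupancy_logit(
    params: OccupancyParams,
    *,
    elev,
    lat,
    snag,
    age,
    intensity,
    beta0=None,
    z_prev=None,
):
    """Logit-scale occupancy linear predictor.

    ``beta0`` selects the fire intercept (defaults to the hyper-mean
    ``mu_beta0`` for population-level predictions).  ``z_prev`` is last
    year's true occurrence; when absent the first-post-fire-year form (no
    autologistic term) applies.
    """
    if beta0 is None:
        beta0 = params.mu_beta0
    lp = (np.asarray(beta0, dtype=float)
          + params.beta_elev * np.asarray(elev, dtype=float)
          + params.beta_lat * np.asarray(lat, dtype=float)
          + params.beta_snag * np.asarray(snag, dtype=float)
          + params.beta_beetle * np.asarray(intensity, dtype=float)
          + params.beta_age_x_beetle * np.asarray(age, dtype=float) * np.asarray(intensity, dtype=float))
    if z_prev is not None:
        lp = lp + params.phi * np.asarray(z_prev, dtype=float)
    return lp


def occupancy_prob(
    params: OccupancyParams,
    *,
    elev,
    lat,
    snag,
    age,
    intensity,
    beta0=None,
    z_prev=None,
):
    """Occupancy probability (inverse logit of :func:`occupancy_logit`)."""
    return inv_logit(
        occupancy_logit(
            params, elev=elev, lat=lat, snag=snag, age=age,
            intensity=intensity, beta0=beta0, z_prev=z_prev,
        )
    )
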