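"""Exact joint log-likelihood with latent occurrence marginalized out.

The latent per-point occurrence series z_{j,t} is a two-state chain whose
year-t occupancy probability depends on covariates (and, after the first
post-fire year, on z_{j,t-1} through the autologistic term).  Rather than
sampling z by data augmentation, the likelihood marginalizes it exactly
with a scaled two-state forward recursion; a brute-force enumeration over
all 2^T sequences is provided as an independent oracle for testing.

The beetle observation component is a binomial: the summed 0-8 sign scores
over the sampled snags at a point, with numTrees*8 trials and the
deterministic final-year intensity as success probability.  Because
intensity is shared, the gamma parameters enter both components.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy
from scipy.stats import binom as _binom

from .data_model import (
    BeetleSurvey,
    DetectionRecord,
    ModelInputs,
    PointInputs,
    SurveyDataset,
    build_model_inputs,
)
from .model_core import (
    BeetleParams,
    DetectionParams,
    ModelParameters,
    OccupancyParams,
    beetle_intensity,
    detection_prob,
)

__all__ = [
    "PRIOR_PRECISION",
    "TAU_HYPER_SHAPE",
    "TAU_HYPER_RATE",
    "beetle_loglik",
    "interval_emission",
    "site_marginal_loglik",
    "site_marginal_loglik_enumeration",
    "joint_loglik",
    "log_prior",
    "JointModel",
]

#: Precision of the vague N(0, tau=0.1) prior on every fixed effect.
PRIOR_PRECISION = 0.1
#: Gamma hyperprior (shape, rate) on the fire-intercept precision tau_beta0.
TAU_HYPER_SHAPE = 0.1
TAU_HYPER_RATE = 0.1


# ---------------------------------------------------------------------------
# Scalar reference path (one point at a time)
# ---------------------------------------------------------------------------

def beetle_loglik(
    params: BeetleParams,
    survey: BeetleSurvey,
    *,
    age,
    pine: float,
) -> float:
    """Binomial log-likelihood of one point's summed beetle sign score.

    ``age`` is the point's final-year fire age on the fitting scale, so the
    intensity used here is the same deterministic quantity that enters the
    occupancy model at t = T.
    """
    trials = survey.trials
    if not 0 <= survey.activity <= trials:
        raise ValueError(
            f"activity {survey.activity} outside [0, {trials}] for "
            f"num_trees={survey.num_trees}"
        )
    intensity = float(beetle_intensity(params, age, pine))
    return float(_binom.logpmf(survey.activity, trials, intensity))


def interval_emission(
    params: DetectionParams,
    records: list[DetectionRecord],
    z: int,
) -> float:
    """Probability of a point-year's interval outcomes given occurrence z.

    Censored intervals (removal design) are excluded.  With z = 0 detection
    is impossible, so the emission is 1 when every conducted interval is a
    non-detection and 0 otherwise.  A point-year with no conducted intervals
    returns 1 (emission-free year).
    """
    if z not in (0, 1):
        raise ValueError(f"z must be 0 or 1, got {z}")
    active = [r for r in records if not r.censored]
    if z == 0:
        return 0.0 if any(r.detected == 1 for r in active) else 1.0
    prob = 1.0
    for r in active:
        p = detection_prob(params, r.survey_type)
        prob *= p if r.detected == 1 else (1.0 - p)
    return prob


def _emission_from_counts(
    det: DetectionParams, point: PointInputs, t: int, z: int
) -> float:
    """Interval emission at model year t (1-based) from per-type counts."""
    i = t - 1
    if z == 0:
        return 0.0 if (point.det_b[i] + point.det_p[i]) > 0 else 1.0
    p_b = detection_prob(det, 1)
    p_p = detection_prob(det, 0)
    return (
        p_b ** point.det_b[i]
        * (1.0 - p_b) ** point.nd_b[i]
        * p_p ** point.det_p[i]
        * (1.0 - p_p) ** point.nd_p[i]
    )


def _site_base_logit(
    params: ModelParameters, point: PointInputs, t: int
) -> float:
    occ = params.occupancy
    i = t - 1
    intensity = float(
        beetle_intensity(params.beetle, point.age_s[i], point.pine)
    )
    beta0 = occ.beta0[point.fire_index] if occ.beta0.size > 1 else occ.beta0[0]
    return float(
        beta0
        + occ.beta_elev * point.elev
        + occ.beta_lat * point.lat
        + occ.beta_snag * point.snag[i]
        + occ.beta_beetle * intensity
        + occ.beta_age_x_beetle * point.age_s[i] * intensity
    )


def site_marginal_loglik(params: ModelParameters, point: PointInputs) -> float:
    """Log marginal likelihood of one point's detection history.

    Exact sum over all latent occurrence sequences from the point's first
    post-fire year through t = T, computed by the two-state forward
    recursion (no Monte Carlo).  The first modeled year uses the
    no-autologistic form; later years add phi * z_prev on the logit scale.
    """
    det, occ = params.detection, params.occupancy
    ll = 0.0
    f0 = f1 = 0.0
    for t in range(point.t_start, point.T + 1):
        base = _site_base_logit(params, point, t)
        psi0 = float(expit(base))
        psi1 = float(expit(base + occ.phi))
        if t == point.t_start:
            g1, g0 = psi0, 1.0 - psi0
        else:
            g1 = f0 * psi0 + f1 * psi1
            g0 = f0 * (1.0 - psi0) + f1 * (1.0 - psi1)
        h1 = g1 * _emission_from_counts(det, point, t, 1)
        h0 = g0 * _emission_from_counts(det, point, t, 0)
        s = h0 + h1
        if s <= 0.0:
            return -math.inf
        ll += math.log(s)
        f0, f1 = h0 / s, h1 / s
    return ll


def site_marginal_loglik_enumeration(
    params: ModelParameters, point: PointInputs
) -> float:
    """Brute-force oracle: sum over all 2^(T - t_start + 1) z-sequences."""
    det, occ = params.detection, params.occupancy
    years = range(point.t_start, point.T + 1)
    total = 0.0
    for zs in itertools.product((0, 1), repeat=len(list(years))):
        prob = 1.0
        z_prev = None
        for t, z in zip(range(point.t_start, point.T + 1), zs):
            base = _site_base_logit(params, point, t)
            if z_prev is not None:
                base += occ.phi * z_prev
            psi = float(expit(base))
            prob *= psi if z == 1 else (1.0 - psi)
            prob *= _emission_from_counts(det, point, t, z)
            z_prev = z
        total += prob
    if total <= 0.0:
        return -math.inf
    return math.log(total)


def joint_loglik(
    params: ModelParameters,
    data: SurveyDataset | ModelInputs,
) -> float:
    """Joint log-likelihood: detection-history marginals + beetle binomials.

    Beetle intensity is recomputed from the current gamma parameters for
    both components, so a gamma perturbation moves the occupancy component
    as well as the binomial one.
    """
    inputs = data if isinstance(data, ModelInputs) else build_model_inputs(data)
    model = JointModel(inputs)
    return model.loglik(params)


def _normal_logpdf(x, precision: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(0.5 * (np.log(precision) - np.log(2.0 * np.pi))
                        - 0.5 * precision * x * x))


def log_prior(params: ModelParameters) -> float:
    """Log prior density of the full parameter vector.

    Every fixed effect (detection, occupancy slopes, gammas), phi, and the
    intercept hyper-mean mu_beta0 gets the vague Normal(0, precision 0.1);
    each fire intercept is Normal(mu_beta0, tau_beta0); tau_beta0 gets a
    vague Gamma(0.1, 0.1) hyperprior.
    """
    occ = params.occupancy
    if not occ.tau_beta0 > 0:
        return -math.inf
    fixed = np.array([
        params.detection.alpha0, params.detection.alpha_type,
        occ.beta_elev, occ.beta_lat, occ.beta_snag,
        occ.beta_beetle, occ.beta_age_x_beetle, occ.phi, occ.mu_beta0,
        params.beetle.gamma0, params.beetle.gamma_age,
        params.beetle.gamma_pine, params.beetle.gamma_age_x_pine,
    ])
    lp = _normal_logpdf(fixed, PRIOR_PRECISION)
    lp += float(np.sum(
        0.5 * (np.log(occ.tau_beta0) - np.log(2.0 * np.pi))
        - 0.5 * occ.tau_beta0 * (occ.beta0 - occ.mu_beta0) ** 2
    ))
    a, b = TAU_HYPER_SHAPE, TAU_HYPER_RATE
    lp += (a * math.log(b) - math.lgamma(a)
           + (a - 1.0) * math.log(occ.tau_beta0) - b * occ.tau_beta0)
    return lp


# ---------------------------------------------------------------------------
# Vectorized path (all points at once) used by the sampler
# ---------------------------------------------------------------------------

class JointModel:
    """Vectorized likelihood evaluator over a fixed ModelInputs.

    Exposes the components the blockwise sampler needs so unchanged pieces
    (interval emissions, intensity, covariate terms) can be cached across
    Metropolis proposals.  All per-point quantities are returned as vectors;
    sums happen at the caller.
    """

    def __init__(self, inputs: ModelInputs):
        self.inputs = inputs
        self.n = inputs.n_points
        self.T = inputs.T
        self._t_start = inputs.t_start
        self._started = np.stack(
            [inputs.t_start <= t for t in range(1, self.T + 1)], axis=1
        )  # (n, T)
        self._init = np.stack(
            [inputs.t_start == t for t in range(1, self.T + 1)], axis=1
        )
        self._em0 = np.where(inputs.any_det, 0.0, 1.0)
        # log binomial coefficients of the beetle observations (constant)
        k, m = inputs.beetle_activity, inputs.beetle_trials
        self._log_choose = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
        self._cov_static = None  # cache key: (beta_elev, beta_lat, beta_snag)

    # -- components --------------------------------------------------------

    def emissions(self, det: DetectionParams) -> np.ndarray:
        """(n, T) emission probability of the observed intervals given z=1."""
        p_b = expit(det.alpha0 + det.alpha_type)
        p_p = expit(det.alpha0)
        i = self.inputs
        # xlogy/xlog1py keep zero-count cells at 0 even when p saturates
        log_em = (xlogy(i.det_b, p_b) + xlog1py(i.nd_b, -p_b)
                  + xlogy(i.det_p, p_p) + xlog1py(i.nd_p, -p_p))
        return np.exp(log_em)

    @property
    def em0(self) -> np.ndarray:
        """(n, T) emission given z=0: 1 unless a detection was recorded."""
        return self._em0

    def intensity(self, beetle: BeetleParams) -> np.ndarray:
        """(n, T) deterministic beetle sign intensity."""
        i = self.inputs
        lp = (beetle.gamma0
              + beetle.gamma_age * i.age_s
              + beetle.gamma_pine * i.pine[:, None]
              + beetle.gamma_age_x_pine * i.age_s * i.pine[:, None])
        return expit(lp)

    def covariate_term(self, occ: OccupancyParams) -> np.ndarray:
        """(n, T) elevation + latitude + snag part of the occupancy logit."""
        i = self.inputs
        return ((occ.beta_elev * i.elev + occ.beta_lat * i.lat)[:, None]
                + occ.beta_snag * i.snag)

    def beetle_term(self, occ: OccupancyParams, intensity: np.ndarray) -> np.ndarray:
        """(n, T) intensity + age-by-intensity part of the occupancy logit."""
        return (occ.beta_beetle * intensity
                + occ.beta_age_x_beetle * self.inputs.age_s * intensity)

    def occupancy_base(
        self, occ: OccupancyParams, intensity: np.ndarray
    ) -> np.ndarray:
        """(n, T) occupancy logit excluding the autologistic term."""
        beta0 = occ.beta0
        if beta0.size == 1:
            beta0 = np.full(self.inputs.n_fires, float(beta0[0]))
        return (beta0[self.inputs.fire_index][:, None]
                + self.covariate_term(occ)
                + self.beetle_term(occ, intensity))

    # -- likelihoods -------------------------------------------------------

    def site_logliks_from(
        self, em1: np.ndarray, base: np.ndarray, phi: float
    ) -> np.ndarray:
        """(n,) forward-recursion marginal log-likelihood per point."""
        psi0 = expit(base)
        psi1 = expit(base + phi)
        ll = np.zeros(self.n)
        f0 = np.ones(self.n)
        f1 = np.zeros(self.n)
        em0 = self._em0
        for t in range(self.T):
            started = self._started[:, t]
            init = self._init[:, t]
            g1 = np.where(init, psi0[:, t], f0 * psi0[:, t] + f1 * psi1[:, t])
            g0 = np.where(init, 1.0 - psi0[:, t],
                          f0 * (1.0 - psi0[:, t]) + f1 * (1.0 - psi1[:, t]))
            h1 = g1 * em1[:, t]
            h0 = g0 * em0[:, t]
            s = h0 + h1
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(started, np.log(s), 0.0)
                safe = np.where(s > 0.0, s, 1.0)
                f0 = np.where(started, h0 / safe, f0)
                f1 = np.where(started, h1 / safe, f1)
            ll += step
        return ll

    def site_logliks(self, params: ModelParameters) -> np.ndarray:
        em1 = self.emissions(params.detection)
        inten = self.intensity(params.beetle)
        base = self.occupancy_base(params.occupancy, inten)
        return self.site_logliks_from(em1, base, params.occupancy.phi)

    def beetle_logliks(
        self, beetle: BeetleParams, intensity: np.ndarray | None = None
    ) -> np.ndarray:
        """(m,) binomial log-likelihood per beetle-surveyed point (at t=T)."""
        i = self.inputs
        if i.beetle_point.size == 0:
            return np.zeros(0)
        if intensity is None:
            intensity = self.intensity(beetle)
        p = intensity[i.beetle_point, self.T - 1]
        k, m = i.beetle_activity, i.beetle_trials
        return (self._log_choose + k * np.log(p) + (m - k) * np.log1p(-p))

    def loglik(self, params: ModelParameters) -> float:
        inten = self.intensity(params.beetle)
        em1 = self.emissions(params.detection)
        base = self.occupancy_base(params.occupancy, inten)
        site = self.site_logliks_from(em1, base, params.occupancy.phi)
        return float(site.sum() + self.beetle_logliks(params.beetle, inten).sum())

    def log_posterior(self, params: ModelParameters) -> float:
        lp = log_prior(params)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.loglik(params)
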