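"""Forward simulation of the full study from the model's own generative process.

Reproduces the field design — 22 fires burned 2008-2017 in the Sierra
Nevada / Southern Cascades, 4-6 beetle-survey points each (128 total),
staggered woodpecker survey years with gaps, beetle surveys only in the
2018 reference year — and simulates covariates, latent occurrence
sequences, removal-design detection histories, and binomial beetle
activity scores.  The true latent states are returned alongside the
dataset so recovery and calibration tests can score against them.

Covariate distributions are stated assumptions (the field covariates are
not recoverable from summaries): fire-level elevation and latitude are
uniform over the study region's extent with small within-fire jitter, pine
proportion is Beta(2, 2) by default, and snag-count categories drift
downward with fire age as snags fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    MAX_SCORE_PER_TREE,
    SNAG_CATEGORY_VALUES,
    BeetleSurvey,
    DetectionRecord,
    Fire,
    PointCovariates,
    StudyDesign,
    SurveyDataset,
    build_model_inputs,
)
from .likelihood import JointModel
from .model_core import ModelParameters, DetectionParams, OccupancyParams, BeetleParams

__all__ = [
    "TABLE1_LAYOUT",
    "CovariateModel",
    "GeneratorConfig",
    "field_study_params",
    "make_table1_design",
    "make_staggered_design",
    "simulate_dataset",
    "simulate_beetle_dataset",
]

#: The published fire-level layout: (fire, year burned, beetle points,
#: woodpecker survey years).  Every fire was surveyed in 2018.
TABLE1_LAYOUT: tuple[tuple[str, int, int, tuple[int, ...]], ...] = (
    ("Aspen", 2013, 6, (2014, 2015, 2016, 2017, 2018)),
    ("Bald", 2014, 6, (2015, 2016, 2017, 2018)),
    ("Barry Point", 2012, 6, (2013, 2014, 2015, 2018)),
    ("Clark", 2016, 6, (2017, 2018)),
    ("Cold", 2008, 6, (2012, 2013, 2014, 2016, 2017, 2018)),
    ("Cougar", 2011, 6, (2012, 2014, 2015, 2018)),
    ("Cove", 2017, 6, (2018,)),
    ("Fox", 2008, 6, (2011, 2013, 2014, 2015, 2016, 2017, 2018)),
    ("Frog", 2015, 6, (2016, 2017, 2018)),
    ("George", 2012, 5, (2013, 2014, 2015, 2016, 2017, 2018)),
    ("Granite", 2009, 6, (2010, 2011, 2013, 2014, 2015, 2016, 2017, 2018)),
    ("Lion", 2009, 6, (2010, 2011, 2013, 2014, 2015, 2016, 2017, 2018)),
    ("Minerva 5", 2017, 6, (2018,)),
    ("Onion 2", 2008, 5, (2010, 2011, 2012, 2013, 2014, 2015, 2016, 2017, 2018)),
    ("Owens River", 2016, 6, (2017, 2018)),
    ("Peak", 2012, 6, (2015, 2016, 2017, 2018)),
    ("Pier", 2017, 6, (2018,)),
    ("Railroad", 2017, 6, (2018,)),
    ("Rough", 2015, 4, (2017, 2018)),
    ("Scotch", 2008, 6, (2009, 2010, 2012, 2013, 2014, 2015, 2018)),
    ("Soup 2", 2016, 6, (2017, 2018)),
    ("Steele", 2017, 6, (2018,)),
)

_SNAG_CATS = list(SNAG_CATEGORY_VALUES)  # ordered low -> high


def make_table1_design() -> StudyDesign:
    """The exact 22-fire, 128-point study layout with reference year 2018."""
    fires = tuple(
        Fire(fire_id=name, year_burned=burned, n_points=n, survey_years=years)
        for name, burned, n, years in TABLE1_LAYOUT
    )
    return StudyDesign(fires=fires, reference_year=2018)


def make_staggered_design(
    n_fires: int,
    points_per_fire: int = 6,
    reference_year: int = 2018,
    burn_years: Sequence[int] = tuple(range(2008, 2018)),
    survey_reference_only: bool = False,
) -> StudyDesign:
    """Enlarged design with fire ages staggered like the field layout.

    Fire i burns ``burn_years[i % len(burn_years)]``; every post-fire year
    (or only the reference year, for beetle-submodel experiments) is
    surveyed.
    """
    fires = []
    for i in range(n_fires):
        burned = int(burn_years[i % len(burn_years)])
        if survey_reference_only:
            years: tuple[int, ...] = (reference_year,)
        else:
            years = tuple(range(burned + 1, reference_year + 1))
        fires.append(Fire(f"F{i:03d}", burned, points_per_fire, years))
    return StudyDesign(fires=tuple(fires), reference_year=reference_year)


def field_study_params(tau_beta0: float = 1.0) -> ModelParameters:
    """Posterior-mean estimates from the original 22-fire field study.

    Used as the default generating truths for simulation experiments.  The
    between-fire intercept precision was not reported; the default assumes
    an SD of 1 on the logit scale (``tau_beta0 = 1``).  Covariate-dependent
    coefficients apply to the fitting scale (standardized elevation,
    latitude, snag index and fire age; natural-scale pine and intensity).
    """
    return ModelParameters(
        detection=DetectionParams(alpha0=-5.17, alpha_type=5.47),
        occupancy=OccupancyParams(
            beta0=np.array([-1.27]),
            mu_beta0=-1.27,
            tau_beta0=tau_beta0,
            beta_elev=1.25,
            beta_lat=0.93,
            beta_snag=0.14,
            beta_beetle=0.19,
            beta_age_x_beetle=-0.95,
            phi=0.68,
        ),
        beetle=BeetleParams(
            gamma0=-0.13, gamma_age=0.26, gamma_pine=0.36, gamma_age_x_pine=-0.62
        ),
    )


@dataclass(frozen=True)
class CovariateModel:
    """Distributional assumptions for simulated covariates."""

    elev_range: tuple[float, float] = (1200.0, 2400.0)   # m, fire centers
    elev_jitter_sd: float = 50.0                         # m, within fire
    lat_range: tuple[float, float] = (35.5, 41.5)        # deg N, fire centers
    lat_jitter_sd: float = 0.02
    pine_dist: str = "beta"                              # "beta" | "uniform" | "fixed"
    pine_beta: tuple[float, float] = (2.0, 2.0)
    pine_fixed: float = 0.5                              # used when pine_dist="fixed"
    num_trees_probs: tuple[tuple[int, float], ...] = ((6, 0.85), (5, 0.10), (4, 0.05))
    snag_level_mean: float = 2.5     # initial category index (0..5 scale)
    snag_level_sd: float = 1.0
    snag_drift: float = -0.15        # category index per year as snags fall
    snag_noise_sd: float = 0.4
    # relative offsets of the three diameter classes (small, mid, large)
    snag_class_offsets: tuple[float, float, float] = (0.5, 0.0, -1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs: layout, truths, covariates, seed."""

    design: StudyDesign = field(default_factory=make_table1_design)
    true_params: ModelParameters = field(default_factory=field_study_params)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0


def _draw_pine(rng: np.random.Generator, cm: CovariateModel, n: int) -> np.ndarray:
    if cm.pine_dist == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if cm.pine_dist == "beta":
        a, b = cm.pine_beta
        return rng.beta(a, b, n)
    if cm.pine_dist == "fixed":
        return np.full(n, cm.pine_fixed)
    raise ValueError(f"unknown pine distribution {cm.pine_dist!r}")


def _snag_categories(
    rng: np.random.Generator, cm: CovariateModel, level0: float, age: int
) -> tuple[str, str, str]:
    cats = []
    for off in cm.snag_class_offsets:
        level = (level0 + off + cm.snag_drift * (age - 1)
                 + cm.snag_noise_sd * rng.standard_normal())
        cats.append(_SNAG_CATS[int(np.clip(round(level), 0, len(_SNAG_CATS) - 1))])
    return tuple(cats)  # type: ignore[return-value]


def _simulate_covariates(
    rng: np.random.Generator, design: StudyDesign, cm: CovariateModel
) -> dict[str, PointCovariates]:
    covariates: dict[str, PointCovariates] = {}
    for fire in design.fires:
        elev_c = rng.uniform(*cm.elev_range)
        lat_c = rng.uniform(*cm.lat_range)
        pine = _draw_pine(rng, cm, fire.n_points)
        for k in range(fire.n_points):
            pid = f"{fire.fire_id}-p{k:02d}"
            level0 = cm.snag_level_mean + cm.snag_level_sd * rng.standard_normal()
            cats = {
                year: _snag_categories(rng, cm, level0, year - fire.year_burned)
                for year in fire.survey_years
            }
            covariates[pid] = PointCovariates(
                point_id=pid,
                fire_id=fire.fire_id,
                elevation_m=float(elev_c + cm.elev_jitter_sd * rng.standard_normal()),
                latitude=float(lat_c + cm.lat_jitter_sd * rng.standard_normal()),
                pine_prop=float(pine[k]),
                snag_categories=cats,
            )
    return covariates


def _draw_num_trees(rng: np.random.Generator, cm: CovariateModel) -> int:
    vals = [v for v, _ in cm.num_trees_probs]
    probs = np.array([p for _, p in cm.num_trees_probs])
    return int(rng.choice(vals, p=probs / probs.sum()))


def simulate_dataset(
    config: GeneratorConfig,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Simulate a full dataset plus its latent truth record.

    Covariates are drawn from the covariate model; intensity is the
    deterministic logit-linear function of (standardized) fire age and pine
    proportion; occurrence sequences follow the autologistic occupancy
    process from each point's first post-fire year; interval detections
    follow the passive/broadcast layout (alternating points receive the
    3-interval passive survey before the 3-interval broadcast survey) with
    removal censoring; beetle activity is binomial at the reference year.

    Returns ``(dataset, truth)`` where ``truth`` has one row per modeled
    point-year with the true ``z`` and ``intensity``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    design = config.design
    covariates = _simulate_covariates(rng, design, config.covariates)

    skeleton = SurveyDataset(
        design=design, detections=[], beetle=[], covariates=covariates
    ).validate()
    inputs = build_model_inputs(skeleton)
    model = JointModel(inputs)
    params = config.true_params

    # Fire intercepts: use explicit per-fire values when provided, otherwise
    # draw them from the hierarchical normal.
    occ = params.occupancy
    if occ.beta0.size == inputs.n_fires and inputs.n_fires > 1:
        beta0 = occ.beta0.astype(float)
    else:
        beta0 = occ.mu_beta0 + rng.standard_normal(inputs.n_fires) / np.sqrt(occ.tau_beta0)
    params = params.with_beta0(beta0)

    inten = model.intensity(params.beetle)
    base = model.occupancy_base(params.occupancy, inten)

    n, T = inputs.n_points, inputs.T
    z = np.zeros((n, T), dtype=np.int64)
    u = rng.random((n, T))
    for t in range(1, T + 1):
        i = t - 1
        init = inputs.t_start == t
        act = inputs.t_start < t
        z_prev = z[:, i - 1] if i > 0 else np.zeros(n, dtype=np.int64)
        psi = expit(base[:, i] + params.occupancy.phi * z_prev)
        psi_init = expit(base[:, i])
        psi = np.where(init, psi_init, psi)
        z[:, i] = np.where(init | act, (u[:, i] < psi).astype(np.int64), 0)

    p_b = expit(params.detection.alpha0 + params.detection.alpha_type)
    p_p = expit(params.detection.alpha0)
    detections: list[DetectionRecord] = []
    fire_point_counter: dict[str, int] = {}
    point_ids = inputs.point_ids
    for j, pid in enumerate(point_ids):
        cov = covariates[pid]
        fire = design.fire(cov.fire_id)
        k = fire_point_counter.get(cov.fire_id, 0)
        fire_point_counter[cov.fire_id] = k + 1
        # alternating points get the passive survey before the broadcast one
        types = ([0, 0, 0, 1, 1, 1] if k % 2 == 0 else [1, 1, 1])
        for year in fire.survey_years:
            t = design.model_year(year)
            zjt = int(z[j, t - 1])
            detected_yet = False
            for interval, stype in enumerate(types, start=1):
                if detected_yet:
                    detections.append(DetectionRecord(
                        cov.fire_id, pid, year, interval, stype,
                        detected=None, censored=True))
                    continue
                p = (p_b if stype == 1 else p_p) * zjt
                y = int(rng.random() < p)
                detections.append(DetectionRecord(
                    cov.fire_id, pid, year, interval, stype, detected=y))
                if y == 1:
                    detected_yet = True

    beetle: list[BeetleSurvey] = []
    for j, pid in enumerate(point_ids):
        num_trees = _draw_num_trees(rng, config.covariates)
        trials = num_trees * MAX_SCORE_PER_TREE
        p = float(inten[j, T - 1])
        beetle.append(BeetleSurvey(
            point_id=pid, num_trees=num_trees,
            activity=int(rng.binomial(trials, p)),
        ))

    dataset = SurveyDataset(
        design=design, detections=detections, beetle=beetle, covariates=covariates
    ).validate()

    rows = []
    first_year = design.first_model_year
    for j, pid in enumerate(point_ids):
        for t in range(int(inputs.t_start[j]), T + 1):
            rows.append({
                "point_id": pid,
                "year": first_year + t - 1,
                "z": int(z[j, t - 1]),
                "intensity": float(inten[j, t - 1]),
            })
    truth = pd.DataFrame(rows)
    return dataset, truth


def simulate_beetle_dataset(
    n_points: int,
    true_params: ModelParameters,
    seed: int = 0,
    pine_dist: str = "uniform",
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Beetle-submodel-only experiment: final-year activity at many points.

    Points are spread evenly over ten pseudo-fires burned 2008-2017, so
    final-year fire age is (near-)uniform on {1..10}; pine proportion is
    Uniform(0, 1) by default; every point samples six snags (48 binomial
    trials).  No woodpecker surveys are generated, so fitting this dataset
    exercises only the intensity submodel.
    """
    burn_years = list(range(2008, 2018))
    counts = [n_points // 10 + (1 if i < n_points % 10 else 0) for i in range(10)]
    fires = tuple(
        Fire(f"A{by}", by, c, (2018,))
        for by, c in zip(burn_years, counts) if c > 0
    )
    design = StudyDesign(fires=fires, reference_year=2018)
    cm = CovariateModel(pine_dist=pine_dist, num_trees_probs=((6, 1.0),))
    config = GeneratorConfig(
        design=design, true_params=true_params, covariates=cm, seed=seed
    )
    # suppress woodpecker surveys: keep only the beetle outcome
    dataset, truth = simulate_dataset(config)
    dataset = SurveyDataset(
        design=design, detections=[], beetle=dataset.beetle,
        covariates=dataset.covariates,
    ).validate()
    return dataset, truth
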