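"""Randomized instances for validating the marginal-likelihood machinery.

Used by the property tests and the CLI ``check`` subcommand: draws a
random parameter vector and a random single-point survey layout (series
length, first post-fire year, per-year interval counts and outcomes) so
the forward recursion can be compared against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np

from .data_model import PointInputs
from .model_core import (
    BeetleParams,
    DetectionParams,
    ModelParameters,
    OccupancyParams,
)

__all__ = ["random_point_instance"]


def random_point_instance(
    rng: np.random.Generator, max_T: int = 6
) -> tuple[ModelParameters, PointInputs]:
    """A random parameter vector and a random survey layout for one point."""
    T = int(rng.integers(1, max_T + 1))
    t_start = int(rng.integers(1, T + 1))
    params = ModelParameters(
        detection=DetectionParams(*rng.normal(0, 1.5, 2)),
        occupancy=OccupancyParams(
            beta0=rng.normal(0, 1.0, 1),
            mu_beta0=float(rng.normal(0, 1.0)),
            tau_beta0=float(np.exp(rng.normal(0, 0.5))),
            beta_elev=float(rng.normal(0, 1.0)),
            beta_lat=float(rng.normal(0, 1.0)),
            beta_snag=float(rng.normal(0, 1.0)),
            beta_beetle=float(rng.normal(0, 1.0)),
            beta_age_x_beetle=float(rng.normal(0, 1.0)),
            phi=float(rng.normal(0, 1.0)),
        ),
        beetle=BeetleParams(*rng.normal(0, 0.8, 4)),
    )
    det_b = np.zeros(T, dtype=np.int64)
    nd_b = np.zeros(T, dtype=np.int64)
    det_p = np.zeros(T, dtype=np.int64)
    nd_p = np.zeros(T, dtype=np.int64)
    for t in range(t_start, T + 1):
        if rng.random() < 0.3:
            continue  # missing survey year
        n_b = int(rng.integers(0, 4))
        n_p = int(rng.integers(0, 4))
        det_b[t - 1] = rng.binomial(n_b, 0.4)
        nd_b[t - 1] = n_b - det_b[t - 1]
        det_p[t - 1] = rng.binomial(n_p, 0.2)
        nd_p[t - 1] = n_p - det_p[t - 1]
    point = PointInputs(
        point_id="rnd",
        fire_index=0,
        t_start=t_start,
        T=T,
        elev=float(rng.normal()),
        lat=float(rng.normal()),
        pine=float(rng.random()),
        snag=rng.normal(0, 1, T),
        age_s=rng.normal(0, 1, T),
        det_b=det_b,
        nd_b=nd_b,
        det_p=det_p,
        nd_p=nd_p,
    )
    return params, point
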