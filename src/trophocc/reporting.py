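"""Posterior summaries and prediction curves.

Summaries follow the reporting conventions of the study design this
package implements: posterior means with equal-tailed 95% credible
intervals from the pooled post-burn-in draws, a Gelman-Rubin statistic per
parameter, and an "evidence" flag marking intervals that exclude zero.

Prediction curves evaluate the deterministic model surface per retained
draw over a predictor grid and summarize pointwise:

* occupancy vs. beetle-sign intensity at chosen fire ages (the population
  level intercept ``mu_beta0`` stands in for a specific fire);
* beetle-sign intensity vs. years since fire at chosen pine proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, gelman_rubin
from .model_core import inv_logit

__all__ = [
    "DEFAULT_AGE_SCALING",
    "PredictionCurve",
    "summarize_posterior",
    "predict_occupancy_curve",
    "predict_intensity_curve",
]

# Fallback fire-age standardization over the modeled 1-10 year span
# (mean, sample SD), used when draws carry no stored scaling constants.
_ages = np.arange(1, 11, dtype=float)
DEFAULT_AGE_SCALING: tuple[float, float] = (
    float(_ages.mean()), float(_ages.std(ddof=1))
)
del _ages


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter posterior mean, 95% CI, R-hat, and evidence flag.

    Quantiles are equal-tailed (2.5% / 97.5%) over the pooled post-burn-in
    draws; ``evidence`` is True when both CI bounds share a sign.  R-hat is
    NaN when only one chain was run.
    """
    if draws.draws.size == 0:
        raise ValueError("empty posterior draws")
    try:
        rhat = gelman_rubin(draws)
    except ValueError:
        rhat = {name: math.nan for name in draws.names}
    rows = []
    for name in draws.names:
        x = draws.get(name)
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append({
            "parameter": name,
            "mean": float(x.mean()),
            "lower_95": float(lo),
            "upper_95": float(hi),
            "rhat": rhat[name],
            "evidence": bool(lo > 0) or bool(hi < 0),
        })
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class PredictionCurve:
    """Posterior mean response with a 95% ribbon over a predictor grid."""

    x: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    conditioning: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x": self.x, "mean": self.mean,
             "lower_95": self.lower, "upper_95": self.upper}
        )
        for key, value in self.conditioning.items():
            df[key] = value
        if self.label:
            df["label"] = self.label
        return df


def _summarize_matrix(
    x: np.ndarray, resp: np.ndarray, conditioning: dict[str, float], label: str
) -> PredictionCurve:
    return PredictionCurve(
        x=np.asarray(x, dtype=float),
        mean=resp.mean(axis=0),
        lower=np.quantile(resp, 0.025, axis=0),
        upper=np.quantile(resp, 0.975, axis=0),
        conditioning=conditioning,
        label=label,
    )


def _age_to_fitting_scale(draws: PosteriorDraws, age_years) -> np.ndarray:
    mean, sd = draws.scaling.get("age", DEFAULT_AGE_SCALING)
    return (np.asarray(age_years, dtype=float) - mean) / sd


def predict_occupancy_curve(
    draws: PosteriorDraws,
    age_values,
    intensity_grid,
    conditioning: dict[str, float] | None = None,
    ribbon: str = "partial",
) -> dict[float, PredictionCurve]:
    """Occupancy vs. beetle-sign intensity, one curve per fire age.

    ``conditioning`` fixes standardized elevation, latitude and snag index
    (default 0 = study means); the population-level hyper-mean intercept is
    used.  ``ribbon="partial"`` propagates uncertainty only through
    ``beta_beetle`` and ``beta_age_x_beetle`` (other parameters held at
    their posterior means); ``ribbon="full"`` propagates all of them.
    """
    if ribbon not in ("partial", "full"):
        raise ValueError(f"unknown ribbon mode {ribbon!r}")
    cond = {"elev": 0.0, "lat": 0.0, "snag": 0.0}
    cond.update(conditioning or {})
    grid = np.asarray(intensity_grid, dtype=float)

    cols = {name: draws.get(name) for name in
            ("mu_beta0", "beta_elev", "beta_lat", "beta_snag",
             "beta_beetle", "beta_age_x_beetle")}
    if ribbon == "partial":
        for name in ("mu_beta0", "beta_elev", "beta_lat", "beta_snag"):
            cols[name] = np.full_like(cols[name], cols[name].mean())

    intercept = (cols["mu_beta0"]
                 + cols["beta_elev"] * cond["elev"]
                 + cols["beta_lat"] * cond["lat"]
                 + cols["beta_snag"] * cond["snag"])  # (n_draws,)
    out: dict[float, PredictionCurve] = {}
    for age in np.atleast_1d(age_values):
        age_s = float(_age_to_fitting_scale(draws, age))
        slope = cols["beta_beetle"] + cols["beta_age_x_beetle"] * age_s
        psi = inv_logit(intercept[:, None] + slope[:, None] * grid[None, :])
        out[float(age)] = _summarize_matrix(
            grid, psi, {**cond, "age": float(age)}, label=f"age={age:g}"
        )
    return out


def predict_intensity_curve(
    draws: PosteriorDraws,
    age_grid,
    pine_values,
) -> dict[float, PredictionCurve]:
    """Beetle-sign intensity vs. years since fire, one curve per pine value.

    ``age_grid`` is in natural years since fire (converted internally to
    the fitting scale); ribbons are full 95% intervals.
    """
    pine_values = np.atleast_1d(np.asarray(pine_values, dtype=float))
    if np.any((pine_values < 0) | (pine_values > 1)):
        raise ValueError("pine values must lie in [0, 1]")
    grid = np.asarray(age_grid, dtype=float)
    age_s = _age_to_fitting_scale(draws, grid)
    g0 = draws.get("gamma0")
    ga = draws.get("gamma_age")
    gp = draws.get("gamma_pine")
    gap = draws.get("gamma_age_x_pine")
    out: dict[float, PredictionCurve] = {}
    for pine in pine_values:
        lp = (g0[:, None] + ga[:, None] * age_s[None, :]
              + gp[:, None] * pine + gap[:, None] * age_s[None, :] * pine)
        out[float(pine)] = _summarize_matrix(
            grid, inv_logit(lp), {"pine": float(pine)}, label=f"pine={pine:g}"
        )
    return out
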