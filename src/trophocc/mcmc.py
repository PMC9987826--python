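"""Posterior sampling by adaptive Metropolis-within-Gibbs.

The sampler targets the marginalized joint posterior (latent occurrence
integrated out by the forward recursion in :mod:`trophocc.likelihood`), so
no discrete latent states are sampled.  Updates are blocked by submodel:

* detection block (alpha0, alpha_type) - random-walk Metropolis
* occupancy slopes + autologistic phi - random-walk Metropolis
* per-fire intercepts beta0_j - independent scalar random walks, proposed
  jointly and accepted per fire (fires are conditionally independent)
* hyperparameters (mu_beta0, tau_beta0) - exact conjugate Gibbs draws
* beetle block (gamma0, gamma_age, gamma_pine, gamma_ageXpine) - random
  walk against the binomial beetle likelihood plus the occupancy component
  that shares the intensity

Proposal scales adapt only during burn-in (coordinate spreads from running
moments, an overall log-scale tuned toward the target acceptance rate);
after burn-in the kernel is frozen, so the retained chain has the correct
invariant distribution.  Everything is deterministic given (data, config,
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ModelInputs, SurveyDataset, build_model_inputs
from .likelihood import (
    PRIOR_PRECISION,
    TAU_HYPER_RATE,
    TAU_HYPER_SHAPE,
    JointModel,
)
from .model_core import (
    BeetleParams,
    DetectionParams,
    ModelParameters,
    OccupancyParams,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "param_names",
    "initialize_chains",
    "sample_posterior",
    "gelman_rubin",
    "write_draws",
    "read_draws",
]

_FIXED_EFFECT_NAMES = [
    "alpha0", "alpha_type",
    "beta_elev", "beta_lat", "beta_snag", "beta_beetle", "beta_age_x_beetle",
    "phi", "mu_beta0",
]
_GAMMA_NAMES = ["gamma0", "gamma_age", "gamma_pine", "gamma_age_x_pine"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-management settings.

    Defaults mirror the study configuration: three chains of 50,000
    iterations thinned by 50 after a burn-in of 50,000, retaining 1,000
    draws per chain (3,000 pooled).  Tests and reduced refits override
    these.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 50_000
    thin: int = 50
    seed: int = 0
    adapt_window: int = 50
    target_accept: float = 0.3
    init_spread: float = 0.1

    def __post_init__(self):
        if self.n_iter < 0 or self.n_burnin < 0:
            raise ValueError("n_iter and n_burnin must be >= 0")
        if self.thin < 1 or self.n_iter % self.thin != 0:
            raise ValueError(
                f"thin ({self.thin}) must divide n_iter ({self.n_iter}) evenly"
            )
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must be in (0, 1)")
        if self.init_spread < 0:
            raise ValueError("init_spread must be >= 0")

    @property
    def n_retained_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def n_retained_total(self) -> int:
        return self.n_chains * self.n_retained_per_chain


def param_names(fire_ids: Sequence[str], submodel: str = "joint") -> list[str]:
    """Flat parameter-vector names for a given design and submodel."""
    if submodel == "beetle":
        return list(_GAMMA_NAMES)
    if submodel != "joint":
        raise ValueError(f"unknown submodel {submodel!r}")
    return (_FIXED_EFFECT_NAMES + ["tau_beta0"]
            + [f"beta0[{fid}]" for fid in fire_ids] + _GAMMA_NAMES)


def _params_from_state(
    theta: Mapping[str, float], beta0: np.ndarray
) -> ModelParameters:
    return ModelParameters(
        detection=DetectionParams(theta["alpha0"], theta["alpha_type"]),
        occupancy=OccupancyParams(
            beta0=beta0.copy(),
            mu_beta0=theta["mu_beta0"],
            tau_beta0=theta["tau_beta0"],
            beta_elev=theta["beta_elev"],
            beta_lat=theta["beta_lat"],
            beta_snag=theta["beta_snag"],
            beta_beetle=theta["beta_beetle"],
            beta_age_x_beetle=theta["beta_age_x_beetle"],
            phi=theta["phi"],
        ),
        beetle=BeetleParams(
            theta["gamma0"], theta["gamma_age"],
            theta["gamma_pine"], theta["gamma_age_x_pine"],
        ),
    )


@dataclass
class PosteriorDraws:
    """Retained MCMC samples with chain/iteration indexing."""

    names: list[str]
    draws: np.ndarray  # (n_chains, n_retained, n_params)
    config: MCMCConfig
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    dataset_checksum: str = ""
    accept_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 2 and self.draws.ndim != 3:
            raise ValueError("draws must be (chain, iteration, parameter)")
        if self.draws.ndim == 2:
            self.draws = self.draws[None, :, :]
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter axis does not match names")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter across chains."""
        return self.draws[:, :, self.index(name)].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) table."""
        n_c, n_i, n_p = self.draws.shape
        chain = np.repeat(np.arange(n_c), n_i * n_p)
        iteration = np.tile(np.repeat(np.arange(n_i), n_p), n_c)
        parameter = np.tile(np.array(self.names, dtype=object), n_c * n_i)
        return pd.DataFrame(
            {"chain": chain, "iteration": iteration,
             "parameter": parameter, "value": self.draws.reshape(-1)}
        )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _chain_rng(seed: int, chain: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(chain, purpose))
    )


def initialize_chains(
    config: MCMCConfig,
    data: SurveyDataset | ModelInputs,
    submodel: str = "joint",
) -> list[ModelParameters]:
    """Over-dispersed starting values, deterministic in (seed, chain index).

    Fixed effects start at ``init_spread`` times a draw from their vague
    prior; the intercept precision starts at its hyperprior mean (1) jittered
    on the log scale; fire intercepts scatter around the starting hyper-mean.
    ``init_spread = 0`` collapses every chain to the prior mean (zeros).
    """
    inputs = data if isinstance(data, ModelInputs) else build_model_inputs(data)
    prior_sd = 1.0 / math.sqrt(PRIOR_PRECISION)
    starts = []
    for chain in range(config.n_chains):
        rng = _chain_rng(config.seed, chain, 0)
        s = config.init_spread
        draw = {name: s * prior_sd * rng.standard_normal()
                for name in _FIXED_EFFECT_NAMES + _GAMMA_NAMES}
        tau = float(np.exp(s * rng.standard_normal()))
        draw["tau_beta0"] = tau
        beta0 = draw["mu_beta0"] + s * rng.standard_normal(inputs.n_fires) / math.sqrt(tau)
        starts.append(_params_from_state(draw, beta0))
    return starts


# ---------------------------------------------------------------------------
# Adaptive random-walk machinery
# ---------------------------------------------------------------------------

class _Block:
    """One random-walk block: coordinate list, adaptation state."""

    def __init__(self, name: str, coords: list[str], init_sd: float,
                 target: float):
        self.name = name
        self.coords = coords
        self.target = target
        self.log_scale = 0.0
        self.init_sd = init_sd
        d = len(coords)
        self.count = 0
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self._factor_cache: np.ndarray | None = None
        self.accepts = 0.0
        self.proposals = 0
        self.window_accepts = 0.0
        self.window_proposals = 0
        self.batches = 0

    def _factor(self) -> np.ndarray:
        """Cholesky factor of the (regularized) empirical block covariance.

        Correlated coordinates (e.g. the intensity main effect and its age
        interaction) need joint proposals; axis-aligned steps mix far too
        slowly there.  Until enough burn-in history exists the proposal is
        an isotropic step of ``init_sd``.
        """
        d = len(self.coords)
        if self.count < max(100, 20 * d):
            return np.eye(d) * self.init_sd
        cov = self.m2 / (self.count - 1)
        cov = cov + (1e-10 + 1e-6 * np.trace(cov) / d) * np.eye(d)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-8)))
        return chol * (2.38 / math.sqrt(d))

    def propose_step(self, rng: np.random.Generator) -> np.ndarray:
        if self._factor_cache is None:
            self._factor_cache = self._factor()
        z = rng.standard_normal(len(self.coords))
        return math.exp(self.log_scale) * (self._factor_cache @ z)

    def scalar_sd(self) -> float:
        return math.exp(self.log_scale) * self.init_sd

    def observe(self, values: np.ndarray) -> None:
        self.count += 1
        delta = values - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, values - self.mean)

    def record(self, accepted: float, n: int = 1) -> None:
        self.accepts += accepted
        self.proposals += n
        self.window_accepts += accepted
        self.window_proposals += n

    def adapt(self) -> None:
        if self.window_proposals == 0:
            return
        self.batches += 1
        rate = self.window_accepts / self.window_proposals
        step = min(0.25, 2.0 / math.sqrt(self.batches))
        self.log_scale += step * (rate - self.target)
        self.window_accepts = 0.0
        self.window_proposals = 0
        self._factor_cache = None  # refresh the covariance factor

    @property
    def accept_rate(self) -> float:
        return self.accepts / self.proposals if self.proposals else math.nan


class _ChainState:
    """Cached likelihood components for the current parameter values."""

    def __init__(self, model: JointModel, params: ModelParameters):
        self.model = model
        self.theta: dict[str, float] = {
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
        beta0 = params.occupancy.beta0
        if beta0.size == 1 and model.inputs.n_fires > 1:
            beta0 = np.full(model.inputs.n_fires, float(beta0[0]))
        self.beta0 = beta0.astype(float).copy()
        self.refresh()

    def current_params(self) -> ModelParameters:
        return _params_from_state(self.theta, self.beta0)

    def refresh(self) -> None:
        m = self.model
        p = self.current_params()
        self.em1 = m.emissions(p.detection)
        self.inten = m.intensity(p.beetle)
        self.cov_term = m.covariate_term(p.occupancy)
        self.beetle_term = m.beetle_term(p.occupancy, self.inten)
        self.site_ll = m.site_logliks_from(self.em1, self.base(), p.occupancy.phi)
        self.beetle_ll = m.beetle_logliks(p.beetle, self.inten)

    def base(self) -> np.ndarray:
        return (self.beta0[self.model.inputs.fire_index][:, None]
                + self.cov_term + self.beetle_term)

    def vector(self, names: Sequence[str]) -> np.ndarray:
        out = np.empty(len(names))
        for i, name in enumerate(names):
            if name.startswith("beta0["):
                out[i] = self.beta0[self.model.inputs.fire_ids.index(name[6:-1])]
            else:
                out[i] = self.theta[name]
        return out


def _fixed_effect_prior_delta(new: np.ndarray, old: np.ndarray) -> float:
    return float(-0.5 * PRIOR_PRECISION * (np.sum(new * new) - np.sum(old * old)))


def _run_chain(
    model: JointModel,
    start: ModelParameters,
    config: MCMCConfig,
    chain: int,
    submodel: str,
    fixed: Mapping[str, float],
    names: list[str],
) -> tuple[np.ndarray, dict[str, float]]:
    rng = _chain_rng(config.seed, chain, 1)
    state = _ChainState(model, start)
    for name, value in fixed.items():
        if name.startswith("beta0["):
            state.beta0[model.inputs.fire_ids.index(name[6:-1])] = value
        else:
            state.theta[name] = value
    state.refresh()
    if not np.all(np.isfinite(state.site_ll)) or not np.all(np.isfinite(state.beetle_ll)):
        raise RuntimeError(
            "non-finite log-posterior at initialization; re-seed or reduce init_spread"
        )

    def free(coords: list[str]) -> list[str]:
        return [c for c in coords if c not in fixed]

    det_coords = free(["alpha0", "alpha_type"])
    occ_coords = free(["beta_elev", "beta_lat", "beta_snag",
                       "beta_beetle", "beta_age_x_beetle", "phi"])
    gamma_coords = free(_GAMMA_NAMES)
    fixed_fires = {model.inputs.fire_ids.index(n[6:-1])
                   for n in fixed if n.startswith("beta0[")}
    free_fire_mask = np.array(
        [i not in fixed_fires for i in range(model.inputs.n_fires)]
    )

    blocks: dict[str, _Block] = {}
    if submodel == "joint":
        if det_coords:
            blocks["detection"] = _Block("detection", det_coords, 0.5, config.target_accept)
        if occ_coords:
            blocks["occupancy"] = _Block("occupancy", occ_coords, 0.2, config.target_accept)
        if free_fire_mask.any():
            blocks["intercepts"] = _Block(
                "intercepts", ["beta0"], 0.5, 0.44)
    if gamma_coords:
        blocks["beetle"] = _Block("beetle", gamma_coords, 0.05, config.target_accept)

    n_keep = config.n_retained_per_chain
    out = np.empty((n_keep, len(names)))
    keep_i = 0
    fire_index = model.inputs.fire_index
    n_fires = model.inputs.n_fires

    for it in range(config.n_burnin + config.n_iter):
        adapting = it < config.n_burnin

        # --- detection block ------------------------------------------------
        if "detection" in blocks:
            b = blocks["detection"]
            old = np.array([state.theta[c] for c in b.coords])
            new = old + b.propose_step(rng)
            theta_new = dict(zip(b.coords, new))
            det_new = DetectionParams(
                theta_new.get("alpha0", state.theta["alpha0"]),
                theta_new.get("alpha_type", state.theta["alpha_type"]),
            )
            em1_new = model.emissions(det_new)
            site_new = model.site_logliks_from(em1_new, state.base(), state.theta["phi"])
            delta = (site_new.sum() - state.site_ll.sum()
                     + _fixed_effect_prior_delta(new, old))
            if math.log(rng.random()) < delta:
                state.theta.update(theta_new)
                state.em1 = em1_new
                state.site_ll = site_new
                b.record(1.0)
            else:
                b.record(0.0)
            if adapting:
                b.observe(np.array([state.theta[c] for c in b.coords]))
                if (it + 1) % config.adapt_window == 0:
                    b.adapt()

        # --- occupancy slopes + phi ----------------------------------------
        if "occupancy" in blocks:
            b = blocks["occupancy"]
            old = np.array([state.theta[c] for c in b.coords])
            new = old + b.propose_step(rng)
            theta_new = dict(state.theta)
            theta_new.update(zip(b.coords, new))
            occ_new = _params_from_state(theta_new, state.beta0).occupancy
            cov_new = model.covariate_term(occ_new)
            bt_new = model.beetle_term(occ_new, state.inten)
            base_new = (state.beta0[fire_index][:, None] + cov_new + bt_new)
            site_new = model.site_logliks_from(state.em1, base_new, occ_new.phi)
            delta = (site_new.sum() - state.site_ll.sum()
                     + _fixed_effect_prior_delta(new, old))
            if math.log(rng.random()) < delta:
                state.theta = theta_new
                state.cov_term = cov_new
                state.beetle_term = bt_new
                state.site_ll = site_new
                b.record(1.0)
            else:
                b.record(0.0)
            if adapting:
                b.observe(np.array([state.theta[c] for c in b.coords]))
                if (it + 1) % config.adapt_window == 0:
                    b.adapt()

        # --- per-fire intercepts (parallel scalar updates) -----------------
        if "intercepts" in blocks:
            b = blocks["intercepts"]
            sd = b.scalar_sd()
            step = sd * rng.standard_normal(n_fires)
            step[~free_fire_mask] = 0.0
            beta0_new = state.beta0 + step
            base_new = state.base() + step[fire_index][:, None]
            site_new = model.site_logliks_from(state.em1, base_new, state.theta["phi"])
            per_fire = np.bincount(
                fire_index, weights=site_new - state.site_ll, minlength=n_fires
            )
            mu, tau = state.theta["mu_beta0"], state.theta["tau_beta0"]
            per_fire += -0.5 * tau * ((beta0_new - mu) ** 2 - (state.beta0 - mu) ** 2)
            accept = (np.log(rng.random(n_fires)) < per_fire) & free_fire_mask
            if accept.any():
                state.beta0 = np.where(accept, beta0_new, state.beta0)
                pt_accept = accept[fire_index]
                state.site_ll = np.where(pt_accept, site_new, state.site_ll)
            n_free = int(free_fire_mask.sum())
            b.record(float(accept[free_fire_mask].sum()), n_free)
            if adapting and (it + 1) % config.adapt_window == 0:
                b.adapt()

        # --- hyperparameters: conjugate Gibbs ------------------------------
        if submodel == "joint":
            beta0 = state.beta0
            if "mu_beta0" not in fixed:
                tau = state.theta["tau_beta0"]
                prec = n_fires * tau + PRIOR_PRECISION
                mean = tau * beta0.sum() / prec
                state.theta["mu_beta0"] = mean + rng.standard_normal() / math.sqrt(prec)
            if "tau_beta0" not in fixed:
                mu = state.theta["mu_beta0"]
                shape = TAU_HYPER_SHAPE + 0.5 * n_fires
                rate = TAU_HYPER_RATE + 0.5 * float(np.sum((beta0 - mu) ** 2))
                state.theta["tau_beta0"] = rng.gamma(shape, 1.0 / rate)

        # --- beetle block ---------------------------------------------------
        if "beetle" in blocks:
            b = blocks["beetle"]
            old = np.array([state.theta[c] for c in b.coords])
            new = old + b.propose_step(rng)
            theta_new = dict(state.theta)
            theta_new.update(zip(b.coords, new))
            params_new = _params_from_state(theta_new, state.beta0)
            inten_new = model.intensity(params_new.beetle)
            beetle_ll_new = model.beetle_logliks(params_new.beetle, inten_new)
            delta = (beetle_ll_new.sum() - state.beetle_ll.sum()
                     + _fixed_effect_prior_delta(new, old))
            if submodel == "joint":
                bt_new = model.beetle_term(params_new.occupancy, inten_new)
                base_new = state.beta0[fire_index][:, None] + state.cov_term + bt_new
                site_new = model.site_logliks_from(state.em1, base_new, state.theta["phi"])
                delta += site_new.sum() - state.site_ll.sum()
            if math.log(rng.random()) < delta:
                state.theta = theta_new
                state.inten = inten_new
                state.beetle_ll = beetle_ll_new
                if submodel == "joint":
                    state.beetle_term = bt_new
                    state.site_ll = site_new
                b.record(1.0)
            else:
                b.record(0.0)
            if adapting:
                b.observe(np.array([state.theta[c] for c in b.coords]))
                if (it + 1) % config.adapt_window == 0:
                    b.adapt()

        # --- retain ----------------------------------------------------------
        if not adapting and (it - config.n_burnin + 1) % config.thin == 0:
            out[keep_i] = state.vector(names)
            keep_i += 1

    rates = {name: blk.accept_rate for name, blk in blocks.items()}
    return out, rates


def sample_posterior(
    data: SurveyDataset | ModelInputs,
    config: MCMCConfig,
    submodel: str = "joint",
    fixed: Mapping[str, float] | None = None,
    starts: Sequence[ModelParameters] | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the joint model (or the beetle submodel).

    ``submodel="beetle"`` samples only the gamma block against the binomial
    beetle likelihood, for datasets with no (or ignorable) detection data.
    ``fixed`` freezes named parameters at given values (useful for
    sensitivity checks and low-dimensional validation against quadrature).
    """
    inputs = data if isinstance(data, ModelInputs) else build_model_inputs(data)
    fixed = dict(fixed or {})
    model = JointModel(inputs)
    names = param_names(inputs.fire_ids, submodel)
    if starts is None:
        starts = initialize_chains(config, inputs, submodel)
    if len(starts) != config.n_chains:
        raise ValueError("need one starting value per chain")

    all_draws = np.empty((config.n_chains, config.n_retained_per_chain, len(names)))
    rates_acc: dict[str, list[float]] = {}
    for chain in range(config.n_chains):
        draws, rates = _run_chain(
            model, starts[chain], config, chain, submodel, fixed, names
        )
        all_draws[chain] = draws
        for k, v in rates.items():
            rates_acc.setdefault(k, []).append(v)

    return PosteriorDraws(
        names=names,
        draws=all_draws,
        config=config,
        scaling=dict(inputs.scaling),
        dataset_checksum=inputs.checksum,
        accept_rates={k: float(np.mean(v)) for k, v in rates_acc.items()},
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Potential scale reduction factor per parameter.

    Classic between/within form: with m chains of n retained draws each,
    W = mean within-chain variance, B/n = variance of chain means, and
    R-hat = sqrt(((n-1)/n W + B/n) / W).  Identical chains give values
    <= 1; chains stuck at distinct constants diverge.
    """
    m, n, _ = draws.draws.shape
    if m < 2:
        raise ValueError("Gelman-Rubin statistic requires at least two chains")
    if n < 2:
        raise ValueError("Gelman-Rubin statistic requires at least two draws per chain")
    out = {}
    for i, name in enumerate(draws.names):
        x = draws.draws[:, :, i]
        w = float(np.mean(np.var(x, axis=1, ddof=1)))
        b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
        if w == 0.0:
            out[name] = 1.0 if b_over_n == 0.0 else math.inf
            continue
        var_plus = (n - 1) / n * w + b_over_n
        out[name] = math.sqrt(var_plus / w)
    return out


# ---------------------------------------------------------------------------
# Draws I/O (tidy delimited table + metadata sidecar)
# ---------------------------------------------------------------------------

def write_draws(draws: PosteriorDraws, path: str | Path) -> tuple[Path, Path]:
    """Write draws as a tidy CSV plus a YAML run-metadata sidecar."""
    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(path, index=False)
    meta = {
        "config": {
            "n_chains": draws.config.n_chains,
            "n_iter": draws.config.n_iter,
            "n_burnin": draws.config.n_burnin,
            "thin": draws.config.thin,
            "seed": draws.config.seed,
            "adapt_window": draws.config.adapt_window,
            "target_accept": draws.config.target_accept,
            "init_spread": draws.config.init_spread,
        },
        "dataset_checksum": draws.dataset_checksum,
        "accept_rates": {k: float(v) for k, v in draws.accept_rates.items()},
        "scaling": {k: [float(a), float(b)] for k, (a, b) in draws.scaling.items()},
    }
    meta_path = path.with_suffix(".meta.yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path, meta_path


def read_draws(path: str | Path) -> PosteriorDraws:
    """Read draws written by :func:`write_draws`."""
    import yaml

    path = Path(path)
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["parameter"]))
    n_chains = int(df["chain"].max()) + 1
    n_iter = int(df["iteration"].max()) + 1
    arr = np.empty((n_chains, n_iter, len(names)))
    pos = {n: i for i, n in enumerate(names)}
    arr[df["chain"], df["iteration"], [pos[p] for p in df["parameter"]]] = df["value"]
    meta_path = path.with_suffix(".meta.yaml")
    config = MCMCConfig()
    scaling: dict[str, tuple[float, float]] = {}
    checksum = ""
    rates: dict[str, float] = {}
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        config = MCMCConfig(**meta["config"])
        scaling = {k: (v[0], v[1]) for k, v in meta.get("scaling", {}).items()}
        checksum = meta.get("dataset_checksum", "")
        rates = meta.get("accept_rates", {})
    return PosteriorDraws(
        names=names, draws=arr, config=config, scaling=scaling,
        dataset_checksum=checksum, accept_rates=rates,
    )
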