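"""Synthetic round-robin data generation for recovery studies.

The generating design mirrors the simulation conditions the models were
developed under: a two-dimensional relational construct measured by eight
items (four per dimension), networks of 5-100 members, and weakly
structured truths —

* grand mean ``beta0 ~ N(0, 1)``;
* receiver effects ``beta_R_i ~ N(0, 1)`` truncated positive;
* sender effects drawn from the bivariate-normal conditional given
  ``beta_R_i`` with a per-replication correlation ``rho_beta ~ U(0.1, 0.3)``
  and unit marginal scales;
* trait rows bivariate standard normal with a per-replication
  ``rho_theta ~ U(0.2, 0.3)``;
* distance effects (Model 2 only) ``beta_D_i ~ U(-0.4, 0)``;
* unit residual SDs.

Each directed response is the model mean plus independent Gaussian noise.
Replications derive child seeds from a master seed, so every replication
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DyadicResponseTable, NetworkSpec
from .model import _predicted_means
from .parameters import LidmParameters

__all__ = ["SimConfig", "draw_parameters", "generate_dataset",
           "run_replications", "true_parameter_summary"]


@dataclass(frozen=True)
class SimConfig:
    """Generating-design settings (defaults are the study conditions)."""

    n_members: int = 10
    n_subscales: int = 2
    items_per_subscale: int = 4
    model: int = 1
    replications: int = 1
    mu_S: float = 0.0
    mu_R: float = 0.0
    sigma_S: float = 1.0
    sigma_R: float = 1.0
    rho_beta_range: tuple[float, float] = (0.1, 0.3)
    rho_theta_range: tuple[float, float] = (0.2, 0.3)
    beta_D_range: tuple[float, float] = (-0.4, 0.0)
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.n_members < 3:
            raise ValueError("simulated networks need n >= 3")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if not (self.rho_beta_range[0] < self.rho_beta_range[1]
                and self.rho_theta_range[0] < self.rho_theta_range[1]
                and self.beta_D_range[0] < self.beta_D_range[1] <= 0.0):
            raise ValueError("invalid generating ranges")

    @property
    def n_items(self) -> int:
        return self.n_subscales * self.items_per_subscale

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec.balanced(self.n_members, self.n_subscales,
                                    self.items_per_subscale)


def draw_parameters(cfg: SimConfig, seed) -> LidmParameters:
    """Draw one true-parameter point from the generating distributions.

    ``rho_beta`` and ``rho_theta`` are drawn once per call (they are
    replication-level quantities, not item-level ones).
    """
    rng = np.random.default_rng(seed)
    T = cfg.n_items
    n, L = cfg.n_members, cfg.n_subscales

    beta0 = rng.normal(0.0, 1.0)
    rho_b = rng.uniform(*cfg.rho_beta_range)
    rho_t = rng.uniform(*cfg.rho_theta_range)

    # receiver effects: positive-truncated normal, by rejection
    beta_R = np.empty(T)
    for i in range(T):
        v = rng.normal(cfg.mu_R, cfg.sigma_R)
        while v <= 0.0:
            v = rng.normal(cfg.mu_R, cfg.sigma_R)
        beta_R[i] = v
    # senders from the conditional given the (truncated) receiver draw
    cond_mean = cfg.mu_S + rho_b * (cfg.sigma_S / cfg.sigma_R) * (beta_R - cfg.mu_R)
    cond_sd = cfg.sigma_S * np.sqrt(1.0 - rho_b ** 2)
    beta_S = rng.normal(cond_mean, cond_sd)

    cov = np.full((L, L), rho_t)
    np.fill_diagonal(cov, 1.0)
    theta = rng.multivariate_normal(np.zeros(L), cov, size=n)

    beta_D = rng.uniform(*cfg.beta_D_range, size=T) if cfg.model == 2 else None
    return LidmParameters(
        beta0=beta0, beta_S=beta_S, beta_R=beta_R,
        sigma=np.full(T, cfg.residual_sd), theta=theta,
        rho_theta=rho_t, beta_D=beta_D, rho_beta=rho_b,
        lam=rho_b * cfg.sigma_S / cfg.sigma_R,
        sigma_bS=cfg.sigma_S,
    )


def generate_dataset(params: LidmParameters, cfg: SimConfig,
                     seed) -> DyadicResponseTable:
    """One complete round-robin table: model mean + independent N(0, sigma_i^2)
    noise for every ordered pair x item."""
    rng = np.random.default_rng(seed)
    spec = cfg.network_spec()
    n, T = cfg.n_members, cfg.n_items
    if params.n_members != n or params.n_items != T:
        raise ValueError("parameter point does not match the design")
    s, r = np.nonzero(~np.eye(n, dtype=bool))
    s = np.repeat(s, T)
    r = np.repeat(r, T)
    i = np.tile(np.arange(T), n * (n - 1))
    mu = _predicted_means(cfg.model, params, spec, s, r, i)
    y = mu + rng.normal(0.0, params.sigma[i])
    return DyadicResponseTable.from_arrays(spec, s, r, i, y)


def run_replications(cfg: SimConfig, seed: int
                     ) -> list[tuple[LidmParameters, DyadicResponseTable]]:
    """Independent replications with deterministic per-replication child
    seeds spawned from the master seed."""
    out = []
    master = np.random.SeedSequence(seed)
    for child in master.spawn(cfg.replications):
        p_seed, d_seed = child.spawn(2)
        params = draw_parameters(cfg, p_seed)
        table = generate_dataset(params, cfg, d_seed)
        out.append((params, table))
    return out


def true_parameter_summary(draws: list[LidmParameters]) -> pd.DataFrame:
    """Means and SDs of the simulated truths per parameter class (the
    sanity-check table for a batch of replications)."""
    classes: dict[str, list[float]] = {
        "beta0": [], "B_S": [], "B_R": [], "rho_beta": [],
        "Theta": [], "rho_theta": [], "sigma": [], "B_D": [],
    }
    for p in draws:
        classes["beta0"].append(p.beta0)
        classes["B_S"].extend(p.beta_S)
        classes["B_R"].extend(p.beta_R)
        classes["rho_beta"].append(p.rho_beta)
        classes["Theta"].extend(p.theta.ravel())
        classes["rho_theta"].append(p.rho_theta)
        classes["sigma"].extend(p.sigma)
        if p.beta_D is not None:
            classes["B_D"].extend(p.beta_D)
    rows = []
    for name, vals in classes.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        rows.append({"class": name, "mean": arr.mean(),
                     "sd": arr.std(ddof=1) if len(arr) > 1 else 0.0,
                     "count": len(arr)})
    return pd.DataFrame(rows).set_index("class")
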