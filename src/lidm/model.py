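"""Model objects: construction, likelihood/prior evaluation, and fitting.

The public surface follows the statsmodels idiom: build a
:class:`LatentInterdependenceModel` from a :class:`~lidm.data.DyadicResponseTable`
(or a long-format DataFrame), call :meth:`~LatentInterdependenceModel.fit`,
and work with the returned :class:`LidmResults` (posterior draws, EAPs,
convergence diagnostics, summary table).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import DyadicResponseTable, NetworkSpec
from .parameters import LidmParameters, PriorSpec

__all__ = [
    "LatentInterdependenceModel",
    "LidmResults",
    "FitConfig",
    "euclidean_distance",
    "predict_response",
    "log_likelihood",
    "log_prior",
    "param_names",
]

LOG2PI = float(np.log(2.0 * np.pi))


def euclidean_distance(theta_A, theta_B) -> float:
    """Euclidean distance between two members' latent trait vectors.

    For a single trait dimension this is simply ``|theta_A - theta_B|``.
    """
    a = np.atleast_1d(np.asarray(theta_A, dtype=float))
    b = np.atleast_1d(np.asarray(theta_B, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"trait vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _subscale_of(params: LidmParameters, spec: NetworkSpec, item: int) -> int:
    sub = spec.item_to_subscale[item]
    return sub - 1


def predict_response(model: int, params: LidmParameters, spec: NetworkSpec,
                     item: int, sender: int, receiver: int) -> float:
    """Expected (measurement-error-free) response of ``sender`` about
    ``receiver`` on ``item``; all indices 0-based.

    Model 1: ``beta0 + betaS_i theta_S[l] + betaR_i theta_R[l]``.
    Model 2 adds ``betaD_i * E`` where ``E`` is the Euclidean distance
    between the two members' full trait vectors.
    """
    if sender == receiver:
        raise ValueError("self-ratings are undefined (sender == receiver)")
    if model == 2 and params.beta_D is None:
        raise ValueError("Model 2 prediction requires distance effects beta_D")
    l = _subscale_of(params, spec, item)
    mu = (params.beta0
          + params.beta_S[item] * params.theta[sender, l]
          + params.beta_R[item] * params.theta[receiver, l])
    if model == 2:
        E = euclidean_distance(params.theta[sender], params.theta[receiver])
        mu += params.beta_D[item] * E
    return float(mu)


def _predicted_means(model: int, params: LidmParameters, spec: NetworkSpec,
                     s: np.ndarray, r: np.ndarray, i: np.ndarray) -> np.ndarray:
    """Vectorized predicted means for arrays of directed observations."""
    sub = np.asarray(spec.item_to_subscale)[i] - 1
    mu = (params.beta0
          + params.beta_S[i] * params.theta[s, sub]
          + params.beta_R[i] * params.theta[r, sub])
    if model == 2:
        if params.beta_D is None:
            raise ValueError("Model 2 requires beta_D")
        diff = params.theta[s] - params.theta[r]
        mu = mu + params.beta_D[i] * np.sqrt(np.sum(diff * diff, axis=1))
    return mu


def log_likelihood(model: int, params: LidmParameters,
                   data: DyadicResponseTable) -> float:
    """Gaussian log-likelihood of the full round-robin table.

    Factorizes over every directed response: each observation contributes
    the normal log-density with mean :func:`predict_response` and the
    item's residual SD.
    """
    if np.any(params.sigma <= 0):
        raise ValueError("residual scales must be positive")
    s, r, i, y = data.arrays()
    mu = _predicted_means(model, params, data.spec, s, r, i)
    sd = params.sigma[i]
    z = (y - mu) / sd
    return float(np.sum(-0.5 * LOG2PI - np.log(sd) - 0.5 * z * z))


def log_prior(model: int, params: LidmParameters, priors: PriorSpec) -> float:
    """Joint log-prior density at a parameter point.

    Outside the support (non-positive receiver effect, non-negative
    distance effect, correlation outside (0,1), hyperparameters outside
    their bounds) the result is ``-inf`` — distinct from NaN, which would
    indicate an evaluation failure.

    The residual scales are assigned their density through the gamma prior
    on the precisions ``tau_i = 1/sigma_i^2`` including the change-of-
    variables Jacobian, so the value is an honest log-density over the
    stored (sigma) parameterization.
    """
    var0, lamvar, varD = priors.variances()
    if np.any(params.beta_R <= 0):
        return -np.inf
    if model == 2:
        if params.beta_D is None:
            raise ValueError("Model 2 prior requires beta_D")
        if np.any(params.beta_D >= 0):
            return -np.inf
    if not 0.0 < params.rho_theta < 1.0:
        return -np.inf
    lam = params.lam if params.lam is not None else 0.0
    sbS = params.sigma_bS if params.sigma_bS is not None else max(
        priors.sigma_bS_lo, abs(lam) * priors.sigma_bR + 1e-6)
    if not priors.sigma_bS_lo <= sbS <= priors.sigma_bS_hi:
        return -np.inf
    s2c = sbS ** 2 - lam ** 2 * priors.sigma_bR ** 2
    if s2c <= 0:
        return -np.inf

    lp = stats.norm.logpdf(params.beta0, priors.beta0_loc, np.sqrt(var0))
    # receiver effects: N(0, sigma_bR^2) truncated to (0, inf)
    lp += np.sum(stats.truncnorm.logpdf(
        params.beta_R, 0.0, np.inf, loc=0.0, scale=priors.sigma_bR))
    # sender effects conditional on receiver effects
    lp += np.sum(stats.norm.logpdf(
        params.beta_S, lam * params.beta_R, np.sqrt(s2c)))
    # distance effects: -beta_D lognormal
    if model == 2:
        lp += np.sum(stats.lognorm.logpdf(
            -params.beta_D, np.sqrt(varD), scale=np.exp(priors.logD_loc)))
    # traits: rows iid N(0, equicorrelation(rho_theta)); rho ~ U(0,1)
    lp += float(np.sum(stats.multivariate_normal.logpdf(
        params.theta, mean=np.zeros(params.n_dims),
        cov=params.trait_covariance())))
    # residual precisions with Jacobian d tau / d sigma = 2 / sigma^3
    tau = 1.0 / params.sigma ** 2
    lp += np.sum(stats.gamma.logpdf(tau, priors.tau_shape,
                                    scale=1.0 / priors.tau_rate))
    lp += np.sum(np.log(2.0 / params.sigma ** 3))
    # hyperparameters
    lp += stats.norm.logpdf(lam, 0.0, np.sqrt(lamvar))
    lp += -np.log(priors.sigma_bS_hi - priors.sigma_bS_lo)
    return float(lp)


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.

    The default is a desk-scale configuration (4 chains, 2,000 retained
    draws each after 1,000 warm-up sweeps).  :meth:`reference_settings`
    returns the heavyweight configuration used for definitive runs
    (2 chains of 100,000 sweeps, 50,000 burn-in, thinning 2);
    :meth:`reduced` the short-chain configuration for replicated recovery
    studies.  The sampler mixes conjugate Gibbs and slice updates and
    needs no step-size adaptation, so ``adaptation`` sweeps are simply
    added to the burn-in.
    """

    n_chains: int = 4
    iterations: int = 3000
    burnin: int = 1000
    thin: int = 1
    adaptation: int = 0
    seed: int = 0
    prior_only: bool = False

    def __post_init__(self):
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0) -> "FitConfig":
        return cls(n_chains=2, iterations=1300, burnin=500, thin=1, seed=seed)

    @classmethod
    def reference_settings(cls, seed: int = 0) -> "FitConfig":
        return cls(n_chains=2, iterations=100_000, burnin=50_000, thin=2,
                   adaptation=10_000, seed=seed)


def param_names(n: int, L: int, T: int, model: int) -> list[str]:
    """Packed parameter-vector layout shared by the sampler and results."""
    names = ["beta0"]
    names += [f"beta_S[{i}]" for i in range(1, T + 1)]
    names += [f"beta_R[{i}]" for i in range(1, T + 1)]
    names += [f"sigma[{i}]" for i in range(1, T + 1)]
    names += [f"theta[{a},{l}]" for a in range(1, n + 1) for l in range(1, L + 1)]
    names += ["rho_theta", "lam", "sigma_bS", "rho_beta"]
    if model == 2:
        names += [f"beta_D[{i}]" for i in range(1, T + 1)]
    return names


class LatentInterdependenceModel:
    """Latent interdependence model for one round-robin dataset.

    Parameters
    ----------
    data : DyadicResponseTable
        Complete round-robin item responses.
    model : {1, 2}
        1 = sender/receiver main effects only; 2 adds the (negative)
        latent-distance penalty.
    priors : PriorSpec, optional
        Hyperparameters of the weakly-informative prior system.
    """

    def __init__(self, data: DyadicResponseTable, model: int = 1,
                 priors: PriorSpec | None = None):
        if model not in (1, 2):
            raise ValueError(f"model must be 1 or 2, got {model}")
        if data.spec.n_members < 3:
            raise ValueError(
                "estimation needs at least 3 members (2-member networks can "
                "be represented but not meaningfully fitted)")
        self.data = data
        self.model = model
        self.priors = priors if priors is not None else PriorSpec()
        self.spec = data.spec

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, model: int = 1,
                       priors: PriorSpec | None = None) -> "LatentInterdependenceModel":
        return cls(DyadicResponseTable(frame), model=model, priors=priors)

    # ------------------------------------------------------------- evaluation
    def predict(self, params: LidmParameters, item: int, sender: int,
                receiver: int) -> float:
        return predict_response(self.model, params, self.spec, item, sender,
                                receiver)

    def loglike(self, params: LidmParameters) -> float:
        return log_likelihood(self.model, params, self.data)

    def logprior(self, params: LidmParameters) -> float:
        return log_prior(self.model, params, self.priors)

    def logposterior(self, params: LidmParameters) -> float:
        lp = self.logprior(params)
        if not np.isfinite(lp):
            return lp
        return lp + self.loglike(params)

    # ------------------------------------------------------------------- fit
    def fit(self, config: FitConfig | None = None,
            update_mask: np.ndarray | None = None,
            start: LidmParameters | None = None) -> "LidmResults":
        """Sample the posterior by Gibbs-within-slice MCMC.

        ``update_mask`` freezes parameter blocks (order: beta0, beta_S,
        beta_R, beta_D, tau, theta, rho_theta, hyperparameters) — a
        diagnostic hook for conditional-distribution checks.  ``start``
        pins the initial state of every chain (by default each chain gets
        its own overdispersed start).
        """
        from . import _sampler

        cfg = config if config is not None else FitConfig()
        spec = self.spec
        n, L, T = spec.n_members, spec.n_subscales, spec.n_items
        if cfg.prior_only:
            s = np.empty(0, dtype=np.int64)
            r = np.empty(0, dtype=np.int64)
            i = np.empty(0, dtype=np.int64)
            y = np.empty(0, dtype=np.float64)
        else:
            s, r, i, y = self.data.arrays()

        order = np.argsort(i, kind="stable")
        s, r, i, y = s[order], r[order], i[order], y[order]
        item_off = np.zeros(T + 1, dtype=np.int64)
        for ii in range(T):
            item_off[ii + 1] = item_off[ii] + int(np.sum(i == ii))
        mem_lists = [np.flatnonzero((s == a) | (r == a)) for a in range(n)]
        mem_off = np.zeros(n + 1, dtype=np.int64)
        for a in range(n):
            mem_off[a + 1] = mem_off[a] + len(mem_lists[a])
        mem_obs = (np.concatenate(mem_lists) if len(y) else
                   np.empty(0, dtype=np.int64)).astype(np.int64)

        item_sub = np.asarray(spec.item_to_subscale, dtype=np.int64) - 1
        var0, lamvar, varD = self.priors.variances()
        prior_vec = np.array([
            self.priors.beta0_loc, var0, self.priors.sigma_bR, lamvar,
            self.priors.sigma_bS_lo, self.priors.sigma_bS_hi,
            self.priors.logD_loc, varD,
            self.priors.tau_shape, self.priors.tau_rate,
        ])
        if update_mask is None:
            update_mask = np.ones(8, dtype=np.uint8)
        update_mask = np.asarray(update_mask, dtype=np.uint8)

        names = param_names(n, L, T, self.model)
        P = len(names)
        kept = cfg.kept_per_chain
        burn = cfg.burnin + cfg.adaptation
        total = cfg.iterations + cfg.adaptation
        draws = np.empty((cfg.n_chains, kept, P))
        ybar = float(np.mean(y)) if len(y) else 0.0
        for c in range(cfg.n_chains):
            ss = np.random.SeedSequence([int(cfg.seed) % (2 ** 31), c])
            chain_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng([int(cfg.seed) % (2 ** 31), c, 7])
            init = (self._pack(start, n, L, T) if start is not None
                    else self._initial_state(rng, ybar, n, L, T))
            got = _sampler.run_chain(
                self.model, y, s, r, i, item_sub, n, L, T,
                item_off, mem_obs, mem_off,
                total, burn, cfg.thin, chain_seed,
                prior_vec, init, update_mask, draws[c])
            if got != kept:
                raise RuntimeError(
                    f"chain {c} retained {got} draws, expected {kept}")
        return LidmResults(self, cfg, draws, names)

    def _initial_state(self, rng: np.random.Generator, ybar: float,
                       n: int, L: int, T: int) -> np.ndarray:
        """Mildly overdispersed starting point (one per chain)."""
        lam0 = rng.normal(0.0, 0.5)
        sbS0 = max(self.priors.sigma_bS_lo, abs(lam0) * self.priors.sigma_bR) \
            + 0.3 + abs(rng.normal(0.0, 0.5))
        p = LidmParameters(
            beta0=ybar + rng.normal(0.0, 1.0),
            beta_S=rng.normal(0.0, 1.0, T),
            beta_R=np.abs(rng.normal(0.0, 1.0, T)) + 0.05,
            sigma=np.exp(rng.normal(0.0, 0.3, T)),
            theta=rng.normal(0.0, 1.0, (n, L)),
            rho_theta=rng.uniform(0.05, 0.95) if L > 1 else 0.0,
            beta_D=(-np.exp(rng.normal(-1.5, 0.7, T))
                    if self.model == 2 else None),
            lam=lam0, sigma_bS=sbS0,
        )
        return self._pack(p, n, L, T)

    def _pack(self, p: LidmParameters, n: int, L: int, T: int) -> np.ndarray:
        lam = p.lam if p.lam is not None else (
            p.rho_beta if p.rho_beta is not None else 0.0)
        sbS = p.sigma_bS if p.sigma_bS is not None else max(
            self.priors.sigma_bS_lo, abs(lam) * self.priors.sigma_bR + 0.1)
        vec = np.concatenate([
            [p.beta0], p.beta_S, p.beta_R, p.sigma, p.theta.ravel(),
            [p.rho_theta if L > 1 else 0.5, lam, sbS,
             lam * self.priors.sigma_bR / sbS],
            p.beta_D if (self.model == 2 and p.beta_D is not None) else [],
        ])
        expect = len(param_names(n, L, T, self.model))
        if len(vec) != expect:
            raise ValueError("start point does not match the model layout")
        return vec


class LidmResults:
    """Posterior draws and summaries from a fitted model.

    Attributes
    ----------
    draws : ndarray, shape (chains, kept, P)
        Retained draws, packed per :func:`param_names`.
    names : list of str
        Column labels for the packed axis.
    """

    def __init__(self, model: LatentInterdependenceModel, config: FitConfig,
                 draws: np.ndarray, names: list[str]):
        self.model = model
        self.config = config
        self.draws = draws
        self.names = names
        self._index = {nm: k for k, nm in enumerate(names)}
        self._summary: pd.DataFrame | None = None

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (chains, kept)."""
        return self.draws[:, :, self._index[name]]

    def eap(self, name: str) -> float:
        """Posterior mean pooled across chains."""
        return float(np.mean(self.get(name)))

    @property
    def params(self) -> LidmParameters:
        """The EAP point estimate as a parameter object."""
        spec = self.model.spec
        n, L, T = spec.n_members, spec.n_subscales, spec.n_items
        m = self.draws.reshape(-1, self.draws.shape[-1]).mean(axis=0)
        ix = self._index
        theta = np.array([[m[ix[f"theta[{a},{l}]"]] for l in range(1, L + 1)]
                          for a in range(1, n + 1)])
        return LidmParameters(
            beta0=m[ix["beta0"]],
            beta_S=np.array([m[ix[f"beta_S[{i}]"]] for i in range(1, T + 1)]),
            beta_R=np.array([m[ix[f"beta_R[{i}]"]] for i in range(1, T + 1)]),
            sigma=np.array([m[ix[f"sigma[{i}]"]] for i in range(1, T + 1)]),
            theta=theta,
            rho_theta=m[ix["rho_theta"]],
            beta_D=(np.array([m[ix[f"beta_D[{i}]"]] for i in range(1, T + 1)])
                    if self.model.model == 2 else None),
            rho_beta=m[ix["rho_beta"]],
            lam=m[ix["lam"]],
            sigma_bS=m[ix["sigma_bS"]],
        )

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean (EAP), SD, median, R-hat, ESS."""
        if self._summary is None:
            from .diagnostics import summarize
            self._summary = summarize(self.draws, self.names)
        return self._summary

    def rhat(self, name: str) -> float:
        from .diagnostics import gelman_rubin
        return gelman_rubin(self.get(name))

    def ess(self, name: str) -> float:
        from .diagnostics import effective_sample_size
        return effective_sample_size(self.get(name))

    def max_rhat(self) -> float:
        return float(self.summary()["rhat"].max())

    def build_network(self, subscale: int):
        """Trait-level predicted-tie network for one subscale (see
        :mod:`lidm.networks`)."""
        from .networks import build_network
        return build_network(self.params, self.model.model, self.model.spec,
                             subscale, data=self.model.data)

    def save_draws(self, path) -> None:
        """Plain columnar text: one parameter per column, chains stacked."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        pd.DataFrame(flat, columns=self.names).to_csv(path, index=False)
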