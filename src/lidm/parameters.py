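"""Parameter and prior containers for the latent interdependence models.

Model 1 explains a directed response of sender S about receiver R on item i
(measuring trait dimension l) as

    y_iSR = beta0 + betaS_i * theta_S[l] + betaR_i * theta_R[l] + xi_i,

with xi_i ~ N(0, sigma_i^2).  Model 2 adds a latent-distance penalty
``betaD_i * E_SR`` where ``E_SR`` is the Euclidean distance between the two
members' full trait vectors and every ``betaD_i < 0``.

Identification: receiver effects are positive with unit prior scale
(sigma_betaR = 1), traits have unit variance, and the sender-receiver
effect dependence is parameterized by the regression slope ``lam`` of
betaS on betaR together with the marginal sender-effect scale
``sigma_bS``; the implied correlation is ``rho_beta = lam * sigma_bR /
sigma_bS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["LidmParameters", "PriorSpec"]


@dataclass
class LidmParameters:
    """One point in parameter space (generating truth or a posterior EAP).

    Attributes
    ----------
    beta0 : grand mean of all responses (response-scale units).
    beta_S : (T,) item sender effects, unbounded.
    beta_R : (T,) item receiver effects, all > 0.
    sigma : (T,) item residual standard deviations, all > 0.
    theta : (n, L) latent trait scores, one row per member.
    rho_theta : correlation between trait dimensions, in (0, 1) (shared
        off-diagonal of the unit-diagonal trait covariance).
    beta_D : (T,) item latent-distance effects, all < 0; None under Model 1.
    rho_beta : sender-receiver effect correlation (derived identity
        ``lam * sigma_bR / sigma_bS`` when lam/sigma_bS are set).
    lam : regression slope of beta_S on beta_R.
    sigma_bS : marginal scale of the sender effects.
    """

    beta0: float
    beta_S: np.ndarray
    beta_R: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    rho_theta: float = 0.0
    beta_D: np.ndarray | None = None
    rho_beta: float | None = None
    lam: float | None = None
    sigma_bS: float | None = None

    def __post_init__(self):
        self.beta_S = np.atleast_1d(np.asarray(self.beta_S, dtype=float))
        self.beta_R = np.atleast_1d(np.asarray(self.beta_R, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.beta_D is not None:
            self.beta_D = np.atleast_1d(np.asarray(self.beta_D, dtype=float))
        T = len(self.beta_S)
        if not (len(self.beta_R) == len(self.sigma) == T):
            raise ValueError("beta_S, beta_R, sigma must share length T")
        if self.beta_D is not None and len(self.beta_D) != T:
            raise ValueError("beta_D must have length T")
        if np.any(self.beta_R <= 0):
            raise ValueError("receiver effects must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("residual scales must be positive")
        if self.beta_D is not None and np.any(self.beta_D >= 0):
            raise ValueError("distance effects must be negative")
        L = self.theta.shape[1]
        if L > 1 and not -1.0 / (L - 1) < self.rho_theta < 1.0:
            raise ValueError(
                f"rho_theta={self.rho_theta} gives a non-positive-definite "
                "trait covariance"
            )

    @property
    def n_members(self) -> int:
        return self.theta.shape[0]

    @property
    def n_dims(self) -> int:
        return self.theta.shape[1]

    @property
    def n_items(self) -> int:
        return len(self.beta_S)

    @property
    def model(self) -> int:
        """Which model variant this point parameterizes (2 iff beta_D set)."""
        return 2 if self.beta_D is not None else 1

    def trait_covariance(self) -> np.ndarray:
        """Unit-diagonal equicorrelation covariance of the trait rows."""
        L = self.n_dims
        S = np.full((L, L), self.rho_theta)
        np.fill_diagonal(S, 1.0)
        return S

    # -------------------------------------------------------------- io
    def to_dict(self) -> dict:
        d = {
            "beta0": float(self.beta0),
            "beta_S": [float(v) for v in self.beta_S],
            "beta_R": [float(v) for v in self.beta_R],
            "sigma": [float(v) for v in self.sigma],
            "theta": [[float(v) for v in row] for row in self.theta],
            "rho_theta": float(self.rho_theta),
        }
        if self.beta_D is not None:
            d["beta_D"] = [float(v) for v in self.beta_D]
        for k in ("rho_beta", "lam", "sigma_bS"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "LidmParameters":
        return cls(
            beta0=d["beta0"],
            beta_S=np.asarray(d["beta_S"]),
            beta_R=np.asarray(d["beta_R"]),
            sigma=np.asarray(d["sigma"]),
            theta=np.asarray(d["theta"]),
            rho_theta=d.get("rho_theta", 0.0),
            beta_D=np.asarray(d["beta_D"]) if "beta_D" in d else None,
            rho_beta=d.get("rho_beta"),
            lam=d.get("lam"),
            sigma_bS=d.get("sigma_bS"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LidmParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly-informative prior system.

    Scale-type second parameters (``beta0_scale``, ``lam_scale``,
    ``logD_scale``) are variances by default; set
    ``scales_are_precisions=True`` to read them in the precision
    convention of BUGS-family samplers instead.

    Components (support constraints enforced by the sampler by
    construction):

    * beta0 ~ N(beta0_loc, beta0_scale)
    * beta_R_i ~ N(0, sigma_bR^2) truncated to (0, inf)
    * beta_S_i | beta_R_i ~ N(lam * beta_R_i, sigma_bS^2 - lam^2 sigma_bR^2)
    * lam ~ N(0, lam_scale), restricted to |lam| sigma_bR < sigma_bS
    * sigma_bS ~ Uniform(sigma_bS_lo, sigma_bS_hi)
    * -beta_D_i ~ Lognormal(logD_loc, logD_scale)
    * trait rows ~ N(0, equicorrelation(rho_theta)), rho_theta ~ U(0, 1)
    * precisions 1/sigma_i^2 ~ Gamma(tau_shape, tau_rate)
    """

    beta0_loc: float = 0.0
    beta0_scale: float = 10.0
    sigma_bR: float = 1.0
    lam_scale: float = 1000.0
    sigma_bS_lo: float = 1.0
    sigma_bS_hi: float = 1000.0
    logD_loc: float = 0.0
    logD_scale: float = 10.0
    tau_shape: float = 0.01
    tau_rate: float = 0.01
    scales_are_precisions: bool = False

    def variances(self) -> tuple[float, float, float]:
        """(var beta0, var lam, var log(-beta_D)) in the variance convention."""
        if self.scales_are_precisions:
            return (1.0 / self.beta0_scale, 1.0 / self.lam_scale,
                    1.0 / self.logD_scale)
        return (self.beta0_scale, self.lam_scale, self.logD_scale)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)

    def __post_init__(self):
        if self.sigma_bR <= 0 or self.beta0_scale <= 0 or self.lam_scale <= 0 \
                or self.logD_scale <= 0 or self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("all prior scales must be positive")
        if not 0 < self.sigma_bS_lo < self.sigma_bS_hi:
            raise ValueError("sigma_bS bounds must satisfy 0 < lo < hi")
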