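"""Convergence diagnostics and posterior summaries.

Implements the classic potential-scale-reduction factor (between/within
chain variance ratio) and an autocorrelation-based effective sample size
(Geyer initial-positive-sequence truncation, chains combined), the two
quantities reported alongside every posterior summary.  These are the
textbook estimators rather than the rank-normalized split variants found
in modern libraries, so they can be checked directly against their
defining formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "effective_sample_size", "summarize",
           "DiagnosticError"]


class DiagnosticError(ValueError):
    """Diagnostic undefined for the given chains (e.g. a single chain for
    R-hat, or a constant chain for ESS)."""


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat.

    Parameters
    ----------
    chains : array (m, n) of m >= 2 chains with n >= 10 draws each.

    Notes
    -----
    ``R = sqrt(V / W)`` with ``W`` the mean within-chain variance and
    ``V = (n-1)/n W + B/n`` the pooled variance estimate (``B/n`` the
    variance of the chain means).  Values marginally below 1 are sampling
    noise, so the estimate is floored at 1; chains sampling different
    distributions give values well above 1.1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise DiagnosticError("R-hat needs at least two chains")
    m, n = c.shape
    if n < 10:
        raise DiagnosticError("R-hat needs chains of length >= 10")
    W = float(np.mean(np.var(c, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(c, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    V = (n - 1) / n * W + B_over_n
    return max(1.0, float(np.sqrt(V / W)))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance function via FFT (lag 0..n-1)."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    return acov


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective number of independent draws in autocorrelated chains.

    Combines chains the way Stan does (within-chain autocovariances
    averaged, scaled by the pooled variance), sums paired autocorrelations
    while they remain positive (Geyer's initial positive sequence), and
    caps the result at the total draw count.  A constant chain has no
    information about mixing; that raises :class:`DiagnosticError`.
    """
    c = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = c.shape
    if n < 10:
        raise DiagnosticError("ESS needs chains of length >= 10")
    if np.all(c == c[:, :1]):
        raise DiagnosticError("ESS undefined for constant chains")
    chain_vars = np.var(c, axis=1, ddof=1)
    W = float(np.mean(chain_vars))
    if m > 1:
        B_over_n = float(np.var(np.mean(c, axis=1), ddof=1))
        var_plus = (n - 1) / n * W + B_over_n
    else:
        var_plus = (n - 1) / n * W + W / n
    acov = np.mean([_autocovariance(c[j]) for j in range(m)], axis=0)
    rho = 1.0 - (W - acov) / var_plus  # rho[0] == 1 up to rounding
    # Geyer: sum consecutive lag pairs while their sum stays positive
    tau = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        tau += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tau)
    return float(min(ess, m * n))


def summarize(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Posterior summary table: mean (EAP), SD, median, R-hat, ESS per
    parameter, chains pooled for the moments.

    Parameters with degenerate draws get NaN diagnostics rather than an
    error so a full table is always produced.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.size == 0:
        raise ValueError("draws must be a non-empty (chains, kept, P) array")
    m, n, P = draws.shape
    if P != len(names):
        raise ValueError("names must match the packed parameter axis")
    flat = draws.reshape(-1, P)
    rows = []
    for k in range(P):
        ch = draws[:, :, k]
        try:
            rhat = gelman_rubin(ch) if m >= 2 else np.nan
        except DiagnosticError:
            rhat = np.nan
        try:
            ess = effective_sample_size(ch)
        except DiagnosticError:
            ess = np.nan
        rows.append({
            "parameter": names[k],
            "mean": flat[:, k].mean(),
            "sd": flat[:, k].std(ddof=1) if flat.shape[0] > 1 else 0.0,
            "median": float(np.median(flat[:, k])),
            "rhat": rhat,
            "ess": ess,
        })
    return pd.DataFrame(rows).set_index("parameter")
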