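"""MCMC convergence diagnostics.

Two checks are provided, mirroring standard practice for chain-based
meta-analysis: the Gelman-Rubin potential scale reduction factor
(PSR), comparing within- and between-chain variance across replicate
chains (convergence is conventionally declared at PSR < 1.1), and
Geweke's Z, comparing the mean of the first 10% of a chain with the
mean of the last 50% using spectral-density-at-zero standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = ["gelman_rubin", "geweke", "spectrum0_ar", "DiagnosticsReport", "diagnose"]

PSR_THRESHOLD = 1.1


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    ``PSR = sqrt(((n-1)/n * W + B/n) / W)`` where W is the mean
    within-chain variance and B is n times the variance of the chain
    means.  Degenerate identical chains (B = 0) report 1.0 with a
    warning; zero within-chain variance is undefined and reports NaN.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = chains[0].size
    if n < 10 or any(c.size != n for c in chains):
        raise ValueError("chains must be equal length with at least 10 draws")
    w = float(np.mean([c.var(ddof=1) for c in chains]))
    means = np.array([c.mean() for c in chains])
    b = n * float(means.var(ddof=1))
    if w == 0.0:
        warnings.warn("zero within-chain variance; PSR undefined")
        return float("nan")
    if b == 0.0:
        warnings.warn("identical chains; PSR degenerate, reporting 1.0")
        return 1.0
    return math.sqrt(((n - 1) / n * w + b / n) / w)


def spectrum0_ar(x: np.ndarray, max_order: Optional[int] = None) -> float:
    """Spectral density of a time series at frequency zero.

    An autoregressive model is fitted by least squares with the order
    chosen by AIC (orders 0..max_order); the spectrum at zero is
    ``sigma2 / (1 - sum(phi))^2``.  Dividing by the series length gives
    the squared standard error of the series mean under dependence.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for spectral estimation")
    x = x - x.mean()
    v0 = float(x.var(ddof=0))
    if v0 == 0.0:
        raise ValueError("zero variance series")
    if max_order is None:
        max_order = min(int(10 * math.log10(n)), n // 4, 20)
    best_aic, best = math.inf, (0, v0, np.zeros(0))
    for p in range(0, max_order + 1):
        if p == 0:
            sigma2 = v0
            phi = np.zeros(0)
        else:
            ybar = x[p:]
            Z = np.column_stack([x[p - k:n - k] for k in range(1, p + 1)])
            phi, *_ = np.linalg.lstsq(Z, ybar, rcond=None)
            resid = ybar - Z @ phi
            sigma2 = float(resid @ resid) / (n - p)
            if sigma2 <= 0:
                continue
        aic = n * math.log(sigma2) + 2.0 * p
        if aic < best_aic:
            best_aic, best = aic, (p, sigma2, phi)
    _, sigma2, phi = best
    denom = (1.0 - float(phi.sum())) ** 2
    if denom <= 1e-12:
        denom = 1e-12
    return sigma2 / denom


def geweke(
    chain: np.ndarray,
    first: float = 0.10,
    last: float = 0.50,
    se_method: str = "spectral",
) -> float:
    """Geweke convergence Z score.

    Compares the mean of the first ``first`` fraction of the chain with
    the mean of the last ``last`` fraction:
    ``z = (mean_first - mean_last) / sqrt(se_first^2 + se_last^2)``.
    Standard errors use the spectral density at zero by default; the
    ``"naive"`` method uses ``s / sqrt(n)`` (appropriate for
    independent draws).
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    if n < 20:
        raise ValueError("geweke requires a chain of length >= 20")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("segment fractions must be positive with first + last <= 1")
    a = chain[: max(int(first * n), 2)]
    b = chain[n - max(int(last * n), 2):]
    if a.var(ddof=0) == 0.0 or b.var(ddof=0) == 0.0:
        raise ValueError("zero variance in a Geweke segment")
    if se_method == "spectral":
        var_a = spectrum0_ar(a) / a.size
        var_b = spectrum0_ar(b) / b.size
    elif se_method == "naive":
        var_a = a.var(ddof=1) / a.size
        var_b = b.var(ddof=1) / b.size
    else:
        raise ValueError("se_method must be 'spectral' or 'naive'")
    return float((a.mean() - b.mean()) / math.sqrt(var_a + var_b))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics for one fit."""

    psr: Dict[str, float]
    geweke_z: Dict[str, float]
    pass_psr: Dict[str, bool]

    @property
    def converged(self) -> bool:
        return all(self.pass_psr.values())

    def as_dict(self) -> dict:
        return {"psr": self.psr, "geweke_z": self.geweke_z,
                "pass_psr": self.pass_psr, "converged": self.converged}


def diagnose(samples) -> DiagnosticsReport:
    """PSR (across chains, if >= 2) and Geweke Z (worst chain) for every
    fixed effect and variance component of a :class:`PosteriorSamples`."""
    psr: Dict[str, float] = {}
    gz: Dict[str, float] = {}
    n_chains = samples.settings.n_chains

    def handle(name: str, which: str, j: int) -> None:
        chains = samples.per_chain(which, j)
        if n_chains >= 2:
            psr[name] = gelman_rubin(chains)
        try:
            zs = [geweke(c) for c in chains]
            gz[name] = max(zs, key=abs)
        except ValueError:
            gz[name] = float("nan")

    for j, name in enumerate(samples.beta_names):
        handle(f"beta:{name}", "beta", j)
    for j, name in enumerate(samples.sigma2_names):
        if samples.units_fixed is not None and name == "units":
            continue
        handle(f"sigma2:{name}", "sigma2", j)
    pass_psr = {k: (not math.isnan(v)) and v < PSR_THRESHOLD for k, v in psr.items()}
    return DiagnosticsReport(psr=psr, geweke_z=gz, pass_psr=pass_psr)
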