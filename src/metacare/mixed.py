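"""Bayesian Gaussian mixed-model meta-regression by Gibbs sampling.

Model, for effect size ``y_i`` (Fisher's Z) with known sampling
variance ``v_i``::

    y_i = x_i' beta + u_class(i) + u_family(i) + u_species(i)
          + u_study(i) + m_i + e_i

``m_i ~ N(0, v_i)`` is the measurement effect whose variance is *fixed*
at the known sampling variance, ``e_i ~ N(0, sigma2_units)`` is the
estimated residual, and each random block ``u`` is i.i.d. normal with
its own variance (or, in the phylogenetic variant, correlated through a
relatedness matrix ``A``: ``u ~ N(0, sigma2 * A)``).

The sampler is partially collapsed: ``m`` and ``e`` are marginalised
out of the beta and random-block conditionals (which therefore use
heteroscedastic weights ``1/(v_i + sigma2_units)``), and ``e`` is drawn
afresh from its full conditional only to feed the conjugate
inverse-gamma update of ``sigma2_units``.  This leaves the stationary
distribution unchanged while mixing better than sampling ``m``
explicitly, and makes the no-random-effects, fixed-units-variance case
draw exactly from the closed-form conjugate posterior.

Priors mirror common practice for this model class: diffuse normal
N(0, 1e8) on fixed effects and either an inverse-gamma(V=1, nu=0.002)
prior on each variance or a parameter-expanded (half-Cauchy inducing)
prior with working-parameter prior N(alpha_mu, alpha_V).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, stats

from .dataset import DesignMatrixBundle

__all__ = [
    "Prior",
    "MCMCSettings",
    "PosteriorSamples",
    "ParamSummary",
    "FitSummary",
    "fit",
    "summarize",
    "pmcmc",
    "dic",
]

_RANDOM_ORDER = ("class", "family", "species", "study")


@dataclass(frozen=True)
class Prior:
    """Prior hyperparameters for the meta-regression."""

    variance_prior: str = "inverse_gamma"  # or "parameter_expanded"
    V: float = 1.0
    nu: float = 0.002
    alpha_mu: float = 0.0
    alpha_V: float = 625.0  # 25^2
    fixed_effect_variance: float = 1e8

    def __post_init__(self) -> None:
        if self.variance_prior not in ("inverse_gamma", "parameter_expanded"):
            raise ValueError("variance_prior must be inverse_gamma or parameter_expanded")
        if self.V <= 0 or self.nu <= 0 or self.alpha_V <= 0:
            raise ValueError("V, nu and alpha_V must all be positive")

    @classmethod
    def parameter_expanded(cls) -> "Prior":
        """Half-Cauchy-inducing prior (V=1, nu=1, alpha_mu=0, alpha_V=25^2)."""
        return cls(variance_prior="parameter_expanded", V=1.0, nu=1.0)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain schedule: iterations, burn-in, thinning, number of chains."""

    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def reference_schedule(cls, seed: int = 0, n_chains: int = 3) -> "MCMCSettings":
        """The long production schedule: 3,000,000 iterations, 2,500,000
        burn-in, thinning 100 — 5,000 retained draws per chain."""
        return cls(iterations=3_000_000, burn_in=2_500_000, thin=100,
                   n_chains=n_chains, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0, n_chains: int = 3) -> "MCMCSettings":
        """Short schedule for interactive use and testing."""
        return cls(iterations=6_000, burn_in=2_000, thin=4,
                   n_chains=n_chains, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws from :func:`fit`, all chains concatenated."""

    beta: np.ndarray            # (draws, p)
    sigma2: np.ndarray          # (draws, k)
    deviance: np.ndarray        # (draws,)
    beta_names: List[str]
    sigma2_names: List[str]
    chain_id: np.ndarray        # (draws,) chain index per draw
    u_mean: Dict[str, np.ndarray]   # posterior mean of each random block
    settings: MCMCSettings
    prior: Prior
    units_fixed: Optional[float] = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def per_chain(self, which: str, index: int) -> List[np.ndarray]:
        """Draws of one named parameter split by chain."""
        src = self.beta if which == "beta" else self.sigma2
        return [src[self.chain_id == c, index] for c in range(self.settings.n_chains)]


def _sorted_bundle(bundle: DesignMatrixBundle) -> Tuple[DesignMatrixBundle, np.ndarray]:
    """Canonical row ordering so results are invariant to input permutation."""
    keys = [bundle.X[:, j] for j in range(bundle.X.shape[1] - 1, -1, -1)]
    keys += [bundle.meas_var, bundle.response]
    keys += [bundle.groups[name] for name in reversed(list(bundle.groups))]
    order = np.lexsort(tuple(keys))
    sorted_bundle = DesignMatrixBundle(
        response=bundle.response[order],
        meas_var=bundle.meas_var[order],
        X=bundle.X[order],
        columns=bundle.columns,
        coding=bundle.coding,
        groups={k: v[order] for k, v in bundle.groups.items()},
        group_labels=bundle.group_labels,
    )
    return sorted_bundle, order


class _Block:
    """State for one random-effect block inside a chain."""

    def __init__(self, name: str, idx: np.ndarray, n_levels: int,
                 cov: Optional[np.ndarray], prior: Prior, rng: np.random.Generator):
        self.name = name
        self.idx = idx
        self.n_levels = n_levels
        self.prior = prior
        self.px = prior.variance_prior == "parameter_expanded" and cov is None
        self.cov = cov
        if cov is not None:
            if cov.shape != (n_levels, n_levels):
                raise ValueError(f"covariance for block {name!r} has wrong shape")
            # ridge for near-singular relatedness matrices
            try:
                self.cov_inv = linalg.inv(cov)
            except linalg.LinAlgError:
                warnings.warn(f"relatedness matrix for {name!r} singular; adding 1e-8 ridge")
                self.cov_inv = linalg.inv(cov + 1e-8 * np.eye(n_levels))
        start_scale = math.exp(rng.normal(0.0, 1.0))
        self.sigma2 = 0.05 * start_scale
        self.u = np.zeros(n_levels)
        if self.px:
            self.alpha = 1.0
            self.xi = np.zeros(n_levels)
            self.s2_xi = self.sigma2

    def update(self, resid: np.ndarray, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Gibbs update of this block's effects and variance.

        `resid` excludes this block's contribution on entry; the return
        value is the new contribution Z u to subtract.
        """
        nu, V = self.prior.nu, self.prior.V
        sw = np.bincount(self.idx, weights=w, minlength=self.n_levels)
        swr = np.bincount(self.idx, weights=w * resid, minlength=self.n_levels)
        if self.cov is not None:
            prec = np.diag(sw) + self.cov_inv / self.sigma2
            chol = linalg.cho_factor(prec, lower=True)
            mean = linalg.cho_solve(chol, swr)
            z = rng.standard_normal(self.n_levels)
            self.u = mean + linalg.solve_triangular(chol[0], z, lower=True, trans="T")
            quad = float(self.u @ self.cov_inv @ self.u)
            shape = (nu + self.n_levels) / 2.0
            scale = (nu * V + quad) / 2.0
            self.sigma2 = max(scale / rng.gamma(shape), 1e-12)
        elif self.px:
            # u = alpha * xi with xi ~ N(0, s2_xi), alpha ~ N(alpha_mu, alpha_V)
            a2 = self.alpha**2
            prec = a2 * sw + 1.0 / self.s2_xi
            mean = self.alpha * swr / prec
            self.xi = mean + rng.standard_normal(self.n_levels) / np.sqrt(prec)
            xi_row = self.xi[self.idx]
            prec_a = float((w * xi_row**2).sum()) + 1.0 / self.prior.alpha_V
            mean_a = (float((w * xi_row * resid).sum())
                      + self.prior.alpha_mu / self.prior.alpha_V) / prec_a
            self.alpha = mean_a + rng.standard_normal() / math.sqrt(prec_a)
            shape = (nu + self.n_levels) / 2.0
            scale = (nu * V + float(self.xi @ self.xi)) / 2.0
            self.s2_xi = max(scale / rng.gamma(shape), 1e-12)
            self.u = self.alpha * self.xi
            self.sigma2 = max(self.alpha**2 * self.s2_xi, 1e-12)
        else:
            prec = sw + 1.0 / self.sigma2
            mean = swr / prec
            self.u = mean + rng.standard_normal(self.n_levels) / np.sqrt(prec)
            shape = (nu + self.n_levels) / 2.0
            scale = (nu * V + float(self.u @ self.u)) / 2.0
            self.sigma2 = max(scale / rng.gamma(shape), 1e-12)
        return self.u[self.idx]


def _run_chain(
    bundle: DesignMatrixBundle,
    prior: Prior,
    settings: MCMCSettings,
    chain: int,
    blocks_spec: List[Tuple[str, np.ndarray, int, Optional[np.ndarray]]],
    units_variance: Optional[float],
) -> dict:
    rng = np.random.default_rng(settings.seed + chain)
    y, v, X = bundle.response, bundle.meas_var, bundle.X
    n, p = X.shape
    prior_prec_beta = 1.0 / prior.fixed_effect_variance

    beta = rng.normal(0.0, 0.5, size=p) if chain > 0 else np.zeros(p)
    blocks = [_Block(name, idx, nl, cov, prior, rng) for name, idx, nl, cov in blocks_spec]
    s2_units = units_variance if units_variance is not None else 0.05 * math.exp(rng.normal(0, 1))

    contrib = np.zeros(n)
    for b in blocks:
        contrib += b.u[b.idx]

    n_ret = settings.retained_per_chain
    out_beta = np.empty((n_ret, p))
    out_sigma2 = np.empty((n_ret, len(blocks) + 1))
    out_dev = np.empty(n_ret)
    u_sum = {b.name: np.zeros(b.n_levels) for b in blocks}
    kept = 0

    for it in range(settings.iterations):
        d = v + s2_units
        w = 1.0 / d

        # fixed effects (m, e marginalised out)
        r_beta = y - contrib
        XtW = X.T * w
        prec = XtW @ X + prior_prec_beta * np.eye(p)
        chol = linalg.cho_factor(prec, lower=True)
        mean = linalg.cho_solve(chol, XtW @ r_beta)
        z = rng.standard_normal(p)
        beta = mean + linalg.solve_triangular(chol[0], z, lower=True, trans="T")
        resid = r_beta - X @ beta

        # random blocks
        for b in blocks:
            resid += b.u[b.idx]
            zu = b.update(resid, w, rng)
            resid -= zu
        contrib = y - X @ beta - resid

        # units (residual) variance via its full conditional, unless fixed
        if units_variance is None:
            shrink = s2_units / d
            e = shrink * resid + rng.standard_normal(n) * np.sqrt(shrink * v)
            shape = (prior.nu + n) / 2.0
            scale = (prior.nu * prior.V + float(e @ e)) / 2.0
            s2_units = max(scale / rng.gamma(shape), 1e-12)

        if not np.all(np.isfinite(beta)):
            raise FloatingPointError(
                f"sampler diverged at iteration {it} of chain {chain}: beta={beta!r}"
            )

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 and kept < n_ret:
            d_now = v + s2_units
            out_beta[kept] = beta
            out_sigma2[kept] = [b.sigma2 for b in blocks] + [s2_units]
            out_dev[kept] = float(
                np.sum(np.log(2.0 * math.pi * d_now) + resid**2 / d_now)
            )
            for b in blocks:
                u_sum[b.name] += b.u
            kept += 1

    return {
        "beta": out_beta,
        "sigma2": out_sigma2,
        "deviance": out_dev,
        "u_mean": {k: s / max(kept, 1) for k, s in u_sum.items()},
    }


def fit(
    bundle: DesignMatrixBundle,
    prior: Prior = Prior(),
    settings: MCMCSettings = MCMCSettings(),
    *,
    random_effects: Optional[Sequence[str]] = None,
    block_cov: Optional[Dict[str, np.ndarray]] = None,
    units_variance: Optional[float] = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler.

    Parameters
    ----------
    random_effects:
        Names of grouping factors to include (default: all groupings
        present in the bundle, in nesting order class, family, species,
        study).  Factors with a single level are dropped with a warning.
    block_cov:
        Optional per-block covariance (relatedness) matrix; the block's
        effects are then ``u ~ N(0, sigma2 * A)``.
    units_variance:
        If given, the residual "units" variance is held fixed at this
        value instead of being estimated.
    """
    bundle, _ = _sorted_bundle(bundle)
    if random_effects is None:
        random_effects = [k for k in _RANDOM_ORDER if k in bundle.groups]
    block_cov = block_cov or {}

    blocks_spec: List[Tuple[str, np.ndarray, int, Optional[np.ndarray]]] = []
    for name in random_effects:
        if name not in bundle.groups:
            raise ValueError(f"no grouping {name!r} in bundle")
        idx = bundle.groups[name]
        n_levels = len(bundle.group_labels[name])
        if n_levels < 2:
            warnings.warn(f"random factor {name!r} has a single level; dropped")
            continue
        blocks_spec.append((name, idx, n_levels, block_cov.get(name)))

    results = [
        _run_chain(bundle, prior, settings, c, blocks_spec, units_variance)
        for c in range(settings.n_chains)
    ]
    n_ret = settings.retained_per_chain
    sigma2_names = [name for name, *_ in blocks_spec] + ["units"]
    u_mean = {
        name: np.mean([res["u_mean"][name] for res in results], axis=0)
        for name, *_ in blocks_spec
    }
    return PosteriorSamples(
        beta=np.concatenate([res["beta"] for res in results]),
        sigma2=np.concatenate([res["sigma2"] for res in results]),
        deviance=np.concatenate([res["deviance"] for res in results]),
        beta_names=list(bundle.columns),
        sigma2_names=sigma2_names,
        chain_id=np.repeat(np.arange(settings.n_chains), n_ret),
        u_mean=u_mean,
        settings=settings,
        prior=prior,
        units_fixed=units_variance,
    )


def pmcmc(draws: np.ndarray) -> float:
    """Two-sided MCMC tail probability that a parameter crosses zero.

    ``p = 2 * max(1/N, min(#draws > 0, #draws < 0) / N)``, capped at 1;
    the 1/N floor reflects the finite number of retained draws.
    """
    draws = np.asarray(draws)
    n = draws.size
    if n < 2:
        raise ValueError("pmcmc requires at least 2 draws")
    n_pos = int((draws > 0).sum())
    n_neg = int((draws < 0).sum())
    p = 2.0 * max(1.0 / n, min(n_pos, n_neg) / n)
    return min(p, 1.0)


def _kde_mode(draws: np.ndarray) -> float:
    lo, hi = draws.min(), draws.max()
    if hi - lo < 1e-14:
        return float(lo)
    kde = stats.gaussian_kde(draws)
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class ParamSummary:
    mean: float
    sd: float
    mode: float
    ci_low: float
    ci_high: float
    pmcmc: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "mode": self.mode,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pmcmc": self.pmcmc,
        }


@dataclass
class FitSummary:
    """Posterior summaries: per-parameter mean/SD/mode/95% CI/pMCMC,
    DIC, and the percent of random variation per component."""

    fixed: Dict[str, ParamSummary]
    variance: Dict[str, ParamSummary]
    variance_percent: Dict[str, float]
    dic: Optional[float] = None
    extras: Dict[str, ParamSummary] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "fixed": {k: v.as_dict() for k, v in self.fixed.items()},
            "variance": {k: v.as_dict() for k, v in self.variance.items()},
            "variance_percent": self.variance_percent,
            "dic": self.dic,
            "extras": {k: v.as_dict() for k, v in self.extras.items()},
        }


def summarize_draws(draws: np.ndarray, with_pmcmc: bool = True) -> ParamSummary:
    """Posterior mean, SD, KDE mode, central 95% CI and pMCMC of a vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("no draws")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ParamSummary(
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        mode=_kde_mode(draws),
        ci_low=float(lo),
        ci_high=float(hi),
        pmcmc=pmcmc(draws) if with_pmcmc and draws.size > 1 else None,
    )


def summarize(samples: PosteriorSamples, bundle: Optional[DesignMatrixBundle] = None) -> FitSummary:
    """Summarise retained draws; if the bundle is supplied DIC is included.

    The variance-percent table divides each component's posterior-mean
    variance by the summed posterior means over {taxonomic levels,
    study, units}; the fixed measurement variance is excluded from the
    denominator.
    """
    if samples.n_draws < 100:
        raise ValueError("summarize requires at least 100 retained draws")
    fixed = {
        name: summarize_draws(samples.beta[:, j])
        for j, name in enumerate(samples.beta_names)
    }
    variance = {
        name: summarize_draws(samples.sigma2[:, j], with_pmcmc=False)
        for j, name in enumerate(samples.sigma2_names)
    }
    means = {k: v.mean for k, v in variance.items()}
    total = sum(means.values())
    variance_percent = {k: 100.0 * m / total for k, m in means.items()}
    dic_value = dic(samples, bundle) if bundle is not None else None
    return FitSummary(fixed=fixed, variance=variance,
                      variance_percent=variance_percent, dic=dic_value)


def dic(samples: PosteriorSamples, bundle: DesignMatrixBundle) -> float:
    """Deviance information criterion.

    ``DIC = mean(deviance) + pD`` with ``pD = mean(deviance) -
    deviance(posterior-mean parameters)``; the deviance is the marginal
    Gaussian deviance ``-2 log N(y | X beta + Z u, diag(v_i +
    sigma2_units))`` with random effects plugged in.
    """
    bundle, _ = _sorted_bundle(bundle)
    dbar = float(samples.deviance.mean())
    beta_bar = samples.beta.mean(axis=0)
    units_idx = samples.sigma2_names.index("units")
    s2_units = (
        samples.units_fixed
        if samples.units_fixed is not None
        else float(samples.sigma2[:, units_idx].mean())
    )
    mu = bundle.X @ beta_bar
    for name, u in samples.u_mean.items():
        mu = mu + u[bundle.groups[name]]
    d = bundle.meas_var + s2_units
    dev_at_mean = float(
        np.sum(np.log(2.0 * math.pi * d) + (bundle.response - mu) ** 2 / d)
    )
    return dbar + (dbar - dev_at_mean)
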