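"""Small-study-effect (publication bias) tests.

Two complementary checks on a set of effect sizes with known sampling
variances:

* **Trim and fill** (Duval & Tweedie): a rank-based estimate of the
  number of studies suppressed on one side of the funnel, iterated with
  a REML random-effects re-fit, followed by mirror-imputation of the
  missing points and a bias-adjusted pooled estimate.  This operates on
  the flattened data and ignores the hierarchical structure — it is a
  coarse screen, not a model-based correction.
* **Egger-type regression inside the mixed model**: the effect's
  standard error enters the taxonomic mixed meta-regression as a
  covariate; funnel asymmetry is flagged when the posterior 95% CI of
  the SE slope excludes zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .dataset import DesignMatrixBundle, EffectRecord, build_design
from .mixed import FitSummary, MCMCSettings, PosteriorSamples, Prior, fit, summarize

__all__ = [
    "RandomEffectsFit",
    "FunnelData",
    "TrimFillResult",
    "reml_random_effects",
    "trim_fill",
    "egger_design",
    "egger_mixed",
]


@dataclass
class RandomEffectsFit:
    """Pooled effect from a univariate random-effects meta-analysis."""

    mu: float
    tau2: float
    se_mu: float
    ci95: Tuple[float, float]
    k: int


def _profile_mu(effects: np.ndarray, variances: np.ndarray, tau2: float) -> Tuple[float, float]:
    w = 1.0 / (variances + tau2)
    mu = float((w * effects).sum() / w.sum())
    return mu, float(1.0 / w.sum())


def restricted_loglik(tau2: float, effects: np.ndarray, variances: np.ndarray) -> float:
    """Restricted log-likelihood of the model y_i ~ N(mu, v_i + tau2)."""
    w = 1.0 / (variances + tau2)
    mu = (w * effects).sum() / w.sum()
    return float(
        -0.5 * (np.sum(np.log(variances + tau2)) + math.log(w.sum())
                + np.sum(w * (effects - mu) ** 2))
    )


def reml_random_effects(effects: Sequence[float], variances: Sequence[float]) -> RandomEffectsFit:
    """REML estimate of between-study variance tau2 and pooled mean.

    tau2 maximises the restricted likelihood on [0, upper]; the pooled
    mean is the tau2-weighted mean with weights ``1/(v_i + tau2)`` and
    a Wald 95% CI.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 effects")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    if np.ptp(y) == 0.0:
        mu, var_mu = _profile_mu(y, v, 0.0)
        se = math.sqrt(var_mu)
        return RandomEffectsFit(mu, 0.0, se, (mu - 1.96 * se, mu + 1.96 * se), y.size)
    upper = max(10.0 * float(y.var(ddof=1)), 1e-3)
    res = optimize.minimize_scalar(
        lambda t: -restricted_loglik(t, y, v),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML optimisation failed: {res.message}")
    tau2 = float(max(res.x, 0.0))
    # snap to the boundary when it is at least as good
    if restricted_loglik(0.0, y, v) >= restricted_loglik(tau2, y, v):
        tau2 = 0.0
    mu, var_mu = _profile_mu(y, v, tau2)
    se = math.sqrt(var_mu)
    return RandomEffectsFit(mu, tau2, se, (mu - 1.96 * se, mu + 1.96 * se), y.size)


@dataclass
class FunnelData:
    """Effects and SEs for a funnel plot, with imputed points flagged."""

    effects: np.ndarray
    ses: np.ndarray
    filled: np.ndarray  # boolean

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"effect": self.effects, "se": self.ses, "filled": self.filled}
        )


@dataclass
class TrimFillResult:
    k0: int
    side: str  # side on which studies are estimated missing
    unadjusted: RandomEffectsFit
    adjusted: RandomEffectsFit
    funnel: FunnelData
    stable: bool = True


def _estimator_k0(dev: np.ndarray, estimator: str) -> int:
    """Rank-based estimate of the number of suppressed studies.

    `dev` are deviations from the pooled centre with the *excess*
    (observed surplus) side mapped to positive values.  L0 uses the
    Wilcoxon-type rank sum of positive deviations; R0 uses the length
    of the run of largest ranks on the excess side minus one.
    """
    n = dev.size
    ranks = np.argsort(np.argsort(np.abs(dev))) + 1  # ranks of |dev|, 1..n
    if estimator == "L0":
        t_n = float(ranks[dev > 0].sum())
        k0 = (4.0 * t_n - n * (n + 1.0)) / (2.0 * n - 1.0)
        return max(0, int(round(k0)))
    if estimator == "R0":
        order = np.argsort(-ranks)  # largest rank first
        gamma = 0
        for i in order:
            if dev[i] > 0:
                gamma += 1
            else:
                break
        return max(0, gamma - 1)
    raise ValueError("estimator must be 'L0' or 'R0'")


def _one_side_trim(
    y: np.ndarray, v: np.ndarray, excess_sign: float, estimator: str, max_iter: int
) -> Tuple[int, bool]:
    """Iterate centre-estimation and trimming for one assumed excess side.

    Returns the stabilised k0 (number of points estimated missing on the
    *opposite* side) and a stability flag.
    """
    n = y.size
    k0 = 0
    for _ in range(max_iter):
        keep = np.ones(n, dtype=bool)
        if k0 > 0:
            dev0 = excess_sign * (y - reml_random_effects(y, v).mu)
            # trim the k0 most extreme excess-side points (by signed deviation)
            order = np.argsort(-dev0)
            keep[order[:k0]] = False
        centre = reml_random_effects(y[keep], v[keep]).mu if keep.sum() >= 2 else float(np.mean(y[keep]))
        dev = excess_sign * (y - centre)
        new_k0 = min(_estimator_k0(dev, estimator), n - 2)
        if new_k0 == k0:
            return k0, True
        k0 = new_k0
    return k0, False


def trim_fill(
    effects: Sequence[float],
    variances: Sequence[float],
    estimator: str = "L0",
    side: str = "auto",
    max_iter: int = 50,
) -> TrimFillResult:
    """Duval-Tweedie trim and fill over a REML random-effects model.

    ``side`` names the side of the funnel on which studies are suspected
    *missing* ("left", "right", or "auto" to pick the side with the
    larger estimated k0).  The k0 most extreme points on the opposite
    (excess) side are mirrored about the trimmed centre, and the pooled
    effect is re-estimated including the imputed points.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 3:
        raise ValueError("trim and fill requires at least 3 effects")
    unadjusted = reml_random_effects(y, v)

    candidates = {"left": -1.0, "right": 1.0}
    if side in candidates:
        sides = {side: candidates[side]}
    elif side == "auto":
        sides = candidates
    else:
        raise ValueError("side must be 'left', 'right' or 'auto'")

    best: Tuple[str, int, bool] = ("right", 0, True)
    for name, missing_sign in sides.items():
        # excess side is opposite the missing side
        k0, stable = _one_side_trim(y, v, -missing_sign, estimator, max_iter)
        if k0 > best[1]:
            best = (name, k0, stable)
    chosen_side, k0, stable = best

    if k0 >= y.size / 2:
        warnings.warn("k0 >= half the studies; trim-and-fill result unstable")
        stable = False

    if k0 == 0:
        funnel = FunnelData(y.copy(), np.sqrt(v), np.zeros(y.size, dtype=bool))
        return TrimFillResult(0, chosen_side, unadjusted, unadjusted, funnel, stable)

    excess_sign = -candidates[chosen_side]
    dev0 = excess_sign * (y - reml_random_effects(y, v).mu)
    order = np.argsort(-dev0)
    trimmed = np.ones(y.size, dtype=bool)
    trimmed[order[:k0]] = False
    centre = reml_random_effects(y[trimmed], v[trimmed]).mu
    mirror_idx = order[:k0]
    y_fill = 2.0 * centre - y[mirror_idx]
    v_fill = v[mirror_idx]
    y_all = np.concatenate([y, y_fill])
    v_all = np.concatenate([v, v_fill])
    adjusted = reml_random_effects(y_all, v_all)
    funnel = FunnelData(
        y_all,
        np.sqrt(v_all),
        np.concatenate([np.zeros(y.size, dtype=bool), np.ones(k0, dtype=bool)]),
    )
    return TrimFillResult(k0, chosen_side, unadjusted, adjusted, funnel, stable)


def egger_design(records: Sequence[EffectRecord]) -> DesignMatrixBundle:
    """Design bundle for the mixed-model Egger test: intercept + SE.

    The standard error enters untransformed so the slope is directly
    interpretable as change in Fisher-Z per unit SE.
    """
    bundle = build_design(records, terms=())
    se = np.sqrt(bundle.meas_var)
    return DesignMatrixBundle(
        response=bundle.response,
        meas_var=bundle.meas_var,
        X=np.column_stack([np.ones(bundle.n_obs), se]),
        columns=["intercept", "se"],
        coding={"se": {"type": "covariate_raw"}},
        groups=bundle.groups,
        group_labels=bundle.group_labels,
    )


def egger_mixed(
    records: Sequence[EffectRecord],
    prior: Prior = Prior(),
    settings: MCMCSettings = MCMCSettings(),
    random_effects: Optional[Sequence[str]] = None,
) -> Tuple[FitSummary, PosteriorSamples, bool]:
    """Mixed-model Egger regression.

    Fits Fisher-Z effects, inverse-variance weighted, on their standard
    errors under the same nested random structure as the main
    meta-analysis.  Returns the fit summary, the raw draws, and a flag
    that is True when the SE slope's 95% CI excludes zero (funnel
    asymmetry).
    """
    bundle = egger_design(records)
    samples = fit(bundle, prior, settings, random_effects=random_effects)
    summary = summarize(samples, bundle)
    slope = summary.fixed["se"]
    asymmetric = not (slope.ci_low <= 0.0 <= slope.ci_high)
    return summary, samples, asymmetric
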