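"""Publication-bias machinery: REML random effects, trim-and-fill, Egger."""

import math

import numpy as np
import pytest
from scipy import optimize

from metacare.bias import (
    egger_design,
    egger_mixed,
    reml_random_effects,
    restricted_loglik,
    trim_fill,
)
from metacare.dataset import DesignMatrixBundle, EffectRecord
from metacare.effects import EffectSize
from metacare.mixed import MCMCSettings, fit

from conftest import short_settings

# 10-point funnel built by deleting the 3 most extreme right-hand points
# of a symmetric 13-point funnel (precise core, imprecise extremes)
FUNNEL_Y = np.array([-0.55, -0.42, -0.30, -0.11, -0.07, -0.03,
                     0.0, 0.035, 0.075, 0.115])
FUNNEL_V = np.array([0.30, 0.25, 0.20, 0.012, 0.009, 0.006,
                     0.004, 0.006, 0.009, 0.012])


def test_reml_all_effects_equal_gives_tau2_zero():
    fit_ = reml_random_effects([0.3, 0.3, 0.3, 0.3], [0.1, 0.2, 0.05, 0.4])
    assert fit_.mu == pytest.approx(0.3)
    assert fit_.tau2 == 0.0


def test_reml_matches_grid_maximisation():
    """tau2 from the bounded optimiser must match an independent 1-D grid
    maximisation of the restricted likelihood to 1e-6."""
    rng = np.random.default_rng(11)
    y = rng.normal(0.3, 0.3, 30)
    v = np.full(30, 0.05)
    est = reml_random_effects(y, v)
    # two-stage grid, written against the restricted-likelihood formula
    coarse = np.linspace(0.0, 1.0, 2001)
    ll = [restricted_loglik(t, y, v) for t in coarse]
    t0 = coarse[int(np.argmax(ll))]
    fine = np.linspace(max(t0 - 5e-4, 0.0), t0 + 5e-4, 2001)
    llf = [restricted_loglik(t, y, v) for t in fine]
    t_grid = fine[int(np.argmax(llf))]
    assert est.tau2 == pytest.approx(t_grid, abs=1e-6)


def test_reml_tau2_zero_reduces_to_fixed_effect_pooling():
    rng = np.random.default_rng(12)
    v = rng.uniform(0.01, 0.1, 25)
    y = rng.normal(0.2, np.sqrt(v))  # no heterogeneity beyond sampling error
    est = reml_random_effects(y, v)
    w = 1.0 / (v + est.tau2)
    assert est.mu == pytest.approx(float((w * y).sum() / w.sum()), abs=1e-12)
    if est.tau2 == 0.0:
        w0 = 1.0 / v
        assert est.mu == pytest.approx(float((w0 * y).sum() / w0.sum()), abs=1e-12)


def test_reml_tau2_recovery_simulation():
    rng = np.random.default_rng(13)
    tau2_true = 0.05
    estimates = []
    for _ in range(20):
        v = rng.uniform(0.01, 0.1, 200)
        y = rng.normal(0.0, np.sqrt(v + tau2_true))
        estimates.append(reml_random_effects(y, v).tau2)
    assert np.mean(estimates) == pytest.approx(tau2_true, rel=0.2)


def test_trim_fill_symmetric_funnel_imputes_nothing():
    d = np.array([0.05, 0.13, 0.22, 0.34, 0.47])
    y = np.concatenate([[0.2], 0.2 + d, 0.2 - d])
    v = np.concatenate([[0.01], np.linspace(0.02, 0.2, 5), np.linspace(0.02, 0.2, 5)])
    res = trim_fill(y, v)
    assert res.k0 == 0
    assert res.adjusted.mu == res.unadjusted.mu
    assert not res.funnel.filled.any()


def _oracle_trim_fill(y, v):
    """Independent step-by-step execution of the iterative L0 procedure:
    own REML (scipy bounded optimiser on the restricted likelihood written
    out here), explicit rank arithmetic, explicit mirroring."""

    def reml_mu(yy, vv):
        def nll(t):
            w = 1.0 / (vv + t)
            mu = (w * yy).sum() / w.sum()
            return 0.5 * (np.log(vv + t).sum() + math.log(w.sum())
                          + (w * (yy - mu) ** 2).sum())
        res = optimize.minimize_scalar(nll, bounds=(0.0, max(10 * yy.var(ddof=1), 1e-3)),
                                       method="bounded", options={"xatol": 1e-10})
        t = res.x if nll(res.x) < nll(0.0) else 0.0
        w = 1.0 / (vv + t)
        return float((w * yy).sum() / w.sum())

    def l0(dev):
        n = dev.size
        ranks = np.argsort(np.argsort(np.abs(dev))) + 1
        t_n = ranks[dev > 0].sum()
        return max(0, int(round((4.0 * t_n - n * (n + 1.0)) / (2.0 * n - 1.0))))

    best = (0, None)
    for excess in (-1.0, 1.0):  # excess side left / right
        k0 = 0
        for _ in range(50):
            keep = np.ones(y.size, bool)
            if k0:
                dev0 = excess * (y - reml_mu(y, v))
                keep[np.argsort(-dev0)[:k0]] = False
            centre = reml_mu(y[keep], v[keep])
            k0_new = min(l0(excess * (y - centre)), y.size - 2)
            if k0_new == k0:
                break
            k0 = k0_new
        if k0 > best[0]:
            best = (k0, excess)
    k0, excess = best
    if k0 == 0:
        return 0, reml_mu(y, v)
    dev0 = excess * (y - reml_mu(y, v))
    idx = np.argsort(-dev0)[:k0]
    keep = np.ones(y.size, bool)
    keep[idx] = False
    centre = reml_mu(y[keep], v[keep])
    y_all = np.concatenate([y, 2 * centre - y[idx]])
    v_all = np.concatenate([v, v[idx]])
    return k0, reml_mu(y_all, v_all)


def test_trim_fill_matches_hand_executed_oracle():
    res = trim_fill(FUNNEL_Y, FUNNEL_V)
    k0_oracle, mu_oracle = _oracle_trim_fill(FUNNEL_Y, FUNNEL_V)
    assert res.k0 == k0_oracle == 3         # the three deleted points are recovered
    assert res.side == "right"              # they were missing on the right
    assert res.adjusted.mu == pytest.approx(mu_oracle, abs=1e-8)
    assert res.funnel.filled.sum() == 3


def test_trim_fill_idempotent_on_filled_output():
    res = trim_fill(FUNNEL_Y, FUNNEL_V)
    again = trim_fill(res.funnel.effects, res.funnel.ses**2)
    assert again.k0 == 0


def test_trim_fill_mirroring_preserves_centre():
    res = trim_fill(FUNNEL_Y, FUNNEL_V)
    filled = res.funnel.effects[res.funnel.filled]
    dev0 = -(FUNNEL_Y - res.unadjusted.mu)
    original = FUNNEL_Y[np.argsort(-dev0)[: res.k0]]
    keep = np.ones(FUNNEL_Y.size, bool)
    keep[np.argsort(-dev0)[: res.k0]] = False
    centre = reml_random_effects(FUNNEL_Y[keep], FUNNEL_V[keep]).mu
    assert (filled + original) / 2 == pytest.approx(centre, abs=1e-10)


def test_trim_fill_too_few_points_raises():
    with pytest.raises(ValueError):
        trim_fill([0.1, 0.2], [0.1, 0.1])


def test_egger_design_uses_raw_se(paper_records):
    records, _ = paper_records
    bundle = egger_design(records)
    assert bundle.columns == ["intercept", "se"]
    assert bundle.X[:, 1] == pytest.approx(np.sqrt(bundle.meas_var))


def test_egger_slope_matches_wls_closed_form():
    """Single group, no random effects, units variance fixed: the SE slope
    posterior mean equals the weighted least squares solution."""
    rng = np.random.default_rng(8)
    n = 60
    v = rng.uniform(0.01, 0.2, n)
    se = np.sqrt(v)
    y = 0.2 + 2.0 * se + rng.normal(0, se)
    X = np.column_stack([np.ones(n), se])
    bundle = DesignMatrixBundle(response=y, meas_var=v, X=X,
                                columns=["intercept", "se"], coding={},
                                groups={}, group_labels={})
    s = fit(bundle, settings=MCMCSettings(iterations=5000, burn_in=1000, thin=1,
                                          n_chains=1, seed=3), units_variance=0.0)
    w = 1.0 / v
    wls = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
    draws = s.beta[:, 1]
    mcse = draws.std() / math.sqrt(draws.size)
    assert abs(draws.mean() - wls[1]) < 3 * mcse


def test_egger_detects_constructed_dependence():
    """Effects built as 2*SE + noise must yield an SE-slope CI excluding 0."""
    rng = np.random.default_rng(21)
    recs = []
    for i in range(80):
        n = int(rng.integers(10, 120))
        se = math.sqrt(1.0 / (n - 3))
        zr = 2.0 * se + rng.normal(0, se * 0.5)
        fam = i % 5
        recs.append(EffectRecord(
            effect=EffectSize.from_r(math.tanh(zr), n), effect_id=f"e{i}",
            study_id=f"s{i % 20}", species=f"sp{i % 10}", family=f"f{fam}",
            tax_class=f"c{fam % 2}",
        ))
    summary, _, asymmetric = egger_mixed(recs, settings=short_settings(seed=2, n_chains=2))
    assert asymmetric
    assert summary.fixed["se"].ci_low > 0
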