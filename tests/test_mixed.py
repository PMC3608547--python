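"""Gibbs sampler correctness: conjugate limits, independent integration
oracle, schedule arithmetic, pMCMC, DIC and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from metacare.dataset import DesignMatrixBundle
from metacare.diagnostics import gelman_rubin
from metacare.mixed import (
    MCMCSettings,
    PosteriorSamples,
    Prior,
    dic,
    fit,
    pmcmc,
    summarize,
    summarize_draws,
)
from metacare.simulate import SyntheticConfig, generate_dataset
from metacare import build_design

from conftest import short_settings


def _flat_bundle(y, v, X=None, columns=None, groups=None, labels=None):
    n = len(y)
    return DesignMatrixBundle(
        response=np.asarray(y, float), meas_var=np.asarray(v, float),
        X=np.ones((n, 1)) if X is None else X,
        columns=columns or ["intercept"], coding={},
        groups=groups or {}, group_labels=labels or {},
    )


def test_schedule_arithmetic():
    s = MCMCSettings.reference_schedule()
    assert (s.iterations, s.burn_in, s.thin) == (3_000_000, 2_500_000, 100)
    assert s.retained_per_chain == 5000
    assert MCMCSettings(iterations=1000, burn_in=100, thin=7).retained_per_chain == 128
    with pytest.raises(ValueError):
        MCMCSettings(iterations=100, burn_in=100, thin=1)


def test_intercept_only_matches_conjugate_posterior():
    """With no random effects and the units variance fixed, the intercept
    posterior is the closed-form inverse-variance-weighted normal."""
    rng = np.random.default_rng(5)
    n = 20
    v = rng.uniform(0.02, 0.3, n)
    y = rng.normal(0.4, np.sqrt(v))
    bundle = _flat_bundle(y, v)
    s = fit(bundle, settings=MCMCSettings(iterations=6000, burn_in=1000, thin=1,
                                          n_chains=1, seed=2), units_variance=0.0)
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    var = 1.0 / w.sum()
    draws = s.beta[:, 0]
    mcse = draws.std() / math.sqrt(draws.size)
    assert abs(draws.mean() - mu) < 3 * mcse
    # posterior variance of the conjugate normal (draws are iid here)
    assert draws.var() == pytest.approx(var, rel=0.15)


def test_gibbs_matches_grid_integration_oracle():
    """Two-level toy (10 groups x 5 obs, known v_i): posterior means of the
    mean and the group variance agree with fine-grid numerical integration
    of the marginal posterior within Monte-Carlo error."""
    rng = np.random.default_rng(77)
    G, m = 10, 5
    v = rng.uniform(0.02, 0.1, G * m)
    groups = np.repeat(np.arange(G), m)
    u = rng.normal(0, math.sqrt(0.08), G)
    y = 0.3 + u[groups] + rng.normal(0, np.sqrt(v))

    def loglik(beta, s2):
        ll = 0.0
        for g in range(G):
            idx = groups == g
            vg = v[idx]
            r = y[idx] - beta
            sinv = (1 / vg).sum()
            quad = (r**2 / vg).sum() - s2 * ((r / vg).sum() ** 2) / (1 + s2 * sinv)
            ll += -0.5 * (np.log(vg).sum() + math.log1p(s2 * sinv) + quad)
        return ll

    nu, V = 0.002, 1.0
    betas = np.linspace(-0.1, 0.8, 121)
    s2s = np.linspace(1e-4, 0.6, 240)
    logp = np.array([[loglik(b, s2) - (nu / 2 + 1) * math.log(s2) - nu * V / (2 * s2)
                      for s2 in s2s] for b in betas])
    p = np.exp(logp - logp.max())
    e_beta = (p.sum(axis=1) * betas).sum() / p.sum()
    e_s2 = (p.sum(axis=0) * s2s).sum() / p.sum()

    bundle = _flat_bundle(y, v, groups={"study": groups},
                          labels={"study": [f"g{i}" for i in range(G)]})
    s = fit(bundle, settings=MCMCSettings(iterations=16000, burn_in=4000, thin=2,
                                          n_chains=3, seed=5), units_variance=0.0)

    def batch_mcse(x, nb=40):
        k = x.size // nb
        bm = x[: nb * k].reshape(nb, k).mean(axis=1)
        return bm.std(ddof=1) / math.sqrt(nb)

    assert abs(s.beta[:, 0].mean() - e_beta) < 3 * batch_mcse(s.beta[:, 0])
    assert abs(s.sigma2[:, 0].mean() - e_s2) < 3 * batch_mcse(s.sigma2[:, 0])


def test_ols_limit_without_measurement_error():
    rng = np.random.default_rng(3)
    n = 50
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [0.2, 0.5] + rng.normal(0, 0.3, n)
    bundle = _flat_bundle(y, np.full(n, 1e-8), X=X, columns=["b0", "b1"])
    s = fit(bundle, settings=short_settings(seed=1))
    bhat = np.linalg.lstsq(X, y, rcond=None)[0]
    assert s.beta.mean(axis=0) == pytest.approx(bhat, abs=0.02)


def test_row_permutation_leaves_draws_identical():
    records, _ = generate_dataset(SyntheticConfig.paper_like(seed=5))
    b1 = build_design(records)
    perm = np.random.default_rng(0).permutation(len(records))
    b2 = build_design([records[i] for i in perm])
    st_ = MCMCSettings(iterations=400, burn_in=100, thin=1, n_chains=1, seed=9)
    s1, s2 = fit(b1, settings=st_), fit(b2, settings=st_)
    assert np.array_equal(s1.beta, s2.beta)
    assert np.array_equal(s1.sigma2, s2.sigma2)


def test_same_seed_reproducible_and_chains_disperse():
    records, _ = generate_dataset(SyntheticConfig.paper_like(seed=8))
    bundle = build_design(records)
    st_ = MCMCSettings(iterations=1500, burn_in=500, thin=2, n_chains=2, seed=4)
    s1, s2 = fit(bundle, settings=st_), fit(bundle, settings=st_)
    assert np.array_equal(s1.beta, s2.beta)
    # different chains are genuinely different trajectories
    assert not np.array_equal(s1.per_chain("beta", 0)[0], s1.per_chain("beta", 0)[1])


def test_three_chains_reach_psr_threshold(paper_bundle):
    s = fit(paper_bundle, settings=MCMCSettings(iterations=6000, burn_in=2000,
                                                thin=4, n_chains=3, seed=11))
    psr = gelman_rubin(s.per_chain("beta", 0))
    assert psr < 1.1


def test_parameter_expanded_prior_agrees_with_inverse_gamma(paper_bundle):
    """Both variance priors should give compatible intercept posteriors on a
    dataset where the variances are well away from zero."""
    st_ = MCMCSettings(iterations=6000, burn_in=2000, thin=4, n_chains=2, seed=3)
    s_ig = fit(paper_bundle, prior=Prior(), settings=st_)
    s_px = fit(paper_bundle, prior=Prior.parameter_expanded(), settings=st_)
    m_ig, m_px = s_ig.beta[:, 0].mean(), s_px.beta[:, 0].mean()
    sd = s_ig.beta[:, 0].std()
    # different priors: posteriors should be compatible, not identical
    assert abs(m_ig - m_px) < sd


@pytest.mark.parametrize(
    "pos, neg, total, expected",
    [(5000, 0, 5000, 2 / 5000), (2500, 2500, 5000, 1.0), (4900, 100, 5000, 0.04)],
)
def test_pmcmc_examples(pos, neg, total, expected):
    draws = np.concatenate([np.ones(pos), -np.ones(neg)])
    assert pmcmc(draws) == pytest.approx(expected)


@given(st.integers(2, 500), st.integers(0, 500))
@hsettings(derandomize=True, max_examples=30)
def test_pmcmc_bounds(n_pos, n_neg):
    if n_pos + n_neg < 2:
        n_neg = 2 - n_pos
    draws = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    p = pmcmc(draws)
    assert 2.0 / draws.size <= p <= 1.0


def test_summarize_constant_and_normal_draws():
    s = summarize_draws(np.full(500, 3.25))
    assert (s.mean, s.mode, s.ci_low, s.ci_high) == (3.25, 3.25, 3.25, 3.25)
    rng = np.random.default_rng(0)
    sn = summarize_draws(rng.standard_normal(5000))
    assert sn.ci_low == pytest.approx(-1.96, abs=0.1)
    assert sn.ci_high == pytest.approx(1.96, abs=0.1)


def test_variance_percent_sums_to_100(paper_bundle):
    s = fit(paper_bundle, settings=short_settings(seed=2))
    summ = summarize(s, paper_bundle)
    assert sum(summ.variance_percent.values()) == pytest.approx(100.0, abs=1e-6)
    assert set(summ.variance_percent) == {"class", "family", "species", "study", "units"}


def test_dic_constant_deviance_gives_pd_zero():
    n = 10
    y = np.zeros(n)
    v = np.ones(n)
    bundle = _flat_bundle(y, v)
    dev = float(np.sum(np.log(2 * math.pi * (v + 1.0)) + y**2 / (v + 1.0)))
    samples = PosteriorSamples(
        beta=np.zeros((200, 1)), sigma2=np.ones((200, 1)),
        deviance=np.full(200, dev), beta_names=["intercept"],
        sigma2_names=["units"], chain_id=np.zeros(200, dtype=int),
        u_mean={}, settings=MCMCSettings(iterations=400, burn_in=200, thin=1,
                                         n_chains=1, seed=0), prior=Prior(),
    )
    assert dic(samples, bundle) == pytest.approx(dev, abs=1e-9)


def test_dic_discriminates_strong_signal_and_not_noise():
    """DIC must prefer the interaction model when the interaction is strong,
    and show no systematic preference for a spurious extra covariate."""
    from metacare.suite import select_by_dic

    st_ = MCMCSettings(iterations=3000, burn_in=1000, thin=2, n_chains=2, seed=0)
    complete = {"multiple_paternity": 0.0, "zr_cost": 0.0,
                "zr_benefit": 0.0, "prop_male_care": 0.0}
    wins_strong = 0
    deltas_null = []
    for rep in range(6):
        cfg = SyntheticConfig.paper_like(
            seed=600 + rep,
            beta_true={"intercept": 0.365, "zr_cost": 0.02,
                       "multiple_paternity": 0.02,
                       "zr_cost:multiple_paternity": 0.35},
            missingness=complete,
        )
        recs, _ = generate_dataset(cfg)
        sel = select_by_dic(recs, ["zr_cost", "multiple_paternity"],
                            [("zr_cost", "multiple_paternity")], settings=st_)
        wins_strong += sel["best_model"] != "main"

        cfg0 = SyntheticConfig.paper_like(
            seed=700 + rep,
            beta_true={"intercept": 0.365, "zr_cost": 0.02,
                       "multiple_paternity": 0.02},
            missingness=complete,
        )
        recs0, _ = generate_dataset(cfg0)
        sel0 = select_by_dic(recs0, ["zr_cost", "multiple_paternity"],
                             [("zr_cost", "multiple_paternity")], settings=st_)
        d = sel0["dic_by_model"]["main+zr_cost:multiple_paternity"] \
            - sel0["dic_by_model"]["main"]
        deltas_null.append(d)
    assert wins_strong >= 5
    # a pure-noise interaction produces no systematic large DIC drop
    assert np.mean(deltas_null) > -2.0


def test_singleton_random_factor_dropped_with_warning():
    rng = np.random.default_rng(1)
    n = 12
    y = rng.normal(0, 0.3, n)
    v = np.full(n, 0.05)
    bundle = _flat_bundle(
        y, v,
        groups={"class": np.zeros(n, dtype=int), "study": np.arange(n) % 4},
        labels={"class": ["only"], "study": ["a", "b", "c", "d"]},
    )
    with pytest.warns(UserWarning, match="single level"):
        s = fit(bundle, settings=short_settings(seed=0))
    assert s.sigma2_names == ["study", "units"]
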