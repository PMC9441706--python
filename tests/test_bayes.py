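"""Hierarchical model density, sampler contract, diagnostics,
strategy classification."""

import math

import numpy as np
import pytest
from scipy import stats as ss

import apastep as ap
from apastep.bayes import (
    PRIOR_ALPHA_SD,
    PRIOR_SIGMA_ALPHA_SCALE,
    PRIOR_SIGMA_K_UPPER,
    HierarchicalModel,
    HierarchicalPosterior,
    classify_strategy,
    fit,
    invlogit,
    log_posterior,
    split_rhat,
)


def _toy_model():
    return HierarchicalModel(
        mu_sm_mm=np.array([45.0, 44.0]),
        mu_sl_mm=np.array([30.0, 28.0]),
        y_mm=[np.array([41.0, 43.0, 40.0]), np.array([35.0, 37.0])],
        participants=["P1", "P2"],
    )


def _naive_log_posterior(model, alpha, sigma_alpha, alpha_k, sigma_k):
    """Term-by-term oracle using scipy distributions."""
    lp = ss.norm.logpdf(alpha, 0.0, PRIOR_ALPHA_SD)
    lp += ss.halfcauchy.logpdf(sigma_alpha, scale=PRIOR_SIGMA_ALPHA_SCALE)
    for k in range(model.n_participants):
        lp += ss.uniform.logpdf(sigma_k[k], 0, PRIOR_SIGMA_K_UPPER)
        lp += ss.norm.logpdf(alpha_k[k], alpha, sigma_alpha)
        theta = 1 / (1 + math.exp(-alpha_k[k]))
        mu_d = theta * model.mu_sm_mm[k] + (1 - theta) * model.mu_sl_mm[k]
        for y in model.y_mm[k]:
            lp += ss.norm.logpdf(y, mu_d, sigma_k[k])
    return lp


def test_log_posterior_matches_naive_summation():
    model = _toy_model()
    args = (0.7, 0.9, np.array([1.2, -0.3]), np.array([3.0, 2.5]))
    assert log_posterior(model, *args) == pytest.approx(
        _naive_log_posterior(model, *args), abs=1e-10
    )


def test_log_posterior_out_of_support_is_minus_inf():
    model = _toy_model()
    assert log_posterior(model, 0.0, -1.0, np.zeros(2), np.ones(2)) == -math.inf
    assert log_posterior(model, 0.0, 1.0, np.zeros(2), np.array([1.0, 1001.0])) == -math.inf


def test_saturated_weight_reduces_to_medial_mean():
    """alpha_k -> +inf makes the likelihood a Gaussian at mu_SM."""
    model = HierarchicalModel(
        mu_sm_mm=np.array([45.0]),
        mu_sl_mm=np.array([30.0]),
        y_mm=[np.array([45.0])],
        participants=["P1"],
    )
    sigma = 2.0
    lp_full = log_posterior(model, 0.0, 1.0, np.array([40.0]), np.array([sigma]))
    lp_priors = (
        ss.norm.logpdf(0.0, 0.0, PRIOR_ALPHA_SD)
        + ss.halfcauchy.logpdf(1.0, scale=PRIOR_SIGMA_ALPHA_SCALE)
        + ss.uniform.logpdf(sigma, 0, PRIOR_SIGMA_K_UPPER)
        + ss.norm.logpdf(40.0, 0.0, 1.0)
    )
    # the single datum sits exactly at the mode of its Gaussian
    assert lp_full - lp_priors == pytest.approx(
        -math.log(sigma * math.sqrt(2 * math.pi)), abs=1e-9
    )


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_likelihood_dominance_concentrates_theta_near_one():
    rng = np.random.default_rng(0)
    model = HierarchicalModel(
        mu_sm_mm=np.array([45.0]),
        mu_sl_mm=np.array([30.0]),
        y_mm=[45.0 + 0.05 * rng.standard_normal(40)],
        participants=["P1"],
    )
    post = fit(model, chains=4, iterations=3000, warmup=1000, seed=1)
    theta = post.draws["theta_k"][:, :, 0]
    assert theta.mean() > 0.97


def test_fit_deterministic_under_seed(summary_cohort):
    _, table, _ = summary_cohort
    model = HierarchicalModel.from_cohort(table)
    a = fit(model, chains=2, iterations=1200, warmup=400, seed=9)
    b = fit(model, chains=2, iterations=1200, warmup=400, seed=9)
    assert np.array_equal(a.draws["alpha"], b.draws["alpha"])
    assert a.summary().equals(b.summary())


def test_split_rhat_iid_chains_near_one():
    # sampling noise can push the estimate marginally below 1
    rng = np.random.default_rng(4)
    draws = rng.standard_normal((4, 10_000))
    r = split_rhat(draws)
    assert 0.999 <= r <= 1.01


def test_split_rhat_disjoint_chains_large():
    draws = np.vstack([np.zeros(100), np.ones(100)])
    assert split_rhat(draws) > 5.0


def test_split_rhat_duplicated_chain_matches_split_only():
    """Duplicating one chain leaves only the within-chain split to
    detect nonstationarity."""
    rng = np.random.default_rng(5)
    one = rng.standard_normal(10_000)
    dup = np.vstack([one, one])
    halves = np.vstack([one[:5000], one[5000:]])
    assert split_rhat(dup) == pytest.approx(split_rhat(halves), abs=0.01)


def test_split_rhat_agrees_with_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(6)
    draws = rng.standard_normal((4, 2000)) + rng.normal(0, 0.05, size=(4, 1))
    mine = split_rhat(draws)
    theirs = float(az.rhat(az.convert_to_dataset(draws))["x"].values.item())
    assert mine == pytest.approx(theirs, abs=0.005)


def test_split_rhat_requires_two_chains():
    with pytest.raises(ValueError):
        split_rhat(np.zeros((1, 100)))


def _posterior_with_theta(value):
    draws = {
        "alpha": np.zeros((2, 8)),
        "sigma_alpha": np.ones((2, 8)),
        "alpha_k": np.full((2, 8, 1), math.log(value / (1 - value))),
        "sigma_k": np.ones((2, 8, 1)),
        "theta_group": np.full((2, 8), value),
        "theta_k": np.full((2, 8, 1), value),
    }
    return HierarchicalPosterior(
        draws=draws, participants=["P1"], converged=True, max_rhat=1.0
    )


@pytest.mark.parametrize(
    "theta,label",
    [(0.9, "medial"), (0.5, "intermediate"), (2.0 / 3.0, "medial"), (0.2, "lateral"),
     (1.0 / 3.0, "lateral")],
)
def test_strategy_classification_boundaries(theta, label):
    out = classify_strategy(_posterior_with_theta(theta))
    assert out["label"].iloc[0] == label
    assert out["ci_low"].iloc[0] <= out["theta_mean"].iloc[0] <= out["ci_high"].iloc[0]


def test_prior_weight_symmetric_about_half():
    """Forward draws from the priors alone put theta symmetrically
    around 0.5."""
    rng = np.random.default_rng(7)
    n = 200_000
    alpha = rng.normal(0.0, PRIOR_ALPHA_SD, n)
    sigma_a = np.abs(PRIOR_SIGMA_ALPHA_SCALE * rng.standard_cauchy(n))
    alpha_k = rng.normal(alpha, sigma_a)
    assert invlogit(alpha_k).mean() == pytest.approx(0.5, abs=0.02)


def test_posterior_summary_contains_credible_means(summary_cohort):
    _, table, _ = summary_cohort
    model = HierarchicalModel.from_cohort(table)
    post = fit(model, chains=4, iterations=2000, warmup=500, seed=2)
    s = post.summary().set_index("parameter")
    for name in ("alpha", "sigma_alpha"):
        row = s.loc[name]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]
        assert row["ci_low"] <= row["median"] <= row["ci_high"]
    # alpha, sigma_alpha, theta_group + (alpha_k, sigma_k, theta_k) per participant
    assert len(s) == 3 + 3 * model.n_participants


def test_insufficient_dual_trials_rejected():
    with pytest.raises(ValueError, match="2 dual trials"):
        HierarchicalModel(
            mu_sm_mm=np.array([45.0]),
            mu_sl_mm=np.array([30.0]),
            y_mm=[np.array([40.0])],
            participants=["P1"],
        ).validate()
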