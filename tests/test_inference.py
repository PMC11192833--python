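"""WAIC arithmetic, HDI, the DE-MCMC kernel on known targets, and the
hierarchical posterior pieces."""

import numpy as np
import pytest

from orthomem.inference import (
    DEFAULT_SPECS,
    FitConfig,
    ParameterSpec,
    ParticipantData,
    de_mcmc_sample,
    group_logdensity,
    hdi,
    participant_log_posterior,
    split_rhat,
    waic,
)


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------


def test_waic_hand_computation():
    ll = np.array([[-1.0, -2.0], [-1.5, -2.5], [-0.5, -1.5]])
    report = waic(ll)
    lppd = sum(np.log(np.mean(np.exp(ll[:, i]))) for i in range(2))
    p_waic = sum(np.var(ll[:, i], ddof=1) for i in range(2))
    assert report["lppd"] == pytest.approx(lppd)
    assert report["p_waic"] == pytest.approx(p_waic)
    assert report["waic"] == pytest.approx(-2 * (lppd - p_waic))


def test_waic_identical_draws_has_zero_penalty():
    ll = np.tile(np.array([-1.2, -0.7, -2.0]), (5, 1))
    report = waic(ll)
    assert report["p_waic"] == pytest.approx(0.0)
    assert report["waic"] == pytest.approx(-2 * ll[0].sum())


def test_waic_penalty_grows_with_irrelevant_noise():
    rng = np.random.default_rng(2)
    base = np.tile(rng.normal(-1.0, 0.1, size=30), (40, 1))
    noisy = base + rng.normal(0.0, 0.4, size=base.shape)
    assert waic(noisy)["p_waic"] > waic(base)["p_waic"]


def test_waic_requires_two_draws():
    with pytest.raises(ValueError):
        waic(np.array([[-1.0, -2.0]]))


def test_hdi_of_symmetric_sample_is_central():
    x = np.random.default_rng(3).normal(size=40_000)
    lo, hi = hdi(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.08)
    assert hi == pytest.approx(1.96, abs=0.08)


# ---------------------------------------------------------------------------
# DE-MCMC kernel
# ---------------------------------------------------------------------------


def test_de_mcmc_recovers_correlated_normal_target():
    cov = np.array([[1.0, 0.8], [0.8, 1.0]])
    mean = np.array([1.5, -0.5])
    prec = np.linalg.inv(cov)

    def logpdf(x):
        d = x - mean
        return -0.5 * d @ prec @ d

    draws = de_mcmc_sample(logpdf, d=2, n_chains=10, n_iter=2000, seed=4)
    flat = draws.reshape(-1, 2)
    # MC standard error with a conservative effective-sample deflation
    se = np.sqrt(np.diag(cov) / (len(flat) / 20))
    assert np.all(np.abs(flat.mean(axis=0) - mean) < 3 * se)
    corr = np.corrcoef(flat.T)[0, 1]
    assert corr == pytest.approx(0.8, abs=0.1)


def test_de_mcmc_determinism_and_degenerate_tuning():
    logpdf = lambda x: -0.5 * float(x @ x)
    d1 = de_mcmc_sample(logpdf, d=2, n_iter=100, seed=9)
    d2 = de_mcmc_sample(logpdf, d=2, n_iter=100, seed=9)
    assert np.array_equal(d1, d2)
    with pytest.raises(ValueError):
        de_mcmc_sample(logpdf, d=2, gamma_de=0.0, jitter=0.0)
    with pytest.raises(ValueError):
        de_mcmc_sample(logpdf, d=3, n_chains=4)


def test_split_rhat_flags_divergent_chains():
    rng = np.random.default_rng(5)
    good = rng.normal(size=(4, 400))
    bad = good + np.array([0.0, 0.0, 5.0, 5.0])[:, None]
    assert split_rhat(good) < 1.05
    assert split_rhat(bad) > 1.5


# ---------------------------------------------------------------------------
# Hierarchical posterior pieces
# ---------------------------------------------------------------------------


def test_flat_group_prior_reduces_to_likelihood_plus_constant():
    specs = (ParameterSpec("x", "real"),)
    wide = participant_log_posterior(-10.0, [0.3], np.array([0.0]), np.array([1e6]), specs)
    wide2 = participant_log_posterior(-12.0, [0.3], np.array([0.0]), np.array([1e6]), specs)
    assert wide - wide2 == pytest.approx(2.0)


def test_normal_normal_shrinkage_closed_form():
    """With a quadratic 'likelihood' centred at x-hat, tightening the
    group SD pulls the posterior mode toward mu by the conjugate
    shrinkage weight."""
    specs = (ParameterSpec("x", "real"),)
    x_hat, lik_sd, mu = 2.0, 0.5, 0.0
    grid = np.linspace(-1, 3, 4001)
    for group_sd in (10.0, 0.5, 0.1):
        post = [
            participant_log_posterior(
                -0.5 * ((x - x_hat) / lik_sd) ** 2, [x], np.array([mu]), np.array([group_sd]), specs
            )
            for x in grid
        ]
        mode = grid[int(np.argmax(post))]
        weight = (1 / lik_sd**2) / (1 / lik_sd**2 + 1 / group_sd**2)
        assert mode == pytest.approx(weight * x_hat + (1 - weight) * mu, abs=2e-3)


def test_out_of_support_parameters_get_minus_inf():
    specs = (ParameterSpec("b", "positive"),)
    assert group_logdensity(np.array([-0.5]), np.array([1.0]), np.array([0.5]), specs) == -np.inf
    assert np.isfinite(
        group_logdensity(np.array([0.5]), np.array([1.0]), np.array([0.5]), specs)
    )


def test_trial_below_t0_propagates_minus_inf():
    data = ParticipantData(
        rt=[0.6, 0.2],
        old=[True, False],
        is_target=[True, False],
        sim_flat=[0.5, 0.4],
        offsets=[0, 1],
        list_len=[1, 1],
    )
    config = FitConfig()
    theta = {"V_target": 1.0, "V_lure": -1.0, "gamma_target": 0.0, "gamma_lure": 0.0,
             "B": 1.0, "t0": 0.25, "V0": 2.0, "eta_target": 1.2, "p": 3.0}
    pw = data.pointwise_loglik(theta, config)
    assert np.isfinite(pw[0]) and pw[1] == -np.inf
    assert data.loglik(theta, config) == -np.inf


def test_chain_loglik_matches_scalar_path():
    rng = np.random.default_rng(8)
    n = 50
    data = ParticipantData(
        rt=rng.uniform(0.4, 1.5, n),
        old=rng.uniform(size=n) < 0.5,
        is_target=rng.uniform(size=n) < 0.5,
        sim_flat=rng.uniform(0, 0.8, n * 5),
        offsets=np.arange(0, 5 * n, 5),
        list_len=np.full(n, 5.0),
    )
    config = FitConfig()
    names = [s.name for s in DEFAULT_SPECS]
    matrix = np.array([
        [1.0, -1.0, 0.5, 20.0, 1.0, 0.25, 2.0, 1.2, 3.0],
        [0.8, -0.9, 0.0, 50.0, 1.2, 0.30, 1.8, 1.0, 2.0],
    ])
    batched = data.chain_loglik({n_: matrix[:, j] for j, n_ in enumerate(names)}, config.A)
    for row, expected in zip(matrix, batched):
        assert data.loglik(dict(zip(names, row)), config) == pytest.approx(expected)


def test_posterior_predictive_recovers_data_level_summaries():
    """A short hierarchical fit's posterior predictive brackets the
    observed hit and false alarm rates of the fitted dataset."""
    from orthomem.inference import fit_recognition_model, posterior_predictive
    from orthomem.synthetic_data import StudyDesign, simulate_study

    design = StudyDesign(n_participants=2, n_test_trials=80, list_length=30, pool_size=300)
    trials, _ = simulate_study(design, FitConfig(), seed=14)

    def summarize(frame):
        return {
            "hr": (frame.loc[frame.status == "target", "response"] == "old").mean(),
            "far": (frame.loc[frame.status == "lure", "response"] == "old").mean(),
        }

    fit, _ = fit_recognition_model(trials, FitConfig(), n_iter=80, seed=14)
    pred = posterior_predictive(fit, trials, FitConfig(), summarize, n_draws=20, seed=14)
    pred = pred.set_index("summary")
    observed = summarize(trials)
    for key in ("hr", "far"):
        row = pred.loc[key]
        assert 0.0 <= row["hdi_low"] <= row["mean"] <= row["hdi_high"] <= 1.0
        # predictive interval brackets the data summary (wide by design
        # at this chain length)
        assert row["hdi_low"] - 0.1 <= observed[key] <= row["hdi_high"] + 0.1
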