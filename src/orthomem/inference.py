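"""Hierarchical Bayesian estimation by differential-evolution MCMC
(DE-MCMC) and WAIC model comparison.

Participant-level parameters are tied together by group-level normal or
truncated-normal distributions with mean ``mu`` and SD ``sigma``; the
posterior combines each participant's trial likelihoods, the density of
their parameters under the group distributions, and weak priors on the
group parameters.  Chains propose crossover moves

    theta* = theta_i + gamma_DE * (theta_j - theta_k) + U(-jitter, jitter)

with ``j != k != i`` drawn per step, which adapts proposals to the
strong parameter correlations typical of accumulator models.  Updates
are blocked: each participant's vector and each group (mu, sigma) pair
is a separate Metropolis block.

Model comparison uses the widely applicable information criterion

    WAIC = -2 * (lppd - p_waic)

with ``lppd = sum_i log mean_s exp(ll_si)`` and the penalty
``p_waic = sum_i var_s(ll_si)`` computed from the pointwise
log-likelihood matrix over posterior draws; lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from . import lba as _lba
from .global_similarity import pairwise_profile
from .lba import LBAParams, simulate_trials
from .orthography import EdgeMix, ExteriorWeights, OverlapParams

__all__ = [
    "ParameterSpec",
    "FitConfig",
    "ParticipantData",
    "DEFAULT_SPECS",
    "waic",
    "hdi",
    "split_rhat",
    "de_mcmc_sample",
    "participant_log_posterior",
    "hierarchical_de_mcmc",
    "HierarchicalFit",
    "fit_recognition_model",
    "fit_single_participant",
    "posterior_predictive",
]

_SUPPORT_BOUNDS = {
    "real": (-np.inf, np.inf),
    "positive": (0.0, np.inf),
    "unit": (0.0, 1.0),
}


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter in the hierarchy.

    ``support`` selects the group-level family: ``real`` -> normal,
    ``positive``/``unit`` -> normal truncated to the support.
    ``mu_prior`` is the (mean, sd) of the normal prior on the group
    mean (truncated to the support); ``sigma_prior`` the scale of the
    half-normal prior on the group SD.  ``by_condition`` marks
    parameters that replicate across experimental conditions when a
    dataset has them (the recognition fit surface maps V and gamma by
    probe status).
    """

    name: str
    support: str = "real"
    mu_prior: tuple[float, float] = (0.0, 2.0)
    sigma_prior: float = 0.5
    init: float = 0.0
    by_condition: bool = False

    def __post_init__(self) -> None:
        if self.support not in _SUPPORT_BOUNDS:
            raise ValueError(f"unknown support {self.support!r}")


def _trunc_normal_logpdf(x, mu, sigma, lo: float, hi: float):
    """Log-density of N(mu, sigma) truncated to [lo, hi]; -inf outside
    the bounds or for nonpositive sigma."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sigma
        log_kernel = -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        if np.isneginf(lo) and np.isposinf(hi):
            log_z = 0.0
        else:
            zlo = -np.inf if np.isneginf(lo) else (lo - mu) / sigma
            zhi = np.inf if np.isposinf(hi) else (hi - mu) / sigma
            mass = (1.0 if np.isposinf(hi) else ndtr(zhi)) - (
                0.0 if np.isneginf(lo) else ndtr(zlo)
            )
            log_z = np.log(mass)
        out = np.where((x >= lo) & (x <= hi) & (sigma > 0), log_kernel - log_z, -np.inf)
    return out


def group_logdensity(theta, mu, sigma, specs: Sequence[ParameterSpec]):
    """Log-density of participant parameter vector(s) under the group
    distributions; ``theta`` has shape (..., d)."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros(theta.shape[:-1])
    for j, spec in enumerate(specs):
        lo, hi = _SUPPORT_BOUNDS[spec.support]
        out = out + _trunc_normal_logpdf(theta[..., j], mu[..., j], sigma[..., j], lo, hi)
    return out


def participant_log_posterior(
    loglik: float, theta, mu, sigma, specs: Sequence[ParameterSpec]
) -> float:
    """Unnormalized log-posterior contribution of one participant:
    data log-likelihood plus the group-level density of their
    parameters."""
    return float(loglik) + float(group_logdensity(np.asarray(theta), mu, sigma, specs))


# ---------------------------------------------------------------------------
# WAIC / summaries
# ---------------------------------------------------------------------------


def waic(ll_matrix) -> dict:
    """WAIC from a draws x trials pointwise log-likelihood matrix."""
    ll = np.asarray(ll_matrix, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, trials) matrix with at least 2 draws")
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return {"waic": -2.0 * (lppd - p_waic), "lppd": lppd, "p_waic": p_waic}


def hdi(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    k = max(int(np.ceil(prob * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def split_rhat(chains_draws) -> float:
    """Split-chain R-hat for a (chains, draws) array (via arviz)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.asarray(chains_draws, dtype=float)))


# ---------------------------------------------------------------------------
# DE-MCMC kernels
# ---------------------------------------------------------------------------


def _de_proposal(state: np.ndarray, rng: np.random.Generator, gamma_de: float, jitter: float):
    """Crossover proposals for every chain from two other distinct
    chains; ``state`` has shape (n_chains, d)."""
    n = state.shape[0]
    j = rng.integers(0, n - 1, size=n)
    j = j + (j >= np.arange(n))
    k = rng.integers(0, n - 2, size=n)
    # map k into {0..n-1} \ {i, j}
    lo = np.minimum(np.arange(n), j)
    hi = np.maximum(np.arange(n), j)
    k = k + (k >= lo)
    k = k + (k >= hi)
    step = gamma_de * (state[j] - state[k])
    noise = rng.uniform(-jitter, jitter, size=state.shape)
    return state + step + noise


def de_mcmc_sample(
    log_posterior: Callable[[np.ndarray], float],
    d: int,
    n_chains: int | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    gamma_de: float | None = None,
    jitter: float = 1e-4,
    burn_frac: float = 0.5,
    init: np.ndarray | None = None,
    init_scale: float = 0.1,
) -> np.ndarray:
    """Plain (non-hierarchical) DE-MCMC on a d-dimensional target.

    Returns post-burn-in draws of shape (n_chains, kept, d);
    deterministic given ``seed``.
    """
    if n_chains is None:
        n_chains = 2 * d + 2
    if n_chains < 2 * d + 1:
        raise ValueError(f"need at least {2 * d + 1} chains for a {d}-dimensional block")
    if gamma_de is None:
        gamma_de = 2.38 / np.sqrt(2.0 * d)
    if gamma_de == 0.0 and jitter == 0.0:
        raise ValueError("gamma_de = jitter = 0 leaves chains degenerate (proposals never move)")
    rng = np.random.default_rng(seed)
    if init is None:
        state = rng.normal(0.0, 1.0, size=(n_chains, d))
    else:
        init = np.asarray(init, dtype=float)
        state = init + init_scale * rng.standard_normal((n_chains, d))
    logp = np.array([log_posterior(s) for s in state])
    for c in np.flatnonzero(~np.isfinite(logp)):  # re-jitter dead starts
        for _ in range(100):
            if init is None:
                state[c] = rng.normal(0.0, 1.0, size=d)
            else:
                state[c] = init + init_scale * rng.standard_normal(d)
            logp[c] = log_posterior(state[c])
            if np.isfinite(logp[c]):
                break
    keep_from = int(burn_frac * n_iter)
    draws = np.empty((n_chains, n_iter - keep_from, d))
    for it in range(n_iter):
        prop = _de_proposal(state, rng, gamma_de, jitter)
        logp_prop = np.array([log_posterior(s) for s in prop])
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.uniform(size=n_chains)) < (logp_prop - logp)
        state[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        if it >= keep_from:
            draws[:, it - keep_from, :] = state
    return draws


# ---------------------------------------------------------------------------
# Recognition-model fit surface
# ---------------------------------------------------------------------------

DEFAULT_SPECS: tuple[ParameterSpec, ...] = (
    ParameterSpec("V_target", "real", (0.0, 3.0), 1.0, init=0.5, by_condition=True),
    ParameterSpec("V_lure", "real", (0.0, 3.0), 1.0, init=-0.5, by_condition=True),
    ParameterSpec("gamma_target", "real", (0.0, 300.0), 30.0, init=0.0, by_condition=True),
    ParameterSpec("gamma_lure", "real", (0.0, 300.0), 30.0, init=20.0, by_condition=True),
    ParameterSpec("B", "positive", (1.0, 1.0), 0.5, init=1.0),
    ParameterSpec("t0", "positive", (0.3, 0.3), 0.1, init=0.25),
    ParameterSpec("V0", "positive", (2.0, 2.0), 0.5, init=2.0),
    ParameterSpec("eta_target", "positive", (1.0, 1.0), 0.3, init=1.2),
    ParameterSpec("p", "positive", (2.0, 5.0), 0.5, init=2.0),
)


@dataclass(frozen=True)
class FitConfig:
    """What to fit and what to hold fixed.

    The representation parameters (scheme, exterior weights, overlap
    schedule, edge mix, epsilon) are fixed so pairwise similarities can
    be precomputed once per dataset; the LBA parameters and the
    nonlinearity ``p`` are free.  ``free_p = False`` pins ``p`` at
    ``p_fixed`` (the linear model at 1.0).  The start-point range ``A``
    is held at a common design value.
    """

    scheme: str = "open-bigram"
    ew: ExteriorWeights = ExteriorWeights()
    op: OverlapParams | None = None
    mix: EdgeMix = EdgeMix()
    epsilon: float = 0.0
    free_p: bool = True
    p_fixed: float = 1.0
    A: float = 0.5

    def specs(self) -> tuple[ParameterSpec, ...]:
        specs = [s for s in DEFAULT_SPECS if s.name != "p" or self.free_p]
        return tuple(specs)


class ParticipantData:
    """One participant's trials with precomputed pairwise similarities.

    Stores the probe-to-list similarity values of every trial in a flat
    array with per-trial offsets, so a proposal only has to re-apply
    the power transform and the LBA likelihood.
    """

    def __init__(self, rt, old, is_target, sim_flat, offsets, list_len):
        self.rt = np.asarray(rt, dtype=float)
        self.old = np.asarray(old, dtype=bool)
        self.is_target = np.asarray(is_target, dtype=bool)
        self.sim_flat = np.asarray(sim_flat, dtype=float)
        self.offsets = np.asarray(offsets, dtype=np.intp)
        self.list_len = np.asarray(list_len, dtype=float)
        self.n_trials = len(self.rt)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, config: FitConfig) -> "ParticipantData":
        """Build from a trial table (columns ``probe``, ``study_list``
        as word lists or ';'-joined strings, ``status``, ``response``,
        ``rt_seconds``)."""
        cache: dict[tuple[str, str], float] = {}
        sims, offsets, list_len = [], [], []
        pos = 0
        for _, row in trials.iterrows():
            study = row["study_list"]
            if isinstance(study, str):
                study = study.split(";")
            probe = row["probe"]
            values = np.empty(len(study))
            for i, word in enumerate(study):
                key = (probe, word)
                if key not in cache:
                    cache[key] = pairwise_profile(
                        probe,
                        [word],
                        config.scheme,
                        ew=config.ew,
                        op=config.op,
                        mix=config.mix,
                        epsilon=config.epsilon,
                    )[0]
                values[i] = cache[key]
            offsets.append(pos)
            pos += len(study)
            sims.append(values)
            list_len.append(len(study))
        return cls(
            rt=trials["rt_seconds"].to_numpy(float),
            old=(trials["response"].to_numpy() == "old"),
            is_target=(trials["status"].to_numpy() == "target"),
            sim_flat=np.concatenate(sims) if sims else np.empty(0),
            offsets=offsets,
            list_len=list_len,
        )

    def global_similarity(self, p: float) -> np.ndarray:
        powered = self.sim_flat**p
        return np.add.reduceat(powered, self.offsets) / self.list_len

    def _drifts(self, theta: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        g = self.global_similarity(theta["p"])
        shift = np.where(
            self.is_target,
            theta["V_target"] + theta["gamma_target"] * g,
            theta["V_lure"] + theta["gamma_lure"] * g,
        )
        return theta["V0"] + shift, theta["V0"] - shift

    def chain_loglik(
        self, theta: Mapping[str, np.ndarray], A: float, pointwise: bool = False
    ) -> np.ndarray:
        """Log-likelihood for many parameter vectors at once.

        ``theta`` maps names to (C,) arrays (one entry per chain);
        returns (C,) sums or the (C, trials) pointwise matrix.
        """
        names = ("V_target", "V_lure", "gamma_target", "gamma_lure", "B", "t0", "V0",
                 "eta_target", "p")
        V_t, V_l, g_t, g_l, B, t0, V0, eta_t, p = (
            np.atleast_1d(np.asarray(theta[n], dtype=float)) for n in names
        )
        valid = (B > 0) & (t0 >= 0) & (eta_t > 0) & (p > 0)
        C = len(B)
        powered = self.sim_flat[None, :] ** np.where(valid, p, 1.0)[:, None]
        g = np.add.reduceat(powered, self.offsets, axis=1) / self.list_len[None, :]
        tgt = self.is_target[None, :]
        shift = np.where(
            tgt, V_t[:, None] + g_t[:, None] * g, V_l[:, None] + g_l[:, None] * g
        )
        v_old = V0[:, None] + shift
        v_new = V0[:, None] - shift
        eta = np.where(tgt, eta_t[:, None], 1.0)
        b = A + np.where(valid, B, 1.0)[:, None]
        tau = self.rt[None, :] - t0[:, None]
        ok = valid[:, None] & (tau > 0)
        tau = np.where(ok, tau, 1.0)
        old = self.old[None, :]
        b_w = b  # thresholds are shared between accumulators
        v_w = np.where(old, v_old, v_new)
        v_l_acc = np.where(old, v_new, v_old)
        pdf_w = _lba._density_vec(tau, b_w, A, v_w, eta)
        cdf_l = _lba._cdf_vec(tau, b_w, A, v_l_acc, eta)
        # Density floor: the closed-form density cancels to exactly 0 in
        # the far-left tail (fast RT, high threshold) although the true
        # value is merely tiny; flooring keeps such trials finite so
        # chains are not stranded by single extreme observations.
        with np.errstate(divide="ignore", invalid="ignore"):
            p_neg = ndtr(-v_old / eta) * ndtr(-v_new / eta)
            ll = (
                np.log(np.maximum(pdf_w, 1e-30))
                + np.log1p(-np.minimum(cdf_l, 1.0 - 1e-16))
                - np.log1p(-np.minimum(p_neg, 1.0 - 1e-16))
            )
        ll = np.where(ok, ll, -np.inf)
        return ll if pointwise else ll.sum(axis=1)

    def pointwise_loglik(self, theta: Mapping[str, float], config: FitConfig) -> np.ndarray:
        arrs = {k: np.atleast_1d(float(v)) for k, v in theta.items()}
        return self.chain_loglik(arrs, config.A, pointwise=True)[0]

    def loglik(self, theta: Mapping[str, float], config: FitConfig) -> float:
        return float(np.sum(self.pointwise_loglik(theta, config)))


def _theta_dict(vector: np.ndarray, specs: Sequence[ParameterSpec], config: FitConfig) -> dict:
    theta = {spec.name: float(v) for spec, v in zip(specs, vector)}
    if not config.free_p:
        theta["p"] = config.p_fixed
    return theta


# ---------------------------------------------------------------------------
# Hierarchical sampler
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalFit:
    """Posterior draws from :func:`hierarchical_de_mcmc`.

    Group-level arrays have shape (chains, kept, d); participant-level
    (chains, kept, P, d).
    """

    param_names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    accept_rate: float

    def mu_draws(self, name: str) -> np.ndarray:
        return self.mu[..., self.param_names.index(name)]

    def mu_hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        return hdi(self.mu_draws(name), prob)

    def rhat(self) -> dict[str, float]:
        return {name: split_rhat(self.mu_draws(name)) for name in self.param_names}

    def max_rhat(self) -> float:
        return max(self.rhat().values())

    def flat_theta(self) -> np.ndarray:
        """Participant draws flattened to (draws, P, d)."""
        c, k, p, d = self.theta.shape
        return self.theta.reshape(c * k, p, d)


def hierarchical_de_mcmc(
    loglik_fn: Callable[[int, np.ndarray], float],
    specs: Sequence[ParameterSpec],
    n_participants: int,
    n_chains: int | None = None,
    n_iter: int = 500,
    seed: int = 0,
    gamma_de: float | None = None,
    jitter: float = 1e-4,
    burn_frac: float = 0.5,
    migrate_prob: float = 0.1,
    theta_init: np.ndarray | None = None,
    group_sweeps: int = 5,
) -> HierarchicalFit:
    """Blocked DE-MCMC over participant vectors and group (mu, sigma).

    ``loglik_fn(p, theta_matrix)`` returns participant ``p``'s data
    log-likelihood for a (chains, d) matrix of parameter vectors as a
    (chains,) array.  Participant blocks use crossover proposals among
    chains; each parameter's (mu, sigma) pair is its own 2-D block.
    Chains are initialized overdispersed around each parameter's
    ``init`` value with spread tied to its prior scale.  Deterministic
    given ``seed``.
    """
    d = len(specs)
    if n_chains is None:
        n_chains = max(2 * d + 2, 8)
    if n_chains < 2 * d + 1:
        raise ValueError(f"need at least {2 * d + 1} chains for {d} free parameters")
    if gamma_de is None:
        gamma_de = 2.38 / np.sqrt(2.0 * d)
    rng = np.random.default_rng(seed)

    sig_scale = np.array([s.sigma_prior for s in specs])
    if theta_init is not None:
        # start around per-participant point estimates: chain mu around
        # their mean, sigma around their spread, theta jittered locally
        theta_init = np.asarray(theta_init, dtype=float)
        center = theta_init.mean(axis=0)
        spread = np.maximum(theta_init.std(axis=0), 0.05 * np.abs(center) + 0.01)
        mu = center + 0.5 * spread * rng.standard_normal((n_chains, d))
        sigma = np.abs(spread * (1.0 + 0.3 * rng.standard_normal((n_chains, d)))) + 1e-3
        theta = theta_init[None, :, :] + 0.3 * spread[None, None, :] * rng.standard_normal(
            (n_chains, n_participants, d)
        )
    else:
        mu_init = np.array([s.init for s in specs])
        mu_spread = np.array([max(0.1, 0.3 * s.mu_prior[1]) for s in specs])
        mu = mu_init + mu_spread * rng.standard_normal((n_chains, d))
        sigma = np.abs(0.5 * sig_scale * (1.0 + 0.5 * rng.standard_normal((n_chains, d)))) + 1e-3
        theta = mu[:, None, :] + sigma[:, None, :] * rng.standard_normal(
            (n_chains, n_participants, d)
        )
    for j, spec in enumerate(specs):  # keep initial states inside support
        lo, hi = _SUPPORT_BOUNDS[spec.support]
        lo_eff = lo + 1e-3 if np.isfinite(lo) else lo
        mu[:, j] = np.clip(mu[:, j], lo_eff, hi)
        theta[:, :, j] = np.clip(theta[:, :, j], lo_eff, hi)

    loglik = np.empty((n_chains, n_participants))
    for p in range(n_participants):
        loglik[:, p] = loglik_fn(p, theta[:, p, :])
        for _ in range(50):  # re-jitter dead starts toward the center
            bad = np.flatnonzero(~np.isfinite(loglik[:, p]))
            if len(bad) == 0:
                break
            center = (
                theta_init[p] if theta_init is not None else theta[:, p, :].mean(axis=0)
            )
            theta[bad, p, :] = 0.5 * (theta[bad, p, :] + center)
            loglik[bad, p] = loglik_fn(p, theta[bad, p, :])
    group_dens = np.empty((n_chains, n_participants))
    for c in range(n_chains):
        group_dens[c] = group_logdensity(theta[c], mu[c], sigma[c], specs)

    mu_prior_m = np.array([s.mu_prior[0] for s in specs])
    mu_prior_s = np.array([s.mu_prior[1] for s in specs])
    sig_prior_s = np.array([s.sigma_prior for s in specs])
    bounds = [_SUPPORT_BOUNDS[s.support] for s in specs]

    def group_block_logp(j: int, mu_j, sigma_j, theta_c_j):
        """Posterior of one (mu_j, sigma_j) pair given the chain's
        participant values; vectorized over chains."""
        lo, hi = bounds[j]
        dens = _trunc_normal_logpdf(theta_c_j, mu_j[:, None], sigma_j[:, None], lo, hi).sum(axis=1)
        prior_mu = _trunc_normal_logpdf(mu_j, mu_prior_m[j], mu_prior_s[j], lo, hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            prior_sig = np.where(
                sigma_j > 0, -0.5 * (sigma_j / sig_prior_s[j]) ** 2, -np.inf
            )
            out = dens + prior_mu + prior_sig
        return np.where(np.isnan(out), -np.inf, out)

    keep_from = int(burn_frac * n_iter)
    kept = n_iter - keep_from
    mu_draws = np.empty((n_chains, kept, d))
    sigma_draws = np.empty((n_chains, kept, d))
    theta_draws = np.empty((n_chains, kept, n_participants, d))
    n_accept = 0
    n_prop = 0
    gamma_group = 2.38 / np.sqrt(2.0 * 2)

    for it in range(n_iter):
        # occasional full-length (gamma_DE = 1) proposals help chains
        # traverse long curved ridges such as the gamma-p tradeoff
        long_jump = rng.uniform() < 0.1
        g_part = 1.0 if long_jump else gamma_de
        g_group = 1.0 if long_jump else gamma_group
        # --- group blocks: one (mu_j, sigma_j) pair at a time; several
        # sweeps per iteration since these are cheap relative to the
        # participant likelihoods and mix the slowest
        for _ in range(group_sweeps):
            for j in range(d):
                cur = np.column_stack([mu[:, j], sigma[:, j]])
                prop = _de_proposal(cur, rng, g_group, jitter)
                logp_cur = group_block_logp(j, cur[:, 0], cur[:, 1], theta[:, :, j])
                logp_prop = group_block_logp(j, prop[:, 0], prop[:, 1], theta[:, :, j])
                with np.errstate(invalid="ignore"):
                    accept = np.log(rng.uniform(size=n_chains)) < (logp_prop - logp_cur)
                mu[accept, j] = prop[accept, 0]
                sigma[accept, j] = prop[accept, 1]
        for c in range(n_chains):
            group_dens[c] = group_logdensity(theta[c], mu[c], sigma[c], specs)

        # --- participant blocks
        for p in range(n_participants):
            cur = theta[:, p, :]
            prop = _de_proposal(cur, rng, g_part, jitter)
            dens_prop = group_logdensity(prop, mu, sigma, specs)
            ll_prop = np.where(np.isfinite(dens_prop), loglik_fn(p, prop), -np.inf)
            logp_cur = loglik[:, p] + group_dens[:, p]
            logp_prop = ll_prop + dens_prop
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.uniform(size=n_chains)) < (logp_prop - logp_cur)
            theta[accept, p, :] = prop[accept]
            loglik[accept, p] = ll_prop[accept]
            group_dens[accept, p] = dens_prop[accept]
            n_accept += int(accept.sum())
            n_prop += n_chains

        # --- migration during burn-in: cyclically offer states of a
        # random chain subset so stranded chains can join the mode
        if it < keep_from and rng.uniform() < migrate_prob:
            m = int(rng.integers(2, max(n_chains // 2, 3)))
            ring = rng.choice(n_chains, size=m, replace=False)
            src = np.roll(ring, 1)
            for p in range(n_participants):
                incoming = theta[src, p, :].copy()
                ll_in = loglik[src, p].copy()
                dens_in = group_logdensity(incoming, mu[ring], sigma[ring], specs)
                logp_cur = loglik[ring, p] + group_dens[ring, p]
                with np.errstate(invalid="ignore"):
                    accept = np.log(rng.uniform(size=m)) < (ll_in + dens_in - logp_cur)
                dest = ring[accept]
                theta[dest, p, :] = incoming[accept]
                loglik[dest, p] = ll_in[accept]
                group_dens[dest, p] = dens_in[accept]
            for j in range(d):
                mu_in = mu[src, j].copy()
                sig_in = sigma[src, j].copy()
                logp_cur = group_block_logp(j, mu[ring, j], sigma[ring, j], theta[ring][:, :, j])
                logp_in = group_block_logp(j, mu_in, sig_in, theta[ring][:, :, j])
                with np.errstate(invalid="ignore"):
                    accept = np.log(rng.uniform(size=m)) < (logp_in - logp_cur)
                dest = ring[accept]
                mu[dest, j] = mu_in[accept]
                sigma[dest, j] = sig_in[accept]
            for c in range(n_chains):
                group_dens[c] = group_logdensity(theta[c], mu[c], sigma[c], specs)

        if it >= keep_from:
            mu_draws[:, it - keep_from] = mu
            sigma_draws[:, it - keep_from] = sigma
            theta_draws[:, it - keep_from] = theta

    return HierarchicalFit(
        param_names=tuple(s.name for s in specs),
        mu=mu_draws,
        sigma=sigma_draws,
        theta=theta_draws,
        accept_rate=n_accept / max(n_prop, 1),
    )


def fit_recognition_model(
    trials: pd.DataFrame,
    config: FitConfig = FitConfig(),
    n_chains: int | None = None,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[HierarchicalFit, list[ParticipantData]]:
    """Hierarchical fit of the global-similarity LBA model to a trial
    table with a ``participant_id`` column."""
    specs = config.specs()
    participants = []
    for _, sub in trials.groupby("participant_id", sort=True):
        participants.append(ParticipantData.from_trials(sub, config))
    names = [s.name for s in specs]

    def loglik_fn(p: int, matrix: np.ndarray) -> np.ndarray:
        arrs = {n: matrix[:, j] for j, n in enumerate(names)}
        if not config.free_p:
            arrs["p"] = np.full(matrix.shape[0], config.p_fixed)
        return participants[p].chain_loglik(arrs, config.A)

    theta_init = np.array(
        [_participant_map(part, specs, config) for part in participants]
    )
    fit = hierarchical_de_mcmc(
        loglik_fn,
        specs,
        len(participants),
        n_chains=n_chains,
        n_iter=n_iter,
        seed=seed,
        theta_init=theta_init,
    )
    return fit, participants


def _init_vector(specs: Sequence[ParameterSpec], data: ParticipantData) -> np.ndarray:
    """Spec init values, with t0 started safely below the fastest RT
    so every chain begins with a finite likelihood."""
    x0 = np.array([s.init for s in specs])
    names = [s.name for s in specs]
    if "t0" in names:
        x0[names.index("t0")] = min(x0[names.index("t0")], 0.8 * float(data.rt.min()))
    return x0


def _participant_map(
    data: ParticipantData, specs: Sequence[ParameterSpec], config: FitConfig
) -> np.ndarray:
    """Rough per-participant penalized-likelihood point estimate used
    to initialize the chains (Nelder-Mead from each ParameterSpec's init value;
    the weak group priors act as the penalty)."""
    from scipy.optimize import minimize

    prior_m = np.array([s.mu_prior[0] for s in specs])
    prior_s = np.array([s.mu_prior[1] for s in specs])
    bounds = [_SUPPORT_BOUNDS[s.support] for s in specs]

    def neg_post(vector: np.ndarray) -> float:
        for j, (lo, hi) in enumerate(bounds):
            if not lo <= vector[j] <= hi:
                return 1e12
        penalty = float(np.sum(0.5 * ((vector - prior_m) / prior_s) ** 2))
        return penalty - data.loglik(_theta_dict(vector, specs, config), config)

    x0 = _init_vector(specs, data)
    res = minimize(neg_post, x0, method="Nelder-Mead",
                   options={"maxiter": 150 * len(specs), "xatol": 1e-3, "fatol": 1e-2})
    return res.x


def pointwise_loglik_matrix(
    fit: HierarchicalFit,
    participants: Sequence[ParticipantData],
    config: FitConfig,
    max_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """(draws, trials) pointwise log-likelihoods over thinned posterior
    draws, for WAIC."""
    specs = config.specs()
    theta = fit.flat_theta()
    rng = np.random.default_rng(seed)
    if theta.shape[0] > max_draws:
        idx = rng.choice(theta.shape[0], size=max_draws, replace=False)
        theta = theta[idx]
    rows = []
    for draw in theta:
        row = [
            part.pointwise_loglik(_theta_dict(draw[p], specs, config), config)
            for p, part in enumerate(participants)
        ]
        rows.append(np.concatenate(row))
    return np.asarray(rows)


def fit_single_participant(
    trials: pd.DataFrame,
    config: FitConfig = FitConfig(),
    n_chains: int | None = None,
    n_iter: int = 600,
    seed: int = 0,
) -> tuple[np.ndarray, ParticipantData]:
    """Non-hierarchical fit of one participant's trials: the group
    priors act as plain priors.  Returns draws (chains, kept, d)."""
    specs = config.specs()
    data = ParticipantData.from_trials(trials, config)

    prior_m = np.array([s.mu_prior[0] for s in specs])
    prior_s = np.array([s.mu_prior[1] for s in specs])
    bounds = [_SUPPORT_BOUNDS[s.support] for s in specs]

    def log_post(vector: np.ndarray) -> float:
        lp = 0.0
        for j, (lo, hi) in enumerate(bounds):
            lp += float(_trunc_normal_logpdf(vector[j], prior_m[j], prior_s[j], lo, hi))
        if not np.isfinite(lp):
            return -np.inf
        return lp + data.loglik(_theta_dict(vector, specs, config), config)

    init = _init_vector(specs, data)
    draws = de_mcmc_sample(
        log_post,
        d=len(specs),
        n_chains=n_chains,
        n_iter=n_iter,
        seed=seed,
        init=init,
        init_scale=0.05,
    )
    return draws, data


def single_participant_waic(
    draws: np.ndarray,
    data: ParticipantData,
    config: FitConfig,
    max_draws: int = 200,
    seed: int = 0,
) -> dict:
    """WAIC of a single-participant fit from thinned draws."""
    specs = config.specs()
    flat = draws.reshape(-1, draws.shape[-1])
    rng = np.random.default_rng(seed)
    if flat.shape[0] > max_draws:
        flat = flat[rng.choice(flat.shape[0], size=max_draws, replace=False)]
    ll = np.asarray(
        [data.pointwise_loglik(_theta_dict(v, specs, config), config) for v in flat]
    )
    return waic(ll)


def posterior_predictive(
    fit: HierarchicalFit,
    trials: pd.DataFrame,
    config: FitConfig,
    summarize: Callable[[pd.DataFrame], Mapping[str, float]],
    n_draws: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate datasets from sampled posterior draws and summarize.

    For each sampled draw, every trial is re-simulated with that draw's
    participant parameters and ``summarize`` is applied to the
    simulated table; returns per-summary mean and 95% HDI.
    """
    specs = config.specs()
    theta = fit.flat_theta()
    rng = np.random.default_rng(seed)
    idx = rng.choice(theta.shape[0], size=min(n_draws, theta.shape[0]), replace=False)
    pids = sorted(trials["participant_id"].unique())
    parts = {pid: ParticipantData.from_trials(sub, config) for pid, sub in trials.groupby("participant_id")}
    records = []
    for i in idx:
        sim_frames = []
        for p, pid in enumerate(pids):
            theta_p = _theta_dict(theta[i, p], specs, config)
            part = parts[pid]
            params = LBAParams(
                A=config.A,
                B_old=theta_p["B"],
                B_new=theta_p["B"],
                t0=theta_p["t0"],
                V0=theta_p["V0"],
                eta_target=theta_p["eta_target"],
            )
            v_old, v_new = part._drifts(theta_p)
            sub = trials[trials["participant_id"] == pid].copy()
            for status, mask in (("target", part.is_target), ("lure", ~part.is_target)):
                if np.any(mask):
                    resp, rt = simulate_trials(v_old[mask], v_new[mask], params, rng, status)
                    sub.loc[sub.index[mask], "response"] = resp
                    sub.loc[sub.index[mask], "rt_seconds"] = rt
            sim_frames.append(sub)
        records.append(dict(summarize(pd.concat(sim_frames))))
    frame = pd.DataFrame(records)
    out = []
    for col in frame.columns:
        lo, hi = hdi(frame[col].to_numpy(), 0.95)
        out.append({"summary": col, "mean": frame[col].mean(), "hdi_low": lo, "hdi_high": hi})
    return pd.DataFrame(out)
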