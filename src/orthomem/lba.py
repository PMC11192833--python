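"""Two-accumulator linear ballistic accumulator (LBA) for old/new
choice and response time.

Each response ("old", "new") has a linear, noiseless accumulator racing
to its threshold ``b = A + B``.  Trial-to-trial stochasticity comes
from the start point, uniform on ``[0, A]``, and the drift rate, normal
with mean ``v`` and SD ``eta``.  The response is the first accumulator
to reach threshold; RT is the decision time plus the non-decision time
``t0``.

Global similarity ``g`` enters through the mean drift rates

    v_old = V0 + V + gamma * g        v_new = V0 - (V + gamma * g)

so higher similarity speeds "old" decisions exactly as it slows "new"
ones (``v_old + v_new = 2 * V0``).  Drift-rate SD is set by probe
status -- 1 for lures (a scaling convention) and ``eta_target`` for
targets -- and applies to both accumulators on a trial.

Trials on which both sampled drifts are negative would never finish;
the simulator redraws the drift pair, and the likelihood divides by
``1 - P(both drifts <= 0)`` so simulator and likelihood form a matched
pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LBAParams",
    "TrialDrift",
    "drift_rates",
    "lba_defective_density",
    "lba_defective_cdf",
    "trial_log_likelihood",
    "simulate_trials",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


@dataclass(frozen=True)
class LBAParams:
    """Decision-model parameters.

    ``V`` and ``gamma`` may be scalars or mappings keyed by
    ``(condition, status)`` or by ``status`` alone; ``status`` is
    ``"target"`` or ``"lure"``.
    """

    A: float = 0.5
    B_old: float = 1.0
    B_new: float = 1.0
    t0: float = 0.25
    V0: float = 2.0
    eta_target: float = 1.0
    V: float | Mapping = 0.5
    gamma: float | Mapping = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("start-point range A must be >= 0")
        if self.B_old <= 0 or self.B_new <= 0:
            raise ValueError("threshold offsets B must be positive")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.eta_target <= 0:
            raise ValueError("eta_target must be positive")

    @property
    def b_old(self) -> float:
        return self.A + self.B_old

    @property
    def b_new(self) -> float:
        return self.A + self.B_new

    def eta(self, status: str) -> float:
        return self.eta_target if status == "target" else 1.0

    @staticmethod
    def _lookup(value, condition, status) -> float:
        if isinstance(value, Mapping):
            for key in ((condition, status), status, condition):
                if key in value:
                    return float(value[key])
            raise KeyError(f"no entry for condition={condition!r}, status={status!r}")
        return float(value)

    def V_for(self, condition=None, status: str = "target") -> float:
        return self._lookup(self.V, condition, status)

    def gamma_for(self, condition=None, status: str = "target") -> float:
        return self._lookup(self.gamma, condition, status)


@dataclass(frozen=True)
class TrialDrift:
    """Mean drift rates of the two accumulators on one trial."""

    v_old: float
    v_new: float


def drift_rates(g: float, params: LBAParams, condition=None, status: str = "lure") -> TrialDrift:
    """Map global similarity to the mirror-image drift-rate pair."""
    v = params.V_for(condition, status)
    gam = params.gamma_for(condition, status)
    shift = v + gam * g
    return TrialDrift(v_old=params.V0 + shift, v_new=params.V0 - shift)


# ---------------------------------------------------------------------------
# Single-accumulator first-passage distribution
# ---------------------------------------------------------------------------


def lba_defective_density(t, b: float, A: float, v, eta: float):
    """Density of one accumulator reaching ``b`` at decision time ``t``
    (not conditioned on winning, nor on the drift being positive).

    ``A = 0`` degenerates to the distribution of ``b / drift``.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_accumulator(b, A, eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = t * eta
        if A == 0.0:
            out = b / (t * ts) * _phi((b - t * v) / ts)
        else:
            z1 = (b - A - t * v) / ts
            z2 = (b - t * v) / ts
            out = (-v * ndtr(z1) + eta * _phi(z1) + v * ndtr(z2) - eta * _phi(z2)) / A
    out = np.where(t > 0, np.maximum(out, 0.0), 0.0)
    return float(out) if out.ndim == 0 else out


def lba_defective_cdf(t, b: float, A: float, v, eta: float):
    """CDF companion of :func:`lba_defective_density`; tends to
    ``P(drift > 0)`` (< 1 when negative drifts are possible) as ``t``
    grows."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_accumulator(b, A, eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = t * eta
        if A == 0.0:
            out = ndtr((t * v - b) / ts)
        else:
            z1 = (b - A - t * v) / ts
            z2 = (b - t * v) / ts
            out = (
                1.0
                + (b - A - t * v) / A * ndtr(z1)
                - (b - t * v) / A * ndtr(z2)
                + ts / A * (_phi(z1) - _phi(z2))
            )
    out = np.where(t > 0, np.clip(out, 0.0, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def _check_accumulator(b: float, A: float, eta: float) -> None:
    if A < 0:
        raise ValueError("A must be >= 0")
    if b <= A:
        raise ValueError("threshold b must exceed the start-point range A")
    if eta <= 0:
        raise ValueError("eta must be positive")


# ---------------------------------------------------------------------------
# Trial likelihood and simulation
# ---------------------------------------------------------------------------


def _log_norm_constant(v_old, v_new, eta: float):
    """log of 1 - P(both drifts <= 0), the redraw normalization."""
    p_both_neg = ndtr(-np.asarray(v_old) / eta) * ndtr(-np.asarray(v_new) / eta)
    return np.log1p(-p_both_neg)


def trial_log_likelihood(rt, response, v_old, v_new, params: LBAParams, status: str = "lure"):
    """Log-likelihood of observed (response, RT) pairs.

    ``rt`` in seconds; ``response`` an array of "old"/"new" labels (or
    booleans, True = "old").  Vectorized over trials with per-trial
    drift rates.  ``rt <= t0`` yields ``-inf``.
    """
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    v_old = np.broadcast_to(np.asarray(v_old, dtype=float), rt.shape)
    v_new = np.broadcast_to(np.asarray(v_new, dtype=float), rt.shape)
    resp = np.atleast_1d(np.asarray(response))
    if resp.dtype.kind in "US":
        old = resp == "old"
    else:
        old = resp.astype(bool)
    old = np.broadcast_to(old, rt.shape)
    eta = params.eta(status)
    tau = rt - params.t0
    valid = tau > 0
    tau_safe = np.where(valid, tau, 1.0)

    b_w = np.where(old, params.b_old, params.b_new)
    b_l = np.where(old, params.b_new, params.b_old)
    v_w = np.where(old, v_old, v_new)
    v_l = np.where(old, v_new, v_old)

    # winner density and loser survivor, accumulator-wise
    pdf_w = _density_vec(tau_safe, b_w, params.A, v_w, eta)
    cdf_l = _cdf_vec(tau_safe, b_l, params.A, v_l, eta)
    with np.errstate(divide="ignore"):
        ll = np.log(pdf_w) + np.log1p(-cdf_l) - _log_norm_constant(v_old, v_new, eta)
    ll = np.where(valid & (pdf_w > 0) & (cdf_l < 1), ll, -np.inf)
    return ll if ll.shape != (1,) else float(ll[0])


def _density_vec(t, b, A: float, v, eta: float):
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = t * eta
        if A == 0.0:
            return np.maximum(b / (t * ts) * _phi((b - t * v) / ts), 0.0)
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        return np.maximum((-v * ndtr(z1) + eta * _phi(z1) + v * ndtr(z2) - eta * _phi(z2)) / A, 0.0)


def _cdf_vec(t, b, A: float, v, eta: float):
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = t * eta
        if A == 0.0:
            return ndtr((t * v - b) / ts)
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        return np.clip(
            1.0
            + (b - A - t * v) / A * ndtr(z1)
            - (b - t * v) / A * ndtr(z2)
            + ts / A * (_phi(z1) - _phi(z2)),
            0.0,
            1.0,
        )


def simulate_trials(
    v_old,
    v_new,
    params: LBAParams,
    rng: np.random.Generator,
    status: str = "lure",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (response, rt) for trials with given mean drift rates.

    Start points are uniform on [0, A]; drift pairs with both values
    <= 0 are redrawn.  Returns an array of "old"/"new" labels and an RT
    array in seconds.
    """
    v_old = np.atleast_1d(np.asarray(v_old, dtype=float))
    v_new = np.broadcast_to(np.asarray(v_new, dtype=float), v_old.shape).copy()
    n = v_old.shape[0]
    eta = params.eta(status)

    d_old = rng.normal(v_old, eta)
    d_new = rng.normal(v_new, eta)
    stuck = (d_old <= 0) & (d_new <= 0)
    while np.any(stuck):
        idx = np.flatnonzero(stuck)
        d_old[idx] = rng.normal(v_old[idx], eta)
        d_new[idx] = rng.normal(v_new[idx], eta)
        stuck[idx] = (d_old[idx] <= 0) & (d_new[idx] <= 0)

    k_old = rng.uniform(0.0, params.A, size=n) if params.A > 0 else np.zeros(n)
    k_new = rng.uniform(0.0, params.A, size=n) if params.A > 0 else np.zeros(n)
    with np.errstate(divide="ignore"):
        t_old = np.where(d_old > 0, (params.b_old - k_old) / d_old, np.inf)
        t_new = np.where(d_new > 0, (params.b_new - k_new) / d_new, np.inf)
    old_wins = t_old < t_new
    rt = params.t0 + np.where(old_wins, t_old, t_new)
    response = np.where(old_wins, "old", "new")
    return response, rt
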