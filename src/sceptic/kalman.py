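"""Kalman-filter uncertainty tracking (the "Fixed U+V" model variant).

Each temporal basis element carries a posterior mean mu_b (expected value,
updated with a *fixed* learning rate alpha, exactly as the full-maintenance
delta rule) and a posterior standard deviation sigma_b. The uncertainty
shrinks with sampling according to the Kalman gain

    k_b(i) = sigma_b(i)^2 / (sigma_b(i)^2 + sigma_rew^2),
    sigma_b(i+1) = [1 - e_b(i|t) k_b(i)] sigma_b(i),

where sigma_rew^2 is the measurement noise (by default the reward variance
of a typical run) and e_b the eligibility of the element for the chosen RT.
Initializing sigma_b0^2 = sigma_rew^2 makes the first-trial gain exactly 0.5.

The decision function is Q(i) = V(i) + tau * U(i), where V and U are the
mean- and sigma-weighted basis evaluations and tau weights uncertainty:
positive tau produces uncertainty-directed exploration, negative tau
uncertainty aversion. Choice is a softmax over Q.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import TemporalBasis, ValueFunction, basis_matrix, eligibility, softmax_probs

__all__ = ["KalmanState", "DecisionFunction", "kf_step", "decision_q",
           "uncertainty_percentile", "kf_gain"]


@dataclass(frozen=True)
class KalmanState:
    """Per-element means and uncertainties of the Fixed U+V learner."""

    means: np.ndarray      # mu_b, points
    sigmas: np.ndarray     # sigma_b, points (standard deviations)
    sigma_rew: float       # measurement noise scale, points
    alpha: float = 0.1     # fixed learning rate for the means
    tau: float = 0.0       # uncertainty weight (sign-free)
    beta: float = 20.0     # softmax temperature over Q
    trial: int = 0

    def __post_init__(self):
        if self.sigma_rew <= 0:
            raise ValueError("sigma_rew must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    @classmethod
    def fresh(cls, basis: TemporalBasis, sigma_rew: float, **kw) -> "KalmanState":
        """Initialize with zero means and sigma_b0 = sigma_rew (gain 0.5)."""
        n = basis.n_basis
        return cls(means=np.zeros(n), sigmas=np.full(n, float(sigma_rew)),
                   sigma_rew=float(sigma_rew), **kw)


@dataclass(frozen=True)
class DecisionFunction:
    grid: np.ndarray
    values: np.ndarray        # V(i)
    uncertainties: np.ndarray  # U(i)
    q_values: np.ndarray      # Q(i) = V + tau * U


def kf_gain(state: KalmanState) -> np.ndarray:
    """Per-element Kalman gain k_b = sigma_b^2 / (sigma_b^2 + sigma_rew^2)."""
    s2 = state.sigmas ** 2
    return s2 / (s2 + state.sigma_rew ** 2)


def kf_step(state: KalmanState, basis: TemporalBasis, rt_ms: float,
            reward: float) -> tuple[KalmanState, float]:
    """One trial's mean/uncertainty update; returns (new state, scalar RPE)."""
    e = eligibility(basis, rt_ms)
    mu, sig = state.means, state.sigmas
    rpe = float(reward) - float(mu @ basis_matrix(basis, rt_ms)[:, 0])
    gain = kf_gain(state)
    new_mu = mu + e * state.alpha * (float(reward) - mu)
    new_sig = (1.0 - e * gain) * sig
    return replace(state, means=new_mu, sigmas=new_sig, trial=state.trial + 1), rpe


def decision_q(state: KalmanState, basis: TemporalBasis) -> DecisionFunction:
    """Evaluate V, U and Q = V + tau U on the choice grid."""
    phi = basis.phi_grid
    v = state.means @ phi
    u = state.sigmas @ phi
    return DecisionFunction(grid=basis.grid, values=v, uncertainties=u,
                            q_values=v + state.tau * u)


def choose_rt_q(state: KalmanState, basis: TemporalBasis,
                rng: np.random.Generator) -> tuple[int, float]:
    """Sample a response bin from the softmax over the decision function Q."""
    df = decision_q(state, basis)
    p = softmax_probs(df.q_values, state.beta)
    j = int(rng.choice(p.size, p=p))
    return j, float(df.grid[j])


def uncertainty_percentile(state: KalmanState, basis: TemporalBasis,
                           rt_ms: float) -> float:
    """Percentile (0-100, midrank ties) of U(rt) among the grid's U values.

    This within-trial normalization removes the slow global decay of
    uncertainty over a learning episode: all-equal sigmas give 50.
    """
    rt_ms = float(rt_ms)
    if rt_ms < 0 or rt_ms > basis.interval_ms:
        raise ValueError(f"rt {rt_ms} outside [0, {basis.interval_ms}] ms")
    df = decision_q(state, basis)
    u_rt = float(state.sigmas @ basis_matrix(basis, rt_ms)[:, 0])
    return float(stats.percentileofscore(df.uncertainties, u_rt, kind="mean"))


def value_fn(state: KalmanState, basis: TemporalBasis) -> ValueFunction:
    """The KF mean value function V(i) on the choice grid."""
    return ValueFunction(grid=basis.grid, values=state.means @ basis.phi_grid)
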