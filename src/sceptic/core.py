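"""Temporal-basis-function value learning for the clock task.

The value of responding at time t within the 4-s interval is approximated by
a set of unnormalized Gaussian radial basis functions (temporal basis
functions, TBFs),

    phi_b(t) = exp(-(t - mu_b)^2 / (2 s_b^2)),

whose heights are scaled by learned weights w_b so that the value function
on trial i is V(i) = w(i) @ phi. Feedback obtained at the chosen RT is
propagated to temporally adjacent elements through an eligibility vector
e_b in [0, 1], the (renormalized) overlap of a Gaussian generalization
kernel centered at the RT with each element's receptive field.

Two maintenance rules are implemented:

- *selective*: unchosen elements' weights decay toward a reversion point h
  (0 by default) at rate gamma scaled by (1 - e_b), compressing the value
  representation onto preferred response times;
- *full*: the plain delta rule with no decay.

Choice is a softmax over a 40-bin (100 ms) discretization of the interval
with temperature beta. The prominence of the global value maximum is
quantified by the Shannon entropy of the normalized weight vector, and
RT_Vmax is the grid time of the value function's global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TemporalBasis", "AgentState", "ValueFunction", "build_basis", "eligibility",
    "eval_value", "update_weights", "shannon_entropy", "rt_vmax", "choose_rt",
    "softmax_probs", "rw_trial_update", "adjacent_overlap",
]

VARIANTS = ("selective", "full")


@dataclass(frozen=True)
class TemporalBasis:
    """Evenly spaced Gaussian TBFs tiling the decision interval.

    ``centers`` span the closed interval [0, T]; ``width_sq`` is the shared
    receptive-field variance s_b^2 (ms^2) chosen so that adjacent elements'
    normalized densities overlap by ``overlap_target``; ``gen_width_sq`` is
    the generalization-kernel variance s_g^2 (defaults to s_b^2). ``grid``
    holds the 40 bin-center evaluation times (100 ms bins).
    ``truncate`` switches eligibility to integration on [0, T] only.
    """

    n_basis: int
    interval_ms: float
    centers: np.ndarray
    width_sq: float
    gen_width_sq: float
    grid: np.ndarray
    truncate: bool = False

    @property
    def phi_grid(self) -> np.ndarray:
        """Basis matrix Phi[b, j] = phi_b(grid_j), shape (n_basis, n_grid)."""
        return basis_matrix(self, self.grid)

    @property
    def n_bins(self) -> int:
        return self.grid.size


def basis_matrix(basis: TemporalBasis, times) -> np.ndarray:
    """Evaluate every element at ``times``; shape (n_basis, len(times))."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    d = t[None, :] - basis.centers[:, None]
    return np.exp(-d * d / (2.0 * basis.width_sq))


def adjacent_overlap(delta: float, sd: float) -> float:
    """Overlap coefficient of two equal-variance normal densities a distance
    ``delta`` apart: the integral of their pointwise minimum."""
    return float(2.0 * stats.norm.cdf(-abs(delta) / (2.0 * sd)))


def build_basis(n_basis: int = 24, interval_ms: float = 4000.0,
                overlap_target: float = 0.5, n_bins: int = 40,
                gen_width_sq: float | None = None,
                truncate: bool = False) -> TemporalBasis:
    """Construct the default temporal basis.

    The shared width is solved numerically so that the overlap coefficient
    (integral of the pointwise minimum of adjacent normalized densities)
    equals ``overlap_target``.
    """
    if n_basis < 2:
        raise ValueError("need at least 2 basis elements")
    if not 0.0 < overlap_target < 1.0:
        raise ValueError("overlap target must lie in (0, 1)")
    centers = np.linspace(0.0, interval_ms, n_basis)
    delta = centers[1] - centers[0]
    sd = optimize.brentq(lambda s: adjacent_overlap(delta, s) - overlap_target,
                         1e-6 * delta, 1e3 * delta)
    width_sq = sd * sd
    bin_w = interval_ms / n_bins
    grid = (np.arange(n_bins) + 0.5) * bin_w
    return TemporalBasis(n_basis=n_basis, interval_ms=float(interval_ms),
                         centers=centers, width_sq=width_sq,
                         gen_width_sq=width_sq if gen_width_sq is None else float(gen_width_sq),
                         grid=grid, truncate=truncate)


def eligibility(basis: TemporalBasis, rt_ms: float) -> np.ndarray:
    """Eligibility e_b of each element for an update after a response at rt.

    e_b is the integral of the product of a normalized Gaussian
    generalization kernel N(rt, s_g^2) with the element's receptive field,
    divided by the perfect-overlap value so that e_b = 1 when the RT sits on
    the element's center and s_g^2 = s_b^2. With ``basis.truncate`` the
    integrals run over [0, T] only (edge elements then generalize less);
    otherwise the closed form over the whole line is used.
    """
    rt_ms = float(rt_ms)
    if rt_ms < 0 or rt_ms > basis.interval_ms:
        raise ValueError(f"rt {rt_ms} outside [0, {basis.interval_ms}] ms")
    sb2, sg2 = basis.width_sq, basis.gen_width_sq
    if not basis.truncate:
        # int N(x; rt, sg2) * exp(-(x-mu)^2/(2 sb2)) dx over R equals
        # sqrt(sb2/(sb2+sg2)) * exp(-(rt-mu)^2/(2 (sb2+sg2))); the prefactor
        # is the perfect-overlap value and cancels on renormalization.
        d = rt_ms - basis.centers
        return np.exp(-d * d / (2.0 * (sb2 + sg2)))
    T = basis.interval_ms

    def kernel_overlap(center, mu, kvar):
        # truncated Gaussian-product integral via the product-of-Gaussians identity
        s2 = sb2 * kvar / (sb2 + kvar)
        m = (sb2 * center + kvar * mu) / (sb2 + kvar)
        pref = np.sqrt(sb2 / (sb2 + kvar)) * np.exp(-(center - mu) ** 2 / (2.0 * (sb2 + kvar)))
        frac = stats.norm.cdf((T - m) / np.sqrt(s2)) - stats.norm.cdf((0.0 - m) / np.sqrt(s2))
        return pref * frac

    raw = kernel_overlap(rt_ms, basis.centers, sg2)
    perfect = kernel_overlap(basis.centers, basis.centers, sb2)
    return raw / perfect


@dataclass(frozen=True)
class ValueFunction:
    grid: np.ndarray
    values: np.ndarray


def eval_value(weights: np.ndarray, basis: TemporalBasis) -> ValueFunction:
    """V(i) = w(i) @ phi evaluated on the choice grid."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (basis.n_basis,):
        raise ValueError(f"expected {basis.n_basis} weights, got shape {weights.shape}")
    return ValueFunction(grid=basis.grid, values=weights @ basis.phi_grid)


def value_at(weights: np.ndarray, basis: TemporalBasis, rt_ms: float) -> float:
    """Model-predicted value at an arbitrary time (not just grid points)."""
    return float(np.asarray(weights, float) @ basis_matrix(basis, rt_ms)[:, 0])


@dataclass(frozen=True)
class AgentState:
    """Weights and parameters of a TBF learner.

    alpha: learning rate in (0, 1); gamma: selective-maintenance decay in
    (0, 1) (ignored by the full variant); h: reversion point (points);
    beta: softmax temperature (> 0, in points).
    """

    weights: np.ndarray
    variant: str = "selective"
    alpha: float = 0.1
    gamma: float = 0.3
    h: float = 0.0
    beta: float = 20.0
    trial: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @classmethod
    def fresh(cls, basis: TemporalBasis, **kw) -> "AgentState":
        return cls(weights=np.zeros(basis.n_basis), **kw)


def update_weights(state: AgentState, basis: TemporalBasis, rt_ms: float,
                   reward: float) -> tuple[AgentState, float]:
    """One trial's learning update; returns (new state, scalar RPE).

    The per-element delta rule is
    w_b <- w_b + e_b * alpha * (reward - w_b); the selective variant
    additionally decays unchosen elements,
    w_b <- w_b - gamma * (1 - e_b) * (w_b - h).
    The returned RPE is reward - V(rt) with the pre-update value function.
    """
    e = eligibility(basis, rt_ms)
    w = state.weights
    rpe = float(reward) - value_at(w, basis, rt_ms)
    new_w = w + e * state.alpha * (float(reward) - w)
    if state.variant == "selective":
        new_w = new_w - state.gamma * (1.0 - e) * (w - state.h)
    return replace(state, weights=new_w, trial=state.trial + 1), rpe


def shannon_entropy(weights: np.ndarray, eps: float = 1e-12) -> float:
    """Shannon entropy (nats) of the normalized weight vector.

    By convention a (near-)zero total weight — e.g. before any learning —
    returns log(n), the entropy of the uniform distribution.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total < eps:
        return float(np.log(w.size))
    p = w / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def rt_vmax(vf: ValueFunction) -> float:
    """Grid time of the value function's global maximum (earliest on ties)."""
    return float(vf.grid[int(np.argmax(vf.values))])


def softmax_probs(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax p_j proportional to exp(V_j / beta), computed stably."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = np.asarray(values, dtype=float) / float(beta)
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def choose_rt(vf: ValueFunction, beta: float, rng: np.random.Generator) -> tuple[int, float]:
    """Sample a response bin from the softmax policy; returns (bin, rt_ms)."""
    p = softmax_probs(vf.values, beta)
    j = int(rng.choice(p.size, p=p))
    return j, float(vf.grid[j])


def rw_trial_update(v: float, reward: float, alpha: float) -> tuple[float, float]:
    """Trial-level Rescorla–Wagner update; returns (new value, RPE)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    rpe = float(reward) - float(v)
    return float(v) + alpha * rpe, rpe
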