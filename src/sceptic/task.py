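"""Clock-task reward contingencies.

The clock task presents a 4-s decision interval; the chosen stopping time
(response time, RT) is rewarded probabilistically according to one of four
monotone time-varying contingencies that trade reward probability against
magnitude:

- ``IEV``  increasing expected value (learnable; best RTs late)
- ``DEV``  decreasing expected value (learnable; best RTs early)
- ``CEV``  constant expected value (unlearnable)
- ``CEVR`` constant expected value with the probability/magnitude
  tradeoff reversed relative to CEV

Each contingency is parameterized by a linear reward-probability ramp and a
linear expected-value profile; magnitude is their ratio, which is monotone.
All curve parameters are exposed so alternative functional forms can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Contingency", "TrialOutcome", "make_contingency", "trial_ev", "sample_outcome",
           "CONTINGENCY_KINDS", "DEFAULT_PARAMS"]

CONTINGENCY_KINDS = ("IEV", "DEV", "CEV", "CEVR")

#: default curve parameters per kind: reward probability runs linearly from
#: p0 to p1 across the interval; expected value runs linearly from ev0 to ev1
#: (points); magnitude is ev/prob.
DEFAULT_PARAMS = {
    "IEV": dict(p0=0.85, p1=0.35, ev0=60.0, ev1=120.0),
    "DEV": dict(p0=0.35, p1=0.85, ev0=120.0, ev1=60.0),
    "CEV": dict(p0=0.85, p1=0.35, ev0=80.0, ev1=80.0),
    "CEVR": dict(p0=0.35, p1=0.85, ev0=80.0, ev1=80.0),
}


@dataclass(frozen=True)
class Contingency:
    """A reward contingency mapping response time to probability and magnitude.

    Attributes
    ----------
    kind : str
        One of ``IEV``, ``DEV``, ``CEV``, ``CEVR``.
    interval_ms : float
        Duration of the decision phase (default 4000 ms).
    prob_fn, mag_fn : callable
        Vectorized maps from rt (ms) to reward probability in [0, 1] and
        reward magnitude in points (>= 0).
    """

    kind: str
    interval_ms: float
    prob_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    mag_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)


@dataclass(frozen=True)
class TrialOutcome:
    rt_ms: float
    rewarded: bool
    reward: float
    probability: float
    magnitude: float


def make_contingency(kind: str, params: dict | None = None,
                     interval_ms: float = 4000.0) -> Contingency:
    """Construct one of the four clock-task contingencies.

    Parameters default to :data:`DEFAULT_PARAMS` for the kind; pass a dict
    with keys ``p0, p1, ev0, ev1`` (and optionally ``interval_ms``) to
    override. Raises ``ValueError`` for an unknown kind or probabilities
    outside [0, 1].
    """
    if kind not in CONTINGENCY_KINDS:
        raise ValueError(f"unknown contingency kind {kind!r}; expected one of {CONTINGENCY_KINDS}")
    p = dict(DEFAULT_PARAMS[kind])
    if params:
        p.update(params)
    interval_ms = float(p.pop("interval_ms", interval_ms))
    p0, p1, ev0, ev1 = (float(p[k]) for k in ("p0", "p1", "ev0", "ev1"))
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise ValueError(f"probability endpoints must lie in [0,1], got {p0}, {p1}")
    if min(ev0, ev1) < 0:
        raise ValueError("expected value must be nonnegative")

    def prob_fn(rt_ms, _p0=p0, _p1=p1, _T=interval_ms):
        frac = np.clip(np.asarray(rt_ms, dtype=float) / _T, 0.0, 1.0)
        return _p0 + (_p1 - _p0) * frac

    def mag_fn(rt_ms, _ev0=ev0, _ev1=ev1, _T=interval_ms):
        frac = np.clip(np.asarray(rt_ms, dtype=float) / _T, 0.0, 1.0)
        ev = _ev0 + (_ev1 - _ev0) * frac
        prob = prob_fn(rt_ms)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(prob > 0, ev / np.where(prob > 0, prob, 1.0), 0.0)

    return Contingency(kind=kind, interval_ms=interval_ms, prob_fn=prob_fn, mag_fn=mag_fn)


def trial_ev(c: Contingency, rt_ms) -> np.ndarray | float:
    """Expected value prob(rt) * magnitude(rt); rt must lie in [0, interval]."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt < 0) or np.any(rt > c.interval_ms):
        raise ValueError(f"rt outside [0, {c.interval_ms}] ms")
    out = c.prob_fn(rt) * c.mag_fn(rt)
    return float(out) if np.isscalar(rt_ms) else out


def sample_outcome(c: Contingency, rt_ms: float, rng: np.random.Generator) -> TrialOutcome:
    """Draw one probabilistic outcome for the chosen response time.

    A response at or beyond the end of the interval is a missed trial and
    earns 0 points.
    """
    rt_ms = float(rt_ms)
    if rt_ms < 0 or rt_ms > c.interval_ms:
        raise ValueError(f"rt {rt_ms} outside [0, {c.interval_ms}] ms")
    prob = float(c.prob_fn(rt_ms))
    mag = float(c.mag_fn(rt_ms))
    if rt_ms >= c.interval_ms:
        return TrialOutcome(rt_ms, False, 0.0, prob, mag)
    rewarded = bool(rng.random() < prob)
    return TrialOutcome(rt_ms, rewarded, mag if rewarded else 0.0, prob, mag)
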