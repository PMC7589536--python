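"""Synthetic populations, behavioral datasets and imaging-like fixtures.

Everything the pipeline consumes can be generated here without downloads:

- populations of simulated subjects with parameters drawn in transformed
  space (logit for learning rate alpha and decay gamma, log for the softmax
  temperature beta, identity for the uncertainty weight tau);
- full clock-task experiments — 8 runs x 50 trials on the 4-s interval with
  the four contingencies and exponential inter-trial intervals — played by
  TBF agents, together with their ground-truth latent trajectories;
- subject-level "brain beta" covariates with a plantable linear coupling to
  agent parameters, for testing the brain-behavior moderation analyses;
- elongated voxel masks at a known sagittal-plane rotation and event-locked
  activity time courses with planted shapes, for the long-axis module.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, kalman
from .task import CONTINGENCY_KINDS, make_contingency, sample_outcome

__all__ = [
    "PopulationSpec", "BetaCouplingSpec", "SimResult", "gen_population",
    "simulate_experiment", "gen_betas", "gen_mask", "gen_timecourses",
    "DEFAULT_SCHEDULE",
]

#: counterbalanced default contingency order, 8 runs x 50 trials
DEFAULT_SCHEDULE = ("DEV", "IEV", "CEV", "CEVR", "IEV", "DEV", "CEVR", "CEV")

# population means/SDs in transformed space; chosen to produce moderately
# exploitative learners (alpha ~ 0.1, gamma ~ 0.4, beta ~ 20 points,
# mildly uncertainty-averse tau) with realistic between-subject spread
_DEFAULT_DISTS = {
    "alpha_t": (-2.2, 0.5),
    "gamma_t": (-0.4, 0.5),
    "beta_t": (3.0, 0.4),
    "tau_t": (-0.3, 0.3),
}


@dataclass(frozen=True)
class PopulationSpec:
    n_subjects: int = 70
    dists: dict = field(default_factory=lambda: dict(_DEFAULT_DISTS))
    schedule: tuple = DEFAULT_SCHEDULE
    n_trials: int = 50
    variant: str = "selective"
    seed: int = 0


@dataclass(frozen=True)
class BetaCouplingSpec:
    """Linear couplings from transformed agent parameters to synthetic
    regional regression coefficients ("betas"); zero coupling yields betas
    independent of behavior."""

    couplings: dict = field(default_factory=lambda: {
        "ph_rpe_beta": {"beta_t": 1.0},     # exploratory agents: high temperature
        "ah_entropy_beta": {"beta_t": -1.0},  # exploitative agents
    })
    noise_sd: float = 0.5
    seed: int = 0


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def gen_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a subject parameter table; columns hold both transformed
    (``*_t``) and natural-scale parameters."""
    rng = np.random.default_rng(spec.seed)
    rows = {"subject": np.arange(1, spec.n_subjects + 1)}
    for name, (m, sd) in spec.dists.items():
        if sd < 0:
            raise ValueError(f"negative SD for {name}")
        rows[name] = rng.normal(m, sd, size=spec.n_subjects)
    df = pd.DataFrame(rows)
    df["alpha"] = _expit(df["alpha_t"])
    df["gamma"] = _expit(df["gamma_t"])
    df["beta"] = np.exp(df["beta_t"])
    df["tau"] = df.get("tau_t", 0.0)
    return df


@dataclass
class SimResult:
    """A simulated experiment: the behavioral table plus latent trajectories.

    ``trials`` has one row per (subject, run, trial) with choices, outcomes,
    decision signals and event onsets. ``value_grids``/``u_grids`` map
    subject id to (n_trials_total, n_bins) arrays of the decision-time value
    and uncertainty functions, for survival-table construction.
    """

    trials: pd.DataFrame
    value_grids: dict
    u_grids: dict
    basis: core.TemporalBasis


def _draw_iti(rng, mean_s=2.5, lo=1.0, hi=10.0):
    # exponential family truncated to [lo, hi] s
    while True:
        x = lo + rng.exponential(mean_s)
        if x <= hi:
            return x


def simulate_experiment(params: pd.DataFrame,
                        schedule: tuple = DEFAULT_SCHEDULE,
                        n_trials: int = 50,
                        variant: str = "selective",
                        basis: core.TemporalBasis | None = None,
                        seed: int = 0,
                        track_uncertainty: bool = True,
                        feedback_dur_s: float = 0.9) -> SimResult:
    """Simulate the full clock-task experiment for every subject in ``params``.

    Agents choose by softmax over their decision-time value function (the
    ``selective`` or ``full`` TBF learner, or ``kalman`` for the Fixed U+V
    variant choosing on Q = V + tau U). When ``track_uncertainty`` is set, a
    Fixed U+V observer with matched alpha is replayed on the agent's own
    choices to provide uncertainty signals regardless of the generating
    variant. Learning state resets at every run boundary.
    """
    if basis is None:
        basis = core.build_basis()
    bad = set(schedule) - set(CONTINGENCY_KINDS)
    if bad:
        raise ValueError(f"unknown contingencies in schedule: {bad}")
    rng = np.random.default_rng(seed)
    recs = []
    value_grids: dict = {}
    u_grids: dict = {}
    for _, prow in params.iterrows():
        subj = int(prow["subject"])
        srng = np.random.default_rng(rng.integers(2 ** 31))
        v_rows, u_rows = [], []
        for run_i, kind in enumerate(schedule, start=1):
            cont = make_contingency(kind)
            if variant in ("selective", "full"):
                agent = core.AgentState.fresh(
                    basis, variant=variant, alpha=float(prow["alpha"]),
                    gamma=float(prow["gamma"]) if variant == "selective" else 0.0,
                    beta=float(prow["beta"]))
            elif variant == "kalman":
                sigma_rew = _reference_reward_sd(cont, srng)
                agent = kalman.KalmanState.fresh(
                    basis, sigma_rew=sigma_rew, alpha=float(prow["alpha"]),
                    tau=float(prow.get("tau", 0.0)), beta=float(prow["beta"]))
            else:
                raise ValueError(f"unknown variant {variant!r}")
            observer = None
            clock_onset = 0.0
            for trial in range(1, n_trials + 1):
                if variant == "kalman":
                    df = kalman.decision_q(agent, basis)
                    vf = core.ValueFunction(grid=df.grid, values=df.values)
                    probs = core.softmax_probs(df.q_values, agent.beta)
                    j = int(srng.choice(probs.size, p=probs))
                    rt = float(df.grid[j])
                    weights_like = agent.means
                else:
                    vf = core.eval_value(agent.weights, basis)
                    j, rt = core.choose_rt(vf, agent.beta, srng)
                    weights_like = agent.weights
                out = sample_outcome(cont, rt, srng)
                if observer is None and track_uncertainty:
                    observer = kalman.KalmanState.fresh(
                        basis, sigma_rew=_reference_reward_sd(cont, srng),
                        alpha=float(prow["alpha"]))
                ent = core.shannon_entropy(np.maximum(weights_like, 0.0))
                rtv = core.rt_vmax(vf)
                if observer is not None:
                    u_df = kalman.decision_q(observer, basis)
                    u_cho = float(observer.sigmas @ core.basis_matrix(basis, rt)[:, 0])
                    u_pct = kalman.uncertainty_percentile(observer, basis, rt)
                    u_rows.append(u_df.uncertainties.copy())
                else:
                    u_cho, u_pct = np.nan, np.nan
                    u_rows.append(np.full(basis.n_bins, np.nan))
                v_rows.append(vf.values.copy())
                iti = _draw_iti(srng)
                feedback_onset = clock_onset + rt / 1000.0
                if variant == "kalman":
                    agent, rpe = kalman.kf_step(agent, basis, rt, out.reward)
                else:
                    agent, rpe = core.update_weights(agent, basis, rt, out.reward)
                if observer is not None:
                    observer, _ = kalman.kf_step(observer, basis, rt, out.reward)
                recs.append(dict(
                    subject=subj, run=run_i, trial=trial, contingency=kind,
                    rt_ms=rt, bin=j, rewarded=int(out.rewarded), reward=out.reward,
                    probability=out.probability, magnitude=out.magnitude,
                    rpe=rpe, entropy=ent, rt_vmax=rtv,
                    value_chosen=float(vf.values[j]), value_max=float(vf.values.max()),
                    u_chosen=u_cho, u_percentile=u_pct,
                    clock_onset=clock_onset, feedback_onset=feedback_onset,
                    feedback_dur=feedback_dur_s, iti=iti))
                clock_onset = feedback_onset + feedback_dur_s + iti
        value_grids[subj] = np.asarray(v_rows)
        u_grids[subj] = np.asarray(u_rows)
    return SimResult(trials=pd.DataFrame.from_records(recs),
                     value_grids=value_grids, u_grids=u_grids, basis=basis)


def _reference_reward_sd(cont, rng, n=200):
    """Measurement-noise scale: SD of returns over a typical run, estimated
    by uniform sampling of the interval (a Monte Carlo stand-in for the
    'variance of returns from a typical run')."""
    rts = rng.uniform(0.0, cont.interval_ms * 0.999, size=n)
    rewards = np.array([sample_outcome(cont, rt, rng).reward for rt in rts])
    sd = float(rewards.std())
    return max(sd, 1e-6)


def gen_betas(params: pd.DataFrame, coupling: BetaCouplingSpec | None = None) -> pd.DataFrame:
    """Synthetic subject-level regional betas linearly coupled to agent
    parameters (in transformed space) plus Gaussian noise."""
    if coupling is None:
        coupling = BetaCouplingSpec()
    rng = np.random.default_rng(coupling.seed)
    out = pd.DataFrame({"subject": params["subject"].to_numpy()})
    for beta_name, weights in coupling.couplings.items():
        vals = np.zeros(len(params))
        for pname, w in weights.items():
            if pname not in params.columns:
                raise ValueError(f"unknown parameter column {pname!r}")
            x = params[pname].to_numpy(dtype=float)
            sd = x.std()
            vals = vals + w * (x - x.mean()) / (sd if sd > 0 else 1.0)
        vals = vals + rng.normal(0.0, coupling.noise_sd, size=len(params))
        out[beta_name] = vals
    return out


def gen_mask(angle_deg: float, n_voxels: int = 400, thickness: float = 1.0,
             seed: int = 0, length_mm: float = 80.0, hemisphere: str = "L",
             voxel_mm: float = 1.0):
    """Elongated voxel cloud along a sagittal-plane line rotated clockwise
    by ``angle_deg`` from the AC-PC axis; returns a ``longaxis.VoxelMask``.

    Points are spread along the axis with Gaussian perpendicular jitter of
    ``thickness`` mm, then snapped to an integer grid (duplicates replaced
    so the voxel count is exact).
    """
    from .longaxis import VoxelMask
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(angle_deg)
    axis = np.array([np.cos(theta), -np.sin(theta)])   # (y, z), clockwise
    perp = np.array([np.sin(theta), np.cos(theta)])
    x0 = -25.0 if hemisphere == "L" else 25.0
    seen, ijk = set(), []
    t_positions = np.linspace(-length_mm / 2, length_mm / 2, n_voxels)
    i, max_attempts = 0, 200 * n_voxels
    while len(ijk) < n_voxels:
        if i >= max_attempts:
            raise ValueError(
                f"infeasible geometry: cannot place {n_voxels} unique voxels "
                f"(length {length_mm} mm, thickness {thickness} mm, "
                f"{voxel_mm} mm grid)")
        t = t_positions[i % n_voxels] if i < n_voxels else rng.uniform(-length_mm / 2, length_mm / 2)
        i += 1
        off = rng.normal(0.0, thickness)
        y, z = t * axis + off * perp
        x = x0 + rng.normal(0.0, thickness)
        vox = (int(round(x / voxel_mm)), int(round(y / voxel_mm)), int(round(z / voxel_mm)))
        if vox not in seen:
            seen.add(vox)
            ijk.append(vox)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return VoxelMask(ijk=np.asarray(ijk, dtype=int), affine=affine,
                     probabilities=np.ones(n_voxels), hemisphere=hemisphere)


_SHAPES = ("ramp-to-event", "on-off", "delayed-sustained")


def gen_timecourses(event_times: np.ndarray, shape: str = "on-off",
                    noise_sd: float = 0.0, seed: int = 0,
                    duration_s: float | None = None,
                    amplitude: float = 1.0, dt: float = 1.0):
    """A 1 s-sampled activity series with a planted event-locked shape.

    Shapes: ``ramp-to-event`` rises linearly over the 4 s before each event
    and peaks 1 s before it; ``on-off`` is a 3-s box starting at the event;
    ``delayed-sustained`` is a 6-s box starting 3 s after the event.
    Returns (times, series).
    """
    if shape not in _SHAPES:
        raise ValueError(f"unknown shape {shape!r}; expected one of {_SHAPES}")
    event_times = np.asarray(event_times, dtype=float)
    rng = np.random.default_rng(seed)
    t_end = float(event_times.max()) + 15.0
    times = np.arange(0.0, t_end + dt, dt)
    series = np.zeros_like(times)
    for ev in event_times:
        rel = times - ev
        if shape == "ramp-to-event":
            m = (rel >= -4.0) & (rel <= -1.0)
            series[m] += amplitude * (rel[m] + 4.0) / 3.0
            m2 = (rel > -1.0) & (rel <= 1.0)
            series[m2] += amplitude * (1.0 - rel[m2]) / 2.0
        elif shape == "on-off":
            d = 3.0 if duration_s is None else duration_s
            series[(rel >= 0.0) & (rel < d)] += amplitude
        else:  # delayed-sustained
            d = 6.0 if duration_s is None else duration_s
            series[(rel >= 3.0) & (rel < 3.0 + d)] += amplitude
    series = series + rng.normal(0.0, noise_sd, size=series.size)
    return times, series
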