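"""Model-based regressor construction for event-related designs.

Trial-wise decision signals from a fitted trajectory are turned into
predicted-response time courses the way model-based fMRI analyses build
parametric regressors:

1. signals are mean-centered within run;
2. for each trial a unit-height boxcar spanning the aligned phase (clock
   phase for entropy and uncertainty, feedback phase for the reward
   prediction error) is convolved with a canonical double-gamma
   hemodynamic response function (HRF);
3. the convolved response is renormalized to peak height 1 — so amplitude
   encodes the signal, not the phase duration — multiplied by the trial's
   centered signal value, and summed across trials;
4. the summed regressor is resampled to the repetition-time grid (1 s) and
   high-pass filtered (0.008 Hz) with a Gaussian-weighted running-line
   detrender, the same filter applied to the data.

The internal convolution grid is 0.1 s.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["extract_trial_signals", "double_gamma_hrf", "build_dm_regressor",
           "highpass", "regressor_correlation", "SIGNAL_ALIGNMENT"]

#: which task phase each signal is aligned to
SIGNAL_ALIGNMENT = {
    "rpe": "feedback",
    "entropy": "clock",
    "u_percentile": "clock",
    "rt_vmax": "clock",
    "delta_rt_vmax": "feedback",
    "value_chosen": "clock",
}


def extract_trial_signals(trajectory: pd.DataFrame,
                          signals=("rpe", "entropy", "u_percentile"),
                          feedback_dur: float = 0.9) -> pd.DataFrame:
    """Per-trial signal table with onsets/durations (s), signals
    mean-centered within run (``*_c`` columns).

    ``delta_rt_vmax`` — the trial-to-trial shift of the global value
    maximum — is derived as the within-run first difference of ``rt_vmax``
    (0 on the first trial of a run).
    """
    req = {"subject", "run", "trial", "rt_ms", "clock_onset", "feedback_onset"}
    missing = req - set(trajectory.columns)
    if missing:
        raise ValueError(f"trajectory lacks columns {sorted(missing)}")
    df = trajectory.sort_values(["subject", "run", "trial"]).copy()
    if df.groupby(["subject", "run"])["trial"].apply(
            lambda t: (np.diff(t) != 1).any()).any():
        raise ValueError("missing trials in trajectory")
    df["clock_dur"] = df["rt_ms"] / 1000.0
    df["feedback_dur"] = df.get("feedback_dur", feedback_dur)
    if "rt_vmax" in df.columns:
        df["delta_rt_vmax"] = (df.groupby(["subject", "run"])["rt_vmax"]
                               .diff().fillna(0.0))
    for sig in signals:
        if sig not in df.columns:
            raise ValueError(f"signal {sig!r} not in trajectory")
        df[sig + "_c"] = df[sig] - df.groupby(["subject", "run"])[sig].transform("mean")
    keep = ["subject", "run", "trial", "clock_onset", "clock_dur",
            "feedback_onset", "feedback_dur"]
    keep += [c for c in df.columns if c.endswith("_c")]
    keep += [s for s in ("rt_vmax", "delta_rt_vmax") if s in df.columns]
    return df[keep]


def double_gamma_hrf(dt: float = 0.1, duration: float = 32.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``; peak normalized to 1.

    Positive lobe peaking near ``peak_delay`` s minus an undershoot peaking
    near ``undershoot_delay`` s scaled by 1/``ratio``; zero at t = 0.
    """
    if dt <= 0:
        raise ValueError("sampling step must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    pos = stats.gamma.pdf(t, peak_delay, scale=1.0)
    neg = stats.gamma.pdf(t, undershoot_delay, scale=1.0)
    h = pos - neg / ratio
    return h / h.max()


def _trial_response(onset, dur, signal, grid_len, dt, hrf):
    """One trial's convolved, peak-renormalized, signal-scaled response."""
    if dur < 0:
        raise ValueError("negative trial duration")
    box = np.zeros(grid_len)
    i0 = int(round(onset / dt))
    i1 = max(i0 + 1, int(round((onset + dur) / dt)))
    box[i0:min(i1, grid_len)] = 1.0
    resp = np.convolve(box, hrf)[:grid_len]
    peak = np.abs(resp).max()
    if peak > 0:
        resp /= peak
    return resp * signal


def build_dm_regressor(signals: pd.DataFrame, which: str,
                       hrf: np.ndarray | None = None,
                       tr: float = 1.0, dt: float = 0.1,
                       run_dur: float | None = None) -> pd.DataFrame:
    """Duration-modulated regressor for one signal of one run's trials.

    ``signals`` is one run of :func:`extract_trial_signals` output;
    ``which`` names a signal (its ``_c`` mean-centered column is used).
    Returns a DataFrame with columns ``time`` (the TR grid) and ``value``.
    """
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    col = which if which.endswith("_c") else which + "_c"
    if col not in signals.columns:
        raise ValueError(f"no mean-centered column {col!r}")
    align = SIGNAL_ALIGNMENT.get(which.removesuffix("_c"), "clock")
    onsets = signals[f"{align}_onset"].to_numpy(dtype=float)
    durs = signals[f"{align}_dur"].to_numpy(dtype=float)
    vals = signals[col].to_numpy(dtype=float)
    if run_dur is None:
        run_dur = float((onsets + durs).max()) + 20.0
    grid_len = int(np.ceil(run_dur / dt)) + 1
    total = np.zeros(grid_len)
    for onset, dur, val in zip(onsets, durs, vals):
        total += _trial_response(onset, dur, val, grid_len, dt, hrf)
    hi_times = np.arange(grid_len) * dt
    tr_times = np.arange(0.0, run_dur + tr / 2, tr)
    return pd.DataFrame({"time": tr_times,
                         "value": np.interp(tr_times, hi_times, total)})


def highpass(series: np.ndarray, cutoff_hz: float = 0.008,
             tr: float = 1.0) -> np.ndarray:
    """High-pass filter by subtracting a Gaussian-weighted running-line fit.

    The smoother's kernel SD is 1/(4 * cutoff) seconds, which passes a
    0.05 Hz oscillation essentially unattenuated while removing most of the
    amplitude below ~0.004 Hz at the default 0.008 Hz cutoff. A series
    shorter than one filter window is returned unchanged with a warning.
    """
    y = np.asarray(series, dtype=float)
    sigma_s = 1.0 / (4.0 * cutoff_hz)
    n = y.size
    if n * tr < 1.0 / cutoff_hz:
        warnings.warn("series shorter than one filter window; passing through")
        return y.copy()
    t = np.arange(n) * tr
    fitted = np.empty(n)
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_s) ** 2)
        sw = w.sum()
        tm = (w * t).sum() / sw
        ym = (w * y).sum() / sw
        dt_ = t - tm
        denom = (w * dt_ * dt_).sum()
        slope = (w * dt_ * (y - ym)).sum() / denom if denom > 0 else 0.0
        fitted[i] = ym + slope * (t[i] - tm)
    return y - fitted


def regressor_correlation(df: pd.DataFrame, col_a: str, col_b: str,
                          subject: str = "subject", run: str = "run"):
    """Per-run Pearson correlation of two regressors and a pooled summary.

    The pooled estimate is the mean of subject-level mean correlations with
    a t-based 95% interval across subjects (the hierarchical unit). Runs
    where either regressor has zero variance are flagged missing.
    """
    rows = []
    for (s, r), g in df.groupby([subject, run]):
        a, b = g[col_a].to_numpy(float), g[col_b].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            rows.append(dict(subject=s, run=r, r=np.nan))
        else:
            rows.append(dict(subject=s, run=r, r=float(np.corrcoef(a, b)[0, 1])))
    per_run = pd.DataFrame(rows)
    subj_means = per_run.dropna(subset=["r"]).groupby("subject")["r"].mean()
    m = float(subj_means.mean())
    if len(subj_means) > 1:
        se = float(subj_means.std(ddof=1) / np.sqrt(len(subj_means)))
        tcrit = stats.t.ppf(0.975, len(subj_means) - 1)
        ci = (m - tcrit * se, m + tcrit * se)
    else:
        se, ci = np.nan, (np.nan, np.nan)
    return per_run, dict(pooled_r=m, se=se, ci_low=ci[0], ci_high=ci[1],
                         n_subjects=int(len(subj_means)))
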