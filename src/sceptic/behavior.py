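"""Behavioral indices of exploration and exploitation.

Two multilevel-regression indices operationalize the explore/exploit
continuum on the clock task:

- *exploration*: the lag-1 autocorrelation of response times. Regressing
  RT_t on RT_{t-1} (and its interactions with the previous outcome and a
  subject-level moderator such as a regional "brain beta"), a weaker
  autocorrelation means larger trial-to-trial RT swings, i.e. more
  exploration. Autocorrelation is preferred over |RT_t - RT_{t-1}|, whose
  distribution is zero-inflated and scale-dependent.
- *convergence (exploitation)*: the effect of the previous trial's global
  value maximum location (RT_Vmax) on the current RT, and its growth late
  in learning via an inverse-trial (-1/trial) interaction.

The module also builds counting-process survival tables for hazard models
of *when* within the interval a response occurs: one row per (trial x
100 ms bin) restricted to the 1000-3500 ms analysis window, with learned
value and uncertainty sampled per bin as time-varying covariates, censoring
of post-response bins by construction, and optional censoring of no-go
zones at the window edges. Model fitting itself is delegated to statsmodels
(mixed models) and lifelines (Cox); the design construction is the
substance here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["make_lagged_table", "exploration_index", "convergence_index",
           "build_survival_table", "rescale_within_subject", "fit_hazard_model"]


def make_lagged_table(trials: pd.DataFrame,
                      moderators: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trial table with one-trial-lagged predictors; lags never cross run
    boundaries (first trial of each run has missing lagged fields).

    Adds ``rt_prev``, ``reward_prev`` (binary), ``rt_vmax_prev`` and the
    inverse-trial term ``inv_trial`` = -1/trial; subject-level moderator
    columns are joined on ``subject``.
    """
    df = trials.sort_values(["subject", "run", "trial"]).copy()
    g = df.groupby(["subject", "run"], sort=False)
    df["rt_prev"] = g["rt_ms"].shift(1)
    df["reward_prev"] = g["rewarded"].shift(1)
    if "rt_vmax" in df.columns:
        df["rt_vmax_prev"] = g["rt_vmax"].shift(1)
    df["inv_trial"] = -1.0 / df["trial"]
    if moderators is not None:
        df = df.merge(moderators, on="subject", how="left", validate="m:1")
    return df


def _mixed_fit(formula: str, table: pd.DataFrame, needed: list[str]):
    import statsmodels.formula.api as smf
    data = table.dropna(subset=needed).copy()
    if data["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data["subject"],
                                re_formula="1",
                                vc_formula={"run": "0 + C(run)"})
            res = model.fit(reml=True)
        except Exception:
            # fall back to subject random intercepts only (e.g. single run)
            model = smf.mixedlm(formula, data, groups=data["subject"], re_formula="1")
            res = model.fit(reml=True)
    out = pd.DataFrame({"coef": res.params, "se": res.bse,
                        "z": res.params / res.bse, "p": res.pvalues})
    out.index.name = "term"
    return out, res


def exploration_index(table: pd.DataFrame, moderator: str):
    """RT autocorrelation model: rt_t ~ rt_prev * reward_prev * moderator
    with random intercepts for subject and run-in-subject.

    A smaller ``rt_prev`` coefficient means weaker autocorrelation — more
    exploration; negative rt_prev x moderator terms identify moderators
    associated with greater exploration. Returns (coefficient table,
    statsmodels result).
    """
    t = table.rename(columns={moderator: "mod"})
    if t["mod"].std() == 0:  # no moderator variance: drop its terms
        formula = "rt_ms ~ rt_prev * reward_prev"
        return _mixed_fit(formula, t, ["rt_ms", "rt_prev", "reward_prev"])
    formula = "rt_ms ~ rt_prev * reward_prev * mod"
    return _mixed_fit(formula, t, ["rt_ms", "rt_prev", "reward_prev", "mod"])


def convergence_index(table: pd.DataFrame, moderator: str):
    """Global-maximum convergence model:
    rt_t ~ rt_vmax_prev * inv_trial * moderator + rt_prev.

    Positive ``rt_vmax_prev`` terms indicate exploitation of the learned
    value maximum; the inv_trial interaction tests whether convergence
    strengthens late in learning. Returns (coefficient table, result).
    """
    t = table.rename(columns={moderator: "mod"})
    if t["mod"].std() == 0:
        formula = "rt_ms ~ rt_vmax_prev * inv_trial + rt_prev"
        return _mixed_fit(formula, t,
                          ["rt_ms", "rt_vmax_prev", "inv_trial", "rt_prev"])
    formula = "rt_ms ~ rt_vmax_prev * inv_trial * mod + rt_prev"
    return _mixed_fit(formula, t,
                      ["rt_ms", "rt_vmax_prev", "inv_trial", "mod", "rt_prev"])


def build_survival_table(trials: pd.DataFrame, value_grids: dict,
                         u_grids: dict, window=(1000.0, 3500.0),
                         bin_ms: float = 100.0, censor_no_go: bool = False,
                         no_go_ms: float = 100.0,
                         rescale: bool = True,
                         grid_bin_ms: float = 100.0) -> pd.DataFrame:
    """Counting-process rows (start, stop, event) per trial x 100 ms bin.

    Only the ``window`` interval is modeled; a trial responding before the
    window start contributes no rows; bins after the response are absent;
    the response bin (possibly partial) carries the event flag unless the
    response falls past the window end (then the trial is censored at the
    end). Value and uncertainty are sampled at each bin's start from the
    trial's decision-time functions (``value_grids``/``u_grids``: subject
    -> (n_trials, n_grid) arrays on the 100 ms choice grid) and are, by
    default, standardized within subject. With ``censor_no_go``, bins within
    ``no_go_ms`` of the window edges are dropped (events there censored).
    """
    lo, hi = float(window[0]), float(window[1])
    rows = []
    for subj, g in trials.sort_values(["subject", "run", "trial"]).groupby("subject"):
        vg, ug = value_grids[subj], u_grids[subj]
        for i, (_, tr) in enumerate(g.iterrows()):
            rt = float(tr["rt_ms"])
            if rt < lo:
                continue
            end = min(rt, hi)
            start = lo
            while start < end:
                stop = min(start + bin_ms, end)
                j = min(int(start // grid_bin_ms), vg.shape[1] - 1)
                rows.append(dict(
                    subject=subj, run=int(tr["run"]), trial=int(tr["trial"]),
                    start=start, stop=stop,
                    event=int(stop == rt and rt <= hi),
                    value=float(vg[i, j]), uncertainty=float(ug[i, j])))
                start = stop
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if censor_no_go:
        keep = (df["start"] >= lo + no_go_ms) & (df["stop"] <= hi - no_go_ms)
        df = df[keep].reset_index(drop=True)
    if rescale:
        df = rescale_within_subject(df, ["value", "uncertainty"])
    return df


def rescale_within_subject(df: pd.DataFrame, cols,
                           subject: str = "subject") -> pd.DataFrame:
    """Standardize columns to mean 0 / SD 1 within each subject; a constant
    series within a subject becomes zeros with a warning."""
    out = df.copy()
    for col in cols:
        def z(x):
            sd = x.std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(f"constant {col!r} within a subject; rescaled to zeros")
                return x * 0.0
            return (x - x.mean()) / sd
        out[col] = out.groupby(subject)[col].transform(z)
    return out


def fit_hazard_model(survival: pd.DataFrame, covariates=("value", "uncertainty")):
    """Cox time-varying hazard fit of the survival table (lifelines).

    Returns the fitted CoxTimeVaryingFitter; the within-trial clock is the
    time scale and each (subject, run, trial) is an observation unit.
    """
    from lifelines import CoxTimeVaryingFitter
    df = survival.copy()
    df["id"] = (df["subject"].astype(str) + "_" + df["run"].astype(str)
                + "_" + df["trial"].astype(str))
    cols = ["id", "start", "stop", "event", *covariates]
    ctv = CoxTimeVaryingFitter(penalizer=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df[cols], id_col="id", start_col="start", stop_col="stop",
                event_col="event")
    return ctv
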