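# sceptic

Temporal-basis-function reinforcement learning for the **clock task** — a
continuous-action paradigm in which a dot sweeps a 4-second interval and
the chosen stopping time (response time, RT) earns a probabilistic reward
under one of four monotone probability/magnitude contingencies (IEV, DEV,
CEV, CEVR). The package is for computational cognitive neuroscientists who
want a tested, end-to-end pipeline from task simulation through model
fitting to model-based fMRI regressors, behavioral exploration/exploitation
indices, and hippocampal long-axis geometry — all runnable on synthetic
data, no downloads required.

## The model

Value over the interval is approximated by 24 unnormalized Gaussian
temporal basis functions,

    phi_b(t) = exp[-(t - mu_b)^2 / (2 s_b^2)],      V(i) = w(i) phi,

with centers evenly tiling [0, 4000] ms and a shared width chosen so that
adjacent elements' normalized densities overlap by 50%. After a response at
time t earning `reward`, every element updates by an eligibility-weighted
delta rule; under *selective maintenance* unchosen elements also decay:

    w_b(i+1) = w_b(i) + e_b(i|t) alpha [reward(i|t) - w_b(i)]
               - gamma (1 - e_b(i|t)) (w_b(i) - h),

where `e_b` in [0, 1] is the (renormalized) overlap of a Gaussian
generalization kernel at t with the element's receptive field; the
*full-maintenance* variant drops the decay term. Choice is a softmax with
temperature `beta` over a 40-bin (100 ms) grid. Derived decision signals:
the reward prediction error `reward - V(rt)`, the Shannon entropy of the
normalized weights (low entropy = one prominent "value bump"), and
RT_Vmax, the time of the global value maximum. A Kalman-filter variant
("fixed U+V") tracks per-element uncertainty sigma_b with gain-scheduled
shrinkage and chooses on Q = V + tau·U, giving uncertainty-directed
(tau > 0) or uncertainty-averse (tau < 0) policies.

Fitting is hierarchical MAP ("empirical Bayes"): subject parameters live in
transformed space (logit alpha/gamma, log beta) under a Gaussian population
prior; an outer loop alternates subject fits with population mean/SD
updates, then trajectories can be recomputed at the group-mean parameters.

## Worked example

```python
from sceptic import synth, signals, fitting

pop = synth.gen_population(synth.PopulationSpec(n_subjects=4, seed=0))
sim = synth.simulate_experiment(pop, schedule=("IEV", "DEV"), seed=1)
print(sim.trials.head())
pop_fit = fitting.fit_population(sim.trials, "selective")
print(fitting.natural_params("selective", pop_fit.mean))
```

prints (abridged)

```
 subject  run  trial contingency  rt_ms  reward    rpe  entropy  rt_vmax  u_percentile
       1    1      1         IEV 2050.0  152.84 152.84     3.18     50.0         67.50
       1    1      2         IEV  350.0   80.93  80.93     1.47   2050.0         65.00
       1    1      3         IEV  650.0   90.73  85.47     2.14   2050.0         32.50

{'alpha': 0.156, 'gamma': 0.567, 'beta': 17.795}
```

Trial 1 starts with maximal entropy (log 24 = 3.18 nats) and an RPE equal
to the obtained reward (all values start at zero); as learning proceeds the
entropy falls and RT_Vmax tracks the emerging value bump. The fitted
group-mean parameters are on their natural scales: learning rate ~0.16,
selective decay ~0.57, softmax temperature ~18 points.

Building fMRI-style regressors from the same simulation:

```python
tbl = signals.extract_trial_signals(sim.trials)
run = tbl[(tbl.subject == 1) & (tbl.run == 1)]
rpe_regressor = signals.build_dm_regressor(run, "rpe")       # feedback-aligned
ent_regressor = signals.build_dm_regressor(run, "entropy")   # clock-aligned
```

Each trial contributes a duration-modulated boxcar convolved with a
double-gamma HRF, peak-renormalized to 1 so amplitude encodes the
(run-mean-centered) signal rather than decision time, summed across trials
and resampled to the 1 s repetition-time grid. On this synthetic session
the pooled RPE–entropy regressor correlation is r = 0.16 — the two signals
are separable in a joint GLM.

A command-line interface mirrors the library:
`sceptic synth`, `sceptic simulate`, `sceptic fit`, `sceptic analyze`,
`sceptic longaxis` (NIfTI masks in, rotation angle and quantile bins out).

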