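# Methods notes

## Task environment

The clock task's four contingencies are implemented as a parameterized
monotone pair: reward probability runs linearly from `p0` to `p1` across
the 4000 ms interval and expected value linearly from `ev0` to `ev1`
(points); magnitude is their ratio, a monotone ratio of linear functions.
Defaults (IEV: p 0.85→0.35, EV 60→120; DEV the mirror image; CEV:
p 0.85→0.35, EV 80; CEVR: p 0.35→0.85, EV 80) give CEV a decreasing
probability / increasing magnitude tradeoff and CEVR the reverse, with EV
constant by construction for both. Only the monotonicity/constancy
structure matters downstream, and every curve parameter is exposed so
alternative functional forms can be swapped in. A response at or past
4000 ms scores zero (missed trial). Time is milliseconds throughout; the
decision interval is the half-open [0, 4000).

## Temporal basis and eligibility

24 Gaussian elements span the closed interval ends; the shared width is
solved by root-finding so that the overlap coefficient of adjacent
normalized densities — the integral of their pointwise minimum, for equal
variances `2*Phi(-delta/(2s))` — equals the 0.5 target (default width
~128.9 ms SD at 173.9 ms spacing). Basis functions are evaluated, not
truncated or renormalized, at the interval edges.

Eligibility integrates a normalized Gaussian generalization kernel
(variance `s_g^2`, default equal to the element variance) against each
unnormalized receptive field. As printed, that integral peaks at 1/sqrt(2)
under perfect overlap, so it is divided by the perfect-overlap value,
giving the closed form `exp(-(rt - mu_b)^2 / (2 (s_b^2 + s_g^2)))` and a
maximum of exactly 1. A `truncate` switch instead integrates over [0, T]
with per-element renormalization, under which edge elements generalize
less; the default is the untruncated form. Tests verify both against
scipy quadrature at 1e-8.

Entropy is computed over the 24 normalized element weights (not the 40-bin
value function), in nats; a total weight below 1e-12 returns log(24), the
maximal-uncertainty convention appropriate for the pre-learning state.
RT_Vmax ties break to the earliest grid time. The choice grid has 40 bins
of 100 ms; bin j maps to the bin-center time (j + 0.5) * 100 ms.

## Kalman (fixed U+V) variant

Means update with a fixed learning rate (identical to the full-maintenance
rule, verified by a paired-trajectory test); only the uncertainties follow
the Kalman gain. Sigmas are stored as standard deviations; the gain
consumes their squares. The measurement-noise scale defaults to the
empirical reward SD of the run being processed (for replay/fitting) or a
uniform-sampling Monte Carlo estimate of a typical run's reward SD (for
generative agents); both are overridable, since "variance of returns of a
typical run" admits either a pooled or per-contingency reading. The
uncertainty percentile of the chosen action is a midrank percentile
(0-100) of U(rt) against the same trial's 40-bin U values; with untouched
uniform sigmas the basis envelope makes U slightly lower at the interval
edges, so early-trial percentiles sit near, not exactly at, 50.

## Fitting

The likelihood of a trial is the softmax probability of the observed
100 ms bin under the *pre-update* decision function; learning state resets
at run boundaries. Parameters are estimated in transformed space (logit
alpha/gamma, log beta, identity tau) by L-BFGS-B with 5 starts at the
10-90% prior quantiles and bounds +-8; posterior SDs come from a
central-difference diagonal Hessian (step 0.01). A fit is flagged
unconverged when the optimizer fails everywhere or the *data* likelihood
has no curvature at the mode (flat likelihood; the posterior SDs then fall
back to the prior scale). Inner loops are numba-compiled; the pure-numpy
step functions serve as the cross-checking reference implementation.

The population loop runs in two phases. Updating the population SD from
the first iteration collapses the prior: along the alpha-beta likelihood
ridge the Laplace curvature badly understates posterior spread, so the
mode-variance + posterior-variance update spirals toward the SD floor and
freezes the population mean wherever the initial prior pulled it. The loop
therefore first localizes the population *mean* under the fixed
weakly-informative prior SD (default 1.0; mean-change tolerance 5e-3),
then updates mean and SD jointly (population variance = spread of modes +
mean posterior variance, SD floor 0.1) until the change drops below 1e-3
or stops decreasing, within 50 total iterations. Subjects are
multi-started only on the first round and warm-started afterwards.
`refit_group_means` replays every subject's trajectory at the group-mean
parameters, removing parameter-scaling differences from cross-subject
signal comparisons.

Known limitation: with ~400 trials of softmax choices the learning rate
and temperature are weakly identified individually (a curved likelihood
valley); hierarchical shrinkage restores a usable truth/estimate
correlation (~0.6-0.7 in recovery simulations at 20 x 400) but leaves a
skewness-induced bias of roughly +0.15 with ~0.2 sampling noise on the
transformed population means — about one to two ideal-observer standard
errors at that sample size. The decay parameter gamma is well identified
(recovery correlation ~0.9).

## Regressors

The double-gamma HRF uses the conventional constants (gamma-pdf peak at
6 s, undershoot at 16 s, ratio 1:6), peak-normalized, zero at t = 0. Per
trial, a unit boxcar spanning the aligned phase (clock phase with RT
duration for entropy/uncertainty; 0.9 s feedback phase for RPE) is
convolved on a 0.1 s grid, renormalized to peak 1, scaled by the
run-mean-centered signal (centering precedes the per-trial
multiplication), summed across trials, and linearly resampled to the 1 s
repetition-time grid. Overlapping trials sum; negative durations are
rejected. The exact-peak contract holds on the convolution grid; the 1 s
resampling can sample slightly off-peak, as in any TR-sampled design.

The high-pass filter subtracts a Gaussian-weighted running-line fit. The
kernel SD is 1/(4 * cutoff) seconds — 31.25 s at the default 0.008 Hz —
chosen so the filter passes 0.05 Hz within 10% while removing more than
80% of a 0.002 Hz oscillation; a series shorter than one cutoff period is
passed through with a warning. Pooled regressor correlations are the mean
of subject-level mean run correlations with a t-interval across subjects.

## Behavioral indices and survival design

Exploration is operationalized as the lag-1 RT autocorrelation (weaker
autocorrelation = larger RT swings = more exploration) rather than
|delta RT|, whose distribution is zero-inflated and scale-dependent. Lags
never cross run boundaries. Mixed models use statsmodels MixedLM with a
subject random intercept and a run-within-subject variance component
(falling back to subject-only when the component is inestimable); when a
moderator has zero variance its terms are dropped from the design.

The survival table models only 1000-3500 ms, in 100 ms counting-process
bins; the response bin (possibly partial) carries the event, responses
past 3500 ms are censored at the window end, and responses before 1000 ms
contribute no rows. Value and uncertainty are sampled at each bin's start
from the trial's decision-time functions and standardized within subject
by default. No-go censoring drops one bin width (configurable) at each
window edge, since exact no-go boundaries are not externally specified.
Cox time-varying fits are delegated to lifelines with a small ridge
penalty for separation robustness.

## Long-axis geometry

Coordinates are RAS mm; a clockwise rotation theta means the axis
direction in the sagittal (y, z) plane is (cos theta, -sin theta).
Extreme-voxel ordering projects (y, z) onto a configurable direction,
default (1, -1)/sqrt(2) — anteroinferior (large y, small z) scores high —
rather than y + z, which does not separate the anatomical corners for a
clockwise-rotated axis. Because ordering by an oblique key biases the
10-voxel extreme sets sideways, the selection is iterated with the key
realigned to each successive estimate (4 passes; the first pass is the
single anatomical-key estimate, which suffices near 45 degrees). Slopes
use the two extreme-set centroids per hemisphere (unweighted), averaged
across hemispheres arithmetically. Quantile bins are assigned by ordinal
rank along the projected axis (label 1 = posterior-most), guaranteeing
counts differ by at most one; left/right masks are binned separately and
not mirrored. Event-locked time courses interpolate linearly onto a 1 s
grid and mark samples beyond the series support or at/after the next
trial's onset as missing, never imputed. Per-(time, bin) regressions are
corrected across cells by Benjamini-Yekutieli at rate 0.05.

## Synthetic data

The default population mirrors the study scale (70 subjects, 8 runs x 50
trials, counterbalanced contingencies); tests use reduced presets (2-20
subjects, 1-8 runs) for speed. Generating distributions in transformed
space are alpha_t ~ N(-2.2, 0.5) (alpha ~ 0.1), gamma_t ~ N(-0.4, 0.5),
beta_t ~ N(3.0, 0.4) (beta ~ 20 points), tau_t ~ N(-0.3, 0.3) (mildly
uncertainty-averse) — moderately exploitative learners with realistic
between-subject spread. ITIs are exponential with a 2.5 s scale truncated
to [1, 10] s. Synthetic "brain betas" are linear functions of standardized
transformed parameters plus Gaussian noise; zero coupling yields
independence. Synthetic masks are jittered voxel clouds along a known
sagittal line (default 80 mm length, 1 mm grid, 1 mm perpendicular
jitter — geometry at which the 10-voxel-extreme rotation estimator's noise
is well under the 1 degree test band); planted time-course shapes are a
ramp peaking 1 s before the event, a 3 s on-off box, and a
delayed-sustained box starting 3 s after the event.

What the generator does *not* emulate: BOLD physiology and noise, motion,
the study's optimizer-derived ITI sequences (only the distributional
family), emotion stimuli, and age structure. Passing tests therefore
demonstrate correctness of the algorithms and recoverability under the
model's own assumptions, not performance on real neuroimaging data.
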