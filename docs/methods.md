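# Methods

## The model

`statehmm` segments trial-by-trial rodent choice behavior into discrete
performance states with a hidden Markov model whose emissions are
multinomial (softmax) generalized linear models. On trial $t$ a mouse
sees a stimulus of signed value $u_t \in [-1, 1]$ (negative =
left-target, positive = right-target) and emits a choice
$y_t \in \{L, R, Nr\}$ (left lick, right lick, no response). Conditional
on the hidden state $z_t = k$,

$$\Pr(y_t = c \mid z_t = k, u_t) =
\frac{\exp(w_c^{(k)} u_t + b_c^{(k)})}{\sum_{c'} \exp(w_{c'}^{(k)} u_t + b_{c'}^{(k)})},$$

so each state carries its own set of three psychometric curves. States
evolve as a first-order Markov chain with row-stochastic transition
matrix $A$ ($K \times K$) and initial distribution $\pi$; every session
is an independent chain (inference restarts from $\pi$, expected
transitions never span sessions).

**Gauge.** The softmax over three categories is over-parameterized; we
pin the no-response category to $w = b = 0$ in every state. Any gauge
gives identical probabilities; this one makes $w$ and $b$ directly
interpretable as log-odds of responding versus not responding.

**Inference.** Posteriors and the marginal likelihood come from the
scaled forward-backward recursions with emissions evaluated in the log
domain; per-step normalization makes chains of thousands of trials with
up to seven states underflow-free (checked at $T = 2000$, $K = 7$). The
inner recursions are numba-compiled with a pure-numpy fallback. A
path-enumeration oracle verifies exactness to $10^{-10}$ relative on
small instances.

**Fitting.** EM maximizes the log-likelihood (MLE) or, optionally, the
log-posterior (MAP) with a zero-mean Gaussian prior of variance 2 on
every free GLM parameter (weights and biases of the two non-reference
categories) and a symmetric Dirichlet($\alpha$=2) prior on the rows of
$A$. The M-step is closed-form for $A$ (expected transition counts,
plus $\alpha - 1$ pseudo-counts under MAP) and $\pi$ (expected initial
counts), and numeric (L-BFGS with analytic gradients, warm-started) for
each state's GLM on the $\gamma$-weighted multinomial log-likelihood. A
guard keeps the old GLM parameters whenever the optimizer fails to
improve, so the EM objective is non-decreasing by construction; a
monotonicity assertion raises if it ever is not. Defaults: tolerance
$10^{-4}$ in the objective, 300 iterations max, random initialization
with a sticky transition matrix (0.9 diagonal plus Dirichlet noise),
uniform $\pi$, N(0, 1) GLM parameters. $\pi$ is estimated by default;
a fixed uniform $\pi$ is selectable.

## Model selection and choice prediction

The number of states is chosen by 5-fold cross-validation across
sessions (folds keyed on session content, so scores are invariant to
session ordering): for each $K$ from 1 to 7 the best of 10 random EM
restarts on the training sessions is scored by held-out log-likelihood
per trial. The "plateau" is operationalized as: chosen $K$ = smallest
$K$ whose mean test log-likelihood is within 0.002 nats/trial of the
maximum over the scan (threshold configurable). The final model is a
single best-of-restarts MLE fit to all sessions.

Choice-prediction accuracy withholds rotating contiguous blocks of
trials (12 trials per block, every 5th block per fold, so each fold
tests ~20%) and predicts each withheld choice by online filtering: the
state belief is updated on observed trials and propagated through $A$
across withheld trials without conditioning on their choices; the
prediction is the argmax choice of the argmax-belief state's GLM at the
trial's stimulus (ties to the lowest index). Short blocks matter: with
a single 20%-of-session slab the belief decays to stationarity across
the ~60-trial gap and multi-state models lose their advantage, whereas
12-trial blocks preserve it (we observe 12–17 percentage-point gains of
a 3-state over a 1-state model on sticky synthetic data).

## State labels and stereotypes

A trial belongs to its argmax posterior state when that posterior is at
least 0.8 (inclusive), otherwise it is indeterminate. Each state is
classified into one of six stereotypes from its response profile at the
easiest stimuli ($u = \pm 1$): disengaged (P(Nr) ≥ 0.5 on both sides),
optimal (correct lick ≥ 0.5 on both), left/right bias (one lick
direction ≥ 0.5 on both), avoid-right/avoid-left (correct lick on one
side, no-response on the other); any profile that fires no rule falls
back to the nearest of the six idealized profiles in total-variation
distance, so the map is total. The 0.5 thresholds are our construction
— the categories themselves are qualitative. Dwell epochs never merge
across session boundaries, and an indeterminate run only counts as a
"transition duration" when flanked by two discrete epochs.

## Physiological features

Raw traces are conditioned as: linear interpolation of pupil dropouts
strictly shorter than 200 ms (longer gaps stay masked; gap length is
measured between the flanking valid samples), second-order
Savitzky-Golay smoothing at the native rate (500 ms window for pupil,
200 ms for face motion energy and locomotion speed — constants, ramps
and parabolas pass unchanged), then linear-interpolation upsampling to
1 kHz. Smoothing precedes upsampling (the order is a design choice; a
second-order filter at the native rate is the conservative reading).
Pupil and face are divided by the session maximum. The per-trial value
of each measure is the 1 kHz sample immediately (strictly) before
stimulus onset. Rolling variability is the sample SD (ddof = 1) and CV
over the preceding 10 trials, requiring at least 3 valid predecessors
(earlier trials are missing, never padded); statistics use only past
trials, so no leakage is possible. The movement index is the sum of
z-scored face and locomotion values, z-scored across all included
trials of a subject (not per session) so the index is comparable across
sessions; the same construction applies to their 10-trial SDs. Face
motion energy from a frame stack is the ROI-mean absolute frame-to-frame
intensity change, session-max normalized. CV10 is computed but not used
downstream.

## Arousal analyses

State probabilities along a measure use 10 equal-count (quantile) bins;
bins with fewer than 20 trials are reported but excluded from fits. The
optimal pupil diameter is the argmax, restricted to the observed pupil
range, of a polynomial fit (weighted by bin count) of optimal-state
probability versus binned pupil. Degree is selected among 1–6 by
cross-validated r² with an elbow rule: residuals are pooled across
folds into a single r² per degree (per-fold r² over two held-out bins
is meaningless), test predictions are clipped to [0, 1] (the target is
a probability, and high-degree polynomials explode when edge bins are
held out), the CV is averaged over five fold assignments, and the elbow
is the smallest degree after which the incremental gain of the monotone
envelope falls below 10% of the total gain. A noiseless parabola
selects degree 2 exactly; on inverted-U data the recovered optimum is
insensitive to the chosen degree (any degree ≥ 2 lands within the bin
resolution).

Quadratic state regressions use standardized per-trial measure values,
their 10-trial SDs, squared values, and pairwise interactions, fit by
least squares to the per-trial posterior probability of a stereotype
(soft target; a hard-label option exists) with 5-fold CV r². The
state-conditioned pupil-movement correlation is the Pearson r over the
per-trial pre-stimulus values of trials labelled with each stereotype
(≥ 10 trials required). Transition-aligned variability extracts the
sd10 columns on the ±10 trials around each entry into (exit from) the
optimal state, subtracts the window-start baseline, and averages across
transitions; the window width is read off the analysis design, not a
measured constant. A "stationary trials" control uses pre-stimulus
locomotion < 0.01 m/s.

## State decoding

A support-vector machine with an RBF kernel discriminates optimal-state
trials from disengaged or sub-optimal-state trials using six features
(three measures × value and sd10), or four in the movement-index
variant (pupil and movement index × value and sd10). Classes are
balanced by seeded subsampling to the minority count (≥ 25 complete
trials per class required); features are standardized with
training-fold statistics only; C = 1 and the kernel width follows the
median pairwise-distance heuristic (both logged and configurable; the
original hyperparameters are unstated). Accuracy is the mean over 5
stratified test folds, and significance is the z-score of that accuracy
against 1000 classifiers whose training labels were permuted (test
folds untouched). Feature contributions shuffle the complementary
feature subset across trials within the training folds. On signal-free
data the permutation null is centered at 0.5 with the binomial spread
$\sqrt{0.25/n}$.

## The synthetic generator

The generator emulates head-fixed discrimination sessions: a few
hundred trials per session, stimuli drawn uniformly from the task grids
(visual angles {0, 18, 36, 54, 72, 90}° map to values {±1, ±0.6, ±0.2};
the auditory grid uses the same symmetric values), stimuli lasting
1.2 s with a uniform 5 ± 2 s inter-trial interval (the distribution
shape is unstated; uniform is the simplest bounded choice; lick-resets
of the ITI are not simulated), a sticky hidden chain sampled from the
ground-truth transition matrix (chains never cross sessions), and
choices drawn from the true state's softmax GLM.

Two canonical ground truths are bundled. The study-condition default
(`default_glmhmm(3)`) has disengaged, optimal, and left-bias states —
the profile mix the analyses need (a disengaged state is required for
the U-shaped disengagement analyses). The recovery truth
(`recovery_glmhmm()`) has three responsive states (optimal, left-bias,
right-bias) with moderate slopes: parameter-recovery experiments need
every weight to be expressed in the data, and both rarely-responding
states and very steep (saturating) psychometrics carry little
information about their stimulus weights — with 4000 trials even an
oracle given the true state labels cannot pin individual weights of
such states better than ~20%.

Physiology: per trial, a bivariate standard normal (pupil factor,
movement factor) with state-dependent correlation sets latent targets;
face and locomotion load on the shared movement factor with coefficient
$\sqrt{0.9}$ plus independent jitter (so the two movement channels
correlate at ~0.9, and the configured pupil-movement correlation
reaches the empirical movement index with ~3% attenuation). Traces are
built at 50 Hz by interpolating through the targets anchored at the
sample immediately before each onset — so pre-stimulus samples carry
exactly the configured state-conditional moments — plus an AR(1)
"wiggle" (persistence 0.8, amplitude half the mean target SD) pinned to
zero at the anchors. Pupil and face are clipped to [0, 1], locomotion
to ≥ 0, and each session includes a brief pre-task burst to 1.0 in
pupil and face so the session maximum of these max-normalized measures
is genuinely attained (otherwise re-normalization in the feature
pipeline would rescale the already-normalized traces and bias the
recovered pupil optimum upward by several percent).

The default coupling places the optimal state at intermediate pupil and
movement with low variability and weak pupil-movement correlation
(0.1), and the non-optimal states at the arousal extremes with higher
variability and strong coupling (0.8) — the inverted-U structure. The
state means are deliberately overlapping (gaps of ~1.5–2 within-state
SDs): real pupil distributions overlap heavily across states, and
widely separated means would also let the ~1–2% of trials that the
choice model mislabels act as extreme leverage points in state-
conditioned correlations.

What the generator does **not** emulate: lapses or history dependence
within a state, input-driven transitions, lick timing, pupil light
reflexes, video frames (face energy is generated directly as a trace),
session-to-session drift, or realistic noise spectra. Passing tests
therefore demonstrate that the estimation and analysis machinery is
correct under the model's own assumptions — not that the model is a
complete account of real physiology.

## Problem sizes and numerical choices

Desk-scale experiments use 10 sessions × 400 trials (recovery, pipeline
round-trip) or × 200–300 trials (model-selection replicates, prediction
contrast), with scaled restarts (2–5) and a relaxed EM tolerance
(1e-3–2e-3 nats) where many fits are needed; these sizes mirror the
deposited study's per-subject scale (hundreds of trials per session,
≥ 10 sessions). Ties in any argmax break to the lowest index.
Degenerate inputs (zero-variance z-scores, empty sessions, chains with
zero-likelihood data, sub-minimum decoder classes) raise validation
errors or return missing values as documented rather than propagating
NaNs.

## Known limitations

- The GLM input is the scalar stimulus value plus bias; the interface
  accepts d-dimensional inputs but the bundled analyses do not use
  history or bias-correction covariates.
- No variational or stochastic inference; EM with restarts only.
- Discrete states only: slow continuous drifts in engagement are
  represented, at best, as indeterminate trials.
- The NWB reader maps fields by configurable names but is exercised
  only when `pynwb` is installed; the tabular dialect is the tested
  path.
- Stereotype thresholds (0.5 at the easiest stimuli) are a sharp
  operationalization of qualitative categories; profiles near the
  boundaries are resolved by the total-variation fallback.
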