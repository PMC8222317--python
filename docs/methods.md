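# Methods

## The task and what the package computes

A listener hears a train of auditory clicks generated by a Poisson process
at 60 Hz and must report, as quickly as possible, when the underlying rate
steps up or down. The rate changes by ±10, ±30, or ±50 Hz (equal
probability) at a time drawn from an exponential distribution (mean 3.5 s)
offset by a guaranteed 1 s pre-change period and truncated at 7.5 s, which
makes the change hazard flat over most of the trial. Before each trial a
cue says "increase", "decrease" (informative, 50% of trials), or "either"
(uninformative). A response within 0.8 s after the change that names the
correct direction is a hit; a response before the change is a false alarm;
no response is a miss. Responses within 0.75 s of onset and responses
opposite an informative cue are treated as attention lapses and excluded.

The package provides (i) a simulator of this design with a model-based
synthetic observer, (ii) the model-free analyses used to characterize such
data — psychometric thresholds, false-alarm estimators, reaction times,
psychophysical reverse correlation — and (iii) a sequential-sampling model
of the decision process, solved by Fokker–Planck propagation and fit by
maximum likelihood, with posterior approximation and model-evidence
comparison.

## The decision model

The decision variable (DV) `a` is a leaky estimate of the click rate,
in Hz:

    da = (c − a/τ) dt + σ_process dW,       c = C / (dt · τ),

where `C` is the (possibly depression-scaled) number of clicks in each
`dt = 0.02 s` input bin, `τ` is the exponential filter width, and
`σ_process` (Hz·s^−1/2) is diffusion noise on the DV. Dividing the bin
click rate `C/dt` by `τ` scales the DV to Hz, so the DV fluctuates around
the running click rate and detection bounds are expressed in Hz.
Detection is the first passage of the DV through a sticky (absorbing)
bound: an upper bound for increase detection, a lower bound for decrease
detection. Bounds are inactive for the first 0.8 s of the trial, the
period in which a change cannot yet have occurred and a baseline DV
estimate forms. The reported response time adds a Gaussian non-decision
time (mean `μ_NDT`, SD `σ_NDT`), representing sensory and motor latency.

Under the uninformative cue two single-bound processes — one increase
detector, one decrease detector, optionally with separate filter widths —
run on the same click train with independent process noise; the first
bound crossing determines the report, and one non-decision time is added
to the winning crossing.

Optional short-term input depression multiplies each click's magnitude by
the current adaptation state; after the click the state is scaled by 0.45
and relaxes to 1 with a 0.02 s time constant (values taken from prior
human Poisson-clicks work). The state before the multiplicative hit is
what the triggering click contributes.

## Numerical solution

The response-time distribution for a trial is computed by propagating a
discretized probability distribution of DV values, starting from a point
mass at 0 Hz at stimulus onset:

- **Grid.** Uniform, default 501 points, spanning from below 0 Hz to above
  twice the baseline rate (the largest post-change rate), padded by several
  stationary SDs (`σ_process √(τ/2)`); both bounds and the origin are
  interior. Mass that would leave the grid on an unbounded side is lumped
  into the edge cell — an effective reflecting wall far from the bound,
  where accuracy is immaterial.
- **One-step transition.** Over one bin the OU law with constant drive is
  exactly Gaussian (mean `α a + (1−α) C/dt`, `α = e^{−dt/τ}`, variance
  `σ²τ(1−α²)/2`), so the propagator reassigns each cell's mass by
  integrating that Gaussian over destination cells. This conserves
  probability to machine precision and reproduces the OU mean and
  stationary variance to well under 1%. When the Gaussian step SD falls
  below 0.35 grid cells it is floored there — a resolution limit that
  keeps the deposit smooth; parameter regions this affects (σ_process
  below roughly 2 Hz·s^−1/2 on coarse grids) lie far from the operating
  range of the synthetic observer.
- **Sticky bounds with bridge crossing.** While bounds are active,
  endpoint mass beyond a bound is absorbed, and surviving within-step
  paths are additionally absorbed with the Brownian-bridge crossing
  probability `exp(−2(b−x₀)(b−x₁)/s²)`. Crossing probabilities therefore
  have continuous-time semantics: a fine-step Euler–Maruyama simulation of
  the same process (with its own bridge test) converges to the propagated
  densities (Kolmogorov–Smirnov distance < 0.01 at 0.002 s simulation
  steps). The forward simulator spreads each input bin's clicks evenly
  over its substeps so simulator and solver describe the same process.
  At bound activation (0.8 s), mass already beyond a bound is absorbed.
- **Per-bin crossing mass** forms the bound-crossing distribution;
  convolving with the discretized Gaussian NDT filter (support truncated
  at ±5 SD and at zero latency, tails lumped into the end taps) gives the
  RT distribution. For the two-process model the probability of an
  "increase" response in bin k is the upper process's crossing mass times
  the probability the lower process has not yet crossed (with the tiny
  same-bin double-crossing mass split evenly), an attribution that
  telescopes exactly so response densities plus joint survival sum to one.

## Likelihood

Response trials (hits and cue-consistent false alarms) contribute the sum
of the direction-matched RT density over a 0.2 s window centered on the
response time, measured from stimulus onset. Miss trials contribute the
probability that no response registered by trial end: the interior
(un-crossed) mass **plus crossing mass whose non-decision time lands after
the stimulus ended**. The second term is a deliberate design choice: an
observer whose bound crossing occurs near trial end but whose motor
response would arrive after the stimulus stops produces no recorded
response, and omitting that mass makes the likelihood internally
inconsistent with the generative process (miss trials on large-change
stimuli would be assigned probabilities near zero, and simulation-based
parameter recovery fails). A floor of 1e-10 keeps single-trial likelihoods
finite. Trials excluded from analysis (early, cue-opposite,
wrong-direction) are excluded from the likelihood without renormalization,
matching the analysis convention for the behavioral data; the mass
involved is small.

Response-trial propagation is truncated 0.4 s past the response (crossing
mass later than that cannot reach the likelihood window for any
non-decision time inside the prior box except a negligible Gaussian tail).

## Fitting

Condition models: informed-increase (τ, upper bound, σ_process, μ_NDT,
σ_NDT), informed-decrease (lower bound instead), uninformed (two
single-bound processes, shared σ_process and NDT, with either one shared τ
or separate τ_inc/τ_dec). A sharing map can additionally bind σ_NDT across
all three condition models (`fit_all_conditions`), implemented as a
block-coordinate pass: each condition is fit independently, a single
σ_NDT is then re-optimized against the cached crossing densities with each
condition's μ_NDT re-profiled, and the posterior stage runs at the shared
optimum.

**Point stage.** Derivative-free search over a box prior
(τ ∈ [0.02, 2] s, upper bound ∈ [60, 150] Hz, lower bound ∈ [5, 60] Hz,
σ_process ∈ [0.1, 50] Hz·s^−1/2, μ_NDT ∈ [0.1, 0.6] s,
σ_NDT ∈ [0.01, 0.2] s; log scale for τ, σ_process, σ_NDT), structured as a
profile likelihood: the parameters that shape the propagation (filter
widths, bounds, process noise) are the outer search space; for each outer
candidate the two NDT parameters are optimized in an inner Nelder–Mead
against cached crossing densities, which only requires re-weighting
precomputed crossing-mass blocks (no propagation). The outer search runs
space-filling screening starts (plus a physiologically motivated start:
bounds ≈ 2.5 shot-noise SDs from baseline), Nelder–Mead from the best
start, and coordinate sweeps that guard against stalling on ridges or on
the flat low-σ face; the best point ever evaluated is retained.

**Posterior stage.** A Laplace approximation at the optimum under the
uniform prior: a central-difference Hessian in the transformed
coordinates (optionally estimated on a trial subsample and rescaled)
defines a Gaussian posterior truncated to the prior box; 100,000 draws
give posterior means (the reported point estimates), 5th/95th credible
intervals, and a log-model-evidence estimate (the Laplace integral with a
box-truncation correction). Posteriors piling onto a prior edge are
flagged in the diagnostics. Model comparison reports the evidence
difference together with BIC and AIC; for nested pairs the smaller model
is fit first and its optimum seeds the larger one, so the larger model's
likelihood can never fall below the nested optimum.

## Model-free estimators

Hit rates condition on the change having played (false alarms and excluded
trials leave the denominator) and carry exact Clopper–Pearson binomial
intervals. The psychometric threshold is the |Δ| at 50% hits on a logistic
fit with the floor fixed at zero and a free ceiling ≤ 1 (hit rates at
small changes approach zero, while large changes may saturate below one —
the ceiling absorbs lapse-like misses); the interval convention throughout
is the 5th/95th percentile of 1000 bootstrap replicates, resampling trials
rather than per-level rates. Informed false-alarm rates divide
cue-consistent premature responses by all trials of that cue; uninformed
rates per direction discount the other direction's false alarms from the
denominator. The reverse-correlation kernel smooths click times with a
causal, unit-area half-Gaussian (σ = 0.075 s) — unit area makes the trace
read in Hz against the 60 Hz baseline — on a 0.01 s lag grid spanning
1.5 s before the response; the kernel-start knot is fit against a fixed
60 Hz baseline by default (configurable), with ties broken toward the
response. Bootstrap hypothesis tests follow the pseudo-null convention:
two-sided p-values refer a t-statistic to resamples of the pooled groups,
one-sided p-values count bootstrapped differences opposite in sign to the
observed one, both with add-one smoothing.

## The synthetic observer (generator defaults)

The generator's defaults define the study conditions for every test:
upper bounds 83.9 Hz (uninformed) and 78.3 Hz (informed) — the ordering
and values recovered from pooled human data — and filter widths
τ_inc = 0.4 s, τ_dec = 0.15 s, respecting the finding that increase
detection uses a substantially longer timescale. The remaining values are
not published and were chosen once, on the criterion that the observer's
behavior lands in the range human subjects produce on this task:
σ_process = 4 Hz·s^−1/2, lower bounds 28 Hz (informed) / 24 Hz
(uninformed), μ_NDT = 0.35 s, σ_NDT = 0.06 s. With these settings the
observer's false-alarm rates are higher under informative cues than
uninformative ones, hit rates rise from ~0.2 at |Δ| = 10 Hz toward
saturation at |Δ| = 50 Hz with informed > uninformed, mean hit reaction
times are ≈ 0.53 s informed vs ≈ 0.57 s uninformed, and reverse-
correlation kernel amplitudes are smaller informed than uninformed —
the qualitative pattern of the human data. Because click shot noise
(variance ≈ rate/2τ) dominates the DV fluctuations, the informed/
uninformed false-alarm contrast is driven by the bound difference, as in
the fitted human models.

What the generator does **not** emulate: across-subject heterogeneity,
attention lapses (early and cue-opposite responses arise only as tails of
the NDT distribution, not as a separate lapse process), learning or
fatigue across the session, and any deviation of real listeners from the
OU observer (e.g. non-exponential evidence filtering). Passing tests
therefore demonstrate internal consistency of estimator and model code
under the stated design, not the validity of the OU model for human
listeners.

## Problem sizes and numerical settings used by the test suite

Chosen as the package's default desk-scale study:

- Solver fidelity checks: 501-point grid; Monte-Carlo oracle 10⁵
  Euler–Maruyama paths at 0.002 s steps on fixed trials.
- Probability conservation: a 1000-trial batch, tolerance 1e-4.
- Parameter recovery: 10 replicates × 1000 informed-increase trials,
  fit on a 201-point grid with a 400-trial Hessian subsample; replicates
  after the first initialize their search at the preceding replicate's
  optimum (each replicate's data are independent; only the starting point
  is carried). The 201-point grid resolves the generating σ_process
  (step SD ≈ 0.55 Hz vs. the 0.35-cell floor); a 121-point grid does
  not, and visibly biases σ_process and τ.
- Model selection: uninformed-only datasets of 2000 trials on a
  121-point grid; four selection replicates per generating scenario
  (separate-width truth and shared-width truth), each required to pick
  the correct structure by both evidence and BIC on every replicate. The first replicate
  runs the full search; later replicates warm-start from the previous
  one. Within a comparison the smaller model's optimum seeds the larger
  model, and if the larger model's likelihood advantage falls in a range
  optimizer under-convergence could produce (under 30 log-units), the
  larger model's optimum is mapped back to re-polish the smaller model,
  so structure — not search luck — decides. Evidence comes from the
  forward-difference subsampled-Hessian Laplace estimate.
- Reverse correlation: kernels on a 0.01 s grid over the final 1.5 s
  before the response.

## Known limitations

- The Laplace posterior is a local Gaussian approximation; credible
  intervals for weakly identified parameters (notably σ_NDT, which the
  0.2 s likelihood window blunts) can be too narrow, and σ_NDT itself is
  recovered with a substantial negative bias at these trial counts. The
  recovery harness reports these numbers rather than hiding them.
- The evidence estimate is a Laplace lower-bound-style approximation, not
  a variational or nested-sampling estimate; it is validated behaviorally
  (correct model selection on synthetic data), not against an exact
  marginal likelihood.
- The 0.35-cell kernel floor makes the likelihood insensitive to
  σ_process below about half a grid cell per √bin; fits on coarse grids
  should not be trusted to distinguish very small process-noise values.
- Depression-enabled batch propagation quantizes effective click counts
  to multiples of 0.25 so trials can share transition stencils; the
  single-trial reference path is exact.
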