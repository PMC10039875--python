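# Methods

`synaptomap` implements an analysis pipeline for functional synaptic
connectivity mapping experiments in which many candidate presynaptic
neurons are optogenetically stimulated one at a time (brief spiral scans at
10 Hz) while one postsynaptic neuron is held in whole-cell voltage clamp.
The pipeline turns the continuous current recording into per-target
connected/not-connected calls with connection strengths, and then asks
which anatomical and physiological features of cell pairs predict
connectivity. Because raw recordings of this kind are rarely deposited,
the package ships a first-class synthetic-data generator that reproduces
the statistical structure the analysis assumes, and every stage is
validated against it.

## EPSC detection and decomposition (`epsc_detect`)

The detector operates on the inverted trace (inward currents are negative
in storage; detection sees positive-going events) resampled to 5000
samples/s, in six stages:

1. **Detrending.** A 10th-percentile filter of 50 ms width estimates the
   baseline; it is smoothed by downsampling to 200 Hz, median filtering
   over 15 ms, and linear upsampling. Subtracting it and shifting to zero
   median yields the zero-baseline trace S. Noise is summarized by the
   robust estimate SD = 1.4826 × MAD. The median smoother uses edge
   padding (not zero padding) so that the whole stage is exactly invariant
   to constant offsets.
2. **Deconvolution.** S is deconvolved against the canonical EPSC kernel
   k(t) = exp(−t/τ_decay)(1 − exp(−t/τ_rise)) with τ_decay = 3.5 ms,
   τ_rise = 0.7 ms. The kernel is discretized at the trace resolution,
   truncated below 10⁻⁴ of its peak, and scaled to unit peak so that
   deconvolved mass is directly in pA. The nonnegative, L1-penalized
   inverse problem is solved by FISTA (FFT convolutions), with an outer
   loop of at most 10 iterations steering the penalty so the residual RMS
   matches the noise allowance 0.8 × SD; when even the empty solution is
   within the allowance the deconvolution is exactly zero (nothing to
   explain), and in the near-noiseless limit the penalty tends to zero
   and the solve approaches plain least squares.
3. **Detection.** Peaks of the triangle-filtered (2.5 ms) deconvolved
   trace with height and prominence ≥ 0.5 × SD and spacing ≥ 2.0 ms give
   provisional onsets ô; provisional heights ĥ are the deconvolved mass in
   [ô − 0.4, ô + 0.8] ms. An absolute floor of 0.01 pA on the peak
   threshold guards the SD → 0 limit.
4. **Clustering.** Segments where the denoised trace (deconvolved ⊛
   kernel) exceeds 1.8 × SD, extended by −10/+20 ms and by ±10 ms around
   member events, are merged when overlapping; each event belongs to
   exactly one cluster. Events outside every segment (possible for small
   events) get a singleton segment spanning [ô − 10, ô + 30] ms.
5. **Fitting.** Each cluster is decomposed as a shared offset plus a sum
   of kernels with per-event height, onset, τ_rise and τ_decay, assuming
   linear summation at the soma. The objective is
   RMS(S − model)/SD + RMS(o − ô)/5 with heights and time constants in log
   scale; the search boxes are h ∈ [ĥ/15, 3ĥ], o ∈ ô ± 10 ms,
   0.5 < τ_decay < 50 ms, 0.1 < τ_rise < 10 ms with τ_decay > τ_rise
   (enforced by penalty). Global search uses dual annealing with
   iterations proportional to the cluster's event count, refined by
   Powell's method; the annealing seed is configurable for
   reproducibility.
6. **Thresholding.** Fitted events with height ≤ 2.5 × SD are discarded.

On the reference synthetic benchmark (60 s at 5 kHz, 2 Hz spontaneous
events of mean 15 pA, noise SD 2 pA, 4 pA slow drift) the pipeline reaches
F1 ≈ 0.96 with median onset error below 0.1 ms and median amplitude error
below 5%; the acceptance suite asserts the looser bounds F1 ≥ 0.9, onset
≤ 1 ms, amplitude ≤ 15%.

## Connectivity inference (`connect_infer`)

For each stimulated target the event record is summarized per protocol
repetition as: spontaneous segments (≤ 90 ms stretches within ±5 s of the
target's train, outside every stimulation window of any target) with their
durations and event counts; evoked segments (the 90 ms after each
stimulus; the last 10 ms of a 100 ms inter-pulse interval is a guard) with
counts; and the exact latencies of events in evoked segments.

Three pairs of Bayesian models are compared. The null of each pair
explains all counts with a single spontaneous rate per repetition
(Gamma-prior Poisson) and treats latencies as uniform on [0, 90) ms; the
connected alternative adds an evoked-events-per-trial parameter e_p
(Gamma prior, mean = sd = 0.5) to the evoked-count rate and a latency
"bump" so that latencies follow the mixture w·bump + (1 − w)·uniform with
w = e_p/(e_p + rate·90). The rate-and-time pair uses both likelihood
blocks; the time-only pair uses only the latency mixture, with a
Beta(2, 2) prior directly on the bump weight (its null has no free
parameters); the rate-only pair uses only the counts. In models 1–6 the
bump is a fixed gamma density with mean 12.96 ms and sd 6.33 ms — the
moments of the population PSTH gamma fit (shape 4.1896, scale 3.0942 ms).
The spontaneous-rate prior defaults to mean = sd = the recording's
empirical spontaneous rate (floored at 10⁻⁴ events/ms), all exposed in
`ModelPriors`.

Posteriors are sampled by an adaptive Hamiltonian Monte Carlo sampler
(see below). Each comparison is scored by pointwise expected log
predictive density under Pareto-smoothed importance-sampling leave-one-out
(smoothing via arviz), and converted to model weights by
Bayesian-bootstrap pseudo-BMA (Dirichlet-weighted ELPD replicates,
averaged softmax). A target is called connected when
(w_rt ≥ 0.5) ∧ (w_t ≥ 0.4) ∧ (w_r ≥ 0.4); an override hook accepts
external (manually curated) labels. For connected targets a variable-bump
model replaces the fixed gamma bump with a normal whose center has a gamma
prior (mean 13 ms, sd 5 ms) and whose width has a gamma prior (mean
5.5 ms, sd 1.5 ms) bounded to [3, 8] ms via a logistic transform; a config
switch makes the width prior reuse the center hyperparameters instead,
since the source formulation is ambiguous on this point. Connection
strength per stimulation is the average of EPSC amplitudes with latencies
in [2, 30) ms, weighted by the posterior-median normal bump density;
stimuli without in-window events contribute zero, consistent with
weighted-input summaries that count absent responses as zero.

The population latency distribution is fit by maximum likelihood as
w·Gamma(k, θ) + (1 − w)·Uniform(0, 90) (Nelder-Mead then BFGS on
log/logit-transformed parameters), with confidence intervals from the
finite-difference observed information. The population connected fraction
is ĉ = E·f/(N·n·e_p).

## MCMC sampler (`_mcmc`)

All Bayesian models are sampled by a compact Hamiltonian Monte Carlo
implementation: leapfrog integration on unconstrained parameters
(log/logit transforms with Jacobians in the densities), dual-averaging
step-size adaptation to a target acceptance rate (0.9 by default, 0.95 for
the reference profiles), a diagonal mass matrix estimated from the middle
half of warmup, and path lengths jittered uniformly over the upper half of
a maximum leapfrog count to avoid resonances. Chains are vectorized in
numpy. Gradients are analytic for the Horseshoe model and central-finite-
difference (batched) for the low-dimensional connectivity models, where a
gradient costs two density evaluations per dimension. Transitions with an
energy error beyond 1000 are counted as divergences; results are flagged
when divergences exceed 1% of draws or split-R̂ exceeds 1.05. The
`paper` profile mirrors the reference settings (5000 warmup / 2000 draws /
4 chains for connectivity; 10000 warmup for the Horseshoe); the `fast`
profile (1000/500/2, and 1200/800/2 with 48 leapfrog steps for the
Horseshoe) is used in tests so the suite completes on one CPU.

## Photocurrent handling (`artifact_clean`)

Direct photocurrents in stimulus-aligned snippets ([−20, +90] ms) are
identified by an operationalization of manual criteria: a deflection in
≥ 90% of trials, onset latency < 2 ms, onset jitter < 0.5 ms, and mean
pairwise trial-waveform correlation ≥ 0.9 (each threshold configurable; an
override file can supply manual labels). Targets whose photocurrent
exceeds 20 pA are excluded outright. Smaller photocurrents are removed by
subtracting the mean of trials that contain no detected EPSC within 30 ms
of the stimulus (EPSC-free trials come from the event table, nothing is
re-detected); a glutamate-blocker trace set, when available, supplies the
template instead. Compound responses are quantified as baseline mean
([−20, +2] ms) minus window minimum ([+2, +25] ms), positive for inward
responses and exactly offset-invariant.

## Intrinsic properties and spike validation (`ephys_features`)

From a square-pulse protocol (≈ −200 to +400 pA): input resistance is the
peak deflection at the smallest negative current over that current;
τ_m comes from fitting a(1 − e^(−t/τ)) + c over the 10–90% rise of that
deflection; C_m = τ_m/R_in; the sag ratio is (V_min − V_ss)/(V_min − V_bl)
on the strongest hyperpolarizing sweep with V_min taken from the first 30%
of the pulse. Output gain is the regression slope of firing rate on
current over the spiking range (two-point slope available as an option);
bursting (ISI2/ISI1) and adaptation (ISIlast/ISI2) indices use the sweep
closest to 80% of the maximal rate, ties broken toward the lower current;
spike waveform features use the first spike of the lowest-rate spiking
sweep, with threshold defined as the voltage where dV/dt first exceeds
20 mV/ms before the peak (configurable; the source is silent on the
criterion), amplitude as peak − threshold, and half-width at
threshold + amplitude/2.

Whether a stimulated target actually spiked is validated from its raw
per-stimulus fluorescence: the OLS slope across the train must have a
nonnegative lower 95% confidence bound, otherwise the target is excluded;
ΔF/F₀ uses the first stimulus as baseline. Note that at exactly zero
true slope this rule excludes ~97.5% of targets (the lower bound of a 95%
interval is below zero except in the upper one-sided tail), which is the
intended conservative behavior.

## Determinants of connectivity (`determinants`)

Cell-pair features are preprocessed by log-transforming strictly positive,
skewed features (adaptation and bursting indices, capacitance, gain, input
resistance, spike half-width) and logit-transforming the sag ratio; rows
outside the transform domains are rejected with reasons. Multicollinearity
is removed by robust ZCA whitening: the correlation matrix is estimated by
the minimum covariance determinant method (support fraction 0.75 by
default), eigendecomposed, and the symmetric map W = U Λ^(−1/2) Uᵀ applied
to robustly standardized features, so whitened coefficients are
comparable across features.

Feature selection uses the Horseshoe prior stack β_j = z_j·λ_j·τ with
z ~ N(0, 1), λ = r_local·√ρ_local, τ = r_global·√ρ_global,
r ~ N(0, 1), ρ_local ~ InvGamma(1.5, 1.5) (ν = 3 half-t local scales),
ρ_global ~ InvGamma(0.5, 0.5) (half-Cauchy global scale), and intercept
β₀ ~ N(−3.67, 1) (≈ logit of the 0.025 prevalence); the inverse-gamma
parameters are shape/rate by default with a shape/scale switch. Features
with |posterior median β| > 0.05 are selected (a 0.05 change in log odds
≈ 5% change in odds per SD of a whitened feature).

Predictive information is quantified by the mean Bernoulli cross-entropy
(natural log, predictions clipped to [10⁻¹², 1 − 10⁻¹²]) of an
unregularized logistic regression under stratified cross-validation with
exactly one connected pair per fold and negatives split evenly; the same
folds are reused across feature subsets so comparisons are paired.
Controls: the non-cross-validated entropy, fits on shuffled labels
(count configurable, 10,000 by default), and the closed-form entropy of a
constant prediction at the prevalence.

A caveat established while validating this module: at n = 5000 pairs and
prevalence 0.025 the per-coefficient standard error is ≈ 0.09, so a
chance association of ≈ 2.5 standard errors (|β̂| ≈ 0.22) sits at the
Horseshoe's effective shrinkage threshold and can retain a posterior
median above the 0.05 selection cutoff. Exact recovery of a planted
sparse support therefore fails in a minority of random datasets for
purely statistical reasons; the acceptance suite measures this directly.

## Map geometry and summaries (`map_analysis`)

Slice-referenced coordinates come from three mutually orthogonal planes:
the least-squares surface plane of a point cloud (signed distance = depth
in slice, reported as AP), a midline plane through the dorsal and ventral
midline ends orthogonalized to the surface (ML), and a dorsal-end plane
orthogonal to both (DV). The construction is an isometry composition, so
inter-cell distances are preserved. Map summaries: connection probability
restricted to a 300 µm radius (distance bias control); mean strength over
connected cells without a radius cap; weighted input as the mean strength
over responsive cells with non-connected cells counted as zero
(responsive-only by design — non-responsive cells are excluded from
analysis upstream); and weighted input split by the sign of the
presynaptic ML/DV offset. The co-stimulation bias counts, per cell,
neighbors inside an axis-aligned ellipsoid whose full axes default to the
measured spiking-probability FWHM (axial 55.9 µm, radial 24.2 µm;
semi-axis = FWHM available as the alternative reading); with f_co the
fraction of cells with ≥ 1 in-ellipsoid neighbor, measured probabilities
overestimate truth by 1 − 1/(1 + f_co). The slicing-depth effect pools
connectivity in two equal-thickness shells (surface→recorded-cell depth
vs depth→2×depth). Light-power compensation is exp(depth/τ) with
τ = 147.6 µm; the tissue light-propagation model behind τ is not
re-implemented — τ is an input parameter.

## Synthetic data (`synthgen`)

The generator emulates the recording conditions the analysis assumes:
sequential trains of 10 pulses (7.2 ms) at 10 Hz, up to three protocol
repetitions, a ~420 × 420 × 300 µm³ scanned volume; spontaneous EPSCs as a
homogeneous Poisson process (2 Hz default); evoked events per stimulus as
Poisson(e_p) with e_p = 0.5 for connected targets; evoked latencies from
the gamma bump (mean 12.96 ms, sd 6.33 ms) or a normal bump; amplitudes
lognormal with mean 15 pA (the experiment does not constrain the
spontaneous amplitude distribution; lognormal is the conventional choice
and is configuration, not a fidelity claim); white noise of SD 2 pA plus a
1/f-like slow drift (superposed sinusoids, SD 4 pA default) standing in
for holding-current drift; optional reproducible low-latency
photocurrents. Traces render events linearly with the unit-peak kernel,
so the ground-truth table re-renders the noiseless trace exactly. Epoch-
level data can also be drawn directly under the connectivity models
(bypassing trace rendering) for sampler-level validation. Pair-feature
tables draw correlated Gaussian features (AR(1) by default, any
positive-definite correlation accepted) with Bernoulli labels from a known
logistic model. Current-step protocols plant exact passive parameters
(RC responses; the sag trace charges to V_min and relaxes with a 150 ms
time constant) and exact spiking structure (integer spike counts on a
known f-I line; ISI patterns realizing requested bursting/adaptation
indices). One master seed feeds every stream.

What the generator does not emulate: optics and photostimulation physics
(spiral paths, opsin kinetics beyond a fixed waveform, indicator
photophysics beyond a per-stimulus scalar), non-stationary spontaneous
rates, correlated network events, electrode/access-resistance artifacts,
or truncated dendritic morphology. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical assumptions,
not robustness to every feature of real recordings.

## Problem sizes and numerical choices

Test problem sizes are chosen so the full suite runs on one CPU in tens
of minutes: the detection benchmark uses one 60 s trace; connectivity
recovery uses 40 targets × 20 stimuli with the fast MCMC profile;
Horseshoe recovery uses 10 + 10 datasets of 5000 pairs; the PSTH refit
uses 150,000 latencies. Probabilities are clipped at 10⁻¹² before logs;
mixture densities at 10⁻³⁰⁰; rate parameters are floored at 10⁻⁴
events/ms; gamma priors parameterized by (mean, sd) use shape = (μ/σ)²,
scale = σ²/μ, with a (shape, scale) constructor alongside. Ties in the
80%-rate sweep selection go to the lower current; the kernel's closed-form
peak time τ_r·ln(1 + τ_d/τ_r) is used for normalization rather than a
numeric maximization.
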