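# Methods

## The generative model

Induced (non-phase-locked) spectral power in a motor network of five
regions — bilateral primary motor cortex (iM1, cM1; the ipsilesional
hemisphere is left by convention), bilateral premotor cortex (iPM, cPM), and
the supplementary motor area (SMA) — is modelled as a linear dynamical
system over spectral power states:

    τ · ġ(t) = A g(t) + C u(t)

`g` stacks, per region, the deviation of spectral power from its pre-movement
baseline; `A` (units 1/s) holds the coupling parameters within and between
regions; `C` weights the driving input `u(t)`; τ is a scale factor.  A
positive entry of `A` means power changes at the source frequency push power
at the target frequency in the same direction; a negative entry, the
opposite direction.  *Linear* coupling stays within a frequency (diagonal of
a region-pair block), *nonlinear* (cross-frequency) coupling occupies the
off-diagonal entries; in the reduced mode representation used for fitting
(below) the same distinction is expressed within/across SVD modes, the
standard convention for induced-response DCM.

The input is the premotor drive during self-initiated movement: a gamma
density starting at the beginning of the preparation window (−1000 ms
relative to EMG onset), peaking at −400 ms, with dispersion 400 ms.  We read
"dispersion" as the standard deviation of the waveform (a config flag
switches to a FWHM reading); with the default reading the shape solves to
k = 4, θ = 200 ms.  τ is fixed at 1 throughout: it is not identifiable
jointly with the scale of `A` and `C`, so coupling magnitudes absorb it.
The input enters only at SMA, at all frequencies, through `C`.

## Model space

Twelve candidate models over the five regions, in two groups of six.
Group 1 (models 1–6) restricts intrinsic (within-region) coupling to linear
terms; group 2 (models 7–12) allows nonlinear intrinsic coupling.  Within
each group, one model is fully connected (models 6 and 12) and five reduced
variants drop one or two efferents of a premotor area (to the other PM or to
an M1).  The exact membership of the reduced variants is configurable; the
default set drops {iPM→cPM}, {cPM→iPM}, {iPM→iM1, iPM→cPM},
{cPM→cM1, cPM→iPM}, and {iPM→cM1, cPM→iM1}.  Region coordinates follow the
Human Motor Area Template (e.g. left M1 at MNI −37 −26 60).

A note on the linear-coupling constraint: with K = 4 modes over 45
frequencies, demanding that a mode-space block project to an *exactly
diagonal* frequency-frequency matrix admits only the zero block (the
constraint map has full rank K²), which would delete linear connections
outright.  We therefore express linearity as within-mode coupling (diagonal
K×K block), which reduces to exact frequency-diagonality when the basis is
the identity (full rank) and is the convention induced-response DCM uses.

## Preprocessing

Epoched source-level trials (−2200..+500 ms around EMG onset, 256 Hz) are
transformed with a 7-cycle Morlet wavelet on a 4–48 Hz grid (1 Hz steps by
default; the range is fixed, the resolution configurable).  Power is
calibrated so a sinusoid of amplitude a yields a²/2 at its own frequency at
any frequency (undoing the 1/f scale of L2-normalized wavelets); epochs are
zero-padded when the lowest-frequency wavelet (713 samples at 4 Hz) exceeds
the epoch, and samples within half a wavelet of an epoch edge are flagged.
The per-trial spectrograms are averaged, cropped to the preparation window
(−1000..0 ms), and baseline-corrected by subtracting the mean power over
−1000..−833 ms per frequency.  Trials are epoched much wider than the
analysis window precisely so that wavelet edge effects fall outside it.

The frequency axis is then reduced by SVD to K = 4 modes.  One basis is
computed from the frequency × (source·time·condition) concatenation of all
spectrograms — a single shared basis keeps coupling comparable across
regions and subjects; per-source bases were rejected for that reason.  The
sign of each loading column is fixed by making its largest-magnitude element
positive, so results do not depend on the linear-algebra backend.  Mode
trajectories are differentiated by central differences after a light
moving-average smoothing (3 samples at 256 Hz); endpoints use one-sided
differences.

## Inversion: gradient matching with closed-form evidence

Given `g` and `u`, the state equation is linear in (A, C), so each state row
is a Bayesian linear regression of ġᵢ on the permitted states and the input:
Gaussian priors N(0, 1) on free coupling parameters, N(−1, 1) on the
intrinsic within-mode decay terms (power deviations are expected to
dissipate), and closed-form posterior and log marginal likelihood per row.
The design uses the same smoothed trajectories the derivative was estimated
from (smoothing is linear and commutes with the dynamics; a noisy raw design
would introduce errors-in-variables attenuation).  The observation noise
variance is estimated per state from OLS residuals under the fully connected
design, then held fixed across all 12 models so log evidences are
comparable.  This estimator is exact, fast, and testable against brute-force
quadrature (the package's tests verify the evidence of a two-parameter toy
to < 1e−4 nats); the reference variational trajectory-matching scheme was
deliberately not reimplemented, since the scientific contract — coupling
signs/strengths and evidence for model selection — is preserved by the
linear-in-parameters formulation.

The fraction of variance explained is computed by re-integrating the fitted
system (RK4 at the data step, piecewise-linear input) from g(−1000 ms) = 0
and comparing with the observed trajectories (1 − SSE/SST).  Because
gradient matching does not constrain the posterior mean to be stable, a fit
can lie marginally on the unstable side and make the one-second open-loop
rollout diverge; in that case the rollout uses the minimally damped system
(spectrum shifted so max Re(eig) = −0.05/s) and the fit is flagged
(`rollout_stabilized`).  Evidence and coupling estimates are never modified.

### Identifiability

With a single driving input, the state trajectories are strongly collinear,
so individual coupling parameters have null-space freedom: only predictions
(and well-identified directions such as the intrinsic decay) are pinned
down.  Consequences, verified by the test suite: exact parameter recovery
holds when the design is full-rank (independent trajectories), while
ODE-generated data from one input recover predictions (variance explained
≥ 0.99 noise-free) but not every individual entry; and intervention effects
injected into the ground truth can surface on correlated entries of the
fitted coupling-change maps rather than exactly at the injected frequency
pair.  The statistical layer (smoothing, permutation FWE) is therefore
validated on maps with known focal changes, separately from the estimator.

## Random-effects model selection

Subject-wise log evidences (summed over sessions) enter the standard
variational random-effects scheme: model identity is a random effect with
Dirichlet(α₀ = 1) prior over model frequencies; responsibilities
u_nm ∝ exp(lnE_nm + ψ(α_m) − ψ(Σα)) and counts alternate until the change in
α falls below 1e−6.  Exceedance probabilities — the posterior probability
that a model is the most frequent in the population — are computed
analytically via the Beta distribution for two models and by seeded
Monte-Carlo Dirichlet sampling otherwise (sample count and seed are part of
the result).  Note the expected model probability is bounded by
(N+1)/(N+M), ≈ 0.82 at N = 8, M = 3 — exceedance probabilities, not expected
probabilities, are the selection criterion.

## Coupling maps and pre/post inference

Fitted mode-space blocks are projected to frequency as V·A_block·Vᵀ; entry
(f_out, f_in) is the influence of source-region power at f_in on
target-region power at f_out.  Per-subject maps are smoothed with a 2-D
Gaussian kernel of 8 Hz FWHM (σ = FWHM/2.3548, truncated at 3σ, renormalized
at the map edges so a constant map is preserved) *before* group testing.

Pre/post differences are tested per connection with a paired t at every
frequency pair; family-wise error over the map is controlled by the
max-statistic sign-flip permutation distribution — exhaustive over all 2ⁿ
subject sign patterns when 2ⁿ ≤ 4096 (256 patterns at n = 8, minimal
attainable two-sided p = 2/256 ≈ 0.0078), seeded Monte Carlo otherwise.
This replaces the random-field-theory FWE of the reference software with an
exact, assumption-free procedure for small n — a deliberate methodological
substitution.  FWE is controlled per connection map ("separately for each
connection"), with no pooling across connections.  Brain–behaviour links use
Spearman rank correlation with an exact permutation p-value for n ≤ 8
(n! ≤ 40320 orders) and the t approximation above that.

## Cortical activity ratio

CAR of an ROI is the summed node current-density strength in that ROI
divided by the summed strength over the whole sensorimotor cortex
(ipsilesional/contralesional M1/S1 and SMA/PM), evaluated in the
−150..−100 ms pre-movement window.  The ROIs partition the nodes, so the
four CARs sum to 1; CAR is invariant to global rescaling of the map.  The
pre/post contrast is a paired t-test with an exact sign-flip permutation
alternative for n ≤ 12; a zero-variance difference vector is flagged rather
than producing an infinite t.  The repeated-measures omnibus ANOVA is out of
scope — the paired post-hoc contrasts are the implemented surface.  The
inverse solution (sLORETA, head models) is likewise out of scope: the module
consumes node-level strengths with ROI labels (3-mm node spacing is carried
as generator metadata only).

## The synthetic cohort

No public data accompany the study design this package emulates, so every
stage is exercised on synthetic cohorts with known truth:

* **Ground truth.**  Per subject, a stable frequency-domain coupling matrix
  respecting a chosen model's mask: intrinsic same-frequency decay
  U(1, 2.5)/s; one smooth Gaussian bump (σ = 3 Hz) per present extrinsic
  connection with peak amplitude ±U(0.25, 0.5)/s and source frequency in an
  energetic band (beta 18–26 Hz or gamma 34–44 Hz, where the input injects
  power); for nonlinear-intrinsic models one gamma→beta bump per region with
  amplitude ±U(0.3, 0.6)/s (source 34–46 Hz, target 14–30 Hz).  Draws are
  rejected until all eigenvalues have negative real part (and until the
  post-session variant is also stable when an intervention effect is
  configured).  These amplitudes were chosen so that every true connection
  carries identifiable signal, the regime a decisively winning fully
  connected model implies.
* **Dynamics and trials.**  The noise-free deviation g(t) is integrated from
  the state equation.  Oscillatory trials are sums of narrowband cosines
  (one per frequency of the generation grid) with amplitude
  √(2·(baseline + g)), independent uniform phases per trial, plus white
  noise at the configured power SNR (default 10 dB); ~48 trials per
  condition, 8 subjects, 2 sessions.  The baseline is 1/f-shaped, scaled per
  region to its own dynamic range and floored so total power stays positive
  (an error names region/frequency/time otherwise).  Intervention effects
  add Gaussian bumps to the post-session truth.
* **Spectral-level shortcut.**  For studies that do not probe the wavelet
  stage itself, noise is added directly to g with the temporal
  autocorrelation a 7-cycle wavelet estimate would have
  (σ_t = 7/(2πf) per frequency) — white-in-time spectral noise would be
  unphysical for trial-averaged wavelet power and cripples derivative
  estimation for reasons unrelated to the method under test.
* **Current-density maps.**  Nodes per ROI with equal base strength scaled
  to target per-ROI shares; i.i.d. unit-mean lognormal noise per node and
  subject (coefficient of variation = configured sd).  Expected CARs equal
  the targets by construction.
* **Seeding.**  One master seed; per-subject, per-session, and per-trial
  streams are spawned from it (numpy seed sequences), so any subset of a
  cohort reproduces bit-identically.

What the generator does *not* emulate: volume conduction and source
leakage, artifacts and their rejection, non-Gaussian and non-stationary
background EEG, phase coupling (the model concerns power only), and
between-session electrode/registration variability.  Passing tests
therefore demonstrate correctness of the computational chain under the
model's own assumptions, not performance on real recordings.

## Study-level checks and problem sizes

The packaged studies (also recomputed by `scripts/acceptance.py`) use sizes
chosen to finish in minutes on one CPU: model recovery — 20 cohorts of 8
subjects at 10 dB (spectral level), all 12 models fitted, RFX-BMS with
50 000 exceedance samples; focal coupling-change detection — 20 replicates,
−0.5 1/s at one pair, within-subject sd 0.1 on spectrally smooth (8 Hz
FWHM) variability, 45×45 maps, n = 8; FWE validity — 500 null replicates of
the same layout; integrator accuracy — 50 random stable 20-state systems
against an augmented-matrix-exponential solution; SVD retention — rank-4
band spectra with 1% noise.  Numerical tolerances: integrator vs oracle
< 1e−8 max abs; evidence vs quadrature < 1e−4 nats; basis orthonormality
1e−10; CAR partition 1e−10.

## Known limitations

* Coupling parameters are only partially identified under a single input;
  localization of effects in frequency-pair space is approximate (see
  Identifiability above).
* The trajectory-refit option (nonlinear least squares initialized at the
  gradient-matching solution) is not implemented; the gradient-matching
  estimator is the single estimation path.
* The linear power-coupling model ignores phase and assumes stationarity of
  coupling within the preparation window.
* Exceedance probabilities for more than two models are Monte-Carlo
  estimates; their error (~1/√n_samples) is quantified by the stored sample
  count and seed.
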