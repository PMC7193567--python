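# dcmir — cross-frequency effective connectivity of the motor network

`dcmir` implements, end to end and on fully synthetic data with known ground
truth, a dynamic-causal-modelling analysis of induced EEG responses during
motor preparation: how time-varying spectral power in one motor region
drives power — at the same or a different frequency — in another, and how an
intervention changes that coupling.  It is aimed at researchers who want a
tested, scriptable reference for this analysis style (or a harness to
validate their own variant) without access to patient EEG.

## The model

Induced power over a 5-region motor network (bilateral M1 and PM, plus SMA;
left = ipsilesional by convention) follows a linear dynamical system

    τ ġ(t) = A g(t) + C u(t)

where `g` stacks baseline-referenced spectral power states per region, `A`
(1/s) holds within- and between-region coupling — within-frequency entries
are *linear* coupling, cross-frequency entries *nonlinear* — and `u(t)` is a
gamma-shaped premotor drive entering at SMA (peak −400 ms before EMG onset,
dispersion 400 ms).  Twelve candidate connectivity models (two groups of
six: linear vs nonlinear intrinsic coupling; fully connected vs missing
premotor efferents) are inverted per subject by Bayesian gradient matching
with closed-form log evidence, compared with random-effects Bayesian model
selection (Dirichlet posterior, exceedance probabilities), and the winning
model's coupling maps are tested pre vs post intervention with an exact
sign-flip max-statistic permutation test (FWE over each 45×45
frequency-pair map).  A separate module computes the cortical activity
ratio (CAR) — ROI current-density strength over total sensorimotor
strength — and its paired pre/post contrasts.  See `docs/methods.md` for
the full account.

## Worked example

The numbered scripts under `analysis/` run the whole study on the demo
cohort (8 virtual subjects × 2 sessions × 48 oscillatory trials, 10 dB SNR,
with two coupling changes injected into the post-session ground truth):

```
python analysis/01_simulate_cohort.py
python analysis/02_time_frequency.py
python analysis/03_fit_models.py
python analysis/04_model_selection.py
python analysis/05_coupling_changes.py
python analysis/06_cortical_activity.py
```

Output of the selection and CAR steps:

```
winning model: 12 (exceedance probability 0.981)

  iM1S1    mean ΔCAR=+0.050 t=+56.28 sign-flip p=0.008*
  cM1S1    mean ΔCAR=-0.050 t=-47.07 sign-flip p=0.008*
  iSMA-PM  mean ΔCAR=-0.001 t=-1.64 sign-flip p=0.148
  cSMA-PM  mean ΔCAR=+0.001 t=+0.80 sign-flip p=0.430
```

Reading: random-effects model selection identifies the data-generating
model — the fully connected network with nonlinear (cross-frequency)
intrinsic coupling — with exceedance probability 0.981 (0.981 is the
ceiling the Dirichlet prior allows at n = 8 and 50 000 posterior samples);
the earlier steps report that 4 SVD modes preserve 98.5% of the spectral
variance and that the winning model explains 56% of the mode-series
variance on this noisy cohort.  The CAR analysis recovers the simulated
post-intervention shift of activation from contralesional to ipsilesional
M1/S1 (±0.05, exact sign-flip p = 2/256) and correctly finds nothing in the
secondary motor ROIs.  Step 05 prints the FWE-surviving coupling changes
together with the injected truth; as `docs/methods.md` discusses, a
single-input network leaves coupling parameters only partially identified,
so effects can surface on correlated entries rather than exactly at the
injected frequency pair.

The same pipeline is scriptable through a CLI (`dcmir run --config
analysis/demo_config.yaml`, or per stage: `dcmir simulate|tfr|fit|bms|
stats|car|validate`).

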