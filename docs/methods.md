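# Methods

This note documents the models, parameter choices and numerical
decisions behind `myotrack`, and what the synthetic-data tests do and do
not demonstrate about real recordings.

## Generative model (`myotrack.simulate`)

A single myosin head in the engineered thick filament is modelled as an
alternating-renewal process observed at fixed frame intervals
(default Δt = 40 µs, i.e. 25,000 fps):

- **Detached state.** Tethered diffusion about the linker anchor,
  emitted as i.i.d. Gaussian positions with SD `detached_sd`
  (default 12.5 nm). Motion blur within the 40 µs exposure is not
  modelled: the emission model the inference assumes is frame-wise
  Gaussian, and the generator matches it.
- **Weak-binding sites.** Each site has a position (nm, relative to the
  detached mean), an access weight, and a mean dwell (µs). From the
  detached state the head encounters actin with per-frame probability
  `1 − exp(−encounter_rate·Δt)` and lands on site k with probability
  proportional to its access weight. Dwells are drawn in continuous
  time from the site's exponential distribution and discretised by
  rounding to whole frames with a minimum of one frame (the
  observability floor). Bound emissions are Gaussian with shared SD
  `bound_sd` (default 4.7 nm).
- **Strong binding.** Optionally one site is ATP-gated: its dwell is
  exponential with mean `1/(rate_slope·[ATP] + rate_intercept)` seconds
  (defaults 0.0038 s⁻¹ nM⁻¹ and 0.17 s⁻¹), i.e. the ATP waiting time.
- **Encounter rate.** The imaging data constrain emission SDs, dwell
  times and access weights but not the detached→binding entry kinetics,
  so `encounter_rate` is a free parameter. The default 1000 s⁻¹ yields
  ~10 % weak-binding occupancy on a 400 ms record, the scale at which
  transient states are comfortably populated without dominating the
  record; strong-binding simulations use ~10 s⁻¹ so that detached and
  bound phases alternate a few times per 400 ms window.
- Lever-arm sub-steps default off (the 40 µs tracking does not resolve
  the second step); a 2D mode adds an independent lateral Gaussian only
  to exercise axis projection.

Back-to-back events at the same site (a new encounter on the first
frame after release) merge into a single run in the frame-quantised
labels; at the default rates this affects ~1–2 % of events.

The spot renderer draws Poisson counts from an isotropic Gaussian PSF
sampled at pixel centres plus uniform background (123 nm px⁻¹ default);
camera-specific noise beyond Poisson is out of scope. The
fluorescent-ATP generator produces baseline-plus-spike traces with
exponential dark gaps (mean `1/event_rate`) and exponential on-times,
sampled at 1000 fps.

## Localisation and projection (`myotrack.localize`)

Radial-symmetry localisation estimates each frame's centre as the point
minimising the weighted squared distances to lines through
midpoint-grid points along the local intensity-gradient direction
(gradients from the 2×2-cell diagonals, 3×3 boxcar smoothing, weights
gradient-magnitude² over distance to a rough centroid). Pixel centres
sit at integer coordinates and positions are reported as px ×
pixel size, which makes oracle comparisons bit-exact. Frames whose
peak-to-background contrast falls below a threshold (default 2 robust
SDs) are flagged with NaN positions. Gaussian refinement fits an
isotropic 2D Gaussian plus constant background in a 9×9 window per
frame; non-convergent frames keep the initial value and are flagged.
On high-SNR synthetic spots the two localisers agree within 0.1 px and
reach ≤ 0.7 nm SD at 10⁶ photons/frame.

Screening keeps tracks whose major-axis peak-to-peak span lies within
[0.5, 1.5] × the expected span and whose major/minor SD ratio is
≥ 1.5. These two rules are an explicit approximation of "exclude
geometrically implausible particles"; both thresholds are exposed.
Projection takes the leading eigenvector of the 2D position covariance;
the sign convention (heavier-tailed side positive, measured by the
skewness of the projections) is recorded in the output metadata because
"forward" is defined biologically and synthetic data must emulate it by
construction.

## Two-state step fit (`myotrack.stepfit`)

`TwoStateHMM` estimates the detached→strong-binding displacement with a
two-state Gaussian HMM in which only the two means and the transition
matrix are free; the emission SDs are fixed (12.5 / 4.7 nm defaults).
Fixing distinct SDs identifies the states, so no occupancy-based
relabelling is needed: the detached state is the broad-SD state by
construction. EM (via hmmlearn, covariances excluded from the update)
runs from a deterministic initialisation — detached mean at the
histogram mode, bound mean at the mean of the 5 % most displaced points
toward the heavier tail — and, because that guess misassigns states
when a record is mostly bound, the swapped initialisation is also fitted
and the higher-likelihood solution kept (still fully deterministic).
Convergence tolerance 10⁻⁶ log-likelihood units, 500 iterations
maximum. A fit whose Viterbi path puts less than 0.5 % of frames in
either state is flagged unreliable. `compare_step_groups` reports group
means/SEMs, the difference with propagated SEM, the two-tailed unpaired
t-test, and Hedges' g with the small-sample correction
J = 1 − 3/(4·df − 1).

## Constrained infinite HMM (`myotrack.ihmm`)

The weak-binding detector is an HDP-HMM with one reserved detached
state (emission SD fixed at 12.5 nm, free mean) and an unbounded pool
of binding states sharing the fixed 4.7 nm emission SD with distinct
free means. All binding→binding transition probabilities are zero:
a binding row renormalises onto {self, detached}, which by the Dirichlet
aggregation property is sampled exactly as a two-entry Dirichlet.
A consequence worth noting: new states can only ever be *entered* from
the detached state, which is also the physically correct picture
(release before rebinding).

Per MCMC sweep: transition rows from their Dirichlet conditionals;
slice variables `u_t ~ U(0, π_{s_{t-1} s_t})`; stick-breaking expansion
of represented states until the detached row's unrepresented mass is
below the smallest slice; forward-filter backward-sampling of the path
under the beam indicators (numba kernel); conjugate Gaussian updates of
the state means (prior N(window mean, 50 nm) — weakly informative over
the ~80 nm physical span); auxiliary table counts (Chinese-restaurant
draws) for the shared base measure; and resampling of both HDP
concentrations under Gamma(1, 1) hyperpriors by the standard
auxiliary-variable schemes. The frame before the window is treated as
detached for the initial distribution.

Chains are initialised with a pool of candidate binding states at data
quantiles (slightly jittered per chain) and a per-frame MAP path. A
cold all-detached start cannot mix — the slice sampler gives newborn
states a negligible entry probability — while from an over-complete
start the sampler prunes rapidly. Initialisation does not affect the
stationary distribution. A chain reports its final sample (iteration
1000 by default); the posterior spread comes from many independently
seeded chains (`fit_repeated`, seeds base, base+1, …, so pooled output
is identical regardless of execution order). Windows longer than
10,000 frames are split by the caller; positions are comparable across
windows because every binding position is referenced to its window's
inferred detached mean.

### State filters

Retained binding states must occupy ≥ 1 % of the window and have a
dwell *time constant* of at least 40 µs (one frame). The time constant
is computed from the state's self-transition fraction,
`τ = −Δt/ln(π̂_kk)`, not from the raw mean of its run lengths: a run can
never be shorter than one frame, so a raw-mean threshold at the frame
time would be vacuous, whereas the self-transition form is ≈ 0 for
states whose "visits" are almost all isolated single frames. That
matters because a narrow-emission state placed anywhere under the broad
detached distribution is almost likelihood-neutral (the expected
likelihood ratio integrates to one) and such noise-absorbing states do
appear in the posterior; they carry essentially no self-persistence and
the filter removes them. On pure detached synthetic data, 0/10 chains
retain any binding state after filtering.

### Dwell-time estimation

A state's dwell events are its maximal runs in the sampled path ×
frame interval. Pooled dwell events are fitted by least squares of the
empirical CDF against `F(t) = 1 − A·exp(−(t − t₀)/τ)` with t₀ the 40 µs
observability floor and the amplitude A free. For genuinely
left-truncated continuous exponentials A fits ≈ 1 and the model reduces
to the textbook truncated form; for frame-quantised dwells the point
mass at one frame would otherwise bias τ ~35 % low, and the free
amplitude lets the fit track the geometric tail decay, which carries
the generating time constant exactly. Ties are collapsed to unique
values weighted by multiplicity, making the fit order-invariant and
giving the expected √2 SE reduction under list duplication. The
closed-form cross-check `mean(dwells) − t₀` is reported alongside. The
reported SE comes from the weighted-LS covariance; because ECDF
residuals are correlated it should be read as an optimistic
lower bound — the chain-to-chain spread is the robust uncertainty.

## Peak summaries (`myotrack.summarize`)

Pooled relative positions over chains are fitted with a K-component 1D
Gaussian mixture (EM via scikit-learn, k-means++ seeded initialisation,
10 restarts, best likelihood kept; K is user-set, default 5, no
automatic model selection). Each retained state is assigned to the peak
whose mean ± 1 SD window contains its position (nearest mean wins on
overlap). A peak's access ratio is, per chain, the fraction of the
chain's *assigned* binding events in that peak — normalising over
assigned events makes the ratios a partition (sum to one over peaks),
matching how accessibilities are reported; event-fraction rather than
frame-fraction is the default so that access and dwell stay independent
quantities (`point_fraction=True` switches). Reported access is the
mean ± SD across chains. Peaks whose access ratio falls below a floor
(default 0.02) are excluded from dwell reporting: too few events to
support a dwell fit. The display histogram bin width (1 nm) never
enters the fit, which uses raw samples.

`dwell_ratio` divides the strong-binding mean dwell predicted by the
rate line at a given [ATP] by a weak-binding dwell, in fold units.
`powerstroke_decompose` subtracts the first-step displacement from the
total and reports the second-step SD under the independence assumption
`√(total² − first²)`, flagged instead when the total SD does not exceed
the first-step SD.

## ATP kinetics (`myotrack.atpkin`)

Traces are ROI means (default 7×7 px) minus the one-pixel perimeter
ring mean. Spikes are frames above baseline + 3 robust SDs (median/MAD)
for ≥ 2 consecutive frames; both thresholds are exposed, and harnesses
that need near-complete detection of large spikes use 5 SDs with a
one-frame minimum. The waiting time is the dark gap (start-to-start
minus on-time). The survival curve is fitted by a two-exponential
mixture on log-spaced support, initialised from a two-means split of
log waits; the slower rate is designated the ATP binding rate. The fit
collapses to a flagged single exponential (rate = 1/mean) when the two
rates are within 10 % or either component's weight falls below 5 % —
single-exponential data otherwise produce spurious splits. The 2.8×
Cy3→ATP correction is applied only through the explicit
`correct_cy3_rate` call, never silently. The rate line is weighted
least squares (1/sd², ordinary when no SDs are given) via statsmodels.

## Problem sizes used in tests and the acceptance script

All simulation checks run at the study scale of a single analysis
window — 10,000 frames (400 ms) at Δt = 40 µs — with 5–12 chains of
1000 MCMC sweeps where repeated inference is needed (the full-scale
analysis would use 1000 chains; chain count only tightens the spread of
pooled summaries, not their location). The dwell-recovery check
simulates four transient sites of 100 µs dwell placed at ±24 and
±36 nm, clear of the detached core: detection accuracy depends strongly
on the density of binding positions relative to the 12.5 nm detached
SD, and sites inside the detached mode acquire enough noise-absorption
contamination to bias their apparent dwell low by ~25 %. Placing the
check sites at ~2 SD isolates dwell estimation from that position-
density effect; the position-density limitation itself is demonstrated
separately (a site at +10 nm is frequently missed altogether).

## Known limitations

- The sampled (as opposed to most-probable) state path fragments runs
  at state boundaries, biasing pooled dwell estimates ~5–15 % low even
  for well-separated sites; the amplitude-free CDF fit absorbs most but
  not all of this.
- Binding sites within ~1 SD of the detached mean are detected with low
  and layout-dependent sensitivity — a property of the model given the
  12.5/4.7 nm emission overlap, not of the sampler.
- The generator emits frame-wise independent Gaussians: no motion blur,
  no tether autocorrelation, no drift, no photophysics beyond
  Poisson + Gaussian noise. Passing tests show the inference chain
  recovers the parameters of this idealised process; they do not
  certify performance under correlated noise or model mismatch in real
  recordings.
- ECDF-based SEs (dwell fits, waiting-time fits) underestimate the true
  sampling uncertainty; cross-chain or cross-trace spread is reported
  alongside and should be preferred.
- Sticky-HDP extensions, 2D emissions, and estimation of the emission
  SDs are deliberately out of scope.
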