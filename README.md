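# myotrack

Single-molecule trajectory inference for myosin heads tracked at
microsecond resolution in engineered (DNA-origami) thick filaments.

During force generation, a muscle myosin II head tethered to the thick
filament diffuses along the actin filament, interacts with it through
sub-millisecond *weak-binding* events, and then commits to a long-lived
*strong-binding* state from which the lever-arm powerstroke is executed.
Gold-nanoparticle darkfield tracking at 25,000 fps (40 µs frames,
~0.7 nm precision) makes this diffusive search directly observable, but
the weak-binding states are hidden inside the detached state's thermal
noise: the detached head emits positions with SD ≈ 12.5 nm while a bound
head emits with SD ≈ 4.7 nm. `myotrack` implements the full analysis
chain that turns such recordings into binding positions, accessibilities,
dwell times and ATP kinetics — together with a synthetic-data generator
so every stage is testable without microscopy data.

## What is inside

| module | role |
| --- | --- |
| `myotrack.simulate` | generative model (`KineticScheme`): detached Gaussian emission, weak-binding sites with exponential dwells, ATP-gated strong binding; spot-image stacks; fluorescent-ATP spike traces |
| `myotrack.localize` | radial-symmetry sub-pixel spot localisation, Gaussian-fit refinement, geometry screening, major-axis projection |
| `myotrack.stepfit` | `TwoStateHMM` — two-state (detached/bound) Gaussian HMM with fixed emission SDs; step size = bound mean − detached mean; group comparison (t-test, Hedges' g) |
| `myotrack.ihmm` | `BindingStateIHMM` — constrained HDP-HMM (infinite HMM) beam sampler: one detached state, unbounded binding states sharing the 4.7 nm emission SD, binding→binding transitions fixed to zero; exact FFBS inner step (numba) |
| `myotrack.summarize` | pooled-position Gaussian-mixture peaks, access ratios, left-truncated exponential dwell fits, weak→strong dwell-prolongation ratio, powerstroke decomposition |
| `myotrack.atpkin` | Cy3-ATP spike detection, double-exponential waiting-time fit, 2.8× Cy3 correction, rate-vs-[ATP] weighted line |

### The core model

The trajectory `x_t` (1D, along the actin axis, Δt = 40 µs) follows a
hidden Markov model with state space `{0, 1, 2, …}`:

- state 0 (*detached*): `x_t ~ N(μ₀, 12.5²)` nm,
- state k ≥ 1 (*binding*): `x_t ~ N(μ_k, 4.7²)` nm,
- transitions out of a binding state go only to itself or to the
  detached state (`π_{k→j} = 0` for binding `j ≠ k`),
- the number of binding states is unbounded, governed by a hierarchical
  Dirichlet process prior with Gamma(1, 1) hyperpriors on both
  concentrations.

Each inference chain runs 1000 beam-sampling sweeps on a 10,000-frame
window and reports its final sample; repeating the inference across many
seeds gives the posterior spread. Inferred states occupying < 1 % of the
window or with dwell time constant < 40 µs (one frame) are excluded.
Binding positions are reported relative to the inferred detached mean.

Downstream, dwell events (maximal path runs × Δt) are fitted with the
left-truncated exponential CDF `F(t) = 1 − A·exp(−(t − 40 µs)/τ)`, and
the strong-binding side is characterised by the ATP waiting time
`1/(slope·[ATP] + intercept)`.

## Worked example

Simulate a head with three weak-binding sites (positions −24, +23,
+36 nm; access weights 0.3/0.5/0.2; dwells 240/510/320 µs), run twelve
constrained-iHMM chains, and summarise:

```python
import myotrack as mt
from myotrack.ihmm import BindingStateIHMM, IHMMConfig

sites = [mt.WeakSite(p, w, d) for p, w, d in
         [(-24.0, 0.3, 240.0), (23.0, 0.5, 510.0), (36.0, 0.2, 320.0)]]
scheme = mt.KineticScheme(sites=sites, encounter_rate=600.0, duration=400_000.0)
traj = mt.simulate_trajectory(scheme, seed=8)

cfg = IHMMConfig(mcmc_iterations=1000, window_frames=10_000, seed=0)
results = BindingStateIHMM(traj, cfg).fit_repeated(n_inferences=12, base_seed=0)

positions = mt.pooled_relative_positions(results)
mix = mt.fit_gaussian_mixture_1d(positions, K=3, seed=0)
print(mix.summary())
for p in mt.summarize_peaks(results, mix):
    print(p.summary())

line = mt.RateFit(slope=0.0038, intercept=0.17)  # s⁻¹ nM⁻¹, s⁻¹
fwd = max((p for p in mt.summarize_peaks(results, mix) if not p.excluded),
          key=lambda p: p.position)
print(f"prolongation at 2 uM ATP: {mt.dwell_ratio(fwd.dwell, line, 2000.0):.0f}x")
```

prints

```
1D Gaussian mixture fit
-----------------------
  mean   -23.58 nm   sd  0.65 nm   weight 0.333
  mean   +23.52 nm   sd  0.59 nm   weight 0.333
  mean   +36.21 nm   sd  0.69 nm   weight 0.333
log-likelihood -74.8  (n = 36)
peak   -23.6 nm (SD 0.7)  access 0.277 +/- 0.137  dwell     266 +/- 3 us
peak   +23.5 nm (SD 0.6)  access 0.482 +/- 0.181  dwell     505 +/- 2 us
peak   +36.2 nm (SD 0.7)  access 0.242 +/- 0.071  dwell     346 +/- 3 us
prolongation at 2 uM ATP: 372x
```

The three pooled-position peaks recover the generating site positions to
well under 1 nm; the access ratios recover the generating weights
(0.3/0.5/0.2) within their chain-to-chain SD; the dwell fits recover the
generating time constants despite the 40 µs frame quantisation; and the
final line converts the most forward peak's weak-binding dwell into its
fold-prolongation upon strong binding at 2 µM ATP.

A thin CLI mirrors the chain: `myotrack simulate traj|stack|atp`,
`myotrack localize`, `myotrack project`, `myotrack stepsize`,
`myotrack infer`, `myotrack summarize` (see `myotrack --help`).

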