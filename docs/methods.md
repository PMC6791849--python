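# Methods

## Model and assumptions

The package treats post-pulse recovery of the yeast cell envelope as two
weakly coupled first-order resealing processes observed through two
different reporters.

**Cell wall (TPP⁺ uptake).**  Slow TPP⁺ absorption is modelled as a
pseudo-second-order reaction between the unfilled capacity `N_m − N` and
the remaining pool `N_s − N`.  `N` is the *absorbed* amount: although the
electrode measures the supernatant concentration, the quantity entering
the model is `N = N_is − [TPP⁺]_supernatant`, which starts at 0 and
saturates at `N_m`.  The model requires `N_m < N_s` (absorption saturates
before the pool is exhausted); the near-degenerate case is handled by the
equal-roots limit below.  A pulse above the permeabilization threshold
adds transient pores whose number decays exponentially with lifetime
`τ_d`, giving the time-dependent absorption coefficient
`k_a(t) = k_a0 + A·e^(−Δt/τ_d)·e^(−t/τ_d)`.  The pore count and the
per-pore rate constant never appear separately in any observable, so only
their product `A` is represented (one amplitude per field strength).
Fast surface adsorption (stage I) and the pre-absorption delay (stage II)
of the raw electrode trace are *not* inside the closed form; they enter
only through the value of `N_s` and through the trace simulator.

**Field dependence.**  The parametric law
`A = b(E_p − E_th)² f² [1 − exp(−t_p/t_ch)]²` is exposed for scaling an
amplitude between field strengths; for identical pulses everything but
the quadratic threshold term cancels.  The two printed forms of the
membrane-charging bracket differ in the exponent's sign; the package uses
the negative (saturating) sign, which is the physically meaningful
charging form — the positive-sign variant diverges with pulse duration.
The threshold used for relative scaling defaults to `E_th = 2.0 kV/cm`;
`b` and `t_ch` need never be specified because per-field amplitudes are
calibrated, not predicted.

**Membrane (fluorescence).**  Dye influx reports membrane
permeabilization; its decay with post-pulse delay is a single exponential
with residual, `I(Δt) = I₀e^(−Δt/τ_l) + I_r`.  The residual absorbs the
slow, ice-bath-prolonged tail of membrane resealing; nothing beyond the
offset is modelled.

## Parameters, units, defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| `N_s` | TPP⁺ pool at start of slow stage | μM | 1.0 (initial probe concentration) |
| `N_m` | maximal accumulable amount | μM | 0.5 (only `R = N_m/N_s` matters; choice documented, not fitted) |
| `t` | incubation time | s | 180 (the 3-minute design) |
| `k_a0` | untreated absorption coefficient | μM⁻¹s⁻¹ | calibrated: 7.329e-4 |
| `A` | pore-term amplitude | μM⁻¹s⁻¹ | calibrated at 5.85 kV/cm: 4.926e-2 |
| `τ_d` | wall-pore lifetime | s | 24 |
| `τ_l` | membrane-pore decay time | s | 20 |
| `I₀`, `I_r` | fluorescence amplitude / residual | a.u. | 100, 20 |
| `f` | cell shape factor | — | 1.5 (spheres) |
| `E_th` | permeabilization threshold | kV/cm | 2.0 |

Time is seconds everywhere except pulse durations (μs, converted at the
boundary); fields are kV/cm, concentrations μM.

## Calibration

`calibrate_from_anchors` inverts the closed form algebraically.  From the
untreated baseline fraction `r₀`: `S₀ = (1 − r₀)/(1 − R r₀)`,
`k_a0 = ln S₀ / ((N_m − N_s) t)`.  From the zero-delay fraction at the
reference field the accumulated rate integral is inverted the same way
and the pore contribution `A τ_d (1 − e^(−t/τ_d))` is solved for `A`.
Both inversions are exact; forward evaluation reproduces the anchors to
machine precision (the tests assert ≤ 1e-10), and an independent
root-finder (Brent bracketing on the forward model) confirms both values.

## Synthetic data

The generators emulate the three experimental designs on their actual
grids: fluorescence delays {10, 30, 90, 180, 360, 600} s; uptake delays
{5, 10, 20, 30, 40, 50, 60, 80, 120, 180} s at fields
{2.93, 4.38, 5.85} kV/cm with 150 μs pulses and 180 s incubation; and the
three-stage electrode trace.  Noise is additive Gaussian on the reported
quantity — σ = 0.03 on the absorbed fraction (chosen so per-curve
adjusted R² on synthetic data spans roughly the 0.34–0.85 range seen in
curve fits of this kind) and σ = 2 a.u. on fluorescence against an
I₀ = 100 amplitude; the experiments themselves do not print their
measurement error, so these are stated assumptions.  Ratios are clipped
to [0, 1].  One master seed spawns an independent `numpy` SeedSequence
stream per replicate, so runs are deterministic and replicates
independent.

What the generator does *not* emulate: electrode electrochemistry (drift,
Nernstian response), cell-to-cell heterogeneity, viability loss, or any
correlation structure in the noise.  Passing recovery tests therefore
show that the estimator is consistent and approximately unbiased under
the stated noise model at the design's grids — not that real measurement
error behaves this way.  Stage-I/II trace constants (amplitude 0.15 μM,
τ = 3 s, 240 s delay stage) are illustrative round numbers inside the
qualitative ranges of the design ("~10 s" fast stage, "3–5 min" delay)
and carry no inferential weight.

## Fitting

Both fits are bounded trust-region least squares
(`scipy.optimize.least_squares`, `trf`, tolerances 1e-14) with analytic
residual evaluation through the closed forms; unweighted, consistent with
a single goodness-of-fit figure per curve.  Bounds: `τ ∈ [1e-3, 1e4] s`,
amplitudes ≥ 0.  Initial guesses are data-driven: a log-linear fit of the
positive fluorescence tail for `τ_l`, anchor-style algebraic inversion of
the smallest-delay point for the uptake amplitudes.  Standard errors come
from the Jacobian via `cov = s²(JᵀJ)⁻¹` with `s² = SSR/(n − p)`
(pseudo-inverse, so rank-deficient problems yield large/NaN SEs rather
than crashes).  By default the uptake fit holds `k_a0` fixed at its
baseline-anchor value — the experimental design measures the untreated
level separately — with a free-`k_a0` mode available.  The shared-`τ_d`
fit estimates one lifetime across all fields plus one amplitude per
field.  Amplitudes within 2 SE of zero (or pinned at the zero bound) are
flagged; if every amplitude is flagged the lifetime is reported as
unidentifiable rather than silently returned.  Degenerate inputs
(constant intensity, all-baseline uptake) return flagged, unconverged
results instead of raising.

Adjusted R² uses `1 − (1 − R²)(n − 1)/(n − p − 1)` and is NaN when the
observations have zero variance.

## Numerical choices

* **Closed form vs ODE.**  The two-root solution is used everywhere; when
  `|N_m − N_s| < 1e-9·N_s` the equal-roots limit
  `N/N_m = N_m K/(1 + N_m K)` of `dN/dt = k_a(N_m − N)²` keeps the API
  continuous across the degeneracy.
* **Oracle integrator.**  `integrate_uptake_ode` is a fixed-step RK4 with
  step `≤ 0.01·min(τ_d, 1/(k_a,max·N_s))`, chosen over adaptive stepping
  so the oracle is bit-for-bit reproducible.  The property suite checks
  closed form against RK4 to ≤ 1e-6 relative over 100 random parameter
  sets; observed agreement is ~1e-11.
* **Monte-Carlo sizes.**  Recovery experiments default to 100 replicates
  of the full design (30 uptake points or 6 fluorescence points each), a
  size at which the replicate mean of either lifetime is stable to a few
  tenths of a second; each full experiment runs in about a second.

## Known limitations

* The wall-free spheroplast observation (no field effect without a wall)
  is representable only as the `A = 0` special case; no separate
  spheroplast model exists.
* Raw measurements behind the published recovery curves are not
  deposited, so printed per-curve adjusted R² values cannot be refit;
  they informed only the synthetic noise scale.
* No Bayesian inference or bootstrap intervals; SEs are linearised.
  Coverage of the ±1.96 SE interval on synthetic data is ~0.95 for the
  uptake design and ~0.84 for the 6-point fluorescence design (small-n
  linearisation optimism).
* The fluorescence residual `I_r` is a free constant; extended on-ice
  resealing dynamics are out of scope.
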