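# pefreseal

Kinetic modelling of how the yeast (*Saccharomyces cerevisiae*) cell wall
and plasma membrane reseal after pulsed-electric-field (PEF)
electroporation, probed by uptake of the lipophilic cation
tetraphenylphosphonium (TPP⁺) and by a membrane-impermeant fluorescent
stain.  The package is aimed at biophysicists analysing post-pulse
recovery experiments: it provides the closed-form kinetics, calibration
from printed anchor values, bounded least-squares fitting, synthetic-data
generation for the three experimental designs, and a command-line
pipeline tying them together.

## The model

TPP⁺ absorption during the slow uptake stage follows a pseudo-second-order
law,

    dN/dt = k_a(t) · (N_m − N)(N_s − N),        N(0) = 0,

where `N` is the absorbed amount (μM), `N_m` the maximal accumulable
amount and `N_s` the TPP⁺ pool at the start of the slow stage.  A pulse
creates transient, non-equilibrium pores in the cell wall that decay with
lifetime `τ_d`, so the absorption coefficient carries a decaying excess:

    k_a(t) = k_a0 + A · exp(−Δt/τ_d) · exp(−t/τ_d),

with `A` the identifiable pore-term amplitude at the applied field and
`Δt` the delay between the pulse and the addition of the probe.  Because
`k_a` is separable in time the ODE has a closed form: with
`K(t) = ∫₀ᵗ k_a du` and `R = N_m/N_s`,

    N/N_m = (1 − S) / (1 − R·S),        S = exp((N_m − N_s)·K(t)).

Above a threshold field the amplitude scales as
`A ∝ b (E_p − E_th)² f² [1 − exp(−t_p/t_ch)]²`.  Membrane resealing is
monitored independently through the fluorescence decay
`I(Δt) = I₀ exp(−Δt/τ_l) + I_r`, with `τ_l` the lipidic-pore decay time.

The headline quantities are the two pore lifetimes — `τ_d ≈ 24 s` for the
wall, `τ_l ≈ 20 s` for the membrane — and the two anchor ratios of the
uptake design: the untreated baseline `N₀/N_m ≈ 0.12` after a 3-minute
incubation and the zero-delay fraction `N/N_m ≈ 0.65` at 5.85 kV/cm.

## Worked example

Calibrate the baseline coefficient and reference pore amplitude from the
two anchor ratios, then run a 100-replicate generate-and-refit recovery
experiment on the three-field uptake design:

```sh
pefreseal calibrate --out demo/cal
pefreseal recover --design uptake --replicates 100 --seed 20191014 --out demo/rec
```

The calibration prints

```json
{
  "k_a0_uM_inv_s_inv": 0.0007328663087977489,
  "A_reference_uM_inv_s_inv": 0.049262376967176294,
  "tau_d_s": 24.0,
  "baseline_ratio": 0.12,
  "delta0_ratio": 0.65,
  "N_m_uM": 0.5,
  "N_s_uM": 1.0,
  "incubation_s": 180.0
}
```

i.e. an untreated absorption coefficient `k_a0 = 7.33e-4 μM⁻¹s⁻¹` (which
forward-evaluates to exactly the 0.12 baseline) and a pore-term amplitude
`A = 4.93e-2 μM⁻¹s⁻¹` at the 5.85 kV/cm reference field (which returns
the 0.65 zero-delay anchor).  The recovery run then reports

```
parameter     truth      mean      bias     rmse       sd  coverage95  n_replicates
    tau_d 24.000000 24.407934  0.407934 1.997567 1.965321        0.95           100
   A_2.93  0.002874  0.003067  0.000193 0.001411 0.001404        0.95           100
   A_4.38  0.018826  0.018633 -0.000193 0.002880 0.002888        0.94           100
   A_5.85  0.049262  0.048556 -0.000707 0.007034 0.007034        0.94           100

Wall-pore lifetime: true tau_d = 24 s, mean fitted = 24.408 s (bias +0.408 s).
```

The shared wall-pore lifetime is recovered with a mean of 24.4 s against
the generating 24 s, and the per-field amplitudes keep their quadratic
field ordering.  The same workflow with `--design fluorescence` recovers
the membrane decay time `τ_l` near 20 s.

Other subcommands: `simulate` writes synthetic datasets (fluorescence,
uptake, or raw electrode traces) as CSV plus a JSON manifest of the
generating parameters; `fit-fluorescence` / `fit-uptake` fit the models to
such tables; `report` summarises a directory of fit outputs.  Every
command writes the resolved configuration next to its outputs and is
byte-for-byte reproducible given the same seed.

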