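# gelcav

Transient bubble dynamics and cavitation in soft gels under mechanical
impact.

When a soft sample — a tissue simulant such as collagen, agarose or
gelatin, or tissue itself — is rapidly accelerated, the acceleration
induces a pressure gradient through the sample.  Pre-existing bubbles
grow with the impact, and small enough bubbles *burst*: their maximum
radius jumps by orders of magnitude across a critical driving pressure.
This package is for researchers in injury biomechanics and soft-matter
cavitation who want to simulate that response, reason about when bursts
occur, and analyze drop-tower-style experiments (acceleration traces,
high-speed bubble imagery, maximum-stretch datasets) end to end.

## What it computes

The core model is a Rayleigh–Plesset equation extended with a
Kelvin–Voigt / neo-Hookean elastic stress for the surrounding gel:

    r r̈ + (3/2)ṙ² = (p_v − p_a(t))/ρ + (p_G0/ρ)(r₀/r)^{3k}
                     − 4ν ṙ/r − 2γ/(ρr) − (μ/2ρ)[5 − 4(r₀/r) − (r₀/r)⁴]

Around it the package provides, as composable modules:

- `materials` — property records, gel concentration→modulus
  calibrations (E_a = 85c^1.8 kPa agarose, E_g = 8c kPa gelatin), and a
  registry of nominal parameter sets;
- `bubble_dynamics` — stiff adaptive integration of the radius
  equation under measured or synthetic impact pulses, with feature
  extraction (λ_max = r_max/r₀, its time, collapse detection);
- `scaling` — the nondimensional form (Cauchy/Deborah/Weber-like
  groups), the linearized oscillator and its damped frequency, the
  inviscid first integral, and the first-order burst estimate
  λ_max = (3/2)(2γ/r₀μ − 2)/(Δp/μ − 5/2) with its critical tension
  (5/2)μ and critical radius γ/μ;
- `sweep` — amplitude sweeps, discontinuous-jump burst detection with
  bisection refinement, the depth–pressure closure p = κρ|a|h²/H, and
  critical-acceleration extraction;
- `fits` — the regression pipeline for the empirical depth-squared law
  λ_max = k(|a|/g)(h_b/H)² + c;
- `imaging` — threshold segmentation, equivalent radii √(A/π),
  nearest-centroid tracking with merge flags, pre-impact baselines, and
  rigid-reference QC;
- `synthetic` — seeded generators for pulses, λ_max datasets, rendered
  bubble image stacks, and fully physics-coupled experiments.

See `docs/methods.md` for the model's assumptions, conventions and
numerical choices.

## Worked example

Simulate a 50 μm bubble in the nominal 8 kPa gel driven by an 18 kPa
tensile pulse peaking at 0.547 ms (the `simulate` subcommand wraps
`gelcav.simulate_bubble`):

```
$ gelcav simulate --r0 50e-6 --pamp 18e3 --out sim_out
lambda_max = 10.6654  t_max_out = 0.000802302 s  collapsed = True
```

The bubble stretches to 10.7× its initial radius, peaking 0.26 ms
*after* the input peak, and then collapses completely once the pulse
releases the stored elastic and surface energy.  Sweep the amplitude
for a submicron bubble and the response becomes discontinuous:

```
$ gelcav sweep --r0 0.5e-6 --pmin 20e3 --pmax 220e3 --n 14 --out sweep_out
burst at p_amp_cn = 119470 Pa, jump = 3.69 orders
```

A 0.5 μm bubble ignores the forcing until ~120 kPa and then bursts,
its maximum stretch jumping by ~3.7 orders of magnitude — the signature
that distinguishes sub-critical (r₀ < γ/μ = 9 μm) bubbles from macro
bubbles, which grow smoothly and linearly.  Finally, generate a
noiseless synthetic maximum-stretch dataset and recover the empirical
depth-squared law exactly:

```
$ gelcav synth --preset lambda-dataset --seed 7 --sigma 0.0 --out synth_out
$ gelcav fit --dataset synth_out/dataset.csv --out fit_out
k = 0.0023  c = 1.0153  R^2 = 1
```

Here `k` is the stretch gained per g of drop amplitude for a bubble at
the bottom of the sample, `c` the rest-state intercept, and R² the
quality of the collapse of all depths onto the single combined law.

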