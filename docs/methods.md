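# Methods

## The model

`gelcav` simulates a single spherical gas/vapor bubble of initial radius
r₀ embedded in a soft gel that is rapidly accelerated by a mechanical
impact.  The far field carries an acceleration-induced pressure
p_a(t) = p_amp·a_n(t), where a_n is the normalized measured acceleration
waveform and p_amp the pressure amplitude at the bubble's depth.  The
radius obeys a Rayleigh–Plesset equation extended with a Kelvin–Voigt /
neo-Hookean viscoelastic stress:

    r r̈ + (3/2) ṙ² = (p_v − p_far(t))/ρ + (p_G0/ρ)(r₀/r)^{3k}
                      − 4ν ṙ/r − 2γ/(ρr) − (μ/2ρ)[5 − 4(r₀/r) − (r₀/r)⁴]

with r(0) = r₀, ṙ(0) = 0, where ρ, μ, ν, γ are the gel's density, shear
modulus, kinematic viscosity and surface tension, p_v the vapor
pressure, and p_G0 the initial pressure of the trapped contaminant gas
(isothermal by default, k = 1).  The rest state λ = r/r₀ = 1 is an exact
equilibrium of the implemented equation.

Assumptions: incompressible medium, no pressure gradient across the
bubble (r small against the depth scale), constant temperature during
expansion, a single non-interacting bubble.  Collapse is not modelled
beyond detection: integration stops at λ = λ_stop (default 0.05) and
flags the trajectory collapsed, since post-collapse physics requires
temperature and compressibility effects outside scope.

## Pressure bookkeeping

Two conventions are implemented (`SolverConfig.pressure_convention`):

- **reduced** (default): ambient pressure is subtracted from both the
  far field and the gas pressure; the dynamics are driven purely by
  departures from atmospheric conditions, and the trapped gas carries
  only its Laplace/vapor excess 2γ/r₀ − p_v.  This is the bookkeeping
  under which the first-order burst theory holds — critical tension
  Δp_cr = (5/2)μ, critical radius r₀ᶜʳ = γ/μ — and under which a 1.1 ms,
  18 kPa tensile pulse grows a 50 μm bubble several-fold and then lets
  it collapse completely.  It presumes that elastic and surface stresses
  dominate the vapor term (4μ + 4γ/r₀ > 3p_v), which holds for the stiff
  nominal gel at every radius of interest and for submicron bubbles in
  any medium.
- **absolute**: full atmospheric bookkeeping (gas starts at
  p_∞ − p_v + 2γ/r₀).  The ~1 atm gas cushion stiffens the response,
  suppresses deep collapse, and stabilizes macro bubbles in near-fluid
  media — the right frame for millimetre-scale bubbles in very soft
  collagen, and the one used by the physics-coupled experiment
  generator.

Both keep λ = 1 as an exact initial equilibrium; positive p_amp means
impact-induced tension (sign flippable via `tension_positive`).

## Nondimensional form and perturbation theory

With λ = r/r₀, t̃ = t/t_ref (t_ref defaults to the pulse peak time) and
a reference radius r_cr, three groups normalized by the shear modulus
control the response: 𝒜 = ρ(r_cr/t_ref)²/μ (inertia), ℬ = 2νρ/(μ t_ref)
(viscosity), 𝒞 = 2γ/(r_cr μ) (surface tension).  `simulate_nondimensional`
integrates the exact nondimensionalization of the radius equation, so
redimensionalized trajectories match the dimensional solver to solver
tolerance, and the physics is invariant to the (arbitrary) choice of
r_cr — both properties are tested.

Small forcing p̃_a = p̃·q(t̃) with |p̃q| ≪ 1 linearizes the equation to a
damped oscillator 𝒜r̃³f̈ + 2ℬr̃ḟ + (2𝒞 + r̃(4 − 3p̃_v))f = −p̃q whose damped
frequency has a closed form; the nonlinear solver's small-amplitude
ring-down reproduces it to well under 1%.  One bookkeeping note: the
oscillator and its frequency are stated (and implemented) in the
reduced convention; under absolute bookkeeping the stiffness gains a
3(p_∞ − p_v)/μ term from the gas cushion.  A second note: the printed
form of the forcing term is used verbatim on the right-hand side
(−p̃q, without an r̃ factor); this affects only the static gain of the
auxiliary linear solver, not the frequency, and the convention is
documented here to avoid surprise when comparing with a re-derivation.

## First integral and burst criticality

For ν ≈ 0 and frozen driving tension Δp = p_v − p_a the radius equation
has an exact first integral giving dλ/dt̃ as a square root of

    (2Δp/3μ)(1 − λ⁻³) + (2p_G0/μλ³)·ln λ
    − (2γ/μr₀)(1/λ)(1 − λ⁻²) + 𝔼*/3,       𝔼* = −5 + 6λ⁻¹ + 2λ⁻³ − 3λ⁻⁴.

(The implementation was re-derived from the radius equation and matches
inviscid trajectories pointwise to solver precision.)  Setting the
radicand to zero at the turning point and keeping terms through O(1/λ)
yields the first-order burst estimate

    λ_max = (3/2)(2γ/(r₀μ) − 2) / (Δp/μ − 5/2),

with two critical quantities: the estimate diverges at Δp_cr = (5/2)μ
(20 kPa for the 8 kPa nominal gel) and its numerator changes sign at
r₀ᶜʳ = γ/μ (9 μm) — below that radius the radicand can go negative,
the real-to-imaginary bifurcation that marks surface-tension-dominated
instability.  A negative radicand is returned as an explicit
imaginary-branch flag, and non-physical estimates (λ < 1) are flagged
rather than reinterpreted.  The estimate is a 1/λ expansion, so it is
validated against full simulations at Δp = 2μ, where λ_max ≈ 3–6 and
agreement is within 15% for r₀ ≥ 20 μm; at small Δp (λ_max near 1) the
expansion degrades by construction.

## Burst detection

`amplitude_sweep` runs one simulation per pressure amplitude with a
fixed pulse shape; `detect_burst` declares a burst when adjacent
λ_max values jump by more than a factor of 10, then bisects the
transition until the bracket is below 0.1% of the amplitude,
classifying midpoints against the geometric mean of the branch values.
Root-finding on dp_amp/dλ_max was rejected as the primary detector: the
fold is numerically fragile, while the jump-plus-bisection rule is
robust and grid-converged (the refined critical amplitude is stable to
one coarse cell under grid halving).  For the nominal gel an r₀ = 0.5 μm
bubble bursts near p_amp ≈ 120 kPa with a jump of ~3.7 orders of
magnitude in λ_max; sweeping r₀ shows bursts only for r₀ ≤ 9 μm,
bracketing the critical size γ/μ.

## Depth–pressure law and regression pipeline

Experimentally, the maximum stretch of macro bubbles grows linearly with
drop amplitude and quadratically with depth.  The package closes the
dimensional gap of p_amp ∝ |a|·h_b² as p_amp = κρ|a|h_b²/H, with the
sample height H carrying the units and κ a dimensionless coupling;
`calibrate_kappa` recovers κ from an observed per-g slope and a
simulated dλ_max/dp_amp.  The regression pipeline fits per-bubble OLS
slopes of λ_max on |a|/g, a free power law of slope versus depth (with
the constrained h² fit reported alongside), and the pooled law
λ_max = k(|a|/g)(h_b/H)² + c with R² = 1 − SS_res/SS_tot.  Ordinary
(unweighted) least squares is used throughout, amplitudes are kept in
g-units (g = 9.81 m/s²), and merged-bubble records are excluded via an
upstream flag rather than by outlier rejection.

## Image pipeline

Frames are thresholded with one global threshold per stack (polarity
configurable; bubbles default to dark-on-bright), labelled with
8-connectivity, and reduced to equivalent radii r = √(A/π).  Tracking is
nearest-centroid per frame; two seeds landing in one region flag both
series merged from that frame on.  The pre-impact baseline r₀ is the
mean over 49 frames ending at impact, and the rigid reference inclusion
is summarized by the mean and normal-approximation 95% CI of r_ref/r₀
after impact.  The interval construction (normal approximation) is a
package choice, and the QC rule is explicit: the CI half-width must be
small against the observed λ_max − 1.  Sub-pixel refinement is not
attempted; the targeted optical regime is ~100 μm per resolvable radius.

## Synthetic data

The generators reproduce the study's conditions: five drop amplitudes
(228.52–516.60 g), a 36 mm sample, eight bubble depths, mean macro
bubble radius 0.52 mm, smooth compact pulses peaking at 0.547 ms over a
~1.1 ms support (piecewise raised cosine; pluggable), per-observation
Gaussian noise on λ_max (default σ = 0.01), and image stacks with
additive pixel noise plus frame-wide multiplicative illumination jitter
(default 2%) and a rigid non-circular reference inclusion.  All
stochastic generators require a seed and are bit-reproducible; ground
truth is always emitted alongside the data.

The physics-coupled experiment (`make_impact_experiment`) uses the
collagen-like registry entry (μ = 10 Pa) under absolute bookkeeping and
κ = 0.12, chosen so the macro bubble stays in its linear-response regime
and acts as a clean pressure gauge; in that regime the per-depth
response is linear (R² > 0.999) and the recovered slope-depth exponent
is 2.0–2.1.  What the generator does not emulate: the larger absolute
deformations of real collagen (the model's macro-bubble compliance is
atmosphere-limited, so default stretches stay below ~1.1), bubble–bubble
interaction, non-spherical equilibrium shapes, and stochastic nucleation
site statistics.  Passing tests therefore demonstrate internal
consistency of model, theory and pipeline — not that the model's
absolute compliance matches any particular gel.

## Numerical choices

- Integrator: `scipy.integrate.solve_ivp` with LSODA (stiffness-
  switching), rtol 1e-8, atol r₀·1e-9 on radius; max step 1/50 of the
  pulse duration; radius maxima located exactly via ṙ = 0 event
  crossings rather than from the sampled grid.
- Collapse cutoff λ_stop = 0.05 and a velocity guard (default 10⁵ m/s)
  terminate runaway collapse; either sets `collapsed=True`.
- Sweep grids are geometric when bursts are expected (thresholds span
  decades); bisection bracket tolerance 0.1% of amplitude.
- Problem sizes: burst sweeps use 14–22 grid points per radius and the
  physics-coupled experiment 5 amplitudes × 6–8 depths, sizes at which
  every reported quantity is grid-converged (halving changes nothing at
  the reported precision).
- Degenerate inputs are rejected early with named errors: non-ascending
  grids, all-equal amplitudes, single-depth designs, thresholds that
  foreground an entire frame, seeds outside frame bounds.

## Known limitations

Collapse and rebound are detected, not modelled.  The first-order
theory is reliable only for λ_max ≫ 1 and ν ≈ 0.  The reduced
bookkeeping is meaningless for media whose rest state is
vapor-unstable without atmospheric support (near-fluids at large r₀);
the solver does not guard against that choice beyond documentation.
Viscosity enters only through the 4νṙ/r term; extensional/polymeric
stresses are absent.  The coupling κ is a free calibration constant:
the study constrains only the proportionality p_amp ∝ |a|h_b².
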