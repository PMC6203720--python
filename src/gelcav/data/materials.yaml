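# Nominal material property registry (SI units).
#
# paper_nominal_gel: soft-gel parameter set used throughout the numerical
# studies; pinned so that the critical quantities (5/2)*mu = 20 kPa and
# gamma/mu = 9 um hold exactly.  Kinematic viscosity defaults to water's,
# since viscosity is not critical for the dynamics of submicron bubbles.
# water: same liquid but rigidity-free (mu = 0).
paper_nominal_gel:
  density: 1000.0            # kg/m^3
  shear_modulus: 8000.0      # Pa
  kinematic_viscosity: 1.0e-6  # m^2/s
  surface_tension: 0.072     # N/m
  vapor_pressure: 2339.0     # Pa, absolute (water, ~20 C)
  ambient_pressure: 101325.0 # Pa, absolute
  polytropic_index: 1.0      # isothermal gas
collagen_like:
  # Near-fluid gel emulating 1% collagen (shear modulus ~10 Pa); used by
  # the physics-coupled macro-bubble experiment generator.
  density: 1000.0
  shear_modulus: 10.0
  kinematic_viscosity: 1.0e-6
  surface_tension: 0.072
  vapor_pressure: 2339.0
  ambient_pressure: 101325.0
  polytropic_index: 1.0
water:
  density: 1000.0
  shear_modulus: 0.0
  kinematic_viscosity: 1.0e-6
  surface_tension: 0.072
  vapor_pressure: 2339.0
  ambient_pressure: 101325.0
  polytropic_index: 1.0
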