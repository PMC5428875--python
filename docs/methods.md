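# Methods

## Measurement model

A rectangular clamped-free beam (length L, width w, thickness t_c,
modulus E_c, density ρ_c) carries a thin adsorbate film (thickness t_f,
density ρ_f, modulus E_f). The fundamental flexural resonance of the bare
beam is the Euler–Bernoulli closed form

    f₁ = (λ₁²/2π)·(t_c/L²)·√(E_c/12ρ_c),   λ₁² = 3.5160.

The film perturbs the resonance through added mass and added bending
stiffness. With τ = t_f/t_c, E_r = E_f/E_c, ρ_r = ρ_f/ρ_c, the relative
shift is expanded to second order in τ:

    Δω/ω₀ = ½(3E_r − ρ_r)τ + (3/8)[ρ_r² + 2E_r(4 − ρ_r) − 7E_r²]τ².

For the films treated here τ ~ 10⁻³, so the expansion error is far below
the 50 mHz instrument noise floor (≈ 9×10⁻⁶ relative). The inversion
solves the quadratic in E_r; of its two roots the physical one is the
root continuous with the first-order solution
(shift + ½ρ_rτ)/((3/2)τ) — the other is O(1/τ²) and unphysical — and it
is selected by proximity to that first-order value rather than by
square-root branch sign, which is robust when the leading coefficient
(−21τ²/8) is nearly degenerate. Shifts more negative than pure mass
loading permits invert to a negative modulus; these are clipped to zero
and flagged rather than raised, because noisy low-coverage data
legitimately produce them. The expansion order (1 or 2) is a
configuration switch; all defaults use order 2.

Sweep frequency data are self-referenced (Δf(RH) = f(RH) − f(0%)). The
absolute shift the inversion needs is reconstructed from the bare-beam
frequency recorded in the sweep metadata (`f_bare_hz`); when a file lacks
it, the layer model's dry-state forward shift anchors the RH 0 point.
Density-series shifts are referenced to the bare cantilever directly.
These are the two referencing modes; they are never mixed implicitly.

The two-layer composite-beam relation (used to decouple a film modulus
from a substrate+film effective modulus) is implemented in the standard
normalized form N/[(E_g t_g + E_f t_f)(t_g + t_f)³] with
N = E_g²t_g⁴ + E_f²t_f⁴ + 2E_gE_f t_g t_f(2t_g² + 2t_f² + 3t_g t_f),
which satisfies the homogeneous-beam identity and matches neutral-axis
integration to 10⁻⁹. An `as_printed` variant without the (t_g+t_f)³
normalization (units Pa·m³) is retained for traceability to the
bending-stiffness form of the same relation; no pipeline path uses it.

## Layer property surfaces

All three surfaces are deterministic, continuous tables with physically
motivated interpolation; every number is overridable per `StrandModel`.

**Thickness.** Hydrated ssDNA anchors (3.1×10¹² cm⁻², 0.3 nm) and
(2.5×10¹³ cm⁻², 1.5 nm) — the molecular-dynamics result that strands lie
flat (one base diameter) at low coverage and stand up as packing
increases. Linear between anchors, flat below the first, and an
exponential approach to a 2.2 nm cap (density scale 1.5×10¹³ cm⁻²) above
the last, since a 20-mer cannot extend indefinitely. Dry layers contract
by a factor 0.8 (hydration stretches the strands). dsDNA uses a 2.0 nm
low-density floor (helix diameter), a 2.6 nm cap and contraction 0.9
(the duplex is structurally stiffer). Thickness at intermediate RH is
linear between the dry and fully hydrated states over [0, 70] % RH and
constant above.

**Modulus.** E(n) is tabulated at RH 0 and RH 70 and linear in RH
between them (the observed behavior is linear and hysteresis-free).
The ssDNA RH-70 table {0.6, 5, 12, 15, 15} GPa at
n = {0.1, 1, 2.5, 3.7, 6.5}×10¹³ cm⁻² rises to a ~15 GPa plateau; the
dry table {0, 1, 4, 5, 10} GPa gives the ~10 GPa hydration tuning range
at 3.7×10¹³ cm⁻² and a dry point near 10 GPa at the highest coverage.
dsDNA is an order of magnitude softer (0.5→2 GPa hydrated, 0.4→1.6 GPa
dry) with weak RH dependence — the duplex shields the water-mediated
strand–strand junctions. The printed literature fit constants for these
curves are shipped verbatim as `PUBLISHED_SS_FIT` / `PUBLISHED_DS_FIT`
presets, but their unit labels are internally inconsistent (the ss
exponential rate overflows unless the density is read in units of
10¹³ cm⁻², and the ds line then yields ~0.1 GPa at the top density);
they are documentation, not defaults.

**Mass density.** ρ = n·[m_strand·(1+m) + N_w(RH)·m_water]/t(n, RH),
with the ss/ds strand mass and water count blended by the hybridization
fraction h, m the excess (nonspecifically adsorbed) mass fraction, and
N_w(RH) linear from 0 to 20 waters/strand (ss) or 40 (ds) at RH 70.

**Effective dynamic strand mass — a deliberate calibration.** The
chemical mass of the thiolated 20-mer probe is ≈ 6140 Da
(`strand_mass()`, from average residue masses). Used directly in the
mass-density bookkeeping, that mass makes the modeled shift-vs-density
curve monotonically negative: at n = 2.5×10¹³ cm⁻², t = 1.5 nm and
E ≈ 12 GPa the mass term exceeds the stiffness term by ~3.5×, and no
zero crossing can occur anywhere — contradicting the observed crossover
at ≈ 2.5×10¹³ cm⁻². The observed crossover, with the observed moduli and
MD thicknesses, implies an effective dynamic layer density of
~500 kg/m³ at that operating point. The default presets therefore carry
an *effective dynamic strand mass* of 2.3797×10⁻²⁴ kg (≈ 1433 Da; ds
twice that), fixed once by requiring the noiseless fully hydrated ss
curve to cross zero at 2.5×10¹³ cm⁻². This is the single calibrated
constant of the package; it represents whatever combination of partial
mass coupling, baseline water adsorption on the reference surface, and
unreported thickness/density bookkeeping underlies the observed balance
point. The chemical mass remains available and is what the XPS
composition model uses. A consequence of the calibration is a second,
downward zero crossing of the model curve near ~4.2×10¹³ cm⁻² (the mass
term is linear in n while the thickness saturates at its cap); the
smallest crossing is the reported critical coverage.

## Fits

- **E(n) families.** `saturating_growth` A/(B + C e^(−n/n0)) is fit in
  the non-redundant form E_max/(1 + R e^(−n/n0)) (the A, B, C
  parameterization has a scale redundancy); the asymptote A/B = E_max is
  the headline parameter. `linear` fits slope/intercept. Weights are
  per-point standard deviations when available — the inversion noise
  σ_E(n) ≈ σ_shift·E_c/(1.5τ(n)), which strongly deweights low-coverage
  points (thin layers amplify shift noise) — else uniform.
- **Hybridization fit.** Bounded least squares (dogbox) of
  (h, m) ∈ [0,1]² through the full forward model against a hybridized
  density series. 1σ errors from the Gauss–Newton curvature at the
  solution; solutions within 10⁻⁶ of a bound are flagged
  `boundary_pinned`. The estimator is consistent (bias → 0 with noise),
  but at the default noise level the bound at m ≥ 0 induces a small
  upward bias (~1 point on the percent scale) in the excess-mass mean
  over replicates.
- **Crossover.** A 600-point log-spaced scan of the forward model over
  [10¹², 10¹⁴] cm⁻² locates sign changes; the smallest bracket is
  refined by Brent's method. dsDNA defaults raise `NoCrossoverError` —
  the curve is mass-dominated everywhere, as expected.
- **Thickness-uncertainty propagation.** The inversion is re-run at
  t(1 ± u) with density co-varied as 1/t (areal mass conserved); ΔE is
  half the spread, one-sided with a flag if a perturbed inversion is
  infeasible. u ≈ 0.28 reproduces a ~33 % relative modulus error at the
  3.7×10¹³ cm⁻²/RH 70 operating point.

## Synthetic data generator

The generator *defines the study conditions*; its defaults are the
stated experimental parameters wherever those exist. RH follows a
triangular ramp at 10 %/min over [0, 70] %, sampled at 1 Hz (841 records
per loop). The frequency branch is the forward model plus white Gaussian
noise of 50 mHz (the PLL noise floor) and has no built-in hysteresis —
matching the observation that frequency loops are nearly closed. The
deflection branch is phenomenological (no quantity is derived from it
beyond hysteresis characterization): −d·(RH/70)^1.5 with
d = 648 nm·(n/10¹³)^0.466, calibrated to −180 nm at 5 min immobilization
and −1550 nm at 24 h through a Langmuir time→density map
n(t) = 7×10¹³(1 − e^(−t/546 min)) cm⁻² (itself only a modeling
convenience — experimental densities come from XPS); a hysteretic lobe
of 8 % of d, shaped 4u(1−u), widens the dehydration branch, plus 5 nm
white noise. XPS records follow the exponential attenuation model with
1 % multiplicative lognormal intensity noise, a 2.0 nm attenuation
length, and dry-state thicknesses (spectra are taken ex situ). All
streams derive from one integer seed through numpy's SeedSequence;
output is byte-identical per seed.

What the generator does *not* emulate: thermal drift, 1/f and
Allan-floor noise shaping, adsorption kinetics beyond the Langmuir
convenience map, surface-stress coupling into the resonance, or
inhomogeneous hybridization across the beam. Recovery tests on this
data therefore validate the analysis chain (inversion, fitting,
referencing, uncertainty bookkeeping) under the assumed noise structure
— not the physical fidelity of the layer model itself, whose anchors are
the external inputs discussed above.

## Numerical and design choices

- Strict SI internally; unit conversion only at interfaces
  (`CantileverGeometry.from_practical`, file readers, CLI).
- λ₁² = 3.5160 as the fundamental-mode constant, overridable per call.
- Root selection and clipping in the inversion as described above; the
  infeasible-shift error carries the quadratic discriminant.
- Bilayer decoupling brackets the root on [0, 10·E_substrate] and
  asserts monotonicity by construction (tested); zero film thickness is
  a degenerate-input error, not a silent limit.
- Table interpolation is piecewise linear (np.interp) everywhere —
  smoothness beyond C⁰ is not needed by any consumer and linear tables
  keep hand-verification trivial.
- Hysteresis loop area integrates |branch difference| on the union grid
  of both branches restricted to their common RH range (the hydration
  apex sample has no dehydration counterpart and is excluded).
- Degenerate inputs: zero-thickness layers with nonzero shift raise;
  τ = 0 with zero shift returns E = 0; I_Au > I_Au⁰ warns and clips the
  thickness at 0.

## Known limitations

- The effective dynamic strand mass is a calibration (see above); the
  package exposes both it and the chemical mass, and a user fitting real
  data should revisit it against an independent mass measurement.
- The modeled ss shift curve turns down again above ~4.2×10¹³ cm⁻²
  instead of remaining positive to the highest measured coverage; the
  thickness cap and plateau modulus bound the stiffness term while the
  mass term keeps growing.
- Water counts per strand (20/40 at RH 70) and the dry contraction
  factors are plausible placeholders, not measured values; all are
  overridable per `StrandModel`.
- The XPS instrument constant mapping corrected P ratios to areal
  density is a free calibration shared by generator and analysis; only
  ratios and round trips are meaningful, not absolute intensities.
- Static deflection is characterized (hysteresis metrics) but never
  converted to surface stress.
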