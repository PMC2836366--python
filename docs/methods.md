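# Methods

## The model

`magshell` computes the transmembrane potentials induced on a spherical cell
and on a concentric spherical organelle (a mitochondrion) by a sinusoidally
alternating magnetic field, in the quasi-static frequency-domain
approximation. The cell is a two-shell structure: two thin membranes divide
space into five homogeneous, isotropic regions — extracellular medium (0),
cytoplasmic membrane (1), cytoplasm (2), organelle membrane (3) and organelle
interior (4) — each characterised by a conductivity σᵢ and permittivity εᵢ
that combine into the complex conductivity Sᵢ = σᵢ + jωεᵢ.

The field of a circular coil, B = B₀ e^{jωt} ẑ′, enters through its vector
potential A (azimuthal about the coil axis). The induced electric field is
E = −jωA − ∇V, where the scalar potential V accounts for charge accumulating
at the dielectric interfaces and satisfies Laplace's equation in each region.
For a cell whose centre sits a distance C off the coil axis, the part of A
that is uniform over the cell has magnitude B₀C/2; its time derivative is the
uniform forcing field of complex amplitude E0 = −jωB₀C/2 (|E0| = ωB₀C/2, and
arg E0 = −90°: the pure Faraday induction lag). The locally rotational part
of A (∝ distance from the cell centre) has no radial component on the spheres
and forces nothing.

Only the degree-1, order-1 spherical harmonic is therefore excited, and in
each region

    V_n(r, θ, φ) = (C_n·r + D_n/r²)·sinθ·cosφ.

Regularity (V finite at the origin, the far field unperturbed) removes the
growing term of region 0 and the decaying term of region 4, leaving eight
complex coefficients fixed by continuity of V and of the normal current
density Sᵢ·(−∂V/∂r − jωA_r) at the four interfaces R₊, R₋, r₊, r₋. The
transmembrane potentials are potential differences across each thin shell,
outer minus inner:

    ψ_cell = V(R₊) − V(R₋),    ψ_org = V(r₊) − V(r₋),

both proportional to sinθ·cosφ. The factor in front — the amplitude
coefficient — carries the maximal polarisation over the sphere (|ψ| peaks on
the equator, vanishes at the poles) and the phase relative to the applied
field.

### Frame and sign conventions

Time convention e^{+jωt}; phases are the arguments of the complex phasors and
map to (−180°, 180°]. The azimuth origin is a free choice — physically it is
set by where the cell sits around the coil axis, and rotating it by 180°
flips the sign of the forcing. `magshell` places the azimuth origin at the
*depolarised* equatorial lobe of the membranes (applied radial field
−E0·sinθ·cosφ), so the reported phase is that of the transmembrane potential
at its depolarisation maximum. In this frame a low-frequency cell membrane
reads close to −90° (induction lag plus a small membrane-charging term), a
convention that makes the phase columns directly comparable with the applied
field's phase.

Table radii are interpreted as *outer* radii; inner radii are derived by
subtracting the membrane thickness. For 5 nm membranes on micrometre spheres
the numerical difference is negligible, but one convention has to be fixed.

## Parameters

Standard values and physiological ranges (SI internally; the config/CLI
boundary uses S/m, As/Vm, µm, nm, T, kHz, mm):

| parameter | standard | range | role |
|---|---|---|---|
| σ₀ | 1.2 S/m | — | extracellular conductivity |
| σ₁, σ₃ | 3×10⁻⁷ S/m | 10⁻⁸–10⁻⁶ (σ₁), 10⁻⁸–10⁻⁵ (σ₃) | membrane conductivities |
| σ₂, σ₄ | 0.3 S/m | 0.1–1.0 | cytoplasm / organelle interior |
| ε₀ | 6.4×10⁻¹⁰ As/Vm | — | extracellular permittivity |
| ε₁, ε₃ | 4.4×10⁻¹¹ As/Vm | 1.8–8.8×10⁻¹¹ | membrane permittivities |
| ε₂, ε₄ | 6.4×10⁻¹⁰ As/Vm | 3.5–7.0×10⁻¹⁰ | bulk permittivities |
| R | 10 µm | 5–100 µm | cell outer radius |
| D | 5 nm | 3–7 nm | cell membrane thickness |
| r | 3 µm | 0.3–5 µm | organelle outer radius |
| d | 5 nm | 1–8 nm | organelle membrane thickness |
| B₀ | 2 T | — | field intensity |
| f | 10 kHz | 2–200 kHz | field frequency |
| C | 10 mm | — | coil-axis offset |

The coil-axis offset C is not part of the published parameter table and the
reference results never state it. The package default of 10 mm was calibrated
once against the low-frequency closed form: with ψ ≈ 1.5·|E0|·R and
|E0| = ωB₀C/2, C = 10 mm reproduces the reference 9.397 mV cell amplitude at
10 kHz to within 0.3%. All amplitudes scale exactly linearly in C (and in
B₀), so this one constant sets only the overall scale, never the shape of
any response; C is always exposed in configuration, never hard-coded.

## Numerical choices

* The eight boundary equations are assembled as a complex 8×8 system and
  solved by LU decomposition per evaluation (microseconds; exact to machine
  precision and immune to transcription error, so the closed-form coefficient
  expressions are never expanded symbolically). Radii are nondimensionalised
  by R₊ and each current-continuity row is scaled by the larger adjacent
  admittance; the condition number at standard parameters is ~1.3×10⁵, and a
  warning is raised above 10¹².
* Transmembrane potentials are evaluated from the membrane region's own
  coefficients with the small radius difference factored out of both terms,
  so thin shells cost no precision to subtractive cancellation.
* f = 0 short-circuits to the all-zero solution (no induction) and the phase
  of an exactly zero phasor is reported as NaN (a distinguished
  "no polarisation" marker, `null` in CLI JSON) rather than an arbitrary
  angle.
* "Maximal polarisation" is always |amplitude coefficient| — the analytic
  maximum over the sphere — never a grid search.
* Residual checks normalise each continuity equation by the larger of its two
  sides with an absolute floor of 10⁻³⁰ in SI units.
* The phase-transition radius uses the sign of Im ψ_org at a 1 kHz probe as
  the regime classifier (−90°-lag regime vs +90°-advance regime) and refines
  the crossing by bisection to 0.01 µm. The reference analysis describes the
  transition only qualitatively; this operationalisation is the package's
  own.
* Parameter sweeps re-validate the geometry at every grid point; invalid
  points (e.g. an organelle that no longer fits in the cell) are flagged
  `valid = False` with NaN responses instead of being dropped.
* Frequency grids default to log spacing at 60 points per decade.

## Independent verification

Two independent routes guard the solver:

* **Transfer-matrix (impedance-ladder) oracle.** The degree-1 amplitude pair
  is propagated across each interface with closed-form 2×2 continuity maps —
  no 8×8 assembly. The propagation is *two-sided*: outward from the organelle
  interior and inward from the far field, matched in the cytoplasm by a 2×2
  solve. (A one-directional ladder is algebraically equivalent but loses
  about seven significant digits crossing both near-insulating membranes;
  each one-membrane half-ladder keeps the agreement with the direct solve
  below 10⁻⁸ relative across 200 random in-range parameter sets, typically
  ~10⁻¹².) A test enforces that the ladder never touches the solver's
  assembly path.
* **Schwan limit.** For the organelle-free cell the classical first-order
  shelled-sphere closed form ψ ≈ 1.5·E0·R₊/(1 + jωτ), with membrane charging
  time τ = R₊·(ε₁/D)·(1/σ₂ + 1/(2σ₀)), agrees with the full solver to 0.5%
  at 10 kHz and asymptotically as f → 0. The ~−1.2° phase deviation from the
  pure induction lag at 10 kHz is the membrane RC charging term.

## Fixture generation

`random_cell` samples each tabulated parameter uniformly within its
lower/upper limits — log-uniformly for conductivities, whose ranges span
decades, linearly otherwise — and redraws geometry until the organelle fits
strictly inside the cytoplasm. Parameters without published limits (σ₀, ε₀,
B₀, C) stay at their standard values. Fixtures exercise the *model's* full
parameter space; they do not emulate biological variability beyond those
ranges, so passing fixture-based tests demonstrates numerical correctness of
the analytical solution, not predictive accuracy for any real cell.

## Limitations

* Frequency-independent σ and ε: valid below ~100 MHz; dielectric relaxation
  (σ(ω), ε(ω)) is deliberately not modelled. The configuration schema keeps
  per-region σ/ε pairs so a dispersive extension would slot in at the
  complex-conductivity evaluation, but no such hook is active.
* Sinusoidal steady state only — no pulse waveforms or transients.
* Perfectly spherical, concentric geometry; a single organelle shell (no
  separate inner/outer mitochondrial membranes); homogeneous isotropic media;
  the coil's field is taken spatially uniform over the cell.
* The quasi-static approximation neglects wave propagation and secondary
  induction.
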