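# Methods

## Physical model

The package solves the Pennes bioheat equation for homogeneous brain tissue
around an internally cooled cylindrical probe:

ρCp ∂T/∂t = ∇·(κ∇T) + ρ_b C_b ω_b(T)(T_b − T) + Q_met(T) + Q_v.

Both thermoregulation terms are exponential functions of the local tissue
temperature, ω_b(T) = a_ω e^{b_ω T} and Q_met(T) = a_Q e^{b_Q T}, with T in
°C throughout the package (at 37 °C the defaults give ω_b ≈ 8.9·10⁻³ 1/s ≈
50 mL/100 g/min and Q_met ≈ 10⁴ W/m³, i.e. physiologic magnitudes; a Kelvin
reading would be unphysical). The perfusion sink is written in the standard
dissipative form ρ_b C_b ω_b (T_b − T); the alternative sign sometimes seen
in print would make diffusion anti-dissipative. ω_b is volume-referenced
(1/s); the effective rates used each step are simply the exponentials
evaluated at the current local temperature. Q_v defaults to zero: the probe
enters as a boundary condition, not a volumetric source.

Two useful derived quantities:

* **Equilibrium temperature** T*: the root of
  ρ_b C_b ω_b(T)(T − T_b) = Q_met(T) + Q_v, found by Brent's method on
  [0, 45] °C. With defaults, T* ≈ 37.0 °C (arterial 36.7 °C plus a
  ≈0.3 °C metabolic offset), consistent with holding the outer boundary at
  37 °C.
* **Thermal penetration length** λ = √(κ/(ρ_b C_b ω_b)) ≈ 3.9 mm at 37 °C.
  λ controls everything about focal cooling: the steady field around a long
  probe is T(r) = T∞ + (Ts − T∞) K₀(r/λ)/K₀(a/λ), so clinically relevant
  cooling is confined to roughly 3λ–4λ from the axis.

### Parameters (defaults; all overridable by config key)

| parameter | default | units | note |
|---|---|---|---|
| tissue ρ, Cp, κ | 1040, 3250, 0.51 | kg/m³, J/(kg·K), W/(m·K) | grey-matter literature values |
| a_ω, b_ω | 0.0012, 0.054 | 1/s, 1/°C | perfusion exponential |
| a_Q, b_Q | 342.45, 0.091 | W/m³, 1/°C | metabolism exponential (a_Q = 0 allowed) |
| blood ρ_b, C_b | 1050, 3600 | kg/m³, J/(kg·K) | standard blood values |
| T_b | core − 0.3 = 36.7 | °C | arterial temperature |
| probe OD, tip length, Ts | 3.3, 25, 15 | mm, mm, °C | tip lengths 12.5/25/50 assessed |
| domain | 8·10⁶ mm³, boundary 37 °C | | equal-volume cylinder in (r,z) mode |

The perfusion/metabolism exponentials are fits to in-vivo data with no
stated validity range; the package clamps nothing and warns outside
[0, 45] °C.

## Discretization and solver

* **Geometry.** Default is an axisymmetric (r, z) reduction: the cubic
  region of interest is replaced by an equal-volume cylinder (radius
  112.84 mm for height 200 mm) with 37 °C Dirichlet data on all outer
  boundaries — an approximation that is excellent because the cooled front
  never approaches the boundary. A 3-D tensor-grid mode cross-checks the
  reduction. The probe is a capped cylinder centred in the domain; its
  nodes are excluded from all tissue metrics.
* **Scheme.** Conservative finite volumes on graded grids: 0.5 mm spacing
  near the probe (configurable), growing geometrically to 4 mm at the far
  boundary. The diffusion operator is a symmetric positive-definite graph
  Laplacian with harmonic-mean face conductivities; in (r, z) the face and
  cell metrics carry the 2πr weight exactly.
* **Time integration.** Implicit Euler, unconditionally stable. The
  nonlinear coefficients are lagged and corrected by fixed-point iteration
  to 10⁻⁶ °C per step. The step grows geometrically (factor 1.2) from 1 s
  to a 60 s cap for one-hour design runs; clinical-scale validation runs
  use a fixed 1 s step (`SolverOptions(dt_max=1)`). Steady solutions use
  the same lagged fixed point without the time term (damped on
  non-contraction) and report a relative nonlinear residual, ≤10⁻⁸ in
  practice.
* **Probe representation.** Default is a Dirichlet surface at the observed
  outer-surface temperature (≈15 °C for the clinical device). A conjugate
  sapphire-shell model (fixed internal coolant temperature, conductive
  shell with no perfusion/metabolism) is available in axisymmetric mode for
  studying material effects; it requires h_fine ≤ shell thickness. In 3-D
  the staircase probe surface is classified half-cell-inclusively
  (node within a + h/2), which centres the staircase's effective radius on
  the nominal one; with 0.4–0.5 mm near-axis spacing the 3-D mid-height
  profile agrees with the axisymmetric solution within 2 % of the
  temperature drop (r ≥ 4 mm) and VOTC volumes within 3 %.
* **Verification.** With coefficients frozen at 37 °C and an effectively
  infinite probe (insulated axial boundaries), the steady solution matches
  the K₀ closed form within 0.2 % of the temperature drop for
  r ∈ [a, 15 mm]; halving the near-probe spacing changes the 136 s
  mild-area metric by <1 %.

## VOTC metrics

Mild/moderate/profound strata use strict thresholds T < 36/34/32 °C. Areas
are evaluated in the axial plane at the probe tip's mid-height, volumes by
2πr dr dz integration (axisymmetric) or slab-wise voxel integration (3-D),
in both cases after linear resampling onto a fine auxiliary grid (0.02 mm
radial for areas, 0.25 mm for volumes), so isotherm locations are resolved
far below the solver grid. Probe-occupied space is excluded — it is not
tissue. On continuous phantoms with known isotherms the disc area and
sphere volume are reproduced to <1 %.

## MR-thermometry emulation

`synthesize_stack` resamples model fields onto the acquisition grid
(2×2×5 mm voxels, probe axis centred, 3 axial slices, ~7.8 s frame
spacing) and adds i.i.d. Gaussian noise per voxel (seeded; the default
0.5 °C is a typical phase-difference thermometry noise level at these voxel
sizes). Voxels within 3 mm of the probe axis are flagged unreliable,
mirroring the susceptibility artifact. `postprocess_stack` reproduces the
clinical chain exactly: per-axial-slice 2-D Gaussian filter (σ = 0.8
acquisition voxels) followed by order-3 spline resampling to 0.5×0.5×5 mm;
it refuses to run twice so data can never be silently double-filtered.
Radial statistics collect voxels intersecting concentric circles (0.5 mm
bins by default) outside the artifact radius and report mean ± standard
error; the probe centroid defaults to the coldest voxel of the final frame.
Cooled-area time series infill the artifact core from the nearest reliable
voxels before thresholding.

What the emulation does and does not capture: it reproduces the geometry,
sampling, artifact footprint and additive noise level of the clinical
chain, so round-trip and statistical properties of the *pipeline* are
fully testable (noiseless round trip recovers a smooth radial phantom to
<0.05 °C; ring standard errors scale as 1/√n within a few percent). It does
not model MR phase physics, motion, drift, or spatially correlated noise —
passing tests say nothing about those. One bias is inherent and worth
noting: Gaussian filtering adds ≈(σ_mm²/2)·∇²T to any field, which near a
probe (large curvature) can exceed 0.5 °C. For this reason the `validate`
command compares an observed stack against the model prediction *pushed
through the identical postprocessing*, never against raw model values, so
reported model–data differences are free of this common-mode blur bias.

## Design sweeps and inverse design

`run_sweep` solves one independent one-hour transient per (surface
temperature, tip length) cell — cells are pure functions of their
parameters, so results are order-invariant and failed cells are flagged
without aborting the sweep. "One hour of cooling" is a transient to
t = 3600 s, not a steady solve, because the mild stratum is still slowly
expanding at clinical time scales. `required_surface_temperature` inverts
the monotone mild-volume-vs-temperature curve with a PCHIP interpolant
(monotonicity violations raise — they indicate solver trouble — and
unreachable targets return infeasible rather than extrapolating).
`length_effect_report` compares per-stratum maxima over the temperature
grid across lengths; the maxima occur at the coldest temperature.

## Known limitations

* **Design-phase extrapolations.** With the stated parameter set the model
  has a hard ceiling on mild-hypothermia volume: the rewarming front sits
  at ≈36 °C where perfusion is near physiologic, so λ ≈ 4 mm there and the
  standard probe saturates at ~15–18 cm³ of mild volume even at 0 °C —
  consistent with the clinical observation of minimal cooling beyond 13 mm,
  but far below some published one-hour design figures (e.g. 100 cm³
  targets), which would require an effective volumetric coupling roughly an
  order of magnitude weaker (λ ≈ 12 mm). A sensitivity scan showed that
  scaling both source magnitudes by a common factor preserves the 37 °C
  equilibrium and reproduces such figures at c ≈ 0.1, at the price of
  breaking the clinical-scale quantities (the stable 3 mm reduction rises
  from ≈8 °C to ≈13 °C). The package keeps the stated parameters; users can
  explore the weak-coupling regime through the blood and tissue property
  keys.
* Homogeneous brain only: no sulci, ventricles, vasculature, skull or
  scalp; no tissue-specific parameter maps.
* Arterial temperature is constant (no systemic-cooling feedback).
* No convective losses anywhere; the probe shaft above the cooled tip is
  treated as tissue.
* The 3-D mode has a staircase probe surface; quantitative work should use
  the axisymmetric mode, with 3-D reserved for cross-checks and
  asymmetric extensions.
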