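# Methods

## Model summary

The solver couples three layers:

1. **Fluid** — D2Q9 lattice-Boltzmann, single-relaxation-time (BGK)
   collision, Guo body-force scheme with the half-step velocity correction,
   so the Chapman–Enskog viscosity is ν = (τ − ½)c_s²Δt with c_s = h/(√3Δt).
   Walls are halfway bounce-back (with the moving-wall momentum correction
   for the shear driver); the channel direction is periodic.  A per-node
   relaxation time carries the cytoplasm/plasma viscosity contrast
   (6.0 / 1.2 cP, ratio 5); mass density is uniform (1 g cm⁻³).
2. **Coupling** — immersed boundary method with the 2D cosine kernel on a
   4h × 4h support, normalized as an exact partition of unity
   (φ(0) = 1/(4h²)); velocity interpolation and force spreading use the
   identical kernel, making them exact adjoints and conserving total spread
   force to machine precision.  Near walls the out-of-domain part of the
   kernel support is folded back by mirror reflection in both operations,
   preserving both properties.  Membrane nodes advect by forward Euler.
   The cell interior is labelled every step by a scanline interior fill of
   each membrane polygon (equivalent to a flood fill for simple polygons).
3. **Membrane** — closed node ring with neo-Hookean segment tension,
   turning-angle bending about the spontaneous curvature, a pressure
   penalty conserving the enclosed (shoelace) area, and Morse cell–cell
   forces, all optionally multiplied by the strain-hardening coefficient
   α(λ) = 1 + D_LD(e^{λβ_LD} − e^{β_LD}) according to the Case I/II/III
   flags.

All internal arithmetic is in lattice units; `LatticeScales` owns the
conversion (powers of h, Δt, ρ₀ per unit tag).  The 2D world is per unit
depth: nodal forces are line forces [dyn cm⁻¹].

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| E_s (membrane shear modulus) | 6·10⁻³ | dyn cm⁻¹ | published physiological value |
| μ_cyto / μ_plasma | 6.0 / 1.2 | cP | published |
| r₀, β, D_e (Morse) | 0.49, 3.84, 1.3·10⁻⁷ | µm, µm⁻¹, surface energy | published |
| a (cell radius for G) | 4.17 | µm | chosen so G(μ_plasma, 150 s⁻¹, a) = 0.125, the quoted reference point; the 12-cell/38%/80×20 µm packing independently implies ≈ 4.02 µm, which the fixture generator uses |
| E_b (bending modulus) | 1·10⁻¹⁰ | dyn cm | free parameter; see "Bending stiffness" |
| k_p (area penalty) | 200 | dyn cm⁻² | free parameter; see "Area conservation" |
| D_LD, β_LD (hardening) | 2.34·10⁻⁴, 8 | – | calibrated; see below |
| R_active (interaction cutoff) | r₀ + 5/β ≈ 1.79 | µm | force decayed below 1% of its scale |
| h (lattice spacing) | 0.25 (channel studies use 1.0, shear studies 0.5) | µm | resolution choice |
| τ_plasma | 0.8 | – | sets Δt via ν_plasma |
| N nodes per cell | 80 (studies use 36–48) | – | Lagrangian spacing ≲ h |

### Calibration of D_LD (scripts/calibrate_ld.py)

The hardening constants are not fixed by theory.  β_LD is held at 8 and
D_LD is bisected (in log space) so that a single cell in simple shear at
G = 0.5 reaches the steady perimeter-extension ceiling λ_C ≈ 1.12 — the
strain level the full model exhibits at the highest studied shear rate
(channel ensemble 1.125 ± 0.040 at 500 s⁻¹).  Because the ceiling value
trades off against the stability of the crowded multi-cell runs, the
procedure has a second stage: if Case III channel runs at 500 s⁻¹ fail by
membrane buckling, D_LD is raised to the smallest value restoring
completion, provided the single-cell ceiling stays inside 1.125 ± 0.040.
The shipped default D_LD = 2.34·10⁻⁴ gives a single-cell ceiling of ≈ 1.08
at G = 0.5 and completes the channel matrix across packing seeds.

### Bending stiffness

The discrete ring buckles at the node scale when the compressive
neo-Hookean tension exceeds roughly E_b/ds² (ds the node arclength).  At
the channel study resolution (h = 1 µm, 36 nodes per cell) that demands
E_b ≈ 10⁻¹⁰ dyn cm — substantially above the physiological bending/shear
ratio, and the price of the coarse discretization.  Sensitivity: at
4·10⁻¹¹ about half the packing seeds fail by pinching at 500 s⁻¹; at
10⁻¹⁰ all sampled seeds complete; single-cell D_xy at G = 0.5 drops by
≈ 0.03 between those two values.

Two bending-related discretization choices matter for robustness:

* **Curvature estimator.**  The circumscribed-circle (Menger) curvature of
  a three-node fold-back cusp is *zero* — the bending force would vanish in
  exactly the pinching configurations the hardened bending must oppose.
  The signed turning-angle curvature κ = θ/ds₀ is used instead (analytic
  gradient, finite-difference verified); it diverges toward ±π/ds₀ at a
  cusp.
* **Hardening argument.**  At a pinch the local segments are compressed
  (λ < 1, where α is clamped at 1), so bending is scaled by
  α(max(λ_local, λ_C)): a globally stretched cell stiffens its compressed
  pinching regions, which is the stated purpose of hardening the flexural
  resistance.

Two further robustness devices: a repulsion-only contact guard between
same-cell nodes at least two apart along the ring (active only below r₀;
rest-shape chords at that separation are ~3× r₀, so it is inert for healthy
shapes), because a membrane folding onto itself has no sub-kernel
hydrodynamic resistance in IBM; and the self-intersection abort fires only
when the intersection persists over five consecutive metric frames, since a
single crossing segment of a resolving node spike heals under the bending
and contact forces.  Persistent intersections (the Case I over-stretch
mode) abort the run with the outcome recorded on the metrics series.

### Area conservation

k_p = 200 dyn cm⁻² holds a quiescent or sheared single cell's area to
within 0.15%.  In the crowded channel the cells ride a dynamic pressure
field and individual areas deviate transiently by up to ~2%; raising k_p
to 800 does not remove this (it is crowding-pressure-driven, not
penalty-limited) but does degrade membrane stability, so 200 is kept.  The
areal hematocrit (sum over cells) stays within ±0.5 percentage points of
38% in all Case III runs.

### Morse surface-energy unit

The printed interaction constants (0.49 µm, 3.84 µm⁻¹, 1.3·10⁻⁷ in a
micrometre-based surface-energy unit) are kept verbatim as defaults, but a
literal µJ µm⁻² reading (0.13 J m⁻²) would overwhelm the elastic scale E_s
by ~10⁵ and exceed measured depletion-mediated RBC adhesion energies
(~10⁻⁷–10⁻⁶ J m⁻²) by the same factor.  The unit is therefore mapped as
J m⁻² when converting the pair force to CGS (`MORSE_ENERGY_TO_CGS`),
giving an interaction-to-elastic force ratio of a few percent, consistent
with the intended aggregation behaviour.  Nodal interaction force = pair
force per area × rest node arclength, applied equal-and-opposite along the
connecting line (momentum-exact).

## Experiments and the scaled-down study conditions

**Simple shear**: one cell centred between counter-moving walls (u = ky,
k = U/Y), integrated until the Taylor index is steady (change of its
1/k-window mean < 2·10⁻³) or a 12/k budget expires (then the trailing
average is reported with a warning).

**Channel**: cells packed in two staggered rows at the target hematocrit
(radius from the exact area fraction), recycled through the periodic ends.
The pressure drive is an equivalent uniform body force G_x (a true open
pressure boundary is incompatible with recycling the cells); G_x is tuned
to the target pseudoshear during a development window of 2 transit times,
then frozen, and ΔP = G_x·L enters the Poiseuille inversion.  A small
seeded jitter (0.05 µm RMS) in the initial packing breaks the mirror
symmetry of the arrangement so the flow develops within the short
simulated window.  Metrics are averaged over the analysis window
(`transit_cycles` material transit times; the reference configuration uses
3 after the 2 development cycles; the per-frame maximum membrane shear
stress entering τ_max is sampled at the metric-frame cadence, ~40 frames
per transit).

**Dynamic-similarity speedup.**  In the Stokes regime the solution depends
on force *ratios* only, so multiplying every membrane force scale
(E_s, E_b, k_p, D_e) and every imposed rate by a common factor S leaves
G, G*, λ_C, D_xy, CFL fraction and μ_rel invariant while shrinking the
simulated window (and hence the step count) by S.  The reference
configuration uses S = 30 for shear and S = 18/6/1.8 for the 50/150/500 s⁻¹
channel runs, keeping the lattice Mach number below 0.01 and the channel
Reynolds number below ≈ 0.3; a test verifies deformation invariance
between S = 20 and S = 40.

Reference study conditions (tests and examples): shear — h = 0.5 µm,
τ_plasma = 1.1, 50×50 lattice, 48 nodes/cell; channel — h = 1.0 µm,
τ_plasma = 0.8 (τ_cyto = 2.0), 80×20 lattice, 36 nodes/cell, 12 cells,
packing seed 1.  These are aggressive reductions chosen so the whole
experiment matrix runs in minutes on one core.

**τ_max / G*** — the maximum over membrane nodes of the viscous
shear-stress magnitude μ·√((∂u/∂x − ∂v/∂y)² + (∂u/∂y + ∂v/∂x)²)
(Mohr-circle radius), from central-difference velocity gradients
interpolated to the nodes with the IBM kernel, using the plasma (exterior)
viscosity.  **CFL width** — per frame and per wall, the distance from the
wall to the nearest membrane point anywhere along the channel, summed over
the two walls, time-averaged, as a fraction of the width.

## What the scaled-down conditions do and do not show

They reproduce: the hardening ceiling (single-cell ε < 0.18 at G = 0.5 and
monotone D_xy(G)); the case ordering λ_C(I) ≫ λ_C(II) ≈ λ_C(III) at 150
and 500 s⁻¹ with the Case I over-stretch failure at 500 s⁻¹; Case III
ensemble λ_C within a few percent of the reference values
(≈1.04/1.09/1.11–1.14 vs 1.044/1.083/1.125 at 50/150/500 s⁻¹); a CFL
fraction of ≈ 22–25% (reference ~26%); hematocrit conservation.

They do **not** reproduce the reference relative viscosity of 1.10: the
measured value is ≈ 1.8–2.1.  With the measured CFL fraction (~0.22) a
two-layer Poiseuille model brackets μ_rel between ~1.3 (core viscosity
1.3× plasma) and ~1.9 (rigid core); at h = 1 µm with ~1–2 lattice nodes in
the lubrication gaps, the packed circular cells shear like a nearly rigid
core and land at the upper bound.  Resolving the gaps (h ≤ 0.25 µm) is the
expected remedy but is outside the desk-scale budget.  Related known
limitations: Case I at 150 s⁻¹ also fails by over-stretching here (at full
resolution it completes with λ_C ≈ 1.23); per-cell areas deviate up to ~2%
transiently; and the single-cell and multi-cell (G*, ε) points collapse
only partially onto one saturating-exponential fit (R² ≈ 0.995 for the
shear set but ≈ 0.7 for the channel set, against ≈ 0.94 at full scale) —
at this resolution near-wall cells in the channel carry more strain per
unit measured membrane stress than isolated sheared cells.

The generator emulates idealized circular resting cells in plane channels:
no biconcave profiles, no membrane viscosity, no fibrinogen-dependent
aggregation strength, strictly 2D mass conservation.  Conclusions about
real microvessel flows should treat the rheology quantitatively (μ_rel,
absolute τ_max) with caution while the deformation phenomenology (strain
ceilings, case contrasts, CFL formation) is robust.

## Numerical guards and degenerate inputs

Lattice Mach |u| > 0.3 or any non-finite velocity aborts with a diagnostic
status; τ ≤ ½ is rejected and τ ≥ 2 warns; extents < 8 lattice nodes are
rejected; collinear curvature triplets return κ = 0; the quadratic 3D→2D
shear-rate conversion warns when its output is non-positive (not
meaningful at very low shear); pairing ties break on the lowest
(cell id, node id); unknown configuration keys are errors.
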