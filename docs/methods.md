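# Methods

`cardioloop` is a reduced-order, closed-loop model of left-ventricular (LV)
mechanics built to study one question: how does the longitudinal stiffness
of the ascending aorta (AA) load the ventricle and degrade its function?
During systole the LV shortens along its long axis, the atrioventricular
(AV) plane descends toward the (stationary) apex, and the aortic root is
dragged apex-ward, stretching the ascending aorta. A stiff aorta resists
that stretch, so the force the ventricle spends pulling on the aortic root
is lost to ejection. The package quantifies this mechanism with
pressure-volume (PV) loops, regional myocardial strains and
volume-averaged myofiber stress under three conditions:

* **baseline** — aortic-root spring 0.5 N/mm, ventricular contractility
  Tmax = 0.2 MPa;
* **stiff_aa** — root spring 10 N/mm (a practically immobilized
  sino-tubular junction), Tmax = 0.2 MPa;
* **stiff_aa_inotropy** — root spring 10 N/mm with contractility doubled
  to Tmax = 0.4 MPa, the expected neuro-humoral compensation.

## Constitutive model

**Passive.** The myocardium is an incompressible, orthotropic hyperelastic
solid with the Holzapfel–Ogden strain energy

Ψ = a/(2b)·exp[b(I₁−3)] + Σ_{i∈{f,s}} a_i/(2b_i)·(exp[b_i(I₄ᵢ−1)²]−1)
  + a_fs/(2b_fs)·(exp[b_fs·I₈fs²]−1),

with the fiber and sheet terms active only in tension (I₄ > 1): collagen-
reinforced fiber families do not stiffen in compression. Ventricular and
atrial parameter rows are shipped as fixtures (`data/materials.yaml`);
stresses are in MPa, lengths in mm, times in s.

The reported second Piola–Kirchhoff stress is `S = 2∂Ψ/∂C − p C⁻¹` with
the reaction pressure `p` fixed by the convention that the transmural
(sheet-normal) component vanishes. Because the reduced kinematics enforce
det F = 1 identically, any multiple of C⁻¹ does zero virtual work, so this
convention does not affect equilibrium; it makes the stress vanish at the
reference state and makes the fiber component equal the isochoric energy
gradient, which is how the finite-difference test oracles are phrased.

**Sheet orientation.** The local frame is (fiber, sheet, sheet-normal)
with the fiber at the transmurally varying helix angle in the wall tangent
plane, the sheet along the cross-fiber *in-plane* direction and the
sheet-normal transmural. This choice is deliberate and matters: systolic
wall thickening reaches radial stretches of 1.4–1.6, and a continuum
accommodates it by sheet shear and slippage between myocyte laminae. A
diagonal reduced kinematics cannot represent that shear; if the stiff
exponential sheet family were placed transmurally, I₄s = λ_r² ≈ 2 would
put the sheet term deep in its exponential and block physiological
thickening at absurd stress levels. With the sheet in-plane, thickening is
resisted only by the isotropic term, while the in-plane sheet family and
the I₈fs coupling still contribute anisotropy where the tissue really is
anisotropic.

**Active.** Fiber tension follows a length-dependent time-varying
elastance:

σ_a(t, E_ff) = (Tmax/2) · Ca₀²/(Ca₀² + ECa₅₀²(l_eff)) · (1 − cos ω(t)),

with l_eff = l_r·√(2E_ff+1), ECa₅₀ = Ca₀max/√(exp[B(l_eff−l₀)]−1), the
relaxation duration t_r = m·l_eff + b, and the phase ω rising linearly to
π at t₀ and continuing to 2π over the relaxation window so the envelope
closes exactly at t₀+t_r. Below l₀ no force develops. The calcium
sensitivity falling with length encodes the Frank–Starling effect.

Because the geometric reference is the end-diastolic (ED) state while
sarcomere length in this law is absolute, the fiber stretch entering the
force-length terms is premultiplied by a uniform **ED fiber prestretch**
(`RunConfig.fiber_prestretch`, calibrated; the corresponding ED sarcomere
length is l_r·prestretch ≈ 2.0–2.1 µm, at the upper physiological range,
as expected at end-diastole). Without it the force-length term would shut
off at normal systolic shortening. The activation clock restarts at each
cycle onset; a single global activation (no excitation propagation) is
used and t₀ = 0.35 s carries the timing.

## Synthetic geometry

The proprietary anatomical heart geometry behind the study is not
available, so a truncated thick-walled prolate ellipsoid stands in: an
endocardial ellipsoid of revolution solved to enclose the target ED cavity
volume (158.3 mL) at the configured long-axis length, offset outward by a
uniform wall thickness and cut by a flat basal plane. Material points on a
(meridian × circumference × transmural) grid carry quadrature volumes
(normalized exactly to the wall volume), a rule-based helix-angle field
(+60° endo to −60° epi by default, linear in depth), orthonormal local
frames, and a 4 circumferential (septal/anterior/lateral/posterior) × 3
axial (basal/mid/apical) region partition. The seed rotates the
circumferential sampling and the pericardial spiral; the continuum
geometry is seed-independent.

Boundary attachments:

* **49 pericardial sites** on a golden-angle spiral over the epicardium,
  spring stiffness graded from apex (high) to base (low). Each spring
  loads only the displacement component along the reference outward
  surface normal — a pericardial sac resists radial excursion but lets the
  wall slide tangentially, and at the apex cap, where the normal is axial,
  it pins the apex (apex displacement stays below 2 mm in all scenarios).
  Isotropic point springs cannot reconcile an 11 mm basal excursion with a
  constrained epicardial radius; normal springs can. The springs are also
  distension-stiffening: outward displacement is resisted 8× more strongly
  than inward motion, through a smooth monotone softplus force law
  (transition width 0.1 mm) whose energy is the exact dilogarithm
  antiderivative. This mirrors the sac's constraint on acute dilation and
  matters for the closed loop: without it, mild aortic stiffening raises
  filling pressure enough to transiently *increase* stroke volume through
  the Frank–Starling response, masking the aortic-load mechanism.
  Stiffness values are calibration parameters bounded by the kinematic
  targets.
* **Aortic-root attachment** on the basal ring with coupling weights over
  the four circumferential regions (default septal 0.4, anterior 0.3,
  posterior 0.2, lateral 0.1, reflecting the aorto-mitral continuity next
  to the septum) and a root-motion ratio < 1: the sino-tubular junction
  sits above the annular plane and travels a fraction of the annular
  excursion (annular excursions of ~16 mm coexist with ~11 mm root
  travel). The AA spring energy is ½·k_aa·d_root², so the same weights
  route the spring reaction back into the regional stretches — the septal
  region carries the largest share of the aortic load, which is why septal
  longitudinal strain is the most sensitive to k_aa.

## Reduced kinematics

Nine generalized coordinates describe the wall: a rigid apex-base
translation mode (`d_avp`, held near zero by the apical springs — the
physiological AV-plane displacement is the stretch contribution
L·(1−λ_long) reported through the basal-ring motion), four regional
longitudinal stretches blended C0 around the circumference, three axial
endocardial-radius scales blended along the axis, and one cos 2θ ovality
mode. Through-wall kinematics treat each level as a locally cylindrical
incompressible thick shell: r′(R)² = (ρR_endo)² + (R²−R_endo²)/λ_long,
giving λ_c = r′/R, λ_r = R/(λ_long·r′) and det F = 1 exactly, with the
physiological transmural gradient (endocardial strains exceed epicardial).
Cavity volume is the divergence-theorem volume of the deformed
endocardial surface (triangulated side wall, apical fan, basal cap) with a
constant discretization correction that makes the reference volume exact.

## Equilibrium and prestress

Quasi-static equilibrium per time step by virtual work: the quadrature sum
of (passive + active) stress contracted with the strain variations of each
coordinate balances cavity-pressure work, pericardial springs and the AA
spring. Pressures convert to stress units through 1 mmHg = 1.333·10⁻⁴ MPa,
stated and tested once. Because the reference is the in-vivo ED state, a
constant generalized prestress (the pressure-work gradient at the
reference EDP, 11.85 mmHg) makes the reference geometry an exact
equilibrium at that pressure — the reduced-order analogue of the inverse
prestress step image-based FEM models perform.

The solver is damped Newton with a finite-difference Jacobian, Broyden
rank-1 updates between refreshes, a per-coordinate step cap, non-monotone
acceptance (the scaled max-norm may spike transiently before the quadratic
phase) and step-halving fallback; convergence at 1e-8 of the
characteristic force scale (the 100 mmHg pressure-work gradient at
reference). Warm starts from the previous time step make typical in-cycle
solves converge in a handful of iterations. There is no randomness
anywhere in the solver.

## Circulation and coupling

The closed loop has four compartments: LV (volume from mechanics),
arterial compliance, pulmonary-venous compliance, and a lumped left atrium
(passive elastance plus an active elastance shaped by the atrial
activation waveform — short 0.05 s time-to-peak — timed in late diastole).
Valves are ideal diodes with small open resistances; no inertance or
regurgitation; the right heart is absent and venous return closes directly
into the pulmonary-venous chamber. Every flow debits one compartment and
credits another within the same update, so total blood volume is conserved
to machine precision over arbitrarily many steps.

Per step, the LV pressure is the root of a scalar volume-match residual:
mechanics volume at that pressure versus the flow-balance volume at the
same pressure (implicit in p_lv, explicit in the other chamber pressures).
A safeguarded secant/bisection iteration with a slope memory solves it to
1e-6 mL; the LV volume carried forward is the flow-balance value, keeping
conservation exact. Cycles repeat until the end-diastolic volume is
periodic (default tolerance 0.5 mL, at most 10 cycles); the default time
step is 5 ms over a 1.0 s cycle (heart rate and step are model choices,
stated here, and halving the step changes cycle-averaged pressures by well
under 0.5%).

## Problem sizes

Production runs use 216 material points (6 axial × 12 circumferential × 3
transmural), a 36 × 36 endocardial surface grid for cavity-volume
integration, dt = 5 ms over a 1.0 s cycle, and at most 10 cycles to the
limit cycle at the 0.5 mL periodicity tolerance; these sizes are the
package's defaults and are refinement-checked by the geometry and
integrator-consistency tests.

## Calibration

The circulation has no published parameter values for this study, so the
defaults in `data/default_config.yaml` are calibrated so that the baseline
scenario lands on the published operating point (EDV 158.3 mL,
EDP 11.85 mmHg, ESP 117.1 mmHg, SV 92.2 mL, systolic root displacement
≈ 11 mm) with all material parameters fixed at their table values. The
calibration surface comprises: total blood volume and slack volumes,
systemic resistance and compliances, atrial elastances, wall thickness,
pericardial stiffness pair, root-motion ratio and the ED fiber prestretch.
Scenarios B and C change **only** k_aa and Tmax on top of the same
calibrated configuration.

## Metrics and conventions

* ED = maximum LV volume of the converged cycle; ES = minimum.
* SV = EDV − ESV exactly; MAP = time-averaged arterial pressure;
  SW = SV·MAP, stored in mmHg·mL. The tabular output labels the stroke-
  work column "Joule" to mirror the layout convention of the tables it
  replicates, but the magnitudes are mmHg·mL (8747.5 mmHg·mL ≈ 1.17 J);
  loop areas (shoelace over the (V,P) cycle, positive counterclockwise)
  agree with SV·MAP to within ~10% at converged operating points.
* Strains are engineering strains between ED and ES states sampled at 12
  locations (4 circumferential × 3 axial) at epicardium and endocardium,
  layers averaged per site before family statistics; radial positive for
  thickening, circumferential/longitudinal negative for shortening.
  Radial/circumferential families report mean ± sd over the 3 axial
  locations, longitudinal over the 4 circumferential regions.
* Myofiber stress is the quadrature-volume-weighted mean at ES of the
  Cauchy-equivalent total fiber stress I₄f·(S_ff,passive + σ_a) (the
  push-forward of the fiber PK2 component under det F = 1).
* Percent change = 100·(comparison − reference)/reference, rounded only at
  presentation. For stress comparisons both the percent change of the
  means and the volume-weighted mean of pointwise percent changes are
  reported; they differ and neither is privileged.

## What the synthetic geometry does and does not emulate

It reproduces the quantities the analysis needs — ED cavity volume, wall
volume, transmural fiber architecture, the 12-site regional sampling
lattice, 49 graded pericardial attachments, a septal-weighted aortic-root
attachment — on an idealized ellipsoid. It does not contain papillary
muscles, mitral apparatus, trigones or an anatomical outflow tract, so
local stress hot spots at those structures are outside the model; only
volume-averaged and region-averaged quantities are comparable. Absolute
simulated values are therefore expected to be directionally and
order-of-magnitude faithful, not exact; the percent-change arithmetic of
the reporting layer, by contrast, is exact by construction.

## Numerical choices and degenerate inputs

Tension-only anisotropy switches at I₄ = 1 (energy is C1 there).
Exponential overflow in the passive law raises a diagnostic naming the
offending term. Strains with 2E_ff+1 ≤ 0 are rejected in the sarcomere
map; in the active-stress evaluation that regime simply produces zero
force (below-slack). Inadmissible deformation states (non-positive
stretches, inverted wall) raise typed errors. The circumferential blend
width (0.5 rad) and axial hat blending are C0 partitions of unity;
region labels are nearest-center. Valve flows are exactly zero at
non-positive pressure gradients (no smoothing); the coupled step iterates
the kink implicitly.

## Known limitations

No torsion mode (the ansatz has no twist coordinate, so torsional
contribution to ejection is folded into the calibrated radial/longitudinal
partition); no sheet shear (see above); no inertia; a lumped atrium and no
right heart; no baroreflex or contractility feedback (deliberate, matching
the study design); AA wall material is not modeled — aortic stiffness
enters only through the root spring; chronic remodeling is out of scope.
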