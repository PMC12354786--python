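# Methods

## Conventions

Stretches are dimensionless: the axial stretch λ_ax is deformed length
over initial length along the pull direction, the transverse stretch
λ_tr deformed over initial width in the sheet plane; both are 1 in the
undeformed state.  Force is normalised per *reference* (initial)
sample width and carried in N/m ("membrane force"); tangent stiffness
is dF/dλ_ax in N/m per unit stretch.  The incremental Poisson's ratio
is ν_inc = −d ln λ_tr / d ln λ_ax, evaluated as
−(λ_ax/λ_tr)·dλ_tr/dλ_ax from a smoothed λ_tr(λ_ax) fit; ν_inc = 1 is
the area-preserving path, ν_inc = 0.5 the incompressible uniaxial one.
Angles are degrees in configuration files and radians internally.
Derivatives always come from smoothed representations, never from
finite differences of raw samples.

## Curve smoothing

`smooth_curve` fits a penalized cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) under the constraint
R² > 0.999 on the fitted samples.  The constraint alone leaves the
penalty undetermined across orders of magnitude, so the operating
penalty is the smallest of three scales:

1. **noise floor** — the penalty at which the residual sum of squares
   equals n·σ̂² (discrepancy principle), with σ̂² estimated from third
   differences (variance 20σ² for white noise; the signal-curvature
   bias is O(f‴h³), negligible at realistic sampling).  This level is
   multiplied by a fixed factor of 10³ because the derived quantities
   are *derivatives* of the fit and the value-optimal penalty leaves
   them visibly rough.  For noise-free data σ̂ ≈ 0 and the fit is
   effectively interpolating, so analytic test curves are reproduced
   to near machine precision.
2. **resolution ceiling** — the penalty whose equivalent kernel
   bandwidth h ≈ (λ·X/n)^¼ equals 4 % of the abscissa range X.  The
   narrowest features the analysis must resolve (the E₁ averaging
   window, the stiffening ramp, the ν_inc bump) are 3–15 % of the
   stretch range, so a 4 % bandwidth bounds the smoothing bias of the
   derivative on these features regardless of the apparent noise.
3. **the R² cap** — the largest penalty still satisfying R² > 0.999,
   found by log-scale bisection; it binds only for very noisy or very
   short records and guarantees the goodness-of-fit contract.

Duplicated abscissae are averaged before fitting; a record whose
noise is so large that no penalty reaches R² > 0.999 raises an error
carrying the best achievable R².

## Summary extraction

Following standard practice for three-regime membrane curves:

* E₁ and ν₁ are means of the tangent stiffness and ν_inc over the
  stretch window 1.02–1.05.
* E₂ is the mean tangent stiffness from λ\* — the first stretch, past
  the steepest point of the stiffening rise, where |dk/dλ| falls below
  0.10·(range of k)/(range of λ) — up to λ_max − 0.05.  The relative
  threshold keeps the rule scale-free.  Two refinements make it robust
  across curve families: the search starts at the maximum of dk/dλ so
  a transient flat spot between the soft regime and the rise cannot be
  mistaken for the final plateau, and the slope signal is
  moving-averaged over 5 % of the grid so residual spline wiggle on
  noisy data does not mask a plateau that is flat on the window scale.
  The default threshold fraction is 0.10: an order of magnitude below
  the regime-II slope of every curve family the package produces,
  while still terminating inside the measured window for network-model
  curves whose final regime is approached asymptotically (at 0.05 the
  detected plateau onset lands at the very edge of the window for
  those curves).
* ν₂ is the mean of ν_inc over a ±0.05 window centred at its peak,
  clipped to the data range.  The peak abscissa is refined by a local
  quadratic fit and all window means are interpolation-based, so the
  summary is invariant to resampling density (< 0.5 % change when the
  grid density doubles).
* Regime bounds are (first stretch where k exceeds 1.2·E₁, λ\*);
  the 1.2 factor is configurable, as are all thresholds
  (`ExtractionConfig`).

## Cyclic analysis

Load reversals are sign changes of the smoothed dλ_ax/dt; runs shorter
than two samples are merged, each boundary is snapped to the local
extremum of the raw stretch (smoothing smears the derivative sign by a
sample or two at sharp reversals), and an initial "unloading" run is
folded forward — a tensile test starts by loading.  Per cycle, the
residual stretch is λ_ax interpolated at the zero-force crossing of
the unloading branch (tolerance 0.5 % of that cycle's peak force,
covering load-cell zero drift; if the branch never crosses zero the
sample closest to zero force is used, and a cycle that stays clearly
above zero force is flagged).  Recovery is the recovered deformation
over the total deformation, 100·(λ_peak − λ_res)/(λ_peak − 1); the
transverse analogue uses 1 − λ_tr as the deformation measure,
100·(λ_tr,res − λ_tr,peak)/(1 − λ_tr,peak), which is 100 % for a fully
elastic cycle.

## Affine isotropic network

Fibers at initial angle θ₀ deform affinely,
λ_f = √(λ_ax²cos²θ₀ + λ_tr²sin²θ₀), carry the linear nominal force
κ_f(λ_f − 1), and are averaged over a uniform orientation distribution
(midpoint rule on [0, π), 360 nodes by default, isotropy error below
10⁻⁶).  The first Piola–Kirchhoff membrane tensor is the orientation
average of p(λ_f)·(â ⊗ a₀); uniaxial response enforces zero transverse
nominal force by bracketed root finding.  Fibers carry compression by
default (`tension_only` and a linear matrix term `matrix_k` are
exposed; a tension-only network needs matrix_k > 0 for the transverse
equilibrium to close).  The small-strain Poisson's ratio is the
classical 2-D affine value 1/3.

Because the fiber law is linear, the normalized shape of the uniaxial
response is parameter-free (force-scale invariance): the tangent
stiffness rises immediately at a decelerating rate — about 5 % by
λ = 1.10 and 20 % over [1, 1.5] — and ν_inc increases monotonically.
That concave two-regime signature, as opposed to the cell wall's
flat–convex–flat three-regime one, is the model's diagnostic role
here, and is what the tests assert.

## Five-beam diamond unit

Geometry: loading nodes C, D at (±s, 0) and transverse nodes A, B at
(0, ±s·tan(θ/2)), so the full angle between the stretching beams
meeting at a loading node is θ.  Four identical stretching beams (AC,
AD, BC, BD) rotate toward the pull direction and elongate elastically
(axial force k_s(λ_beam − 1)); the transverse beam AB shortens and
bends; each stretching beam acts in series with an elastoplastic
connector representing fibril–fibril load transfer.  Model forces are
reported per unit reference width 2·s·tan(θ/2); magnitudes are not
calibrated to experiments — the unit is a mechanism model and only
trends and curve shapes carry meaning.

**Bending law.**  P(δ) for end shortening δ ≥ 0 is a compliant branch
P_cr(1 − exp(−δ/(c_pre·L_AB))) saturating at the critical force P_cr,
plus a hardening branch of asymptotic slope P_cr·c_hard/L_AB that
engages smoothly (knee width 0.01·L_AB) at an onset shortening
c_on·L_AB.  A buckled slender beam deflects at near-constant end force
over a long post-buckling arc before the fold tightens and
re-stiffens, which is what the late onset encodes; the onset at zero
recovers a straight-line hardening law.  Negative shortening is off
the loading path and treated as straight-beam axial response (flagged).

**Connector plasticity.**  A 1-D rate-independent return map: elastic
while |f| ≤ f_slip + H·acc, otherwise the force returns to the yield
surface with Δslip = (|f_trial| − yield)/(k + H).  Hardening uses the
*accumulated* slip (isotropic hardening), which keeps the map exactly
rate independent on reversing load paths; for never-reversing
histories — including the five-beam unit, whose unloading stops at
zero force well before reverse yield — it coincides with |slip|.
Backward Euler with linear hardening is exact per monotone increment,
which the fine-increment oracle test verifies to 10⁻⁸.

**Solver.**  Mirror symmetry reduces each increment to one unknown,
the transverse half-span; the net transverse force on node A (bending
force minus the inward pull of the diagonals, with the return map
evaluated implicitly) is solved by bracketed Brent iteration to
machine precision, and the residual is verified against
10⁻¹⁰·max(k_s, k_c, bending stiffness scale).  Energy bookkeeping
accumulates external work (trapezoid rule), closed-form elastic
energies, and the plastic dissipation Σf·Δslip, which is nonnegative
by construction; the closure gap is below 1 % at the default increment
(Δλ = 0.002).  Cyclic loading unloads until the axial force crosses
zero and refines the crossing by bisection; reloading rejoins the
monotonic envelope exactly because the plastic history is carried
through.

**Defaults and what they encode.**  k_s = 100, k_c = 100 (stiff fiber
stretching, comparable connector), P_cr = 0.4 (soft transverse
bending: the regime-I stiffness is bending-dominated, which is why the
connector sweep leaves E₁ nearly unchanged), c_pre = 0.18 (the
compliant branch stays near-linear through regime I, keeping it flat),
c_on = 0.35 and c_hard = 2000 (rotation is cheap until the transverse
span has lost ~35 %, then locks hard — this ends the Poisson-ratio
rise and hands the load to fiber stretching), f_slip = 1.2 (slip
starts as the diagonals pick up load in regime II, so recovery falls
exactly there), H = 20 (slip hardening; with perfect plasticity the
connector force would saturate and the final regime could not plateau
at a high stiffness), θ₀ = 80°.  The angle sets the rotation slack:
the kinematic bound b = √(L₀² − x²) must reach the locking span inside
the stretch window [1, 1.5], which a 90° diamond misses (its
transition is still incomplete at λ = 1.5) and 80° completes by
λ ≈ 1.38.  With these defaults the unit shows the full phenomenology:
regime-I and regime-III stiffness plateaus flat to a few percent with
E₂/E₁ ≈ 6, an interior ν_inc maximum (≈ 2.9 at λ ≈ 1.16), recovery
100 → 55 % flattening off, and a cyclic envelope on the monotonic
curve to < 1 %.

**Sweeps.**  The connector sweep (k_c × {½, 1, 2}) leaves E₁ within
5 % while E₂ increases strictly — initial stiffness is set by bending
and reorientation, final stiffness by fiber stretch through the
connectors.  The angle sweep uses θ₀ ± 1°: E₁ of a single-orientation
unit is intrinsically angle-sensitive (the transverse lever arm enters
as ~1/b₀⁴, about 6.5 %/deg at the defaults, in every geometric
realization we examined — fixed axial span, fixed width, fixed beam
length, fixed area), so "similar E₁" pins the sweep to small angular
bias, consistent with reading the anisotropic mutant as *slightly*
enhanced fiber alignment; E₂, ν₁ and ν₂ still order strictly with
≥ 1 % margins, stable under grid refinement.

## Plane-stress plate and shells

The hyperelastic energy uses the isochoric/volumetric split
W = ΣC_i0(Ī₁ − 3)^i + (1/D₁)(J − 1)², Ī₁ = J^(−2/3)(λ₁² + λ₂² + λ₃²),
so published (C10, D1) constants carry over; for neo-Hookean
C10 = μ/2, D1 = 2/K.  Uniaxial plane stress solves σ₂ = σ₃ = 0 — for
an isotropic material the two lateral stretches coincide, one
bracketed scalar root find per point, tolerance 10⁻¹⁴ — and reports
the nominal membrane force P₁·t_ref.  With μ = 5/13, K = 5/6 the
small-strain modulus is 1 and Poisson's ratio 0.3 exactly (9Kμ/(3K+μ)
and (3K−2μ)/(2(3K+μ))); the incompressible limit reproduces
μ(λ − λ⁻²) and λ_tr = λ^(−1/2).  The plate's tangent stiffness is
monotone-decreasing over [1, 1.5] for neo-Hookean: whatever
three-regime structure tensile data shows, a homogeneous continuum
plate does not produce it.

Shell inflation uses membrane (Laplace) equilibrium with current
geometry, p = c·T(λ)/(λr₀) with c = 2 for a sphere, where the
equibiaxial membrane tension T comes from the wall law (hyperelastic
plane-stress, Hookean with first-order geometric thinning, or a
prescribed tangent-stiffness profile).  For the Hookean wall the
pressure has a limit point at ε\* = −1 + √(1 + (1−ν)/(2ν)) — beyond it
no equilibrium exists and slight pressure changes produce runaway
stretch — while a wall whose stiffness ramps like the measured
three-regime profile keeps the relation single-valued and steep.

The closed pressurised cylinder under axial force uses a Hookean wall,
first-order kinematics, and current-radius pressure coupling (hoop
stress pr/t, cap force pπr²).  The prescribed radius is that of the
*turgid* reference state (pressure applied, zero axial force), which
is what one measures on a living cell and what makes walls of
different Poisson's ratio comparable at the same geometry; the axial
stretch is measured from that state.  Axial stretch then couples to
radial shrinkage through ν, unloading both the cap force and the hoop
stress, so a higher wall Poisson's ratio makes the pressurised cell
axially stiffer (ν = 0.45 vs 0 at p·r/(t·E) = 0.5: ~1 % — the trend,
not the magnitude, is the point).  At zero pressure the solution
reduces to the bar stiffness 2πrtE to 0.1 %.

## Synthetic data generator

The generator emulates the statistical and mechanical structure of
epidermal-peel tensile records so that every pipeline stage has a
ground-truth oracle:

* tangent stiffness E₁ = 12 N/m before λ = 1.10, cubic-smoothstep ramp
  to E₂ = 70 N/m at 1.25, constant after; force is the exact integral
  of this profile.  The plateau levels are the measured epidermal
  values; the ramp bounds are generator conventions.
* ν_inc is a Gaussian bump ν₁ + (ν₂ − ν₁)exp(−((λ−λ_p)/w)²) with
  ν₁ = 0.30, ν₂ = 1.10, λ_p = 1.30, w = 0.10 — below 1 and nearly flat
  in regime I, exceeding 1 at the peak; λ_tr = exp(−∫ν d ln λ) by fine
  quadrature.
* incremental cycles load along the monotonic envelope and unload
  along a straight chord to the residual stretch set by a recovery
  schedule that smoothsteps from 85 % before the ramp to a 40 % floor
  at its end; the transverse stretch recovers by the same percentage
  toward 1.  Reloading retraces the chord, so the envelope property is
  exact by construction.
* noise is additive Gaussian, independent per sample, on force
  (σ = 0.01 N/m) and transverse stretch (σ = 0.001) only — the axial
  stretch is the displacement-controlled variable.  The levels are
  instrument-scale: a µN-class load cell over a ~0.4 mm strip and
  sub-pixel bead tracking sit at or below them.  All randomness is
  seeded; the same seed is bit-reproducible.
* sampling: 500 points over λ ∈ [1, 1.5] at a constant stretch rate of
  2.5·10⁻³ s⁻¹ (≈ 2.5 µm/s on a ~1 mm gauge).

The returned ground truth (E₁, E₂, ν₁, ν₂) applies the same window
definitions as the analysis to the *noiseless analytic profiles* by
fine quadrature, independently of the spline pipeline; round-trip
tests require agreement within 2 % noise-free and 5 % at the default
noise.  What the generator does **not** emulate: hysteresis between
unloading and reloading (the real tissue is mildly viscous), drift or
correlated noise, bead-tracking dropouts, sample-to-sample biological
variability, and failure.  Passing round trips therefore demonstrate
the pipeline's correctness and noise robustness, not its performance
on pathological records.

## Known limitations

* The five-beam unit is a single mechanism cell: magnitudes are not
  comparable to tissue data, its baseline incremental Poisson's ratio
  is higher than measured (ν₁ ≈ 1.6 at θ₀ = 80°), and at zero axial
  force its transverse span recovers fully, so it does not reproduce
  the observed transverse residual deformation.  A distribution of
  unit sizes and angles with network connectivity would be needed for
  quantitative prediction.
* Only plastic slip is modelled; the rate-dependent hysteresis seen
  between unloading and reloading in real cycles is out of scope.
* Shell analyses are thin-wall membrane theory (a warning fires at
  t/r ≥ 0.1) and the cylinder model is first-order in strain.
* The E₂ window requires the stiffness plateau to begin before
  λ_max − 0.05; records truncated mid-rise raise a diagnostic error
  rather than extrapolating.
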