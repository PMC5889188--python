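# Methods

## Model and assumptions

The whisker is a truncated, linearly tapered cone treated as an
Euler–Bernoulli beam: plane sections, no shear deformation (whisker
slenderness ≫ 100 makes shear terms irrelevant), small-angle deflections,
constant Young's modulus along the shaft, and a single frequency-independent
viscous damping constant applied to every mode. The follicle is a rigid
clamp (zero deflection and slope at the base); the pole is a simple support
at the contact point — zero deflection with continuous slope and bending
moment — active only while the contact force is applied. The force is normal
to the whisker axis (frictionless contact), so axial loading, torsion,
intrinsic curvature, and 3-D effects are outside the model. Axial
compliance of the follicle is neglected. Re-contact after detachment and a
moving contact point are not modeled.

Coordinates: `x` runs from the extrapolated virtual tip (`x = 0`) to the
base (`x = L`); the trimmed tip sits at `x = ℓ`. This puts the cone radius
at `r(x) = ξx` exactly, at the cost of "distance from follicle" being
`L − x`; user-facing sweep outputs carry that column explicitly.

## Quasi-static bending

The small-angle deflection under a point force has a closed form: cubic in
`1/x` between contact and base, and a straight (moment-free) continuation
from the contact point to the tip. The solution is linear in the force, so
the dynamic problem uses the factorization `y_s(x,t) = F(t)·ỹ_s(x)`. The
axial-to-lateral force ratio exposed by `axial_lateral_ratio` is the tangent
of the slope difference between base and contact per unit force; see
"Design choices" for the normalization used in the Fig-style rate
comparison.

## Eigenvalue problems

Four boundary cases are solved: free vibration of the full and truncated
cone, and both cones with the additional simple support. The dimensionless
eigenmode equation `(z⁴χ″)″ = z²χ` is solved by `J₂, Y₂, I₂, K₂` of
argument `2√z` divided by `z`; derivatives follow from Bessel recurrences,
so modes and their first three derivatives are available in closed form
everywhere — this is what keeps ~100-mode expansions cheap and exact.

Numerical choices:

- **Scaling.** `I_ν` and `K_ν` grow/decay like `exp(±2√z)`; boundary
  matrices use `ive`/`kve` with column-wise positive scale factors
  (referenced to the extreme argument of each column), which leaves root
  locations and null spaces unchanged. Determinants stay O(1) up to
  `β ~ 4×10⁴` (the 100th contact mode).
- **Root scanning.** The scan is uniform in `s = √β`, where the asymptotic
  root spacing is constant, starting at `β = 0.25` to exclude the trivial
  `β = 0` degeneracy, with step 0.05 cross-checked at half step (halving
  further on disagreement) so no closely spaced pair is missed; each bracket
  is polished by Brent's method to ~1e-12 relative.
- **Null vectors.** Mode coefficients are the right singular vector of the
  smallest singular value; a second small singular value raises a
  degenerate-root error. This is robust for the 8×8 truncated-contact case
  where cofactor formulas are fragile.
- **Normalization and sign.** Modes are normalized to
  `∫ x̂²X² dx̂ = 1` on a composite Gauss–Legendre grid uniform in `√x̂`
  (where the modes oscillate with constant period), with a forced panel
  break at the contact point; the sign is fixed so the mode is positive at
  its largest-amplitude point closest to the tip, making outputs
  deterministic.
- **Small arguments.** Near the tip of a full-length cone the basis ratios
  `J_ν(2√z)/z^{ν/2}` are evaluated by series below `z = 1e-8`.

The eigenfrequency relation `ω = (β/2)(ξ/L)√(E/ρ)` and its inversion
`E = ρ(2ωL²/(βR))²` convert between dimensionless and physical spectra.

## Forced and free dynamics

Contact-phase modal coefficients obey
`φ̈_j + αφ̇_j + ω_j²φ_j = −[F̈ + αḞ]P_j` with
`P_j = ∫ ỹ_s x² X_j dx` (same kink-aware quadrature as normalization). The
primary engine propagates each mode exactly over the steps of a fine time
grid under a piecewise-linear drive (Nigam–Jennings update: exact
exponential/trigonometric homogeneous part, so it is unconditionally stable
and exact for the oscillation; only the drive interpolation approximates).
Grid defaults: 8000 steps across the onset `[0, τ]` where `F̈` is large, and
40000 across the remaining contact, which puts the engine within ~3e-7
relative of the explicit Duhamel convolution; that convolution, evaluated
by adaptive quadrature, is retained purely as a cross-check oracle (it is
O(T²) and never the hot path). For the ramp force the impulsive `F̈ = sδ(t)`
is handled analytically as an initial modal velocity.

At detachment (`t_f`) the displacement and velocity are projected onto the
free-vibration modes; the free phase is then the closed-form damped
sinusoid per mode. The continuity residual of the re-expansion is recorded
on every run (`ModalEvolution.continuity_residual`; ~1e-6 at 100 modes for
mid-whisker contacts). Follicle loads are `M(L;t) = F(t)(L−c) + EI₀Σφ_jX_j″(L)`
and `V(L;t) = F(t) + EI₀Σφ_j(4X_j″(L)/L + X_j‴(L))`, with the free-phase
analogues after detachment; static and vibrational parts are stored
separately so ratio analyses never need to re-decompose.

Default mode count is 100 (both phases), the point at which doubling the
retained modes moves peak vibrational displacement by well under 0.1%; the
default output grid is 10 μs over `[0, 2t_f]`.

## Force profile

The touch force is the upper part of a truncated Gaussian,
`F_G = F_max/(1−C)·[exp(−((t−a)/b)²) − C]`, on `[τ, t_f]`, preceded by a
cubic–quartic onset that makes `F, Ḟ, F̈` vanish at `t = 0` and join `F_G`
continuously at `τ`. The width follows from `F_G(t_f) = 0`; the center `a`
is the root of the onset-continuity equation. Defaults `C = 0.5`,
`t_f = 10 ms`, `τ = 0.1 ms` define the standard touch. `τ ≤ t_f/10` is
enforced. The slip-fit parameterization by touch half-duration
(`center 2t_d, width 1.2011 t_d`) is internally inconsistent with a smooth
onset (its literal center/width cannot satisfy the continuity conditions,
and its stated peak position conflicts with its own formula); the
constructor keeps only the implied duration `t_f ≈ 3t_d` and re-solves the
center canonically. At `t_f` the force simply ends: the pole leaves with
finite velocity proportional to `Ḟ(t_f)`, no deceleration impulse.

## Distance cues

- `frequency_sweep` / `truncation_sweep`: dimensionless spectra over pole
  position or trimming; the fundamental is single-peaked in `c/L`, mode `j`
  has `j` peaks, and truncation moves high modes far more than the first.
- `excitation_spectrum`: per-mode peak `|φ_j|` over the contact window
  (sampled at 0.5 μs so high-mode peaks are resolved), raw and normalized.
- `ratio_analysis`: vibrational/quasi-static follicle load ratios per
  contact point. "Average" is the ratio of time-averaged magnitudes over
  the contact window (a pointwise-ratio mean diverges whenever the static
  component crosses zero near onset/offset); "maximum" is the ratio of the
  two peak magnitudes. Both are invariant to force amplitude and sign.
- `rate_of_change_comparison`: percent change per millimeter of (i) the
  fundamental contact frequency and (ii) the axial-to-lateral force ratio,
  by centered differences.

## Design choices

- **Force-ratio normalization.** What is held fixed as contact distance
  varies changes the force-ratio curve qualitatively. At fixed applied
  force the ratio `|ỹ_s′(c)|` collapses quadratically near the base, making
  its relative rate enormous (~100%/mm) precisely where whiskers are stiff —
  at odds with the slow proximal variation this cue is known for. At fixed
  push angle (equal base rotation, the natural experimental control) the
  ratio reduces to `(L+2c)/2c`, whose rate is ~2%/mm at proximal contacts
  and exceeds 100%/mm at the tip. The rate comparison therefore defaults to
  the push-angle normalization, with the unit-force variant available.
- **Averaging convention** for ratio tables as above; the proximal-contact
  table values are insensitive to the choice (average ≈ maximum there).
- **Onset sensitivity.** Excitation of modes whose period is much longer
  than τ is insensitive to halving τ below 0.1 ms (<1.5% for modes 1–4 of
  the standard whisker); mode 6 (period ≈ 0.35 ms) sits at the edge of this
  regime and shifts by a few percent. This is physical, not numerical: the
  onset duration controls how far up the spectrum the impact pumps energy.

## Damped-oscillation fitting

Ring-down traces are fit by `A sin(ω̃t + φ)exp(−αt/2)` with
`ω̃ = √(ω² − (α/2)²)`, via Levenberg–Marquardt least squares parameterized
internally by `(A, ω̃, α, φ)` (avoiding the underdamped constraint), with
automatic initialization from the windowed FFT peak and a log-Hilbert-
envelope regression. 0.95 confidence intervals come from the observed
information (curvature) at the optimum; the interval for the undamped `ω`
follows by the delta method. A sampling guard requires ≥ 8 samples per
expected period. Monte-Carlo calibration (200 replicates at 5% amplitude
noise) shows median frequency error below 2% and CI coverage above 90%.

## Synthetic data

The fixture generator produces damped sinusoids with additive white
Gaussian noise at the measured population values (ω near 962 rad/s,
α near 430 rad/s, 5% noise), deterministic per seed. It emulates the
displacement of a single dominant mode after slip-off; it does not emulate
multi-mode content, tracking noise correlated along the whisker, or the
quasi-static trajectory removal step real traces require — so passing fits
demonstrate estimator correctness and calibration, not robustness to those
artifacts.

## Verification strategy

Every layer is checked against an independent route: quasi-statics against
direct double integration of the curvature equation; eigenvalues against a
40-digit evaluation of the unscaled determinant and a 2000-node
finite-difference discretization of the weighted eigenproblem; modal
dynamics against the explicit Duhamel convolution, a closed-form ramp
response, and a Newmark finite-difference integration of the full PDE
(agreement within 2% of peak amplitude); conservation and continuity
invariants (orthonormality, undamped energy, detachment matching) are
asserted at tight tolerances.

## Known limitations

Small-angle, frictionless, 2-D: strong or very distal pushes (path-length
changes, large angles) need a nonlinear model. The rigid-clamp follicle
makes fitted `E` and `α` effective parameters that absorb follicle
compliance. Overdamped modes are rejected rather than handled (all whisker
modes of interest are strongly underdamped). The Fig-8-style force-ratio
rate depends on the sweep normalization as discussed; only the push-angle
variant reproduces slow proximal variation.
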