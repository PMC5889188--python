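# whiskervib

Analytical vibration dynamics of conical whiskers during active object touch.

Rodents sweep their whiskers against objects and localize them from the
mechanical signals transmitted to the follicle. When a whisker strikes a
pole it bends quasi-statically *and* rings: the ringing frequency and the
relative magnitude of vibrational versus quasi-static forces both depend on
where along the whisker contact was made, making them candidate cues for
radial object distance. This package implements a closed-form solution for
those vibrations and the analyses that turn them into distance cues. It is
written for sensory-biomechanics and computational-neuroscience work, but
applies to any truncated conical Euler–Bernoulli beam with an intermediate
simple support.

## The model

A whisker is a linearly tapered elastic cone: radius `r(x) = ξx` with taper
`ξ = R/L`, where `x` runs from the extrapolated tip (`x = 0`) to the base
(`x = L`) and the real, possibly trimmed, tip sits at `x = ℓ`. Transverse
motion obeys the Euler–Bernoulli equation

    (E I(x) y″)″ + μ(x) ÿ + α μ(x) ẏ = F(t) δ(x − c),

with `I(x) = (π/4)ξ⁴x⁴`, `μ(x) = ρπξ²x²`, viscous damping `α`, and a point
force at the pole position `c`. Separating variables and substituting
`z = qx`, `q² = 4ρω²/(Eξ²)` reduces the spatial problem to
`(z⁴χ″)″ = z²χ`, whose general solution is spanned by

    J₂(2√z)/z,  Y₂(2√z)/z,  I₂(2√z)/z,  K₂(2√z)/z.

Boundary conditions — clamped base, free tip, and (during contact) a simple
support at `c` — yield a characteristic determinant per case; its roots
`β_j = q_j L` are the dimensionless eigenfrequencies, with
`ω_j = (β_j/2)(ξ/L)√(E/ρ)`. The modified Bessel terms grow like
`exp(2√z)`, so determinants and mode evaluations use exponentially scaled
`I`/`K` throughout, which keeps ~100 modes numerically exact.

During contact the displacement splits exactly into a quasi-static part
`F(t)·ỹ_s(x)` (closed form) and a vibrational part `Σ φ_j(t) X_j(x)` over
the contact-constrained modes, each coefficient obeying a damped oscillator
driven by `−[F̈ + αḞ] P_j`. The touch force is a truncated Gaussian with a
C² smooth onset of duration τ. At detachment the state is projected onto
the free-vibration modes and rings down in closed form. Bending moment
`M(L;t)` and shear `V(L;t)` at the follicle follow from the modal second
and third derivatives at the base.

## Worked example

```python
import numpy as np
from whiskervib import (BoundaryCase, ContactConfig, ForceProfile,
                        find_eigenvalues, follicle_signal, simulate_touch,
                        standard_whisker, young_modulus_from_frequency)

# dimensionless spectrum of the freely vibrating full-length cone
betas = find_eigenvalues(BoundaryCase.FREE_FULL, 5)
print("free-cone betas:", np.round(betas, 3))

# Young's modulus from a measured fundamental frequency (962 rad/s)
E = young_modulus_from_frequency(L=17.14e-3, R=37.15e-6, rho=1000.0,
                                 omega_measured=962.0)
print(f"E = {E/1e9:.2f} GPa   (f = {962.0/2/np.pi:.0f} Hz)")

# a standard 10 ms, 1 uN touch at c/L = 0.6 on the standard whisker
geom = standard_whisker()
contact = ContactConfig.from_relative(geom, 0.6)
profile = ForceProfile.gaussian_smooth(F_max=1e-6)
evol = simulate_touch(geom, contact, profile, n_modes=100)
sig = follicle_signal(evol, np.arange(0.0, profile.t_f, 10e-6))
print(f"first contact frequency: {evol.contact_omegas()[0]/2/np.pi:.0f} Hz")
print(f"peak static moment:  {np.abs(sig.M_static).max()*1e9:.2f} nN*m")
print(f"peak vibrational moment: {np.abs(sig.M_vib).max()*1e9:.2f} nN*m")
print(f"vibrational/static shear (time-averaged): "
      f"{np.mean(np.abs(sig.V_vib))/np.mean(np.abs(sig.V_static)):.3f}")
```

prints

```
free-cone betas: [ 8.719 21.146 38.454 60.68  87.834]
E = 3.04 GPa   (f = 153 Hz)
first contact frequency: 210 Hz
peak static moment:  7.20 nN*m
peak vibrational moment: 1.16 nN*m
vibrational/static shear (time-averaged): 0.194
```

The `betas` are the natural frequencies of the free cone in dimensionless
form (geometry-independent). The modulus line inverts the first of them
against a measured whisker's ring-down frequency. The touch simulation
shows that for a mid-whisker contact the constrained fundamental rises to
210 Hz and the vibrational shear at the follicle carries about a fifth of
the quasi-static signal — a ratio that grows dramatically for contacts
nearer the tip.

A command-line interface wraps the same pipelines:

```bash
whiskervib eigen --case free-full --modes 10 --out eigen.csv
whiskervib simulate --config run.yaml
whiskervib sweep --kind frequency
whiskervib fixtures --seed 7 && whiskervib fit --input fixtures/trace_00.csv
```

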