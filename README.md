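# cwdip

Continuous-wave EPR dipolar distance-distribution and spin-label mobility
analysis for site-directed spin labeling (SDSL) studies — built around the
system that motivated it: the intrinsically disordered N-terminal extension
of cardiac troponin I (cTnI), probed by nitroxide labels (MSL/MTSL) at
*i*, *i*+4 cysteine pairs to distinguish α-helical from melted structure.

## What it computes

**Interspin distances from dipolar broadening.** Two nitroxides at distance
*r* couple through space; in a frozen (rigid-limit, 170 K) powder sample the
coupling splits each resonance by

    ΔB(θ) = ±(C_dd / 2r³)(3cos²θ − 1),     C_dd = 18.57 G·nm³,

whose powder average is the Pake doublet (perpendicular singularities at
±C_dd/2r³, parallel shoulders at ±C_dd/r³).  The double-labeled spectrum is
the convolution of the single-labeled spectrum with this broadening kernel
averaged over a distance distribution

    P(r) = Σᵢ fᵢ · N(r; rᵢ, Δrᵢ) + f_non,

one or two Gaussians (center *r* ∈ 0.8–2.8 nm, FWHM Δ*r* ∈ 0.04–2 nm,
fraction *f*) plus a non-interacting pool (reported together with fitted
distances beyond 2.5 nm, where CW broadening is undetectable).  The inverse
problem minimizes χ² = Σ(data − model)²/σ² over bounded parameters with
multi-start Levenberg-Marquardt or Monte-Carlo/simplex searches, and 1- vs
2-Gaussian models are compared by their χ² ratio.  An *i*,*i*+4 pair on an
α-helix sits near 0.9 nm with a narrow width; broad 1–2.5 nm distributions
indicate disorder.

**Side-chain mobility.** From room-temperature spectra the package measures
the effective outer splitting 2T_eff and converts it to an effective
rotational correlation time with the Goldman relation

    τ_eff = a (1 − T_eff/T_max)^b,    a = 5.4×10⁻¹⁰ s, b = −1.36, T_max = 35 G,

computes slow/fast peak-height ratios, and decomposes two-component
(fast + immobilized) spectra by subtracting a scaled mobile reference until
the sharp fast-motion features null.

**Synthetic data.** No public spectra accompany the study system, so a
first-class generator produces rigid-limit and motion-averaged nitroxide
powder spectra (first-order resonance fields, Voigt lines, order-parameter
tensor scaling), dipolar pair spectra from any distance model, composites
and seeded noise — every analysis stage is validated end-to-end against
known ground truth.

## Worked example

Simulate the MTSL-labeled 43/47 pair in complex with troponin C from its
published two-Gaussian model, then fit it back:

```python
from cwdip import FitOptions, fit_distance, forward_model, simulate_powder
from cwdip.registry import get_model
from cwdip.simulate import NitroxideSystem

single = simulate_powder(NitroxideSystem(), orientations=800)
truth = get_model("cTnI(43/47MTSL)+cTnC", 2)
double = forward_model(single, truth)

fit = fit_distance(double, single, FitOptions(n_gaussians=2, n_starts=8, seed=1))
for c in fit.model.sorted_by_r().components:
    print(f"r = {c.r:.2f} nm, dr = {c.dr:.2f} nm, f = {100*c.f:.0f}%")
print(f"non-interacting/beyond-2.5 pool: {100*fit.model.f_non:.0f}%")
```

prints

```
r = 0.91 nm, dr = 0.10 nm, f = 48%
r = 1.21 nm, dr = 1.32 nm, f = 29%
non-interacting/beyond-2.5 pool: 23%
```

— the narrow 0.91 nm / 48% component is the α-helix signature of the 43/47
segment when bound to troponin C; the broad 1.21 nm component is the
residual melted fraction.  The same workflow is available from the shell:

```bash
cwdip sim-spectrum --out single.dat
cwdip sim-pair --single single.dat --label "cTnI(43/47MTSL)+cTnC" --out pair.dat
cwdip fit-distance --double pair.dat --single single.dat --gaussians 2 --seed 1
cwdip benchmark --out-dir bench/      # full recovery suite
```

## Layout

- `cwdip.spectra` — spectrum container, ASCII I/O, double integration,
  spin-count normalization, resampling
- `cwdip.simulate` — synthetic powder/mobile/pair/composite generator
- `cwdip.dipolar` — Pake kernel, Gaussian distribution averaging, forward
  convolution model
- `cwdip.fitting` — bounded 1-/2-Gaussian fits, χ² comparison, bootstrap
  uncertainties, report tables
- `cwdip.mobility` — T_eff, τ_eff, slow/fast ratio, spectral subtraction
- `cwdip.registry` — published reference distance models for the cTnI
  N-extension spin-label pairs
- `cwdip.pipeline` / `cwdip.cli` — end-to-end orchestration and the `cwdip`
  command-line tool

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
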