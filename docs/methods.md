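# Methods

This note documents the models implemented in `cwdip`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want to audit.

## Forward model: dipolar broadening of CW spectra

A pair of nitroxide labels at interspin distance *r* experiences a secular
point-dipole coupling.  In field units the two split lines sit at

    ΔB(θ) = ±(C_dd / 2r³)(3cos²θ − 1)

with θ the angle between the interspin vector and the applied field.  The
dipolar constant is computed at import time from CODATA constants,

    ν_dd(r) = (μ0/4π) g² μ_B² / (h r³) = 52.04 MHz·nm³ / r³   (g = g_e),
    C_dd = ν_dd / (g μ_B/h) = 18.57 G·nm³,

and stored on every kernel object rather than hard-coded, so its provenance
is auditable.  Powder averaging uses a 1800-point quarter-sphere θ grid with
sin θ weights; each stick is deposited linearly onto the offset axis and the
kernel is symmetrized and normalized to unit area.  A doubling test (and an
independent closed-form oracle in the test suite, which integrates the
u = cos θ distribution analytically per bin) bounds the discretization
error.  Orientation correlation between the label frames and the interspin
vector is ignored (uncorrelated powder), exchange coupling J is not modeled,
and no pseudosecular corrections are applied below 0.8 nm; fits falling in
those regimes simply report their χ².

Distance distributions are one or two Gaussians (center r, FWHM Δr,
fraction f) plus a non-interacting fraction f_non.  Distribution-averaged
kernels are weighted sums over a fixed distance grid (0.02 nm steps,
0.4–4.0 nm; finer than any reported Δr uncertainty).  Each Gaussian is
truncated to [max(0.4 nm, r − 3σ), r + 3σ] and renormalized; kernels on the
grid are tabulated once per offset axis and reused, which makes a fit
evaluation a matrix product plus one FFT per component.  Widths below the
grid resolution fall back to the single-distance kernel.

The double-labeled spectrum is f_non·S + Σ fᵢ·(S ⊛ Kᵢ), with S the
single-labeled first-derivative spectrum — valid on the derivative because
differentiation commutes with convolution.  The convolution is circular
(FFT product; the kernel is alias-folded onto the spectrum grid), which
conserves the spectral sum exactly.  Distribution tails at very short
distance produce patterns wider than the sweep; their wrapped mass appears
as a near-flat background, mimicking the experimental invisibility of such
spins.  One measured consequence: the *double integral* (a linearly
weighted sum) is conserved to ~1e-8 for patterns contained in the sweep but
can shift by a few percent when a wide distribution reaches below
~0.6 nm, because wrapped mass re-enters at the opposite edge.  The fitting
pipeline therefore compares lineshapes at matched spin count (see below).

A related measured fact: the distribution-kernel maximum is *not* monotone
in Δr at fixed r.  Flattening holds up to moderate widths, but a wide
Gaussian's long-distance tail weights near-zero-offset kernels and
re-sharpens the peak (at r = 1.2 nm the maximum for Δr = 0.1/0.5/1.0 nm is
0.106/0.072/0.085 in grid units).  The peak *position* does move inward
monotonically, and that is what the property test asserts.

## Inverse problem

The fit minimizes χ² = Σ(data − model)²/σ² over 3 or 6 bounded parameters
(r ∈ [0.8, 2.8] nm, Δr ∈ [0.04, 2] nm, f ∈ [0, 1]); for two Gaussians
f_non = 1 − f₁ − f₂ is constrained to [0, 1] by a penalty residual rather
than a simplex transform, keeping parameters directly comparable to report
tables.  Components are always reported sorted by ascending r (ties broken
by larger f) to prevent label switching.  Fitted centers beyond 2.5 nm are
pooled with f_non in reports, since CW broadening cannot distinguish them.

Two optimizers share the objective:

* **Levenberg-Marquardt multi-start** (default): lmfit/MINPACK with bound
  transforms, started from a seeded Latin-hypercube over the bounds
  (default 8 starts; infeasible fraction starts are rescaled onto the
  simplex).  The global best over starts is returned.
* **Monte-Carlo/simplex**: a seeded budget of uniform random proposals
  (default 2000) whose three leaders are refined by Nelder-Mead.

σ defaults to the standard deviation of the outer 5% edge windows of the
data (with a floor so noiseless synthetic spectra fall back to an
unweighted χ²).  Because this normalization is a package choice, absolute
χ² values are comparable only within one analysis; the 1-Gaussian /
2-Gaussian χ² *ratio* (2-Gaussian preferred above a configurable 1.2) is
the intended comparison.

**Matched-spin-count fitting.** The experimental workflow normalizes the
double- and single-labeled spectra to the same number of spins before
fitting.  When heavy broadening moves integral weight around the sweep
window (above), a fixed-amplitude model would inherit a few-percent scale
error from that normalization.  With `FitOptions.match_spin_count=True`
(used by the pipeline and CLI) each prediction's raw double integral is
rescaled onto the data's, so data and model are compared as lineshapes at
equal spin count and generator parameters are recovered exactly.  The
low-level `fit_distance` default leaves the scale fixed, which is correct
when both inputs are already consistently normalized.

**Uncertainties** are residual-bootstrap standard deviations (default 100
seeded replicates refit from the best point), reported as the larger of the
bootstrap and LM-covariance estimates, and flagged unreliable when more
than 20% of replicates fail.  This is a documented substitute for whatever
"best estimate ± uncertainty" procedure produced published tables; absolute
agreement of uncertainty magnitudes is therefore not asserted beyond order
of magnitude.

## Mobility analyses

* **T_eff** — half the separation between the outermost low-field maximum
  and high-field minimum of the derivative spectrum, each refined by a
  5-point parabola fit in centered index units (exactly
  translation-invariant; ~0.02 G resolution on a 0.1 G grid).  Extrema are
  accepted above a prominence of 2% of peak-to-peak; fully averaged spectra
  whose outer features merge with the central triplet raise a dedicated
  error instead of returning a bogus splitting.
* **τ_eff = a(1 − T_eff/T_max)^b** with a = 5.4×10⁻¹⁰ s, b = −1.36,
  T_max = 35 G — applied as an empirical relation, exactly as printed;
  T_eff ≥ T_max reports the rigid limit rather than a finite time.  The
  closed form is cross-checked against a symbolic evaluation in the tests.
* **Slow/fast ratio** — max |intensity| in a user-supplied low-field slow
  window over that in the fast window; invariant to overall scaling.
* **Two-component subtraction** — the historical procedure is subtraction
  "by eye"; the algorithmic endpoint implemented here grid-searches the
  removed fraction x ∈ [0, 1] in 0.005 steps (plus local parabolic
  refinement) to minimize the *sharp* content of the residual
  composite − x·reference: the squared second difference within windows of
  ±3 G around the three most prominent reference extrema.  The curvature
  filter makes the criterion nearly blind to the broad immobilized
  background that overlaps the same field region — a plain squared-residual
  criterion is biased by several percent through the mobile/immobile
  overlap, while the curvature criterion recovers known mixing fractions
  to better than ±0.01 across 0.2–0.6 immobile.  A guard keeps the
  difference's double integral above −1% of the composite's, and an optimum
  at the search boundary is flagged.  The removed fraction x refers to the
  mobile reference; the immobile remainder is 1 − x of the composite (both
  readings of a "subtracted N%" statement are thus recoverable).

## Synthetic generator

The generator emulates the statistical structure of the study's inputs:

* **Rigid-limit powder spectra** (170 K convention): first-order resonance
  fields B = hν/(gμ_B) − A·m_I over a sin θ-weighted quarter-sphere grid
  (defaults 200 θ × 20 φ points; a doubling test shows <0.5% RMS change),
  ellipsoid-interpolated g and A, Voigt line (Gaussian 3 G, Lorentzian 1 G
  FWHM — conventions, since intrinsic linewidths for these labels are not
  published), absorption area normalized to a configurable spin amplitude.
  Defaults g = (2.0086, 2.0066, 2.0032), A = (6, 6, 35) G: A_zz = 35 G
  fixes the rigid-limit T_max; the g values are conventional nitroxide
  magnitudes, a declared fixture convention.
* **Motion-averaged spectra** via an order parameter S ∈ [0, 1] scaling
  tensor anisotropies about their isotropic means, giving a controllable
  T_eff ≈ a_iso + S(A_zz − a_iso).  This deliberately replaces dynamic
  (stochastic-Liouville) lineshape theory: the mobility formulas under test
  need spectra with controllable splitting and sharp/broad character, not
  correlation-time-resolved lineshapes.  Consequently passing tests
  validate the *analysis* operations, not any claim that the generator
  reproduces real motional lineshapes; linewidth–mobility correlations,
  saturation, field modulation and instrumental baselines are all absent.
* **Pair spectra, composites, noise**: the forward model applied to a
  generated single-label spectrum; convex mixtures on a shared axis; white
  Gaussian noise of σ = peak-to-peak/SNR, seeded and reproducible.

Acquisition conventions follow the study design: 200 G sweeps near 3430 G
at 9.6 GHz for rigid-limit distance work, 100 G sweeps centered on the
isotropic resonance (~3437–3440 G at 9.65 GHz) for room-temperature
mobility work.  The subtraction benchmark uses a mobile reference at
S = 0.3 mixed with a rigid spectrum at immobile fractions spanning the
0.30–0.45 range of interest.

## Benchmark sizes and runtimes

The registry stores the published 1-/2-Gaussian models for ten labeled
samples.  The standard benchmark (`cwdip benchmark`) regenerates a
noiseless pair spectrum per model on a 1024-point axis with 800
orientations, refits each from scratch (8 Latin-hypercube starts), and
scores recovery at (0.03 nm, 0.05 nm, 3 points); the five-fraction
subtraction sweep is scored at ±2 points.  The full suite (27 cases)
completes in well under a minute on one CPU; the pytest suite, which adds
the 20-model recovery grid and bootstrap-uncertainty sweeps, runs in a few
minutes.  These sizes were chosen as the smallest at which the convergence
tests (orientation doubling, grid recovery) hold with wide margin.

## Known limitations

* No vendor binary I/O (Bruker BES3T/WinEPR); two-column ASCII only.
* Secular dipolar model: no exchange coupling J, no pseudosecular terms,
  no half-field transitions — short-distance (<0.8 nm) or
  exchange-narrowed spectra will fit poorly and should be judged by their
  χ² and residuals.
* χ² normalization is internal; absolute values are not comparable to
  other software.
* The Goldman τ_eff relation is applied exactly as printed, without
  modeling its validity range.
* Gaussian truncation at the distance-grid bounds (0.4 nm) with
  renormalization is one of several defensible conventions; fits with wide
  components reaching that bound are sensitive to it at the percent level.
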