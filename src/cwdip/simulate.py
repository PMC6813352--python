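"""Synthetic nitroxide CW-EPR spectrum generator.

Produces rigid-limit and partially motion-averaged powder spectra, dipolar
pair spectra, two-component composites and noisy realizations, so the whole
analysis chain can be exercised and validated without experimental data.

The rigid-limit spectrum is a first-order powder sum: for each orientation
(θ, φ) on a sin θ-weighted spherical grid and each ¹⁴N nuclear projection
m_I ∈ {−1, 0, +1}, the resonance field is

    B(θ, φ, m_I) = h ν / (g(θ, φ) μ_B) − A(θ, φ) · m_I

with the angle-dependent g-factor and hyperfine coupling interpolated on the
principal-value ellipsoids.  The stick pattern is convolved with a Voigt
line and differentiated to the detected first-derivative form.

Motional averaging is modeled by an order parameter S ∈ [0, 1] that scales
the tensor anisotropies about their isotropic means, giving a controllable
effective splitting T_eff ≈ a_iso + S·(A_zz − a_iso) without invoking
dynamic lineshape theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import constants
from scipy.special import voigt_profile

from .dipolar import DistanceModel, forward_model
from .spectra import AxisMismatchError, FieldSpectrum

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# hν/(μ_B) prefactor: resonance field in Gauss = _H_OVER_MUB * ν_GHz / g
_H_OVER_MUB_G_PER_GHZ = constants.h / constants.value("Bohr magneton") * 1e9 * 1e4


@dataclass(frozen=True)
class NitroxideSystem:
    """Magnetic parameters of a nitroxide spin label.

    ``A_zz = 35 G`` fixes the rigid-limit outer splitting 2T_max = 70 G;
    the g-values are conventional X-band nitroxide magnitudes.  Linewidths
    are FWHM of the Gaussian and Lorentzian parts of the Voigt line.
    """

    g_principal: tuple[float, float, float] = (2.0086, 2.0066, 2.0032)
    A_principal: tuple[float, float, float] = (6.0, 6.0, 35.0)  # Gauss
    linewidth_gaussian: float = 3.0  # G FWHM
    linewidth_lorentzian: float = 1.0  # G FWHM
    mw_frequency: float = 9.6  # GHz

    def __post_init__(self):
        if self.linewidth_gaussian <= 0 or self.linewidth_lorentzian <= 0:
            raise ValueError("linewidths must be positive")
        if max(self.A_principal) != self.A_principal[2]:
            raise ValueError("A_zz must be the largest hyperfine value")

    @property
    def a_iso(self) -> float:
        return float(np.mean(self.A_principal))

    @property
    def g_iso(self) -> float:
        return float(np.mean(self.g_principal))

    def scaled(self, S: float) -> "NitroxideSystem":
        """Tensors with anisotropies scaled by order parameter S about the
        isotropic means."""
        if not 0.0 <= S <= 1.0:
            raise ValueError("order parameter S must be in [0, 1]")
        g = tuple(self.g_iso + S * (gi - self.g_iso) for gi in self.g_principal)
        A = tuple(self.a_iso + S * (Ai - self.a_iso) for Ai in self.A_principal)
        return replace(self, g_principal=g, A_principal=A)


@dataclass(frozen=True)
class NoiseSpec:
    """White-noise specification: peak-to-peak signal over noise σ, seeded."""

    snr: float
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def default_axis(
    center: float = 3430.0, sweep: float = 200.0, n: int = 1024
) -> np.ndarray:
    """Uniform field axis (Gauss); defaults match a 200 G rigid-limit sweep."""
    return np.linspace(center - sweep / 2, center + sweep / 2, n)


def simulate_powder(
    sys: NitroxideSystem,
    axis: np.ndarray | None = None,
    orientations: int = 200,
    amplitude: float = 1.0,
    temperature: float = 170.0,
    label: str = "powder",
) -> FieldSpectrum:
    """Rigid-limit nitroxide powder spectrum (first derivative).

    ``orientations`` is the θ-point count of the quarter-sphere grid; the
    φ grid uses one tenth as many points (g/A tensors here are near-axial,
    so φ converges quickly).  The absorption area is normalized to
    ``amplitude`` before differentiation, so the double integral of the
    returned derivative equals ``amplitude``.
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    if orientations < 200:
        raise ValueError("orientations must be >= 200")
    gx, gy, gz = sys.g_principal
    Ax, Ay, Az = sys.A_principal
    extent = 2 * Az + 6 * sys.linewidth_gaussian
    if axis[-1] - axis[0] < extent:
        warnings.warn(
            f"axis span {axis[-1] - axis[0]:.0f} G narrower than spectral "
            f"extent ~{extent:.0f} G; spectrum will be truncated",
            stacklevel=2,
        )
    n_theta = orientations
    n_phi = max(8, orientations // 10)
    theta = (np.arange(n_theta) + 0.5) * (0.5 * np.pi / n_theta)
    phi = (np.arange(n_phi) + 0.5) * (0.5 * np.pi / n_phi)  # orthorhombic symmetry
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    cp, sp = np.cos(phi)[None, :], np.sin(phi)[None, :]
    l1, l2, l3 = st * cp, st * sp, ct * np.ones_like(cp)
    g_eff = np.sqrt(gx**2 * l1**2 + gy**2 * l2**2 + gz**2 * l3**2)
    A_eff = np.sqrt(Ax**2 * l1**2 + Ay**2 * l2**2 + Az**2 * l3**2)
    w = (st * np.ones_like(cp)).ravel()
    B0 = _H_OVER_MUB_G_PER_GHZ * sys.mw_frequency / g_eff
    step = axis[1] - axis[0]
    absorption = np.zeros(axis.size)
    for m_i in (-1.0, 0.0, 1.0):
        b_res = (B0 - A_eff * m_i).ravel()
        absorption += _deposit_clipped(b_res, w, axis[0], step, axis.size)
    sigma = sys.linewidth_gaussian / _FWHM_TO_SIGMA
    gamma = sys.linewidth_lorentzian / 2.0
    half = int(np.ceil((4 * sys.linewidth_gaussian + 20 * gamma) / step))
    off = np.arange(-half, half + 1) * step
    line = voigt_profile(off, sigma, gamma)
    line /= line.sum()
    absorption = np.convolve(absorption, line, mode="same")
    area = np.trapezoid(absorption, axis)
    absorption *= amplitude / area
    deriv = np.gradient(absorption, axis)
    return FieldSpectrum(
        axis,
        deriv,
        mw_frequency=sys.mw_frequency,
        temperature=temperature,
        label=label,
    )


def _deposit_clipped(positions, weights, origin, step, n):
    x = (positions - origin) / step
    i0 = np.floor(x).astype(int)
    frac = x - i0
    out = np.zeros(n)
    ok = (i0 >= 0) & (i0 < n - 1)
    np.add.at(out, i0[ok], weights[ok] * (1.0 - frac[ok]))
    np.add.at(out, i0[ok] + 1, weights[ok] * frac[ok])
    return out


def simulate_mobile(
    sys: NitroxideSystem,
    S: float,
    axis: np.ndarray | None = None,
    orientations: int = 200,
    amplitude: float = 1.0,
    label: str = "mobile",
) -> FieldSpectrum:
    """Partially motion-averaged spectrum with order parameter S.

    S = 1 reproduces the rigid limit; S = 0 collapses to an isotropic
    three-line spectrum with splitting a_iso.  By construction the effective
    splitting is T_eff ≈ a_iso + S·(A_zz − a_iso).

    The default axis is a 100 G sweep centered on the isotropic resonance
    field of ``sys`` (≈3440 G at 9.65 GHz), the conventional room-temperature
    acquisition window.
    """
    if axis is None:
        center = _H_OVER_MUB_G_PER_GHZ * sys.mw_frequency / sys.g_iso
        axis = default_axis(center=center, sweep=100.0)
    return simulate_powder(
        sys.scaled(S),
        axis,
        orientations=orientations,
        amplitude=amplitude,
        temperature=295.0,
        label=label,
    )


def make_pair_spectrum(single: FieldSpectrum, model: DistanceModel) -> FieldSpectrum:
    """Dipolar-broadened double-label spectrum from a single-label one."""
    return forward_model(single, model)


def mix_spectra(components: list[tuple[FieldSpectrum, float]]) -> FieldSpectrum:
    """Pointwise convex combination of spectra sharing one field axis."""
    if not components:
        raise ValueError("need at least one component")
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fracs.sum()}")
    base = components[0][0]
    out = np.zeros_like(base.intensity)
    for s, f in components:
        if not base.same_axis(s):
            raise AxisMismatchError("all components must share one field axis")
        out += f * s.intensity
    return base.with_intensity(out, label="mixture")


def add_noise(s: FieldSpectrum, spec: NoiseSpec) -> FieldSpectrum:
    """Add seeded white Gaussian noise of σ = peak-to-peak/snr."""
    rng = np.random.default_rng(spec.seed)
    sigma = s.peak_to_peak() / spec.snr
    return s.with_intensity(s.intensity + rng.normal(0.0, sigma, s.n_points))
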