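"""Room-temperature spin-label mobility analyses.

Three quantities characterize side-chain mobility in a nitroxide spectrum:

* the effective outer splitting 2T_eff, the field separation between the
  low-field maximum and high-field minimum of the first-derivative spectrum,
  which grows toward the rigid limit 2T_max = 70 G as motion slows;
* the effective rotational correlation time from the empirical relation

      τ_eff = a · (1 − T_eff / T_max)^b,   a = 5.4×10⁻¹⁰ s, b = −1.36,
      T_max = 35 G,

  valid for 0 ≤ T_eff < T_max (at T_eff = T_max the label is at the rigid
  limit and τ_eff diverges);
* the peak-height ratio between the slow (immobilized) and fast components
  at low field, a steric-hindrance indicator for two-component spectra.

Two-component composites are decomposed by spectral subtraction: removing a
fraction x of a mobile reference until the sharp fast-motion features null,
leaving the immobilized component (fraction 1 − x of the composite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectra import AxisMismatchError, FieldSpectrum, double_integral

GOLDMAN_A = 5.4e-10  # s
GOLDMAN_B = -1.36
T_MAX = 35.0  # G, rigid-limit half-splitting


class RigidLimitError(ValueError):
    """Raised when T_eff >= T_max, where no finite correlation time exists."""


class UnresolvedSplittingError(ValueError):
    """Raised when the outer extrema cannot be resolved (fast-motion regime)."""


@dataclass
class MobilityResult:
    """Effective splitting, correlation time and slow/fast ratio."""

    T_eff: float  # Gauss
    tau_eff: float | None  # seconds; None at/beyond the rigid limit
    slow_fast_ratio: float | None = None


@dataclass
class SubtractionResult:
    """Outcome of two-component spectral subtraction.

    ``fraction`` is the portion x of the reference removed;
    ``difference = composite − x·reference`` (before display scaling);
    ``multiplier`` rescales the difference's peak-to-peak to the composite's
    for display; ``boundary`` flags an optimum at the search-range edge.
    """

    fraction: float
    difference: FieldSpectrum
    criterion_value: float
    multiplier: float
    boundary: bool = False


def _parabolic_refine(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-grid extremum position from a parabola through 5 points.

    The fit is done in centered index units for numerical stability, so the
    result is exactly invariant to field translation and robust to overall
    intensity scaling.
    """
    half = 2
    lo = max(0, idx - half)
    hi = min(y.size, idx + half + 1)
    if hi - lo < 3:
        return float(x[idx])
    t = np.arange(lo, hi, dtype=float) - idx
    coeff = np.polyfit(t, y[lo:hi], 2)
    if coeff[0] == 0:
        return float(x[idx])
    tv = -coeff[1] / (2 * coeff[0])
    if not (t[0] <= tv <= t[-1]):
        return float(x[idx])
    step = x[1] - x[0]
    return float(x[idx] + tv * step)


def measure_teff(s: FieldSpectrum, prominence: float = 0.02) -> float:
    """Half the splitting between the outermost low-field maximum and
    high-field minimum of the first-derivative spectrum (Gauss).

    ``prominence`` is the minimum peak prominence as a fraction of the
    peak-to-peak amplitude; extrema merging into the central triplet (fully
    averaged spectra) raise :class:`UnresolvedSplittingError`.
    """
    y = s.intensity
    ptp = s.peak_to_peak()
    if ptp <= 0:
        raise UnresolvedSplittingError("flat spectrum")
    maxima, _ = find_peaks(y, prominence=prominence * ptp)
    minima, _ = find_peaks(-y, prominence=prominence * ptp)
    if maxima.size == 0 or minima.size == 0:
        raise UnresolvedSplittingError(
            "no resolvable outer extrema; spectrum is in the fast-motion regime"
        )
    i_lo = maxima[0]  # outermost low-field maximum
    i_hi = minima[-1]  # outermost high-field minimum
    if i_hi <= i_lo:
        raise UnresolvedSplittingError("outer extrema not resolved")
    b_lo = _parabolic_refine(s.field, y, i_lo)
    b_hi = _parabolic_refine(s.field, y, i_hi)
    return 0.5 * (b_hi - b_lo)


def tau_eff(T_eff: float, a: float = GOLDMAN_A, b: float = GOLDMAN_B,
            T_max: float = T_MAX) -> float:
    """Effective rotational correlation time (s) from the outer splitting.

    Implements τ_eff = a(1 − T_eff/T_max)^b; strictly increasing in T_eff on
    [0, T_max) since b < 0.
    """
    if T_eff < 0:
        raise ValueError("T_eff must be non-negative")
    if T_eff >= T_max:
        raise RigidLimitError(
            f"T_eff = {T_eff} G at or beyond the rigid limit {T_max} G; "
            "no finite correlation time"
        )
    return a * (1.0 - T_eff / T_max) ** b


def slow_fast_ratio(
    s: FieldSpectrum,
    slow_window: tuple[float, float],
    fast_window: tuple[float, float],
) -> float:
    """Peak-height ratio of the slow to fast component at low field.

    ``slow_window`` must sit at lower field than ``fast_window`` (the
    immobilized feature appears outside the motionally narrowed line); the
    ratio compares the maximum |intensity| within each window and is
    invariant under overall intensity scaling.
    """
    s_lo, s_hi = slow_window
    f_lo, f_hi = fast_window
    if s_hi > f_lo:
        raise ValueError("slow window must lie at lower field than fast window")
    for name, (lo, hi) in (("slow", slow_window), ("fast", fast_window)):
        if lo >= hi:
            raise ValueError(f"{name} window is empty")
        if lo < s.field[0] or hi > s.field[-1]:
            raise ValueError(f"{name} window outside the field axis")
    m_slow = (s.field >= s_lo) & (s.field <= s_hi)
    m_fast = (s.field >= f_lo) & (s.field <= f_hi)
    if not m_slow.any() or not m_fast.any():
        raise ValueError("window contains no samples")
    num = float(np.abs(s.intensity[m_slow]).max())
    den = float(np.abs(s.intensity[m_fast]).max())
    if den == 0:
        raise ValueError("fast window has zero amplitude")
    return num / den


def analyze_mobility(
    s: FieldSpectrum,
    slow_window: tuple[float, float] | None = None,
    fast_window: tuple[float, float] | None = None,
    prominence: float = 0.02,
) -> MobilityResult:
    """Convenience wrapper: T_eff, τ_eff and (optionally) slow/fast ratio."""
    T = measure_teff(s, prominence=prominence)
    try:
        tau = tau_eff(T)
    except RigidLimitError:
        tau = None
    ratio = None
    if slow_window is not None and fast_window is not None:
        ratio = slow_fast_ratio(s, slow_window, fast_window)
    return MobilityResult(T_eff=T, tau_eff=tau, slow_fast_ratio=ratio)


def _fast_feature_windows(
    reference: FieldSpectrum, n_features: int = 3, half_width: float = 3.0
) -> np.ndarray:
    """Boolean mask over the axis marking the sharp fast-motion features.

    The features are the ``n_features`` most prominent extrema of the
    reference spectrum, each extended ±``half_width`` G.
    """
    y = reference.intensity
    ptp = reference.peak_to_peak()
    cands = []
    for sign in (1.0, -1.0):
        peaks, props = find_peaks(sign * y, prominence=1e-3 * ptp)
        cands.extend(zip(peaks, props["prominences"]))
    if not cands:
        raise ValueError("reference spectrum has no detectable features")
    cands.sort(key=lambda t: -t[1])
    mask = np.zeros(reference.n_points, dtype=bool)
    for idx, _ in cands[:n_features]:
        center = reference.field[idx]
        mask |= np.abs(reference.field - center) <= half_width
    return mask


def subtract_component(
    composite: FieldSpectrum,
    reference: FieldSpectrum,
    step: float = 0.005,
    n_features: int = 3,
    feature_half_width: float = 3.0,
) -> SubtractionResult:
    """Remove the mobile reference component from a two-component composite.

    Grid-searches the removed fraction x ∈ [0, 1] (then refines locally by
    parabola) minimizing the sharp-feature content of the residual
    ``composite − x·reference`` within the fast-feature windows auto-detected
    from the reference, subject to the difference's double integral staying
    above −1% of the composite's.  "Sharp content" is the squared second
    difference of the residual, which nulls the narrow fast-motion lines
    while being nearly blind to the broad immobilized background that
    overlaps the same field region.  Both inputs should be normalized to the
    same number of spins.
    """
    if not composite.same_axis(reference):
        raise AxisMismatchError("composite and reference must share one axis")
    mask = _fast_feature_windows(reference, n_features, feature_half_width)
    curv_c = np.diff(composite.intensity, 2)[mask[1:-1]]
    curv_r = np.diff(reference.intensity, 2)[mask[1:-1]]
    di_comp = double_integral(composite).value
    di_ref = double_integral(reference).value

    xs = np.arange(0.0, 1.0 + step / 2, step)
    # quadratic criterion in x, evaluated exactly on the grid
    crit = np.array([float(np.sum((curv_c - x * curv_r) ** 2)) for x in xs])
    feasible = di_comp - xs * di_ref >= -0.01 * abs(di_comp)
    if not feasible.any():
        feasible[:] = True
    crit_masked = np.where(feasible, crit, np.inf)
    i = int(np.argmin(crit_masked))
    boundary = i in (0, xs.size - 1)
    x = _parabolic_refine(xs, crit, i) if not boundary else float(xs[i])
    x = float(np.clip(x, 0.0, 1.0))
    diff = composite.with_intensity(
        composite.intensity - x * reference.intensity, label="difference"
    )
    ptp = diff.peak_to_peak()
    multiplier = composite.peak_to_peak() / ptp if ptp > 0 else 1.0
    return SubtractionResult(
        fraction=x,
        difference=diff,
        criterion_value=float(np.sum((curv_c - x * curv_r) ** 2)),
        multiplier=float(multiplier),
        boundary=boundary,
    )
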