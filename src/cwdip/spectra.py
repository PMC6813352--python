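"""Field-swept CW-EPR spectrum container, I/O, integration and normalization.

A continuous-wave EPR spectrum is recorded as the first derivative of the
microwave absorption versus the swept magnetic field.  The number of spins in
the sample is proportional to the *double* integral of that derivative, which
is the basis for spin-count normalization when comparing single- and
double-labeled samples.

All field values are in Gauss throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or array violates the format contract."""


class AxisMismatchError(ValueError):
    """Raised when two spectra are combined on different field axes."""


class DegenerateSpectrumError(ValueError):
    """Raised when an operation requires a non-degenerate spectrum."""


_MIN_POINTS = 64
_AXIS_RTOL = 1e-9


@dataclass
class FieldSpectrum:
    """A uniformly sampled first-derivative EPR spectrum.

    Parameters
    ----------
    field :
        Magnetic-field axis in Gauss, strictly increasing, uniformly spaced,
        at least 64 points.
    intensity :
        First-derivative absorption signal (arbitrary units), same length.
    center_field, sweep_width :
        Acquisition metadata in Gauss; derived from the axis when omitted.
    mw_frequency :
        Microwave frequency in GHz (X-band default 9.6).
    temperature :
        Sample temperature in Kelvin (rigid-limit default 170).
    label :
        Free-text sample identifier.
    """

    field: np.ndarray
    intensity: np.ndarray
    center_field: float | None = None
    sweep_width: float | None = None
    mw_frequency: float = 9.6
    temperature: float = 170.0
    label: str = ""

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.field.shape != self.intensity.shape:
            raise SpectrumFormatError(
                "field and intensity must be 1-D arrays of equal length"
            )
        if self.field.size < _MIN_POINTS:
            raise SpectrumFormatError(
                f"spectrum needs >= {_MIN_POINTS} points, got {self.field.size}"
            )
        steps = np.diff(self.field)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 1
            raise SpectrumFormatError(
                f"field axis not strictly increasing at row {bad}"
            )
        dB = steps[0]
        if not np.allclose(steps, dB, rtol=_AXIS_RTOL, atol=_AXIS_RTOL * dB):
            bad = int(np.argmax(~np.isclose(steps, dB, rtol=_AXIS_RTOL))) + 1
            raise SpectrumFormatError(
                f"field axis not uniformly spaced at row {bad}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumFormatError("intensity contains non-finite values")
        span = float(self.field[-1] - self.field[0])
        if self.sweep_width is None:
            self.sweep_width = span
        elif abs(self.sweep_width - span) > dB:
            raise SpectrumFormatError(
                f"sweep_width {self.sweep_width} G inconsistent with axis span "
                f"{span:.6g} G"
            )
        if self.center_field is None:
            self.center_field = float(0.5 * (self.field[0] + self.field[-1]))

    @property
    def step(self) -> float:
        """Field increment in Gauss."""
        return float(self.field[1] - self.field[0])

    @property
    def n_points(self) -> int:
        return int(self.field.size)

    def peak_to_peak(self) -> float:
        """Peak-to-peak amplitude of the derivative signal."""
        return float(self.intensity.max() - self.intensity.min())

    def same_axis(self, other: "FieldSpectrum") -> bool:
        return self.field.shape == other.field.shape and np.allclose(
            self.field, other.field, rtol=_AXIS_RTOL, atol=1e-9
        )

    def with_intensity(self, intensity: np.ndarray, **meta) -> "FieldSpectrum":
        """Copy with a new intensity array (and optionally new metadata)."""
        return replace(self, intensity=np.asarray(intensity, float), **meta)


@dataclass
class SpinCount:
    """Double integral of a first-derivative spectrum (a.u.·G²).

    ``warning`` is set when the baseline-corrected absorption dips
    significantly negative, indicating a distorted or drifting spectrum.
    """

    value: float
    baseline_window_fraction: float = 0.05
    warning: bool = False


_HEADER_KEYS = {
    "center_field_G": ("center_field", float),
    "sweep_width_G": ("sweep_width", float),
    "mw_frequency_GHz": ("mw_frequency", float),
    "temperature_K": ("temperature", float),
    "label": ("label", str),
}


def read_spectrum(path, dialect: str = "two-column-ascii") -> FieldSpectrum:
    """Read a spectrum from a two-column ASCII file.

    The native dialect is whitespace-separated ``field_G  intensity`` rows
    with optional ``# key: value`` header lines (keys ``center_field_G``,
    ``sweep_width_G``, ``mw_frequency_GHz``, ``temperature_K``, ``label``).
    ``dialect="jcamp-dx-like"`` additionally accepts ``##KEY=value`` headers.
    """
    if dialect not in ("two-column-ascii", "jcamp-dx-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##") and dialect == "jcamp-dx-like":
                key, _, val = line[2:].partition("=")
                _store_header(meta, key.strip(), val.strip())
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                _store_header(meta, key.strip(), val.strip())
                continue
            parts = line.split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}: row {lineno}: expected two columns"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: row {lineno}: non-numeric value"
                ) from exc
    if len(rows) < _MIN_POINTS:
        raise SpectrumFormatError(
            f"{path}: needs >= {_MIN_POINTS} data rows, got {len(rows)}"
        )
    arr = np.asarray(rows, dtype=float)
    try:
        return FieldSpectrum(arr[:, 0], arr[:, 1], **meta)
    except SpectrumFormatError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def _store_header(meta: dict, key: str, val: str) -> None:
    if key in _HEADER_KEYS:
        attr, conv = _HEADER_KEYS[key]
        meta[attr] = conv(val)


def write_spectrum(s: FieldSpectrum, path) -> None:
    """Write a spectrum in the native ASCII dialect at full precision."""
    buf = io.StringIO()
    buf.write(f"# center_field_G: {float(s.center_field)!r}\n")
    buf.write(f"# sweep_width_G: {float(s.sweep_width)!r}\n")
    buf.write(f"# mw_frequency_GHz: {float(s.mw_frequency)!r}\n")
    buf.write(f"# temperature_K: {float(s.temperature)!r}\n")
    if s.label:
        buf.write(f"# label: {s.label}\n")
    for b, y in zip(s.field.tolist(), s.intensity.tolist()):
        buf.write(f"{b!r} {y!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def to_csv(s: FieldSpectrum, path) -> None:
    """Export a spectrum as a two-column CSV (field_G, intensity)."""
    import pandas as pd

    pd.DataFrame({"field_G": s.field, "intensity": s.intensity}).to_csv(
        path, index=False
    )


def _edge_baseline(field, signal, window_fraction):
    """Linear baseline through the outer edge windows of a signal."""
    n = field.size
    k = max(2, int(round(window_fraction * n)))
    idx = np.r_[0:k, n - k : n]
    coeff = np.polyfit(field[idx], signal[idx], 1)
    return np.polyval(coeff, field)


def double_integral(
    s: FieldSpectrum,
    baseline_window_fraction: float = 0.05,
    correct_baseline: bool = True,
) -> SpinCount:
    """Double integral of the first-derivative spectrum.

    A linear baseline fit to the outer edge windows is removed from the
    derivative, the result is integrated once (trapezoid) to the absorption
    lineshape, the absorption is re-zeroed at both edges by subtracting a
    linear ramp, and a second trapezoid integration yields the spin count.
    The result is proportional to the number of spins in the sample.

    With ``correct_baseline=False`` the derivative is integrated as-is
    (no edge-window fit, no ramp) — useful for exact-conservation checks on
    synthetic spectra that have no baseline by construction.
    """
    if not (0.0 < baseline_window_fraction <= 0.25):
        raise ValueError("baseline_window_fraction must be in (0, 0.25]")
    if not correct_baseline:
        absorption = _cumtrapz0(s.intensity, s.field)
        return SpinCount(
            float(np.trapezoid(absorption, s.field)), baseline_window_fraction
        )
    y = s.intensity - _edge_baseline(s.field, s.intensity, baseline_window_fraction)
    absorption = _cumtrapz0(y, s.field)
    # re-zero the absorption edges against drift before the second integral
    ramp = absorption[0] + (absorption[-1] - absorption[0]) * (
        (s.field - s.field[0]) / (s.field[-1] - s.field[0])
    )
    absorption = absorption - ramp
    value = float(np.trapezoid(absorption, s.field))
    scale = float(np.abs(absorption).max())
    warning = bool(scale > 0 and absorption.min() < -0.05 * scale and value <= 0)
    return SpinCount(value, baseline_window_fraction, warning)


def _cumtrapz0(y, x):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def normalize_to_spins(
    s: FieldSpectrum,
    reference: FieldSpectrum,
    baseline_window_fraction: float = 0.05,
    correct_baseline: bool = True,
) -> FieldSpectrum:
    """Scale ``s`` so its double integral matches that of ``reference``.

    Both spectra must share one field axis; the returned spectrum represents
    the same lineshape at the reference's spin count.  For drift-free
    spectra (in particular generator output, where heavy dipolar broadening
    legitimately raises the edge level) pass ``correct_baseline=False`` so
    the edge-window fit does not remove real broadened signal.
    """
    if not s.same_axis(reference):
        raise AxisMismatchError("spectra must share an identical field axis")
    di_ref = double_integral(
        reference, baseline_window_fraction, correct_baseline
    ).value
    di_s = double_integral(s, baseline_window_fraction, correct_baseline).value
    if abs(di_ref) < 1e-300 or abs(di_s) < 1e-300:
        raise DegenerateSpectrumError("zero spin count; cannot normalize")
    return s.with_intensity(s.intensity * (di_ref / di_s))


def resample(s: FieldSpectrum, target_axis: np.ndarray) -> FieldSpectrum:
    """Cubic-spline resampling of a spectrum onto a new field axis.

    The target axis must lie inside the source range (no extrapolation).
    """
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis[0] < s.field[0] - 1e-12 or target_axis[-1] > s.field[-1] + 1e-12:
        raise ValueError(
            "target axis extends beyond the source field range "
            f"[{s.field[0]:.6g}, {s.field[-1]:.6g}] G"
        )
    spline = CubicSpline(s.field, s.intensity)
    return FieldSpectrum(
        target_axis,
        spline(target_axis),
        mw_frequency=s.mw_frequency,
        temperature=s.temperature,
        label=s.label,
    )
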