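"""Dipolar kernel and forward-model properties.

The analytic oracle used here inverts the powder angle distribution in
closed form: for a stick at offset B(u) = ±(Δ/2)(3u² − 1) with u = cos θ
uniform on [0, 1] per hemisphere branch, the mass in an offset bin equals
the u-interval it maps from, u(B) = sqrt((2B/Δ + 1)/3).  This path shares
no code with the θ-grid deposition used by the implementation.
"""

import numpy as np
import pytest

from cwdip.dipolar import (
    C_DD_G_NM3,
    DIPOLAR_FREQ_MHZ_NM3,
    MHZ_PER_GAUSS,
    DistanceComponent,
    DistanceModel,
    KernelTruncationError,
    _circular_convolve,
    distribution_kernel,
    forward_model,
    offsets_for,
    pake_kernel,
)
from cwdip.simulate import NitroxideSystem, simulate_powder
from cwdip.spectra import double_integral


def analytic_pake_bin_masses(r: float, offsets: np.ndarray) -> np.ndarray:
    """Closed-form Pake kernel: per-bin mass from the u = cos θ CDF."""
    delta = C_DD_G_NM3 / r**3
    edges = np.r_[offsets - 0.5 * np.diff(offsets)[0],
                  offsets[-1] + 0.5 * np.diff(offsets)[0]]

    def branch_cdf(b):  # mass of one branch below offset b
        u2 = (2.0 * np.clip(b, -delta / 2, delta) / delta + 1.0) / 3.0
        return np.sqrt(np.clip(u2, 0.0, 1.0))

    mass = branch_cdf(edges[1:]) - branch_cdf(edges[:-1])
    mass = 0.5 * (mass + mass[::-1])  # the mirrored branch
    return mass / mass.sum()


@pytest.fixture(scope="module")
def offsets():
    """Offset axis for single-distance kernels at r >= 0.8 nm."""
    return offsets_for(0.195, 0.8)


@pytest.fixture(scope="module")
def full_offsets():
    """Offset axis holding the full distance grid (down to 0.4 nm), needed
    when a Gaussian component's lower tail reaches short distances."""
    return offsets_for(0.195, 0.4)


class TestPakeKernel:
    def test_dipolar_constant_from_physical_constants(self):
        # ν_dd(1 nm) = 52.04 MHz and 2.8025 MHz/G are the conventional values
        assert DIPOLAR_FREQ_MHZ_NM3 == pytest.approx(52.04, abs=0.01)
        assert MHZ_PER_GAUSS == pytest.approx(2.8025, abs=0.001)
        assert C_DD_G_NM3 == pytest.approx(52.04 / 2.8025, rel=1e-3)

    def test_perpendicular_splitting_at_1nm(self, offsets):
        # peak-to-peak of the absorption kernel = C_dd / r^3 ≈ 18.6 G
        k = pake_kernel(1.0, offsets)
        pos = offsets[np.argmax(np.where(offsets > 0, k.weights, -1.0))]
        neg = offsets[np.argmax(np.where(offsets < 0, k.weights, -1.0))]
        assert pos - neg == pytest.approx(C_DD_G_NM3, abs=2 * k.step)
        assert pos - neg == pytest.approx(18.6, abs=2 * k.step)

    def test_unit_area_and_exact_symmetry(self, offsets):
        for r in (0.8, 1.0, 1.7, 2.5):
            k = pake_kernel(r, offsets)
            assert k.weights.sum() * k.step == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_array_equal(k.weights, k.weights[::-1])

    def test_inverse_cube_scaling(self, offsets):
        k1 = pake_kernel(1.0, offsets)
        k2 = pake_kernel(2.0, offsets)
        peak1 = offsets[np.argmax(np.where(offsets > 0, k1.weights, -1.0))]
        peak2 = offsets[np.argmax(np.where(offsets > 0, k2.weights, -1.0))]
        assert peak2 == pytest.approx(peak1 / 8.0, abs=2 * k1.step)

    def test_large_distance_concentrates_at_zero(self, offsets):
        k = pake_kernel(10.0, offsets)
        near = np.abs(k.offsets) <= k.step
        assert k.weights[near].sum() * k.step > 0.999

    def test_matches_analytic_powder_average(self):
        for r in (0.9, 1.2, 1.8):
            # resolve the pattern: ~100 bins across the parallel extent
            delta = C_DD_G_NM3 / r**3
            step = delta / 100.0
            offs = np.arange(-120, 121) * step
            k = pake_kernel(r, offs)
            oracle = analytic_pake_bin_masses(r, offs)
            impl = k.weights * k.step
            # away from the integrable singularity the bin masses agree
            smooth = np.abs(np.abs(offs) - delta / 2) > 3 * step
            np.testing.assert_allclose(
                impl[smooth], oracle[smooth], atol=2e-3 * oracle.max()
            )
            assert impl[smooth].sum() == pytest.approx(
                oracle[smooth].sum(), abs=2e-3
            )

    def test_second_moment_closed_form(self, offsets):
        # E[x²] over the Pake pattern = (Δ/2)² · 4/5 with u = cos θ uniform
        for r in (0.9, 1.2):
            k = pake_kernel(r, offsets)
            m2 = np.sum(k.weights * k.offsets**2) * k.step
            delta = C_DD_G_NM3 / r**3
            assert m2 == pytest.approx(0.8 * (delta / 2) ** 2, rel=1e-3)

    def test_truncated_axis_rejected(self):
        small = np.arange(-10, 10.1, 0.2)
        with pytest.raises(KernelTruncationError):
            pake_kernel(0.8, small)


class TestDistributionKernel:
    def test_delta_width_limit(self, offsets):
        narrow = distribution_kernel(DistanceComponent(1.2, 1e-4, 1.0), offsets)
        point = pake_kernel(1.2, offsets)
        np.testing.assert_allclose(narrow.weights, point.weights, atol=1e-6)

    def test_wider_distribution_is_flatter(self, full_offsets):
        # flattening holds while the Gaussian stays clear of long distances;
        # beyond that the near-zero-offset tail sharpens the peak again,
        # so the monotone check stops at moderate widths
        maxima = [
            distribution_kernel(DistanceComponent(1.2, dr, 1.0), full_offsets)
            .weights.max()
            for dr in (0.1, 0.3, 0.5)
        ]
        assert maxima[0] > maxima[1] > maxima[2]

    def test_peak_position_moves_inward_with_width(self, full_offsets):
        positions = []
        for dr in (0.1, 0.5, 1.0):
            k = distribution_kernel(DistanceComponent(1.2, dr, 1.0), full_offsets)
            positions.append(abs(k.offsets[np.argmax(k.weights)]))
        assert positions[0] > positions[1] > positions[2]

    def test_symmetry_and_unit_area(self, full_offsets):
        for r, dr in ((0.9, 0.1), (1.4, 0.5), (2.0, 1.5)):
            k = distribution_kernel(DistanceComponent(r, dr, 1.0), full_offsets)
            np.testing.assert_array_equal(k.weights, k.weights[::-1])
            assert k.weights.sum() * k.step == pytest.approx(1.0, abs=1e-9)


class TestConvolution:
    def test_fft_equals_direct_summation(self):
        # independent O(n²) circular convolution oracle on a 256-point grid
        rng = np.random.default_rng(5)
        n = 256
        field = np.linspace(3330, 3430, n)
        y = rng.normal(size=n)
        offs = offsets_for(field[1] - field[0], 1.2)
        k = pake_kernel(1.4, offs)
        fft_out = _circular_convolve(y, k)
        kd = k.weights * k.step
        center = (k.offsets.size - 1) // 2
        direct = np.zeros(n)
        for j in range(k.offsets.size):
            direct += kd[j] * np.roll(y, j - center)
        np.testing.assert_allclose(fft_out, direct, atol=1e-10)

    def test_forward_model_identity_for_noninteracting(self, rigid_single):
        out = forward_model(rigid_single, DistanceModel((), f_non=1.0))
        np.testing.assert_array_equal(out.intensity, rigid_single.intensity)

    def test_area_conservation(self, rigid_single):
        di0 = double_integral(rigid_single, correct_baseline=False).value
        for model in (
            DistanceModel.single(0.9, 0.1, 1.0),
            DistanceModel.single(1.5, 0.3, 0.6),
            DistanceModel.double(0.9, 0.1, 0.5, 1.8, 0.4, 0.3),
        ):
            out = forward_model(rigid_single, model)
            di = double_integral(out, correct_baseline=False).value
            assert di == pytest.approx(di0, rel=1e-6)

    def test_linear_in_fractions(self, rigid_single):
        m_a = DistanceModel.single(0.9, 0.1, 1.0)
        m_b = DistanceModel.single(1.8, 0.3, 1.0)
        mixed = DistanceModel.double(0.9, 0.1, 0.4, 1.8, 0.3, 0.6)
        out_mixed = forward_model(rigid_single, mixed)
        combo = (
            0.4 * forward_model(rigid_single, m_a).intensity
            + 0.6 * forward_model(rigid_single, m_b).intensity
        )
        np.testing.assert_allclose(out_mixed.intensity, combo, atol=1e-12)

    def test_broadening_monotone_in_inverse_cube(self, rigid_single):
        near = forward_model(rigid_single, DistanceModel.single(0.9, 0.1, 0.5))
        far = forward_model(rigid_single, DistanceModel.single(1.8, 0.1, 0.5))
        amp0 = rigid_single.peak_to_peak()
        assert near.peak_to_peak() < far.peak_to_peak() < amp0

    def test_beyond_2p5nm_indistinguishable_from_noninteracting(self):
        # for r >= 2.5 nm the broadening is below the intrinsic 3 G linewidth
        single = simulate_powder(NitroxideSystem(), orientations=400)
        out = forward_model(single, DistanceModel.single(2.5, 0.04, 1.0))
        rms = np.sqrt(np.mean((out.intensity - single.intensity) ** 2))
        assert rms < 0.02 * single.peak_to_peak()


class TestDistanceModelValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            DistanceModel((DistanceComponent(1.0, 0.1, 0.5),), f_non=0.6)

    def test_component_count_enforced(self):
        comps = tuple(DistanceComponent(1.0 + 0.2 * i, 0.1, 0.3) for i in range(3))
        with pytest.raises(ValueError):
            DistanceModel(comps, f_non=0.1)

    def test_sorted_by_r_orders_components(self):
        m = DistanceModel.double(1.8, 0.3, 0.3, 0.9, 0.1, 0.5)
        s = m.sorted_by_r()
        assert [c.r for c in s.components] == [0.9, 1.8]

    def test_serialization_round_trip(self):
        m = DistanceModel.double(0.91, 0.10, 0.48, 1.21, 1.32, 0.29)
        back = DistanceModel.from_dict(m.to_dict())
        assert back == m
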