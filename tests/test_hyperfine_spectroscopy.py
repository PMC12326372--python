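"""HYSCORE ridge prediction and ELDOR-detected NMR spectra."""

import numpy as np
import pytest

from flavospin.fieldsweep import OrientationWeights
from flavospin.hyperfine_spectroscopy import (
    antidiagonal_crossings,
    difference_spectrum,
    eldor_stick_spectrum,
    hyscore_peaks,
    ridge_map,
)
from flavospin.spin_system import (
    GTensor,
    Nucleus,
    PrincipalTensor,
    SpinSystem,
    ValidationError,
    larmor_frequency,
)
from flavospin.synthetic import make_fixture


@pytest.fixture(scope="module")
def n15n5_peaks():
    system = make_fixture("15N5")
    return hyscore_peaks(system, 0, 1217.2, 34.15, 42.0)


@pytest.fixture(scope="module")
def n15n10_peaks():
    system = make_fixture("15N10")
    return hyscore_peaks(system, 0, 1217.2, 34.15, 42.0)


class TestHyscorePeaks:
    def test_strong_coupling_long_ridge(self, n15n5_peaks):
        """The highly anisotropic 15N(5) interaction (Az = 74 vs
        2*nu_L ~ 10.5 MHz) produces a long strong-coupling ridge in the
        (+,-) quadrant; only near-in-plane orientations (secular
        coupling 5.6) drop into the weak regime."""
        strong = n15n5_peaks.select(n15n5_peaks.quadrant == -1)
        assert len(strong) > 0
        assert strong.weight.sum() > 0
        coords = strong.coordinates()
        spread = coords.max(0) - coords.min(0)
        assert spread.max() > 25.0

    def test_weak_coupling_short_ridge_on_antidiagonal(self):
        """13C(2) with |A| < 2 MHz gives a short (+,+) ridge hugging the
        anti-diagonal through (nu_L, nu_L)."""
        system = make_fixture("13C2")
        peaks = hyscore_peaks(system, 0, 1221.4, 34.264, 42.0)
        nu_l = larmor_frequency("13C", 1221.4)
        assert np.all(peaks.quadrant == 1)
        assert np.all(np.abs(peaks.nu1 + peaks.nu2 - 2 * nu_l) < 0.5)
        assert np.all(np.abs(peaks.coordinates() - nu_l) < 2.0)

    def test_uncoupled_nucleus_sits_on_diagonal(self):
        system = SpinSystem(g=GTensor())
        system.add_nucleus(Nucleus("13C"), PrincipalTensor((0.0, 0.0, 0.0)))
        peaks = hyscore_peaks(system, 0, 1221.4, 34.264, 42.0)
        nu_l = larmor_frequency("13C", 1221.4)
        assert np.allclose(peaks.nu1, nu_l, atol=1e-9)
        assert np.allclose(peaks.nu2, nu_l, atol=1e-9)
        # fully allowed EPR transitions: no modulation, zero weight
        assert np.all(peaks.weight == 0.0)

    def test_strong_regime_frequency_difference_bound(self, n15n5_peaks):
        """|nu_alpha - nu_beta| <= 2 nu_L (+ curvature tolerance) for
        strong-coupling correlations."""
        nu_l = larmor_frequency("15N", 1217.2)
        diff = np.abs(n15n5_peaks.nu1 - n15n5_peaks.nu2)
        assert np.all(diff <= 2 * nu_l + 0.5)

    def test_phi_invariance_for_axial_collinear_tensor(self):
        """With an axial tensor collinear with g, peak positions depend
        on the polar angle only."""
        system = make_fixture("15N5")
        from flavospin.nuclear_freq import nuclear_frequencies_exact

        for cos_t in (0.3, 0.7):
            sin_t = np.sqrt(1 - cos_t**2)
            ref = None
            for phi in (0.0, 0.4, 1.1):
                n = (sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t)
                tset = nuclear_frequencies_exact(system, 0, n, 1217.2)
                freqs = np.array(tset.frequencies(0.5) + tset.frequencies(-0.5))
                if ref is None:
                    ref = freqs
                else:
                    assert np.allclose(freqs, ref, atol=1e-9)

    def test_empty_when_nothing_excited(self):
        system = make_fixture("15N5")
        with pytest.warns(UserWarning):
            sel = OrientationWeights(
                np.array([[0.0, 0.0, 1.0]]), np.array([1.0]), np.array([0.0])
            )
            peaks = hyscore_peaks(system, 0, 1217.2, orientations=sel)
        assert len(peaks) == 0


class TestAntidiagonalCrossings:
    def test_axial_weak_tensor_single_crossing_per_side(self, n15n10_peaks):
        """15N(10) in-plane coupling 3.2 MHz: crossings at nu_L +/- 1.6."""
        nu_l = larmor_frequency("15N", 1217.2)
        crossings = antidiagonal_crossings(n15n10_peaks, nu_l)
        assert len(crossings) == 2
        positions = sorted(c for c, _ in crossings)
        assert positions == pytest.approx([nu_l - 1.6, nu_l + 1.6], abs=0.1)
        for _, a_perp in crossings:
            assert a_perp == pytest.approx(3.2, abs=0.1)

    def test_rhombic_tensor_two_in_plane_values(self):
        """The 13C(4a) ridge ends recover |Ax| = 13.5 and |Ay| = 9 with
        signs opposite to Az (they fall in the weak (+,+) quadrant)."""
        system = make_fixture("13C4a")
        peaks = hyscore_peaks(system, 0, 1221.4, 34.264, 42.0)
        nu_l = larmor_frequency("13C", 1221.4)
        implied = sorted({round(a, 1) for _, a in antidiagonal_crossings(peaks, nu_l)})
        assert implied[0] == pytest.approx(9.0, abs=0.3)
        assert implied[-1] == pytest.approx(13.5, abs=0.3)

    def test_empty_peak_set_rejected(self):
        from flavospin.hyperfine_spectroscopy import CorrelationPeakSet

        with pytest.raises(ValidationError):
            antidiagonal_crossings(
                CorrelationPeakSet(np.empty(0), np.empty(0), np.empty(0, dtype=int),
                                   np.empty(0), [], np.empty(0, dtype=int)),
                5.0,
            )


class TestRidgeMap:
    def test_mass_conservation_and_symmetry(self, n15n10_peaks):
        m = ridge_map(n15n10_peaks, freq_range_MHz=(0.0, 30.0), n_points=256)
        assert m.intensity.sum() == pytest.approx(n15n10_peaks.weight.sum(), abs=1e-6)
        assert np.allclose(m.intensity, m.intensity.T)

    def test_coarse_grid_warns(self, n15n10_peaks):
        with pytest.warns(UserWarning, match="coarse"):
            ridge_map(n15n10_peaks, freq_range_MHz=(0.0, 50.0), n_points=32)


class TestEldor:
    def test_13c4a_tail_signal_shape(self):
        """Tail-observer ELDOR of 13C(4a): signal support ~[6, 33] MHz on
        each side with maxima near the strong-coupling pair +/-30, +/-11."""
        system = make_fixture("13C4a-labeled")
        spec = eldor_stick_spectrum(system, 3, 1225.0, 34.264, 1.0)
        pos = spec.amplitude[spec.axis > 0]
        axis = spec.axis[spec.axis > 0]
        support = axis[pos > 0.02 * pos.max()]
        assert support.min() == pytest.approx(6.0, abs=2.0)
        assert support.max() == pytest.approx(33.0, abs=2.0)
        upper = axis[(axis > 20)]
        peak_hi = upper[np.argmax(pos[axis > 20])]
        lower = axis[(axis < 20)]
        peak_lo = lower[np.argmax(pos[axis < 20])]
        assert peak_hi == pytest.approx(30.0, abs=2.0)
        assert peak_lo == pytest.approx(11.0, abs=2.0)
        # mirror symmetry about the detection frequency
        neg = spec.amplitude[spec.axis < 0][::-1]
        assert np.allclose(neg, pos, atol=1e-9)

    def test_canonical_orientation_gives_zero_signal(self):
        system = make_fixture("13C4a")
        single = OrientationWeights(
            np.array([[0.0, 0.0, 1.0]]), np.array([1.0]), np.array([1.0])
        )
        spec = eldor_stick_spectrum(system, 0, 1225.0, orientations=single)
        assert np.all(spec.amplitude == 0.0)

    def test_uncoupled_nucleus_gives_zero_signal(self):
        system = SpinSystem(g=GTensor())
        system.add_nucleus(Nucleus("13C"), PrincipalTensor((0.0, 0.0, 0.0)))
        spec = eldor_stick_spectrum(system, 0, 1222.7, 34.264, 1.0)
        assert np.all(spec.amplitude == 0.0)


class TestDifferenceSpectrum:
    def test_isolates_added_nucleus(self):
        """The [13C(2,4a)] minus [13C(2)] subtraction leaves only the
        13C(4a) sticks: stick accumulation is linear over nuclei when the
        same orientation selection applies to both samples."""
        from flavospin.fieldsweep import orientation_selection

        both = make_fixture("13C4a-labeled")  # wt nuclei + 13C(4a)
        sel = orientation_selection(both, 1225.0, 34.264, 1.0, n_knots=400)

        def total(system, indices):
            specs = [
                eldor_stick_spectrum(system, i, 1225.0, orientations=sel)
                for i in indices
            ]
            out = specs[0].copy()
            out.amplitude = np.sum([s.amplitude for s in specs], axis=0)
            return out

        labeled = total(both, range(4))
        background = total(both, range(3))
        diff = difference_spectrum(labeled, background)
        only_4a = eldor_stick_spectrum(both, 3, 1225.0, orientations=sel)
        assert np.allclose(diff.amplitude, only_4a.amplitude, atol=1e-9)

    def test_anticommutative(self):
        axis = np.linspace(-5, 5, 11)
        a = np.random.default_rng(0).normal(size=11)
        b = np.random.default_rng(1).normal(size=11)
        from flavospin.fieldsweep import Spectrum1D

        s1 = Spectrum1D(axis, a, "MHz", "stick")
        s2 = Spectrum1D(axis, b, "MHz", "stick")
        d12 = difference_spectrum(s1, s2)
        d21 = difference_spectrum(s2, s1)
        assert np.allclose(d12.amplitude, -d21.amplitude)

    def test_axis_mismatch_rejected(self):
        from flavospin.fieldsweep import Spectrum1D

        s1 = Spectrum1D(np.linspace(0, 1, 5), np.zeros(5), "MHz", "stick")
        s2 = Spectrum1D(np.linspace(0, 2, 5), np.zeros(5), "MHz", "stick")
        with pytest.raises(ValidationError):
            difference_spectrum(s1, s2)
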