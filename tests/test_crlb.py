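"""Single-line Fisher information, CRLB and dose-allocation sweeps."""

import numpy as np
import pytest

import dectsim as ds
from dectsim.crlb import (
    LineObject,
    _spectrum_terms,
    fisher_matrix,
    signal_moments,
    sweep_allocation,
    thickness_sweep,
    transmission,
)
from dectsim.spectra import SpectralPair

from .conftest import mono_spectrum


class TestTransmission:
    def test_empty_object_is_transparent(self, tissue, bone):
        obj = LineObject(0.0, 0.0)
        e = np.array([50.0, 100.0, 500.0])
        np.testing.assert_allclose(transmission(obj, tissue, bone, e), 1.0)

    def test_doubling_mass_squares_transmission(self, tissue, bone):
        e = np.geomspace(30.0, 3000.0, 20)
        t1 = transmission(LineObject(20.0, 1.0), tissue, bone, e)
        t2 = transmission(LineObject(40.0, 2.0), tissue, bone, e)
        np.testing.assert_allclose(t2, t1**2, rtol=1e-12)

    def test_hand_beer_lambert_at_100kev(self, tissue, bone):
        # A_t = 40, A_b = 1.85 g/cm^2 with tabulated knot values
        expected = np.exp(-(0.1705 * 40.0 + 0.1855 * 1.85))
        got = transmission(LineObject(40.0, 1.85), tissue, bone, np.array([100.0]))
        assert got[0] == pytest.approx(expected, rel=1e-12)


class TestSignalMoments:
    def test_counting_response_gives_poisson_variance(
        self, counting_detector, tissue, bone
    ):
        obj = LineObject(10.0, 1.0)
        s = ds.generate_kv_spectrum(120.0)
        s = ds.Spectrum(s.energies, s.fluence, dose_uGy=1.0)
        lam, sig2 = signal_moments([s], obj, tissue, bone, counting_detector)
        np.testing.assert_allclose(sig2, lam, rtol=1e-12)

    def test_single_bin_eid_variance(self, ideal_detector, tissue, bone):
        obj = LineObject(5.0, 0.5)
        e0 = 150.0
        s = mono_spectrum(e0, 1e5)
        lam, sig2 = signal_moments([s], obj, tissue, bone, ideal_detector)
        assert sig2[0] == pytest.approx(e0 * lam[0], rel=1e-12)

    def test_two_bin_hand_sum(self, ideal_detector, tissue, bone):
        obj = LineObject(2.0, 0.0)
        e = np.array([60.0, 100.0])
        n = np.array([1e4, 2e4])
        s = ds.Spectrum(e, n, dose_uGy=1.0)
        t = np.exp(-tissue.mu_rho(e) * 2.0)
        lam_hand = np.sum(e * n * t)
        sig2_hand = np.sum(e**2 * n * t)
        lam, sig2 = signal_moments([s], obj, tissue, bone, ideal_detector)
        assert lam[0] == pytest.approx(lam_hand, rel=1e-12)
        assert sig2[0] == pytest.approx(sig2_hand, rel=1e-12)


class TestFisherMatrix:
    def _toy_pair(self):
        return (mono_spectrum(60.0, 3e5, "lo"), mono_spectrum(120.0, 3e5, "hi"))

    def test_symmetry(self, detector, tissue, bone):
        obj = LineObject.from_thickness(t_bone_cm=2.0)
        s1, s2 = self._toy_pair()
        fr = fisher_matrix((s1, s2), obj, tissue, bone, detector)
        assert fr.fisher[0, 1] == fr.fisher[1, 0]

    def test_analytic_derivatives_match_finite_differences(
        self, ideal_detector, tissue, bone
    ):
        s = ds.generate_kv_spectrum(120.0)
        s = ds.Spectrum(s.energies, s.fluence, dose_uGy=1.0)
        a = np.array([10.0, 2.0])
        h = 1e-4
        _, _, dlam, dsig2 = _spectrum_terms(
            s, LineObject(*a), tissue, bone, ideal_detector
        )
        for j in range(2):
            ap, am = a.copy(), a.copy()
            ap[j] += h
            am[j] -= h
            lp, sp = signal_moments([s], LineObject(*ap), tissue, bone, ideal_detector)
            lm, sm = signal_moments([s], LineObject(*am), tissue, bone, ideal_detector)
            assert dlam[j] == pytest.approx((lp[0] - lm[0]) / (2 * h), rel=1e-6)
            assert dsig2[j] == pytest.approx((sp[0] - sm[0]) / (2 * h), rel=1e-6)

    def test_monoenergetic_closed_form(self, counting_detector, tissue, bone):
        # counting detector, two single lines: F = M^T diag(1/lam) M + 1/2 K
        e1, e2, n0 = 60.0, 120.0, 1e6
        obj = LineObject(5.0, 1.0)
        s1, s2 = mono_spectrum(e1, n0), mono_spectrum(e2, n0)
        fr = fisher_matrix((s1, s2), obj, tissue, bone, counting_detector)
        mu = np.array(
            [
                [float(tissue.mu_rho(e1)), float(bone.mu_rho(e1))],
                [float(tissue.mu_rho(e2)), float(bone.mu_rho(e2))],
            ]
        )
        lam = np.array(
            [
                n0 * np.exp(-(mu[0] @ obj.a)),
                n0 * np.exp(-(mu[1] @ obj.a)),
            ]
        )
        expected = np.zeros((2, 2))
        for i in range(2):
            grad = -lam[i] * mu[i]
            expected += np.outer(grad, grad) / lam[i]
            expected += 0.5 * np.outer(grad, grad) / lam[i] ** 2
        np.testing.assert_allclose(fr.fisher, expected, rtol=1e-10)

    def test_identical_spectra_flagged_singular(self, counting_detector, tissue, bone):
        s = mono_spectrum(80.0, 1e5)
        fr = fisher_matrix((s, s), obj := LineObject(5.0, 1.0),
                           tissue, bone, counting_detector)
        assert fr.singular
        np.testing.assert_array_equal(fr.snr, 0.0)


class TestSweeps:
    def test_swap_symmetry(self, detector, standard_spectra):
        obj = LineObject.from_thickness(t_bone_cm=1.0)
        a, b = standard_spectra["80kV"], standard_spectra["140kV"]
        fwd = sweep_allocation(SpectralPair(low=a, high=b), obj, detector=detector)
        rev = sweep_allocation(SpectralPair(low=b, high=a), obj, detector=detector)
        np.testing.assert_allclose(
            fwd.snr_tissue, rev.snr_tissue[::-1], rtol=1e-9
        )

    def test_snr_increases_with_total_dose(self, detector, standard_spectra):
        obj = LineObject.from_thickness(t_bone_cm=1.0)
        peaks = []
        for dose in (0.25, 0.5, 1.0, 2.0, 4.0):
            lo = ds.scale_to_dose(standard_spectra["80kV"], dose)
            hi = ds.scale_to_dose(standard_spectra["140kV"], dose)
            pair = SpectralPair(low=lo, high=hi, total_dose_uGy=dose)
            curve = sweep_allocation(pair, obj, detector=detector, r_grid=[0.5])
            peaks.append(curve.snr_tissue[0])
        assert np.all(np.diff(peaks) > 0)

    def test_grid_has_99_points_and_peak_on_grid(self, detector, standard_spectra):
        obj = LineObject.from_thickness(t_bone_cm=1.0)
        pair = SpectralPair(
            low=standard_spectra["80kV"], high=standard_spectra["140kV"]
        )
        curve = sweep_allocation(pair, obj, detector=detector)
        assert curve.r_grid.size == 99
        assert curve.peak_tissue[0] in curve.r_grid

    def test_tissue_snr_decreases_with_bone_thickness(
        self, detector, standard_spectra
    ):
        pair = SpectralPair(
            low=standard_spectra["80kV"], high=standard_spectra["140kV"]
        )
        sweep = thickness_sweep(pair, np.arange(1.0, 6.0), detector=detector)
        assert np.all(np.diff(sweep["peak_snr_tissue"]) < 0)
        assert np.all(np.isfinite(sweep["peak_snr_tissue"]))
        assert np.all(sweep["peak_snr_bone"] > 0)
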