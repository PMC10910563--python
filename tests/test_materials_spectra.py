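"""Material tables, synthetic spectra, dose normalization and allocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dectsim as ds
from dectsim.errors import (
    DegenerateInputError,
    EnergyRangeError,
    ParameterError,
    TableFormatError,
)
from dectsim.spectra import DOSE_FACTOR_UGY, SpectralPair, allocate

from .conftest import mono_spectrum

# Reference mass attenuation values (cm^2/g) transcribed once from the
# standard NIST/XCOM compilations; the packaged tables must agree within 2%.
XCOM_REFERENCE = {
    "water": [
        (10.0, 5.329), (20.0, 0.8096), (40.0, 0.2683), (60.0, 0.2059),
        (80.0, 0.1837), (100.0, 0.1707), (200.0, 0.1370), (500.0, 0.09687),
        (1000.0, 0.07072), (6000.0, 0.02770),
    ],
    "tissue": [
        (10.0, 5.367), (20.0, 0.8206), (40.0, 0.2698), (60.0, 0.2061),
        (80.0, 0.1837), (100.0, 0.1705), (200.0, 0.1367), (500.0, 0.09663),
        (1000.0, 0.07054), (6000.0, 0.02772),
    ],
    "bone": [
        (10.0, 28.51), (20.0, 4.001), (40.0, 0.6655), (60.0, 0.3148),
        (80.0, 0.2229), (100.0, 0.1855), (200.0, 0.1309), (500.0, 0.09022),
        (1000.0, 0.06566), (6000.0, 0.02734),
    ],
}


class TestMaterials:
    def test_knot_lookup_is_exact(self, water):
        # queries at tabulation knots return the stored value
        assert water.mu_rho(80.0) == pytest.approx(0.1837, rel=1e-12)
        assert water.muen_rho(1000.0) == pytest.approx(0.03103, rel=1e-12)

    def test_midbin_query_is_bracketed(self, water):
        # log-log interpolation stays between neighboring knots
        lo, hi = water.mu_rho(60.0), water.mu_rho(80.0)
        mid = water.mu_rho(70.0)
        assert min(lo, hi) < mid < max(lo, hi)

    @pytest.mark.parametrize("name", sorted(XCOM_REFERENCE))
    def test_tables_match_reference_values(self, name):
        mat = ds.get_material(name)
        for e, ref in XCOM_REFERENCE[name]:
            assert mat.mu_rho(e) == pytest.approx(ref, rel=0.02)

    def test_out_of_range_query_raises(self, water):
        with pytest.raises(EnergyRangeError):
            water.mu_rho(0.5)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("energy_kev,something\n10,0.5\n20,0.4\n", "missing required column"),
            ("energy_kev,mu_over_rho\n10,0.5\n10,0.4\n", "not strictly increasing"),
            ("energy_kev,mu_over_rho\n10,0.5\n20,-0.4\n", "non-positive"),
            ("energy_kev,mu_over_rho\n10,0.5\n20,abc\n", "row 3"),
        ],
    )
    def test_malformed_table_errors_name_the_row(self, tmp_path, content, match):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(TableFormatError, match=match):
            ds.load_attenuation_table(p, density=1.0)


class TestKvSpectrum:
    def test_endpoint_energy_equals_tube_voltage(self):
        s = ds.generate_kv_spectrum(80.0)
        assert s.energies[s.fluence > 0].max() < 80.0
        assert s.fluence[s.energies >= 80.0].sum() == 0.0

    def test_mean_energy_ordering_with_kvp(self):
        assert (
            ds.generate_kv_spectrum(140.0).mean_energy
            > ds.generate_kv_spectrum(80.0).mean_energy
        )

    def test_filtration_hardens_the_beam(self):
        soft = ds.generate_kv_spectrum(120.0, filtration_mm_al=2.0)
        hard = ds.generate_kv_spectrum(120.0, filtration_mm_al=6.0)
        assert hard.mean_energy > soft.mean_energy

    @pytest.mark.parametrize("kvp", [30.0, 160.0])
    def test_kvp_out_of_range(self, kvp):
        with pytest.raises(ParameterError):
            ds.generate_kv_spectrum(kvp)


class TestMvSpectrum:
    def test_treatment_beam_extends_to_endpoint(self):
        s = ds.generate_mv_spectrum(6.0, mode="treatment")
        assert s.energies.max() <= 6000.0
        assert s.fluence[s.energies < 6000.0].sum() > 0

    def test_detuned_endpoint_below_3mev(self):
        s = ds.generate_mv_spectrum(mode="detuned")
        assert s.energies[s.fluence > 0].max() < 3000.0
        with pytest.raises(ParameterError):
            ds.generate_mv_spectrum(4.0, mode="detuned")

    def test_detuned_softer_than_treatment(self):
        assert (
            ds.generate_mv_spectrum(mode="detuned").mean_energy
            < ds.generate_mv_spectrum(mode="treatment").mean_energy
        )


class TestDose:
    def test_monoenergetic_closed_form(self, water):
        # single-term quadrature: N * exp(-mu_w d) * (muen/rho) * E
        e0, n0, d = 100.0, 1e6, 20.0
        s = mono_spectrum(e0, n0)
        expected = (
            DOSE_FACTOR_UGY
            * n0
            * np.exp(-float(water.mu(e0)) * d)
            * float(water.muen_rho(e0))
            * e0
        )
        assert ds.dose_at_depth(s, depth_cm=d) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=0.0, max_value=1e6))
    def test_dose_is_linear_in_fluence(self, c):
        s = ds.generate_kv_spectrum(100.0)
        base = ds.dose_at_depth(s)
        assert ds.dose_at_depth(s.scaled(c)) == pytest.approx(c * base, rel=1e-12)

    def test_zero_fluence_spectrum_has_zero_dose(self):
        s = ds.Spectrum(np.array([50.0, 60.0]), np.array([0.0, 0.0]))
        assert ds.dose_at_depth(s) == 0.0
        with pytest.raises(DegenerateInputError):
            ds.scale_to_dose(s)

    def test_scale_to_dose_hits_target_and_is_idempotent(self):
        s = ds.generate_kv_spectrum(120.0)
        s1 = ds.scale_to_dose(s, 1.0)
        assert ds.dose_at_depth(s1) == pytest.approx(1.0, rel=1e-9)
        s2 = ds.scale_to_dose(s1, 1.0)
        np.testing.assert_allclose(s2.fluence, s1.fluence, rtol=1e-12)
        s_double = ds.scale_to_dose(s, 2.0)
        np.testing.assert_allclose(s_double.fluence, 2.0 * s1.fluence, rtol=1e-12)


class TestAllocation:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(r=st.floats(min_value=0.01, max_value=0.99))
    def test_dose_conservation_over_r(self, r, standard_spectra):
        pair = SpectralPair(
            low=standard_spectra["80kV"], high=standard_spectra["140kV"], r=r
        )
        low, high = allocate(pair)
        d_lo, d_hi = ds.dose_at_depth(low), ds.dose_at_depth(high)
        assert d_hi == pytest.approx(r * pair.total_dose_uGy, rel=1e-9)
        assert d_lo + d_hi == pytest.approx(pair.total_dose_uGy, rel=1e-9)

    def test_table_style_split(self, standard_spectra):
        pair = SpectralPair(
            low=standard_spectra["80kV"], high=standard_spectra["detunedMV"], r=0.92
        )
        _, high = allocate(pair)
        assert ds.dose_at_depth(high) == pytest.approx(0.92, rel=1e-9)

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.2, 1.5])
    def test_r_outside_unit_interval(self, r, standard_spectra):
        with pytest.raises(ParameterError):
            SpectralPair(
                low=standard_spectra["80kV"], high=standard_spectra["140kV"], r=r
            )

    def test_unnormalized_member_rejected(self, standard_spectra):
        raw = ds.generate_kv_spectrum(80.0)  # no dose tag
        with pytest.raises(ParameterError):
            allocate(SpectralPair(low=raw, high=standard_spectra["140kV"]))


class TestSpectrumFiles:
    def test_round_trip(self, tmp_path):
        s = ds.scale_to_dose(ds.generate_kv_spectrum(100.0), 1.0)
        p = tmp_path / "spec.csv"
        ds.write_spectrum(s, p)
        back = ds.read_spectrum(p)
        np.testing.assert_allclose(back.energies, s.energies)
        np.testing.assert_allclose(back.fluence, s.fluence, rtol=1e-9)
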