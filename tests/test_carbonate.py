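"""Carbonate constants, speciation, saturation state, and unit plumbing."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from achromatium.carbonate import (
    WaterSample,
    calcite_proton_yield,
    compute_constants,
    conductivity_to_salinity,
    hydrogen_activity_coefficient,
    omega_calcite,
    read_water_samples,
    speciate,
)
from achromatium.errors import InputError, ValidityError

# Published stoichiometric constants used to pin the formulation
# transcriptions: freshwater values at 25 degC (Harned & Davis / Harned &
# Scholes; Plummer & Busenberg for calcite) and S=35, 25 degC seawater
# values (Millero et al. 2006 on the SWS scale; Mucci 1983 for calcite).
LITERATURE_CHECKS = [
    # (temperature_c, salinity, attr, expected, atol)
    (25.0, 0.0, "pk1", 6.352, 0.02),
    (25.0, 0.0, "pk2", 10.329, 0.02),
    (25.0, 35.0, "pk1", 5.8401, 0.01),
    (25.0, 35.0, "pk2", 8.9660, 0.01),
]
KSP_CHECKS = [
    (25.0, 0.0, -8.48, 0.02),   # Plummer & Busenberg freshwater limit
    (25.0, 35.0, -6.3693, 0.01),  # Mucci seawater value
]


class TestConstants:
    @pytest.mark.parametrize("t, s, attr, expected, atol", LITERATURE_CHECKS)
    def test_pk_matches_published_tabulations(self, t, s, attr, expected, atol):
        c = compute_constants(t, s, "millero06")
        assert getattr(c, attr) == pytest.approx(expected, abs=atol)

    @pytest.mark.parametrize("t, s, expected, atol", KSP_CHECKS)
    def test_ksp_matches_published_fits(self, t, s, expected, atol):
        c = compute_constants(t, s, "millero06")
        assert math.log10(c.ksp_calcite) == pytest.approx(expected, abs=atol)

    def test_seawater_pk1_within_formulation_spread(self):
        # independent fits put pK1(25 degC, S 35) between ~5.84 and ~5.89
        for form in ("millero06", "cai_wang98"):
            c = compute_constants(25.0, 35.0, form)
            corrected = c.pk1 if c.scale == "concentration" else (
                c.pk1 + math.log10(hydrogen_activity_coefficient(25, 35, "fh_seawater"))
            )
            assert 5.82 <= corrected <= 5.90

    def test_ionic_strength_raises_k1(self):
        fresh = compute_constants(25.0, 0.0)
        sea = compute_constants(25.0, 35.0)
        assert sea.k1 > fresh.k1

    def test_deterministic(self):
        a = compute_constants(29.6, 17.5)
        b = compute_constants(29.6, 17.5)
        assert (a.k1, a.k2, a.ksp_calcite) == (b.k1, b.k2, b.ksp_calcite)

    @pytest.mark.parametrize(
        "t, s, fragment",
        [(-5.0, 10.0, "temperature"), (60.0, 10.0, "temperature"),
         (25.0, -1.0, "salinity"), (25.0, 99.0, "salinity")],
    )
    def test_out_of_range_names_bound(self, t, s, fragment):
        with pytest.raises(ValidityError, match=fragment):
            compute_constants(t, s)

    def test_unknown_formulation(self):
        with pytest.raises(InputError, match="formulation"):
            compute_constants(25.0, 0.0, "nosuch")


class TestSpeciate:
    def test_basin_co2_near_200_uM(self, basin, basin_constants):
        sp = speciate(basin, basin_constants)
        assert sp.co2_aq_molar * 1e6 == pytest.approx(200.0, rel=0.30)

    def test_formulations_agree_at_basin(self, basin):
        co2 = {}
        for form in ("millero06", "cai_wang98"):
            c = compute_constants(basin.temperature_c, basin.salinity, form)
            co2[form] = speciate(basin, c).co2_aq_molar
        assert co2["millero06"] == pytest.approx(co2["cai_wang98"], rel=0.15)

    def test_freshwater_closed_form(self):
        # 2 mM bicarbonate at pH 7.35 with pK1 ~ 6.35: CO2 = 2 mM * 10^-1
        sample = WaterSample("fresh", 25.0, 7.35, 2e-3, salinity_psu=0.0)
        c = compute_constants(25.0, 0.0)
        sp = speciate(sample, c)
        assert sp.co2_aq_molar == pytest.approx(
            2e-3 * 10 ** (c.pk1 - 7.35), rel=1e-12
        )
        assert sp.co2_aq_molar * 1e6 == pytest.approx(200.0, rel=0.02)

    def test_ph_equal_pk1_splits_equally(self):
        c = compute_constants(25.0, 0.0)
        sample = WaterSample("eq", 25.0, c.pk1, 2e-3, salinity_psu=0.0)
        sp = speciate(sample, c, ph_scale="free")
        assert sp.co2_aq_molar == pytest.approx(sp.hco3_molar, rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(
        t=st.floats(5, 45), s=st.floats(0, 45), ph=st.floats(5, 10),
        hco3=st.floats(1e-5, 0.05),
    )
    def test_dic_conservation(self, t, s, ph, hco3):
        sample = WaterSample("p", t, ph, hco3, salinity_psu=s)
        sp = speciate(sample, compute_constants(t, s))
        total = sp.co2_aq_molar + sp.hco3_molar + sp.co3_molar
        assert total == pytest.approx(sp.dic_molar, rel=1e-12)

    def test_co2_strictly_decreasing_in_ph(self, basin_constants):
        previous = math.inf
        for ph in [6.5, 7.0, 7.5, 8.0, 8.5]:
            sample = WaterSample("m", 29.6, ph, 2e-3, salinity_psu=17.5)
            co2 = speciate(sample, basin_constants).co2_aq_molar
            assert co2 < previous
            previous = co2

    def test_omega_populated_iff_calcium(self, basin_constants):
        with_ca = WaterSample("a", 29.6, 7.03, 2e-3, salinity_psu=17.5,
                              calcium_molar=11.1e-3)
        without = WaterSample("b", 29.6, 7.03, 2e-3, salinity_psu=17.5)
        assert speciate(with_ca, basin_constants).omega_calcite is not None
        assert speciate(without, basin_constants).omega_calcite is None

    def test_missing_bicarbonate_rejected(self, basin_constants):
        sample = WaterSample("x", 29.6, 7.0, 0.0, salinity_psu=17.5)
        with pytest.raises(InputError, match="bicarbonate"):
            speciate(sample, basin_constants)


class TestOmega:
    def test_saturation_boundary(self):
        assert omega_calcite(1e-3, 1e-4, 1e-7) == pytest.approx(1.0)

    def test_linear_in_calcium(self):
        assert omega_calcite(2e-3, 1e-5, 1e-7) == pytest.approx(
            2 * omega_calcite(1e-3, 1e-5, 1e-7)
        )

    def test_basin_is_undersaturated(self, basin):
        # Both formulations put the basin below calcite saturation,
        # consistent with calcite precipitating intracellularly rather
        # than from ambient water chemistry.
        for form in ("millero06", "cai_wang98"):
            c = compute_constants(basin.temperature_c, basin.salinity, form)
            omega = speciate(basin, c).omega_calcite
            assert 0.3 < omega < 1.0

    def test_nonpositive_input_rejected(self):
        with pytest.raises(InputError):
            omega_calcite(0.0, 1e-5, 1e-7)


class TestProtonYield:
    @pytest.mark.parametrize("mol", [0.0, 1.0, 5e-11, 0.05e-9])
    def test_one_to_one(self, mol):
        assert calcite_proton_yield(mol) == mol

    def test_linear(self):
        assert calcite_proton_yield(3.0) + calcite_proton_yield(4.0) == \
            calcite_proton_yield(7.0)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            calcite_proton_yield(-1e-12)


class TestConductivity:
    def test_seawater_reference_point(self):
        assert conductivity_to_salinity(53.087, 25.0) == pytest.approx(35.0)

    def test_zero(self):
        assert conductivity_to_salinity(0.0, 25.0) == 0.0

    def test_basin_is_half_seawater(self):
        # 28.9-32.6 mS/cm at basin temperatures -> roughly half seawater
        low = conductivity_to_salinity(28.9, 29.6)
        high = conductivity_to_salinity(32.6, 31.7)
        assert 16.0 <= low <= 19.0
        assert 16.0 <= high <= 19.5

    @settings(deadline=None, max_examples=30)
    @given(c=st.floats(0.1, 60), dc=st.floats(0.1, 5))
    def test_monotone_in_conductivity(self, c, dc):
        assert conductivity_to_salinity(c + dc, 25.0) > \
            conductivity_to_salinity(c, 25.0)


class TestWaterIO:
    def test_round_trip(self, tmp_path):
        csv = tmp_path / "water.csv"
        csv.write_text(
            "label,temperature_c,ph,bicarbonate_mM,conductivity_ms_cm,"
            "calcium_mM,sulfide_uM\n"
            "basin,29.6,7.03,2.0,28.9,11.1,33.1\n"
            "outflow,29.0,7.11,2.0,29.7,,\n"
        )
        samples = read_water_samples(csv)
        assert [s.label for s in samples] == ["basin", "outflow"]
        assert samples[0].bicarbonate_molar == pytest.approx(2e-3)
        assert samples[0].calcium_molar == pytest.approx(11.1e-3)
        assert samples[1].calcium_molar is None
        assert 16 < samples[0].salinity < 19

    def test_missing_columns_named(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text("label,temperature_c,ph\nx,25,7\n")
        with pytest.raises(InputError, match="bicarbonate_mM"):
            read_water_samples(csv)

    def test_sample_invariants(self):
        with pytest.raises(ValidityError):
            WaterSample("bad", 75.0, 7.0, 2e-3, salinity_psu=10.0)
        with pytest.raises(ValidityError):
            WaterSample("bad", 25.0, 1.0, 2e-3, salinity_psu=10.0)
        with pytest.raises(InputError):
            WaterSample("bad", 25.0, 7.0, -1e-3, salinity_psu=10.0)
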