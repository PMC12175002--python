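"""Optical-property models: scalar values, units, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slim import (
    ChromophoreTable,
    LayerComposition,
    build_skin_medium,
    composite_absorption,
    default_skin_spec,
    dermis_reduced_scattering,
    epidermis_reduced_scattering,
    load_default_chromophore_table,
    melanin_absorption,
    reduced_to_full_scattering,
    transport_mfp,
)
from slim.skin_optics import WavelengthLookupError, scale_layer_scattering

WAVELENGTHS = (471.0, 526.0, 591.0, 621.0, 691.0, 731.0, 811.0, 851.0)


class TestMelaninAbsorption:
    def test_zero_fraction_gives_zero(self):
        assert melanin_absorption(0.0, 621.0) == 0.0

    def test_power_law_value(self):
        # direct scalar evaluation of 1.7e11 * 0.02 * 471**-3.48
        assert melanin_absorption(0.02, 471.0) == pytest.approx(1.6958, abs=2e-3)

    def test_linearity_in_volume_fraction(self):
        assert melanin_absorption(0.10, 471.0) == pytest.approx(
            5.0 * melanin_absorption(0.02, 471.0), rel=1e-12
        )

    @pytest.mark.parametrize("fv,wl", [(-0.01, 500.0), (0.02, 0.0), (0.02, -5.0)])
    def test_invalid_inputs(self, fv, wl):
        with pytest.raises(ValueError):
            melanin_absorption(fv, wl)


class TestScatteringPowerLaws:
    def test_epidermis_at_471(self):
        assert epidermis_reduced_scattering(471.0) == pytest.approx(7.805, abs=5e-3)

    def test_dermis_values(self):
        assert dermis_reduced_scattering(471.0) == pytest.approx(5.335, abs=5e-3)
        assert dermis_reduced_scattering(851.0) == pytest.approx(2.176, abs=5e-3)

    def test_monotone_decrease(self):
        vals = [dermis_reduced_scattering(w) for w in WAVELENGTHS]
        assert np.all(np.diff(vals) < 0)
        vals_epi = [epidermis_reduced_scattering(w) for w in WAVELENGTHS]
        assert np.all(np.diff(vals_epi) < 0)

    def test_epidermis_exceeds_dermis_everywhere(self):
        for w in WAVELENGTHS:
            assert epidermis_reduced_scattering(w) > dermis_reduced_scattering(w)

    def test_vanishes_at_long_wavelength(self):
        # both power-law terms decay to zero (the Rayleigh-like term slowly)
        assert epidermis_reduced_scattering(1e12) < 1e-2


class TestCompositeAbsorption:
    def test_zero_composition(self, chromophore_table):
        comp = LayerComposition()
        assert composite_absorption(comp, 526.0, chromophore_table) == 0.0

    @given(scale=st.floats(0.1, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneous_degree_one_in_concentrations(self, scale):
        table = load_default_chromophore_table()
        base = LayerComposition(37.21, 9.30, 0.0, 0.0)
        scaled = LayerComposition(37.21 * scale, 9.30 * scale, 0.0, 0.0)
        mua1 = composite_absorption(base, 621.0, table)
        mua2 = composite_absorption(scaled, 621.0, table)
        assert mua2 == pytest.approx(scale * mua1, rel=1e-12)

    def test_additivity_of_chromophore_terms(self, chromophore_table):
        hb_only = LayerComposition(37.21, 9.30, 0.0, 0.0)
        water_only = LayerComposition(0.0, 0.0, 0.70, 0.05)
        both = LayerComposition(37.21, 9.30, 0.70, 0.05)
        assert composite_absorption(both, 731.0, chromophore_table) == pytest.approx(
            composite_absorption(hb_only, 731.0, chromophore_table)
            + composite_absorption(water_only, 731.0, chromophore_table),
            rel=1e-12,
        )

    def test_missing_wavelength_raises_naming_it(self, chromophore_table):
        with pytest.raises(WavelengthLookupError, match="600"):
            composite_absorption(LayerComposition(), 600.0, chromophore_table)

    def test_optin_interpolation(self):
        table = load_default_chromophore_table(interpolate=True)
        mid = composite_absorption(LayerComposition(10.0, 5.0, 0, 0), 700.0, table)
        lo = composite_absorption(LayerComposition(10.0, 5.0, 0, 0), 691.0, table)
        hi = composite_absorption(LayerComposition(10.0, 5.0, 0, 0), 731.0, table)
        assert min(lo, hi) <= mid <= max(lo, hi)


class TestDermisTransport:
    """Units check: the cm->mm pipeline must reproduce printed l* values."""

    @pytest.fixture(autouse=True)
    def _setup(self, chromophore_table, skin_spec):
        self.table = chromophore_table
        self.comp = skin_spec.compositions[1]

    def lstar(self, wl):
        mua = composite_absorption(self.comp, wl, self.table)
        return transport_mfp(mua, dermis_reduced_scattering(wl))

    def test_lstar_526(self):
        assert self.lstar(526.0) == pytest.approx(0.21, rel=0.10)

    def test_lstar_851(self):
        assert self.lstar(851.0) == pytest.approx(0.46, rel=0.10)

    def test_lstar_ratio_851_471(self):
        assert self.lstar(851.0) / self.lstar(471.0) == pytest.approx(2.6, rel=0.10)

    def test_scattering_to_absorption_span(self):
        ratios = [
            dermis_reduced_scattering(w)
            / composite_absorption(self.comp, w, self.table)
            for w in WAVELENGTHS
        ]
        assert min(ratios) == pytest.approx(17.0, rel=0.10)
        assert max(ratios) == pytest.approx(404.0, rel=0.10)


class TestConversions:
    def test_reduced_to_full_identity_at_g0(self):
        assert reduced_to_full_scattering(1.0, 0.0) == 1.0

    def test_reduced_to_full_closed_form(self):
        assert reduced_to_full_scattering(2.175, 0.8) == pytest.approx(10.875)

    @given(musp=st.floats(0.0, 50.0), g=st.floats(-0.99, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, musp, g):
        mus = reduced_to_full_scattering(musp, g)
        assert mus * (1.0 - g) == pytest.approx(musp, rel=1e-9, abs=1e-12)

    def test_transport_mfp_simple(self):
        assert transport_mfp(0.0, 1.0) == 1.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            transport_mfp(0.0, 0.0)
        with pytest.raises(ValueError):
            reduced_to_full_scattering(1.0, 1.0)


class TestBuildSkinMedium:
    def test_layer_stack_geometry(self, skin_spec, chromophore_table):
        m = build_skin_medium(skin_spec, 621.0, chromophore_table)
        assert m.total_depth == pytest.approx(7.5)
        np.testing.assert_allclose(m.boundaries, [0.0, 0.05, 0.25, 1.35, 7.5])
        assert [lay.name for lay in m.layers] == [
            "epidermis", "papillary_dermis", "reticular_dermis", "subcutis",
        ]
        assert [lay.g for lay in m.layers] == [0.8, 0.8, 0.8, 0.75]
        assert [lay.n for lay in m.layers] == [1.37, 1.4, 1.4, 1.44]

    def test_epidermis_has_no_hemoglobin(self, skin_spec):
        comp = skin_spec.compositions[0]
        assert comp.c_hbo2 == 0.0 and comp.c_hb == 0.0 and comp.f_blood == 0.0

    def test_dermal_layers_share_properties(self, skin_spec, chromophore_table):
        for wl in WAVELENGTHS:
            m = build_skin_medium(skin_spec, wl, chromophore_table)
            pap, ret = m.layers[1], m.layers[2]
            assert pap.mua == ret.mua
            assert pap.mus == ret.mus

    def test_epidermal_absorption_modes(self, chromophore_table):
        additive = default_skin_spec(melanin_fv=0.02)
        melanin_only = default_skin_spec(
            melanin_fv=0.02, epidermis_baseline_absorption=False
        )
        ma = build_skin_medium(additive, 851.0, chromophore_table).layers[0].mua
        mm = build_skin_medium(melanin_only, 851.0, chromophore_table).layers[0].mua
        assert mm == pytest.approx(melanin_absorption(0.02, 851.0))
        assert ma > mm

    def test_subcutis_below_dermis_scattering(self, skin_spec, chromophore_table):
        for wl in WAVELENGTHS:
            m = build_skin_medium(skin_spec, wl, chromophore_table)
            assert m.layers[3].musp < m.layers[2].musp

    def test_missing_subcutis_entry(self, chromophore_table):
        from slim import SkinModelSpec

        spec = SkinModelSpec(subcutis_musp_table={471.0: 1.8})
        with pytest.raises(WavelengthLookupError):
            build_skin_medium(spec, 851.0, chromophore_table)

    def test_scale_layer_scattering(self, skin_spec, chromophore_table):
        m = build_skin_medium(skin_spec, 621.0, chromophore_table)
        m2 = scale_layer_scattering(m, "papillary_dermis", 0.5)
        assert m2.layers[1].mus == pytest.approx(0.5 * m.layers[1].mus)
        assert m2.layers[1].musp == pytest.approx(0.5 * m.layers[1].musp)
        for k in (0, 2, 3):
            assert m2.layers[k] == m.layers[k]


class TestChromophoreTableValidation:
    def test_rejects_unsorted_wavelengths(self):
        with pytest.raises(ValueError):
            ChromophoreTable(
                wavelength_nm=[500.0, 400.0],
                eps_hbo2=[1.0, 1.0],
                eps_hb=[1.0, 1.0],
                mua_water=[0.0, 0.0],
                mua_lipid=[0.0, 0.0],
            )

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            ChromophoreTable(
                wavelength_nm=[400.0, 500.0],
                eps_hbo2=[1.0, -1.0],
                eps_hb=[1.0, 1.0],
                mua_water=[0.0, 0.0],
                mua_lipid=[0.0, 0.0],
            )

    def test_composition_validation(self):
        with pytest.raises(ValueError):
            LayerComposition(f_water=0.8, f_lipid=0.3)
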