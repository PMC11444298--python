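"""Reaction rate laws and interface flux laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import pyccm
from pyccm.kinetics import (
    O2Stoichiometry,
    bica_flux,
    ca_rate,
    coupled_sources,
    membrane_flux,
    rubisco_rates,
    rubisco_rates_jac,
    spontaneous_dic_rates,
    stomatal_flux,
)
from pyccm.parameters import default_parameters, proton_concentration

P = default_parameters()


class TestRubisco:
    def test_vmax_ratio(self):
        assert P.Rub_Vmax_o == pytest.approx(0.21 * P.Rub_Vmax_c)
        assert P.Rub_Vmax_o == pytest.approx(1596.0)

    def test_saturation_limit(self):
        vc, vo = rubisco_rates(1e9, 200.0, P)
        assert vc == pytest.approx(7600.0, rel=1e-6)

    def test_half_saturation_identity(self):
        o2 = 264.0
        co2 = P.km_co2 * (1 + o2 / P.km_o2)
        vc, _ = rubisco_rates(co2, o2, P)
        assert vc == pytest.approx(3800.0, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rubisco_rates(-1.0, 200.0, P)

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_competitive_inhibition_monotonicity(self, co2, o2):
        vc, vo = rubisco_rates(co2, o2, P)
        vc2, vo2 = rubisco_rates(co2 * 1.01, o2, P)
        assert vc2 > vc and vo2 < vo  # CO2 promotes Vc, inhibits Vo

    def test_jacobian_matches_finite_differences(self):
        co2, o2, h = 7.3, 250.0, 1e-6
        vc, vo, dcc, dco, doo, doc = rubisco_rates_jac(co2, o2, P)
        assert dcc == pytest.approx(
            (rubisco_rates(co2 + h, o2, P)[0] - vc) / h, rel=1e-4)
        assert doc == pytest.approx(
            (rubisco_rates(co2 + h, o2, P)[1] - vo) / h, rel=1e-4)


class TestCarbonicAnhydrase:
    def test_zero_at_equilibrium(self):
        pH = 8.0
        co2 = 10.0
        hco3 = P.CA_Keq * co2 / proton_concentration(pH)
        assert ca_rate(co2, hco3, pH, 270.0, P) == pytest.approx(0.0, abs=1e-9)

    def test_first_order_limit(self):
        rate = ca_rate(1e-3, 0.0, 8.0, 270.0, P)
        assert rate == pytest.approx(270.0 * P.CA_kcat * 1e-3 / P.CA_Km_CO2,
                                     rel=1e-3)

    def test_direct_arithmetic_oracle(self):
        # independent evaluation of the reversible rate expression
        pH, co2, hco3, conc = 8.0, 10.0, 100.0, 270.0
        h = 10.0 ** (-pH) * 1e6
        expected = conc * P.CA_kcat * (co2 - hco3 * h / P.CA_Keq) / (
            P.CA_Km_CO2 + hco3 * (P.CA_Km_CO2 / P.CA_Km_HCO3) + co2)
        assert ca_rate(co2, hco3, pH, conc, P) == pytest.approx(expected, rel=1e-12)

    def test_catalysis_preserves_equilibrium(self):
        """Closed-pot relaxation: with a consistent equilibrium constant,
        adding CA changes the speed, never the endpoint."""
        pH = 7.2
        params = P.replace(CA_Keq=P.spontaneous_keq)

        def rhs(t, y, conc_ca):
            co2, h2co3, hco3 = y
            hyd, deprot = spontaneous_dic_rates(co2, h2co3, hco3, pH, params)
            ca = ca_rate(co2, hco3, pH, conc_ca, params)
            return [-hyd - ca, hyd - deprot, deprot + ca]

        y0 = [30.0, 0.0, 5.0]
        ends = []
        for conc in (0.0, 270.0):
            sol = solve_ivp(rhs, (0, 500.0), y0, args=(conc,),
                            method="LSODA", rtol=1e-10, atol=1e-12)
            ends.append(sol.y[:, -1])
        np.testing.assert_allclose(ends[0], ends[1], rtol=1e-6)
        # and the endpoint is the analytic equilibrium of the conserved pool
        h = proton_concentration(pH)
        k1 = params.kf_hyd / params.kr_dehyd
        k2 = params.kf_deprot / (params.kr_prot * h)
        co2_eq = sum(y0) / (1 + k1 + k1 * k2)
        assert ends[0][0] == pytest.approx(co2_eq, rel=1e-6)


class TestSpontaneous:
    def test_hydration_rate_value(self):
        hyd, _ = spontaneous_dic_rates(10.0, 0.0, 0.0, 7.0, P)
        assert hyd == pytest.approx(0.6)

    def test_joint_equilibrium_is_stationary(self):
        pH = 7.2
        co2 = 10.0
        h2co3 = co2 * P.kf_hyd / P.kr_dehyd
        hco3 = h2co3 * P.kf_deprot / (P.kr_prot * proton_concentration(pH))
        hyd, deprot = spontaneous_dic_rates(co2, h2co3, hco3, pH, P)
        assert hyd == pytest.approx(0.0, abs=1e-10)
        assert deprot == pytest.approx(0.0, abs=1e-6)

    def test_protonation_ratio_at_equilibrium(self):
        # [H2CO3]/[HCO3] at pH 7.2 equilibrium = kr_prot*[H+]/kf_deprot
        h = proton_concentration(7.2)
        assert P.kr_prot * h / P.kf_deprot == pytest.approx(3.155e-4, rel=1e-3)


class TestFluxLaws:
    def test_membrane_antisymmetry_and_zero(self):
        assert membrane_flux(3500.0, 5.0, 5.0) == 0.0
        assert membrane_flux(3500.0, 7.0, 3.0) == -membrane_flux(3500.0, 3.0, 7.0)

    def test_membrane_scale(self):
        # 3.5e-3 m/s x 1e-3 mol/m^3 = 3.5e-6 mol/(m^2 s); internally
        # 3500 um/s x 1 uM = 3500 uM um/s with 1 uM um^3 = 1e-21 mol
        flux = membrane_flux(3500.0, 1.0, 0.0)
        mol_per_m2_s = flux * 1e-21 / 1e-12
        assert mol_per_m2_s == pytest.approx(3.5e-3 * 1e-3, rel=1e-12)

    def test_bica_half_saturation_and_saturation(self):
        assert bica_flux(217.0, 1.85e-4, 217.0) == pytest.approx(9.25e-5)
        assert bica_flux(0.0, 1.85e-4, 217.0) == 0.0
        assert bica_flux(1e9, 1.85e-4, 217.0) == pytest.approx(1.85e-4, rel=1e-6)

    def test_stomatal_linearity(self):
        f1 = stomatal_flux(16.62, 14.0, 0.4375, 37.0)
        f2 = stomatal_flux(16.62, 14.0, 0.875, 37.0)
        assert f2 == pytest.approx(2 * f1)
        assert stomatal_flux(10.0, 10.0, 0.4375, 37.0) == 0.0


class TestCoupledSources:
    def test_photorespiratory_return_stoichiometry(self):
        src = coupled_sources(0.0, 2.0)
        assert src["co2_cytosol"] == pytest.approx(1.0)  # half per oxygenation
        assert coupled_sources(5.0, 0.0)["co2_cytosol"] == 0.0

    def test_o2_presets(self):
        d = O2Stoichiometry.preset("default")
        f = O2Stoichiometry.preset("farquhar")
        # net cellular O2 balance per (Vc, Vo) = (1, 1):
        net_d = d.evolved_per_carbox + d.evolved_per_oxy - 1.0 - d.photoresp_o2_per_oxy
        net_f = f.evolved_per_carbox + f.evolved_per_oxy - 1.0 - f.photoresp_o2_per_oxy
        assert net_d == pytest.approx(-0.5)   # Vc - 1.5 Vo
        assert net_f == pytest.approx(0.5)    # Vc - 0.5 Vo
        with pytest.raises(ValueError):
            O2Stoichiometry.preset("bogus")

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            coupled_sources(-1.0, 0.0)
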