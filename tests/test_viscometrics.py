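"""Jones–Dole B-coefficients and viscous-flow activation parameters."""

import numpy as np
import pytest

from caffsol import (
    CAFFEINE,
    FitError,
    ViscositySeries,
    activation_entropy_enthalpy,
    activation_mu1,
    activation_mu2,
    analyze_activation,
    generate_density,
    generate_viscosity,
    harmonic_mean_temperature,
    jones_dole_fit,
    structure_classify,
)
from caffsol.constants import AVOGADRO_NA, GAS_CONSTANT_R, PLANCK_H
from caffsol.fixtures import activation_inputs, jones_dole_b
from caffsol.synthetic import DEFAULT_MOLALITIES

TEMPS = [293.15, 298.15, 303.15, 308.15, 313.15]


class TestJonesDole:
    def test_null_effect(self, truth0, ss_solvent, solute):
        density = generate_density(truth0, ss_solvent, solute, DEFAULT_MOLALITIES)
        eta0 = ss_solvent.eta0_at(298.15)
        m, _ = density.at_temperature(298.15)
        flat = ViscositySeries(
            molality=m, temperature=[298.15] * len(m), viscosity=[eta0] * len(m)
        )
        B, _ = jones_dole_fit(flat, density, ss_solvent, solute, 298.15)
        assert B == pytest.approx(0.0, abs=1e-14)

    def test_exact_recovery_from_zero_noise(self, truth0, ss_solvent, solute):
        density = generate_density(truth0, ss_solvent, solute, DEFAULT_MOLALITIES)
        visc = generate_viscosity(truth0, ss_solvent, solute, DEFAULT_MOLALITIES, density)
        B, r2 = jones_dole_fit(visc, density, ss_solvent, solute, 298.15)
        assert B == pytest.approx(0.490, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_viscosity_rescaling(self, truth0, ss_solvent, solute):
        import dataclasses

        density = generate_density(truth0, ss_solvent, solute, DEFAULT_MOLALITIES)
        visc = generate_viscosity(truth0, ss_solvent, solute, DEFAULT_MOLALITIES, density)
        scaled_solvent = dataclasses.replace(
            ss_solvent, eta0={t: 2.0 * v for t, v in ss_solvent.eta0.items()}
        )
        scaled_visc = ViscositySeries(
            molality=visc.molality,
            temperature=visc.temperature,
            viscosity=2.0 * visc.viscosity,
        )
        B0, _ = jones_dole_fit(visc, density, ss_solvent, solute, 298.15)
        B1, _ = jones_dole_fit(scaled_visc, density, scaled_solvent, solute, 298.15)
        assert B1 == pytest.approx(B0, rel=1e-12)


class TestStructureClassification:
    def test_mixed_solvent_row_is_structure_maker(self):
        b = jones_dole_b()
        label, slope = structure_classify(
            dict(zip(b["temperature_K"], b["B_ss_dm3_mol"]))
        )
        assert label == "structure-maker"
        assert slope < 0

    def test_water_row_is_atypical_structure_maker(self):
        b = jones_dole_b()
        label, slope = structure_classify(
            dict(zip(b["temperature_K"], b["B_water_dm3_mol"]))
        )
        assert label == "atypical structure-maker"
        assert slope > 0

    def test_negative_B_is_structure_breaker(self):
        label, _ = structure_classify({t: -0.1 for t in TEMPS})
        assert label == "structure-breaker"

    def test_mixed_signs_indeterminate(self):
        label, _ = structure_classify({293.15: 0.1, 298.15: -0.1, 303.15: 0.1})
        assert label == "indeterminate"


class TestActivation:
    def test_mu1_zero_at_unit_argument(self):
        v1 = 18.18
        eta0 = PLANCK_H * AVOGADRO_NA / (v1 * 1e-6) * 1e3  # mPa·s making ln(1)
        assert activation_mu1(eta0, v1, 293.15) == pytest.approx(0.0, abs=1e-12)

    def test_mu1_reproduces_published_row(self):
        # eta0 back-solved; forward evaluation must land on the printed values
        from caffsol.fixtures import ss_solvent_reference

        sv = ss_solvent_reference()
        ref = activation_inputs()
        for _, row in ref.iterrows():
            T = row["temperature_K"]
            mu1 = activation_mu1(sv.eta0_at(T), row["v1bar_cm3_mol"], T)
            assert round(mu1, 2) == row["dmu1_kJ_mol"]

    def test_mu1_logarithm_shift(self):
        a = activation_mu1(1.047, 18.18, 293.15)
        b = activation_mu1(2.094, 18.18, 293.15)
        assert b - a == pytest.approx(
            GAS_CONSTANT_R * 293.15 * np.log(2) / 1000, rel=1e-10
        )

    def test_mu2_published_value_at_low_temperature(self):
        mu2 = activation_mu2(9.42, 0.501, 18.18, 131.46, 293.15)
        assert round(mu2, 2) == 91.77

    def test_mu2_null_case(self):
        assert activation_mu2(9.0, 0.0, 18.0, 18.0, 300.0) == 9.0

    def test_mu2_high_temperature_within_rounding(self):
        mu2 = activation_mu2(8.92, 0.436, 18.30, 134.33, 313.15)
        assert mu2 == pytest.approx(87.43, rel=5e-4)

    def test_mu2_increasing_in_B(self):
        lo = activation_mu2(9.42, 0.4, 18.18, 131.46, 293.15)
        hi = activation_mu2(9.42, 0.5, 18.18, 131.46, 293.15)
        assert hi > lo

    def test_entropy_enthalpy_published_values(self):
        ref = activation_inputs()
        dmu2 = dict(zip(ref["temperature_K"], ref["dmu2_kJ_mol"]))
        t_hm = harmonic_mean_temperature(TEMPS)
        dS2, dH2 = activation_entropy_enthalpy(dmu2, t_hm)
        assert dS2 == pytest.approx(239.66, rel=0.005)
        assert dH2 == pytest.approx(162.33, rel=0.005)

    def test_constant_dmu2(self):
        dS2, dH2 = activation_entropy_enthalpy({t: 90.0 for t in TEMPS}, 302.99)
        assert dS2 == pytest.approx(0.0, abs=1e-9)
        assert dH2 == pytest.approx(90.0, rel=1e-9)

    def test_exact_line_closed_form(self):
        dmu2 = {t: 100.0 - 0.2 * t for t in TEMPS}
        dS2, dH2 = activation_entropy_enthalpy(dmu2, 302.99)
        assert dS2 == pytest.approx(200.0, rel=1e-10)
        assert dH2 == pytest.approx(100.0, rel=1e-10)

    def test_dmu2_exceeds_dmu1_on_reference_grid(self, ss_solvent):
        ref = activation_inputs()
        B = dict(zip(jones_dole_b()["temperature_K"], jones_dole_b()["B_ss_dm3_mol"]))
        v2 = dict(zip(ref["temperature_K"], ref["v2bar_cm3_mol"]))
        act = analyze_activation(B, v2, ss_solvent)
        for T in act.temperatures:
            assert act.dmu2_per_T[T] > act.dmu1_per_T[T]
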