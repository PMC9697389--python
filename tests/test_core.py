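"""Domain types, conversions and CSV/JSON round trips."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caffsol import (
    CAFFEINE,
    DensitySeries,
    DissolutionThermo,
    DomainError,
    SchemaError,
    SolubilityTable,
    SoluteSpec,
    SolventReference,
    TableParseError,
    ValidationError,
    ViscositySeries,
    molarity_from_molality,
    mole_fraction,
    read_results,
    read_table,
    write_results,
)
from caffsol.fixtures import fixture_path
from caffsol.synthetic import GroundTruth


class TestMoleFraction:
    @pytest.mark.parametrize(
        "solubility, expected",
        [
            (0.0, 0.0),
            (16.33, 0.001512642018041889),  # hand arithmetic: n/(n + 1000/18.015)
            (194.19, 0.017696202904672328),  # one mole of solute per kg water
        ],
    )
    def test_known_values(self, solubility, expected):
        assert mole_fraction(solubility, CAFFEINE) == pytest.approx(expected, rel=1e-12)

    def test_negative_solubility_rejected(self):
        with pytest.raises(DomainError):
            mole_fraction(-1.0, CAFFEINE)

    @given(st.floats(min_value=0.01, max_value=500.0), st.floats(min_value=0.01, max_value=500.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if lo == hi:
            return
        assert mole_fraction(lo, CAFFEINE) < mole_fraction(hi, CAFFEINE)


class TestMolarity:
    def test_zero_molality(self):
        assert molarity_from_molality(0.0, 1.05, CAFFEINE) == 0.0

    def test_known_value(self):
        assert molarity_from_molality(0.1, 1.0, CAFFEINE) == pytest.approx(
            0.09809509141972045, rel=1e-12
        )

    def test_dilute_limit_is_molality(self):
        tiny = SoluteSpec("point-mass", 1e-12)
        assert molarity_from_molality(0.2, 1.0, tiny) == pytest.approx(0.2, rel=1e-9)

    @given(
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=0.5, max_value=1.5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_bounded_by_m_rho(self, m, rho):
        assert molarity_from_molality(m, rho, CAFFEINE) < m * rho


class TestTableInvariants:
    def test_solubility_needs_three_temperatures(self):
        with pytest.raises(ValidationError, match="3"):
            SolubilityTable(temperature=[293.15, 298.15], solubility=[1.0, 2.0])

    def test_solubility_rows_sorted_on_construction(self):
        t = SolubilityTable(
            temperature=[313.15, 293.15, 303.15], solubility=[3.0, 1.0, 2.0]
        )
        assert list(t.temperature) == [293.15, 303.15, 313.15]
        assert list(t.solubility) == [1.0, 2.0, 3.0]

    def test_negative_density_names_row(self):
        m = [0.01, 0.02, 0.03, 0.04]
        with pytest.raises(ValidationError, match="row"):
            DensitySeries(
                molality=m, temperature=[298.15] * 4, density=[1.0, 1.0, -1.0, 1.0]
            )

    def test_viscosity_needs_three_nonzero_molalities_per_T(self):
        with pytest.raises(ValidationError, match="3 nonzero"):
            ViscositySeries(
                molality=[0.0, 0.01, 0.02],
                temperature=[298.15] * 3,
                viscosity=[1.0, 1.01, 1.02],
            )

    def test_solvent_grids_must_match(self):
        with pytest.raises(ValidationError, match="grid"):
            SolventReference(
                description="bad",
                rho0={293.15: 1.0, 298.15: 1.0},
                eta0={293.15: 1.0},
                v1bar={293.15: 18.0, 298.15: 18.0},
            )


class TestReadTable:
    def test_fixture_solubility_has_five_rows(self):
        table = read_table(fixture_path("table1_solubility_water.csv"), "solubility")
        assert len(table) == 5
        assert table.solubility[0] == 16.33

    def test_empty_data_section_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("temperature_K,solubility_g_per_kg\n")
        with pytest.raises(ValidationError, match="3"):
            read_table(p, "solubility")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("temperature_K,conc\n293.15,1\n")
        with pytest.raises(SchemaError, match="solubility_g_per_kg"):
            read_table(p, "solubility")

    def test_non_numeric_cell_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "molality_mol_kg,temperature_K,density_g_cm3\n"
            "0.01,298.15,1.0\n0.02,298.15,oops\n0.03,298.15,1.0\n"
        )
        with pytest.raises(TableParseError, match="line 3"):
            read_table(p, "density")

    def test_negative_density_in_file_rejected(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text(
            "molality_mol_kg,temperature_K,density_g_cm3\n"
            "0.01,298.15,1.0\n0.02,298.15,-0.5\n0.03,298.15,1.0\n"
        )
        with pytest.raises(ValidationError, match="row"):
            read_table(p, "density")


class TestResultsRoundTrip:
    @pytest.mark.parametrize(
        "obj",
        [
            DissolutionThermo(
                t_hm=302.98500229245207,
                dsol_H=26.50490797010862,
                dsol_G=13.117864165729838,
                dsol_S=0.0441838497057261,
                zeta_H=0.664417427353345,
                zeta_TS=0.33558257264665503,
                fit_r2=0.9600035990428001,
                n_points=5,
            ),
            GroundTruth(
                vphi0_per_T={293.15: 131.46},
                sv_per_T={293.15: 75.46},
                B_per_T={293.15: 0.501},
                dsol_H=0.13,
                dsol_G=13.28,
                seed=7,
            ),
        ],
    )
    def test_write_then_read_is_bit_identical(self, obj, tmp_path):
        p = tmp_path / "out.json"
        write_results(obj, p)
        loaded = read_results(p)
        for f in dataclasses.fields(obj):
            value = getattr(obj, f.name)
            if isinstance(value, dict):
                assert loaded[f.name] == {str(k): v for k, v in value.items()}
            else:
                assert loaded[f.name] == value
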