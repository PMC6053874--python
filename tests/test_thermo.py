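import numpy as np
import pytest

from dhbpka import (
    FreeEnergySet,
    ThermoConfig,
    compare_solvation_models,
    delta_g_solution,
    pka_from_cycle,
    relative_error_pct,
    rt_ln10_kcal,
)
from dhbpka.errors import AlignmentError, ConfigurationError
from dhbpka.fixtures import load_solvation_table
from dhbpka.thermo import pka_table_from_free_energies, read_free_energy_table


def fes(dg=10.0, an=-70.0, hyd=-110.0, acid=-5.0, water=-6.0, **kw):
    return FreeEnergySet(dg, an, hyd, acid, water, **kw)


class TestDeltaGSolution:
    def test_all_zero(self):
        assert delta_g_solution(fes(0, 0, 0, 0, 0)) == 0.0

    def test_signed_sum(self):
        assert delta_g_solution(fes(10, -70, -110, -5, -6)) == pytest.approx(-159.0)

    def test_sign_flip_linearity(self):
        a = delta_g_solution(fes(3.2, -61.5, -102.0, -7.1, -8.3))
        b = delta_g_solution(fes(-3.2, 61.5, 102.0, 7.1, 8.3))
        assert a == -b

    def test_shift_of_anion_term_shifts_output_by_same_amount(self):
        base = delta_g_solution(fes())
        shifted = delta_g_solution(fes(an=-70.0 + 2.5))
        assert shifted - base == pytest.approx(2.5)

    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            fes(dg=np.inf)
        with pytest.raises(ConfigurationError):
            fes(model="COSMO")


class TestPkaFromCycle:
    def test_zero_energy_gives_minus_log_water(self):
        f = fes(0, 0, 0, 0, 0)
        assert pka_from_cycle(f, apply_correction=False) == pytest.approx(
            -np.log10(55.34), abs=1e-12
        )

    def test_inverting_catechol_cpcm_value(self):
        # dG_sol chosen so the corrected pKa equals the published CPCM
        # catechol value
        target = 8.82
        dg = 1.364 * (target + np.log10(55.34) + 4.54)
        f = fes(dg, 0, 0, 0, 0)
        assert pka_from_cycle(f, apply_correction=True) == pytest.approx(target, abs=1e-10)

    @pytest.mark.parametrize("dg", [-150.0, 0.0, 13.7, 300.0])
    def test_correction_is_exactly_4_54(self, dg):
        f = fes(dg, 0, 0, 0, 0)
        on = pka_from_cycle(f, apply_correction=True)
        off = pka_from_cycle(f, apply_correction=False)
        assert off - on == pytest.approx(4.54, abs=1e-12)

    def test_affine_in_delta_g_with_slope_inverse_1364(self):
        p1 = pka_from_cycle(fes(0, 0, 0, 0, 0), apply_correction=False)
        p2 = pka_from_cycle(fes(1.364, 0, 0, 0, 0), apply_correction=False)
        assert p2 - p1 == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_identity(self):
        cfg = ThermoConfig()
        pka = 9.37
        dg = cfg.kcal_per_pka_unit * (pka + np.log10(cfg.water_molarity))
        back = pka_from_cycle(fes(dg, 0, 0, 0, 0), cfg, apply_correction=False)
        assert back == pytest.approx(pka, abs=1e-10)


class TestRTln10:
    def test_standard_temperature(self):
        assert round(rt_ln10_kcal(298.15), 3) == 1.364

    def test_zero_limit(self):
        assert rt_ln10_kcal(0.0) == 0.0

    def test_linearity_in_temperature(self):
        assert rt_ln10_kcal(2 * 298.15) == pytest.approx(2 * rt_ln10_kcal(298.15))


class TestRelativeError:
    @pytest.mark.parametrize(
        "exp,calc,expected",
        [(8.83, 8.58, 2.83), (5.93, 5.13, 13.49), (7.77, 7.77, 0.0)],
    )
    def test_values(self, exp, calc, expected):
        assert relative_error_pct(exp, calc) == pytest.approx(expected, abs=0.005)

    def test_zero_experimental_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_error_pct(0.0, 5.0)


class TestCompareSolvationModels:
    def test_published_table_ranking(self):
        out = compare_solvation_models(load_solvation_table())
        by_model = out.set_index("model")
        assert by_model.loc["CPCM", "rank"] == 1
        assert by_model.loc["IPCM", "rank"] == 3  # worst
        assert by_model.loc["CPCM", "max_error_pct"] <= 3.0

    def test_identical_values_zero_error(self):
        import pandas as pd

        df = pd.DataFrame(
            {"compound": ["a", "b", "c"], "experimental": [4, 9, 12.5], "PCM": [4, 9, 12.5]}
        )
        out = compare_solvation_models(df)
        assert out.loc[0, "max_error_pct"] == 0.0

    def test_unmatched_compounds_raise(self):
        import pandas as pd

        df = pd.DataFrame({"compound": ["a"], "PCM": [4.0]})
        with pytest.raises(AlignmentError):
            compare_solvation_models(df, pd.Series({"b": 4.0}))


class TestFreeEnergyTable:
    def test_round_trip_and_pka_computation(self, tmp_path):
        import pandas as pd

        cfg = ThermoConfig()
        dg = cfg.kcal_per_pka_unit * (8.82 + np.log10(cfg.water_molarity) + 4.54)
        df = pd.DataFrame(
            [
                {
                    "compound": "Catechol",
                    "model": "CPCM",
                    "site": "OH_m",
                    "dG_gas": dg,
                    "dGsolv_anion": -65.0,
                    "dGsolv_hydronium": -105.0,
                    "dGsolv_acid": -63.0,
                    "dGsolv_water": -107.0,
                }
            ]
        )
        path = tmp_path / "fes.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_free_energy_table(path)
        out = pka_table_from_free_energies(table, "CPCM")
        assert out.loc[0, "pka"] == pytest.approx(8.82, abs=0.01)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("compound\tmodel\nCatechol\tCPCM\n")
        with pytest.raises(ConfigurationError):
            read_free_energy_table(path)
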