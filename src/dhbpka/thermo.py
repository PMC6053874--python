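"""Thermodynamic-cycle pKa calculation from free-energy inputs.

The proton-exchange cycle combines the gas-phase free energy of
HA + H2O -> A- + H3O+ with continuum-solvation free energies of each
species to obtain the solution-phase reaction free energy

    dG_sol = dG_gas + dGsolv(A-) + dGsolv(H3O+) - dGsolv(HA) - dGsolv(H2O)

from which

    pKa = dG_sol / 1.364 - log10([H2O]),

1.364 kcal/mol being RT ln10 at 298.15 K, and the water molarity term
accounting for the explicit water in the exchange scheme.  An empirical
correction of 4.54 pH units (Pliego) offsets the systematic error of the
scheme.  This module consumes tabulated free energies (kcal/mol); it
never performs quantum chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FreeEnergySet",
    "ThermoConfig",
    "delta_g_solution",
    "pka_from_cycle",
    "rt_ln10_kcal",
    "relative_error_pct",
    "compare_solvation_models",
    "read_free_energy_table",
]

#: molar gas constant, kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.98720425e-3

SOLVATION_MODELS = ("PCM", "IPCM", "CPCM")


@dataclass(frozen=True)
class FreeEnergySet:
    """The five free-energy terms of the cycle for one compound and one
    solvation model, all in kcal/mol."""

    dG_gas: float
    dGsolv_anion: float
    dGsolv_hydronium: float
    dGsolv_acid: float
    dGsolv_water: float
    model: str = "CPCM"
    temperature_K: float = 298.15

    def __post_init__(self):
        terms = (
            self.dG_gas,
            self.dGsolv_anion,
            self.dGsolv_hydronium,
            self.dGsolv_acid,
            self.dGsolv_water,
        )
        if not all(np.isfinite(terms)):
            raise ConfigurationError("all free-energy terms must be finite")
        if self.model not in SOLVATION_MODELS:
            raise ConfigurationError(f"model must be one of {SOLVATION_MODELS}")


@dataclass(frozen=True)
class ThermoConfig:
    """Constants of the pKa expression.

    ``kcal_per_pka_unit`` is kept at the conventional printed value 1.364
    rather than recomputed, for bit-reproducibility;
    :func:`rt_ln10_kcal` exists to validate it.  ``water_molarity`` is
    pure water at 25 C.  ``pliego_correction`` is the empirical offset of
    the proton-exchange scheme, in pH units.
    """

    water_molarity: float = 55.34
    kcal_per_pka_unit: float = 1.364
    pliego_correction: float = 4.54

    def __post_init__(self):
        if min(self.water_molarity, self.kcal_per_pka_unit, self.pliego_correction) <= 0:
            raise ConfigurationError("all thermo constants must be positive")


def delta_g_solution(fes: FreeEnergySet) -> float:
    """Solution-phase reaction free energy of the cycle, kcal/mol."""
    return (
        fes.dG_gas
        + fes.dGsolv_anion
        + fes.dGsolv_hydronium
        - fes.dGsolv_acid
        - fes.dGsolv_water
    )


def pka_from_cycle(
    fes: FreeEnergySet, cfg: ThermoConfig | None = None, apply_correction: bool = True
) -> float:
    """pKa from the cycle free energies, optionally Pliego-corrected."""
    cfg = cfg or ThermoConfig()
    pka = delta_g_solution(fes) / cfg.kcal_per_pka_unit - np.log10(cfg.water_molarity)
    if apply_correction:
        pka -= cfg.pliego_correction
    return float(pka)


def rt_ln10_kcal(temperature_K: float) -> float:
    """R*T*ln(10) in kcal/mol; 1.364 at 298.15 K."""
    if temperature_K < 0:
        raise ValueError("temperature must be >= 0 K")
    return GAS_CONSTANT_KCAL * temperature_K * np.log(10.0)


def relative_error_pct(experimental: float, calculated: float) -> float:
    """100 * |experimental - calculated| / experimental."""
    if experimental == 0:
        raise ZeroDivisionError("experimental pKa must be nonzero")
    return 100.0 * abs(experimental - calculated) / experimental


def compare_solvation_models(
    computed: pd.DataFrame, experimental: pd.Series | None = None
) -> pd.DataFrame:
    """Per-model relative errors against experiment, ranked by max error.

    ``computed`` has a ``compound`` column, one column per solvation
    model, and optionally an ``experimental`` column; otherwise
    ``experimental`` must be a Series indexed by compound.  Returns one
    row per model with per-compound errors (percent), their max and mean,
    sorted best (smallest max error) first.
    """
    df = computed.set_index("compound") if "compound" in computed else computed.copy()
    if experimental is None:
        if "experimental" not in df:
            raise AlignmentError("no experimental values provided")
        experimental = df.pop("experimental")
    experimental = experimental.reindex(df.index)
    if experimental.isna().any():
        missing = list(experimental[experimental.isna()].index)
        raise AlignmentError(f"compounds without experimental value: {missing}")
    models = [c for c in df.columns if c != "site"]
    if not models:
        raise AlignmentError("no solvation-model columns to compare")
    rows = []
    for model in models:
        errs = {
            name: relative_error_pct(experimental[name], df.loc[name, model])
            for name in df.index
        }
        rows.append(
            {
                "model": model,
                **{f"err_{n}": e for n, e in errs.items()},
                "max_error_pct": max(errs.values()),
                "mean_error_pct": float(np.mean(list(errs.values()))),
            }
        )
    out = pd.DataFrame(rows).sort_values("max_error_pct", kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


FREE_ENERGY_COLUMNS = [
    "compound",
    "model",
    "site",
    "dG_gas",
    "dGsolv_anion",
    "dGsolv_hydronium",
    "dGsolv_acid",
    "dGsolv_water",
]


def read_free_energy_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of cycle free energies (kcal/mol) with columns
    compound, model, site, dG_gas, dGsolv_anion, dGsolv_hydronium,
    dGsolv_acid, dGsolv_water and optionally hbond (true/false rows give
    alternative conformers with/without the intramolecular hydrogen
    bond)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(FREE_ENERGY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"free-energy table missing columns {sorted(missing)}")
    return df


def pka_table_from_free_energies(
    df: pd.DataFrame,
    model: str,
    cfg: ThermoConfig | None = None,
    apply_correction: bool = True,
) -> pd.DataFrame:
    """Cycle pKa for every (compound, site) row of one solvation model."""
    sel = df[df["model"] == model]
    if sel.empty:
        raise AlignmentError(f"no rows for solvation model {model!r}")
    rows = []
    for _, r in sel.iterrows():
        fes = FreeEnergySet(
            dG_gas=r["dG_gas"],
            dGsolv_anion=r["dGsolv_anion"],
            dGsolv_hydronium=r["dGsolv_hydronium"],
            dGsolv_acid=r["dGsolv_acid"],
            dGsolv_water=r["dGsolv_water"],
            model=model,
        )
        row = {
            "compound": r["compound"],
            "site": r["site"],
            "model": model,
            "pka": round(pka_from_cycle(fes, cfg, apply_correction), 2),
        }
        if "hbond" in sel.columns:
            row["hbond"] = r["hbond"]
        rows.append(row)
    return pd.DataFrame(rows)
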