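"""Published reference tables shipped with the package.

Three tables for 24 substituted 1,2-dihydroxybenzenes: spectrophotometric
(experimental) pKa values with their uncertainties, DFT/CPCM site-resolved
pKa values with Hammett sigma_p constants, and the three-compound
solvation-model comparison (PCM/IPCM/CPCM vs experiment).

The experimental pKa1 of 4-ethylcatechol appears as 8.32 in the
experimental table and 8.29 in the solvation-model table; both are kept
as printed in their respective sources.  "Hydrocaffeic acid" and
"3,4-dihydroxydihydrocinnamic acid" are synonyms of the same compound;
the longer name is used throughout.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .validation import CompoundRecord

__all__ = [
    "load_experimental_table",
    "load_computational_table",
    "load_solvation_table",
    "paper_fixtures",
]

_DATA = files("dhbpka") / "data"


def load_experimental_table() -> pd.DataFrame:
    """Spectrophotometric pKa1-3 with uncertainties, 24 compounds."""
    with (_DATA / "experimental_pka.csv").open() as fh:
        return pd.read_csv(fh)


def load_computational_table() -> pd.DataFrame:
    """Site-resolved computed pKa (OH_m / OH_p / RH) and sigma_p."""
    with (_DATA / "computational_pka.csv").open() as fh:
        return pd.read_csv(fh)


def load_solvation_table() -> pd.DataFrame:
    """First pKa of three compounds: experiment vs PCM/IPCM/CPCM."""
    with (_DATA / "solvation_models.csv").open() as fh:
        return pd.read_csv(fh)


def _parse_rh(raw) -> tuple[float, ...] | None:
    # a substituent deprotonating twice is printed as "a/b"
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, str):
        return tuple(float(v) for v in raw.split("/"))
    return (float(raw),)


def paper_fixtures() -> list[CompoundRecord]:
    """All 24 compounds as merged :class:`CompoundRecord` objects."""
    exp = load_experimental_table().set_index("compound")
    comp = load_computational_table().set_index("compound")
    records = []
    for name, crow in comp.iterrows():
        erow = exp.loc[name]
        pkas, sds = [], []
        for i in (1, 2, 3):
            v = erow[f"pka{i}"]
            if pd.notna(v):
                pkas.append(float(v))
                sds.append(float(erow[f"pka{i}_sd"]))
        sites: dict = {}
        if pd.notna(crow["pka_ohm"]):
            sites["OH_m"] = float(crow["pka_ohm"])
        if pd.notna(crow["pka_ohp"]):
            sites["OH_p"] = float(crow["pka_ohp"])
        rh = _parse_rh(crow["pka_rh"])
        if rh is not None:
            sites["RH"] = rh
        sigma = float(crow["sigma_p"]) if pd.notna(crow["sigma_p"]) else None
        records.append(
            CompoundRecord(
                name=name,
                experimental_pkas=tuple(pkas),
                experimental_sds=tuple(sds),
                computed_site_pkas=sites,
                sigma_p=sigma,
                substituent=crow["substituent"],
            )
        )
    return records


def fixture_record(name: str) -> CompoundRecord:
    """Single compound by name (case-insensitive)."""
    for rec in paper_fixtures():
        if rec.name.lower() == name.lower():
            return rec
    raise KeyError(name)
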