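"""Simulate reference pH titrations for the spectral analysis.

Generates catechol-like diprotic titration spectra (ground truth
pKa 8.83 / 13.07) on the default pH 2-14 x 190-500 nm grids, noiseless
and at instrument-like noise, and writes them for the downstream recovery
step.  Spectra go to scratch/ (they are bulky intermediates); a small
description table goes to results/.
"""

from pathlib import Path

import pandas as pd

from dhbpka import AcidSystem, default_species_spectra, simulate_titration

SCRATCH = Path("scratch/titrations")
RESULTS = Path("results")


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    system = AcidSystem((8.83, 13.07))
    spectra = default_species_spectra(system.n_species)

    rows = []
    for label, noise_sd, seed in [("noiseless", 0.0, 0), ("noisy", 0.002, 1)]:
        series = simulate_titration(system, spectra, noise_sd=noise_sd, seed=seed)
        path = SCRATCH / f"catechol_{label}.csv"
        series.to_csv(path)
        rows.append(
            {
                "label": label,
                "path": str(path),
                "noise_sd_AU": noise_sd,
                "seed": seed,
                "n_wavelengths": series.wavelengths_nm.size,
                "n_ph": series.ph_values.size,
            }
        )
        print(f"wrote {path}  ({rows[-1]['n_wavelengths']} x {rows[-1]['n_ph']})")

    pd.DataFrame(rows).to_csv(RESULTS / "titration_inventory.csv", index=False)
    print(f"inventory -> {RESULTS / 'titration_inventory.csv'}")


if __name__ == "__main__":
    main()
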