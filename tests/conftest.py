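import numpy as np
import pytest

from dhbpka import (
    AcidSystem,
    SpeciesSpectrum,
    default_species_spectra,
    simulate_titration,
)

CATECHOL_PKAS = (8.83, 13.07)


@pytest.fixture(scope="session")
def catechol_system() -> AcidSystem:
    """Diprotic system with the catechol reference constants."""
    return AcidSystem(CATECHOL_PKAS)


@pytest.fixture(scope="session")
def catechol_series(catechol_system):
    """Noiseless catechol-like titration on the default grids."""
    return simulate_titration(
        catechol_system, default_species_spectra(3), noise_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def monoprotic_series():
    """Noiseless monoprotic titration, pKa 9, bands mirror-symmetric
    about the 284 nm isosbestic point."""
    system = AcidSystem([9.0])
    spectra = [
        SpeciesSpectrum(bands=((275.0, 9.0, 0.85),), label=0),
        SpeciesSpectrum(bands=((293.0, 9.0, 0.85),), label=1),
    ]
    return simulate_titration(system, spectra, noise_sd=0.0, seed=0)


def ideal_hh_trace(pka: float, a_acid: float, a_base: float, ph):
    """Closed-form monoprotic absorbance trace."""
    ph = np.asarray(ph, float)
    f = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return a_acid + (a_base - a_acid) * f
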