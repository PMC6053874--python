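"""Synthetic UV-Vis titration spectra.

Emulates a Britton-Robinson pH titration of a 1 mmol/L chromophore read on
a diode-array spectrophotometer: each protonation state has a pure spectrum
built from Gaussian bands, and the recorded absorbance at every
(wavelength, pH) cell is the Beer-Lambert mixture of the species spectra
weighted by the equilibrium mole fractions, plus optional additive
instrument noise.  The raw spectra behind the published titrations were
never deposited, so this generator is what makes every estimation method in
the package testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt
import pandas as pd

from .errors import ConfigurationError
from .speciation import AcidSystem, species_fractions

__all__ = [
    "SpeciesSpectrum",
    "TitrationSeries",
    "simulate_titration",
    "default_ph_grid",
    "default_wavelength_grid",
    "default_species_spectra",
]

#: default additive noise, absorbance units; small diode-array-like value
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Pure spectrum of one protonation state as a sum of Gaussian bands.

    ``bands`` is a sequence of ``(center_nm, width_nm, peak_absorbance)``
    triples; ``label`` is the species index (0 = fully protonated).
    """

    bands: tuple[tuple[float, float, float], ...]
    label: int = 0

    def __post_init__(self):
        bands = tuple((float(c), float(w), float(a)) for c, w, a in self.bands)
        for c, w, a in bands:
            if w <= 0:
                raise ConfigurationError(f"band width must be positive, got {w}")
            if a < 0:
                raise ConfigurationError(f"peak absorbance must be >= 0, got {a}")
        object.__setattr__(self, "bands", bands)

    def absorbance(self, wavelengths_nm) -> npt.NDArray[np.float64]:
        """Evaluate the spectrum on a wavelength grid."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(lam)
        for c, w, a in self.bands:
            out += a * np.exp(-0.5 * ((lam - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class TitrationSeries:
    """Absorbance matrix over a wavelength grid and a pH grid.

    ``absorbance[i, j]`` is the reading at ``wavelengths_nm[i]`` and
    ``ph_values[j]``; an optional blank spectrum per wavelength may be
    attached.
    """

    wavelengths_nm: npt.NDArray[np.float64]
    ph_values: npt.NDArray[np.float64]
    absorbance: npt.NDArray[np.float64] = field(repr=False)
    blank: npt.NDArray[np.float64] | None = field(default=None, repr=False)

    def __post_init__(self):
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        ph = np.asarray(self.ph_values, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (lam.size, ph.size):
            raise ConfigurationError(
                f"absorbance shape {a.shape} does not match grids ({lam.size}, {ph.size})"
            )
        if np.any(np.diff(lam) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ConfigurationError("absorbance must be finite")
        if self.blank is not None:
            blank = np.asarray(self.blank, dtype=float)
            if blank.shape != lam.shape:
                raise ConfigurationError("blank must match the wavelength grid")
            object.__setattr__(self, "blank", blank)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "ph_values", ph)
        object.__setattr__(self, "absorbance", a)

    # -- grid helpers -------------------------------------------------
    def wavelength_index(self, lam: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths_nm - lam)))
        if abs(self.wavelengths_nm[idx] - lam) > 1e-6:
            raise KeyError(f"wavelength {lam} nm not on the grid")
        return idx

    def ph_index(self, ph: float) -> int:
        idx = int(np.argmin(np.abs(self.ph_values - ph)))
        if abs(self.ph_values[idx] - ph) > 1e-6:
            raise KeyError(f"pH {ph} not on the grid")
        return idx

    def trace(self, lam: float) -> npt.NDArray[np.float64]:
        """Absorbance-vs-pH trace at one wavelength."""
        return self.absorbance[self.wavelength_index(lam)]

    def ph_slice(self, ph_min: float, ph_max: float) -> "TitrationSeries":
        """Sub-series restricted to a pH window (inclusive)."""
        mask = (self.ph_values >= ph_min - 1e-9) & (self.ph_values <= ph_max + 1e-9)
        return TitrationSeries(
            self.wavelengths_nm, self.ph_values[mask], self.absorbance[:, mask], self.blank
        )

    # -- disk format --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: first column ``wavelength_nm``, then one column
        per pH with the header formatted to 2 decimals."""
        df = pd.DataFrame(
            self.absorbance, columns=[f"{p:.2f}" for p in self.ph_values]
        )
        df.insert(0, "wavelength_nm", self.wavelengths_nm)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "wavelength_nm":
            raise ConfigurationError("first CSV column must be 'wavelength_nm'")
        lam = df["wavelength_nm"].to_numpy(float)
        ph = np.array([float(c) for c in df.columns[1:]])
        return cls(lam, ph, df.iloc[:, 1:].to_numpy(float))


def default_ph_grid(step: float = 0.25) -> npt.NDArray[np.float64]:
    """pH grid 2.0-14.0 (the titration range useful for biological and
    oxidation-process work) at the given step."""
    if step <= 0:
        raise ConfigurationError("pH step must be positive")
    n = int(round((14.0 - 2.0) / step))
    return np.round(2.0 + step * np.arange(n + 1), 10)


def default_wavelength_grid(step: float = 1.0) -> npt.NDArray[np.float64]:
    """Wavelength grid 190-500 nm covering the reported analysis
    wavelengths (194-450 nm)."""
    n = int(round((500.0 - 190.0) / step))
    return np.round(190.0 + step * np.arange(n + 1), 10)


def default_species_spectra(n_species: int) -> list[SpeciesSpectrum]:
    """Generic chromophore model: each deprotonation red-shifts the main
    band by 18 nm at constant width and intensity.

    Centers fall at 269, 287, 305, 323 nm so that consecutive-species
    band pairs cross exactly on the 1 nm default grid, the way a clean
    two-species equilibrium shows an isosbestic point.  A fixed far-UV
    shoulder common to all species adds background without affecting any
    difference signal.
    """
    spectra = []
    for s in range(n_species):
        bands = (
            (210.0, 12.0, 1.1),
            (269.0 + 18.0 * s, 9.0, 0.85),
        )
        spectra.append(SpeciesSpectrum(bands=bands, label=s))
    return spectra


def simulate_titration(
    system: AcidSystem,
    species_spectra,
    wavelengths=None,
    ph_values=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationSeries:
    """Beer-Lambert mixture of species spectra weighted by speciation.

    absorbance(lambda, pH) = sum_s fraction_s(pH) * A_s(lambda)
                             + Gaussian(0, noise_sd)

    Reproducible for a fixed ``seed``; ``noise_sd`` in absorbance units.
    """
    if len(species_spectra) != system.n_species:
        raise ConfigurationError(
            f"need {system.n_species} species spectra for {system.n_protons} "
            f"dissociations, got {len(species_spectra)}"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, float)
    ph = default_ph_grid() if ph_values is None else np.asarray(ph_values, float)
    pure = np.stack([sp.absorbance(lam) for sp in species_spectra])  # (n_species, n_lam)
    frac = species_fractions(system, ph).fractions  # (n_species, n_ph)
    a = pure.T @ frac  # (n_lam, n_ph)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return TitrationSeries(lam, ph, a)
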