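"""Equilibrium speciation of polyprotic acids.

The Henderson-Hasselbalch relation

    pH = pKa + log10([base]/[acid])

for each successive dissociation step fixes the mole fractions of the
n+1 protonation states of an n-protic acid at every pH.  Those fractions
weight the pure-species spectra in every spectrophotometric method in this
package and in the titration simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .errors import InvalidSystemError

__all__ = ["AcidSystem", "SpeciationProfile", "species_fractions", "hh_pka_from_ratio"]

#: allowed per-dissociation site tags: hydroxyl meta / para to the
#: 4-substituent, or a dissociable proton on the substituent itself
SITE_LABELS = ("OH_m", "OH_p", "RH")


@dataclass(frozen=True)
class AcidSystem:
    """A mono- to tetraprotic acid defined by its ordered pKa values.

    Parameters
    ----------
    pkas
        Strictly increasing macroscopic pKa values, one per dissociation.
    site_labels
        Optional tag per dissociation, one of ``OH_m``, ``OH_p``, ``RH``.
    """

    pkas: tuple[float, ...]
    site_labels: tuple[str, ...] | None = None

    def __init__(self, pkas, site_labels=None):
        pkas = tuple(float(p) for p in pkas)
        if not 1 <= len(pkas) <= 4:
            raise InvalidSystemError(f"1-4 dissociable protons supported, got {len(pkas)}")
        if not all(np.isfinite(pkas)):
            raise InvalidSystemError("all pKa values must be finite")
        if any(b <= a for a, b in zip(pkas, pkas[1:])):
            raise InvalidSystemError(f"pKa values must be strictly increasing, got {pkas}")
        if site_labels is not None:
            site_labels = tuple(site_labels)
            if len(site_labels) != len(pkas):
                raise InvalidSystemError("need one site label per dissociation")
            bad = [s for s in site_labels if s not in SITE_LABELS]
            if bad:
                raise InvalidSystemError(f"unknown site labels {bad}; allowed {SITE_LABELS}")
        object.__setattr__(self, "pkas", pkas)
        object.__setattr__(self, "site_labels", site_labels)

    @property
    def n_protons(self) -> int:
        return len(self.pkas)

    @property
    def n_species(self) -> int:
        return len(self.pkas) + 1


@dataclass(frozen=True)
class SpeciationProfile:
    """Mole fractions of each protonation state over a pH grid.

    ``fractions[s, j]`` is the fraction of the species that has lost ``s``
    protons at ``ph_grid[j]``; columns sum to one.
    """

    ph_grid: npt.NDArray[np.float64]
    fractions: npt.NDArray[np.float64] = field(repr=False)


def species_fractions(system: AcidSystem, ph_grid) -> SpeciationProfile:
    """Mole fraction of every protonation state at each pH.

    For species ``s`` (s protons removed) the unnormalised abundance is
    ``10**(s*pH - sum(pKa_1..pKa_s))``; the largest exponent is factored
    out before exponentiation so that e.g. pH 14 with pKa 2 cannot
    overflow.
    """
    ph = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    if ph.size == 0 or not np.all(np.isfinite(ph)):
        raise ValueError("ph_grid must be non-empty and finite")
    cum_pka = np.concatenate([[0.0], np.cumsum(system.pkas)])  # (n_species,)
    s = np.arange(system.n_species)
    log_abund = s[:, None] * ph[None, :] - cum_pka[:, None]  # (n_species, n_ph)
    log_abund -= log_abund.max(axis=0, keepdims=True)
    abund = 10.0 ** log_abund
    fractions = abund / abund.sum(axis=0, keepdims=True)
    return SpeciationProfile(ph_grid=ph, fractions=fractions)


def hh_pka_from_ratio(ph: float, ratio_base_over_acid: float) -> float:
    """Invert Henderson-Hasselbalch: pKa = pH - log10([base]/[acid])."""
    if not ratio_base_over_acid > 0:
        raise ValueError(f"base/acid ratio must be positive, got {ratio_base_over_acid}")
    return float(ph) - float(np.log10(ratio_base_over_acid))
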