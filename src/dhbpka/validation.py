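"""Validation analyses: experimental-vs-computed pairing, correlation, and
Hammett-based assignment of the first deprotonation site.

For a 4-substituted catechol the two phenolic hydroxyls are labelled by
their position relative to the substituent: OH_m (meta) and OH_p (para);
RH marks a dissociable proton on the substituent itself (e.g. a carboxylic
acid).  Electron-donating substituents (Hammett sigma_p < 0) leave the
meta hydroxyl most acidic; electron-withdrawing ones (sigma_p > 0)
stabilise the para phenolate by resonance and invert the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .errors import PairingError

__all__ = [
    "CompoundRecord",
    "SubstituentClass",
    "pair_sorted",
    "correlation_r2",
    "classify_substituent",
    "first_deprotonation_site",
]

SITE_KEYS = ("OH_m", "OH_p", "RH")

#: substituents that are inductively electron-withdrawing but pi-donating
#: (weakly deactivating halogens / hydroxyl); their printed sigma_p does
#: not predict the deprotonation order, so they are flagged as exceptions
#: to the sigma-sign rule.
WEAK_PI_DONORS = frozenset({"chloro", "fluoro", "bromo", "iodo", "hydroxyl"})


class SubstituentClass(str, Enum):
    EDG = "EDG"
    EWG = "EWG"
    NEUTRAL = "neutral"
    NOT_CLASSIFIABLE = "not_classifiable"


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's experimental and computed acidity data.

    ``computed_site_pkas`` maps ``OH_m``/``OH_p``/``RH`` to one or more
    pKa values (a substituent may deprotonate twice, so ``RH`` can carry
    two values).
    """

    name: str
    experimental_pkas: tuple[float, ...] = ()
    experimental_sds: tuple[float, ...] = ()
    computed_site_pkas: dict = field(default_factory=dict)
    sigma_p: float | None = None
    substituent: str | None = None

    def __post_init__(self):
        if not self.experimental_pkas and not self.computed_site_pkas:
            raise PairingError(f"{self.name}: no experimental or computed values")
        bad = set(self.computed_site_pkas) - set(SITE_KEYS)
        if bad:
            raise PairingError(f"{self.name}: unknown site keys {sorted(bad)}")

    def computed_values(self) -> list[float]:
        """All computed pKa values, flattened, in ascending order."""
        vals: list[float] = []
        for site in SITE_KEYS:
            v = self.computed_site_pkas.get(site)
            if v is None:
                continue
            vals.extend(v if isinstance(v, (tuple, list)) else [v])
        return sorted(vals)


def pair_sorted(record: CompoundRecord) -> list[tuple[float, float]]:
    """Pair experimental and computed pKa values per dissociation index.

    Both sides are sorted ascending; the computed list is truncated to the
    number of experimental values and paired index-wise.  This reflects
    that macroscopic dissociation constants come out of a titration in
    acidity order, whatever site each belongs to.
    """
    exp = sorted(record.experimental_pkas)
    comp = record.computed_values()
    if not exp or not comp:
        raise PairingError(f"{record.name}: need both experimental and computed values")
    return list(zip(exp, comp[: len(exp)]))


def correlation_r2(pairs) -> float:
    """Ordinary least-squares coefficient of determination of computed
    (y) against experimental (x) pKa."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if np.ptp(x) == 0:
        raise ValueError("experimental values are constant; r^2 undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


def per_index_r2(records) -> dict[int, float]:
    """r^2 of the pKa1 / pKa2 / pKa3 ... series over all compounds that
    have the given dissociation index."""
    series: dict[int, list[tuple[float, float]]] = {}
    for rec in records:
        for i, pair in enumerate(pair_sorted(rec)):
            series.setdefault(i, []).append(pair)
    return {i: correlation_r2(p) for i, p in sorted(series.items())}


def classify_substituent(sigma_p: float | None) -> SubstituentClass:
    """Hammett sign rule: sigma < 0 donates electron density (EDG),
    sigma > 0 withdraws it (EWG), sigma = 0 is the unsubstituted
    reference."""
    if sigma_p is None or not np.isfinite(sigma_p):
        return SubstituentClass.NOT_CLASSIFIABLE
    if sigma_p < 0:
        return SubstituentClass.EDG
    if sigma_p > 0:
        return SubstituentClass.EWG
    return SubstituentClass.NEUTRAL


@dataclass(frozen=True)
class SiteAssignment:
    name: str
    first_hydroxyl_site: str  # OH_m or OH_p
    rh_is_global_minimum: bool
    substituent_class: SubstituentClass
    consistent: bool | None  # None when the sigma rule cannot be applied
    exception: bool


def first_deprotonation_site(record: CompoundRecord) -> SiteAssignment:
    """Which hydroxyl loses its proton first, and whether that agrees
    with the Hammett classification of the 4-substituent.

    The site is the hydroxyl (OH_m/OH_p) of minimum computed pKa; a
    substituent proton (RH) more acidic than both hydroxyls is reported
    separately via ``rh_is_global_minimum``.  A compound is flagged as an
    exception when the observed hydroxyl contradicts the sigma-sign rule,
    or when its substituent is a weak pi-donor (halogen, hydroxyl) whose
    inductive electron withdrawal would predict OH_p yet OH_m
    deprotonates first.
    """
    hydroxyls = {
        s: min(v) if isinstance(v, (tuple, list)) else v
        for s, v in record.computed_site_pkas.items()
        if s in ("OH_m", "OH_p") and v is not None
    }
    if not hydroxyls:
        raise PairingError(f"{record.name}: no computed hydroxyl pKa")
    site = min(hydroxyls, key=hydroxyls.get)
    rh = record.computed_site_pkas.get("RH")
    rh_min = min(rh) if isinstance(rh, (tuple, list)) else rh
    rh_global = rh_min is not None and rh_min < min(hydroxyls.values())

    cls = classify_substituent(record.sigma_p)
    if cls in (SubstituentClass.NOT_CLASSIFIABLE, SubstituentClass.NEUTRAL):
        consistent = None
    else:
        predicted = "OH_m" if cls is SubstituentClass.EDG else "OH_p"
        consistent = site == predicted
    weak_pi = (
        record.substituent in WEAK_PI_DONORS and site == "OH_m"
    )
    exception = (consistent is False) or weak_pi
    return SiteAssignment(
        name=record.name,
        first_hydroxyl_site=site,
        rh_is_global_minimum=bool(rh_global),
        substituent_class=cls,
        consistent=consistent,
        exception=exception,
    )
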