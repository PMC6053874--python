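"""Method-selection cascade for multi-step titration spectra.

For each dissociation the estimators are tried in a fixed order --
raw-spectrum isosbestic intersection, first- then second-derivative
isosbestic, zero-crossing, baseline-to-peak, three-point closed form --
and the first success is reported together with the reason every earlier
method was skipped.  Transition windows are located from the largest
pH-derivative of the whole absorbance matrix, one per dissociation, with
boundaries at the midpoints between neighbouring transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DhbPkaError,
    MethodFailure,
    MethodInapplicableError,
    ParameterError,
    UnresolvedDissociationError,
)
from .spectral import (
    PkaEstimate,
    SeokInputs,
    baseline_to_peak_pka,
    derivative_spectra,
    find_isosbestic_points,
    intersection_pka,
    seok_pka,
    select_wavelength_pair,
    zero_crossing_pka,
)
from .synth import TitrationSeries

__all__ = ["CascadeConfig", "Attempt", "DissociationResult", "CascadeReport", "run_cascade"]


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds of the cascade; defaults match the package's
    synthetic-instrument assumptions."""

    sg_window: int = 7
    sg_polyorder: int = 3
    zero_tol: float = 0.02  # fraction of a derivative column's max amplitude
    isosbestic_threshold: float | None = None  # None = adaptive
    seok_quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)
    min_transition_separation: float = 1.0  # pH units between detected windows

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ParameterError(f"unknown cascade options: {sorted(unknown)}")
        cfg = cls(**known)
        if cfg.sg_window % 2 != 1 or cfg.sg_window <= cfg.sg_polyorder:
            raise ParameterError("need odd sg_window > sg_polyorder")
        return cfg


@dataclass(frozen=True)
class Attempt:
    method: str
    status: str  # "ok" or "skipped"
    reason: str = ""


@dataclass(frozen=True)
class DissociationResult:
    index: int  # 1-based dissociation number
    ph_window: tuple[float, float]
    estimate: PkaEstimate
    attempts: tuple[Attempt, ...]


@dataclass(frozen=True)
class CascadeReport:
    results: tuple[DissociationResult, ...] = field(default=())

    @property
    def pkas(self) -> tuple[float, ...]:
        return tuple(r.estimate.pka for r in self.results)

    def to_dict(self) -> dict:
        return {
            "results": [
                {
                    "dissociation": r.index,
                    "ph_window": list(r.ph_window),
                    "pka": round(r.estimate.pka, 2),
                    "method": r.estimate.method,
                    "wavelengths_nm": list(r.estimate.wavelengths_nm),
                    "derivative_order": r.estimate.derivative_order,
                    "diagnostics": r.estimate.diagnostics,
                    "skipped": [
                        {"method": a.method, "reason": a.reason}
                        for a in r.attempts
                        if a.status == "skipped"
                    ],
                }
                for r in self.results
            ]
        }


def transition_windows(
    series: TitrationSeries, n_dissociations: int, min_separation: float = 1.0
) -> list[tuple[float, float]]:
    """One pH window per dissociation, centred on the largest overall
    |dA/dpH| responses, with midpoint boundaries between neighbours."""
    ph = series.ph_values
    if ph.size < 5:
        raise ParameterError("need at least 5 pH points to locate transitions")
    rate = np.abs(np.diff(series.absorbance, axis=1)).mean(axis=0) / np.diff(ph)
    mid = 0.5 * (ph[:-1] + ph[1:])
    step = float(np.median(np.diff(ph)))
    distance = max(1, int(round(min_separation / step)))
    peaks, props = find_peaks(rate, distance=distance)
    if peaks.size < n_dissociations:
        # weak or edge transitions: fall back to the largest rate samples
        order = np.argsort(rate)[::-1]
        chosen: list[int] = []
        for idx in order:
            if all(abs(mid[idx] - mid[c]) >= min_separation for c in chosen):
                chosen.append(int(idx))
            if len(chosen) == n_dissociations:
                break
        peaks = np.array(sorted(chosen))
    else:
        top = peaks[np.argsort(rate[peaks])[::-1][:n_dissociations]]
        peaks = np.sort(top)
    centers = mid[peaks]
    bounds = [float(ph[0])]
    bounds += [float(0.5 * (a + b)) for a, b in zip(centers, centers[1:])]
    bounds.append(float(ph[-1]))
    # snap to the grid so window edges are valid pH columns
    bounds = [float(ph[int(np.argmin(np.abs(ph - b)))]) for b in bounds]
    return [(bounds[k], bounds[k + 1]) for k in range(len(centers))]


def _increasing_wavelength(series: TitrationSeries, window) -> float:
    """Wavelength of largest absorbance rise across the window."""
    sub = series.ph_slice(*window)
    diff = sub.absorbance[:, -1] - sub.absorbance[:, 0]
    i = int(np.argmax(diff))
    if diff[i] <= 0:
        raise MethodInapplicableError("no wavelength with increasing absorbance")
    return float(sub.wavelengths_nm[i])


def run_cascade(
    series: TitrationSeries,
    n_dissociations: int,
    config: CascadeConfig | None = None,
) -> CascadeReport:
    """Estimate every dissociation constant of a titration series.

    Deterministic: identical inputs and configuration give an identical
    report.  Raises :class:`UnresolvedDissociationError` if every method
    fails for some transition.
    """
    if not 1 <= int(n_dissociations) <= 4:
        raise ParameterError("n_dissociations must be in 1..4")
    cfg = config or CascadeConfig()
    windows = transition_windows(series, n_dissociations, cfg.min_transition_separation)

    derivs: dict[int, TitrationSeries] = {}

    def deriv(order: int) -> TitrationSeries:
        if order not in derivs:
            derivs[order] = derivative_spectra(series, order, cfg.sg_window, cfg.sg_polyorder)
        return derivs[order]

    results = []
    for k, window in enumerate(windows, start=1):
        attempts: list[Attempt] = []
        estimate = None

        def attempt(name, fn):
            nonlocal estimate
            if estimate is not None:
                return
            try:
                estimate = fn()
                attempts.append(Attempt(name, "ok"))
            except (MethodFailure, ParameterError, DhbPkaError, KeyError) as exc:
                attempts.append(Attempt(name, "skipped", str(exc)))

        def isosbestic_route(data: TitrationSeries, order: int):
            # gate on the interquartile core of the window: near the edges
            # the neighbouring dissociations contribute residual fractions
            # that inflate the spread at a genuine isosbestic wavelength
            ph_in = data.ph_values[
                (data.ph_values >= window[0]) & (data.ph_values <= window[1])
            ]
            core = (
                (float(np.quantile(ph_in, 0.25)), float(np.quantile(ph_in, 0.75)))
                if ph_in.size >= 12
                else window
            )
            cands = find_isosbestic_points(data, core, cfg.isosbestic_threshold)
            if not cands:
                raise MethodInapplicableError("no isosbestic point in this window")
            lam1, lam2, pair_diag = select_wavelength_pair(data, window)
            est = intersection_pka(data, lam1, lam2, window, derivative_order=order)
            # refine: unmix pure-species spectra with the current estimate
            # so residual transition fractions at the window edges do not
            # bias the wavelength pairing
            for _ in range(3):
                lam1, lam2, pair_diag = select_wavelength_pair(
                    data, window, pka_hint=est.pka
                )
                new = intersection_pka(data, lam1, lam2, window, derivative_order=order)
                converged = abs(new.pka - est.pka) < 1e-4
                est = new
                if converged:
                    break
            diag = dict(est.diagnostics)
            diag["isosbestic_nm"] = cands[0][0]
            diag["isosbestic_spread"] = cands[0][1]
            diag.update(pair_diag)
            return PkaEstimate(est.pka, est.method, est.wavelengths_nm, order, diag)

        def seok_route():
            lam = _increasing_wavelength(series, window)
            sub = series.ph_slice(*window)
            cols = [int(round(q * (sub.ph_values.size - 1))) for q in cfg.seok_quantiles]
            if len(set(cols)) < 3:
                raise MethodInapplicableError("window too narrow for three points")
            trace = sub.trace(lam)
            inputs = SeokInputs(
                *(float(sub.ph_values[c]) for c in cols),
                *(float(trace[c]) for c in cols),
            )
            return seok_pka(inputs, wavelength=lam)

        attempt("isosbestic_intersection", lambda: isosbestic_route(series, 0))
        attempt("derivative_isosbestic_1", lambda: isosbestic_route(deriv(1), 1))
        attempt("derivative_isosbestic_2", lambda: isosbestic_route(deriv(2), 2))
        attempt(
            "zero_crossing",
            lambda: zero_crossing_pka(
                deriv(1), window[0], window[1], window, 1, cfg.zero_tol
            ),
        )
        attempt(
            "baseline_to_peak",
            lambda: baseline_to_peak_pka(
                series, _increasing_wavelength(series, window), window
            ),
        )
        attempt("seok", seok_route)

        if estimate is None:
            raise UnresolvedDissociationError(
                k, {a.method: a.reason for a in attempts if a.status == "skipped"}
            )
        results.append(
            DissociationResult(
                index=k, ph_window=window, estimate=estimate, attempts=tuple(attempts)
            )
        )
    return CascadeReport(results=tuple(results))
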