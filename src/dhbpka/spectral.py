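"""Spectrophotometric pKa estimation from pH-titration spectra.

Five estimators operate on a :class:`~dhbpka.synth.TitrationSeries`:

isosbestic intersection
    When a two-species equilibrium shows an isosbestic point, the
    absorbance-vs-pH traces at two wavelengths on opposite sides of it
    cross at the pH where the two species are equimolar, i.e. at pKa.
derivative isosbestic
    The same analysis on Savitzky-Golay first or second wavelength
    derivatives, which often restores an isosbestic hidden by overlapping
    bands in the raw spectra.
zero-crossing
    Two wavelengths where one species' derivative signal vanishes while
    the other's is large, so each trace selectively monitors one species;
    the magnitude traces intersect at pKa.
baseline-to-peak
    At a single wavelength whose signal grows with pH, the distances of
    the trace to its acid and base limiting values give the base/acid
    concentration ratio; pH = pKa + log10(M/N) is fitted by least squares.
seok
    A closed form for pKa from three (pH, absorbance) points on one
    sigmoid transition, with the two unknown limiting absorbances
    eliminated algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .errors import (
    DegenerateSeriesError,
    IllConditionedError,
    InsufficientDataError,
    MethodInapplicableError,
    NoCrossingError,
    NoTransitionError,
    ParameterError,
)
from .synth import TitrationSeries

__all__ = [
    "PkaEstimate",
    "SeokInputs",
    "derivative_spectra",
    "estimate_noise_sd",
    "find_isosbestic_points",
    "select_wavelength_pair",
    "intersection_pka",
    "zero_crossing_pka",
    "baseline_to_peak_pka",
    "seok_pka",
]

METHODS = (
    "isosbestic_intersection",
    "derivative_isosbestic",
    "zero_crossing",
    "baseline_to_peak",
    "seok",
)


@dataclass(frozen=True)
class PkaEstimate:
    """One dissociation constant with its provenance and diagnostics."""

    pka: float
    method: str
    wavelengths_nm: tuple[float, ...] = ()
    derivative_order: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}")
        if self.derivative_order not in (0, 1, 2):
            raise ParameterError("derivative_order must be 0, 1 or 2")
        if not np.isfinite(self.pka):
            raise ParameterError("pKa must be finite")

    def rounded(self, ndigits: int = 2) -> float:
        """Display precision used in reported tables."""
        return round(self.pka, ndigits)


# ---------------------------------------------------------------------
# preprocessing


def derivative_spectra(
    series: TitrationSeries, order: int, window: int = 7, polyorder: int = 3
) -> TitrationSeries:
    """Column-wise Savitzky-Golay derivative with respect to wavelength."""
    if order not in (1, 2):
        raise ParameterError("order must be 1 or 2")
    if window % 2 != 1 or window <= polyorder or order > polyorder:
        raise ParameterError("need odd window > polyorder >= order")
    if window > series.wavelengths_nm.size:
        raise ParameterError("window larger than the wavelength grid")
    steps = np.diff(series.wavelengths_nm)
    if np.ptp(steps) > 1e-9 * steps[0]:
        raise ParameterError("wavelength grid must be uniform for differentiation")
    deriv = savgol_filter(
        series.absorbance, window, polyorder, deriv=order, delta=steps[0], axis=0
    )
    return TitrationSeries(series.wavelengths_nm, series.ph_values, deriv, series.blank)


def estimate_noise_sd(series: TitrationSeries) -> float:
    """Robust additive-noise estimate from second differences along pH.

    For i.i.d. noise the second difference has variance 6 sigma^2; the
    smooth titration signal contributes little to the median because most
    (wavelength, pH) cells sit outside any transition.
    """
    a = series.absorbance
    if a.shape[1] < 3:
        return 0.0
    d2 = a[:, 2:] - 2.0 * a[:, 1:-1] + a[:, :-2]
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


# ---------------------------------------------------------------------
# isosbestic analysis


def find_isosbestic_points(
    series: TitrationSeries,
    ph_window: tuple[float, float] | None = None,
    threshold: float | None = None,
) -> list[tuple[float, float]]:
    """Wavelengths where absorbance is independent of pH within a window.

    Candidates are interior local minima of the across-pH standard
    deviation lying below a threshold; they are returned sorted by spread
    (best first).  An empty list signals "no isosbestic point: use the
    next method".  The default threshold adapts to the data: 5x the noise
    estimate or 2% of the strongest pH response in the window, whichever
    is larger, so that small leakage from a neighbouring dissociation
    does not mask a genuine crossing.  A series with no pH response at
    all (flat, single species) raises :class:`DegenerateSeriesError`.
    """
    sub = series if ph_window is None else series.ph_slice(*ph_window)
    if sub.ph_values.size < 3:
        raise ParameterError("pH window must contain at least 3 columns")
    spread = sub.absorbance.std(axis=1)
    scale = max(1.0, float(np.max(np.abs(sub.absorbance))))
    floor = 1e-12 * scale
    max_spread = float(spread.max())
    if max_spread < floor:
        raise DegenerateSeriesError("no pH-dependent signal anywhere in the window")
    noise = estimate_noise_sd(sub)
    if max_spread < 10.0 * noise:
        return []  # pH response indistinguishable from noise
    if threshold is None:
        threshold = max(5.0 * noise, 0.02 * max_spread, floor)
    interior = np.arange(1, spread.size - 1)
    is_min = (spread[interior] <= spread[interior - 1]) & (
        spread[interior] <= spread[interior + 1]
    )
    # an isosbestic point carries real absorbance that is pH-independent;
    # wavelengths outside every band also have tiny spread but no signal
    signal = np.abs(sub.absorbance).mean(axis=1)
    has_signal = signal[interior] >= 0.05 * float(signal.max())
    cand = interior[is_min & has_signal & (spread[interior] < threshold)]
    out = [(float(sub.wavelengths_nm[i]), float(spread[i])) for i in cand]
    out.sort(key=lambda t: t[1])
    return out


def select_wavelength_pair(
    series: TitrationSeries,
    ph_window: tuple[float, float],
    pka_hint: float | None = None,
) -> tuple[float, float, dict]:
    """Choose the two monitoring wavelengths for the intersection method.

    The crossing of two single-wavelength traces falls exactly at the
    transition midpoint iff the sum of the pure acid and base species
    spectra is equal at the two wavelengths.  Starting from the extremes
    of the acid-to-base difference spectrum, the partner wavelength is
    picked on the opposite-sign side so as to match that sum, which makes
    the estimate unbiased by construction instead of relying on band
    symmetry.

    Without ``pka_hint`` the window's edge columns stand in for the pure
    species.  Given a hint, the pure spectra are unmixed from the edge
    columns with two-state speciation factors, which removes the bias the
    residual transition fractions at the window edges would otherwise
    introduce (the cascade iterates on this).
    """
    sub = series.ph_slice(*ph_window)
    if sub.ph_values.size < 3:
        raise ParameterError("pH window must contain at least 3 columns")
    ph = sub.ph_values
    acid = sub.absorbance[:, 0]
    base = sub.absorbance[:, -1]
    exclude = None
    if pka_hint is not None:
        # unmix the pure spectra from two columns close to the transition
        # midpoint, where the fractions of species belonging to the
        # neighbouring dissociations are smallest
        f_acid = lambda p: 1.0 / (1.0 + 10.0 ** (p - pka_hint))  # noqa: E731
        i1 = int(np.argmin(np.abs(ph - max(ph[0], pka_hint - 0.75))))
        i2 = int(np.argmin(np.abs(ph - min(ph[-1], pka_hint + 0.75))))
        fa1, fa2 = f_acid(ph[i1]), f_acid(ph[i2])
        det = fa1 - fa2
        if i1 != i2 and abs(det) > 0.3:
            c1, c2 = sub.absorbance[:, i1], sub.absorbance[:, i2]
            acid = ((1.0 - fa2) * c1 - (1.0 - fa1) * c2) / det
            base = (fa1 * c2 - fa2 * c1) / det
            # wavelengths where the two-state model cannot explain the
            # window edges are dominated by a neighbouring species; keep
            # the trace pair away from them
            resid = np.zeros_like(acid)
            for j in (0, ph.size - 1):
                fa = f_acid(ph[j])
                resid += np.abs(sub.absorbance[:, j] - fa * acid - (1.0 - fa) * base)
            exclude = resid > 0.25 * float(np.max(np.abs(base - acid)))
    diff = base - acid
    total = base + acid
    if exclude is not None:
        masked = np.where(exclude, 0.0, diff)
        # only apply the mask if it leaves a usable two-sided response
        if np.max(np.abs(masked)) > 0.3 * np.max(np.abs(diff)):
            diff = masked
    noise = estimate_noise_sd(sub)
    amp = float(np.max(np.abs(diff)))
    if amp < max(10.0 * noise, 1e-12 * max(1.0, float(np.max(np.abs(sub.absorbance))))):
        raise MethodInapplicableError("no acid-to-base spectral difference")

    def best_pair(anchor_sign: int):
        anchor = int(np.argmax(anchor_sign * diff))
        if anchor_sign * diff[anchor] <= 0:
            return None
        opposite = np.flatnonzero(anchor_sign * diff < -0.2 * anchor_sign * diff[anchor])
        if opposite.size == 0:
            opposite = np.flatnonzero(anchor_sign * diff < -10.0 * noise)
        if opposite.size == 0:
            return None
        partner = opposite[int(np.argmin(np.abs(total[opposite] - total[anchor])))]
        mismatch = abs(total[partner] - total[anchor])
        return anchor, int(partner), mismatch

    pairs = [p for p in (best_pair(+1), best_pair(-1)) if p is not None]
    if not pairs:
        raise MethodInapplicableError("difference spectrum is one-sided; no trace pair")
    i, j, mismatch = min(pairs, key=lambda p: p[2])
    lam1, lam2 = sorted((float(sub.wavelengths_nm[i]), float(sub.wavelengths_nm[j])))
    return lam1, lam2, {"sum_mismatch": float(mismatch), "diff_amplitude": amp}


def _cross_traces(ph, y1, y2, ph_window=None):
    """pH of the crossing of two traces, linearly interpolated; handles
    multiple crossings by preferring the one inside the active window."""
    d = np.asarray(y1, float) - np.asarray(y2, float)
    crossings = []
    for j in range(d.size - 1):
        if d[j] == 0.0 and d[j + 1] == 0.0:
            continue
        if d[j] == 0.0:
            crossings.append((float(ph[j]), abs(d[j + 1] - d[j])))
        elif d[j] * d[j + 1] < 0.0:
            t = d[j] / (d[j] - d[j + 1])
            crossings.append((float(ph[j] + t * (ph[j + 1] - ph[j])), abs(d[j + 1] - d[j])))
    if not crossings:
        raise NoCrossingError("traces never intersect in the pH range")
    diag = {"n_crossings": len(crossings)}
    if len(crossings) == 1:
        return crossings[0][0], diag
    diag["ambiguous"] = True
    if ph_window is not None:
        inside = [c for c in crossings if ph_window[0] <= c[0] <= ph_window[1]]
        if inside:
            center = 0.5 * (ph_window[0] + ph_window[1])
            return min(inside, key=lambda c: abs(c[0] - center))[0], diag
    # fall back to the steepest crossing (strongest transition)
    return max(crossings, key=lambda c: c[1])[0], diag


def intersection_pka(
    series: TitrationSeries,
    lambda_low: float,
    lambda_high: float,
    ph_window: tuple[float, float] | None = None,
    derivative_order: int = 0,
    absolute: bool = False,
) -> PkaEstimate:
    """pKa from the crossing of the absorbance-vs-pH traces at two
    wavelengths flanking an isosbestic point."""
    i = series.wavelength_index(lambda_low)
    j = series.wavelength_index(lambda_high)
    if i == j:
        raise NoCrossingError("identical wavelengths: traces cannot cross")
    y1, y2 = series.absorbance[i], series.absorbance[j]
    if absolute:
        y1, y2 = np.abs(y1), np.abs(y2)
    ph_cross, diag = _cross_traces(series.ph_values, y1, y2, ph_window)
    method = "isosbestic_intersection" if derivative_order == 0 else "derivative_isosbestic"
    return PkaEstimate(
        pka=ph_cross,
        method=method,
        wavelengths_nm=(float(series.wavelengths_nm[i]), float(series.wavelengths_nm[j])),
        derivative_order=derivative_order,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------
# zero-crossing


def zero_crossing_pka(
    series_derivative: TitrationSeries,
    ph_acid: float,
    ph_base: float,
    ph_window: tuple[float, float] | None = None,
    derivative_order: int = 1,
    zero_tol: float = 0.02,
) -> PkaEstimate:
    """pKa from two selective wavelengths in a derivative series.

    lambda_1 is a wavelength where the acid-side derivative spectrum is
    (numerically) zero and the base-side signal is largest, so its trace
    follows only the basic species; lambda_2 has the roles swapped.  The
    magnitude traces are then intersected.  "Zero" means below
    ``zero_tol`` (default 2%) of that column's maximum amplitude.
    """
    col_a = series_derivative.absorbance[:, series_derivative.ph_index(ph_acid)]
    col_b = series_derivative.absorbance[:, series_derivative.ph_index(ph_base)]
    max_a, max_b = float(np.max(np.abs(col_a))), float(np.max(np.abs(col_b)))
    if max_a < 1e-12 or max_b < 1e-12:
        raise DegenerateSeriesError("derivative spectra carry no signal")

    def selective(zero_col, zero_max, signal_col):
        zeros = np.flatnonzero(np.abs(zero_col) < zero_tol * zero_max)
        if zeros.size == 0:
            return None
        return zeros[int(np.argmax(np.abs(signal_col[zeros])))]

    i = selective(col_a, max_a, col_b)
    j = selective(col_b, max_b, col_a)
    if i is None or j is None or i == j:
        raise MethodInapplicableError("no selective zero-crossing wavelength pair")
    est = intersection_pka(
        series_derivative,
        float(series_derivative.wavelengths_nm[min(i, j)]),
        float(series_derivative.wavelengths_nm[max(i, j)]),
        ph_window=ph_window,
        derivative_order=derivative_order,
        absolute=True,
    )
    diag = dict(est.diagnostics)
    diag["amplitude_ratio"] = float(np.abs(col_b[i]) / np.abs(col_a[j]))
    return PkaEstimate(
        pka=est.pka,
        method="zero_crossing",
        wavelengths_nm=est.wavelengths_nm,
        derivative_order=derivative_order,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------
# baseline-to-peak


def baseline_to_peak_pka(
    series: TitrationSeries,
    wavelength: float,
    ph_fit_range: tuple[float, float] | None = None,
    a_acid_limit: float | None = None,
    a_base_limit: float | None = None,
    floor: float | None = None,
) -> PkaEstimate:
    """pKa from the log ratio of distances to the limiting absorbances.

    M(pH) = A(pH) - A_acid and N(pH) = A_base - A(pH) are proportional to
    the base and acid concentrations, so log10(M/N) is linear in pH with
    unit slope and pKa = -intercept/slope.  The slope is left free as a
    diagnostic.  Limits default to the edge columns of the fit range.
    """
    idx = series.wavelength_index(wavelength)
    ph = series.ph_values
    y = series.absorbance[idx]
    if ph_fit_range is not None:
        mask = (ph >= ph_fit_range[0] - 1e-9) & (ph <= ph_fit_range[1] + 1e-9)
        ph, y = ph[mask], y[mask]
    if ph.size < 3:
        raise InsufficientDataError("fewer than 3 points in the fit range")
    a_acid = float(y[0]) if a_acid_limit is None else float(a_acid_limit)
    a_base = float(y[-1]) if a_base_limit is None else float(a_base_limit)
    amplitude = a_base - a_acid
    noise = estimate_noise_sd(series)
    if abs(amplitude) < max(10.0 * noise, 1e-12):
        raise NoTransitionError("acid and base limits coincide: no transition amplitude")
    if amplitude < 0:
        raise MethodInapplicableError("absorbance does not increase with pH here")
    diag = {}
    if np.any(np.diff(y) < -max(5.0 * noise, 1e-12)):
        diag["non_monotone"] = True
    m = y - a_acid
    n = a_base - y
    if floor is None:
        # keep only points where M and N clear 5% of the amplitude: near
        # the plateaus a small error in an estimated limit dominates the
        # distance and its log ratio
        floor = max(3.0 * noise, 0.05 * amplitude)
    usable = (m > floor) & (n > floor)
    if usable.sum() < 3:
        raise InsufficientDataError("fewer than 3 points with usable M and N")
    fit = stats.linregress(ph[usable], np.log10(m[usable] / n[usable]))
    if fit.slope <= 0:
        raise MethodInapplicableError("log(M/N) does not increase with pH")
    diag.update(
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n_points=int(usable.sum()),
    )
    return PkaEstimate(
        pka=float(-fit.intercept / fit.slope),
        method="baseline_to_peak",
        wavelengths_nm=(float(series.wavelengths_nm[idx]),),
        diagnostics=diag,
    )


# ---------------------------------------------------------------------
# three-point (Seok) closed form


@dataclass(frozen=True)
class SeokInputs:
    """Three (pH, absorbance) points on one dissociation transition,
    read at a single wavelength; pH1 < pH2 < pH3."""

    ph1: float
    ph2: float
    ph3: float
    a1: float
    a2: float
    a3: float

    def __post_init__(self):
        if not (self.ph1 < self.ph2 < self.ph3):
            raise ParameterError("need pH1 < pH2 < pH3")

    @property
    def a(self) -> float:
        """pH2 - pH1."""
        return self.ph2 - self.ph1

    @property
    def b(self) -> float:
        """pH3 - pH1."""
        return self.ph3 - self.ph1


def seok_pka(inputs: SeokInputs, wavelength: float | None = None) -> PkaEstimate:
    """Closed-form pKa from three points on a monoprotic sigmoid.

    Eliminating the unknown limiting absorbances A_HA and A_L from
    A(pH) = (A_HA + A_L*10^(pH-pKa)) / (1 + 10^(pH-pKa)) at the three pH
    values gives 10^(pH1-pKa) as a ratio of two linear combinations of
    A1, A2, A3 with coefficients in 10^a and 10^b:

        K = [(10^b-10^a)A1 + (1-10^b)A2 + (10^a-1)A3]
            / [(10^a-10^b)A1 + (10^(a+b)-10^a)A2 + (10^b-10^(a+b))A3]

        pKa = pH1 - log10(K)

    The expression is invariant to uniform scaling of the absorbances.
    """
    a1, a2, a3 = float(inputs.a1), float(inputs.a2), float(inputs.a3)
    if a1 == a2 == a3:
        raise NoTransitionError("equal absorbances at all three pH: no transition")
    ta = 10.0 ** inputs.a
    tb = 10.0 ** inputs.b
    num = (tb - ta) * a1 + (1.0 - tb) * a2 + (ta - 1.0) * a3
    den = (ta - tb) * a1 + (ta * tb - ta) * a2 + (tb - ta * tb) * a3
    scale = max(abs(a1), abs(a2), abs(a3)) * max(ta, tb)
    if abs(den) < 1e-12 * scale:
        raise IllConditionedError("denominator vanishes for these points")
    k = num / den
    if k <= 0:
        raise IllConditionedError("points are not consistent with one transition")
    return PkaEstimate(
        pka=float(inputs.ph1 - np.log10(k)),
        method="seok",
        wavelengths_nm=() if wavelength is None else (float(wavelength),),
        diagnostics={"k": float(k)},
    )
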