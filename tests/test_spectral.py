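import numpy as np
import pytest
from scipy.optimize import least_squares

from dhbpka import (
    AcidSystem,
    SeokInputs,
    SpeciesSpectrum,
    TitrationSeries,
    baseline_to_peak_pka,
    derivative_spectra,
    find_isosbestic_points,
    intersection_pka,
    seok_pka,
    simulate_titration,
    zero_crossing_pka,
)
from dhbpka.errors import (
    DegenerateSeriesError,
    MethodFailure,
    NoCrossingError,
    NoTransitionError,
    ParameterError,
)
from dhbpka.spectral import select_wavelength_pair


def ideal_hh_trace(pka, a_acid, a_base, ph):
    f = 1.0 / (1.0 + 10.0 ** (pka - np.asarray(ph, float)))
    return a_acid + (a_base - a_acid) * f


def flat_series(value=0.5, n_ph=25):
    lam = np.arange(250.0, 351.0)
    ph = np.linspace(2.0, 14.0, n_ph)
    return TitrationSeries(lam, ph, np.full((lam.size, ph.size), value))


# ---------------------------------------------------------------------


class TestDerivativeSpectra:
    def test_constant_spectrum_first_derivative_is_zero(self):
        d = derivative_spectra(flat_series(), order=1)
        assert np.abs(d.absorbance).max() < 1e-12

    def test_gaussian_band_first_derivative_zero_at_center(self):
        lam = np.arange(250.0, 351.0)
        band = 0.8 * np.exp(-0.5 * ((lam - 300.0) / 10.0) ** 2)
        ts = TitrationSeries(lam, np.array([7.0, 8.0]), np.tile(band, (2, 1)).T)
        d = derivative_spectra(ts, order=1)
        zero = lam[np.argmin(np.abs(d.absorbance[:, 0]))]
        assert abs(zero - 300.0) <= 1.0  # within one grid step

    def test_linear_spectrum_second_derivative_is_zero(self):
        lam = np.arange(250.0, 351.0)
        ts = TitrationSeries(lam, np.array([7.0, 8.0]), np.tile(0.01 * lam, (2, 1)).T)
        d = derivative_spectra(ts, order=2)
        assert np.abs(d.absorbance).max() < 1e-10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"order": 1, "window": 4},  # even window
            {"order": 1, "window": 3, "polyorder": 3},  # window <= polyorder
            {"order": 1, "window": 1001},  # larger than grid
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ParameterError):
            derivative_spectra(flat_series(), **kwargs)


# ---------------------------------------------------------------------


class TestFindIsosbestic:
    def test_constructed_crossing_found_with_tiny_spread(self):
        # bands equal at exactly 300 nm by mirror symmetry
        system = AcidSystem([8.0])
        spectra = [
            SpeciesSpectrum(bands=((290.0, 10.0, 0.5),)),
            SpeciesSpectrum(bands=((310.0, 10.0, 0.5),)),
        ]
        series = simulate_titration(system, spectra)
        points = find_isosbestic_points(series, (2.0, 14.0))
        assert points and points[0][0] == 300.0
        assert points[0][1] < 1e-10

    def test_single_species_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            find_isosbestic_points(flat_series(), (2.0, 14.0))

    def test_pure_noise_yields_empty_list(self):
        rng = np.random.default_rng(5)
        lam = np.arange(250.0, 351.0)
        ph = np.linspace(2.0, 14.0, 49)
        ts = TitrationSeries(lam, ph, rng.normal(0, 0.002, (lam.size, ph.size)))
        assert find_isosbestic_points(ts, (2.0, 14.0)) == []

    def test_requires_three_columns(self):
        with pytest.raises(ParameterError):
            find_isosbestic_points(flat_series(n_ph=2), (2.0, 14.0))


# ---------------------------------------------------------------------


class TestIntersection:
    def test_symmetric_monoprotic_recovers_pka(self, monoprotic_series):
        est = intersection_pka(monoprotic_series, 275.0, 293.0, (2.0, 14.0))
        assert est.pka == pytest.approx(9.0, abs=0.01)
        assert est.method == "isosbestic_intersection"

    def test_identical_wavelengths_cannot_cross(self, monoprotic_series):
        with pytest.raises(NoCrossingError):
            intersection_pka(monoprotic_series, 275.0, 275.0)

    def test_catechol_first_transition(self, catechol_series):
        lam1, lam2, _ = select_wavelength_pair(catechol_series, (2.0, 11.0))
        est = intersection_pka(catechol_series, lam1, lam2, (2.0, 11.0))
        assert est.pka == pytest.approx(8.83, abs=0.02)

    def test_no_crossing_raises(self):
        ph = np.linspace(2.0, 14.0, 25)
        f = 1.0 / (1.0 + 10.0 ** (8.0 - ph))
        a = np.vstack([0.1 + 0.2 * f, 0.5 + 0.2 * f])  # parallel traces
        ts = TitrationSeries(
            np.array([250.0, 251.0]), ph, a
        )
        with pytest.raises(NoCrossingError):
            intersection_pka(ts, 250.0, 251.0)


# ---------------------------------------------------------------------


class TestZeroCrossing:
    def test_monoprotic_distinct_band_centers(self, monoprotic_series):
        d1 = derivative_spectra(monoprotic_series, 1)
        est = zero_crossing_pka(d1, 2.0, 14.0, (2.0, 14.0))
        assert est.pka == pytest.approx(9.0, abs=0.05)
        assert est.method == "zero_crossing"

    def test_identically_zero_derivative_is_degenerate(self):
        d = derivative_spectra(flat_series(), 1)
        with pytest.raises(DegenerateSeriesError):
            zero_crossing_pka(d, 2.0, 14.0)

    def test_catechol_first_transition(self, catechol_series):
        d1 = derivative_spectra(catechol_series, 1)
        est = zero_crossing_pka(d1, 2.0, 11.0, (2.0, 11.0))
        assert est.pka == pytest.approx(8.83, abs=0.05)


# ---------------------------------------------------------------------


class TestBaselineToPeak:
    def test_ideal_sigmoid_exact_pka_and_unit_slope(self):
        ph = np.round(np.arange(0.0, 16.01, 0.25), 10)
        trace = ideal_hh_trace(8.0, 0.1, 0.9, ph)
        ts = TitrationSeries(
            np.array([300.0, 301.0]), ph, np.vstack([trace, trace])
        )
        est = baseline_to_peak_pka(ts, 300.0, a_acid_limit=0.1, a_base_limit=0.9)
        assert est.pka == pytest.approx(8.0, abs=1e-6)
        assert est.diagnostics["slope"] == pytest.approx(1.0, abs=1e-6)

    def test_edge_estimated_limits_still_accurate(self):
        ph = np.round(np.arange(0.0, 16.01, 0.25), 10)
        trace = ideal_hh_trace(8.0, 0.1, 0.9, ph)
        ts = TitrationSeries(np.array([300.0, 301.0]), ph, np.vstack([trace, trace]))
        est = baseline_to_peak_pka(ts, 300.0)
        assert est.pka == pytest.approx(8.0, abs=1e-4)
        assert est.diagnostics["slope"] == pytest.approx(1.0, abs=1e-4)

    def test_no_transition_amplitude_errors(self):
        with pytest.raises(MethodFailure):
            baseline_to_peak_pka(flat_series(), 300.0)

    def test_catechol_first_transition(self, catechol_series):
        est = baseline_to_peak_pka(catechol_series, 287.0, (2.0, 11.0))
        assert est.pka == pytest.approx(8.83, abs=0.05)

    def test_too_few_points(self):
        ph = np.array([7.0, 8.0, 9.0])
        trace = ideal_hh_trace(8.0, 0.1, 0.9, ph)
        ts = TitrationSeries(np.array([300.0, 301.0]), ph, np.vstack([trace, trace]))
        with pytest.raises(MethodFailure):
            baseline_to_peak_pka(ts, 300.0)


# ---------------------------------------------------------------------


def seok_numeric_oracle(inputs: SeokInputs) -> float:
    """Independent route: solve the three-point monoprotic system
    A_i = (A_HA + A_L K_i) / (1 + K_i) numerically for (A_HA, A_L, pKa)."""

    def residuals(p):
        a_ha, a_l, pka = p
        out = []
        for ph, a in [
            (inputs.ph1, inputs.a1),
            (inputs.ph2, inputs.a2),
            (inputs.ph3, inputs.a3),
        ]:
            k = 10.0 ** (ph - pka)
            out.append((a_ha + a_l * k) / (1.0 + k) - a)
        return out

    sol = least_squares(
        residuals, [inputs.a1, inputs.a3, inputs.ph2], method="lm", xtol=1e-15
    )
    return float(sol.x[2])


def seok_points(pka, a_ha, a_l, ph1, ph2, ph3):
    def f(ph):
        k = 10.0 ** (ph - pka)
        return (a_ha + a_l * k) / (1.0 + k)

    return SeokInputs(ph1, ph2, ph3, f(ph1), f(ph2), f(ph3))


class TestSeok:
    def test_three_points_on_known_sigmoid(self):
        inp = seok_points(7.0, 0.1, 0.9, 6.0, 7.0, 8.0)
        est = seok_pka(inp)
        assert est.pka == pytest.approx(7.0, abs=1e-10)
        assert est.pka == pytest.approx(seok_numeric_oracle(inp), abs=1e-8)

    def test_high_pka_transition(self):
        # a third-dissociation-like transition near the top of the range
        inp = seok_points(11.75, 0.2, 1.1, 10.9, 11.7, 12.6)
        est = seok_pka(inp)
        assert est.pka == pytest.approx(11.75, abs=1e-6)

    def test_equal_absorbances_have_no_transition(self):
        with pytest.raises(NoTransitionError):
            seok_pka(SeokInputs(6.0, 7.0, 8.0, 0.5, 0.5, 0.5))

    def test_ph_ordering_enforced(self):
        with pytest.raises(ParameterError):
            SeokInputs(8.0, 7.0, 9.0, 0.1, 0.2, 0.3)

    def test_matches_numeric_oracle_over_many_random_inputs(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            pka = rng.uniform(3.0, 11.0)
            a_ha = rng.uniform(0.0, 0.5)
            a_l = a_ha + rng.uniform(0.2, 1.0)
            ph1 = pka + rng.uniform(-1.5, -0.2)
            ph2 = ph1 + rng.uniform(0.3, 1.5)
            ph3 = ph2 + rng.uniform(0.3, 1.5)
            inp = seok_points(pka, a_ha, a_l, ph1, ph2, ph3)
            worst = max(worst, abs(seok_pka(inp).pka - seok_numeric_oracle(inp)))
        assert worst < 1e-8


# ---------------------------------------------------------------------


class TestScalingInvariance:
    """All estimators are invariant to uniform absorbance scaling."""

    SCALE = 3.7

    def scaled(self, series):
        return TitrationSeries(
            series.wavelengths_nm, series.ph_values, self.SCALE * series.absorbance
        )

    def test_intersection(self, monoprotic_series):
        a = intersection_pka(monoprotic_series, 275.0, 293.0).pka
        b = intersection_pka(self.scaled(monoprotic_series), 275.0, 293.0).pka
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_crossing(self, monoprotic_series):
        a = zero_crossing_pka(derivative_spectra(monoprotic_series, 1), 2.0, 14.0).pka
        b = zero_crossing_pka(
            derivative_spectra(self.scaled(monoprotic_series), 1), 2.0, 14.0
        ).pka
        assert a == pytest.approx(b, abs=1e-10)

    def test_baseline_to_peak(self, monoprotic_series):
        a = baseline_to_peak_pka(monoprotic_series, 293.0).pka
        b = baseline_to_peak_pka(self.scaled(monoprotic_series), 293.0).pka
        assert a == pytest.approx(b, abs=1e-10)

    def test_seok(self):
        inp = seok_points(7.4, 0.1, 0.8, 6.5, 7.3, 8.2)
        scaled = SeokInputs(
            inp.ph1,
            inp.ph2,
            inp.ph3,
            self.SCALE * inp.a1,
            self.SCALE * inp.a2,
            self.SCALE * inp.a3,
        )
        assert seok_pka(inp).pka == pytest.approx(seok_pka(scaled).pka, abs=1e-12)
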