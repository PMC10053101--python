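import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apkin.core_io import (
    DegenerateDataError,
    DomainError,
    DoseResponseTable,
    KineticDataset,
    ThermalSeries,
    UnderDeterminedError,
)
from apkin.kinetic_models import (
    MMParams,
    eval_michaelis_menten,
    fit_exponential,
    fit_michaelis_menten,
    fit_quadratic,
    fit_sigmoid_dose_response,
    michaelis_menten,
    sigmoid_dose_response,
    specific_activity,
    timecourse_slope,
)
from conftest import ols_oracle


class TestEvalMichaelisMenten:
    @pytest.mark.parametrize("s,km,vmax,expected", [
        (100.0, 100.0, 2.0, 1.0),        # half-saturation: v = Vmax/2 at S=Km
        (0.0, 100.0, 2.0, 0.0),
        (2102.0, 2102.0, 0.75, 0.375),   # partitioned-isoform parameter set
    ])
    def test_known_points(self, s, km, vmax, expected):
        p = MMParams(km, vmax)
        assert eval_michaelis_menten(s, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_substrate_rejected(self):
        with pytest.raises(DomainError):
            eval_michaelis_menten(-1.0, MMParams(100.0, 2.0))

    def test_saturates_at_vmax(self):
        p = MMParams(10.0, 3.0)
        assert eval_michaelis_menten(1e12, p) == pytest.approx(3.0, rel=1e-6)


class TestFitMichaelisMenten:
    def test_noise_free_recovery_small_grid(self):
        s = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        ds = KineticDataset.from_arrays(s, michaelis_menten(s, 1.0, 1.0))
        fit = fit_michaelis_menten(ds)
        assert fit.Km == pytest.approx(1.0, rel=1e-6)
        assert fit.Vmax == pytest.approx(1.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery_lysate_scale(self):
        """The 16-level 0–6000 µM design identifies a weak-affinity enzyme
        (Km 4068 µM, Vmax 0.89) exactly from noise-free data."""
        s = np.linspace(0, 6000, 16)
        ds = KineticDataset.from_arrays(s, michaelis_menten(s, 4068.0, 0.89))
        fit = fit_michaelis_menten(ds)
        assert fit.Km == pytest.approx(4068.0, rel=1e-6)
        assert fit.Vmax == pytest.approx(0.89, rel=1e-6)

    def test_all_zero_velocities_degenerate(self):
        ds = KineticDataset.from_arrays([1, 2, 3, 4], [0.0, 0.0, 0.0, 0.0])
        with pytest.raises(DegenerateDataError):
            fit_michaelis_menten(ds)

    def test_too_few_levels(self):
        ds = KineticDataset.from_arrays([1, 2, 3], [0.1, 0.2, 0.3])
        with pytest.raises(UnderDeterminedError):
            fit_michaelis_menten(ds)

    def test_on_means_equals_fit_of_level_means(self):
        rng = np.random.default_rng(3)
        s = np.repeat(np.linspace(0, 800, 10), 3)
        v = michaelis_menten(s, 50.0, 20.0) + rng.normal(0, 1.0, s.size)
        ds = KineticDataset.from_arrays(s, v)
        a = fit_michaelis_menten(ds, on_means=True)
        b = fit_michaelis_menten(ds.level_means())
        assert a.Km == pytest.approx(b.Km, rel=1e-9)
        assert a.Vmax == pytest.approx(b.Vmax, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        km=st.floats(min_value=50.0, max_value=3000.0),
        vmax=st.floats(min_value=0.5, max_value=100.0),
    )
    def test_noise_free_recovery_property(self, km, vmax):
        """gen→fit is the identity (rel. err < 1e-6) whenever Km lies inside
        the substrate range."""
        s = np.linspace(0, 6000, 16)
        ds = KineticDataset.from_arrays(s, michaelis_menten(s, km, vmax))
        fit = fit_michaelis_menten(ds)
        assert fit.Km == pytest.approx(km, rel=1e-6)
        assert fit.Vmax == pytest.approx(vmax, rel=1e-6)


class TestFitSigmoid:
    DOSES = np.array([0.0, 1430.0, 4289.0, 7150.0, 8579.0, 12868.0])
    GEN = dict(Bo=1.98, To=4.95, ED50=4605.0, hill=-0.002)

    def _table(self, **over):
        p = {**self.GEN, **over}
        y = sigmoid_dose_response(self.DOSES, p["Bo"], p["To"], p["ED50"], p["hill"])
        return DoseResponseTable(tuple(self.DOSES), tuple(y))

    def test_noise_free_recovery_to_4_sig_digits(self):
        fit = fit_sigmoid_dose_response(self._table())
        assert fit.Bo == pytest.approx(self.GEN["Bo"], rel=1e-4)
        assert fit.To == pytest.approx(self.GEN["To"], rel=1e-4)
        assert fit.ED50 == pytest.approx(self.GEN["ED50"], rel=1e-4)
        assert fit.hill_slope == pytest.approx(self.GEN["hill"], rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_caption_rescaling_identity(self):
        """Dividing the dose axis by 500 re-expresses the fit with offset
        ED50/500 and an implied Hill slope of −1/500."""
        fit = fit_sigmoid_dose_response(self._table())
        cap = fit.caption_rescaled(500.0)
        assert cap["offset"] == pytest.approx(9.21, abs=0.01)
        assert cap["implied_hill"] == -1.0 / 500.0
        assert cap["bottom"] == pytest.approx(1.98, rel=1e-4)
        assert cap["span"] == pytest.approx(2.97, rel=1e-4)

    def test_constant_response_degenerate(self):
        tab = DoseResponseTable(tuple(self.DOSES), (3.0,) * 6)
        with pytest.raises(DegenerateDataError):
            fit_sigmoid_dose_response(tab)

    def test_too_few_doses(self):
        tab = DoseResponseTable((0.0, 1.0, 2.0, 3.0), (1.0, 2.0, 3.0, 4.0))
        with pytest.raises(UnderDeterminedError):
            fit_sigmoid_dose_response(tab)

    def test_ed50_vs_halfway_crossing_oracle(self):
        """ED50 from a noisy fit agrees with a dense-grid half-way-crossing
        search on the fitted curve within one grid step."""
        rng = np.random.default_rng(11)
        x = np.repeat(self.DOSES, 4)
        y = sigmoid_dose_response(x, **{
            "Bo": self.GEN["Bo"], "To": self.GEN["To"],
            "ED50": self.GEN["ED50"], "hill": self.GEN["hill"]})
        fit = fit_sigmoid_dose_response(
            DoseResponseTable(tuple(x), tuple(y + rng.normal(0, 0.25, x.size))))
        grid = np.linspace(0.0, 12868.0, 20001)
        step = grid[1] - grid[0]
        curve = sigmoid_dose_response(grid, fit.Bo, fit.To, fit.ED50,
                                      fit.hill_slope)
        halfway = (fit.Bo + fit.To) / 2.0
        crossing = grid[np.argmin(np.abs(curve - halfway))]
        assert abs(crossing - fit.ED50) <= step


class TestFitExponential:
    def test_exact_points(self):
        x = np.array([0.0, 10.0, 20.0])
        ts = ThermalSeries(tuple(x), tuple(2.0 * np.exp(0.1 * x)))
        fit = fit_exponential(ts)
        assert fit.J0 == pytest.approx(2.0, rel=1e-8)
        assert fit.b == pytest.approx(0.1, rel=1e-8)

    def test_constant_series_gives_zero_rate(self):
        ts = ThermalSeries((10.0, 20.0, 30.0, 40.0), (5.0,) * 4)
        fit = fit_exponential(ts)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.J0 == pytest.approx(5.0, rel=1e-12)

    def test_decaying_isoform_curve_recovered(self):
        """A falling thermal response (J0 3.014, b −0.0218 per °C over
        22–80 °C) is recovered exactly from noise-free data."""
        x = np.linspace(22, 80, 24)
        ts = ThermalSeries(tuple(x), tuple(3.014 * np.exp(-0.0218 * x)))
        fit = fit_exponential(ts)
        assert fit.J0 == pytest.approx(3.014, rel=1e-8)
        assert fit.b == pytest.approx(-0.0218, rel=1e-8)

    def test_negative_responses_fall_back_to_direct_nls(self):
        x = np.linspace(0, 40, 9)
        y = 2.0 * np.exp(-0.08 * x)
        y[-1] = -0.001  # one below zero: log-space init impossible
        fit = fit_exponential(ThermalSeries(tuple(x), tuple(y)))
        assert fit.b < 0


class TestFitQuadratic:
    def test_exact_coefficients_machine_precision(self):
        x = np.linspace(0, 80, 12)
        y = 1.0 - 0.05 * x + 0.001 * x * x
        fit = fit_quadratic(ThermalSeries(tuple(x), tuple(y)))
        assert fit.c0 == pytest.approx(1.0, abs=1e-9)
        assert fit.c1 == pytest.approx(-0.05, abs=1e-11)
        assert fit.c2 == pytest.approx(0.001, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_host_lysate_curve_recovered(self):
        x = np.linspace(22, 80, 24)
        y = 2.209 - 0.064 * x + 0.0007 * x * x
        fit = fit_quadratic(ThermalSeries(tuple(x), tuple(y)))
        assert fit.c0 == pytest.approx(2.209, rel=1e-9)
        assert fit.c1 == pytest.approx(-0.064, rel=1e-9)
        assert fit.c2 == pytest.approx(0.0007, rel=1e-9)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.linspace(22, 80, 24)
        y = 2.2 - 0.06 * x + 0.0007 * x * x + rng.normal(0, 0.2, x.size)
        fit = fit_quadratic(ThermalSeries(tuple(x), tuple(y)))
        X = np.column_stack([np.ones_like(x), x, x * x])
        beta, se, _, _ = ols_oracle(X, y)
        np.testing.assert_allclose([fit.c0, fit.c1, fit.c2], beta, rtol=1e-12)
        np.testing.assert_allclose([fit.se_c0, fit.se_c1, fit.se_c2], se,
                                   rtol=1e-12)

    def test_under_determined(self):
        with pytest.raises(UnderDeterminedError):
            fit_quadratic(ThermalSeries((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)))


class TestAssayLayer:
    def test_unit_slope_time_course(self):
        fit = timecourse_slope([0, 15, 30, 45], [0, 15, 30, 45])
        assert fit.slope == pytest.approx(1.0, abs=1e-14)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-14)

    def test_constant_product_zero_slope(self):
        fit = timecourse_slope([0, 15, 30, 45], [2.0, 2.0, 2.0, 2.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-14)

    def test_noisy_line_matches_ols_oracle_exactly(self, rng):
        t = np.array([0.0, 15.0, 30.0, 45.0])
        p = 0.8 * t + rng.normal(0, 0.5, t.size)
        fit = timecourse_slope(t, p)
        beta, se, _, _ = ols_oracle(np.column_stack([np.ones_like(t), t]), p)
        assert fit.slope == pytest.approx(beta[1], rel=1e-13)
        assert fit.se == pytest.approx(se[1], rel=1e-13)

    def test_duplicate_times_singular(self):
        with pytest.raises(DegenerateDataError):
            timecourse_slope([0, 0, 0], [1, 2, 3])

    def test_specific_activity_unit_definition(self):
        # 30 nmol pNP in 30 min by 1 mg protein = 1 U/mg
        assert specific_activity(3.0, 0.1, 1.0, 30.0) == pytest.approx(1.0)

    def test_specific_activity_zero_and_scaling(self):
        assert specific_activity(0.0, 0.1, 1.0, 30.0) == 0.0
        one = specific_activity(3.0, 0.1, 1.0, 30.0)
        assert specific_activity(3.0, 0.1, 2.0, 30.0) == pytest.approx(one / 2)

    @pytest.mark.parametrize("protein,minutes", [(0.0, 30.0), (1.0, 0.0)])
    def test_specific_activity_domain(self, protein, minutes):
        with pytest.raises(DomainError):
            specific_activity(1.0, 0.1, protein, minutes)
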