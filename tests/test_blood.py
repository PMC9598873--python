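"""Blood-gas chemistry: Hill curve, contents, and the CO2-curve fit."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from hfmox import (
    BloodConstants,
    CO2FitParams,
    bicarbonate,
    co2_content,
    co2_fit_content,
    co2_fit_slope,
    fit_co2_curve,
    hill_inverse,
    hill_saturation,
    hill_slope,
    o2_content,
    oxyhemoglobin_grams,
    peters_slope_rhs,
    static_fit_params,
)
from hfmox.blood import BloodGasState, o2_content_slope


class TestHillCurve:
    def test_half_saturation_at_p50(self, consts):
        assert hill_saturation(consts.p50, consts) == pytest.approx(0.5, abs=1e-15)

    def test_zero_pressure_zero_saturation(self, consts):
        assert hill_saturation(0.0, consts) == 0.0

    def test_monotone_increasing_and_bounded(self, consts):
        grid = np.linspace(0.0, 500.0, 200)
        sats = [hill_saturation(p, consts) for p in grid]
        assert all(0.0 <= s < 1.0 for s in sats)
        assert all(b > a for a, b in zip(sats, sats[1:]))

    def test_negative_pressure_rejected(self, consts):
        with pytest.raises(ValueError):
            hill_saturation(-1.0, consts)

    def test_inverse_matches_bisection_oracle(self, consts):
        # independent oracle: invert hill_saturation numerically
        po2 = bisect(lambda p: hill_saturation(p, consts) - 0.65, 1e-6, 500.0,
                     xtol=1e-9)
        assert hill_inverse(0.65, consts) == pytest.approx(po2, abs=1e-6)
        assert hill_inverse(0.65, consts) == pytest.approx(36.04, rel=1e-3)

    def test_inverse_at_half_saturation_is_p50(self, consts):
        assert hill_inverse(0.5, consts) == consts.p50

    @pytest.mark.parametrize("so2", [0.1, 0.2, 0.3, 0.5, 0.7, 0.9])
    def test_round_trip(self, so2, consts):
        assert hill_saturation(hill_inverse(so2, consts), consts) == pytest.approx(
            so2, rel=1e-9
        )

    def test_inverse_domain(self, consts):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                hill_inverse(bad, consts)

    @pytest.mark.parametrize("po2", [5.0, 29.0, 36.0, 80.0, 200.0])
    def test_slope_matches_finite_difference(self, po2, consts):
        h = 1e-5 * po2
        fd = (hill_saturation(po2 + h, consts) - hill_saturation(po2 - h, consts)) / (2 * h)
        assert hill_slope(po2, consts) == pytest.approx(fd, rel=1e-6)


class TestO2Content:
    def test_zero_at_zero_pressure(self, consts):
        assert o2_content(0.0, consts) == 0.0

    def test_venous_inlet_value(self, consts):
        # independent evaluation of the two terms: dissolved + Hb-bound
        po2 = 36.03
        dissolved = 3.0e-5 * po2
        x = (po2 / 29.0) ** 2.85
        bound = 1.34 * (12.0 / 100.0) * x / (1 + x)
        assert o2_content(po2, consts) == pytest.approx(dissolved + bound, rel=1e-12)
        assert o2_content(po2, consts) == pytest.approx(0.1056, abs=2e-4)

    @pytest.mark.parametrize("po2", [10.0, 36.0, 100.0])
    def test_slope_matches_finite_difference(self, po2, consts):
        h = 1e-4
        fd = (o2_content(po2 + h, consts) - o2_content(po2 - h, consts)) / (2 * h)
        assert o2_content_slope(po2, consts) == pytest.approx(fd, rel=1e-6)

    def test_monotone(self, consts):
        grid = np.linspace(0, 300, 100)
        vals = [o2_content(p, consts) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestBicarbonate:
    def test_zero(self, consts):
        assert bicarbonate(0.0, consts) == 0.0

    def test_venous_value(self, consts):
        # hand evaluation: 0.0301 * 45 * (1 + 10**1.3), 10**1.3 = 19.9526
        assert bicarbonate(45.0, consts) == pytest.approx(
            0.0301 * 45 * (1 + 10**1.3), rel=1e-12
        )
        assert bicarbonate(45.0, consts) == pytest.approx(28.38, abs=5e-3)

    def test_linear(self, consts):
        assert bicarbonate(90.0, consts) == pytest.approx(
            2 * bicarbonate(45.0, consts), rel=1e-12
        )


class TestCO2Content:
    def test_venous_inlet_value(self, consts):
        # hand pipeline: plasma term 2.226*28.380 = 63.17 mL/dL,
        # correction 1 - 0.02924*12/((2.244-0.422*0.65)*(8.74-7.4)) = 0.86706
        plasma = 2.226 * bicarbonate(45.0, consts)
        corr = 1 - 0.02924 * 12 / ((2.244 - 0.422 * 0.65) * (8.74 - 7.4))
        assert co2_content(45.0, 0.65, consts) == pytest.approx(
            plasma * corr / 100.0, rel=1e-12
        )
        assert co2_content(45.0, 0.65, consts) == pytest.approx(0.5478, abs=2e-4)

    def test_zero_pressure(self, consts):
        assert co2_content(0.0, 0.65, consts) == 0.0

    def test_haldane_direction_endpoints(self, consts):
        assert co2_content(45.0, 1.0, consts) < co2_content(45.0, 0.0, consts)

    def test_haldane_direction_grid(self, consts):
        for pco2 in (20.0, 45.0, 80.0):
            vals = [co2_content(pco2, s, consts) for s in np.linspace(0, 1, 21)]
            assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_increasing_in_pco2(self, consts):
        vals = [co2_content(p, 0.65, consts) for p in np.linspace(5, 90, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_nonphysical_hb_rejected(self, consts):
        hot = dataclasses.replace(consts, hb=90.0)
        with pytest.raises(ValueError, match="nonphysical"):
            co2_content(45.0, 1.0, hot)


class TestPetersRelation:
    def test_intercept_limit(self):
        assert peters_slope_rhs(1e-12) == pytest.approx(6.3, abs=1e-9)

    def test_hb_coefficient_from_o2_capacity(self):
        # 0.334 mL/dL per unit O2 capacity times 1.36 mL O2 per g Hb
        assert 0.334 * 1.36 == pytest.approx(0.4542, abs=5e-5)

    def test_value_at_hb12(self):
        assert peters_slope_rhs(12.0) == pytest.approx(11.7504, rel=1e-12)


class TestCO2CurveFit:
    def test_anchor_reproduction(self, consts):
        c = co2_content(45.0, 0.65, consts)
        fit = fit_co2_curve(45.0, c, consts)
        assert co2_fit_content(45.0, fit) == pytest.approx(c, rel=1e-10)

    def test_fit_at_venous_anchor(self, consts):
        fit = fit_co2_curve(45.0, co2_content(45.0, 0.65, consts), consts)
        assert fit.t == pytest.approx(0.315, abs=1e-3)
        assert fit.q == pytest.approx(0.165, abs=1e-3)

    def test_peters_difference_reproduced(self, consts):
        fit = fit_co2_curve(45.0, co2_content(45.0, 0.65, consts), consts)
        diff_dl = 100 * (co2_fit_content(60.0, fit) - co2_fit_content(30.0, fit))
        assert diff_dl == pytest.approx(peters_slope_rhs(consts.hb), rel=1e-8)

    def test_slope_is_content_times_t_over_p(self, consts):
        fit = fit_co2_curve(45.0, co2_content(45.0, 0.65, consts), consts)
        assert co2_fit_slope(45.0, fit) == pytest.approx(
            co2_fit_content(45.0, fit) * fit.t / 45.0, rel=1e-12
        )
        assert co2_fit_slope(45.0, fit) == pytest.approx(3.83e-3, abs=1e-5)

    @pytest.mark.parametrize("pco2", [20.0, 45.0, 70.0])
    def test_slope_matches_finite_difference(self, pco2, consts):
        fit = fit_co2_curve(45.0, co2_content(45.0, 0.65, consts), consts)
        h = 1e-5 * pco2
        fd = (co2_fit_content(pco2 + h, fit) - co2_fit_content(pco2 - h, fit)) / (2 * h)
        assert co2_fit_slope(pco2, fit) == pytest.approx(fd, rel=1e-6)

    def test_slope_positive_decreasing_for_t_below_1(self, consts):
        fit = fit_co2_curve(45.0, co2_content(45.0, 0.65, consts), consts)
        slopes = [co2_fit_slope(p, fit) for p in np.linspace(10, 80, 30)]
        assert all(s > 0 for s in slopes)
        assert all(b < a for a, b in zip(slopes, slopes[1:]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        pco2=st.floats(min_value=25.0, max_value=70.0),
        so2=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_anchor_consistency_property(self, pco2, so2):
        consts = BloodConstants()
        c = co2_content(pco2, so2, consts)
        fit = fit_co2_curve(pco2, c, consts)
        assert co2_fit_content(pco2, fit) == pytest.approx(c, rel=1e-10)

    def test_invalid_anchor_rejected(self, consts):
        with pytest.raises(ValueError):
            fit_co2_curve(-1.0, 0.5, consts)
        with pytest.raises(ValueError):
            fit_co2_curve(45.0, 0.0, consts)

    def test_fit_params_validation(self):
        with pytest.raises(ValueError):
            CO2FitParams(q=0.1, t=0.3, anchor_pco2=45.0, anchor_cco2=0.9)


class TestStaticFit:
    def test_exponent_solves_peters_at_hb15(self, consts):
        fit = static_fit_params(consts)
        diff_dl = 100 * (co2_fit_content(60.0, fit) - co2_fit_content(30.0, fit))
        assert diff_dl == pytest.approx(0.4542 * 15 + 6.3, rel=1e-8)

    def test_static_anchor_below_haldane_curve(self, consts):
        # fully saturated Hb-15 blood stores less CO2 than 65%-saturated
        # Hb-12 blood at the same partial pressure
        static = static_fit_params(consts)
        haldane_c = co2_content(45.0, 0.65, consts)
        assert co2_fit_content(45.0, static) < haldane_c

    def test_anchor_reproduction(self, consts):
        fit = static_fit_params(consts)
        assert co2_fit_content(fit.anchor_pco2, fit) == pytest.approx(
            fit.anchor_cco2, rel=1e-10
        )


class TestOxyhemoglobin:
    @pytest.mark.parametrize(
        "hb, so2, expected",
        [(15.0, 0.65, 9.8), (12.0, 0.65, 7.8), (10.0, 0.0, 0.0)],
    )
    def test_worked_examples(self, hb, so2, expected):
        got = oxyhemoglobin_grams(hb, so2)
        assert float(f"{got:.2g}") == pytest.approx(expected)


class TestBloodGasState:
    def test_from_pressures_consistency(self, consts):
        st_ = BloodGasState.from_pressures(45.0, 36.03, consts)
        assert st_.so2 == hill_saturation(36.03, consts)
        assert st_.c_o2 == o2_content(36.03, consts)
        assert st_.c_co2 == co2_content(45.0, st_.so2, consts)


class TestConstantsValidation:
    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            BloodConstants(hb=-1.0)

    def test_ph_window(self):
        with pytest.raises(ValueError):
            BloodConstants(ph=9.0)
        with pytest.raises(ValueError):
            BloodConstants(ph=6.0)
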