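import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srpkpd.doseresponse import (
    GREATER_THAN_RANGE,
    Curve4PL,
    DoseResponse,
    FourParamLogisticModel,
    fit_4pl,
    fold_ratio,
    interpolate_ic50,
    surviving_fraction,
)
from srpkpd.kill import monolayer_survival_curve
from srpkpd.monolayer import MonolayerSetup
from srpkpd.params import cp506_cell_lines


def _serial_dilution(top_uM=30.0, n=9):
    """1:3 serial dilution series, highest first."""
    return top_uM / 3.0 ** np.arange(n)


def test_exact_4pl_data_recovered():
    truth = Curve4PL(bottom=0.0, top=1.0, ec50=10.0, hill=1.0)
    x = _serial_dilution(300.0, 10)
    data = DoseResponse(x, truth(x))
    fit = fit_4pl(data)
    assert fit.ec50 == pytest.approx(10.0, abs=1e-5)
    assert fit.hill == pytest.approx(1.0, abs=1e-6)
    assert fit.bottom == pytest.approx(0.0, abs=1e-6)
    assert fit.top == pytest.approx(1.0, abs=1e-6)
    assert truth(10.0) == pytest.approx(0.5)


@pytest.mark.parametrize(
    "curve, expected",
    [
        (Curve4PL(0.0, 1.0, 10.0, 1.0), 10.0),
        # 0.4 + 0.6/(1+(x/10)^2) = 0.5  ->  x = 10*sqrt(5)
        (Curve4PL(0.4, 1.0, 10.0, 2.0), 10.0 * np.sqrt(5.0)),
    ],
)
def test_ic50_interpolates_at_half_of_control(curve, expected):
    assert interpolate_ic50(curve) == pytest.approx(expected, rel=1e-9)


def test_non_crossing_curve_returns_above_range_sentinel():
    assert interpolate_ic50(Curve4PL(0.6, 1.0, 10.0, 1.0)) == GREATER_THAN_RANGE


def test_fit_then_interpolate_reproduces_analytic_crossing():
    truth = Curve4PL(bottom=0.1, top=1.0, ec50=4.0, hill=1.7)
    x = _serial_dilution(100.0, 10)
    fit = fit_4pl(DoseResponse(x, truth(x)))
    assert interpolate_ic50(fit) == pytest.approx(interpolate_ic50(truth), rel=1e-3)


def test_flat_response_raises_nonconvergence():
    x = _serial_dilution(30.0, 6)
    with pytest.raises(RuntimeError):
        fit_4pl(DoseResponse(x, np.full_like(x, 0.98)))


def test_too_few_concentrations_rejected():
    with pytest.raises(ValueError):
        FourParamLogisticModel(DoseResponse([1.0, 3.0, 9.0], [1.0, 0.6, 0.2]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(min_value=0.1, max_value=10.0))
def test_ic50_scale_equivariance(alpha):
    curve = Curve4PL(0.05, 1.0, 7.0, 1.3)
    scaled = Curve4PL(0.05, 1.0, 7.0 * alpha, 1.3)
    assert interpolate_ic50(scaled) == pytest.approx(
        alpha * interpolate_ic50(curve), rel=1e-9
    )


def test_kill_model_curve_ic50_matches_direct_crossing(lines):
    """4PL interpolation on a model-generated clonogenic curve agrees with
    the model's own 50% crossing (bisection on SF = exp(-lambda C0))."""
    setup = MonolayerSetup(oxygen_uM=0.0)
    from srpkpd.params import cp506_chain

    chain = cp506_chain()
    line = lines["target"]
    x = _serial_dilution(3.0, 9)
    sf = monolayer_survival_curve(x, setup, chain, line)
    # direct crossing: SF = exp(-lam*C0) = 0.5
    lam = -np.log(sf[0]) / x[0]
    direct = np.log(2.0) / lam
    fit = fit_4pl(DoseResponse(x, sf))
    assert interpolate_ic50(fit) == pytest.approx(direct, rel=0.10)


@pytest.mark.parametrize(
    "treated, control, plated_t, plated_c, expected",
    [
        (50, 100, 1000, 1000, 0.5),
        (100, 100, 1000, 1000, 1.0),
        (20, 400, 10000, 1000, 0.005),
    ],
)
def test_surviving_fraction_ratio_of_plating_efficiencies(
    treated, control, plated_t, plated_c, expected
):
    assert surviving_fraction(treated, control, plated_t, plated_c) == pytest.approx(
        expected
    )


def test_surviving_fraction_zero_control_undefined():
    with pytest.raises(ZeroDivisionError):
        surviving_fraction(10, 0, 1000)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (257.0, 12.8, 20.1),  # aerobic/anoxic wild-type IC50s
        (240.0, 33.1, 7.25),
        (5.0, 5.0, 1.0),
    ],
)
def test_fold_ratio_three_significant_figures(a, b, expected):
    assert fold_ratio(a, b) == pytest.approx(expected, abs=1e-9)


def test_fold_ratio_requires_positive_denominator():
    with pytest.raises(ValueError):
        fold_ratio(1.0, 0.0)
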