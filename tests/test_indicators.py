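"""Indicator formulas against independent term-by-term oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from milkres.curves import fit_quantile_curve
from milkres.indicators import (
    DeviationSeries,
    adjusted_skewness,
    assemble_phenotypes,
    compute_deviations,
    four_sd_edit,
    lag1_autocorrelation,
    ln_variance,
    raw_variance,
)

# ---------------------------------------------------------------------------
# brute-force oracles: plain-Python term-by-term summation, no numpy


def oracle_lnvar(xs):
    n = len(xs)
    m = sum(xs) / n
    ss = sum((x - m) ** 2 for x in xs)
    v = ss / (n - 1)
    return math.log(v) if v > 0 else math.nan


def oracle_rauto(xs):
    n = len(xs)
    m = sum(xs) / n
    num = sum((xs[i] - m) * (xs[i + 1] - m) for i in range(n - 1))
    den = sum((x - m) ** 2 for x in xs)
    return num / den if den > 0 else math.nan


def oracle_skew(xs):
    n = len(xs)
    m = sum(xs) / n
    v = sum((x - m) ** 2 for x in xs) / (n - 1)
    if v <= 0:
        return math.nan
    s = math.sqrt(v)
    return n / ((n - 1) * (n - 2)) * sum(((x - m) / s) ** 3 for x in xs)


# ---------------------------------------------------------------------------
# frozen hand-computed examples


@pytest.mark.parametrize(
    "func, series, expected",
    [
        (ln_variance, [1, -1, 1, -1], math.log(4 / 3)),          # SS=4, n-1=3
        (lag1_autocorrelation, [1, -1, 1, -1], -0.75),           # num -3, den 4
        (lag1_autocorrelation, [1, 2, 3, 4, 5], 0.40),           # num 4, den 10
        (adjusted_skewness, [1, 2, 3, 4, 10], 1.6970562748477142),
        (adjusted_skewness, [-2, -1, 0, 1, 2], 0.0),             # symmetric
        (raw_variance, [9, 11, 9, 11], math.log(4 / 3)),
    ],
)
def test_frozen_examples(func, series, expected):
    assert func(series) == pytest.approx(expected, abs=1e-12)


def test_oracle_equivalence_random_series(rng):
    """Implementation agrees with brute-force oracles to 1e-10 on 100
    random series of varying length."""
    for _ in range(100):
        n = int(rng.integers(4, 60))
        xs = rng.normal(size=n) * rng.uniform(0.1, 10)
        xl = xs.tolist()
        assert ln_variance(xs) == pytest.approx(oracle_lnvar(xl), abs=1e-10)
        assert lag1_autocorrelation(xs) == pytest.approx(oracle_rauto(xl), abs=1e-10)
        assert adjusted_skewness(xs) == pytest.approx(oracle_skew(xl), abs=1e-10)


def test_invariances(rng):
    xs = rng.normal(size=30)
    k = 3.7
    # LnVar shift law: scaling by k adds exactly 2 ln k
    assert ln_variance(k * xs) == pytest.approx(ln_variance(xs) + 2 * math.log(k), abs=1e-12)
    # autocorrelation invariant to affine transforms
    assert lag1_autocorrelation(2.5 * xs - 4) == pytest.approx(
        lag1_autocorrelation(xs), abs=1e-12
    )
    # skewness: scale-invariant, odd under negation
    assert adjusted_skewness(2.5 * xs + 1) == pytest.approx(adjusted_skewness(xs), abs=1e-12)
    assert adjusted_skewness(-xs) == pytest.approx(-adjusted_skewness(xs), abs=1e-12)


@given(st.lists(st.floats(-50, 50), min_size=3, max_size=40))
@settings(derandomize=True, max_examples=60)
def test_rauto_bounded(xs):
    r = lag1_autocorrelation(xs)
    assert math.isnan(r) or -1.0 - 1e-9 <= r <= 1.0 + 1e-9


@pytest.mark.parametrize("func", [ln_variance, lag1_autocorrelation, adjusted_skewness])
def test_degenerate_inputs_are_missing(func):
    assert math.isnan(func([4.2] * 10))   # zero variance
    assert math.isnan(func([1.0]))        # too few points


def test_deviation_worked_examples():
    """3 kg above an expectation of 5 kg is 60%; above 20 kg only 15%."""

    class Flat:
        def __init__(self, e):
            self.e = e
            self.animal_id = 1

        def predict(self, dim):
            return np.full(len(np.atleast_1d(dim)), self.e, dtype=float)

    rec = pd.DataFrame({"animal_id": 1, "dim": [10], "yield_kg": [8.0]})
    ds = compute_deviations(rec, Flat(5.0))
    assert ds.actual[0] == pytest.approx(3.0)
    assert ds.standardized[0] == pytest.approx(0.60)

    rec = pd.DataFrame({"animal_id": 1, "dim": [10], "yield_kg": [23.0]})
    ds = compute_deviations(rec, Flat(20.0))
    assert ds.actual[0] == pytest.approx(3.0)
    assert ds.standardized[0] == pytest.approx(0.15)


def test_zero_deviations_when_curve_interpolates(rng):
    dims = np.arange(1, 200, 14)
    t = dims / 400
    y = 12 + 6 * t - 9 * t**2
    rec = pd.DataFrame({"animal_id": 7, "dim": dims, "yield_kg": y})
    fit = fit_quantile_curve(rec, tau=0.7)
    ds = compute_deviations(rec, fit)
    np.testing.assert_allclose(ds.actual, 0.0, atol=1e-6)
    np.testing.assert_allclose(ds.standardized, 0.0, atol=1e-7)


def test_flat_curve_identities(rng):
    """With a constant expected yield E: rauto1 = rauto2, skew1 = skew2,
    and lnvar2 = lnvar1 − 2 ln E exactly."""
    E = 8.0
    obs = E + rng.normal(size=25)
    actual = obs - E
    std = actual / E
    assert lag1_autocorrelation(actual) == pytest.approx(lag1_autocorrelation(std), abs=1e-12)
    assert adjusted_skewness(actual) == pytest.approx(adjusted_skewness(std), abs=1e-12)
    assert ln_variance(std) == pytest.approx(ln_variance(actual) - 2 * math.log(E), abs=1e-12)


def test_rawvar_equals_lnvar_of_actual_devs_for_constant_curve(rng):
    yields = 10 + rng.normal(size=20)
    devs = yields - yields.mean()
    assert raw_variance(yields) == pytest.approx(ln_variance(devs), abs=1e-12)


# ---------------------------------------------------------------------------
# phenotype assembly and the 4-SD edit


def test_assemble_dim_classes_and_missingness():
    dims = np.array([3, 50, 120, 200, 395])
    ds = DeviationSeries(1, dims, np.zeros(5), np.zeros(5))  # zero variance
    rec = pd.DataFrame({"animal_id": 1, "dim": dims, "yield_kg": 10.0})
    pheno = assemble_phenotypes({1: ds}, rec)
    row = pheno.iloc[0]
    assert row["dim_first_class"] == 1 and row["dim_last_class"] == 10
    assert row["n_obs"] == 5 and row["amy"] == pytest.approx(10.0)
    # zero-variance indicators are missing, row retained
    assert math.isnan(row["lnvar1"]) and math.isnan(row["rauto2"])
    assert math.isnan(row["rawvar"])


def test_four_sd_edit_gross_outlier():
    col = pd.Series([0.0] * 19 + [100.0])
    edited, n = four_sd_edit(col)
    assert n == 1 and math.isnan(edited.iloc[-1])
    assert edited.iloc[:19].notna().all()


def test_four_sd_edit_all_equal_and_gaussian(rng):
    col = pd.Series([5.0] * 50)
    edited, n = four_sd_edit(col)
    assert n == 0 and edited.notna().all()
    col = pd.Series(rng.normal(size=10_000))
    _, n = four_sd_edit(col)
    assert n <= 5  # expected count 2·Φ(−4)·n ≈ 0.6
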