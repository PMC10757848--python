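"""Resilience indicators computed from deviations of observed milk yield
around a cow's fitted lactation curve.

Two deviation series are formed per cow: the *actual* deviation
(observed − expected, in kg) and the *standardized* deviation
((observed − expected)/expected, unitless).  From each series three
indicators are computed — natural-log variance (LnVar), lag-1
autocorrelation (r_auto) and adjusted Fisher–Pearson skewness (Skew) —
giving LnVar1/r_auto1/Skew1 (actual) and LnVar2/r_auto2/Skew2
(standardized).  RawVar is the log variance of the raw test-day yields
themselves, and AMY the arithmetic mean of the yields.  Lower LnVar and
r_auto and higher (less negative) Skew indicate greater resilience to
milk-depressing disturbances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DeviationSeries",
    "compute_deviations",
    "ln_variance",
    "lag1_autocorrelation",
    "adjusted_skewness",
    "raw_variance",
    "assemble_phenotypes",
    "four_sd_edit",
    "INDICATOR_COLUMNS",
]

INDICATOR_COLUMNS = ["lnvar1", "lnvar2", "rauto1", "rauto2", "skew1", "skew2", "rawvar"]


@dataclass
class DeviationSeries:
    """Aligned actual and standardized deviations for one cow, in DIM order."""

    animal_id: int
    dim: np.ndarray
    actual: np.ndarray        # kg
    standardized: np.ndarray  # unitless

    def __post_init__(self):
        self.dim = np.asarray(self.dim)
        if np.any(np.diff(self.dim) <= 0):
            raise ValueError("DIM values must be strictly increasing")


def compute_deviations(records_for_cow: pd.DataFrame, fit) -> DeviationSeries:
    """Deviation series of one cow around its fitted curve.

    ``records_for_cow`` needs columns ``dim`` and ``yield_kg``; ``fit`` is
    a :class:`~milkres.curves.LactationCurveFit`.  Expected yields are
    clamped positive upstream, so the standardized series is well defined.
    """
    rec = records_for_cow.sort_values("dim")
    dim = rec["dim"].to_numpy()
    obs = rec["yield_kg"].to_numpy(dtype=float)
    exp = fit.predict(dim)
    actual = obs - exp
    return DeviationSeries(
        animal_id=fit.animal_id, dim=dim, actual=actual, standardized=actual / exp
    )


def _sample_variance(x: np.ndarray) -> float:
    """(n−1)-denominator sample variance; NaN-free input assumed."""
    n = len(x)
    if n < 2:
        return math.nan
    xb = x.mean()
    return float(np.sum((x - xb) ** 2) / (n - 1))


def _degenerate(v: float, x: np.ndarray) -> bool:
    """Zero variance up to floating-point noise (constant series)."""
    if not math.isfinite(v):
        return True
    scale = max(1.0, float(np.max(np.abs(x))))
    return v <= (1e-10 * scale) ** 2


def ln_variance(devs) -> float:
    """Natural log of the sample variance of a deviation series.

    Returns NaN (missing) when n < 2 or the variance is zero (up to
    floating-point noise), where the log is undefined.
    """
    x = np.asarray(devs, dtype=float)
    v = _sample_variance(x)
    if _degenerate(v, x):
        return math.nan
    return math.log(v)


def lag1_autocorrelation(devs) -> float:
    """Lag-1 autocorrelation: consecutive cross-products over the full
    sum of squares, both about the series mean.  NaN when n < 3 or the
    variance is zero.  Invariant to affine transforms of the series."""
    x = np.asarray(devs, dtype=float)
    n = len(x)
    if n < 3:
        return math.nan
    c = x - x.mean()
    den = float(np.sum(c * c))
    if _degenerate(den / (n - 1), x):
        return math.nan
    num = float(np.sum(c[:-1] * c[1:]))
    return num / den


def adjusted_skewness(devs) -> float:
    """Adjusted Fisher–Pearson skewness:
    n/((n−1)(n−2)) · Σ((x − x̄)/s)³ with s the (n−1)-denominator sample
    standard deviation.  NaN when n < 3 or the variance is zero."""
    x = np.asarray(devs, dtype=float)
    n = len(x)
    if n < 3:
        return math.nan
    v = _sample_variance(x)
    if _degenerate(v, x):
        return math.nan
    s = math.sqrt(v)
    return n / ((n - 1) * (n - 2)) * float(np.sum(((x - x.mean()) / s) ** 3))


def raw_variance(yields) -> float:
    """Log sample variance of the raw test-day yields (RawVar)."""
    return ln_variance(yields)


def _dim_class(dim: int) -> int:
    """10 equal 40-day classes over DIM 1–400 (1–40 → 1, …, 361–400 → 10)."""
    return min(int(math.ceil(dim / 40.0)), 10)


def assemble_phenotypes(
    deviation_series: dict[int, DeviationSeries],
    records: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per cow with the seven indicators, AMY and model covariates.

    Parameters
    ----------
    deviation_series
        Mapping animal_id → :class:`DeviationSeries`.
    records
        Edited test-day records (``animal_id``, ``dim``, ``yield_kg``).
    meta
        Optional cow metadata; if given, its covariate columns
        (breed_group, env, ys, afc_months, …) are merged onto the result.

    A cow with an undefined indicator (zero variance, too few points)
    keeps its row with that field missing (NaN).
    """
    rows = []
    grouped = records.groupby("animal_id")
    for animal_id, ds in deviation_series.items():
        rec = grouped.get_group(animal_id)
        yields = rec.sort_values("dim")["yield_kg"].to_numpy(dtype=float)
        rows.append(
            {
                "animal_id": animal_id,
                "lnvar1": ln_variance(ds.actual),
                "lnvar2": ln_variance(ds.standardized),
                "rauto1": lag1_autocorrelation(ds.actual),
                "rauto2": lag1_autocorrelation(ds.standardized),
                "skew1": adjusted_skewness(ds.actual),
                "skew2": adjusted_skewness(ds.standardized),
                "rawvar": raw_variance(yields),
                "amy": float(yields.mean()),
                "n_obs": len(ds.dim),
                "dim_first_class": _dim_class(int(ds.dim[0])),
                "dim_last_class": _dim_class(int(ds.dim[-1])),
            }
        )
    pheno = pd.DataFrame(rows)
    if meta is not None and len(pheno):
        keep = [
            c
            for c in ("animal_id", "breed_group", "env", "ys", "ys_excluded", "afc_months")
            if c in meta.columns
        ]
        pheno = pheno.merge(meta[keep], on="animal_id", how="left")
    return pheno


def four_sd_edit(column: pd.Series) -> tuple[pd.Series, int]:
    """Set values deviating more than 4 SD from the column mean to missing.

    A single, non-iterative pass: mean and SD come from the pre-edit
    column.  Returns the edited column and the number of values removed.
    An all-equal column (SD = 0) is returned untouched.
    """
    x = column.astype(float)
    valid = x.dropna()
    if len(valid) < 2:
        return x, 0
    mu = valid.mean()
    sd = valid.std(ddof=1)
    if sd == 0.0:
        return x, 0
    mask = (x - mu).abs() > 4.0 * sd
    out = x.mask(mask)
    return out, int(mask.sum())
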