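"""Per-cow lactation curves by fourth-order polynomial quantile regression.

The expected milk yield of a cow at day-in-milk t is modeled as a quartic
in t fitted at an upper quantile (default τ = 0.7) of the conditional
yield distribution.  Fitting above the median makes transient yield
drops — the disturbance signal the resilience indicators quantify —
pull the curve down far less than high yields pull it up, so the curve
approximates the undisturbed production potential.

The check-loss minimization  min_β Σ ρ_τ(y_t − x_tᵀβ),
ρ_τ(u) = u·(τ − 1[u<0]), is solved exactly as a linear program
(HiGHS dual simplex), which is robust on degenerate inputs such as
noise-free records that the curve interpolates exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = ["LactationCurveFit", "CurveFitError", "fit_quantile_curve", "predict_expected_yield"]

#: DIM is divided by this scale before powers are taken, to control the
#: conditioning of the quartic basis (t/400 ∈ (0, 1]).
DIM_SCALE = 400.0

#: floor for predicted yields; standardized deviations divide by the
#: expectation, so it must stay strictly positive
YIELD_FLOOR = 0.01

DEGREE = 4


class CurveFitError(ValueError):
    """Raised for rank-deficient or non-convergent per-cow fits."""


def _basis(dim: np.ndarray) -> np.ndarray:
    t = np.asarray(dim, dtype=float) / DIM_SCALE
    return np.vander(t, DEGREE + 1, increasing=True)


@dataclass
class LactationCurveFit:
    """Quartic quantile-regression fit for one cow.

    ``beta`` are the five coefficients on the scaled basis
    (1, t/400, (t/400)², …); predictions are the contract, the
    coefficients are solver-dependent under LP ties.
    """

    animal_id: int
    tau: float
    beta: np.ndarray
    n_obs: int
    check_loss: float
    converged: bool
    dim_scale: float = DIM_SCALE
    dim_min: float = 1.0
    dim_max: float = 400.0
    clamped: bool = field(default=False)

    def predict(self, dim) -> np.ndarray:
        """Expected yield (kg) at the given DIM, floored at 0.01 kg."""
        scalar = np.isscalar(dim)
        raw = _basis(np.atleast_1d(dim)) @ self.beta
        if np.any(raw < YIELD_FLOOR):
            self.clamped = True
        out = np.maximum(raw, YIELD_FLOOR)
        return float(out[0]) if scalar else out


def fit_quantile_curve(
    records_for_cow: pd.DataFrame, tau: float = 0.7, animal_id: int | None = None
) -> LactationCurveFit:
    """Fit the quartic quantile-regression lactation curve for one cow.

    Parameters
    ----------
    records_for_cow
        Frame with ``dim`` and ``yield_kg`` columns (≥10 records after
        editing; ≥5 distinct DIM values required for identifiability).
    tau
        Quantile level in (0, 1); 0.7 by default, 0.6 is the documented
        alternative.

    Raises
    ------
    CurveFitError
        If fewer than 5 distinct DIM values are present (rank-deficient
        quartic), naming the cow.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if animal_id is None:
        animal_id = int(records_for_cow["animal_id"].iloc[0]) if "animal_id" in records_for_cow else -1
    rec = records_for_cow.sort_values("dim")
    dim = rec["dim"].to_numpy(dtype=float)
    y = rec["yield_kg"].to_numpy(dtype=float)
    n = len(y)
    if len(np.unique(dim)) < DEGREE + 1:
        raise CurveFitError(
            f"cow {animal_id}: only {len(np.unique(dim))} distinct DIM values; "
            f"{DEGREE + 1} needed for a quartic fit"
        )
    X = _basis(dim)
    p = X.shape[1]
    # LP variables: [beta+ (p), beta- (p), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    converged = bool(res.status == 0)
    if not converged:
        beta = np.full(p, np.nan)
        loss = math.nan
        warnings.warn(f"cow {animal_id}: quantile LP did not converge ({res.message})")
    else:
        z = res.x
        beta = z[:p] - z[p : 2 * p]
        resid = y - X @ beta
        loss = float(np.sum(resid * (tau - (resid < 0))))
    return LactationCurveFit(
        animal_id=animal_id,
        tau=tau,
        beta=beta,
        n_obs=n,
        check_loss=loss,
        converged=converged,
        dim_min=float(dim.min()),
        dim_max=float(dim.max()),
    )


def predict_expected_yield(fit: LactationCurveFit, dim) -> np.ndarray:
    """Expected yield at ``dim`` (kg), clamped at 0.01 kg.

    Warns (never errors) when predicting outside the DIM range the
    curve was fitted on (extrapolation).
    """
    d = np.atleast_1d(dim)
    if np.any((d < fit.dim_min) | (d > fit.dim_max)):
        warnings.warn(
            f"cow {fit.animal_id}: predicting outside fitted DIM range "
            f"[{fit.dim_min:.0f}, {fit.dim_max:.0f}] (extrapolation)"
        )
    return fit.predict(dim)


def fit_all_curves(
    records: pd.DataFrame, tau: float = 0.7
) -> tuple[dict[int, LactationCurveFit], list[int]]:
    """Fit every cow in an edited record table.

    Returns (fits by animal_id, list of animal_ids excluded for
    rank-deficiency or non-convergence).
    """
    fits: dict[int, LactationCurveFit] = {}
    excluded: list[int] = []
    for animal_id, grp in records.groupby("animal_id"):
        try:
            fit = fit_quantile_curve(grp, tau=tau, animal_id=int(animal_id))
        except CurveFitError:
            excluded.append(int(animal_id))
            continue
        if not fit.converged:
            excluded.append(int(animal_id))
            continue
        fits[int(animal_id)] = fit
    return fits, excluded
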