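"""Fixed-effect linear models and least-squares means for the
resilience indicators.

The model per indicator is ordinary least squares on breed group,
environment, their interaction, year-season of calving, age at first
calving (factor), number of records (continuous) and first/last DIM
class.  Least-squares means for a factor average the prediction
uniformly over the levels of every other factor (continuous covariates
at their mean) — the standard LSM convention — and pairwise t-tests at
α = 0.05 are summarized as a compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as scipy_qr

__all__ = ["FixedEffectsFit", "LsmTable", "fit_fixed_model", "lsmeans"]

DEFAULT_FACTORS = ["breed_group", "env", "ys", "afc_months", "dim_first_class", "dim_last_class"]
DEFAULT_INTERACTIONS = [("breed_group", "env")]
DEFAULT_COVARIATES = ["n_obs"]


@dataclass
class FixedEffectsFit:
    """An OLS fit with enough encoding metadata to form LSM contrasts.

    ``columns`` maps each design column to its (term, level) origin so a
    prediction row with uniform factor weights can be built exactly.
    """

    result: sm.regression.linear_model.RegressionResultsWrapper
    indicator: str
    factors: list[str]
    interactions: list[tuple[str, str]]
    covariates: list[str]
    levels: dict[str, list]
    covariate_means: dict[str, float]
    columns: list[tuple]          # (kind, term, level-or-None)
    kept: np.ndarray              # indices of non-aliased columns
    dropped_terms: list = field(default_factory=list)
    n_by_level: dict = field(default_factory=dict)


def _encode(
    df: pd.DataFrame,
    factors: list[str],
    interactions: list[tuple[str, str]],
    covariates: list[str],
) -> tuple[np.ndarray, list[tuple], dict, dict]:
    """Full-dummy encoding (no reference level dropped; rank handled by
    pivoted QR downstream so LSMs are invariant to the parameterization)."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[tuple] = [("intercept", None, None)]
    levels: dict[str, list] = {}
    for f in factors:
        lv = sorted(df[f].dropna().unique().tolist())
        levels[f] = lv
        for l in lv:
            cols.append((df[f] == l).to_numpy(dtype=float))
            names.append(("factor", f, l))
    for fa, fb in interactions:
        for la in levels[fa]:
            for lb in levels[fb]:
                cols.append(((df[fa] == la) & (df[fb] == lb)).to_numpy(dtype=float))
                names.append(("interaction", (fa, fb), (la, lb)))
    means: dict[str, float] = {}
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        means[c] = float(x.mean())
        cols.append(x)
        names.append(("covariate", c, None))
    return np.column_stack(cols), names, levels, means


def fit_fixed_model(
    phenotypes: pd.DataFrame,
    indicator: str,
    factors: list[str] | None = None,
    interactions: list[tuple[str, str]] | None = None,
    covariates: list[str] | None = None,
) -> FixedEffectsFit:
    """OLS fit of one indicator on the stated fixed effects.

    Aliased (linearly dependent) columns are detected by pivoted QR and
    dropped deterministically (first-listed columns kept); factors that
    collapse to a single level are reported in ``dropped_terms``.

    Raises
    ------
    ValueError
        If no residual degrees of freedom remain (saturated design).
    """
    factors = [f for f in (factors or DEFAULT_FACTORS) if f in phenotypes.columns]
    interactions = [
        (a, b) for a, b in (interactions if interactions is not None else DEFAULT_INTERACTIONS)
        if a in factors and b in factors
    ]
    covariates = [c for c in (covariates or DEFAULT_COVARIATES) if c in phenotypes.columns]
    df = phenotypes.dropna(subset=[indicator] + factors + covariates).reset_index(drop=True)

    dropped = []
    live_factors = []
    for f in factors:
        if df[f].nunique() < 2:
            dropped.append(f)
        else:
            live_factors.append(f)
    interactions = [(a, b) for a, b in interactions if a in live_factors and b in live_factors]

    X, names, levels, means = _encode(df, live_factors, interactions, covariates)
    # pivoted QR to find a deterministic full-rank column subset
    q, r, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if len(diag) else 1.0)
    rank = int((diag > tol).sum())
    kept = np.sort(piv[:rank])
    y = df[indicator].to_numpy(dtype=float)
    if len(y) - rank <= 0:
        raise ValueError(f"{indicator}: saturated design (n={len(y)}, rank={rank})")
    result = sm.OLS(y, X[:, kept]).fit()

    n_by_level = {
        f: df.groupby(f, observed=True).size().to_dict() for f in live_factors
    }
    return FixedEffectsFit(
        result=result,
        indicator=indicator,
        factors=live_factors,
        interactions=interactions,
        covariates=covariates,
        levels=levels,
        covariate_means=means,
        columns=names,
        kept=kept,
        dropped_terms=dropped,
        n_by_level=n_by_level,
    )


def _lsm_row(fit: FixedEffectsFit, factor: str, level) -> np.ndarray:
    """Design row for (factor = level), uniform over other factors'
    levels and covariates at their means."""
    row = np.zeros(len(fit.columns))
    for j, (kind, term, lv) in enumerate(fit.columns):
        if kind == "intercept":
            row[j] = 1.0
        elif kind == "factor":
            if term == factor:
                row[j] = 1.0 if lv == level else 0.0
            else:
                row[j] = 1.0 / len(fit.levels[term])
        elif kind == "interaction":
            fa, fb = term
            la, lb = lv
            pa = (1.0 if la == level else 0.0) if fa == factor else 1.0 / len(fit.levels[fa])
            pb = (1.0 if lb == level else 0.0) if fb == factor else 1.0 / len(fit.levels[fb])
            row[j] = pa * pb
        elif kind == "covariate":
            row[j] = fit.covariate_means[term]
    return row[fit.kept]


@dataclass
class LsmTable:
    """Least-squares means with pairwise significance letters."""

    factor: str
    table: pd.DataFrame           # level, n, lsm, se, letters
    pairwise_p: pd.DataFrame      # level x level matrix of p-values

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"LSM of {self.factor}\n{self.table.to_string(index=False)}"


def _compact_letters(levels: list, pmat: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from the maximal cliques of the
    non-significance graph (nodes = levels, edge iff p ≥ α).

    One letter per maximal clique guarantees that two levels share a
    letter exactly when their pairwise difference is not significant.
    Factor-level counts here are small, so Bron–Kerbosch enumeration is
    exact and cheap.
    """
    adj = {
        l: {m for m in levels if m != l and pmat.loc[l, m] >= alpha} for l in levels
    }
    cliques: list[set] = []

    def bron_kerbosch(r: set, p: set, x: set):
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(levels), set())
    # deterministic letter order: cliques sorted by first level position
    pos = {l: i for i, l in enumerate(levels)}
    cliques.sort(key=lambda g: sorted(pos[l] for l in g))
    letters = {l: "" for l in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for l in levels:
            if l in g:
                letters[l] += letter
    return letters


def lsmeans(fit: FixedEffectsFit, factor: str, alpha: float = 0.05) -> LsmTable:
    """Least-squares means of one factor with SEs and letter groups.

    LSM_l = x_lᵀ β̂ with x_l averaging uniformly over other factors;
    SE by the linear-combination variance x_lᵀ Cov(β̂) x_l; pairwise
    t-tests (unadjusted) on LSM differences feed the letter display.
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in fitted model {fit.factors}")
    levels = fit.levels[factor]
    beta = fit.result.params
    cov = fit.result.cov_params()
    dfres = int(fit.result.df_resid)
    rows = {l: _lsm_row(fit, factor, l) for l in levels}
    lsm = {l: float(rows[l] @ beta) for l in levels}
    se = {l: float(np.sqrt(rows[l] @ cov @ rows[l])) for l in levels}
    pmat = pd.DataFrame(1.0, index=levels, columns=levels)
    for a, b in itertools.combinations(levels, 2):
        d = rows[a] - rows[b]
        sd = float(np.sqrt(d @ cov @ d))
        t = (lsm[a] - lsm[b]) / sd if sd > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), dfres)
        pmat.loc[a, b] = pmat.loc[b, a] = p
    letters = _compact_letters(levels, pmat, alpha)
    table = pd.DataFrame(
        {
            "level": levels,
            "n": [fit.n_by_level.get(factor, {}).get(l, 0) for l in levels],
            "lsm": [lsm[l] for l in levels],
            "se": [se[l] for l in levels],
            "letters": [letters[l] for l in levels],
        }
    )
    return LsmTable(factor=factor, table=table, pairwise_p=pmat)
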