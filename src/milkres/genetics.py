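"""High-level genetic analyses of the resilience phenotypes.

Builds fixed-effect design matrices from the phenotype table, prunes
the pedigree to phenotyped animals plus their ancestors, constructs the
numerator relationship matrix, and runs univariate / bivariate animal
model REML.  Also derives the two longevity traits.

Fixed effects for the indicator traits: breed group, environment,
year-season of calving, age at first calving (factor), number of
records (continuous) and first/last DIM class.  Longevity models use
breed group, environment, year-season of birth and of exit, lactation
count, exit code, AMY (covariate) and — for productive lifespan only —
age at first calving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editing import assign_season, DEFAULT_SEASON_CALENDAR
from .pedigree import Pedigree, build_A
from .reml import (
    BivariateComponents,
    UnivariateREML,
    VarianceComponents,
    gcv,
    reml_bivariate,
)

__all__ = [
    "INDICATOR_FIXED_EFFECTS",
    "ELIGIBLE_EXIT_CODES",
    "build_design",
    "longevity_traits",
    "UnivariateResult",
    "univariate_analysis",
    "bivariate_analysis",
]

INDICATOR_FIXED_EFFECTS = {
    "factors": ["breed_group", "env", "ys", "afc_months", "dim_first_class", "dim_last_class"],
    "covariates": ["n_obs"],
}

#: exit reasons eligible for the longevity analyses
ELIGIBLE_EXIT_CODES = ("died-disease", "slaughter")

#: log-scale traits whose GCV is √σ²a without division by the mean
LOG_SCALE_TRAITS = ("lnvar1", "lnvar2", "rawvar")


def build_design(
    df: pd.DataFrame,
    factors: list[str],
    covariates: list[str] | None = None,
    add_intercept: bool = True,
) -> np.ndarray:
    """Dummy-coded design matrix (full dummies; rank deficiency is
    handled downstream by projection, so no reference level is
    dropped here)."""
    cols = [np.ones((len(df), 1))] if add_intercept else []
    for f in factors:
        d = pd.get_dummies(df[f].astype("category"), drop_first=True)
        if d.shape[1]:
            cols.append(d.to_numpy(dtype=float))
    for c in covariates or []:
        cols.append(df[c].to_numpy(dtype=float)[:, None])
    return np.hstack(cols) if cols else np.ones((len(df), 1))


def longevity_traits(
    meta: pd.DataFrame, eligible_codes=ELIGIBLE_EXIT_CODES
) -> pd.DataFrame:
    """Productive lifespan and herd life per cow with an eligible exit.

    PLS = days from first calving to exit; HL = days from birth to
    exit.  Cows without an exit date or with an ineligible exit reason
    (e.g. sold for breeding) are excluded.
    """
    m = meta.dropna(subset=["exit_date"])
    m = m[m["exit_code"].isin(eligible_codes)]
    exit_d = pd.to_datetime(m["exit_date"])
    calving = pd.to_datetime(m["first_calving_date"])
    birth = pd.to_datetime(m["birth_date"])
    return pd.DataFrame(
        {
            "animal_id": m["animal_id"].to_numpy(),
            "pls_days": (exit_d - calving).dt.days.to_numpy(),
            "hl_days": (exit_d - birth).dt.days.to_numpy(),
            "exit_code": m["exit_code"].to_numpy(),
        }
    )


@dataclass
class UnivariateResult:
    """Variance components plus trait-level summaries for one indicator."""

    trait: str
    components: VarianceComponents
    gcv: float
    mean: float
    n: int

    def as_dict(self) -> dict:
        c = self.components
        return {
            "trait": self.trait,
            "n": self.n,
            "sigma2_a": c.sigma2_a,
            "sigma2_e": c.sigma2_e,
            "sigma2_p": c.sigma2_p,
            "h2": c.h2,
            "se_h2": c.se_h2,
            "gcv": self.gcv,
            "logl": c.logl,
            "lrt_p": c.lrt_p(),
            "boundary": c.boundary,
        }


def _complete_rows(pheno: pd.DataFrame, trait: str, factors, covariates) -> pd.DataFrame:
    need = [trait] + [f for f in factors if f in pheno.columns] + list(covariates)
    df = pheno.dropna(subset=[c for c in need if c in pheno.columns])
    if "ys_excluded" in df.columns:
        df = df[~df["ys_excluded"].astype(bool)]
    return df


def _relationship_for(ped: Pedigree, animals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A over the pruned pedigree and record→row index for ``animals``."""
    pruned = ped.prune_to(animals.tolist())
    A = build_A(pruned)
    idx = pruned.index_of(animals.tolist())
    return A, idx


def univariate_analysis(
    pheno: pd.DataFrame,
    ped: Pedigree,
    trait: str,
    factors: list[str] | None = None,
    covariates: list[str] | None = None,
) -> UnivariateResult:
    """Univariate animal-model REML for one indicator trait.

    Rows with a missing trait value (after the 4-SD edit) or in an
    excluded year-season group are dropped; the pedigree is pruned to
    the analyzed cows plus their ancestors.
    """
    if factors is None:
        factors = [f for f in INDICATOR_FIXED_EFFECTS["factors"] if f in pheno.columns]
    if covariates is None:
        covariates = [c for c in INDICATOR_FIXED_EFFECTS["covariates"] if c in pheno.columns]
    df = _complete_rows(pheno, trait, factors, covariates)
    if len(df) < 20:
        raise ValueError(f"{trait}: only {len(df)} usable records")
    y = df[trait].to_numpy(dtype=float)
    X = build_design(df, factors, covariates)
    A, idx = _relationship_for(ped, df["animal_id"].to_numpy())
    K = A[np.ix_(idx, idx)]
    comps = UnivariateREML(X, K).fit(y)
    mu = float(y.mean())
    g = gcv(comps.sigma2_a, mean=mu, log_scale=trait in LOG_SCALE_TRAITS) \
        if (trait in LOG_SCALE_TRAITS or mu != 0) else math.nan
    return UnivariateResult(trait=trait, components=comps, gcv=g, mean=mu, n=len(df))


def bivariate_analysis(
    pheno: pd.DataFrame,
    ped: Pedigree,
    trait1: str,
    trait2: str,
    factors: list[str] | None = None,
    covariates: list[str] | None = None,
    fix_rg_zero: bool = False,
) -> BivariateComponents:
    """Bivariate animal-model REML between two columns of the phenotype
    table (two indicators, or an indicator and a longevity trait merged
    onto it).  Non-identical cow sets are supported; when the two traits
    are measured on the same cows the fast path applies.
    """
    if factors is None:
        factors = [f for f in INDICATOR_FIXED_EFFECTS["factors"] if f in pheno.columns]
    if covariates is None:
        covariates = [c for c in INDICATOR_FIXED_EFFECTS["covariates"] if c in pheno.columns]
    d1 = _complete_rows(pheno, trait1, factors, covariates)
    d2 = _complete_rows(pheno, trait2, factors, covariates)
    animals = np.unique(np.concatenate([d1["animal_id"], d2["animal_id"]]))
    pruned = ped.prune_to(animals.tolist())
    A = build_A(pruned)
    idx1 = pruned.index_of(d1["animal_id"].tolist())
    idx2 = pruned.index_of(d2["animal_id"].tolist())
    X1 = build_design(d1, factors, covariates)
    X2 = build_design(d2, factors, covariates)
    return reml_bivariate(
        d1[trait1].to_numpy(float),
        d2[trait2].to_numpy(float),
        X1,
        X2,
        A,
        idx1,
        idx2,
        fix_rg_zero=fix_rg_zero,
    )
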