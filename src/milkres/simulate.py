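"""Synthetic pedigreed dairy herds with test-day milk records,
disturbance episodes and longevity outcomes.

The generator emulates the statistical structure of low-input tropical
dairy herds: three agroecological zones with four climatic seasons
each, crossbred cows classified by taurine fraction, first-parity
lactations recorded at a fixed test-day interval over at most 400 days,
low production levels (template peak ~12 kg), episodic milk-depressing
disturbances with exponential recovery, and cow-level genetic variation
in resilience, yield level and longevity.

Genetic control of resilience enters as a multiplier exp(u/2) on both
the residual coefficient of variation and the disturbance depth, where
u is the cow's latent resilience value (breeding value + permanent
environment).  The log-variance of a cow's deviations is then u plus a
constant plus within-cow sampling noise, so the heritability of LnVar
is the configured target by construction; the within-cow sampling
variance is calibrated by a short internal Monte Carlo rather than
assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import fit_quantile_curve
from .editing import DEFAULT_SEASON_CALENDAR, assign_breed_group
from .indicators import ln_variance
from .pedigree import Pedigree, inbreeding_coefficients

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "SimulatedHerd",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_lactations",
    "simulate_longevity",
    "simulate_herd",
]

#: discrete crossbred grades and their frequencies (zebu crosses through
#: near-pure taurine), chosen to mirror the study's breed-group census
BREED_FRACTION_LEVELS = (0.25, 0.5, 0.625, 0.75, 0.875, 0.9375, 1.0)
BREED_FRACTION_PROBS = (0.15, 0.20, 0.08, 0.07, 0.07, 0.20, 0.23)


@dataclass
class LactationTemplate:
    """Wilmink-type baseline curve a + b·exp(−kt) + c·t.

    Parameterized by interpretable knobs: peak yield (kg), time to peak
    (days) and persistency (post-peak slope, kg/day, negative).
    """

    peak_yield: float = 12.0
    time_to_peak: float = 50.0
    persistency: float = -0.012
    wilmink_k: float = 0.05

    def coefficients(self) -> tuple[float, float, float]:
        k = self.wilmink_k
        tp = self.time_to_peak
        c = self.persistency
        b = c / (k * math.exp(-k * tp))  # f'(tp) = 0
        a = self.peak_yield - b * math.exp(-k * tp) - c * tp
        return a, b, c

    def __call__(self, dim) -> np.ndarray:
        a, b, c = self.coefficients()
        t = np.asarray(dim, dtype=float)
        return a + b * np.exp(-self.wilmink_k * t) + c * t


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic herd.

    Heritability and genetic-correlation targets refer to the latent
    traits: ``lnvar`` (deviation log-variance; higher = less resilient),
    ``amy`` (log yield-level multiplier) and ``longevity`` (productive
    lifespan, days).
    """

    n_base_animals: int = 100
    n_cows: int = 500
    seed: int = 0
    environments: tuple[str, ...] = ("SAA", "SAP", "SH")
    season_calendar: dict = field(default_factory=lambda: DEFAULT_SEASON_CALENDAR)
    breed_fraction_levels: tuple[float, ...] = BREED_FRACTION_LEVELS
    breed_fraction_probs: tuple[float, ...] = BREED_FRACTION_PROBS
    lactation_template: LactationTemplate = field(default_factory=LactationTemplate)
    h2_targets: dict = field(
        default_factory=lambda: {"lnvar": 0.2, "amy": 0.43, "longevity": 0.12}
    )
    rg_targets: dict = field(default_factory=lambda: {("lnvar", "longevity"): -0.45})
    phenotypic_variances: dict = field(
        default_factory=lambda: {"lnvar": 0.45, "amy": 0.10, "longevity": 90000.0}
    )
    disturbance_rate: float = 1.0      # episodes per 100 days
    disturbance_depth: float = 0.3     # fractional yield drop at onset
    recovery_halflife: float = 10.0    # days
    residual_cv: float = 0.15          # baseline multiplicative noise
    test_day_interval: int = 14        # days between test days
    record_span: int = 400             # max DIM recorded
    min_span: int = 200                # shortest simulated lactation
    calving_year_range: tuple[int, int] = (2005, 2015)
    afc_range_months: tuple[int, int] = (22, 50)
    pls_mean_days: float = 1000.0
    exit_rate: float = 0.45            # fraction of cows with an exit record
    env_yield_multipliers: dict = field(
        default_factory=lambda: {"SAA": 1.0, "SAP": 0.9, "SH": 1.1}
    )
    tau: float = 0.7                   # quantile used in calibration fits

    def validate(self) -> None:
        if self.n_base_animals < 2:
            raise ValueError("need at least 2 base animals (one sire, one dam)")
        if self.n_cows < 1:
            raise ValueError("need at least 1 cow")
        for t, h2 in self.h2_targets.items():
            if not 0.0 <= h2 < 1.0:
                raise ValueError(f"h2 target for {t} must be in [0,1), got {h2}")
        for pair, rg in self.rg_targets.items():
            if not -1.0 <= rg <= 1.0:
                raise ValueError(f"rg target for {pair} outside [-1,1]")
        if not 0 < self.record_span <= 400:
            raise ValueError("record_span must be in (0, 400]")
        if self.test_day_interval < 1:
            raise ValueError("test_day_interval must be >= 1 day")
        if not 0.0 <= self.disturbance_depth < 1.0:
            raise ValueError("disturbance_depth must be in [0,1)")
        if abs(sum(self.breed_fraction_probs) - 1.0) > 1e-9:
            raise ValueError("breed fraction probabilities must sum to 1")


@dataclass
class TrueValues:
    """Ground truth carried through the simulation for recovery tests."""

    breeding_values: pd.DataFrame           # animal_id x trait
    permanent_env: pd.DataFrame | None = None  # cow_id x trait (non-genetic)
    merit_multiplier: dict = field(default_factory=dict)  # cow -> baseline scale
    episodes: dict = field(default_factory=dict)  # cow -> [(start, depth, halflife)]


@dataclass
class SimulatedHerd:
    """Bundle returned by :func:`simulate_herd`."""

    pedigree: Pedigree
    records: pd.DataFrame
    meta: pd.DataFrame
    longevity: pd.DataFrame
    true_values: TrueValues
    config: SimulationConfig


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, np.ndarray]:
    """Founder sires/dams plus one generation of recorded cows.

    Founders (ids 1..n_base) have unknown parents; the first half are
    sires, the second half dams.  Each cow draws a random sire and dam,
    giving paternal half-sib families that carry the additive signal.
    Returns the pedigree and the array of cow ids.
    """
    config.validate()
    rng = _rng(config.seed)
    n_base = config.n_base_animals
    n_sires = max(1, n_base // 2)
    sires = np.arange(1, n_sires + 1)
    dams = np.arange(n_sires + 1, n_base + 1)
    if len(dams) == 0:
        raise ValueError("no dams available: increase n_base_animals")
    cows = np.arange(n_base + 1, n_base + config.n_cows + 1)
    animal = np.concatenate([sires, dams, cows])
    sire_col = np.concatenate(
        [np.zeros(n_base, dtype=np.int64), rng.choice(sires, size=config.n_cows)]
    )
    dam_col = np.concatenate(
        [np.zeros(n_base, dtype=np.int64), rng.choice(dams, size=config.n_cows)]
    )
    return Pedigree(animal, sire_col, dam_col), cows


def _genetic_covariance(
    traits: list[str], h2_targets: dict, rg_targets: dict, phenotypic_variances: dict
) -> np.ndarray:
    k = len(traits)
    G = np.zeros((k, k))
    for i, t in enumerate(traits):
        G[i, i] = h2_targets[t] * phenotypic_variances[t]
    for (t1, t2), rg in rg_targets.items():
        if t1 not in traits or t2 not in traits:
            continue
        i, j = traits.index(t1), traits.index(t2)
        G[i, j] = G[j, i] = rg * math.sqrt(G[i, i] * G[j, j])
    ev = np.linalg.eigvalsh(G)
    if ev.min() < -1e-10 * max(1.0, ev.max()):
        raise ValueError(
            f"genetic covariance implied by rg targets {rg_targets} is not "
            f"positive semi-definite (min eigenvalue {ev.min():.3g})"
        )
    return G


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Square-root factor tolerant of exactly-zero variances (h² = 0)."""
    d, U = np.linalg.eigh((G + G.T) / 2.0)
    d = np.clip(d, 0.0, None)
    return U @ np.diag(np.sqrt(d))


def simulate_breeding_values(
    ped: Pedigree,
    h2_targets: dict,
    rg_targets: dict,
    phenotypic_variances: dict,
    seed: int = 0,
) -> TrueValues:
    """Multivariate breeding values over a pedigree.

    Founders draw a ~ N(0, G); descendants use the mendelian-sampling
    recursion a = ½(a_sire + a_dam) + m with
    m ~ N(0, ½(1 − ½(F_s + F_d))·G), so the implied covariance is
    A ⊗ G without ever factoring the dense A.  A trait with h² = 0 gets
    exactly-zero breeding values.
    """
    traits = sorted(h2_targets)
    G = _genetic_covariance(traits, h2_targets, rg_targets, phenotypic_variances)
    L = _psd_factor(G)
    rng = _rng(seed)
    n = len(ped)
    k = len(traits)
    F = inbreeding_coefficients(ped)
    idx = ped._index
    bv = np.zeros((n, k))
    for i in range(n):
        s = idx.get(int(ped.sire[i]), -1)
        d = idx.get(int(ped.dam[i]), -1)
        z = rng.standard_normal(k)
        if s < 0 and d < 0:
            bv[i] = L @ z
        else:
            pa = np.zeros(k)
            seg = 0.0
            if s >= 0:
                pa += 0.5 * bv[s]
                seg += 0.25 * (1.0 + F[s])
            else:
                seg += 0.25  # unknown parent treated as unrelated founder
            if d >= 0:
                pa += 0.5 * bv[d]
                seg += 0.25 * (1.0 + F[d])
            else:
                seg += 0.25
            # Var(m) = (1 − 0.25(1+F_s) − 0.25(1+F_d)) G = 0.5(1 − F̄) G
            mvar = max(0.0, 1.0 - seg)
            bv[i] = pa + math.sqrt(mvar) * (L @ z)
    frame = pd.DataFrame(bv, columns=traits)
    frame.insert(0, "animal_id", ped.animal)
    return TrueValues(breeding_values=frame)


def assign_cow_metadata(
    config: SimulationConfig, cow_ids: np.ndarray, seed: int = 1
) -> pd.DataFrame:
    """Environment, breed fraction, calving/birth dates per cow."""
    rng = _rng(seed)
    n = len(cow_ids)
    env = rng.choice(list(config.environments), size=n)
    frac = rng.choice(config.breed_fraction_levels, size=n, p=config.breed_fraction_probs)
    y0, y1 = config.calving_year_range
    calving = pd.to_datetime(f"{y0}-01-01") + pd.to_timedelta(
        rng.integers(0, (y1 - y0 + 1) * 365, size=n), unit="D"
    )
    afc = rng.integers(config.afc_range_months[0], config.afc_range_months[1] + 1, size=n)
    birth = calving - pd.to_timedelta((afc * 30.44).astype(int), unit="D")
    return pd.DataFrame(
        {
            "animal_id": cow_ids,
            "birth_date": birth.normalize(),
            "first_calving_date": calving.normalize(),
            "afc_months": afc,
            "taurine_fraction": frac,
            "breed_group": [assign_breed_group(f) for f in frac],
            "env": env,
            "exit_date": pd.NaT,
            "exit_code": pd.NA,
            "n_lactations": 1,
        }
    )


def _episode_multiplier(dim: np.ndarray, episodes) -> np.ndarray:
    """Π over episodes of (1 − depth·2^(−(t−start)/halflife)) for t ≥ start."""
    mult = np.ones_like(dim, dtype=float)
    for start, depth, halflife in episodes:
        active = dim >= start
        if halflife <= 0:
            decay = (dim == start).astype(float)
        else:
            decay = np.where(active, 2.0 ** (-(dim - start) / halflife), 0.0)
        mult *= 1.0 - depth * decay
    return np.clip(mult, 0.0, None)


def _lnvar_sampling_variance(config: SimulationConfig, seed: int, n_rep: int = 150) -> float:
    """Within-cow sampling variance of LnVar2 at u = 0, by Monte Carlo.

    Simulates the full within-cow process (episodes, residual, quantile
    fit at the configured τ, standardized-deviation log variance) for a
    reference cow and returns the variance of LnVar2 across replicates.
    """
    rng = _rng(seed)
    template = config.lactation_template
    dims = np.arange(1, config.record_span + 1, config.test_day_interval)
    vals = []
    for _ in range(n_rep):
        base = template(dims)
        n_ep = rng.poisson(config.disturbance_rate / 100.0 * config.record_span)
        episodes = [
            (rng.uniform(1, config.record_span), config.disturbance_depth,
             config.recovery_halflife)
            for _ in range(n_ep)
        ]
        mult = _episode_multiplier(dims, episodes)
        sd = config.residual_cv
        y = base * mult * np.exp(sd * rng.standard_normal(len(dims)) - 0.5 * sd**2)
        y = np.clip(y, 0.01, 45.0)
        rec = pd.DataFrame({"dim": dims, "yield_kg": y})
        try:
            fit = fit_quantile_curve(rec, tau=config.tau, animal_id=0)
        except Exception:
            continue
        exp = fit.predict(dims)
        v = ln_variance((y - exp) / exp)
        if math.isfinite(v):
            vals.append(v)
    if len(vals) < 10:
        return 0.0
    return float(np.var(vals, ddof=1))


def simulate_lactations(
    ped: Pedigree,
    true_values: TrueValues,
    config: SimulationConfig,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, TrueValues]:
    """Test-day records for every cow in ``meta``.

    yield(t) = baseline(t; merit) × Π_episodes(1 − depth·2^(−(t−start)/h))
               × lognormal residual, truncated to (0, 45] kg.

    The cow's latent resilience u (breeding value + permanent
    environment) scales both residual CV and episode depth by
    exp(u/2): genetically resilient cows have smaller, shorter-lived
    deviations.  Episodes are recorded into ``true_values.episodes``.
    """
    config.validate()
    rng = _rng(config.seed + 1)
    bv = true_values.breeding_values.set_index("animal_id")
    template = config.lactation_template

    # permanent-environment variances: remainder of the phenotypic target
    # after genetics and (for lnvar) the calibrated sampling variance
    s_cal = _lnvar_sampling_variance(config, seed=config.seed + 2) if "lnvar" in bv else 0.0
    pe_var: dict[str, float] = {}
    for t in ("lnvar", "amy"):
        if t not in bv.columns:
            continue
        sp2 = config.phenotypic_variances[t]
        sa2 = config.h2_targets[t] * sp2
        rest = sp2 - sa2 - (s_cal if t == "lnvar" else 0.0)
        if rest < 0:
            import warnings

            warnings.warn(
                f"{t}: sampling variance {s_cal:.3f} exceeds the non-genetic "
                "budget; permanent-environment variance clamped to 0"
            )
            rest = 0.0
        pe_var[t] = rest

    rows = []
    pe_rows = []
    episodes_out: dict[int, list] = {}
    merit: dict[int, float] = {}
    for row in meta.itertuples(index=False):
        cow = int(row.animal_id)
        a_ln = float(bv.loc[cow, "lnvar"]) if "lnvar" in bv.columns else 0.0
        a_my = float(bv.loc[cow, "amy"]) if "amy" in bv.columns else 0.0
        p_ln = math.sqrt(pe_var.get("lnvar", 0.0)) * rng.standard_normal()
        p_my = math.sqrt(pe_var.get("amy", 0.0)) * rng.standard_normal()
        u = a_ln + p_ln       # latent resilience (higher = noisier cow)
        v = a_my + p_my       # latent log yield level
        pe_rows.append({"animal_id": cow, "lnvar": p_ln, "amy": p_my})

        span = int(rng.integers(min(config.min_span, config.record_span),
                                config.record_span + 1))
        dims = np.arange(1, span + 1, config.test_day_interval)
        mult_env = config.env_yield_multipliers.get(row.env, 1.0)
        mult_breed = 0.7 + 0.6 * float(row.taurine_fraction)
        m = mult_env * mult_breed * math.exp(v)
        merit[cow] = m
        base = m * template(dims)

        n_ep = rng.poisson(config.disturbance_rate / 100.0 * span)
        depth_scale = math.exp(0.5 * u)
        eps = []
        for _ in range(n_ep):
            start = float(rng.uniform(1, span))
            depth = min(0.95, config.disturbance_depth * depth_scale
                        * math.exp(0.25 * rng.standard_normal()))
            eps.append((start, depth, config.recovery_halflife))
        episodes_out[cow] = eps

        sd = config.residual_cv * math.exp(0.5 * u)
        noise = (
            np.exp(sd * rng.standard_normal(len(dims)) - 0.5 * sd**2)
            if sd > 0
            else np.ones(len(dims))
        )
        y = base * _episode_multiplier(dims, eps) * noise
        y = np.clip(y, 0.01, 45.0)
        calving = pd.Timestamp(row.first_calving_date)
        for d, yk in zip(dims, y):
            rows.append(
                {
                    "animal_id": cow,
                    "dim": int(d),
                    "yield_kg": float(yk),
                    "test_date": (calving + pd.Timedelta(days=int(d))).date().isoformat(),
                    "env": row.env,
                }
            )
    records = pd.DataFrame(rows)
    tv = replace(
        true_values,
        permanent_env=pd.DataFrame(pe_rows),
        merit_multiplier=merit,
        episodes=episodes_out,
    )
    return records, tv


def simulate_longevity(
    ped: Pedigree,
    true_values: TrueValues,
    config: SimulationConfig,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exit dates, exit codes and longevity outcomes.

    Productive lifespan (days from first calving to exit) is the
    configured mean plus the latent longevity value (breeding value +
    normal environment), floored at 1 day.  A fraction ``exit_rate`` of
    cows receives an eligible exit record (death from disease or
    disposal for slaughter); the rest remain censored with no exit.
    Returns (longevity table, meta updated with exit columns).
    """
    rng = _rng(config.seed + 3)
    bv = true_values.breeding_values.set_index("animal_id")
    meta = meta.copy()
    rows = []
    sp2 = config.phenotypic_variances.get("longevity", 0.0)
    h2 = config.h2_targets.get("longevity", 0.0)
    e_sd = math.sqrt(max(0.0, sp2 * (1.0 - h2)))
    for row in meta.itertuples():
        cow = int(row.animal_id)
        if rng.uniform() >= config.exit_rate:
            continue
        a_l = float(bv.loc[cow, "longevity"]) if "longevity" in bv.columns else 0.0
        pls = max(1, int(round(config.pls_mean_days + a_l + e_sd * rng.standard_normal())))
        calving = pd.Timestamp(row.first_calving_date)
        birth = pd.Timestamp(row.birth_date)
        exit_date = calving + pd.Timedelta(days=pls)
        code = "died-disease" if rng.uniform() < 0.5 else "slaughter"
        n_lact = max(1, int(pls // 400) + 1)
        meta.loc[row.Index, "exit_date"] = exit_date
        meta.loc[row.Index, "exit_code"] = code
        meta.loc[row.Index, "n_lactations"] = n_lact
        rows.append(
            {
                "animal_id": cow,
                "exit_date": exit_date.date().isoformat(),
                "exit_code": code,
                "pls_days": pls,
                "hl_days": int((exit_date - birth).days),
                "n_lactations": n_lact,
            }
        )
    cols = ["animal_id", "exit_date", "exit_code", "pls_days", "hl_days", "n_lactations"]
    longevity = pd.DataFrame(rows, columns=cols)
    return longevity, meta


def simulate_herd(config: SimulationConfig) -> SimulatedHerd:
    """Run the full generator: pedigree → breeding values → metadata →
    lactations → longevity."""
    config.validate()
    ped, cows = simulate_pedigree(config)
    tv = simulate_breeding_values(
        ped,
        config.h2_targets,
        config.rg_targets,
        config.phenotypic_variances,
        seed=config.seed + 10,
    )
    meta = assign_cow_metadata(config, cows, seed=config.seed + 20)
    records, tv = simulate_lactations(ped, tv, config, meta)
    longevity, meta = simulate_longevity(ped, tv, config, meta)
    return SimulatedHerd(
        pedigree=ped,
        records=records,
        meta=meta,
        longevity=longevity,
        true_values=tv,
        config=config,
    )
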