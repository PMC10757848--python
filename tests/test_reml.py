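"""Animal-model REML: closed-form limits, recovery, LRT, GCV, Fisher z."""

import math

import numpy as np
import pytest

from milkres.pedigree import Pedigree, build_A
from milkres.reml import (
    BivariateREML,
    UnivariateREML,
    fisher_r_to_z,
    gcv,
    lrt_variance,
    reml_bivariate,
)
from milkres.simulate import SimulationConfig, simulate_breeding_values, simulate_pedigree


def half_sib_setup(n_cows=400, n_base=60, seed=4):
    cfg = SimulationConfig(n_base_animals=n_base, n_cows=n_cows, seed=seed)
    ped, cows = simulate_pedigree(cfg)
    A = build_A(ped)
    idx = ped.index_of(cows.tolist())
    K = A[np.ix_(idx, idx)]
    X = np.ones((n_cows, 1))
    return ped, cows, K, X


def simulate_trait(ped, cows, h2, n_reps, seed, sp2=1.0):
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        tv = simulate_breeding_values(ped, {"t": h2}, {}, {"t": sp2}, seed=seed + rep)
        a = tv.breeding_values.set_index("animal_id").loc[cows, "t"].to_numpy()
        e = math.sqrt(sp2 * (1 - h2)) * rng.standard_normal(len(cows))
        yield 3.0 + a + e


def test_identity_A_recovers_anova_residual_ms(rng):
    """With A = I (all founders) and a balanced one-way design under
    σ²a = 0, the REML residual variance in the no-genetics restriction
    equals the ANOVA residual mean square."""
    n, g = 120, 4
    groups = np.repeat(np.arange(g), n // g)
    X = np.zeros((n, g))
    X[np.arange(n), groups] = 1.0
    y = 2.0 + 0.5 * groups + rng.standard_normal(n)
    solver = UnivariateREML(X, np.eye(n))
    w = solver.T @ y
    s2e0 = float(np.sum(w * w)) / solver.df
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    anova_ms = float(resid @ resid) / (n - g)
    assert s2e0 == pytest.approx(anova_ms, rel=1e-10)


def test_null_trait_estimates_near_zero():
    ped, cows, K, X = half_sib_setup()
    solver = UnivariateREML(X, K)
    h2s = [solver.fit(y).h2 for y in simulate_trait(ped, cows, 0.0, 10, seed=100)]
    assert np.mean(h2s) < 0.06


def test_single_replicate_recovery_within_3se():
    ped, cows, K, X = half_sib_setup(n_cows=800, n_base=80)
    solver = UnivariateREML(X, K)
    y = next(simulate_trait(ped, cows, 0.35, 1, seed=7))
    fit = solver.fit(y)
    assert fit.h2 == pytest.approx(0.35, abs=3 * fit.se_h2)
    assert fit.sigma2_p == pytest.approx(1.0, rel=0.25)


def test_logl_invariant_to_reparameterization():
    """The restricted likelihood is a function of (σ²a, σ²e) only;
    evaluating through (σ²p, h²) round-trips to 1e-8."""
    ped, cows, K, X = half_sib_setup(n_cows=200, n_base=40)
    solver = UnivariateREML(X, K)
    y = next(simulate_trait(ped, cows, 0.3, 1, seed=3))
    w = solver.T @ y
    s2a, s2e = 0.31, 0.72
    s2p, h2 = s2a + s2e, s2a / (s2a + s2e)
    assert solver._logl(w, s2a, s2e) == pytest.approx(
        solver._logl(w, s2p * h2, s2p * (1 - h2)), abs=1e-8
    )


def test_se_shrinks_with_sample_size():
    ses = []
    for n in (250, 1000):
        ped, cows, K, X = half_sib_setup(n_cows=n, n_base=max(40, n // 10), seed=5)
        solver = UnivariateREML(X, K)
        fits = [solver.fit(y) for y in simulate_trait(ped, cows, 0.3, 3, seed=50)]
        ses.append(np.mean([f.se_h2 for f in fits]))
    ratio = ses[0] / ses[1]
    assert 1.3 < ratio < 3.2  # ~2 expected for a 4x sample increase


# ---------------------------------------------------------------------------
# bivariate


def test_duplicated_trait_gives_rg_near_one():
    ped, cows, K, X = half_sib_setup(n_cows=300, n_base=40)
    solver = BivariateREML(X, K)
    y = next(simulate_trait(ped, cows, 0.4, 1, seed=21))
    res = solver.fit(y, y.copy())
    assert res.rg > 0.98
    assert res.rp > 0.99
    assert res.boundary


def test_null_genetic_covariance_centered_on_zero():
    ped, cows, K, X = half_sib_setup(n_cows=400, n_base=60)
    solver = BivariateREML(X, K)
    rng = np.random.default_rng(31)
    rgs = []
    for rep in range(6):
        tv = simulate_breeding_values(
            ped, {"a": 0.3, "b": 0.3}, {("a", "b"): 0.0}, {"a": 1.0, "b": 1.0},
            seed=300 + rep,
        )
        bv = tv.breeding_values.set_index("animal_id").loc[cows]
        y1 = bv["a"].to_numpy() + math.sqrt(0.7) * rng.standard_normal(len(cows))
        y2 = bv["b"].to_numpy() + math.sqrt(0.7) * rng.standard_normal(len(cows))
        rgs.append(solver.fit(y1, y2).rg)
    assert abs(np.mean(rgs)) < 0.25


def test_bivariate_with_zero_covariances_matches_univariate():
    ped, cows, K, X = half_sib_setup(n_cows=300, n_base=40)
    uni = UnivariateREML(X, K)
    biv = BivariateREML(X, K)
    rng = np.random.default_rng(17)
    y1 = next(simulate_trait(ped, cows, 0.3, 1, seed=41))
    y2 = 1.0 + rng.standard_normal(len(cows))
    res = biv.fit(y1, y2, fix_rg_zero=True, fix_re_zero=True)
    f1, f2 = uni.fit(y1), uni.fit(y2)
    assert res.G[0, 0] == pytest.approx(f1.sigma2_a, abs=2e-4)
    assert res.R[0, 0] == pytest.approx(f1.sigma2_e, abs=2e-4)
    assert res.G[1, 1] == pytest.approx(f2.sigma2_a, abs=2e-4)
    assert res.R[1, 1] == pytest.approx(f2.sigma2_e, abs=2e-4)


def test_dense_path_handles_unequal_cow_sets():
    ped, cows, K, X = half_sib_setup(n_cows=250, n_base=40)
    A = build_A(ped)
    rng = np.random.default_rng(53)
    tv = simulate_breeding_values(
        ped, {"a": 0.4, "b": 0.4}, {("a", "b"): -0.6}, {"a": 1.0, "b": 1.0}, seed=77
    )
    bv = tv.breeding_values.set_index("animal_id").loc[cows]
    y1 = bv["a"].to_numpy() + math.sqrt(0.6) * rng.standard_normal(len(cows))
    y2 = bv["b"].to_numpy() + math.sqrt(0.6) * rng.standard_normal(len(cows))
    keep2 = np.arange(len(cows)) % 5 != 0  # second trait missing for 20%
    idx = ped.index_of(cows.tolist())
    res = reml_bivariate(
        y1, y2[keep2], X, X[keep2], A, idx, idx[keep2]
    )
    assert res.converged
    assert -1.0 <= res.rg <= 0.1  # negative correlation detected


# ---------------------------------------------------------------------------
# LRT / GCV / Fisher


def test_lrt_basic_values():
    stat, p = lrt_variance(-100.0, -100.0)
    assert stat == 0.0 and p == pytest.approx(1.0)
    stat, p = lrt_variance(-98.08, -100.0)  # 2*(logL diff) = 3.84
    assert stat == pytest.approx(3.84)
    assert p == pytest.approx(0.05, abs=0.001)
    # boundary mixture halves the p-value for positive statistics
    _, pm = lrt_variance(-98.08, -100.0, mixture=True)
    assert pm == pytest.approx(p / 2, rel=1e-9)


@pytest.mark.parametrize(
    "s2a, expected",
    [(0.057, 0.24), (0.047, 0.22)],
)
def test_gcv_log_scale_traits(s2a, expected):
    assert round(gcv(s2a, log_scale=True), 2) == expected


def test_gcv_mean_scaled_and_degenerate():
    assert gcv(0.25, mean=2.0) == pytest.approx(0.25)
    assert gcv(0.0, mean=5.0) == 0.0
    with pytest.raises(ValueError):
        gcv(0.1, mean=0.0)


def test_fisher_r_to_z():
    z, p = fisher_r_to_z(0.0, 100)
    assert z == 0.0 and p == pytest.approx(1.0)
    z, p = fisher_r_to_z(0.5, 103)
    assert z == pytest.approx(0.5493, abs=1e-4)
    assert z * math.sqrt(100) == pytest.approx(5.493, abs=1e-3)
    assert p < 1e-7
    # monotone unbounded near |r| -> 1
    z_hi, _ = fisher_r_to_z(0.999, 50)
    assert z_hi > fisher_r_to_z(0.99, 50)[0] > fisher_r_to_z(0.9, 50)[0]
    with pytest.raises(ValueError):
        fisher_r_to_z(1.0, 50)
    with pytest.raises(ValueError):
        fisher_r_to_z(0.5, 3)
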