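"""Synthetic-herd generator: structure, determinism, ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from milkres.genetics import longevity_traits
from milkres.pedigree import build_A
from milkres.simulate import (
    LactationTemplate,
    SimulationConfig,
    assign_cow_metadata,
    simulate_breeding_values,
    simulate_herd,
    simulate_lactations,
    simulate_longevity,
    simulate_pedigree,
    _episode_multiplier,
)


def test_smallest_family():
    cfg = SimulationConfig(n_base_animals=2, n_cows=1, seed=0)
    ped, cows = simulate_pedigree(cfg)
    assert len(ped) == 3
    i = ped.index_of([int(cows[0])])[0]
    assert {int(ped.sire[i]), int(ped.dam[i])} == {1, 2}


def test_pedigree_acyclic_and_deterministic():
    cfg = SimulationConfig(n_base_animals=30, n_cows=100, seed=42)
    ped1, _ = simulate_pedigree(cfg)  # Pedigree construction validates acyclicity
    ped2, _ = simulate_pedigree(cfg)
    pd.testing.assert_frame_equal(ped1.to_frame(), ped2.to_frame())


def test_config_validation_errors():
    with pytest.raises(ValueError, match="base animals"):
        SimulationConfig(n_base_animals=1).validate()
    with pytest.raises(ValueError, match="h2"):
        SimulationConfig(h2_targets={"lnvar": 1.2}).validate()
    with pytest.raises(ValueError, match="record_span"):
        SimulationConfig(record_span=500).validate()


def test_h2_zero_trait_has_zero_breeding_values():
    cfg = SimulationConfig(n_base_animals=20, n_cows=50, seed=1)
    ped, _ = simulate_pedigree(cfg)
    tv = simulate_breeding_values(
        ped, {"flat": 0.0, "x": 0.3}, {}, {"flat": 1.0, "x": 1.0}, seed=2
    )
    assert np.all(tv.breeding_values["flat"].to_numpy() == 0.0)
    assert tv.breeding_values["x"].std() > 0


def test_non_psd_rg_targets_rejected():
    cfg = SimulationConfig(n_base_animals=10, n_cows=10, seed=1)
    ped, _ = simulate_pedigree(cfg)
    rg = {("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): -0.9}
    with pytest.raises(ValueError, match="positive semi-definite"):
        simulate_breeding_values(
            ped, {"a": 0.3, "b": 0.3, "c": 0.3}, rg,
            {"a": 1.0, "b": 1.0, "c": 1.0}, seed=3,
        )


def test_breeding_value_moments_match_dense_chol_oracle():
    """Mendelian-sampling recursion against direct sampling from the
    dense Cholesky factor of A on a 50-animal pedigree: marginal
    variances and mid-parent regression agree within Monte-Carlo error."""
    cfg = SimulationConfig(n_base_animals=10, n_cows=40, seed=6)
    ped, cows = simulate_pedigree(cfg)
    A = build_A(ped)
    sp2, h2 = 1.0, 0.4
    sa2 = h2 * sp2

    reps = 400
    rec = np.stack(
        [
            simulate_breeding_values(ped, {"t": h2}, {}, {"t": sp2}, seed=1000 + r)
            .breeding_values["t"].to_numpy()
            for r in range(reps)
        ]
    )
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    rng = np.random.default_rng(7)
    direct = (L @ rng.standard_normal((len(A), reps)) * math.sqrt(sa2)).T

    # marginal variance of every animal ~ diag(A)·σ²a under both routes
    np.testing.assert_allclose(rec.var(axis=0).mean(), sa2 * np.diag(A).mean(), rtol=0.15)
    np.testing.assert_allclose(direct.var(axis=0).mean(), sa2 * np.diag(A).mean(), rtol=0.15)

    # offspring on mid-parent regression ≈ 1 for the recursion
    idx = ped._index
    mid, off = [], []
    for i, (s, d) in enumerate(zip(ped.sire, ped.dam)):
        if s != 0 and d != 0:
            mid.append(0.5 * (rec[:, idx[int(s)]] + rec[:, idx[int(d)]]))
            off.append(rec[:, i])
    mid = np.concatenate(mid)
    off = np.concatenate(off)
    slope = np.polyfit(mid, off, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.08)


def test_monozygotic_duplicates_share_parent_average():
    """Same parents + same segregation seed ⇒ identical draws."""
    cfg = SimulationConfig(n_base_animals=4, n_cows=2, seed=9)
    ped, cows = simulate_pedigree(cfg)
    tv1 = simulate_breeding_values(ped, {"t": 0.3}, {}, {"t": 1.0}, seed=5)
    tv2 = simulate_breeding_values(ped, {"t": 0.3}, {}, {"t": 1.0}, seed=5)
    pd.testing.assert_frame_equal(tv1.breeding_values, tv2.breeding_values)


# ---------------------------------------------------------------------------
# lactations


def noise_free_config(**kw):
    return SimulationConfig(
        n_base_animals=10, n_cows=12, seed=3,
        disturbance_rate=0.0, residual_cv=0.0, **kw
    )


def test_noise_free_records_lie_on_baseline():
    cfg = noise_free_config()
    ped, cows = simulate_pedigree(cfg)
    tv = simulate_breeding_values(
        ped, cfg.h2_targets, cfg.rg_targets, cfg.phenotypic_variances, seed=4
    )
    meta = assign_cow_metadata(cfg, cows, seed=5)
    records, tv = simulate_lactations(ped, tv, cfg, meta)
    template = cfg.lactation_template
    for cow, grp in records.groupby("animal_id"):
        m = tv.merit_multiplier[cow]
        expected = np.clip(m * template(grp["dim"].to_numpy()), 0.01, 45.0)
        np.testing.assert_allclose(grp["yield_kg"].to_numpy(), expected, rtol=1e-12)


def test_single_episode_instant_recovery():
    """depth 0.5 with halflife → 0⁺: the test day at onset is halved,
    the one before untouched."""
    dims = np.array([99, 100, 101])
    mult = _episode_multiplier(dims.astype(float), [(100.0, 0.5, 0.0)])
    assert mult[0] == pytest.approx(1.0)
    assert mult[1] == pytest.approx(0.5)
    assert mult[2] == pytest.approx(1.0)  # instant recovery
    # finite halflife: exponential recovery with the stated half-life
    mult = _episode_multiplier(np.array([100.0, 110.0]), [(100.0, 0.4, 10.0)])
    assert mult[0] == pytest.approx(0.6)
    assert mult[1] == pytest.approx(1 - 0.4 * 0.5)


def test_yields_within_bounds(small_herd):
    y = small_herd.records["yield_kg"]
    assert (y > 0).all() and (y <= 45).all()
    assert small_herd.records["dim"].max() <= 400


def test_herd_determinism_byte_identical(small_config):
    h1 = simulate_herd(small_config)
    h2 = simulate_herd(small_config)
    assert h1.records.to_csv(index=False) == h2.records.to_csv(index=False)
    assert h1.meta.to_csv(index=False) == h2.meta.to_csv(index=False)
    assert h1.longevity.to_csv(index=False) == h2.longevity.to_csv(index=False)


def test_wilmink_template_shape():
    t = LactationTemplate(peak_yield=12.0, time_to_peak=50.0, persistency=-0.012)
    curve = t(np.arange(1, 401))
    peak_dim = int(np.argmax(curve)) + 1
    assert abs(peak_dim - 50) <= 2
    assert curve.max() == pytest.approx(12.0, abs=0.05)
    assert curve[-1] < curve[49]  # declining tail


# ---------------------------------------------------------------------------
# longevity


def test_pls_definition_and_eligibility():
    meta = pd.DataFrame(
        {
            "animal_id": [1, 2, 3],
            "birth_date": pd.to_datetime(["2010-01-01"] * 3),
            "first_calving_date": pd.to_datetime(["2012-01-01"] * 3),
            "exit_date": pd.to_datetime(["2013-01-01", "2014-01-01", "2012-01-01"]),
            "exit_code": ["died-disease", "sold-for-breeding", "slaughter"],
        }
    )
    out = longevity_traits(meta)
    assert out["animal_id"].tolist() == [1, 3]  # ineligible code excluded
    row = out.set_index("animal_id").loc[1]
    assert row["pls_days"] == 366  # 2012 is a leap year
    assert row["hl_days"] == 1096
    assert out.set_index("animal_id").loc[3, "pls_days"] == 0  # exit on calving day


def test_all_censored_config_gives_empty_longevity():
    cfg = SimulationConfig(n_base_animals=10, n_cows=15, seed=2, exit_rate=0.0)
    herd = simulate_herd(cfg)
    assert len(herd.longevity) == 0
    assert longevity_traits(herd.meta).empty


def test_longevity_positive_and_consistent(small_herd):
    lon = small_herd.longevity
    assert (lon["pls_days"] >= 1).all()
    assert (lon["hl_days"] > lon["pls_days"]).all()  # HL includes rearing
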