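"""End-to-end pipeline: simulate → edit → fit curves → indicators →
genetics → LSM reports, with a manifest for reproducibility.

Every stage writes plain CSV into the run directory; the manifest
records the configuration echo, seed, per-stage row counts and
per-rule edit counts, so two runs with the same configuration produce
identical manifests (and numerically identical outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .curves import fit_all_curves
from .editing import EditConfig, apply_record_filters, build_year_season_groups
from .genetics import bivariate_analysis, longevity_traits, univariate_analysis
from .indicators import (
    INDICATOR_COLUMNS,
    assemble_phenotypes,
    compute_deviations,
    four_sd_edit,
)
from .lsmeans import fit_fixed_model, lsmeans
from .simulate import SimulationConfig, simulate_herd

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    When ``records_path`` is unset the synthetic generator provides the
    inputs using ``simulation``.  ``bivariate_pairs`` lists the trait
    pairs fitted with the bivariate animal model (kept short by default:
    the full 7×7 grid is available through the API).
    """

    out_dir: str = "milkres_run"
    seed: int = 0
    tau: float = 0.7
    records_path: str | None = None
    meta_path: str | None = None
    pedigree_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    edits: EditConfig = field(default_factory=EditConfig)
    traits: list = field(default_factory=lambda: INDICATOR_COLUMNS + ["amy"])
    bivariate_pairs: list = field(
        default_factory=lambda: [("lnvar2", "pls_days"), ("lnvar2", "amy")]
    )
    lsm_indicators: list = field(default_factory=lambda: ["lnvar1", "lnvar2", "rawvar"])
    run_genetics: bool = True
    run_lsmeans: bool = True
    stop_after: str | None = None  # stage name: simulate/edit/curves/indicators

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["lactation_template"] = dataclasses.asdict(
            self.simulation.lactation_template
        )
        # tuple-keyed maps (rg targets) are not JSON keys; stringify
        d["simulation"]["rg_targets"] = {
            "+".join(k) if isinstance(k, tuple) else str(k): v
            for k, v in self.simulation.rg_targets.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)


def _finish(manifest: dict, out: Path) -> dict:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to
    ``manifest.json`` in the run directory).

    Raises :class:`PipelineError` naming the failing stage; outputs of
    completed stages are retained for debugging.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "rows": {},
        "edit_log": {},
    }

    stage = "simulate"
    try:
        if config.records_path is None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            herd = simulate_herd(sim)
            records, meta, ped = herd.records, herd.meta, herd.pedigree
            mio.write_tables(
                out,
                records=records,
                meta=meta,
                pedigree=ped.to_frame(),
                true_values=herd.true_values.breeding_values,
                longevity=herd.longevity,
            )
        else:
            records = mio.read_records(config.records_path)
            meta = mio.read_meta(config.meta_path)
            ped = mio.read_pedigree(config.pedigree_path)
        _stage(manifest, stage)
        manifest["rows"]["records_in"] = len(records)
        manifest["rows"]["cows_in"] = len(meta)
        if config.stop_after == "simulate":
            return _finish(manifest, out)

        stage = "edit"
        rec_f, meta_f, edit_log = apply_record_filters(records, meta, config.edits)
        meta_f, census = build_year_season_groups(
            meta_f, config.edits.season_calendar, config.edits.min_ys_group
        )
        edit_log["cows_ys_excluded"] = int(meta_f["ys_excluded"].sum())
        manifest["edit_log"] = edit_log
        manifest["rows"]["records_edited"] = len(rec_f)
        manifest["rows"]["cows_edited"] = len(meta_f)
        mio.write_tables(out, records_edited=rec_f, meta_edited=meta_f, ys_census=census)
        (out / "edit_log.json").write_text(json.dumps(edit_log, indent=2))
        _stage(manifest, stage)
        if len(rec_f) == 0:
            manifest["empty_cohort"] = True
            return _finish(manifest, out)
        if config.stop_after == "edit":
            return _finish(manifest, out)

        stage = "curves"
        fits, excluded = fit_all_curves(rec_f, tau=config.tau)
        fit_rows = [
            {
                "animal_id": f.animal_id, "tau": f.tau, "n_obs": f.n_obs,
                "check_loss": f.check_loss, "converged": f.converged,
                **{f"beta{i}": b for i, b in enumerate(f.beta)},
            }
            for f in fits.values()
        ]
        mio.write_tables(out, curve_fits=pd.DataFrame(fit_rows))
        manifest["rows"]["cows_fitted"] = len(fits)
        manifest["rows"]["cows_fit_excluded"] = len(excluded)
        _stage(manifest, stage)
        if config.stop_after == "curves":
            return _finish(manifest, out)

        stage = "indicators"
        devs = {
            a: compute_deviations(g, fits[a])
            for a, g in rec_f.groupby("animal_id")
            if a in fits
        }
        pheno = assemble_phenotypes(devs, rec_f, meta_f)
        sd_edit_log = {}
        for col in INDICATOR_COLUMNS:
            pheno[col], n_removed = four_sd_edit(pheno[col])
            sd_edit_log[col] = n_removed
        manifest["edit_log"]["four_sd_removed"] = sd_edit_log
        longe = longevity_traits(meta_f)
        pheno = pheno.merge(longe[["animal_id", "pls_days", "hl_days"]], on="animal_id", how="left")
        mio.write_tables(out, phenotypes=pheno)
        manifest["rows"]["cows_phenotyped"] = len(pheno)
        _stage(manifest, stage)
        if config.stop_after == "indicators":
            return _finish(manifest, out)

        if config.run_genetics:
            stage = "genetics"
            gen_rows = []
            for trait in config.traits:
                if trait not in pheno.columns or pheno[trait].notna().sum() < 50:
                    continue
                try:
                    res = univariate_analysis(pheno, ped, trait)
                except Exception as e:  # noqa: BLE001 - reported per trait
                    gen_rows.append({"trait": trait, "error": str(e)})
                    continue
                gen_rows.append(res.as_dict())
            gen = pd.DataFrame(gen_rows)
            mio.write_tables(out, genetics_univariate=gen)

            biv_rows = []
            for t1, t2 in config.bivariate_pairs:
                if t1 not in pheno.columns or t2 not in pheno.columns:
                    continue
                if pheno[t1].notna().sum() < 50 or pheno[t2].notna().sum() < 50:
                    continue
                try:
                    full = bivariate_analysis(pheno, ped, t1, t2)
                    red = bivariate_analysis(pheno, ped, t1, t2, fix_rg_zero=True)
                    from .reml import lrt_variance

                    stat, p = lrt_variance(full.logl, red.logl)
                    biv_rows.append(
                        {
                            "trait1": t1, "trait2": t2, "rg": full.rg, "rp": full.rp,
                            "se_rg": full.se_rg, "lrt_p": p, "logl": full.logl,
                            "boundary": full.boundary,
                        }
                    )
                except Exception as e:  # noqa: BLE001
                    biv_rows.append({"trait1": t1, "trait2": t2, "error": str(e)})
            mio.write_tables(out, genetics_bivariate=pd.DataFrame(biv_rows))
            manifest["rows"]["traits_analyzed"] = int(gen["trait"].notna().sum()) if len(gen) else 0
            _stage(manifest, stage)

        if config.run_lsmeans:
            stage = "lsmeans"
            lsm_frames = []
            lsm_errors = {}
            for ind in config.lsm_indicators:
                if ind not in pheno.columns or pheno[ind].notna().sum() < 30:
                    continue
                try:
                    fit = fit_fixed_model(pheno[~pheno["ys_excluded"].astype(bool)], ind)
                except ValueError as e:  # e.g. saturated design on tiny cohorts
                    lsm_errors[ind] = str(e)
                    continue
                for factor in ("breed_group", "env"):
                    if factor in fit.factors:
                        tab = lsmeans(fit, factor).table.copy()
                        tab.insert(0, "indicator", ind)
                        tab.insert(1, "factor", factor)
                        lsm_frames.append(tab)
            if lsm_errors:
                manifest["lsm_errors"] = lsm_errors
            if lsm_frames:
                mio.write_tables(out, lsm_report=pd.concat(lsm_frames, ignore_index=True))
            _stage(manifest, stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    return _finish(manifest, out)
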