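"""End-to-end orchestration of the synthetic-cohort analysis stages."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, epistasis, finemap, io, scores, synth
from .association import (
    conditional_scan,
    fit_additive_logistic,
    meta_fixed,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "assoc", "condition", "meta", "interact",
    "credible", "score", "serology", "crs", "diagnose",
)

_ETHNICITY_SNPS = {
    "east_asian": {
        "lead": ["rs6707458", "rs230540", "rs9405192"],
        "hla": ["rs9269027", "rs1974461"],
    },
    "european": {
        "lead": ["rs6707458", "rs230540", "rs9405192"],
        "hla": ["rs9271541", "rs9265949", "rs2858309"],
    },
}


def _summary_frame(results, eaf_cases, eaf_controls, effect_alleles) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variant_id": r.variant_id,
                "effect_allele": effect_alleles.get(r.variant_id, "NA"),
                "other_allele": "NA",
                "eaf_cases": eaf_cases[r.variant_id],
                "eaf_controls": eaf_controls[r.variant_id],
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p_wald,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "conditioned_on": ";".join(r.conditioned_on),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> Path:
    """Run the configured stages in order; returns the results directory.

    Every output TSV carries header comments with the package version,
    config hash, and root seed, so reruns of an identical config are
    byte-identical.
    """
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    ethnicity = config.get("ethnicity", "east_asian")
    meta_info = {"config_hash": io.config_hash(config), "seed": seed}

    spec_factory = synth.east_asian_spec if ethnicity == "east_asian" else synth.european_spec
    spec = spec_factory(
        n_cases=int(config.get("n_cases", 1000)),
        n_controls=int(config.get("n_controls", 2000)),
        prevalence=float(config.get("prevalence", 0.001)),
        seed=seed,
    )

    cohort = None
    summary = None
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        if stage == "simulate":
            cohort = synth.simulate_case_control(spec)
            io.write_dosage_tsv(cohort.genotypes, cohort.effect_alleles,
                                out / "genotypes.tsv", meta_info)
            io.write_phenotypes_tsv(cohort.phenotypes, out / "phenotypes.tsv", meta_info)
        elif stage == "assoc":
            cohort = _require(cohort, stage)
            pcs = cohort.phenotypes[cohort.pc_columns()].to_numpy()
            results = [
                fit_additive_logistic(cohort.genotypes[vid], cohort.status,
                                      covariates=pcs, variant_id=vid)
                for vid in cohort.genotypes.columns
            ]
            case_mask = cohort.status == 1
            eaf_cases = (cohort.genotypes[case_mask].mean() / 2).to_dict()
            eaf_controls = (cohort.genotypes[~case_mask].mean() / 2).to_dict()
            summary = _summary_frame(results, eaf_cases, eaf_controls, cohort.effect_alleles)
            io.write_summary_tsv(summary, out / "assoc.tsv", meta_info)
        elif stage == "condition":
            cohort = _require(cohort, stage)
            pcs = cohort.phenotypes[cohort.pc_columns()].to_numpy()
            scan = conditional_scan(
                cohort.genotypes, cohort.status, covariates=pcs,
                threshold=float(config.get("threshold", 5e-8)),
            )
            steps = pd.DataFrame({"round": range(1, len(scan.steps) + 1),
                                  "selected": scan.selected})
            io._write_tsv(steps, out / "conditional_steps.tsv", meta_info, index=False)
        elif stage == "meta":
            cohort = _require(cohort, stage)
            # demonstration meta-analysis: split-half pseudo-cohorts
            rows = []
            half = np.arange(len(cohort.status)) % 2 == 0
            for vid in cohort.genotypes.columns:
                fits = []
                for mask in (half, ~half):
                    fits.append(fit_additive_logistic(
                        cohort.genotypes[vid][mask], cohort.status[mask], variant_id=vid))
                m = meta_fixed([f.beta for f in fits], [f.se for f in fits])
                rows.append({"variant_id": vid, "beta_fixed": m.beta_fixed,
                             "se_fixed": m.se_fixed, "p": m.p, "Q": m.Q,
                             "I2": m.I2, "k_studies": m.k_studies})
            io._write_tsv(pd.DataFrame(rows), out / "meta.tsv", meta_info, index=False)
        elif stage == "interact":
            cohort = _require(cohort, stage)
            snps = _ETHNICITY_SNPS[ethnicity]
            lead = config.get("lead_snps", snps["lead"])
            hla = config.get("hla_snps", snps["hla"])
            shared = [tuple(p) for p in config.get(
                "shared_pairs",
                [(a, b) for i, a in enumerate(lead) for b in lead[i + 1:]],
            )]
            pcs = cohort.phenotypes[cohort.pc_columns()].to_numpy()
            screen = epistasis.interaction_screen(
                cohort.genotypes, cohort.status, lead, hla, shared,
                covariates=pcs, family_alpha=float(config.get("family_alpha", 0.05)),
            )
            io._write_tsv(screen, out / "interaction_screen.tsv", meta_info, index=False)
        elif stage == "credible":
            summary = _require(summary, stage, "assoc")
            cs = finemap.credible_set(
                summary["variant_id"], summary["beta"], summary["se"],
                W=float(config.get("prior_w", finemap.DEFAULT_PRIOR_W)),
            )
            io._write_tsv(cs.table, out / "credible_set.tsv", meta_info, index=False)
        elif stage == "score":
            cohort = _require(cohort, stage)
            definition = scores.load_score_definition(
                ethnicity, config.get("score_definition"))
            scored = scores.compute_grs(cohort.genotypes, definition)
            cohort.phenotypes["grs_raw"] = scored["grs_raw"]
            cohort.phenotypes["grs"] = scored["grs"]
        elif stage == "serology":
            cohort = _require(cohort, stage)
            serology = synth.default_serology(ethnicity)
            synth.simulate_antibody(cohort, serology, seed=seed + 1)
        elif stage == "crs":
            cohort = _require(cohort, stage)
            calibration = scores.load_crs_calibration(ethnicity)
            crs = scores.compute_crs(
                cohort.phenotypes["grs"], cohort.phenotypes["titer_u_ml"], calibration)
            cohort.phenotypes["crs"] = crs["crs"].to_numpy()
            io.write_phenotypes_tsv(cohort.phenotypes, out / "scored_phenotypes.tsv", meta_info)
        elif stage == "diagnose":
            cohort = _require(cohort, stage)
            rows = []
            for score_col in ("grs", "crs"):
                if score_col not in cohort.phenotypes.columns:
                    continue
                roc = diagnostics.auroc(cohort.phenotypes[score_col], cohort.status)
                rows.append({"score": score_col, "auroc": roc.auroc,
                             "ci_low": roc.ci95[0], "ci_high": roc.ci95[1],
                             "n_cases": roc.n_cases, "n_controls": roc.n_controls})
                cuts = diagnostics.cutoff_table(cohort.phenotypes[score_col], cohort.status)
                io._write_tsv(cuts, out / f"cutoffs_{score_col}.tsv", meta_info, index=False)
            if "grs" in cohort.phenotypes.columns:
                deciles = diagnostics.decile_or(
                    cohort.phenotypes["grs"], cohort.status,
                    basis=config.get("decile_basis", "all"))
                io._write_tsv(deciles, out / "decile_or.tsv", meta_info, index=False)
            io._write_tsv(pd.DataFrame(rows), out / "auroc.tsv", meta_info, index=False)
        logger.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)
    return out


def _require(obj, stage: str, needs: str = "simulate"):
    if obj is None:
        raise ConfigError(f"stage {stage!r} requires stage {needs!r} to run first")
    return obj
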