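"""End-to-end orchestration: simulate/ingest -> exclusions -> markers ->
harmonization -> residualization -> PLS -> mediation -> report.

Every stage draws its seed deterministically from one master seed via a
fixed stage-index counter, so stages are independently reproducible and
changing e.g. the permutation count does not perturb fold assignments
or the synthetic draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from brainaging.cohort import (
    RISK_FACTORS,
    CohortTable,
    ExclusionRule,
    apply_exclusions,
    read_cohort,
)
from brainaging.markers import compute_marker_panel
from brainaging.mediation import mediation_table, run_mediation_suite
from brainaging.pls import (
    bootstrap_stability,
    crossval_score_correlation,
    fit_pls,
    per_marker_regressions,
    permutation_test,
    score_correlation,
)
from brainaging.prep import UKB_DOMAIN_MAP, DomainMap, normalize_grip, residualize, zscore
from brainaging.synth import GroundTruth, SyntheticConfig, generate_cohort

logger = logging.getLogger("brainaging")

#: Fixed stage indices for seed derivation; appending new stages keeps
#: existing ones reproducible.
STAGE_INDEX = {
    "simulate": 0,
    "markers": 1,
    "permutation": 2,
    "bootstrap": 3,
    "mediation": 4,
    "crossval": 5,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (counter scheme)."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    """Serializable configuration for one full analysis run."""

    seed: int = 0
    n_subjects: int = 2000
    cohort_path: str | None = None  # None -> simulate
    schema: dict[str, str] = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    exclusion_rules: list[dict] = field(default_factory=lambda: [
        {"name": "psmd_outlier", "column": "psmd", "kind": "sd_outlier", "k": 3.0}
    ])
    confounds: list[str] = field(default_factory=lambda: ["age", "sex", "education"])
    n_folds: int = 5
    n_perm: int = 500
    n_boot: int = 500
    cv_folds: int = 10
    gap_variants: bool = False
    wmh_floor: float = 1e-3
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=False)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive table: mean and SD per numeric variable, % female."""
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    df = cohort.data
    rows = [
        {
            "variable": "sex_pct_female",
            "mean": 100.0 * float((df["sex"] == "female").mean()),
            "sd": np.nan,
        }
    ]
    skip = set(cohort.md_value_columns) | set(cohort.morphometry) | {"subject_id", "sex"}
    for col in df.columns:
        if col in skip:
            continue
        vals = df[col].to_numpy(float)
        rows.append({"variable": col, "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))})
    return pd.DataFrame(rows)


def _clinical_matrix(cohort: CohortTable, domain_map: DomainMap) -> pd.DataFrame:
    """Domain scores + motor variables for the PLS clinical block."""
    from brainaging.prep import build_domain_scores

    df = cohort.data
    tests = df[[c for c in cohort.test_columns if c in domain_map.domains]]
    clinical = build_domain_scores(tests, domain_map)
    if {"grip_left", "grip_right", "height"}.issubset(df.columns):
        clinical["grip_normalized"] = zscore(
            normalize_grip(df["grip_left"], df["grip_right"], df["height"])
        )
    if "accelerometry" in df.columns:
        clinical["accelerometry"] = zscore(df["accelerometry"].to_numpy(float))
    if "timed_up_and_go" in df.columns:
        clinical["timed_up_and_go"] = zscore(df["timed_up_and_go"].to_numpy(float))
    return clinical


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle with a JSON-able manifest."""
    manifest: dict = {"seed": config.seed, "stages": {}}
    bundle: dict = {"manifest": manifest}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage: cohort -------------------------------------------------
    if config.cohort_path:
        logger.info("reading cohort from %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path, schema=config.schema or None)
        truth = None
    else:
        sim_cfg = SyntheticConfig(
            n_subjects=config.n_subjects,
            seed=stage_seed(config.seed, "simulate"),
            **config.synthetic,
        )
        cohort, truth = generate_cohort(sim_cfg)
        bundle["ground_truth"] = truth
    manifest["stages"]["cohort"] = {"n_input": cohort.n_subjects}

    # -- stage: exclusions ---------------------------------------------
    rules = [ExclusionRule(**r) for r in config.exclusion_rules]
    rules = [r for r in rules if r.column in cohort.data.columns]
    ids_before = cohort.subject_ids.to_numpy().astype(str)
    cohort, report = apply_exclusions(cohort, rules)
    if truth is not None:
        keep = ~np.isin(ids_before, np.asarray(report.excluded_ids, dtype=str))
        truth = GroundTruth(
            delta=truth.delta[keep],
            eta=truth.eta[keep],
            a_k=truth.a_k,
            b=truth.b,
            c_prime_k=truth.c_prime_k,
            psmd_target=None if truth.psmd_target is None else truth.psmd_target[keep],
        )
        bundle["ground_truth"] = truth
    manifest["stages"]["exclusions"] = json.loads(report.to_json())
    manifest["stages"]["exclusions"].pop("excluded_ids")
    bundle["cohort"] = cohort
    bundle["exclusion_report"] = report

    # -- stage: markers ------------------------------------------------
    panel, brain_age = compute_marker_panel(
        cohort,
        n_folds=config.n_folds,
        seed=stage_seed(config.seed, "markers") % (2**32),
        gap_variants=config.gap_variants,
        wmh_floor=config.wmh_floor,
    )
    bundle["marker_panel"] = panel
    bundle["brain_age"] = brain_age
    manifest["stages"]["markers"] = {"cv_metrics": brain_age.cv_metrics}

    # -- stage: harmonization ------------------------------------------
    clinical = _clinical_matrix(cohort, UKB_DOMAIN_MAP)
    bundle["clinical"] = clinical

    # -- stage: residualization ----------------------------------------
    df = cohort.data
    conf_cols = []
    for c in config.confounds:
        conf_cols.append(cohort.sex_codes() if c == "sex" else df[c].to_numpy(float))
    confounds = np.column_stack(conf_cols)
    marker_cols = [c for c in panel.columns if c != "subject_id"]
    X = residualize(panel[marker_cols].to_numpy(float), confounds)
    # covariates ride along in the clinical block as deconfounding checks
    y_names = list(clinical.columns) + config.confounds
    Y_clin = residualize(clinical.to_numpy(float), confounds)
    Y = np.column_stack([Y_clin, confounds - confounds.mean(axis=0)])

    # -- stage: PLS ----------------------------------------------------
    anchor = marker_cols.index("relative_brain_age")
    model = fit_pls(X, Y, sign_anchor=anchor, x_names=marker_cols, y_names=y_names)
    perm = permutation_test(X, Y, n_perm=config.n_perm, seed=stage_seed(config.seed, "permutation"))
    boot = bootstrap_stability(X, Y, n_boot=config.n_boot, seed=stage_seed(config.seed, "bootstrap"))
    r_sp = score_correlation(model, lv=0)
    cv_r = crossval_score_correlation(
        X, Y, k=config.cv_folds, seed=stage_seed(config.seed, "crossval") % (2**32)
    )
    bundle.update(pls_model=model, permutation=perm, bootstrap=boot)
    manifest["stages"]["pls"] = {
        "covariance_explained": model.covariance_explained.tolist(),
        "p_fdr": perm.p_fdr.tolist(),
        "lv1_spearman": r_sp,
        "lv1_spearman_cv": cv_r,
        "bootstrap_ratios_lv1": dict(zip(marker_cols, boot.bootstrap_ratios[:, 0].tolist())),
    }

    # -- stage: per-marker regressions ---------------------------------
    bundle["regressions"] = per_marker_regressions(
        panel[marker_cols], clinical, covariates=confounds
    )

    # -- stage: mediation ----------------------------------------------
    present = [f for f in RISK_FACTORS if f in df.columns]
    results = run_mediation_suite(
        df[present],
        model.imaging_scores[:, 0],
        model.clinical_scores[:, 0],
        covariates=confounds,
        n_boot=config.n_boot,
        seed=stage_seed(config.seed, "mediation"),
    )
    med_table = mediation_table(results)
    bundle["mediation"] = results
    bundle["mediation_table"] = med_table
    manifest["stages"]["mediation"] = {
        "classification": dict(zip(med_table["risk_factor"], med_table["classification"]))
    }

    # -- outputs -------------------------------------------------------
    if out_dir:
        summarize_cohort(cohort).to_csv(out_dir / "cohort_summary.csv", index=False)
        panel.to_csv(out_dir / "marker_panel.csv", index=False)
        clinical.to_csv(out_dir / "clinical_matrix.csv", index=False)
        pd.DataFrame(model.U, index=marker_cols).to_csv(out_dir / "imaging_loadings.csv")
        pd.DataFrame(model.V, index=y_names).to_csv(out_dir / "clinical_loadings.csv")
        pd.DataFrame(
            {
                "singular_value": model.singular_values,
                "covariance_explained": model.covariance_explained,
                "p_raw": perm.p_raw,
                "p_fdr": perm.p_fdr,
            }
        ).to_csv(out_dir / "lv_summary.csv", index=False)
        scores = pd.DataFrame(
            {
                "subject_id": cohort.subject_ids,
                "imaging_score_lv1": model.imaging_scores[:, 0],
                "clinical_score_lv1": model.clinical_scores[:, 0],
            }
        )
        scores.to_csv(out_dir / "subject_scores.csv", index=False)
        med_table.to_csv(out_dir / "mediation.csv", index=False)
        bundle["regressions"].to_csv(out_dir / "per_marker_regressions.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
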