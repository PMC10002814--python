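"""End-to-end pipeline: synthesize -> gate -> select -> stratify -> jmi -> stats.

A single master seed fans out to per-stage seeds through
:func:`csfstrat._utils.spawn_seeds` (numpy SeedSequence spawning); no stage
consumes global unseeded randomness, so a run directory is bit-reproducible
from its config. Every stage writes its outputs plus an entry in
``manifest.json`` recording the stage parameters and derived seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gating, jmi, selection, stats, stratify, synthetic
from ._utils import spawn_seeds

logger = logging.getLogger(__name__)

STAGES = ("synth", "gate", "select", "stratify", "jmi", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class RunConfig:
    """Pipeline parameters. Defaults mirror the reference workflow:
    RFE stop size 14, permutation B=100000, embedding repeats 100, KNN k=5,
    JMI panel size 5, 6-fold CV, BH FDR q=0.20, ratio cutoff fitted by
    mixture model ("auto") with the strict > convention."""

    outdir: str = "run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    cutoff: str | float = "auto"  # "auto" -> mixture fit; else a number
    cutoff_on_log_scale: bool = False
    stop_size: int = 14
    split_fraction: float = 0.8
    permutation_B: int = 100_000
    repeats: int = 100
    knn_k: int = 5
    uncertainty_band: tuple[float, float] = (0.4, 0.6)
    jmi_target_size: int = 5
    jmi_bins: int = 5
    cv_folds: int = 6
    fdr_q: float = 0.20
    stats_n_boot: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        return cfg

    def validate(self, n_peptides: int) -> None:
        if self.stop_size >= n_peptides:
            raise ValueError("stop_size must be smaller than the number of peptides")
        if self.jmi_target_size >= n_peptides:
            raise ValueError("jmi_target_size must be smaller than the number of peptides")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.permutation_B < 100:
            raise ValueError("permutation_B must be >= 100")
        if self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def validate_inputs(subjects_path, peptides_path) -> list[str]:
    """Schema check for a subject table and peptide matrix pair.

    Returns the full list of violations (empty when well-formed).
    """
    violations: list[str] = []
    try:
        subjects = pd.read_csv(subjects_path, index_col=0)
    except Exception as e:  # unreadable
        return [f"subjects: unreadable ({e})"]
    try:
        peptides = pd.read_csv(peptides_path, index_col=0)
    except Exception as e:
        return [f"peptides: unreadable ({e})"]

    for col in ("group", "cognitively_normal", "abeta42", "ttau", "ptau"):
        if col not in subjects.columns:
            violations.append(f"subjects: missing column {col!r}")
    for col in ("abeta42", "ttau", "ptau"):
        if col in subjects.columns:
            vals = pd.to_numeric(subjects[col], errors="coerce")
            bad = subjects.index[(vals <= 0) | vals.isna()]
            for sid in bad:
                row = subjects.index.get_loc(sid) + 2  # 1-based + header
                violations.append(f"subjects: non-positive {col} for {sid} (row {row})")
    missing_in_pep = subjects.index.difference(peptides.index)
    for sid in missing_in_pep:
        violations.append(f"alignment: subject {sid} missing from peptide matrix")
    missing_in_subj = peptides.index.difference(subjects.index)
    for sid in missing_in_subj:
        violations.append(f"alignment: peptide row {sid} missing from subject table")
    if not peptides.empty and not np.issubdtype(peptides.to_numpy().dtype, np.number):
        violations.append("peptides: non-numeric abundance values")
    return violations


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, writing outputs and a manifest under config.outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.CohortSpec(**config.cohort) if config.cohort else synthetic.CohortSpec()
    config.validate(spec.n_peptides)
    stage_seeds = dict(zip(STAGES, spawn_seeds(config.seed, len(STAGES))))
    manifest = {"master_seed": config.seed, "stages": []}

    def record(stage, **params):
        manifest["stages"].append({"stage": stage, "seed": stage_seeds[stage], **params})

    # --- synth
    try:
        spec = dataclasses.replace(spec, seed=stage_seeds["synth"])
        subjects, peptides, truth = synthetic.generate_cohort(spec)
        synthetic.write_cohort(out, subjects, peptides, truth)
        record("synth", n_subjects=len(subjects), n_peptides=spec.n_peptides)
    except Exception as e:
        raise PipelineError("synth", str(e)) from e

    # --- gate
    try:
        panel = gating.AnalytePanel(subjects[["abeta42", "ttau", "ptau"]])
        ratio = panel.ratio().to_numpy()
        if config.cutoff == "auto":
            # the cutoff is derived from the cognitively normal cohort, whose
            # ratio distribution is the bimodal negative/positive mixture
            cn_ratio = ratio[subjects["cognitively_normal"].to_numpy().astype(bool)]
            model = gating.fit_ratio_mixture(cn_ratio, on_log_scale=config.cutoff_on_log_scale,
                                             seed=stage_seeds["gate"])
            if model.cutoff is None:
                raise RuntimeError("mixture fit degenerate; no cutoff derived")
            cutoff = model.cutoff
            (out / "cutoff_model.json").write_text(json.dumps(model.to_dict(), indent=2))
        else:
            cutoff = float(config.cutoff)
        gates = gating.gate_subjects(panel, cutoff, subjects["cognitively_normal"])
        gates.to_frame().to_csv(out / "gated_groups.csv")
        record("gate", cutoff=cutoff, mode=str(config.cutoff))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("gate", str(e)) from e

    # peptide abundances are positive and right-skewed; all classifier and
    # embedding stages work on the log scale
    log_pep = np.log(peptides)

    # --- select (control vs AD panel), using the gated labels
    try:
        ref_mask = gates.isin([synthetic.GROUP_CONTROL, synthetic.GROUP_AD])
        X_ref = log_pep[ref_mask.to_numpy()]
        y_ref = gates[ref_mask].to_numpy()
        sel = selection.select_panel(X_ref, y_ref, stop_size=config.stop_size,
                                     fraction=config.split_fraction,
                                     seed=stage_seeds["select"])
        null = selection.permutation_null(sel.panel, X_ref, y_ref, sel.train_idx,
                                          sel.test_idx, B=config.permutation_B,
                                          seed=stage_seeds["select"])
        (out / "panel.json").write_text(json.dumps({
            "panel": sel.panel,
            "selected": sel.selected,
            "elimination": sel.elimination,
            "metrics": sel.metrics.as_dict(),
            "permutation_p": null.pvalues,
            "permutation_B": null.B,
        }, indent=2))
        record("select", stop_size=config.stop_size, panel=sel.panel, B=null.B)
    except Exception as e:
        raise PipelineError("select", str(e)) from e

    # --- stratify AsymAD
    try:
        order = subjects.index
        ref_idx = np.flatnonzero(gates.isin([synthetic.GROUP_CONTROL, synthetic.GROUP_AD]).to_numpy())
        qry_idx = np.flatnonzero((gates == synthetic.GROUP_ASYMAD).to_numpy())
        ref_labels = np.where(gates.iloc[ref_idx] == synthetic.GROUP_AD, "AD", "CN/BM-")
        strat = stratify.stability_stratify(
            log_pep[sel.panel].to_numpy(), ref_idx, ref_labels, qry_idx,
            repeats=config.repeats, k=config.knn_k, band=config.uncertainty_band,
            seed=stage_seeds["stratify"])
        strat_table = strat.table.copy()
        strat_table.index = order[qry_idx]
        strat_table.index.name = "subject_id"
        strat_table.to_csv(out / "stratification.csv")
        apoe_p = None
        labeled = strat_table[strat_table["final_label"] != stratify.LABEL_UNCERTAIN]
        if labeled["final_label"].nunique() == 2:
            res, table, freqs = stratify.apoe_enrichment(
                subjects.loc[labeled.index, "apoe"], labeled["final_label"])
            apoe_p = res.pvalue
            freqs.to_csv(out / "apoe_allele_freqs.csv")
        record("stratify", repeats=config.repeats, k=config.knn_k,
               n_ad_like=int((strat_table["final_label"] == synthetic.SUBGROUP_AD_LIKE).sum()),
               n_control_like=int((strat_table["final_label"] == synthetic.SUBGROUP_CONTROL_LIKE).sum()),
               n_uncertain=int((strat_table["final_label"] == stratify.LABEL_UNCERTAIN).sum()),
               apoe_fisher_p=apoe_p)
    except Exception as e:
        raise PipelineError("stratify", str(e)) from e

    # --- jmi sub-grouping panel
    try:
        labeled_ids = labeled.index
        if labeled["final_label"].nunique() < 2:
            raise RuntimeError("stratification produced a single subgroup")
        X_asym = log_pep.loc[labeled_ids]
        y_sub = labeled["final_label"].to_numpy()
        tr, te = selection.split_train_test(y_sub, fraction=1 - 0.2,
                                            seed=stage_seeds["jmi"])
        js = jmi.jmi_select(X_asym.iloc[tr], y_sub[tr],
                            target_size=config.jmi_target_size, bins=config.jmi_bins)
        acc, cm, _, _ = jmi.evaluate_subgroup_panel(X_asym, y_sub, js.selected,
                                                    seed=stage_seeds["jmi"])
        cv = jmi.cross_validated_roc(X_asym, y_sub, js.selected, k=config.cv_folds,
                                     seed=stage_seeds["jmi"])
        (out / "jmi_panel.json").write_text(json.dumps({
            "panel": js.selected, "step_scores": js.step_scores,
            "holdout_accuracy": acc, "confusion": cm.tolist(),
            "cv_mean_auc": cv.mean_auc, "cv_se_auc": cv.se_auc,
            "cv_fold_aucs": cv.fold_aucs,
        }, indent=2))
        record("jmi", target_size=config.jmi_target_size, panel=js.selected,
               holdout_accuracy=acc, cv_mean_auc=cv.mean_auc)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("jmi", str(e)) from e

    # --- cohort statistics
    try:
        results = []
        analyte_z = {}
        for a in ("ttau", "ptau", "abeta42"):
            z, _ = gating.standardize(np.log(subjects[a].to_numpy()))
            analyte_z[a] = z
        cov = subjects[["age", "sex", "race", "education"]]
        score_cols = [c for c in synthetic.default_cognition_loadings() if c in subjects]
        for score in score_cols:
            for a, z in analyte_z.items():
                results.append(stats.median_regression(
                    subjects[score].to_numpy(), z, covariates=cov,
                    outcome_name=score, analyte_name=a,
                    n_boot=config.stats_n_boot, seed=stage_seeds["stats"]))
        table = stats.regression_table(results, q=config.fdr_q)
        table.to_csv(out / "regression_results.csv", index=False)
        record("stats", n_models=len(results), fdr_q=config.fdr_q)
    except Exception as e:
        raise PipelineError("stats", str(e)) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
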