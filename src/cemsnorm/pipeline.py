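"""End-to-end workflow orchestration.

`run_synthetic_pipeline` exercises every stage on a generated cohort with
known truth: the clean (upstream-aligned) matrix of the discovery samples
stands in for the reference runs, the stable set is selected on it, the
warped per-sample peak lists are then matched / aligned / normalized
against that reference, and the discovery statistics, classifier and
blinded validation scoring run on the stacked normalized matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import biomarkers, qc, simulate, stable
from .config import PipelineConfig
from .datatypes import FeatureMatrix, ReferenceDataset
from .io import save_reference
from .processing import process_cohort
from .simulate import SimulationConfig


def _write_report(out_dir: Path, name: str, payload: dict,
                  cfg: PipelineConfig) -> None:
    payload = {**payload, **cfg.provenance()}
    (out_dir / name).write_text(json.dumps(payload, indent=1, default=str))


def run_synthetic_pipeline(cfg: PipelineConfig,
                           sim_cfg: Optional[SimulationConfig] = None,
                           n_validation: tuple[int, int] = (7, 17),
                           out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Simulate, build reference, select standards, normalize, test, score.

    ``sim_cfg`` group sizes are the discovery cohort; ``n_validation``
    control/disease samples are generated on top and scored blinded.
    Returns a report dict; artifacts are written when ``out_dir`` is given.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig(seed=cfg.seed)
    full = SimulationConfig(**{**sim_cfg.__dict__,
                               "n_control": sim_cfg.n_control + n_validation[0],
                               "n_disease": sim_cfg.n_disease + n_validation[1]})
    cohort = simulate.generate_cohort(full)
    groups = cohort.matrix.groups
    ctrl = [s for s in cohort.matrix.sample_ids if groups[s] == "control"]
    dis = [s for s in cohort.matrix.sample_ids if groups[s] == "disease"]
    disc_ids = ctrl[:sim_cfg.n_control] + dis[:sim_cfg.n_disease]
    valid_ids = ctrl[sim_cfg.n_control:] + dis[sim_cfg.n_disease:]

    # reference: the clean, upstream-aligned discovery matrix
    ref_matrix = cohort.matrix.subset_samples(disc_ids)
    stable_set = stable.select_stable_features(
        ref_matrix, method=cfg.stable_method, n_candidates=cfg.n_candidates,
        start=cfg.start_size)
    ref = ReferenceDataset(matrix=ref_matrix, stable=stable_set.features,
                           mt_window=(cfg.new_mt_lo, cfg.new_mt_hi),
                           provenance=cfg.provenance())

    pls = {pl.sample_id: pl for pl in cohort.peak_lists}
    disc_fm, disc_reports = process_cohort(
        [pls[s] for s in disc_ids], ref, groups=groups.loc[disc_ids],
        tol=cfg.mass_tol, mt_gate=cfg.mt_gate,
        iterations=cfg.alignment_iterations, span=cfg.loess_span,
        mt_window=(cfg.new_mt_lo, cfg.new_mt_hi))
    valid_fm, valid_reports = process_cohort(
        [pls[s] for s in valid_ids], ref, groups=groups.loc[valid_ids],
        tol=cfg.mass_tol, mt_gate=cfg.mt_gate,
        iterations=cfg.alignment_iterations, span=cfg.loess_span,
        mt_window=(cfg.new_mt_lo, cfg.new_mt_hi))

    # discovery statistics
    filtered = biomarkers.group_presence_filter(disc_fm,
                                                cfg.group_min_presence)
    pmv = qc.classify_pmv(filtered)
    pmv_sum = qc.pmv_summary(pmv)
    imputed = biomarkers.impute_missing(filtered, mode="discovery")
    diff = biomarkers.wilcoxon_bh(imputed, positive_label="disease",
                                  alpha=cfg.bh_alpha)
    sig_ids = list(diff.index[diff["significant"]])
    report: dict = {
        "n_reference_features": int(ref_matrix.n_features),
        "n_stable": stable_set.size,
        "stable_m_value": stable_set.m_value,
        "n_filtered_features": int(filtered.n_features),
        "n_significant": len(sig_ids),
        "pmv_summary": pmv_sum["count"].to_dict(),
        "stable_recovery": simulate.set_recovery(stable_set.features,
                                                 cohort.truth.stable_ids),
        "differential_recovery": simulate.set_recovery(
            sig_ids, cohort.truth.differential_ids),
    }

    if sig_ids:
        model = biomarkers.train_classifier(
            imputed.subset_features(sig_ids), positive_label="disease",
            C=cfg.svm_c, gamma=cfg.svm_gamma)
        vx = valid_fm.subset_features(sig_ids)
        vimp = biomarkers.impute_missing(
            vx, mode="validation",
            discovery_means=model.imputation_means)
        scored = biomarkers.score_samples(model, vimp)
        metrics = biomarkers.evaluate_predictions(
            scored, groups.loc[valid_ids], positive_label="disease",
            seed=cfg.seed)
        report["validation"] = metrics
    else:
        model, scored = None, None
        report["validation"] = None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_reference(ref, out_dir / "reference.zip")
        (out_dir / "stable.json").write_text(json.dumps({
            "features": stable_set.features,
            "m_value": stable_set.m_value,
            "trace": stable_set.trace}, indent=1))
        diff.to_csv(out_dir / "differential.tsv", sep="\t")
        if model is not None:
            (out_dir / "model.json").write_text(
                json.dumps(model.to_dict(), indent=1))
            scored.to_csv(out_dir / "validation_scores.tsv", sep="\t")
        _write_report(out_dir, "pipeline_report.json", report, cfg)
    return report
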