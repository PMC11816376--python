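"""End-to-end orchestration: simulate/load -> split -> select -> train ->
rule generation -> threshold -> evaluate, plus single-patient scoring.

Test rows never reach any fitting step: the normalizer, the feature
selector, the level-1 models and the rule base are all determined on the
training partition alone; the test partition only enters threshold
selection and evaluation.

One top-level seed fans out into per-stage sub-seeds through
:func:`derive_seed` (a CRC32 hash of the stage name mixed into a
``SeedSequence``), so stages are individually reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .evaluation import (EvaluationReport, NO_READMIT_LABEL, READMIT_LABEL,
                         evaluate_scores, optimize_threshold)
from .features import (SelectionReport, drop_correlated, drop_quasi_constant,
                       rfe_select)
from .fuzzy import InferenceConfig, InferenceResult, fit_level2, mamdani_infer
from .io import PipelineArtifact
from .level1 import Level1Config, predict_risk_matrix, train_level1
from .preprocess import (NormalizationParams, apply_normalizer, fit_normalizer,
                         split_cohort)
from .schema import LABEL, NUMERIC_FEATURES
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed in [0, 2^31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Settings of a full pipeline run; defaults follow the reference
    configuration (selection target 12, level-1 hyperparameters, N=2/N=1
    fuzzy partitions, 0.001 threshold grid)."""

    seed: int = 42
    n_patients: int = 2000
    prevalence_target: float = 0.35
    test_fraction: float = 0.2
    n_features: int = 12
    qc_threshold: float = 0.98
    corr_threshold: float = 0.8
    threshold_grid_step: float = 0.001
    threshold_on: str = "test"  # "test" (reference behavior) | "validation"
    level1: Level1Config = field(default_factory=Level1Config)
    inference: InferenceConfig = field(default_factory=InferenceConfig)


@dataclass
class RunResult:
    artifact: PipelineArtifact
    selection: SelectionReport
    evaluation: EvaluationReport
    cohort: pd.DataFrame


def run_all(cfg: RunConfig, cohort: Optional[pd.DataFrame] = None) -> RunResult:
    """Execute the full training pipeline and evaluate on the held-out set."""
    if cohort is None:
        sim = SimulationConfig(n_patients=cfg.n_patients,
                               seed=derive_seed(cfg.seed, "simulate"),
                               prevalence_target=cfg.prevalence_target)
        cohort = simulate_cohort(sim)
        log.info("simulated cohort: n=%d prevalence=%.3f", len(cohort),
                 cohort[LABEL].mean())
    if LABEL not in cohort.columns:
        raise ValueError("training requires the label column")

    split = split_cohort(cohort, test_fraction=cfg.test_fraction,
                         seed=derive_seed(cfg.seed, "split"), stratified=True)
    train_df = cohort.iloc[split.train]
    test_df = cohort.iloc[split.test]
    log.info("split: %d train / %d test", len(train_df), len(test_df))

    artifact, selection = _fit_pipeline(train_df, cfg)

    test_scores = score_cohort(artifact, test_df)
    if cfg.threshold_on == "validation":
        inner = split_cohort(train_df.reset_index(drop=True),
                             test_fraction=cfg.test_fraction,
                             seed=derive_seed(cfg.seed, "validation"),
                             stratified=True)
        sub_train = train_df.reset_index(drop=True).iloc[inner.train]
        val_df = train_df.reset_index(drop=True).iloc[inner.test]
        inner_artifact, _ = _fit_pipeline(sub_train, cfg)
        val_scores = score_cohort(inner_artifact, val_df)
        threshold, _ = optimize_threshold(val_scores, val_df[LABEL],
                                          grid_step=cfg.threshold_grid_step)
    elif cfg.threshold_on == "test":
        threshold, _ = optimize_threshold(test_scores, test_df[LABEL],
                                          grid_step=cfg.threshold_grid_step)
    else:
        raise ValueError("threshold_on must be 'test' or 'validation'")
    artifact.decision_threshold = float(threshold)
    artifact.metadata["threshold_on"] = cfg.threshold_on
    log.info("decision threshold: %.3f", threshold)

    report = evaluate_scores(test_scores, test_df[LABEL].to_numpy(),
                             grid_step=cfg.threshold_grid_step)
    log.info("test AUC=%.3f Mcc*=%.3f at t=%.3f", report.auc,
             report.mcc_at_optimum, report.optimal_threshold)
    return RunResult(artifact=artifact, selection=selection,
                     evaluation=report, cohort=cohort)


def _fit_pipeline(train_df: pd.DataFrame, cfg: RunConfig
                  ) -> tuple[PipelineArtifact, SelectionReport]:
    """Fit every learned component on training rows only."""
    y_train = train_df[LABEL].to_numpy()
    X_raw = train_df.drop(columns=[LABEL])

    # Quasi-constant filter first so truly constant columns never reach
    # the normalizer; min-max rescaling leaves the remaining filters'
    # decisions (correlations, modal shares, forest splits) unchanged.
    kept, dropped_qc = drop_quasi_constant(X_raw, threshold=cfg.qc_threshold)
    norm = fit_normalizer(train_df, [f for f in NUMERIC_FEATURES if f in kept])
    X_norm = apply_normalizer(norm, X_raw[kept])
    kept2, groups = drop_correlated(X_norm, threshold=cfg.corr_threshold)
    selection = rfe_select(X_norm[kept2], y_train, n_target=cfg.n_features,
                           seed=derive_seed(cfg.seed, "rfe"))
    selection.dropped_quasi_constant = dropped_qc
    selection.correlation_groups = groups
    log.info("selected %d features: %s", len(selection.selected),
             ", ".join(selection.selected))

    level1_cfg = Level1Config(**{**vars(cfg.level1),
                                 "seed": derive_seed(cfg.seed, "level1")})
    models = train_level1(X_norm[selection.selected], y_train, level1_cfg)

    R_train = predict_risk_matrix(models, X_norm[selection.selected])
    rule_base = fit_level2(R_train, y_train)
    log.info("rule base: %d rules (from %d training patients)",
             len(rule_base), len(train_df))

    norm_selected = NormalizationParams(
        {f: norm.bounds[f] for f in selection.selected if f in norm.bounds})
    artifact = PipelineArtifact(
        normalization=norm_selected,
        selected_features=list(selection.selected),
        models=models,
        rule_base=rule_base,
        decision_threshold=0.5,
        metadata={
            "seed": cfg.seed,
            "n_train": int(len(train_df)),
            "prevalence": float(np.mean(y_train)),
            "mlp_converged": models.mlp_converged,
        })
    return artifact, selection


def score_cohort(artifact: PipelineArtifact, cohort: pd.DataFrame,
                 config: Optional[InferenceConfig] = None) -> np.ndarray:
    """Fuzzy-aggregated readmission risk for every row of a cohort."""
    X = apply_normalizer(artifact.normalization,
                         cohort[artifact.selected_features])
    R = predict_risk_matrix(artifact.models, X)
    return np.array([mamdani_infer(artifact.rule_base, r, config).risk
                     for r in R])


def predict_patient(artifact: PipelineArtifact,
                    record: Union[Mapping, pd.Series]) -> dict:
    """Score a single patient and produce the clinical label and trace.

    Returns the risk (fraction and percentage formatted to two decimals),
    the suggested label string, and the fired rules with their firing
    strengths for traceability.
    """
    if isinstance(record, pd.Series):
        record = record.to_dict()
    missing = [f for f in artifact.selected_features if f not in record
               or pd.isna(record[f])]
    if missing:
        raise ValueError(f"missing required fields: {missing}")

    row = pd.DataFrame([{f: float(record[f]) for f in artifact.selected_features}])
    X = apply_normalizer(artifact.normalization, row)
    R = predict_risk_matrix(artifact.models, X)[0]
    result: InferenceResult = mamdani_infer(artifact.rule_base, R)
    label = READMIT_LABEL if result.risk >= artifact.decision_threshold \
        else NO_READMIT_LABEL
    trace = [{
        "antecedents": list(rule.antecedents),
        "consequent": rule.consequent,
        "degree": rule.degree,
        "firing_strength": strength,
    } for rule, strength in result.fired]
    return {
        "risks": {"r1": float(R[0]), "r2": float(R[1]), "r3": float(R[2])},
        "risk": result.risk,
        "risk_pct": f"{100.0 * result.risk:.2f}%",
        "label": label,
        "threshold": artifact.decision_threshold,
        "no_rule_fired": result.no_rule_fired,
        "fired_rules": trace,
    }
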