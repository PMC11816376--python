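"""Cohort CSV I/O and trained-pipeline artifact serialization.

Cohorts are plain CSV files with a header row of canonical snake_case
column names (verbose clinical-table headers are accepted and mapped).
Missing data are handled by complete-case analysis: any row with a
missing value in a required column is dropped and counted, never imputed.

A trained pipeline is a single JSON artifact holding the normalization
bounds, selected features, the three level-1 model payloads, the fuzzy
rule base and partitions, the decision threshold, and training metadata.
All numeric fields are serialized at full double precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import schema as _schema
from .fuzzy import RuleBase
from .level1 import Level1Models, models_to_payload, payload_to_models
from .preprocess import NormalizationParams
from .schema import (CohortValidationError, FEATURE_NAMES, HEADER_ALIASES,
                     LABEL, SCHEMA_VERSION, SchemaError, check_value)

PathLike = Union[str, os.PathLike]


class ArtifactError(ValueError):
    """The artifact file is corrupted, truncated or incomplete."""


def read_cohort(path: PathLike, require_label: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rows with any missing value in a required column are dropped; the
    count is stored in ``frame.attrs["n_dropped"]``.  Unknown or missing
    columns raise :class:`SchemaError`; out-of-range values raise
    :class:`CohortValidationError` naming the first offending row/field.
    """
    frame = pd.read_csv(path)
    frame = frame.rename(columns=HEADER_ALIASES)

    unknown = [c for c in frame.columns if c not in FEATURE_NAMES + (LABEL,)]
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if require_label and LABEL not in frame.columns:
        missing.append(LABEL)
    if unknown or missing:
        parts = []
        if unknown:
            parts.append(f"unknown columns: {unknown}")
        if missing:
            parts.append(f"missing columns: {missing}")
        raise SchemaError("; ".join(parts))

    required = list(frame.columns)
    complete = frame.dropna(subset=required)
    n_dropped = len(frame) - len(complete)

    for name in complete.columns:
        values = complete[name].to_numpy()
        for row, value in zip(complete.index, values):
            msg = check_value(name, value)
            if msg is not None:
                raise CohortValidationError(f"row {row}: {msg}")

    out = complete.reset_index(drop=True)
    out.attrs["schema_version"] = SCHEMA_VERSION
    out.attrs["n_dropped"] = n_dropped
    return out


def write_cohort(cohort: pd.DataFrame, path: PathLike) -> PathLike:
    """Write a validated cohort CSV in canonical column order."""
    columns = [c for c in FEATURE_NAMES if c in cohort.columns]
    if LABEL in cohort.columns:
        columns.append(LABEL)
    cohort[columns].to_csv(path, index=False)
    return path


@dataclass
class PipelineArtifact:
    """Everything needed to score a new patient with a trained system."""

    normalization: NormalizationParams
    selected_features: list[str]
    models: Level1Models
    rule_base: RuleBase
    decision_threshold: float
    metadata: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ArtifactError("selected_features must be non-empty")
        bad = [f for f in self.selected_features if f not in FEATURE_NAMES]
        if bad:
            raise ArtifactError(f"selected features outside schema: {bad}")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ArtifactError("decision_threshold must lie in [0, 1]")


def save_artifact(artifact: PipelineArtifact, path: PathLike) -> PathLike:
    """Serialize the trained pipeline to a JSON file (full float precision)."""
    payload = {
        "schema_version": artifact.schema_version,
        "normalization": artifact.normalization.to_dict(),
        "selected_features": list(artifact.selected_features),
        "level1_models": models_to_payload(artifact.models),
        "rule_base": artifact.rule_base.to_dict(),
        "decision_threshold": artifact.decision_threshold,
        "metadata": artifact.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    return path


def load_artifact(path: PathLike) -> PipelineArtifact:
    """Load a pipeline artifact; corrupted or partial JSON raises
    :class:`ArtifactError` and never yields a partial object."""
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ArtifactError(f"cannot parse artifact {path}: {exc}") from exc
    try:
        return PipelineArtifact(
            schema_version=payload["schema_version"],
            normalization=NormalizationParams.from_dict(payload["normalization"]),
            selected_features=list(payload["selected_features"]),
            models=payload_to_models(payload["level1_models"]),
            rule_base=RuleBase.from_dict(payload["rule_base"]),
            decision_threshold=float(payload["decision_threshold"]),
            metadata=dict(payload.get("metadata", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ArtifactError):
            raise
        raise ArtifactError(f"incomplete artifact {path}: {exc}") from exc
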