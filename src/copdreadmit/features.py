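"""Two-step feature selection: filters, then recursive elimination.

The sequence is fixed: (1) drop quasi-constant variables (modal value in
at least 98% of rows), (2) group variables whose pairwise Pearson
correlation exceeds 0.8 in absolute value and keep one per group, then
(3) recursive feature elimination (RFE) with a random-forest importance
ranker, removing one variable per refit until the target count (default
12) remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE


@dataclass(frozen=True)
class CorrelationGroup:
    """A connected component of the |r| > threshold graph."""

    members: tuple[str, ...]
    kept: str


@dataclass
class SelectionReport:
    """Outcome of the full selection sequence."""

    dropped_quasi_constant: list[str] = field(default_factory=list)
    correlation_groups: list[CorrelationGroup] = field(default_factory=list)
    rfe_ranking: list[tuple[str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_quasi_constant": list(self.dropped_quasi_constant),
            "correlation_groups": [
                {"members": list(g.members), "kept": g.kept}
                for g in self.correlation_groups
            ],
            "rfe_ranking": [[name, imp] for name, imp in self.rfe_ranking],
            "selected": list(self.selected),
        }


def drop_quasi_constant(X: pd.DataFrame, threshold: float = 0.98
                        ) -> tuple[list[str], list[str]]:
    """Return (kept, dropped); a column is dropped iff its modal value
    occurs in at least ``threshold`` of the rows."""
    kept, dropped = [], []
    n = len(X)
    for name in X.columns:
        modal_share = X[name].value_counts().iloc[0] / n
        (dropped if modal_share >= threshold else kept).append(name)
    return kept, dropped


def drop_correlated(X: pd.DataFrame, threshold: float = 0.8
                    ) -> tuple[list[str], list[CorrelationGroup]]:
    """Group columns with |Pearson r| > threshold; keep one per group.

    Groups are connected components of the correlation graph; the kept
    member is the earliest in column (schema) order.  Binary columns take
    part as-is (point-biserial correlation is Pearson on 0/1 codes).
    """
    names = list(X.columns)
    mat = X.to_numpy(dtype=float)
    if np.any(mat.std(axis=0) == 0):
        bad = [n for n, s in zip(names, mat.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance columns {bad}; apply drop_quasi_constant first")
    corr = np.corrcoef(mat, rowvar=False)
    adj = (np.abs(corr) > threshold)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)

    kept: list[str] = []
    groups: list[CorrelationGroup] = []
    for comp in np.unique(labels):
        members = [names[i] for i in np.flatnonzero(labels == comp)]
        kept.append(members[0])
        if len(members) > 1:
            groups.append(CorrelationGroup(members=tuple(members), kept=members[0]))
    kept.sort(key=names.index)
    return kept, groups


def _default_ranker(seed: Optional[int]) -> RandomForestClassifier:
    # Forest ranker: 100 trees, Gini impurity, unbounded depth,
    # min_samples_split=2 — the same configuration as the level-1 forest.
    return RandomForestClassifier(
        n_estimators=100, criterion="gini", max_depth=None,
        min_samples_split=2, random_state=seed, n_jobs=1)


def rfe_select(X: pd.DataFrame, y: Sequence[int], n_target: int = 12,
               seed: Optional[int] = 42,
               ranker: Optional[RandomForestClassifier] = None) -> SelectionReport:
    """Recursive feature elimination down to ``n_target`` features.

    One feature (the least important by mean impurity decrease) is removed
    per refit.  The report lists the survivors ordered by importance from
    a final refit on the selected set.
    """
    p = X.shape[1]
    if n_target > p:
        raise ValueError(f"n_target={n_target} exceeds available features ({p})")
    if ranker is None:
        ranker = _default_ranker(seed)

    if n_target == p:
        selected = list(X.columns)
    else:
        rfe = RFE(estimator=ranker, n_features_to_select=n_target, step=1)
        rfe.fit(X.to_numpy(dtype=float), np.asarray(y))
        selected = [name for name, keep in zip(X.columns, rfe.support_) if keep]

    final = ranker
    final.fit(X[selected].to_numpy(dtype=float), np.asarray(y))
    order = np.argsort(-final.feature_importances_, kind="stable")
    ranking = [(selected[i], float(final.feature_importances_[i])) for i in order]
    return SelectionReport(rfe_ranking=ranking, selected=[name for name, _ in ranking])


def select_features(X: pd.DataFrame, y: Sequence[int], n_target: int = 12,
                    qc_threshold: float = 0.98, corr_threshold: float = 0.8,
                    seed: Optional[int] = 42) -> SelectionReport:
    """Run the full quasi-constant -> correlation -> RFE sequence."""
    kept, dropped = drop_quasi_constant(X, threshold=qc_threshold)
    kept2, groups = drop_correlated(X[kept], threshold=corr_threshold)
    report = rfe_select(X[kept2], y, n_target=n_target, seed=seed)
    report.dropped_quasi_constant = dropped
    report.correlation_groups = groups
    return report
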