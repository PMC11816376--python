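"""Wang-Mendel rule generation and Mamdani inference over (R1, R2, R3).

This is the aggregation level of the system.  Each level-1 risk lives on
[0, 1] and is covered by a uniform triangular partition of 2N+1 sections
(N = 2 for the three antecedents, hence 5 sections; N = 1 for the
consequent, hence 3, with the central section suppressed because the
training label is binary).  Adjacent triangles overlap so that at every
point the active memberships sum to one (a partition of unity).

Rule learning follows Wang and Mendel's construction: one candidate rule
per training patient, each variable assigned to its maximum-membership
section; conflicts between rules sharing an antecedent tuple are resolved
by a degree coefficient, the product of the memberships of the generating
patient, keeping the single highest-degree rule.

Inference is Mamdani-type: rule firing strength is the minimum of the
antecedent memberships at the input, each rule's consequent set is
clipped at its firing strength, the clipped sets are aggregated pointwise
by maximum, and the crisp risk is the centroid of the aggregate on a
uniform grid over [0, 1].  AND, implication and defuzzification operators
are configurable (product AND, scaled implication and mean-of-maxima are
provided as alternates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

_ANTECEDENT_LABELS_5 = ("very_low", "low", "medium", "high", "very_high")
_CONSEQUENT_LABELS_3 = ("low", "medium", "high")


@dataclass(frozen=True)
class FuzzyPartition:
    """Uniform triangular partition of a closed interval into 2N+1 sections.

    Peaks sit at ``lo + k*(hi-lo)/(2N)`` for k = 0..2N; the end sections
    are half-triangles with membership 1 at the domain endpoints.
    ``suppressed`` lists section indices excluded from rule consequents
    (the central consequent section here, since the label is binary).
    """

    lo: float
    hi: float
    n_param: int
    suppressed: frozenset[int] = frozenset()
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_param < 1:
            raise ValueError("N must be >= 1")
        if self.hi <= self.lo:
            raise ValueError("domain must satisfy hi > lo")
        if any(not 0 <= s < self.n_sections for s in self.suppressed):
            raise ValueError("suppressed index out of range")
        if self.labels and len(self.labels) != self.n_sections:
            raise ValueError("label count must equal section count")

    @property
    def n_sections(self) -> int:
        return 2 * self.n_param + 1

    @property
    def peaks(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_sections)

    @property
    def half_width(self) -> float:
        return (self.hi - self.lo) / (2 * self.n_param)

    def section_label(self, idx: int) -> str:
        if self.labels:
            return self.labels[idx]
        return f"S{idx}"

    def membership(self, x: float) -> np.ndarray:
        """Membership degree of ``x`` in every section.

        At most two entries are nonzero and they sum to one.  ``x`` must
        lie inside the domain; callers clip beforehand.
        """
        if not self.lo <= x <= self.hi:
            raise ValueError(f"x={x} outside domain [{self.lo}, {self.hi}]")
        return np.maximum(0.0, 1.0 - np.abs(x - self.peaks) / self.half_width)

    def membership_grid(self, xs: np.ndarray) -> np.ndarray:
        """Membership of each grid point in each section: (len(xs), 2N+1)."""
        xs = np.asarray(xs, dtype=float)
        return np.maximum(
            0.0, 1.0 - np.abs(xs[:, None] - self.peaks[None, :]) / self.half_width)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "n_param": self.n_param,
                "suppressed": sorted(self.suppressed), "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyPartition":
        return cls(lo=float(d["lo"]), hi=float(d["hi"]), n_param=int(d["n_param"]),
                   suppressed=frozenset(int(s) for s in d["suppressed"]),
                   labels=tuple(d["labels"]))


def build_partition(lo: float, hi: float, n: int,
                    suppressed: Iterable[int] = ()) -> FuzzyPartition:
    """Construct a 2N+1-section triangular partition of [lo, hi]."""
    n_sections = 2 * n + 1
    if n_sections == 5:
        labels: tuple[str, ...] = _ANTECEDENT_LABELS_5
    elif n_sections == 3:
        labels = _CONSEQUENT_LABELS_3
    else:
        labels = tuple(f"S{k}" for k in range(n_sections))
    return FuzzyPartition(lo=lo, hi=hi, n_param=n,
                          suppressed=frozenset(suppressed), labels=labels)


def default_antecedent_partitions() -> tuple[FuzzyPartition, ...]:
    """Three N=2 partitions of [0, 1], one per level-1 risk."""
    return tuple(build_partition(0.0, 1.0, 2) for _ in range(3))


def default_consequent_partition() -> FuzzyPartition:
    """N=1 partition of [0, 1] with the central section suppressed."""
    return build_partition(0.0, 1.0, 1, suppressed=(1,))


@dataclass(frozen=True)
class FuzzyRule:
    """IF R1 is A[0] AND R2 is A[1] AND R3 is A[2] THEN risk is C.

    ``degree`` is the Wang-Mendel conflict-resolution coefficient: the
    product of the memberships of the training patient that generated the
    rule.  ``origin`` is that patient's training-row index (None for
    expert-authored rules).
    """

    antecedents: tuple[int, int, int]
    consequent: int
    degree: float
    origin: Optional[int] = None

    def to_dict(self) -> dict:
        return {"ant": list(self.antecedents), "cons": self.consequent,
                "degree": self.degree, "origin": self.origin}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyRule":
        return cls(antecedents=tuple(int(a) for a in d["ant"]),
                   consequent=int(d["cons"]), degree=float(d["degree"]),
                   origin=None if d.get("origin") is None else int(d["origin"]))


@dataclass
class RuleBase:
    """Conflict-free rule collection plus its partitions.

    ``prevalence`` (training outcome rate) is the fallback output when an
    input fires no stored rule.
    """

    rules: list[FuzzyRule]
    antecedent_partitions: tuple[FuzzyPartition, ...] = field(
        default_factory=default_antecedent_partitions)
    consequent_partition: FuzzyPartition = field(
        default_factory=default_consequent_partition)
    prevalence: Optional[float] = None

    def __len__(self) -> int:
        return len(self.rules)

    def validate(self) -> None:
        seen = set()
        for rule in self.rules:
            if rule.antecedents in seen:
                raise ValueError(f"duplicate antecedents {rule.antecedents}")
            seen.add(rule.antecedents)
            for idx, part in zip(rule.antecedents, self.antecedent_partitions):
                if not 0 <= idx < part.n_sections:
                    raise ValueError(f"antecedent index {idx} out of range")
            if rule.consequent in self.consequent_partition.suppressed:
                raise ValueError("rule consequent is a suppressed section")
            if not 0 <= rule.consequent < self.consequent_partition.n_sections:
                raise ValueError(f"consequent index {rule.consequent} out of range")

    def describe(self) -> str:
        """Human-readable rule listing, one IF/THEN line per rule."""
        lines = []
        for rule in sorted(self.rules, key=lambda r: -r.degree):
            ants = " AND ".join(
                f"R{j + 1} is {part.section_label(idx).upper()}"
                for j, (idx, part) in enumerate(
                    zip(rule.antecedents, self.antecedent_partitions)))
            cons = self.consequent_partition.section_label(rule.consequent).upper()
            lines.append(
                f"IF {ants} THEN readmission risk is {cons} "
                f"(degree {rule.degree:.2f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "antecedent_partitions": [p.to_dict() for p in self.antecedent_partitions],
            "consequent_partition": self.consequent_partition.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "prevalence": self.prevalence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        rb = cls(
            rules=[FuzzyRule.from_dict(r) for r in d["rules"]],
            antecedent_partitions=tuple(
                FuzzyPartition.from_dict(p) for p in d["antecedent_partitions"]),
            consequent_partition=FuzzyPartition.from_dict(d["consequent_partition"]),
            prevalence=None if d.get("prevalence") is None else float(d["prevalence"]),
        )
        rb.validate()
        return rb


def generate_candidate_rules(
        R: np.ndarray, y: Sequence[int],
        antecedent_partitions: Optional[Sequence[FuzzyPartition]] = None,
        consequent_partition: Optional[FuzzyPartition] = None,
) -> list[FuzzyRule]:
    """One candidate rule per training patient.

    Each risk is assigned to its maximum-membership section (ties broken
    toward the lower index); the consequent is the non-suppressed section
    with maximum membership at the binary label (section 0 for y=0,
    section 2 for y=1).  The rule degree is the product of all those
    memberships — the consequent factor is exactly 1 at the domain
    endpoints, but is included for fidelity to the general construction.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("R must be an (n, k) risk matrix")
    parts = tuple(antecedent_partitions) if antecedent_partitions is not None \
        else tuple(build_partition(0.0, 1.0, 2) for _ in range(R.shape[1]))
    cons_part = consequent_partition or default_consequent_partition()
    if R.shape[1] != len(parts):
        raise ValueError("risk matrix width must match antecedent partitions")
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    allowed = np.array([k for k in range(cons_part.n_sections)
                        if k not in cons_part.suppressed])
    rules: list[FuzzyRule] = []
    for i in range(R.shape[0]):
        ant: list[int] = []
        degree = 1.0
        for j, part in enumerate(parts):
            mu = part.membership(R[i, j])
            k = int(np.argmax(mu))  # argmax takes the lowest index on ties
            ant.append(k)
            degree *= float(mu[k])
        mu_cons = cons_part.membership(float(y[i]))[allowed]
        k_cons = int(allowed[np.argmax(mu_cons)])
        degree *= float(np.max(mu_cons))
        rules.append(FuzzyRule(antecedents=tuple(ant), consequent=k_cons,
                               degree=degree, origin=i))
    return rules


def resolve_conflicts(
        candidates: Sequence[FuzzyRule],
        antecedent_partitions: Optional[Sequence[FuzzyPartition]] = None,
        consequent_partition: Optional[FuzzyPartition] = None,
        prevalence: Optional[float] = None) -> RuleBase:
    """Keep the single highest-degree rule per antecedent tuple.

    Degree ties break toward the smaller origin row index (expert rules,
    with origin None, lose ties against data-generated rules).
    """
    if not candidates:
        raise ValueError("candidate rule list is empty")
    best: dict[tuple[int, ...], FuzzyRule] = {}
    for rule in candidates:
        cur = best.get(rule.antecedents)
        if cur is None or rule.degree > cur.degree or (
                rule.degree == cur.degree
                and _origin_key(rule) < _origin_key(cur)):
            best[rule.antecedents] = rule
    rb = RuleBase(
        rules=sorted(best.values(), key=lambda r: r.antecedents),
        antecedent_partitions=tuple(antecedent_partitions)
        if antecedent_partitions is not None else default_antecedent_partitions(),
        consequent_partition=consequent_partition or default_consequent_partition(),
        prevalence=prevalence)
    rb.validate()
    return rb


def _origin_key(rule: FuzzyRule) -> float:
    return float("inf") if rule.origin is None else rule.origin


def merge_expert_rules(base: RuleBase, expert: Sequence[FuzzyRule]) -> RuleBase:
    """Merge expert-authored rules into a learned base.

    Interface stub for the optional knowledge-combination step: conflicts
    resolve by degree exactly as for data-generated rules.  Not exercised
    by the trained system (no expert rules are injected here).
    """
    for rule in expert:
        for idx, part in zip(rule.antecedents, base.antecedent_partitions):
            if not 0 <= idx < part.n_sections:
                raise ValueError(f"expert rule antecedent {idx} out of range")
        if rule.consequent in base.consequent_partition.suppressed or \
                not 0 <= rule.consequent < base.consequent_partition.n_sections:
            raise ValueError("expert rule consequent invalid")
    return resolve_conflicts(
        list(base.rules) + list(expert),
        antecedent_partitions=base.antecedent_partitions,
        consequent_partition=base.consequent_partition,
        prevalence=base.prevalence)


@dataclass(frozen=True)
class InferenceConfig:
    """Operator choices for Mamdani inference.

    Defaults are the canonical configuration: min AND, clipped
    implication, max aggregation, centroid defuzzification on a
    1001-point grid (grid resolution moves the output by < 1e-3).
    """

    and_op: str = "min"           # "min" | "product"
    implication: str = "clip"     # "clip" | "scale"
    defuzzification: str = "centroid"  # "centroid" | "mom"
    resolution: int = 1001


@dataclass(frozen=True)
class InferenceResult:
    """Crisp risk plus the fired-rule trace for explainability."""

    risk: float
    no_rule_fired: bool
    fired: tuple[tuple[FuzzyRule, float], ...]

    def __float__(self) -> float:
        return self.risk


def mamdani_infer(rb: RuleBase, r: Sequence[float],
                  config: Optional[InferenceConfig] = None) -> InferenceResult:
    """Mamdani inference of the readmission risk for one risk triple.

    If no stored rule fires (the input's antecedent region is uncovered),
    the training prevalence recorded in the rule base is returned with
    the ``no_rule_fired`` flag set.
    """
    cfg = config or InferenceConfig()
    if not rb.rules:
        raise ValueError("rule base is empty")
    r = np.asarray(r, dtype=float)
    if r.shape != (len(rb.antecedent_partitions),):
        raise ValueError("input must supply one value per antecedent")
    if np.any(r < 0.0) or np.any(r > 1.0):
        raise ValueError("risk inputs must lie in [0, 1]; clip upstream")

    memberships = [part.membership(val)
                   for part, val in zip(rb.antecedent_partitions, r)]
    fired: list[tuple[FuzzyRule, float]] = []
    for rule in rb.rules:
        mus = [memberships[j][idx] for j, idx in enumerate(rule.antecedents)]
        strength = float(min(mus)) if cfg.and_op == "min" else float(np.prod(mus))
        if strength > 0.0:
            fired.append((rule, strength))

    if not fired:
        fallback = rb.prevalence if rb.prevalence is not None else 0.5
        return InferenceResult(risk=float(fallback), no_rule_fired=True, fired=())

    lo, hi = rb.consequent_partition.lo, rb.consequent_partition.hi
    grid = np.linspace(lo, hi, cfg.resolution)
    cons_mu = rb.consequent_partition.membership_grid(grid)
    agg = np.zeros_like(grid)
    for rule, strength in fired:
        mu = cons_mu[:, rule.consequent]
        clipped = np.minimum(mu, strength) if cfg.implication == "clip" \
            else mu * strength
        np.maximum(agg, clipped, out=agg)

    if cfg.defuzzification == "centroid":
        total = agg.sum()
        risk = float((grid * agg).sum() / total)
    elif cfg.defuzzification == "mom":
        peak = agg.max()
        risk = float(grid[np.isclose(agg, peak)].mean())
    else:
        raise ValueError(f"unknown defuzzification {cfg.defuzzification!r}")
    return InferenceResult(risk=risk, no_rule_fired=False, fired=tuple(fired))


def fit_level2(R_train: np.ndarray, y_train: Sequence[int],
               antecedent_n: int = 2, consequent_n: int = 1) -> RuleBase:
    """Learn the rule base from level-1 risks on training rows only.

    Composition of partition construction, candidate generation and
    conflict resolution; the training outcome rate is recorded as the
    no-rule-fired fallback.
    """
    R_train = np.asarray(R_train, dtype=float)
    parts = tuple(build_partition(0.0, 1.0, antecedent_n)
                  for _ in range(R_train.shape[1]))
    cons = build_partition(0.0, 1.0, consequent_n,
                           suppressed=(consequent_n,))
    candidates = generate_candidate_rules(R_train, y_train,
                                          antecedent_partitions=parts,
                                          consequent_partition=cons)
    return resolve_conflicts(candidates, antecedent_partitions=parts,
                             consequent_partition=cons,
                             prevalence=float(np.asarray(y_train).mean()))
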