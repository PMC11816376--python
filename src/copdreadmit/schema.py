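"""Cohort schema for the 90-day AECOPD readmission problem.

The cohort is a flat table of 39 predictor variables — demographic,
clinical and social — plus a binary outcome column ``readmit_90d``
(any COPD rehospitalization within 90 days of index discharge).
Every categorical variable is binary and coded 0/1; counts and scores
carry closed ranges (mMRC 0-4, CAT 0-40, BADL dependency 0-5, IADL
dependency 0-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SCHEMA_VERSION = "copd-readmit-1"

LABEL = "readmit_90d"

BINARY = "binary"
NUMERIC = "numeric"


class SchemaError(ValueError):
    """Column set does not match the cohort schema."""


class CohortValidationError(ValueError):
    """A cell value violates its column's range constraint."""


@dataclass(frozen=True)
class ColumnSpec:
    """One column of the cohort table.

    ``lo``/``hi`` are inclusive bounds; ``hi=None`` means unbounded above.
    Binary columns implicitly have bounds {0, 1}.
    """

    name: str
    kind: str
    lo: float = 0.0
    hi: Optional[float] = None
    description: str = ""


#: The 39 predictor variables, in canonical order.  This order is the
#: deterministic tie-breaker wherever one member of a group must be kept.
SCHEMA: tuple[ColumnSpec, ...] = (
    ColumnSpec("sex", BINARY, description="male 1 / female 0"),
    ColumnSpec("age", NUMERIC, lo=0, description="years"),
    ColumnSpec("bmi", NUMERIC, lo=0, description="body mass index, kg/m^2"),
    ColumnSpec("active_smoker", BINARY),
    ColumnSpec("drug_abuse", BINARY),
    ColumnSpec("high_alcohol", BINARY, description="high alcohol ingestion"),
    ColumnSpec("pyi", NUMERIC, lo=0, description="pack-year index"),
    ColumnSpec("n_prev_hospitalizations", NUMERIC, lo=0,
               description="hospitalizations in the previous year"),
    ColumnSpec("stay_days", NUMERIC, lo=0, description="days of current stay"),
    ColumnSpec("n_positive_cultures", NUMERIC, lo=0,
               description="positive sputum cultures in the previous year"),
    ColumnSpec("pneumococcal_vacc", BINARY),
    ColumnSpec("influenza_vacc", BINARY),
    ColumnSpec("eos_pct", NUMERIC, lo=0, description="% eosinophils in blood"),
    ColumnSpec("fev1_pct", NUMERIC, lo=0, description="% predicted FEV1"),
    ColumnSpec("mmrc", NUMERIC, lo=0, hi=4, description="mMRC dyspnea scale"),
    ColumnSpec("cat", NUMERIC, lo=0, hi=40, description="COPD Assessment Test"),
    ColumnSpec("anemia", BINARY),
    ColumnSpec("cardiovascular_disease", BINARY),
    ColumnSpec("osa", BINARY, description="obstructive sleep apnea"),
    ColumnSpec("depression_anxiety", BINARY),
    ColumnSpec("hypertension", BINARY),
    ColumnSpec("arteriopathy", BINARY),
    ColumnSpec("diabetes", BINARY),
    ColumnSpec("cancer", BINARY),
    ColumnSpec("home_oxygen", BINARY, description="continuous home oxygen therapy"),
    ColumnSpec("home_niv", BINARY, description="home non-invasive ventilation"),
    ColumnSpec("inhaled_corticosteroids", BINARY, description="at discharge"),
    ColumnSpec("residence_urban", BINARY, description="urban 1 / rural 0"),
    ColumnSpec("income_gt_800", BINARY, description="monthly income > 800 EUR"),
    ColumnSpec("employment_retired", BINARY, description="retired 1 / active 0"),
    ColumnSpec("owns_housing", BINARY),
    ColumnSpec("lives_alone", BINARY),
    ColumnSpec("sleeps_alone", BINARY),
    ColumnSpec("caretaker", BINARY, description="caretaker available"),
    ColumnSpec("social_services", BINARY,
               description="social services use in the last 12 months"),
    ColumnSpec("social_relationships", BINARY,
               description="neighbors/friends 1 / none or family only 0"),
    ColumnSpec("drives_car", BINARY),
    ColumnSpec("badl_dep", NUMERIC, lo=0, hi=5,
               description="basic activities of daily living with dependency"),
    ColumnSpec("iadl_dep", NUMERIC, lo=0, hi=8,
               description="instrumental activities with dependency"),
)

LABEL_SPEC = ColumnSpec(LABEL, BINARY, description="readmitted within 90 days")

FEATURE_NAMES: tuple[str, ...] = tuple(c.name for c in SCHEMA)
NUMERIC_FEATURES: tuple[str, ...] = tuple(c.name for c in SCHEMA if c.kind == NUMERIC)
BINARY_FEATURES: tuple[str, ...] = tuple(c.name for c in SCHEMA if c.kind == BINARY)

_SPEC_BY_NAME = {c.name: c for c in SCHEMA} | {LABEL: LABEL_SPEC}


#: Verbose headers, as printed in clinical summary tables, mapped onto the
#: canonical snake_case names so that hand-exported CSVs load unchanged.
HEADER_ALIASES: dict[str, str] = {
    "Sex": "sex",
    "Age": "age",
    "BMI (kg/m^2)": "bmi",
    "BMI": "bmi",
    "Active smoker": "active_smoker",
    "Drug abuse": "drug_abuse",
    "High ingestion of alcohol": "high_alcohol",
    "Pack-year index (PYI)": "pyi",
    "PYI": "pyi",
    "Number of previous hospitalizations in the previous year": "n_prev_hospitalizations",
    "Hospital stay (days)": "stay_days",
    "Days of stay": "stay_days",
    "Number of positive sputum culture within the previous year": "n_positive_cultures",
    "Number of positive cultures": "n_positive_cultures",
    "Pneumococcal vaccination": "pneumococcal_vacc",
    "Influenza vaccination previous year": "influenza_vacc",
    "% Eosinophils": "eos_pct",
    "% EOS": "eos_pct",
    "% FEV1": "fev1_pct",
    "Dyspnea mMRC": "mmrc",
    "CAT score": "cat",
    "CAT": "cat",
    "Anemia": "anemia",
    "Cardiovascular disease": "cardiovascular_disease",
    "Obstructive sleep apnea": "osa",
    "Depression and/or anxiety": "depression_anxiety",
    "Hypertension": "hypertension",
    "Arteriopathy": "arteriopathy",
    "Diabetes mellitus": "diabetes",
    "Cancer": "cancer",
    "Continuous home oxygen therapy": "home_oxygen",
    "Home non-invasive ventilation": "home_niv",
    "Inhaled corticosteroids at discharge": "inhaled_corticosteroids",
    "Place of residence": "residence_urban",
    "Monthly income > EUR 800": "income_gt_800",
    "Employment status": "employment_retired",
    "Housing situation": "owns_housing",
    "Living alone": "lives_alone",
    "Sleeps alone": "sleeps_alone",
    "Caretaker available": "caretaker",
    "Previous use of social services resources in the last 12 months": "social_services",
    "Social relationships": "social_relationships",
    "Drives car": "drives_car",
    "Number of basic activities of daily living with dependency (BADL)": "badl_dep",
    "BADL": "badl_dep",
    "Number of instrumental activities of daily living with dependency (IADL)": "iadl_dep",
    "IADL": "iadl_dep",
    "90-day readmission": LABEL,
}


def column_spec(name: str) -> ColumnSpec:
    """Return the spec for a canonical column name (label included)."""
    try:
        return _SPEC_BY_NAME[name]
    except KeyError:
        raise SchemaError(f"unknown column: {name!r}") from None


def check_value(name: str, value: float) -> Optional[str]:
    """Return an error message if ``value`` violates ``name``'s constraint."""
    spec = column_spec(name)
    if spec.kind == BINARY:
        if value not in (0, 1):
            return f"{name}={value!r} not in {{0, 1}}"
        return None
    if value < spec.lo:
        return f"{name}={value!r} below minimum {spec.lo}"
    if spec.hi is not None and value > spec.hi:
        return f"{name}={value!r} above maximum {spec.hi}"
    return None
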