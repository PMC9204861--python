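"""Cohort selection, determinant releveling, and sepsis identification criteria.

Six sepsis-identification rules are supported: five ICD-9 code-set rules
(Explicit, Angus, Martin, CMS, CDC) and the consensus clinical rule (Sepsis-3:
SOFA >= 2 within the suspected-infection window). The explicit codes 995.92
(severe sepsis) and 785.52 (septic shock) are fixed by the coding system; the
Angus/Martin/CMS/CDC defaults shipped here are deliberately small illustrative
subsets of the published claims-based lists and are meant to be replaced by
user-supplied lists via the criteria config for any substantive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

RACE_CATEGORIES = (
    "Asian",
    "Black or African American",
    "Hispanic or Latino",
    "Other",
    "White",
)
SEX_CATEGORIES = ("Female", "Male")
MARITAL_CATEGORIES = ("Separated", "Significant other", "Single", "Unknown", "Widowed")
INSURANCE_CATEGORIES = ("Government", "Medicaid", "Medicare", "Private", "Self-pay")
LANGUAGE_CATEGORIES = ("English", "Other", "Spanish")

#: determinant name -> enumerated category set, in reporting order
DETERMINANT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "race": RACE_CATEGORIES,
    "sex": SEX_CATEGORIES,
    "marital": MARITAL_CATEGORIES,
    "insurance": INSURANCE_CATEGORIES,
    "language": LANGUAGE_CATEGORIES,
}

DETERMINANTS = tuple(DETERMINANT_CATEGORIES)

#: columns a patient record must carry (icd9_codes may be an empty set)
REQUIRED_FIELDS = (
    "age",
    "sofa_24h",
    "sirs_24h",
    "race",
    "sex",
    "marital",
    "insurance",
    "language",
    "infection_offset_h",
    "cardiothoracic_service",
    "in_hospital_death",
)


def normalize_code(code: str) -> str:
    """Canonicalize an ICD-9 code for matching: strip whitespace, drop the dot.

    "995.92" and "99592" compare equal; no other normalization is applied.
    """
    return str(code).strip().replace(".", "")


@dataclass(frozen=True)
class CriterionDef:
    """One named sepsis-identification rule.

    ``kind`` is either ``"code_set"`` (patient qualifies iff their ICD-9 codes
    intersect ``code_set``) or ``"sepsis3"`` (SOFA in the first 24 h at or above
    ``sofa_threshold`` and suspected infection within ``infection_window_h``
    hours of ICU admission).
    """

    name: str
    kind: str
    code_set: frozenset[str] = field(default_factory=frozenset)
    sofa_threshold: int = 2
    infection_window_h: float = 24.0

    def __post_init__(self) -> None:
        if self.kind not in ("code_set", "sepsis3"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.kind == "code_set" and not self.code_set:
            raise ValueError(f"criterion {self.name!r}: code_set must be non-empty")
        if self.sofa_threshold < 0:
            raise ValueError(f"criterion {self.name!r}: sofa_threshold must be >= 0")
        object.__setattr__(
            self, "code_set", frozenset(normalize_code(c) for c in self.code_set)
        )


EXPLICIT_CODES = frozenset({"995.92", "785.52"})

#: Illustrative defaults for the claims-based rules (NOT the published lists).
_ILLUSTRATIVE_CODE_SETS: dict[str, frozenset[str]] = {
    "Explicit": EXPLICIT_CODES,
    "Angus": frozenset({"038.9", "038.42", "790.7", "995.91", "785.52"}),
    "Martin": frozenset({"038.9", "038.0", "020.0", "790.7"}),
    "CMS": frozenset({"995.91", "995.92", "785.52"}),
    "CDC": frozenset({"038.9", "995.92", "785.52", "790.7", "038.10"}),
}

CRITERION_NAMES = ("Explicit", "Angus", "Martin", "CMS", "CDC", "Sepsis-3")


def default_criteria() -> list[CriterionDef]:
    """The six criteria with packaged defaults, in reporting order."""
    crits = [
        CriterionDef(name=name, kind="code_set", code_set=_ILLUSTRATIVE_CODE_SETS[name])
        for name in CRITERION_NAMES[:-1]
    ]
    crits.append(CriterionDef(name="Sepsis-3", kind="sepsis3"))
    return crits


def criteria_from_config(path_or_dict) -> list[CriterionDef]:
    """Load criteria from a YAML/JSON config (list of criterion mappings)."""
    if isinstance(path_or_dict, (str, bytes)) or hasattr(path_or_dict, "__fspath__"):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = path_or_dict
    crits = []
    for entry in raw:
        kind = entry.get("kind", "code_set")
        crits.append(
            CriterionDef(
                name=entry["name"],
                kind=kind,
                code_set=frozenset(entry.get("codes", ())),
                sofa_threshold=int(entry.get("sofa_threshold", 2)),
                infection_window_h=float(entry.get("infection_window_h", 24.0)),
            )
        )
    return crits


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def select_cohort(
    patients: pd.DataFrame,
    adult_age: float = 18.0,
    infection_window_h: float = 24.0,
) -> pd.DataFrame:
    """Apply the cohort-selection filters, preserving input order.

    Retains patients who are adults (``age >= adult_age``), whose suspected
    infection falls within ``infection_window_h`` hours of ICU admission in
    either direction, who were not admitted for cardiothoracic surgery
    services, and whose required fields are all present (complete-case
    analysis: any missing required field excludes the record).
    """
    df = patients
    complete = np.ones(len(df), dtype=bool)
    for col in REQUIRED_FIELDS:
        if col not in df.columns:
            raise KeyError(f"patient table lacks required column {col!r}")
        complete &= df[col].notna().to_numpy()
    keep = complete.copy()
    age = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
    off = pd.to_numeric(df["infection_offset_h"], errors="coerce").to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep &= age >= adult_age
        keep &= np.abs(off) <= infection_window_h
    keep &= ~df["cardiothoracic_service"].fillna(True).astype(bool).to_numpy()
    return df.loc[keep]


# ---------------------------------------------------------------------------
# determinant releveling
# ---------------------------------------------------------------------------

def default_mapping_config() -> dict[str, dict[str, str]]:
    """Raw source strings -> the enumerated categories.

    The special key ``"*"`` is the catch-all for unmapped values; race and
    language fall to "Other" and marital status to "Unknown". Sex and insurance
    have no catch-all: an unmapped value there is an error.
    """
    return {
        "race": {
            "WHITE": "White",
            "ASIAN": "Asian",
            "BLACK/AFRICAN AMERICAN": "Black or African American",
            "HISPANIC OR LATINO": "Hispanic or Latino",
            "*": "Other",
        },
        "sex": {"F": "Female", "M": "Male", "FEMALE": "Female", "MALE": "Male"},
        "marital": {
            "MARRIED": "Significant other",
            "LIFE PARTNER": "Significant other",
            "DIVORCED": "Separated",
            "SEPARATED": "Separated",
            "SINGLE": "Single",
            "WIDOWED": "Widowed",
            "UNKNOWN (DEFAULT)": "Unknown",
            "*": "Unknown",
        },
        "insurance": {
            "GOVERNMENT": "Government",
            "MEDICAID": "Medicaid",
            "MEDICARE": "Medicare",
            "PRIVATE": "Private",
            "SELF PAY": "Self-pay",
            "SELF-PAY": "Self-pay",
        },
        "language": {"ENGL": "English", "ENGLISH": "English", "SPAN": "Spanish",
                     "SPANISH": "Spanish", "*": "Other"},
    }


def relevel_determinants(
    raw: pd.DataFrame, mapping_config: Mapping[str, Mapping[str, str]] | None = None
) -> pd.DataFrame:
    """Map free-text determinant strings onto the enumerated categories.

    Values already equal to an enumerated category pass through unchanged.
    Unmapped race/language values fall to "Other" and marital to "Unknown"
    (via each mapping's ``"*"`` entry); an unmapped sex or insurance value is
    rejected, since no catch-all category exists for those determinants.
    """
    mapping_config = mapping_config or default_mapping_config()
    out = raw.copy()
    for det, cats in DETERMINANT_CATEGORIES.items():
        mapping = dict(mapping_config.get(det, {}))
        fallback = mapping.pop("*", None)

        def _map(value: object, det=det, mapping=mapping, cats=cats, fallback=fallback):
            if pd.isna(value):
                return value
            s = str(value).strip()
            if s in cats:
                return s
            if s in mapping:
                return mapping[s]
            if s.upper() in mapping:
                return mapping[s.upper()]
            if fallback is not None:
                return fallback
            raise ValueError(f"unmapped {det} value {s!r} (no catch-all category)")

        mapped = out[det].map(_map)
        bad = mapped.dropna()[~mapped.dropna().isin(cats)]
        if len(bad):
            raise ValueError(f"{det}: mapping produced non-enumerated value {bad.iloc[0]!r}")
        out[det] = mapped
    return out


# ---------------------------------------------------------------------------
# sepsis labelling
# ---------------------------------------------------------------------------

def _as_code_set(codes: object) -> frozenset[str]:
    if isinstance(codes, (frozenset, set, list, tuple)):
        return frozenset(normalize_code(c) for c in codes)
    if codes is None or (isinstance(codes, float) and np.isnan(codes)):
        return frozenset()
    # semicolon-joined string form used in CSV round-trips
    s = str(codes).strip()
    if not s:
        return frozenset()
    return frozenset(normalize_code(c) for c in s.split(";") if c.strip())


def apply_criterion(patient: Mapping, crit: CriterionDef) -> bool:
    """Evaluate one criterion for one patient record (mapping or Series)."""
    if crit.kind == "code_set":
        return not _as_code_set(patient["icd9_codes"]).isdisjoint(crit.code_set)
    sofa = float(patient["sofa_24h"])
    off = float(patient["infection_offset_h"])
    return sofa >= crit.sofa_threshold and abs(off) <= crit.infection_window_h


def label_matrix(
    patients: pd.DataFrame, criteria: Sequence[CriterionDef] | None = None
) -> pd.DataFrame:
    """Boolean patient x criterion sepsis-flag matrix.

    Indexed by ``patient_id``, one boolean column per criterion, in the order
    given. Criterion names must be unique.
    """
    criteria = list(criteria) if criteria is not None else default_criteria()
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate criterion names in {names}")
    code_sets = [_as_code_set(c) for c in patients["icd9_codes"]]
    sofa = patients["sofa_24h"].to_numpy(dtype=float) if len(patients) else np.array([])
    off = (
        patients["infection_offset_h"].to_numpy(dtype=float)
        if len(patients)
        else np.array([])
    )
    cols = {}
    for crit in criteria:
        if crit.kind == "code_set":
            cols[crit.name] = np.array(
                [not cs.isdisjoint(crit.code_set) for cs in code_sets], dtype=bool
            )
        else:
            cols[crit.name] = (sofa >= crit.sofa_threshold) & (
                np.abs(off) <= crit.infection_window_h
            )
    return pd.DataFrame(cols, index=pd.Index(patients["patient_id"], name="patient_id"))
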