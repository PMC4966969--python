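"""Domain types and file I/O shared by all pipeline stages.

Patient records travel as JSON Lines (one patient per line); mapping
tables (symptom glossary, ICD-9 -> PheWAS, PheWAS -> comorbidity group)
are header-bearing CSV/TSV loaded with pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

POLARITIES = frozenset({"affirmed", "negated"})
UNCERTAINTIES = frozenset({"certain", "uncertain"})
SUBJECTS = frozenset({"patient", "other"})
GOLD_LABELS = frozenset({"yes", "no", "maybe", "unknown"})

#: DSM-IV symptom domains used by the diagnostic criteria.
DSM_CATEGORIES = ("social_interaction", "communication", "behavior")

#: ICD-9 codes for Autism (299.0), Asperger's (299.80) and PDD-NOS (299.9).
DEFAULT_INCLUDE_CODES = frozenset({"299.0", "299.80", "299.9"})

#: Rett syndrome, childhood disintegrative disorder, schizophrenia,
#: tuberous sclerosis, fragile X, and severe intellectual disability --
#: conditions whose presence removes a patient from the candidate cohort.
DEFAULT_EXCLUDE_CODES = frozenset(
    {"330.8", "299.1", "295.0", "295.9", "759.5", "759.83", "318.1", "318.2"}
)


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class ConceptMention:
    """One attributed clinical-concept mention extracted from a note.

    ``code`` is a CUI-style concept identifier (e.g. ``C2675043``) or a
    project-specific code (e.g. ``CHIP1000204``).  The three attributes
    mirror what clinical NLP attribute modules emit: whether the concept
    was asserted or negated, whether it was hedged, and whether it refers
    to the patient or to someone else (family history etc.).
    """

    code: str
    polarity: str = "affirmed"
    uncertainty: str = "certain"
    subject: str = "patient"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("mention code must be non-empty")
        if self.polarity not in POLARITIES:
            raise ValidationError(f"bad polarity {self.polarity!r}")
        if self.uncertainty not in UNCERTAINTIES:
            raise ValidationError(f"bad uncertainty {self.uncertainty!r}")
        if self.subject not in SUBJECTS:
            raise ValidationError(f"bad subject {self.subject!r}")


@dataclass
class PatientRecord:
    """One patient: diagnosis codes, concept mentions, optional gold label.

    ``gold_label`` absent (None) means the chart was never reviewed;
    the reviewed verdict "unknown" is a distinct value.
    """

    patient_id: str
    site: str = ""
    icd9_codes: frozenset[str] = field(default_factory=frozenset)
    mentions: tuple[ConceptMention, ...] = ()
    gold_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        self.icd9_codes = frozenset(c.strip() for c in self.icd9_codes)
        self.mentions = tuple(
            m if isinstance(m, ConceptMention) else ConceptMention(**m)
            for m in self.mentions
        )
        if self.gold_label is not None and self.gold_label not in GOLD_LABELS:
            raise ValidationError(
                f"gold_label must be one of {sorted(GOLD_LABELS)}, "
                f"got {self.gold_label!r}"
            )


@dataclass(frozen=True)
class GlossaryMap:
    """Symptom concept code -> DSM-IV category.

    Each code maps to exactly one of the three categories; the loader
    rejects conflicting duplicates.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for code, cat in self.entries.items():
            if cat not in DSM_CATEGORIES:
                raise ValidationError(
                    f"glossary category {cat!r} for {code!r} not in "
                    f"{DSM_CATEGORIES}"
                )

    def category(self, code: str) -> Optional[str]:
        return self.entries.get(code)

    def codes_in(self, category: str) -> list[str]:
        return sorted(c for c, cat in self.entries.items() if cat == category)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ScreenConfig:
    """ICD-9 inclusion/exclusion screen.

    A patient enters the cohort with at least one include code and is
    removed by any exclude code.  One occurrence of an include code
    suffices; codes are compared as exact dotted strings.
    """

    include_codes: frozenset[str] = DEFAULT_INCLUDE_CODES
    exclude_codes: frozenset[str] = DEFAULT_EXCLUDE_CODES

    def __post_init__(self) -> None:
        overlap = set(self.include_codes) & set(self.exclude_codes)
        if overlap:
            raise ValidationError(
                f"include and exclude sets overlap: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Screen/flag bookkeeping: how many of the input patients were kept."""

    n_input: int
    n_flagged: int

    def __post_init__(self) -> None:
        if self.n_input < 0 or self.n_flagged < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_flagged > self.n_input:
            raise ValidationError(
                f"n_flagged={self.n_flagged} exceeds n_input={self.n_input}"
            )

    @property
    def fraction(self) -> float:
        return self.n_flagged / self.n_input if self.n_input else 0.0

    @property
    def pct_flagged(self) -> float:
        """Percentage flagged, rounded to one decimal for display."""
        return round(100.0 * self.fraction, 1)


def summarize_cohort(n_input: int, n_flagged: int) -> CohortSummary:
    """Summarize a screening/flagging step as a percentage of input."""
    return CohortSummary(n_input=n_input, n_flagged=n_flagged)


# ---------------------------------------------------------------------------
# JSON Lines patient I/O


def _record_to_dict(rec: PatientRecord) -> dict:
    d = {
        "patient_id": rec.patient_id,
        "site": rec.site,
        "icd9_codes": sorted(rec.icd9_codes),
        "mentions": [
            {
                "code": m.code,
                "polarity": m.polarity,
                "uncertainty": m.uncertainty,
                "subject": m.subject,
            }
            for m in rec.mentions
        ],
    }
    if rec.gold_label is not None:
        d["gold_label"] = rec.gold_label
    return d


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read patient records from a JSON Lines file.

    Raises ValidationError naming the offending line on malformed JSON,
    schema violations, or duplicate patient ids.  Order is preserved.
    """
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"line {lineno}: malformed JSON ({exc})")
            if "patient_id" not in obj:
                raise ValidationError(f"line {lineno}: missing patient_id")
            try:
                rec = PatientRecord(
                    patient_id=obj["patient_id"],
                    site=obj.get("site", ""),
                    icd9_codes=frozenset(obj.get("icd9_codes", [])),
                    mentions=tuple(obj.get("mentions", [])),
                    gold_label=obj.get("gold_label"),
                )
            except (ValidationError, TypeError) as exc:
                raise ValidationError(f"line {lineno}: {exc}")
            if rec.patient_id in seen:
                raise ValidationError(
                    f"line {lineno}: duplicate patient_id {rec.patient_id!r}"
                )
            seen.add(rec.patient_id)
            records.append(rec)
    return records


def write_patients(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records as JSON Lines (one patient per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_dict(rec), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Mapping tables


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_glossary(path: str | Path) -> GlossaryMap:
    """Load a symptom-code -> DSM-IV-category table (columns code, category).

    Duplicate rows repeating the same category are deduplicated; a code
    mapped to two different categories is an error, as is any category
    outside the three DSM-IV groups.
    """
    df = _read_table(path)
    for col in ("code", "category"):
        if col not in df.columns:
            raise ValidationError(f"glossary file missing column {col!r}")
    entries: dict[str, str] = {}
    for code, cat in zip(df["code"].str.strip(), df["category"].str.strip()):
        if cat not in DSM_CATEGORIES:
            raise ValidationError(
                f"unknown DSM category {cat!r} for code {code!r}"
            )
        if code in entries and entries[code] != cat:
            raise ValidationError(
                f"code {code!r} mapped to both {entries[code]!r} and {cat!r}"
            )
        entries[code] = cat
    return GlossaryMap(entries=entries)


def read_code_map(
    path: str | Path, key_col: str, value_col: str
) -> dict[str, str]:
    """Load a two-column mapping table (e.g. icd9->phewas, phewas->group)."""
    df = _read_table(path)
    for col in (key_col, value_col):
        if col not in df.columns:
            raise ValidationError(f"mapping file missing column {col!r}")
    mapping: dict[str, str] = {}
    for k, v in zip(df[key_col].str.strip(), df[value_col].str.strip()):
        if k in mapping and mapping[k] != v:
            raise ValidationError(
                f"key {k!r} mapped to both {mapping[k]!r} and {v!r}"
            )
        mapping[k] = v
    return mapping


def read_phewas_map(path: str | Path) -> dict[str, str]:
    return read_code_map(path, "icd9", "phewas")


def read_group_map(path: str | Path) -> dict[str, str]:
    return read_code_map(path, "phewas", "group")


# ---------------------------------------------------------------------------
# Bundled toy fixtures (tiny stand-ins for licensed terminology tables)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("ehrpheno").joinpath("data", name))


def toy_glossary_path() -> Path:
    """Synthetic symptom glossary shipped for tests and simulations."""
    return _fixture_path("glossary_toy.csv")


def toy_phewas_map_path() -> Path:
    """Synthetic ICD-9 -> PheWAS rollup table shipped for tests."""
    return _fixture_path("phewas_toy.csv")


def toy_group_map_path() -> Path:
    """Synthetic PheWAS -> comorbidity-group table shipped for tests."""
    return _fixture_path("groups_toy.csv")
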