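"""Rule-based cohort selection: ICD-9 screen plus sequential DSM-IV criteria.

The classifier counts *unique* symptom concepts per DSM-IV category
(Social Interaction, Communication, Behavior/Interests/Activities) and
evaluates three criteria in fixed order: Autistic Disorder, then
Asperger's Syndrome, then PDD-NOS.  The first satisfied criterion wins;
a patient satisfying none is a non-case.  All three ASD subtypes count
as positive for case status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import GlossaryMap, PatientRecord, ScreenConfig

LABEL_AUTISTIC = "autistic_disorder"
LABEL_ASPERGERS = "aspergers"
LABEL_PDDNOS = "pdd_nos"
LABEL_NONCASE = "non_case"

#: Ordinal severity used when a single score is needed (e.g. ROC over
#: discrete rule output): higher = stronger evidence of case status.
LABEL_ORDINAL = {
    LABEL_AUTISTIC: 3,
    LABEL_ASPERGERS: 2,
    LABEL_PDDNOS: 1,
    LABEL_NONCASE: 0,
}


@dataclass(frozen=True)
class AutisticThresholds:
    """Autistic Disorder: >=6 unique symptoms overall with >=2 social,
    >=1 communication and >=1 behavior."""

    min_total: int = 6
    min_social: int = 2
    min_comm: int = 1
    min_behavior: int = 1


@dataclass(frozen=True)
class AspergersThresholds:
    """Asperger's Syndrome: social plus restricted-behavior symptoms,
    without requiring a communication deficit."""

    min_social: int = 2
    min_behavior: int = 1


@dataclass(frozen=True)
class PddNosThresholds:
    """PDD-NOS fallback: social impairment plus at least one symptom in
    either of the other two domains."""

    min_social: int = 1
    min_other: int = 1


@dataclass(frozen=True)
class DsmCriteria:
    """Thresholds for the three sequential criteria; all config-exposed."""

    autistic: AutisticThresholds = AutisticThresholds()
    aspergers: AspergersThresholds = AspergersThresholds()
    pddnos: PddNosThresholds = PddNosThresholds()


@dataclass(frozen=True)
class SymptomCounts:
    """Unique-symptom-code counts per DSM-IV category (not mention counts)."""

    social: int = 0
    communication: int = 0
    behavior: int = 0

    @property
    def total(self) -> int:
        return self.social + self.communication + self.behavior


@dataclass(frozen=True)
class MentionFilter:
    """Which attributed mentions contribute symptom evidence.

    Defaults: negated mentions and mentions about someone other than the
    patient are excluded; uncertain (hedged) mentions still count, since
    soft evidence is how PDD-NOS-like presentations surface in notes.
    """

    require_affirmed: bool = True
    require_patient_subject: bool = True
    require_certain: bool = False

    def accepts(self, mention) -> bool:
        if self.require_affirmed and mention.polarity != "affirmed":
            return False
        if self.require_patient_subject and mention.subject != "patient":
            return False
        if self.require_certain and mention.uncertainty != "certain":
            return False
        return True


@dataclass(frozen=True)
class RuleDecision:
    """Outcome of the sequential DSM-IV classifier for one patient."""

    label: str
    counts: SymptomCounts

    @property
    def is_case(self) -> bool:
        return self.label != LABEL_NONCASE

    @property
    def ordinal_score(self) -> int:
        return LABEL_ORDINAL[self.label]


def screen_cohort(
    patients: list[PatientRecord], config: ScreenConfig | None = None
) -> list[PatientRecord]:
    """ICD-9 inclusion/exclusion screen (pipeline steps 1-2).

    Keeps patients with at least one include code and no exclude code;
    order is preserved.  Any exclude code removes the patient regardless
    of include codes.
    """
    config = config or ScreenConfig()
    out = []
    for p in patients:
        if p.icd9_codes & config.exclude_codes:
            continue
        if p.icd9_codes & config.include_codes:
            out.append(p)
    return out


def count_symptoms(
    record: PatientRecord,
    glossary: GlossaryMap,
    mention_filter: MentionFilter | None = None,
) -> SymptomCounts:
    """Count unique glossary symptom codes per DSM-IV category.

    A code contributes at most once however many times it is mentioned;
    only mentions passing the attribute filter contribute; codes absent
    from the glossary are background concepts and are ignored.
    """
    mention_filter = mention_filter or MentionFilter()
    seen: dict[str, set[str]] = {
        "social_interaction": set(),
        "communication": set(),
        "behavior": set(),
    }
    for m in record.mentions:
        if not mention_filter.accepts(m):
            continue
        cat = glossary.category(m.code)
        if cat is not None:
            seen[cat].add(m.code)
    return SymptomCounts(
        social=len(seen["social_interaction"]),
        communication=len(seen["communication"]),
        behavior=len(seen["behavior"]),
    )


def classify_dsm(
    counts: SymptomCounts, criteria: DsmCriteria | None = None
) -> RuleDecision:
    """Apply the three DSM-IV criteria in order; first satisfied wins."""
    criteria = criteria or DsmCriteria()
    a = criteria.autistic
    if (
        counts.total >= a.min_total
        and counts.social >= a.min_social
        and counts.communication >= a.min_comm
        and counts.behavior >= a.min_behavior
    ):
        return RuleDecision(label=LABEL_AUTISTIC, counts=counts)
    b = criteria.aspergers
    if counts.social >= b.min_social and counts.behavior >= b.min_behavior:
        return RuleDecision(label=LABEL_ASPERGERS, counts=counts)
    c = criteria.pddnos
    if (
        counts.social >= c.min_social
        and (counts.communication + counts.behavior) >= c.min_other
    ):
        return RuleDecision(label=LABEL_PDDNOS, counts=counts)
    return RuleDecision(label=LABEL_NONCASE, counts=counts)


def run_rule_pipeline(
    patients: list[PatientRecord],
    glossary: GlossaryMap,
    screen: ScreenConfig | None = None,
    criteria: DsmCriteria | None = None,
    mention_filter: MentionFilter | None = None,
) -> list[tuple[str, RuleDecision]]:
    """Screen then classify; screened-out patients receive no decision.

    Deterministic given its inputs: output order follows input order of
    the screened patients.
    """
    screened = screen_cohort(patients, screen)
    return [
        (
            p.patient_id,
            classify_dsm(count_symptoms(p, glossary, mention_filter), criteria),
        )
        for p in screened
    ]
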