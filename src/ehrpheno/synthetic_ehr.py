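"""Synthetic EHR cohorts with known structure.

Two generators make every other module testable without clinical data:

* ``gen_phenotyping_cohort`` emits gold-labeled patients whose concept
  vectors carry label-dependent DSM-IV symptom signal on top of a
  Zipf-skewed background vocabulary, mimicking the concept vectors a
  clinical NLP pipeline extracts from notes.
* ``gen_comorbidity_cohort`` emits ICD-9 code sets with planted
  comorbidity-cluster structure (three minority clusters dominated by
  one comorbidity group each, plus a diffuse majority).

Both are pure functions of (config, seed): a fixed seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    ConceptMention,
    GlossaryMap,
    PatientRecord,
    ValidationError,
)

#: Gold-label mix of the chart-review standard being emulated:
#: 44% yes, 10% no, 36% maybe, 10% unknown.
DEFAULT_LABEL_MIX = {"yes": 0.44, "no": 0.10, "maybe": 0.36, "unknown": 0.10}

#: Mean unique symptoms drawn per DSM category, by gold label.  "yes"
#: patients carry strong signal in every domain, "maybe" patients a
#: moderate, mostly-social signal, "no"/"unknown" only stray mentions.
DEFAULT_SYMPTOM_RATES = {
    "yes": {"social_interaction": 4.0, "communication": 2.5, "behavior": 3.5},
    "maybe": {"social_interaction": 1.2, "communication": 0.6, "behavior": 0.8},
    "no": {"social_interaction": 0.2, "communication": 0.1, "behavior": 0.15},
    "unknown": {"social_interaction": 0.3, "communication": 0.2, "behavior": 0.2},
}


@dataclass(frozen=True)
class PhenoSimConfig:
    """Study conditions for the phenotyping-cohort generator."""

    n_patients: int = 2000
    label_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MIX)
    )
    symptom_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SYMPTOM_RATES.items()
        }
    )
    vector_length: float = 344.0  # mean background concepts per patient
    background_vocab: int = 2000
    zipf_exponent: float = 1.2
    exclusion_rate: float = 0.05
    #: attribute noise applied to background mentions only
    negation_rate: float = 0.10
    uncertain_rate: float = 0.10
    other_subject_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.label_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("label_mix must sum to 1")
        for label, rates in self.symptom_rates.items():
            if any(r < 0 for r in rates.values()):
                raise ValidationError(f"negative symptom rate for {label!r}")

    def case_probability(self, label: str) -> float:
        """P(flagged as case | label) under the default DSM thresholds.

        The union of the three sequential criteria reduces to
        (social >= 1) and (communication + behavior >= 1); with
        independent Poisson category counts that probability is
        (1 - e^-s)(1 - e^-(c+b)).  Truncation of counts at the glossary
        category size never crosses the >=1 boundary, so the closed form
        is exact for the generator's sampling scheme.
        """
        r = self.symptom_rates[label]
        p_social = 1.0 - math.exp(-r["social_interaction"])
        p_other = 1.0 - math.exp(-(r["communication"] + r["behavior"]))
        return p_social * p_other

    def designed_case_rate(self) -> float:
        """Expected flagged fraction among screened patients."""
        return sum(
            w * self.case_probability(label)
            for label, w in self.label_mix.items()
        )


def _zipf_weights(vocab_size: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, vocab_size + 1) ** exponent
    return w / w.sum()


def gen_phenotyping_cohort(
    config: PhenoSimConfig, glossary: GlossaryMap
) -> list[PatientRecord]:
    """Generate a gold-labeled cohort of attributed concept vectors.

    Every patient receives an ASD include ICD-9 code; an
    ``exclusion_rate`` fraction additionally receives an exclusion code
    (and is therefore screened out downstream, independent of label).
    Per label and DSM category, the number of unique symptom codes is
    Poisson with the configured mean, truncated at the category's
    glossary size; symptom mentions are always affirmed/patient so the
    designed case rate stays analytic.  Background concepts come from a
    disjoint Zipf-skewed vocabulary with attribute noise at the
    configured rates.
    """
    for cat in ("social_interaction", "communication", "behavior"):
        if not glossary.codes_in(cat):
            raise ValidationError(f"glossary has no codes in {cat!r}")
    rng = np.random.default_rng(config.seed)
    labels = list(config.label_mix)
    probs = np.array([config.label_mix[l] for l in labels])
    bg_codes = [f"C9{j:06d}" for j in range(config.background_vocab)]
    overlap = set(bg_codes) & set(glossary.entries)
    if overlap:
        raise ValidationError("background vocabulary collides with glossary")
    bg_weights = _zipf_weights(config.background_vocab, config.zipf_exponent)
    cat_codes = {
        cat: glossary.codes_in(cat)
        for cat in ("social_interaction", "communication", "behavior")
    }
    patients: list[PatientRecord] = []
    for i in range(config.n_patients):
        label = labels[rng.choice(len(labels), p=probs)]
        icd9 = {"299.0"}
        if rng.random() < config.exclusion_rate:
            icd9.add("330.8")
        mentions: list[ConceptMention] = []
        # symptom signal: unique codes per category, clean attributes
        for cat, codes in cat_codes.items():
            lam = config.symptom_rates[label][cat]
            n_sym = min(int(rng.poisson(lam)), len(codes))
            chosen = rng.choice(len(codes), size=n_sym, replace=False)
            for j in chosen:
                n_rep = 1 + int(rng.poisson(1.0))  # symptoms repeat in notes
                mentions.extend(
                    ConceptMention(code=codes[j]) for _ in range(n_rep)
                )
        # background concepts with attribute noise
        n_bg = int(rng.poisson(config.vector_length))
        bg_idx = rng.choice(config.background_vocab, size=n_bg, p=bg_weights)
        u = rng.random((n_bg, 3))
        for t, j in enumerate(bg_idx):
            mentions.append(
                ConceptMention(
                    code=bg_codes[j],
                    polarity="negated" if u[t, 0] < config.negation_rate
                    else "affirmed",
                    uncertainty="uncertain" if u[t, 1] < config.uncertain_rate
                    else "certain",
                    subject="other" if u[t, 2] < config.other_subject_rate
                    else "patient",
                )
            )
        perm = rng.permutation(len(mentions))
        patients.append(
            PatientRecord(
                patient_id=f"SIM{i:06d}",
                site="synthetic",
                icd9_codes=frozenset(icd9),
                mentions=tuple(mentions[k] for k in perm),
                gold_label=label,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Comorbidity cohort with planted cluster structure


#: Planted latent structure: three minority comorbidity clusters at 10%
#: each plus a diffuse 70% background, matching the observed pattern of
#: 3-4 small clusters (5-20%) and one large undifferentiated cluster.
DEFAULT_CLUSTER_MIX = {
    "psychiatric": 0.10,
    "developmental": 0.10,
    "seizures": 0.10,
    "background": 0.70,
}


@dataclass(frozen=True)
class ComorbSimConfig:
    """Study conditions for the comorbidity-cohort generator."""

    n_patients: int = 2000
    cluster_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MIX)
    )
    in_group_rate: float = 0.45
    background_rate: float = 0.05
    seed: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("cluster_mix must sum to 1")
        # equality is allowed so a no-signal null cohort can be generated
        if self.in_group_rate < self.background_rate:
            raise ValidationError(
                "in_group_rate must be at least background_rate"
            )


def gen_comorbidity_cohort(
    config: ComorbSimConfig,
    phewas_map: Mapping[str, str],
    group_map: Mapping[str, str],
) -> tuple[list[PatientRecord], dict[str, str]]:
    """Generate ICD-9 code sets with planted comorbidity clusters.

    Each patient draws a latent cluster from ``cluster_mix``; every
    ICD-9 code whose PheWAS category belongs to the matching comorbidity
    group is included with probability ``in_group_rate``, all other
    codes with ``background_rate``.  Patients in the background cluster
    draw every code at the background rate.  Returns the records plus
    the latent assignment (patient_id -> cluster name) for recovery
    tests.  Every patient also carries an ASD include code so the
    records pass the ICD-9 screen.
    """
    if not phewas_map or not group_map:
        raise ValidationError("phewas_map and group_map must be non-empty")
    planted = [g for g in config.cluster_mix if g != "background"]
    groups_avail = set(group_map.values())
    missing = set(planted) - groups_avail
    if missing:
        raise ValidationError(
            f"group map lacks planted groups: {sorted(missing)}"
        )
    code_group = {}
    for icd9, phewas in phewas_map.items():
        if phewas not in group_map:
            raise ValidationError(
                f"PheWAS category {phewas!r} missing from group map"
            )
        code_group[icd9] = group_map[phewas]
    codes = sorted(code_group)
    rng = np.random.default_rng(config.seed)
    names = list(config.cluster_mix)
    probs = np.array([config.cluster_mix[g] for g in names])
    patients: list[PatientRecord] = []
    latent: dict[str, str] = {}
    for i in range(config.n_patients):
        cluster = names[rng.choice(len(names), p=probs)]
        rates = np.array(
            [
                config.in_group_rate
                if code_group[c] == cluster
                else config.background_rate
                for c in codes
            ]
        )
        present = rng.random(len(codes)) < rates
        icd9 = {codes[j] for j in np.flatnonzero(present)} | {"299.0"}
        pid = f"COM{i:06d}"
        latent[pid] = cluster
        patients.append(
            PatientRecord(
                patient_id=pid,
                site="synthetic",
                icd9_codes=frozenset(icd9),
            )
        )
    return patients, latent
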