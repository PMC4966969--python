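import pytest

import ehrpheno as e


@pytest.fixture(scope="session")
def glossary():
    return e.read_glossary(e.toy_glossary_path())


@pytest.fixture(scope="session")
def phewas_map():
    return e.read_phewas_map(e.toy_phewas_map_path())


@pytest.fixture(scope="session")
def group_map():
    return e.read_group_map(e.toy_group_map_path())


@pytest.fixture(scope="session")
def pheno_cohort(glossary):
    """Small gold-labeled phenotyping cohort, fixed seed."""
    return e.gen_phenotyping_cohort(
        e.PhenoSimConfig(n_patients=300, seed=1), glossary
    )


@pytest.fixture(scope="session")
def comorb_cohort(phewas_map, group_map):
    """Default planted-comorbidity cohort (n=2000, seed 5) plus plant."""
    return e.gen_comorbidity_cohort(
        e.ComorbSimConfig(), phewas_map, group_map
    )


def make_patient(pid="p1", icd9=("299.0",), codes=(), gold=None, **attrs):
    """Terse patient constructor: one affirmed mention per code."""
    return e.PatientRecord(
        patient_id=pid,
        icd9_codes=frozenset(icd9),
        mentions=tuple(e.ConceptMention(code=c, **attrs) for c in codes),
        gold_label=gold,
    )
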