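import pytest

from phenonorm import generate_fixture

HEARING_IMPAIRMENT_OBO = """\
format-version: 1.2
ontology: hp

[Term]
id: HP:0000365
name: Hearing impairment
alt_id: HP:0000404
synonym: "Deafness" EXACT []
synonym: "Hearing defect" EXACT []
synonym: "Hearing impairment" EXACT []
synonym: "Hypacusis" EXACT []
synonym: "Hearing loss" EXACT []
synonym: "Hypoacusis" EXACT []
xref: SNOMEDCT_US:15188001 "Hearing loss"
xref: UMLS:C1384666

[Term]
id: HP:0000112
name: Abnormality of the kidney
synonym: "Abnormal kidney" EXACT []
xref: SNOMEDCT_US:302292003 "Kidney - Abnormal"
xref: SNOMEDCT_US:700375004 "Kidney structure - Defect"

[Term]
id: HP:0025517
name: Hypoplastic hippocampus
synonym: "Small hippocampus" EXACT []
synonym: "Undeveloped hippocampus" RELATED []

[Term]
id: GO:0008150
name: biological_process

[Term]
id: HP:0999999
name: Obsolete concept
is_obsolete: true
"""


@pytest.fixture(scope="session")
def hearing_obo_text() -> str:
    return HEARING_IMPAIRMENT_OBO


@pytest.fixture(scope="session")
def small_vocab():
    """20 concepts, 2-4 synonyms each, half carrying a hyphenated xref."""
    return generate_fixture(20, (2, 4), xref_rate=0.5, seed=7)


@pytest.fixture(scope="session")
def medium_vocab():
    """200 concepts with synonyms, for retrieval behavior tests."""
    return generate_fixture(200, (1, 4), xref_rate=0.2, seed=11)
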