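import dataclasses

import pytest
from hypothesis import settings

from beprecision import (
    GuideSite,
    NucleotideSequence,
    builtin_catalog,
    find_guide_sites,
)

settings.register_profile("suite", max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


def make_guide(protospacer: str, pam: str = "TGG", flank: str = "") -> GuideSite:
    """A + strand guide with the given protospacer, for rule-engine tests."""
    start = len(flank)
    return GuideSite(
        source_name="test",
        strand="+",
        pam_start=start + len(protospacer),
        pam_end=start + len(protospacer) + len(pam),
        cas_variant="SpCas9",
        pam_motif_matched="NGG",
        pam_sequence=pam,
        protospacer=protospacer.upper(),
        protospacer_interval=(start, start + len(protospacer)),
    )


def protospacer_with(cs: dict[int, str], fill: str = "A") -> str:
    """20-mer with the given bases at PAM-relative positions, 'A' elsewhere."""
    bases = [fill] * 20
    for rel, base in cs.items():
        bases[rel + 20] = base
    return "".join(bases)


@pytest.fixture(scope="session")
def amplicon(catalog):
    """A small amplicon with one SpCas9 NGG guide (Cs at -18 and -14)."""
    ref = NucleotideSequence(
        "ATGATTAGGT" + "AACATTCAAATTGATAATGA" + "TGG" + "CATTAGATTA",
        name="amplicon",
    )
    sites = [
        s
        for s in find_guide_sites(ref, catalog.pam_specs)
        if s.strand == "+" and s.cas_variant == "SpCas9" and s.pam_start == 30
    ]
    assert len(sites) == 1
    return ref, sites[0]
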