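import pytest

from peptaxon.formats_io import PeptideRecord, PeptideTable, ReferenceEntry, ReferenceSet
from peptaxon.synthetic import SyntheticConfig, generate_references


def rec(sample_id, peptide, alc=80.0, mods=(), charge=None, enzyme="trypsin"):
    return PeptideRecord(
        sample_id=sample_id, peptide=peptide, alc=alc, mods=tuple(mods),
        charge=charge, enzyme=enzyme,
    )


@pytest.fixture
def small_table():
    return PeptideTable(
        [
            rec("S1", "PEPTLDE", 87.0),
            rec("S1", "PEPTIDE", 92.0),
            rec("S1", "AAGAGAAK", 49.9),
            rec("S2", "GAGAGAGA", 55.0),
            rec("S2", "LLKAAA", 75.0),
        ]
    )


@pytest.fixture
def tiny_refs():
    return ReferenceSet(
        [
            ReferenceEntry("p1", "AAGAGAAKTTTTT", taxon="tax_a", clade="freshwater"),
            ReferenceEntry("p2", "WWWWPEPTLDEWWWW", taxon="tax_b", clade="marine"),
        ]
    )


@pytest.fixture(scope="session")
def panel_cfg():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def panel(panel_cfg):
    """A 4-taxon, 2-clade reference panel with ground truth (session cached)."""
    return generate_references(panel_cfg)
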