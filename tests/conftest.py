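import numpy as np
import pytest

from miplantpremat.hairpin import (
    HairpinRecord,
    RnaSequence,
    SecondaryStructure,
)


@pytest.fixture(scope="session")
def perfect_hairpin():
    """Precomputed perfect stem-loop (no folding engine needed)."""
    seq = RnaSequence("perfect", "GGGAGGGCAUCGAAAACGAUGCCCUCCC")
    db = "((((((((((((....))))))))))))"
    return HairpinRecord.from_structure(seq, SecondaryStructure(db, -15.0))


@pytest.fixture(scope="session")
def bulged_hairpin():
    """Stem-loop with one bulge: two stems, one hairpin loop."""
    seq = RnaSequence("bulged", "GGCAUGGAAACCAUAGCC")
    db = "((.((((...)))).))."
    return HairpinRecord.from_structure(seq, SecondaryStructure(db, -6.0))


@pytest.fixture(scope="session")
def unpaired_record():
    seq = RnaSequence("flat", "AAAAAAAA")
    return HairpinRecord.from_structure(seq, SecondaryStructure("........", 0.0))


@pytest.fixture(scope="session")
def folded_hairpin():
    """A real folded record with partition-function data (engine)."""
    from miplantpremat.simulate import HairpinSpec, make_hairpin

    record, mature = make_hairpin(
        HairpinSpec(stem_len=30, loop_len=6, gc=0.5, degrade=0.02, seed=42)
    )
    return record, mature
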