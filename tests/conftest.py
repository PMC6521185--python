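import numpy as np
import pytest

from codonuse.codon_bias import RSCUTable, classify_hfc
from codonuse.seqio import (
    FIXTURE_SUBGROUP_HOSTS,
    CodingSequence,
    SequenceSet,
    fixture_rscu_reference,
    load_reference_rscu,
)

SUBGROUPS = ("Ca-CTV", "Cr-CTV", "Cs-CTV")


@pytest.fixture(scope="session")
def fixture_df():
    return load_reference_rscu()


@pytest.fixture(scope="session")
def virus_tables(fixture_df):
    return {
        name: RSCUTable(fixture_df[name].to_dict(), source="pooled-subgroup", label=name)
        for name in SUBGROUPS
    }


@pytest.fixture(scope="session")
def host_refs():
    return {
        name: fixture_rscu_reference(host)
        for name, host in FIXTURE_SUBGROUP_HOSTS.items()
    }


@pytest.fixture(scope="session")
def classifications(virus_tables, host_refs):
    return {
        name: classify_hfc(virus_tables[name], host_refs[name])
        for name in SUBGROUPS
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_seq(codon_string, rec_id="seq1", subgroup=None, host=None):
    codons = tuple(codon_string.split())
    return CodingSequence(id=rec_id, codons=codons, subgroup=subgroup, host=host)


@pytest.fixture
def tiny_set():
    return SequenceSet(
        [
            make_seq("AUG UUU UUC GCU GCU AAA", "a1", "g1", "h1"),
            make_seq("AUG UUU UUU GCC GCU AAG", "a2", "g1", "h1"),
            make_seq("AUG CUU CUC GCA GCG AAA", "b1", "g2", "h2"),
        ]
    )


@pytest.fixture
def random_counts_factory(rng):
    """Random CodonCountTable generator used by property-style tests."""
    from codonuse.genetic_code import SENSE_CODONS
    from codonuse.seqio import CodonCountTable

    def make(total=500, zero_fraction=0.2):
        counts = rng.multinomial(total, np.ones(len(SENSE_CODONS)) / len(SENSE_CODONS))
        mask = rng.random(len(SENSE_CODONS)) < zero_fraction
        counts = np.where(mask, 0, counts)
        return CodonCountTable(dict(zip(SENSE_CODONS, counts.tolist())))

    return make
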