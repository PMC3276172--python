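import numpy as np
import pytest

from pombepop.loci import LocusAlignment, LocusDef


@pytest.fixture
def toy_locus():
    return LocusDef("toy", "I", 100, 100 + 10, "gene")


def make_alignment(seqs, locus=None, strains=None, demes=None):
    """Build a LocusAlignment from a list of equal-length strings."""
    if locus is None:
        locus = LocusDef("toy", "I", 0, len(seqs[0]), "gene")
    if strains is None:
        strains = [f"s{i + 1}" for i in range(len(seqs))]
    matrix = np.array([list(s) for s in seqs], dtype="U1")
    return LocusAlignment(locus=locus, strains=strains, matrix=matrix, demes=demes)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture(scope="session")
def isolate_collection():
    from pombepop.synthetic import fixture_isolate_collection

    return fixture_isolate_collection(seed=0)
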