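import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from apctools.align import AlignmentParams, AlignMode
from apctools.repeats import load_default_profile
from apctools.seqio import Alphabet, SequenceRecord

#: drop-in location for the paper's supplementary protein FASTA (not
#: redistributable; see README).  Acceptance tests that need it fail with a
#: clear message when it is absent.
SUPPLEMENTARY_FASTA = Path(__file__).parent.parent / "data" / "additional_file_1.fasta"


@pytest.fixture(scope="session")
def profile():
    return load_default_profile()


@pytest.fixture
def global_params():
    return AlignmentParams(mode=AlignMode.global_)


@pytest.fixture
def local_params():
    return AlignmentParams(mode=AlignMode.local)


@pytest.fixture
def protein():
    def make(residues, rec_id="p"):
        return SequenceRecord(id=rec_id, residues=residues,
                              alphabet=Alphabet.protein)
    return make


@pytest.fixture
def dna():
    def make(residues, rec_id="d"):
        return SequenceRecord(id=rec_id, residues=residues,
                              alphabet=Alphabet.dna)
    return make


@pytest.fixture
def write_fasta(tmp_path):
    def write(records, name="seqs.fasta"):
        path = tmp_path / name
        lines = []
        for rec_id, residues in records:
            lines.append(f">{rec_id}")
            lines.append(residues)
        path.write_text("\n".join(lines) + "\n")
        return path
    return write
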