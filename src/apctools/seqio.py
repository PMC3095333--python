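"""Sequence, alignment, motif-table and Newick I/O with validation.

All downstream stages consume the record types defined here.  FASTA parsing
is delegated to Biopython; this module adds alphabet validation, duplicate-id
detection and the gap/ambiguity normalisation rules the pipeline relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "AlignedSet",
    "MotifPattern",
    "SeqIOError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_motif_table",
    "write_motif_table",
    "write_newick",
    "read_newick",
    "IUPAC_DNA",
    "PROTEIN_LETTERS",
]

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_LETTERS = set("ACGTN")
#: 15-letter IUPAC nucleotide code (degenerate symbols allowed only in motifs)
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class SeqIOError(ValueError):
    """Raised on malformed input files or invalid records."""


class Alphabet(str, Enum):
    protein = "protein"
    dna = "dna"


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein, CDS or promoter sequence."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.protein
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC nucleotide pattern (PLACE-style)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise SeqIOError(
                f"motif {self.name!r}: pattern shorter than 4 ({self.pattern!r})"
            )
        bad = set(self.pattern) - set(IUPAC_DNA)
        if bad:
            raise SeqIOError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass
class AlignedSet:
    """An aligned set of equal-length gapped sequences ('-' gaps only)."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SeqIOError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SeqIOError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def _validate_residues(seq: str, alphabet: Alphabet, rec_id: str,
                       allow_gaps: bool) -> str:
    seq = seq.upper().replace(".", "-")
    if alphabet is Alphabet.protein and "U" in seq:
        warnings.warn(f"record {rec_id!r}: 'U' mapped to 'X'", stacklevel=3)
        seq = seq.replace("U", "X")
    letters = PROTEIN_LETTERS if alphabet is Alphabet.protein else DNA_LETTERS
    allowed = letters | {"-"} if allow_gaps else letters
    bad = set(seq) - allowed
    if bad:
        raise SeqIOError(
            f"record {rec_id!r}: illegal {alphabet.value} residues {sorted(bad)}"
        )
    return seq


def _parse_fasta(path: str | Path, alphabet: Alphabet,
                 allow_gaps: bool) -> list[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id  # first whitespace-delimited token of the header
        if rec_id in seen:
            raise SeqIOError(f"duplicate id {rec_id!r} in {path}")
        seen.add(rec_id)
        residues = _validate_residues(str(rec.seq), alphabet, rec_id, allow_gaps)
        if not residues:
            raise SeqIOError(f"record {rec_id!r}: empty sequence in {path}")
        out.append(SequenceRecord(id=rec_id, residues=residues,
                                  alphabet=alphabet,
                                  description=rec.description))
    if not out:
        raise SeqIOError(f"empty FASTA file: {path}")
    return out


def read_fasta(path: str | Path,
               alphabet: Alphabet | str = Alphabet.protein) -> list[SequenceRecord]:
    """Read an ungapped FASTA file; gap characters are rejected."""
    return _parse_fasta(path, Alphabet(alphabet), allow_gaps=False)


def read_alignment(path: str | Path,
                   alphabet: Alphabet | str = Alphabet.protein) -> AlignedSet:
    """Read an aligned FASTA file ('-' or '.' gaps) into an AlignedSet."""
    return AlignedSet(_parse_fasta(path, Alphabet(alphabet), allow_gaps=True))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(r.residues), id=r.id,
                  description=r.description[len(r.id):].strip()
                  if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_motif_table(path: str | Path) -> list[MotifPattern]:
    """Read a 2-column TSV of motif name and IUPAC pattern."""
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    motifs: list[MotifPattern] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
        name, pattern = parts[0].strip(), parts[1].strip().upper()
        if name in seen:
            raise SeqIOError(f"{path}:{lineno}: duplicate motif name {name!r}")
        seen.add(name)
        motifs.append(MotifPattern(name=name, pattern=pattern))
    if not motifs:
        raise SeqIOError(f"empty motif table: {path}")
    return motifs


def write_motif_table(motifs: Sequence[MotifPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree with integer supports as internal node labels."""
    from apctools.phylo import tree_to_newick

    Path(path).write_text(tree_to_newick(tree) + "\n")


def read_newick(path: str | Path):
    """Read a Newick file back into a dendropy tree (supports on labels)."""
    from apctools.phylo import newick_to_tree

    return newick_to_tree(Path(path).read_text())
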