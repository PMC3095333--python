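"""Gene rosters and record lookup for the bundled APC analyses.

The published protein identity figures and repeat counts refer to named
genes in a supplementary protein FASTA that cannot be redistributed with
this package.  Drop that file at ``data/apc_proteins.fasta`` (repository
root) or point ``APCTOOLS_PROTEINS`` at it and the corresponding analyses
become runnable.  Header naming schemes vary, so records are located by a
configurable list of regex alternatives (gene symbol and database locus
ids) rather than hard-coded ids.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

from apctools.seqio import SequenceRecord

__all__ = [
    "PARALOG_PAIRS",
    "TPR_REPEAT_COUNTS",
    "TPR_FAMILIES",
    "default_proteins_path",
    "find_record",
]

#: (name_a, patterns_a, name_b, patterns_b, published identity %)
PARALOG_PAIRS = [
    ("OsCDC23_1", ["OsCDC23_1", "Os02g43920"],
     "OsCDC23_2", ["OsCDC23_2", "Os06g46540"], 92.0),
    ("OsAPC11_1", ["OsAPC11_1", "Os03g19059"],
     "OsAPC11_2", ["OsAPC11_2", "Os07g22840"], 97.0),
    ("AtCDC27a", ["AtCDC27a", "At3g16320"],
     "AtCDC27b", ["AtCDC27b", "At2g20000"], 47.0),
    ("PtCDC27_1", ["PtCDC27_1", "Pt835890"],
     "PtCDC27_2", ["PtCDC27_2", "Pt278795"], 88.0),
    ("PtAPC13_1", ["PtAPC13_1", "Pt647861"],
     "PtAPC13_2", ["PtAPC13_2", "Pt660762"], 95.0),
]

#: published repeat-unit counts for the Arabidopsis TPR subunits
TPR_REPEAT_COUNTS = {
    "AtCDC27a": (["AtCDC27a", "At3g16320"], 9),
    "AtCDC27b": (["AtCDC27b", "At2g20000"], 9),
    "AtAPC5": (["AtAPC5", "At1g06590"], 2),
    "AtCDC16": (["AtCDC16", "At1g78770"], 9),
    "AtAPC7": (["AtAPC7", "At2g39090"], 10),
    "AtCDC23": (["AtCDC23", "At3g48150"], 10),
}

#: five TPR subunit families with published per-family sequence counts
#: (the full set totals 61 across the surveyed species)
TPR_FAMILIES = {
    "CDC27": 15,
    "APC5": 11,
    "CDC16": 12,
    "APC7": 9,
    "CDC23": 14,
}


def default_proteins_path() -> Path:
    """Resolve the drop-in supplementary protein FASTA location."""
    env = os.environ.get("APCTOOLS_PROTEINS")
    if env:
        return Path(env)
    return Path(__file__).resolve().parents[2] / "data" / "apc_proteins.fasta"


def find_record(records: list[SequenceRecord],
                patterns: list[str]) -> SequenceRecord | None:
    """First record whose id or description matches any regex alternative."""
    for pattern in patterns:
        rx = re.compile(pattern, re.IGNORECASE)
        for rec in records:
            if rx.search(rec.id) or rx.search(rec.description):
                return rec
    return None


def family_members(records: list[SequenceRecord],
                   family: str) -> list[SequenceRecord]:
    """Records belonging to one TPR subunit family, matched by name.

    The family name must not continue with another digit (so 'APC5' does
    not swallow hypothetical 'APC50' entries), but suffix letters such as
    the 'a'/'b' paralog tags are allowed.
    """
    rx = re.compile(rf"{family}(?!\d)", re.IGNORECASE)
    return [rec for rec in records
            if rx.search(rec.id) or rx.search(rec.description)]
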