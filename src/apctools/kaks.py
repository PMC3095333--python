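"""Pairwise Ka/Ks estimation (Nei–Gojobori counting, Jukes–Cantor correction).

Per-codon synonymous site fractions count, at each codon position, the share
of the three possible nucleotide changes that preserve the amino acid;
changes that would create a stop codon count as nonsynonymous, so the site
counts of each codon always sum to 3.  Observed differences are averaged
with equal weight over all substitution orderings between the two codons,
skipping orderings that pass through a stop codon (all orderings are used
if every one of them does).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from apctools.seqio import Alphabet, SequenceRecord

__all__ = ["KaKsError", "KaKsResult", "kaks", "codon_sites",
           "codon_path_differences", "SENSE_CODONS"]

_BASES = "ACGT"
_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TABLE))


class KaKsError(ValueError):
    pass


def _translate(codon: str) -> str | None:
    return _CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts of a sense codon."""
    aa = _translate(codon)
    if aa is None:
        raise KaKsError(f"{codon} is not a sense codon")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _translate(alt) == aa:  # stops translate to None -> nonsyn
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, pathway-averaged.

    Enumerates every ordering of the differing positions; orderings whose
    intermediate codons are stops are excluded (unless all are, in which
    case every ordering counts).
    """
    for c in (c1, c2):
        if c in _STOPS or _translate(c) is None:
            raise KaKsError(f"{c} is not a sense codon")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(1.0 for a, b in steps if _translate(a) == _translate(b))
        paths.append((through_stop, syn, len(steps) - syn))
    valid = [p for p in paths if not p[0]]
    if not valid:
        valid = paths
    sd = sum(p[1] for p in valid) / len(valid)
    nd = sum(p[2] for p in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float, what: str) -> float:
    if p >= 0.75:
        raise KaKsError(
            f"{what} proportion p = {p:.4f} >= 3/4: correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float  # NaN when Ks == 0 (undefined)
    codons_compared: int

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


_AMBIG = set("N-")


def kaks(cds_a: SequenceRecord, cds_b: SequenceRecord) -> KaKsResult:
    """NG86 Ka/Ks for an aligned pair of equal-length coding sequences.

    Codon columns containing gaps or ambiguity in either sequence are
    excluded pairwise; a shared terminal stop codon is dropped; an internal
    stop in either frame-0 translation is an error.
    """
    for rec in (cds_a, cds_b):
        if rec.alphabet is not Alphabet.dna:
            raise KaKsError(f"record {rec.id!r}: DNA sequence required")
    a, b = cds_a.residues, cds_b.residues
    if len(a) != len(b):
        raise KaKsError(f"sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) % 3:
        raise KaKsError(f"length {len(a)} not a multiple of 3")
    n_codons = len(a) // 3
    codon_pairs: list[tuple[str, str]] = []
    for k in range(n_codons):
        ca, cb = a[3 * k:3 * k + 3], b[3 * k:3 * k + 3]
        if _AMBIG & (set(ca) | set(cb)):
            continue
        if ca in _STOPS or cb in _STOPS:
            if k == n_codons - 1:
                continue  # shared/terminal stop: drop
            raise KaKsError(
                f"internal stop codon at codon {k + 1} "
                f"({cds_a.id if ca in _STOPS else cds_b.id})")
        codon_pairs.append((ca, cb))
    if not codon_pairs:
        raise KaKsError("no comparable codons after filtering")

    S = N = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS, "synonymous")
    Ka = _jukes_cantor(pN, "nonsynonymous")
    ratio = Ka / Ks if Ks > 0 else math.nan
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
                      ratio=ratio, codons_compared=len(codon_pairs))
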