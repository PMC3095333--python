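"""Promoter motif counting and surrogate-null over-representation testing.

The observed count of an IUPAC word in a promoter is compared against the
empirical distribution of its counts over a background promoter set: the
Z score of the observed count against the background mean and standard
deviation yields a one-tailed normal p value, with motifs below the 5%
threshold flagged as over-represented.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from apctools.seqio import IUPAC_DNA, Alphabet, MotifPattern, SequenceRecord

__all__ = [
    "EnrichmentError",
    "NullDistribution",
    "MotifEnrichmentResult",
    "count_motif",
    "surrogate_null",
    "enrichment_test",
    "shared_elements",
    "bh_fdr",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EnrichmentError(ValueError):
    pass


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    # character classes expand to concrete bases only, so an 'N' in the
    # promoter sequence never matches; lookahead counts overlapping hits
    parts = []
    for ch in pattern:
        bases = IUPAC_DNA[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_motif(promoter: SequenceRecord, motif: MotifPattern,
                strand_policy: str = "forward") -> int:
    """Number of (overlapping) match positions of the motif in the promoter.

    ``strand_policy='both'`` adds occurrences of the reverse complement.
    A pattern longer than the promoter yields 0.
    """
    if promoter.alphabet is not Alphabet.dna:
        raise EnrichmentError(f"{promoter.id!r}: DNA sequence required")
    if strand_policy not in ("forward", "both"):
        raise EnrichmentError(f"unknown strand_policy {strand_policy!r}")
    seq = promoter.residues
    n = len(_iupac_regex(motif.pattern).findall(seq))
    if strand_policy == "both":
        n += len(_iupac_regex(reverse_complement(motif.pattern)).findall(seq))
    return n


@dataclass(frozen=True)
class NullDistribution:
    """Per-promoter counts of one motif over a background set."""

    motif_name: str
    counts: tuple[int, ...]
    strand_policy: str = "forward"

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1))

    @property
    def n(self) -> int:
        return len(self.counts)


def surrogate_null(motif: MotifPattern,
                   background: list[SequenceRecord],
                   strand_policy: str = "forward") -> NullDistribution:
    """Empirical null: the motif's count in every background promoter."""
    if len(background) < 2:
        raise EnrichmentError("background needs at least 2 promoters")
    counts = tuple(count_motif(p, motif, strand_policy) for p in background)
    return NullDistribution(motif_name=motif.name, counts=counts,
                            strand_policy=strand_policy)


@dataclass(frozen=True)
class MotifEnrichmentResult:
    gene_id: str
    motif_name: str
    c_true: int
    c_surr_mean: float
    sd_surr: float
    z: float  # NaN flags a degenerate (sd = 0) null
    p_one_tailed: float
    significant: bool
    n_surrogates: int
    p_empirical: float | None = None

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.z)


def enrichment_test(promoter: SequenceRecord, motif: MotifPattern,
                    null: NullDistribution, alpha: float = 0.05,
                    empirical: bool = False) -> MotifEnrichmentResult:
    """Z = (Ctrue - mean) / sd with a one-tailed normal p value.

    A degenerate null (sd = 0) gives p = 0, 1 or 0.5 for counts above,
    below or at the mean, with z flagged as NaN.
    """
    c_true = count_motif(promoter, motif, null.strand_policy)
    mean, sd = null.mean, null.sd
    if sd > 0:
        z = (c_true - mean) / sd
        p = float(norm.sf(z))
    else:
        z = math.nan
        p = 0.0 if c_true > mean else (1.0 if c_true < mean else 0.5)
    p_emp = None
    if empirical:
        ge = sum(1 for c in null.counts if c >= c_true)
        p_emp = (1 + ge) / (null.n + 1)
    return MotifEnrichmentResult(
        gene_id=promoter.id, motif_name=motif.name, c_true=c_true,
        c_surr_mean=mean, sd_surr=sd, z=z, p_one_tailed=p,
        significant=p < alpha, n_surrogates=null.n, p_empirical=p_emp,
    )


def shared_elements(results_a: list[MotifEnrichmentResult],
                    results_b: list[MotifEnrichmentResult]) -> set[str]:
    """Motif names significantly over-represented in both promoters."""
    names_a = [r.motif_name for r in results_a]
    names_b = [r.motif_name for r in results_b]
    if set(names_a) != set(names_b):
        raise EnrichmentError("result lists cover different motif tables")
    sig_a = {r.motif_name for r in results_a if r.significant}
    sig_b = {r.motif_name for r in results_b if r.significant}
    return sig_a & sig_b


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p values (informational column only)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj.tolist()
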