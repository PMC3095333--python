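"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignments are
enumerated as explicit column strings and rescored by parsing gap runs,
tree topologies are enumerated exhaustively and fitted by least squares,
and codon arithmetic goes through Biopython's translate.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


# ---------------------------------------------------------------- alignment

def _enumerate_alignments(a: str, b: str):
    """Yield all gapped alignments of a and b as (row_a, row_b) strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def _score_alignment(row_a: str, row_b: str, matrix, gap_open: float,
                     gap_extend: float, free_end_gaps: bool) -> float:
    n = len(row_a)
    score = 0.0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            score += matrix[ca, cb]
    for row in (row_a, row_b):
        i = 0
        while i < n:
            if row[i] != "-":
                i += 1
                continue
            j = i
            while j < n and row[j] == "-":
                j += 1
            terminal = i == 0 or j == n
            if not (free_end_gaps and terminal):
                score -= gap_open + gap_extend * (j - i - 1)
            i = j
    return score


def brute_force_global(a: str, b: str, matrix, gap_open: float = 10.0,
                       gap_extend: float = 0.5,
                       free_end_gaps: bool = True) -> float:
    """Optimal global score by exhaustive enumeration (lengths <= ~6)."""
    best = -math.inf
    for ra, rb in _enumerate_alignments(a, b):
        best = max(best, _score_alignment(ra, rb, matrix, gap_open,
                                          gap_extend, free_end_gaps))
    return best


def brute_force_local(a: str, b: str, matrix, gap_open: float = 10.0,
                      gap_extend: float = 0.5) -> float:
    """Optimal local score: max over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_force_global(a[i1:i2], b[j1:j2], matrix,
                                           gap_open, gap_extend,
                                           free_end_gaps=False)
                    best = max(best, s)
    return best


# ------------------------------------------------------------------- trees

def five_taxon_topologies(taxa: list[str]):
    """All 15 unrooted topologies on 5 taxa as edge lists.

    Edges are (node, node) tuples; internal nodes are the strings 'X' and
    'Y'.  Built by attaching the 5th taxon to each edge of each of the 3
    quartet topologies.
    """
    assert len(taxa) == 5
    a, b, c, d, e = taxa
    out = []
    for (p, q), (r, s) in [((a, b), (c, d)), ((a, c), (b, d)),
                           ((a, d), (b, c))]:
        quartet = [(p, "X"), (q, "X"), (r, "Y"), (s, "Y"), ("X", "Y")]
        for k, (u, v) in enumerate(quartet):
            edges = [edge for i, edge in enumerate(quartet) if i != k]
            edges += [(u, "Z"), ("Z", v), (e, "Z")]
            out.append(edges)
    return out


def _paths(edges, taxa):
    """Pair -> list of edge indices on the path, via BFS over the tree."""
    adj: dict[str, list[tuple[str, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for i, src in enumerate(taxa):
        stack = [(src, [])]
        seen = {src}
        while stack:
            node, path = stack.pop()
            for nxt, eidx in adj[node]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                stack.append((nxt, path + [eidx]))
                if nxt in taxa:
                    paths[(src, nxt)] = path + [eidx]
    return paths


def best_fit_topology(taxa: list[str], dmat: np.ndarray):
    """Least-squares fit of every 5-taxon topology; returns the best.

    Returns (bipartitions, residual, fitted_path_lengths) of the topology
    with the smallest squared residual (0 for additive input).
    """
    idx = {t: i for i, t in enumerate(taxa)}
    pairs = list(itertools.combinations(taxa, 2))
    y = np.array([dmat[idx[u], idx[v]] for u, v in pairs])
    best = None
    for edges in five_taxon_topologies(taxa):
        paths = _paths(edges, taxa)
        design = np.zeros((len(pairs), len(edges)))
        for r, (u, v) in enumerate(pairs):
            path = paths.get((u, v)) or paths[(v, u)]
            for eidx in path:
                design[r, eidx] = 1.0
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = float(((design @ sol - y) ** 2).sum())
        if best is None or resid < best[1] - 1e-15:
            biparts = topology_bipartitions(edges, taxa)
            fitted = {pair: float(design[r] @ sol)
                      for r, pair in enumerate(pairs)}
            best = (biparts, resid, fitted)
    return best


def topology_bipartitions(edges, taxa):
    """Canonical non-trivial bipartitions of an edge-list topology."""
    ref = min(taxa)
    out = set()
    for k, _ in enumerate(edges):
        remaining = [e for i, e in enumerate(edges) if i != k]
        adj: dict[str, set[str]] = {}
        for u, v in remaining:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        u0 = edges[k][0]
        seen = {u0}
        stack = [u0]
        while stack:
            node = stack.pop()
            for nxt in adj.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(t for t in taxa if t in seen)
        if 2 <= len(side) <= len(taxa) - 2:
            canon = side if ref not in side else frozenset(taxa) - side
            out.add(frozenset(canon))
    return out


# ------------------------------------------------------------------ codons

_BASES = "ACGT"


def oracle_codon_sites(codon: str) -> float:
    """Fractional synonymous sites via Biopython translate."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            alt_aa = str(Seq(alt).translate())
            if alt_aa == aa and alt_aa != "*":
                syn += 1 / 3
    return syn


def oracle_path_differences(c1: str, c2: str):
    """Pathway-averaged (Sd, Nd) via Biopython translate."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if str(Seq(nxt).translate()) == "*" and nxt != c2:
                blocked = True
            if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        results.append((blocked, syn, nonsyn))
    valid = [r for r in results if not r[0]] or results
    sd = sum(r[1] for r in valid) / len(valid)
    nd = sum(r[2] for r in valid) / len(valid)
    return sd, nd


# ------------------------------------------------------------------ motifs

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_count(sequence: str, pattern: str) -> int:
    """Position-by-position set-membership motif count."""
    k = len(pattern)
    n = 0
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in IUPAC[pattern[j]] for j in range(k)):
            n += 1
    return n
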