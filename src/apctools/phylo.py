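"""Poisson-corrected distances, neighbor joining, bootstrap and condensation.

Trees are carried as unrooted :class:`dendropy.Tree` objects; integer
bootstrap percentages live on internal node labels, which is also how they
are serialized to Newick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from apctools.seqio import AlignedSet, Alphabet

__all__ = [
    "DistanceMatrix",
    "PhyloError",
    "poisson_distance",
    "neighbor_joining",
    "bootstrap_support",
    "condense",
    "bipartitions",
    "tree_to_newick",
    "newick_to_tree",
]

_PROTEIN_OK = set(b"ACDEFGHIKLMNPQRSTVWY")
_DNA_OK = set(b"ACGT")


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhyloError("non-zero diagonal")
        if not np.isfinite(self.d).all() or (self.d < -1e-12).any():
            raise PhyloError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.taxa)


def _encode(aln: AlignedSet) -> np.ndarray:
    return np.frombuffer(
        "".join(r.residues for r in aln.records).encode(), dtype=np.uint8
    ).reshape(len(aln), aln.length)


def _usable_mask(mat: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    ok = _PROTEIN_OK if alphabet is Alphabet.protein else _DNA_OK
    good = np.isin(mat, list(ok))
    return good


def poisson_distance(aln: AlignedSet,
                     site_policy: str = "complete") -> DistanceMatrix:
    """d = -ln(1 - p) over usable sites (gap/ambiguity handling per policy).

    ``complete`` drops any column with a gap or ambiguous residue in any
    row before counting; ``pairwise`` drops such columns per pair.
    """
    if site_policy not in ("complete", "pairwise"):
        raise PhyloError(f"unknown site_policy {site_policy!r}")
    mat = _encode(aln)
    good = _usable_mask(mat, aln.records[0].alphabet)
    n = len(aln)
    if site_policy == "complete":
        cols = good.all(axis=0)
        if cols.sum() < 2:
            raise PhyloError(
                f"fewer than 2 usable columns under complete deletion "
                f"({int(cols.sum())} left)")
        mat = mat[:, cols]
        good = good[:, cols]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = good[i] & good[j]
            usable = int(use.sum())
            if usable < 2:
                raise PhyloError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): fewer than 2 "
                    f"usable sites")
            p = float((mat[i, use] != mat[j, use]).sum()) / usable
            if p >= 1.0:
                raise PhyloError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): p = 1, Poisson "
                    f"distance undefined")
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(taxa=list(aln.ids), d=d)


def _leaf_nodes(taxa: list[str],
                tns: dendropy.TaxonNamespace) -> list[dendropy.Node]:
    nodes = []
    for t in taxa:
        taxon = tns.get_taxon(t) or tns.new_taxon(t)
        nodes.append(dendropy.Node(taxon=taxon))
    return nodes


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei agglomeration; returns an unrooted tree (trifurcated root).

    Negative intermediate branch lengths are clamped to zero.  When several
    pairs minimize the Q criterion the lowest (i, j) index pair wins.
    """
    n = len(dm)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(dm.taxa, tns)
    d = dm.d.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best, best_q = None, math.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        i, j = active[a], active[b]
        li = sub[a, b] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        parent = join(i, j, li, lj)
        # distances from the new node to everything still active
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge is represented by the side that does not contain the
    lexicographically smallest taxon.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        canon = frozenset(side) if ref not in side else frozenset(leaves - side)
        out.add(canon)
    return out


def bootstrap_support(aln: AlignedSet, b: int, seed: int = 0,
                      site_policy: str = "complete") -> dendropy.Tree:
    """NJ tree with supports from ``b`` column-resampling replicates.

    Replicate ``r`` draws its columns with ``default_rng(seed ^ r)``, so a
    fixed seed reproduces the supports exactly.
    """
    if b < 1:
        raise PhyloError("need at least one bootstrap replicate")
    tree = neighbor_joining(poisson_distance(aln, site_policy))
    target = {bp: 0 for bp in bipartitions(tree)}
    length = aln.length
    succeeded = 0
    for r in range(b):
        rng = np.random.default_rng(seed ^ r)
        cols = rng.integers(0, length, size=length)
        resampled = AlignedSet([
            type(rec)(id=rec.id,
                      residues="".join(rec.residues[c] for c in cols),
                      alphabet=rec.alphabet, description=rec.description)
            for rec in aln.records
        ])
        try:
            rep = neighbor_joining(poisson_distance(resampled, site_policy))
        except PhyloError:
            continue
        succeeded += 1
        for bp in bipartitions(rep):
            if bp in target:
                target[bp] += 1
    if succeeded == 0:
        raise PhyloError("all bootstrap replicates failed (degenerate input)")
    if succeeded < b:
        warnings.warn(f"{b - succeeded} of {b} replicates were degenerate "
                      f"and skipped")
    _annotate_supports(tree, {bp: round(100 * c / succeeded)
                              for bp, c in target.items()})
    return tree


def _annotate_supports(tree: dendropy.Tree,
                       support: dict[frozenset[str], int]) -> None:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        canon = frozenset(side) if ref not in side else frozenset(leaves - side)
        if canon in support:
            nd.label = str(int(support[canon]))


def node_supports(tree: dendropy.Tree) -> dict[frozenset[str], int]:
    """Map canonical bipartition -> integer support, for labelled nodes."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: dict[frozenset[str], int] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf() or nd.label is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        canon = frozenset(side) if ref not in side else frozenset(leaves - side)
        out[canon] = int(nd.label)
    return out


def condense(tree: dendropy.Tree, min_support: int = 50) -> dendropy.Tree:
    """Collapse internal edges whose support is below ``min_support``.

    Unlabelled internal edges are kept.  The input tree is not modified.
    Condensation is idempotent.
    """
    out = tree.clone(depth=1)
    doomed = []
    for nd in out.preorder_node_iter():
        if nd is out.seed_node or nd.is_leaf() or nd.label is None:
            continue
        if int(nd.label) < min_support:
            doomed.append(nd)
    for nd in doomed:
        nd.edge.collapse()
    return out


def tree_to_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    return s.strip()


def newick_to_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    return tree
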