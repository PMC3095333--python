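"""Synthetic inputs with machine-readable truth records.

Every generator is a pure function of its parameters and an explicit seed,
and returns a :class:`TruthRecord` holding everything needed to recompute
the expected downstream quantities without re-reading the sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from apctools.kaks import SENSE_CODONS, _CODON_TABLE, _STOPS
from apctools.repeats import TPR_UNIT_LENGTH, TprProfile, load_default_profile
from apctools.seqio import (
    IUPAC_DNA,
    AlignedSet,
    Alphabet,
    MotifPattern,
    SequenceRecord,
)

__all__ = [
    "TruthRecord",
    "gen_repeat_protein",
    "gen_tree_sequences",
    "gen_cds_pair",
    "gen_promoter_set",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_LINKER_AA = "GSPNQ"  # low-complexity, scores poorly against the profile


@dataclass
class TruthRecord:
    scenario: str
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"scenario": self.scenario, "parameters": self.parameters},
            indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        obj = json.loads(text)
        return cls(scenario=obj["scenario"], parameters=obj["parameters"])


def _mutate_unit(unit: str, rate: float, rng: np.random.Generator) -> str:
    out = list(unit)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_repeat_protein(n_units: int,
                       unit_mutation_rate: float,
                       duplicated_pairs: list[tuple[int, int]] | None = None,
                       linker_len: int = 8,
                       seed: int = 0,
                       pair_divergence: float = 0.1,
                       profile: TprProfile | None = None,
                       record_id: str = "synthetic_repeat",
                       ) -> tuple[SequenceRecord, TruthRecord]:
    """A protein of repeat units derived from the profile consensus.

    Each unit is an independent mutant of the consensus at
    ``unit_mutation_rate``; units named in ``duplicated_pairs`` (1-based)
    instead descend from a shared ancestor unit, each copy diverging at
    ``pair_divergence``, which plants extra pairwise similarity.  Units are
    joined (and flanked) by random low-complexity linkers.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if not 0 <= unit_mutation_rate < 0.5:
        raise ValueError("unit_mutation_rate must be in [0, 0.5)")
    if not 0 <= pair_divergence < 0.5:
        raise ValueError("pair_divergence must be in [0, 0.5)")
    duplicated_pairs = list(duplicated_pairs or [])
    for i, j in duplicated_pairs:
        if not (1 <= i < j <= n_units):
            raise ValueError(f"bad duplicated pair ({i}, {j})")
    if profile is None:
        profile = load_default_profile()
    consensus = profile.consensus
    rng = np.random.default_rng(seed)

    units: dict[int, str] = {}
    for i, j in duplicated_pairs:
        ancestor = _mutate_unit(consensus, unit_mutation_rate, rng)
        units[i] = _mutate_unit(ancestor, pair_divergence, rng)
        units[j] = _mutate_unit(ancestor, pair_divergence, rng)
    for k in range(1, n_units + 1):
        if k not in units:
            units[k] = _mutate_unit(consensus, unit_mutation_rate, rng)

    def linker() -> str:
        return "".join(_LINKER_AA[rng.integers(len(_LINKER_AA))]
                       for _ in range(linker_len))

    parts = [linker()]
    coords = []
    pos = linker_len
    for k in range(1, n_units + 1):
        parts.append(units[k])
        coords.append((pos + 1, pos + TPR_UNIT_LENGTH))
        pos += TPR_UNIT_LENGTH
        parts.append(linker())
        pos += linker_len
    record = SequenceRecord(id=record_id, residues="".join(parts),
                            alphabet=Alphabet.protein)
    truth = TruthRecord(scenario="repeat_protein", parameters={
        "seed": seed,
        "n_units": n_units,
        "unit_mutation_rate": unit_mutation_rate,
        "pair_divergence": pair_divergence,
        "duplicated_pairs": [list(p) for p in duplicated_pairs],
        "linker_len": linker_len,
        "unit_coordinates": [list(c) for c in coords],
        "profile_version": profile.version,
    })
    return record, truth


def _random_topology(n_taxa: int, branch_length,
                     rng: np.random.Generator) -> dendropy.Tree:
    taxa = [f"T{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)

    def bl() -> float:
        if callable(branch_length):
            return float(branch_length(rng))
        return float(branch_length)

    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(nodes[k])
            nodes[k].edge.length = bl()
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
        nd.edge.length = bl()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(d) substitution events per site, uniform over the other 19."""
    out = seq.copy()
    events = rng.poisson(d, size=len(seq))
    for i in np.nonzero(events)[0]:
        for _ in range(events[i]):
            shift = 1 + rng.integers(19)
            out[i] = (out[i] + shift) % 20
    return out


def gen_tree_sequences(topology: dendropy.Tree | str = "random",
                       n_taxa: int = 8,
                       branch_lengths: float = 0.1,
                       seq_len: int = 500,
                       seed: int = 0,
                       ) -> tuple[AlignedSet, TruthRecord]:
    """Protein sequences evolved along a tree under a Poisson process.

    Substitution events per site on a branch of length d are Poisson(d),
    each replacing the residue uniformly with one of the other 19, so the
    expected proportion of differing sites between two leaves approaches
    ``1 - exp(-path_length)`` (exact up to the small 20-state back-mutation
    term that the Poisson correction also ignores).
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    rng = np.random.default_rng(seed)
    if isinstance(topology, str):
        if topology != "random":
            raise ValueError("topology must be a tree or 'random'")
        tree = _random_topology(n_taxa, branch_lengths, rng)
    else:
        tree = topology
    root_seq = rng.integers(20, size=seq_len)
    sequences: dict[str, np.ndarray] = {}

    def down(node, seq_arr):
        for child in node.child_nodes():
            child_seq = _evolve(seq_arr, child.edge.length or 0.0, rng)
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                down(child, child_seq)

    down(tree.seed_node, root_seq)
    records = [
        SequenceRecord(id=label, residues="".join(_AA[c] for c in seq),
                       alphabet=Alphabet.protein)
        for label, seq in sorted(sequences.items())
    ]
    from apctools.phylo import tree_to_newick

    truth = TruthRecord(scenario="tree_sequences", parameters={
        "seed": seed,
        "seq_len": seq_len,
        "newick": tree_to_newick(tree),
        "taxa": [r.id for r in records],
    })
    return AlignedSet(records), truth


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            for _ in range(n_codons)]


def _evolve_cds(codons: list[str], n_subs: int, omega: float,
                rng: np.random.Generator, max_tries: int = 10 ** 7
                ) -> list[str]:
    """Accept/reject substitutions until ``n_subs`` changes are fixed.

    Synonymous proposals are accepted with probability min(1, 1/omega) and
    nonsynonymous ones with min(1, omega), which plants a Ka/Ks of omega;
    proposals creating stop codons are always rejected.
    """
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_nonsyn = min(1.0, omega)
    out = list(codons)
    done = tries = 0
    while done < n_subs:
        tries += 1
        if tries > max_tries:
            raise ValueError("infeasible omega/divergence combination")
        k = rng.integers(len(out))
        pos = rng.integers(3)
        cur = out[k]
        base = _BASES[rng.integers(4)]
        if base == cur[pos]:
            continue
        nxt = cur[:pos] + base + cur[pos + 1:]
        if nxt in _STOPS:
            continue
        syn = _CODON_TABLE[nxt] == _CODON_TABLE[cur]
        accept_p = p_syn if syn else p_nonsyn
        if rng.random() < accept_p:
            out[k] = nxt
            done += 1
    return out


def gen_cds_pair(n_codons: int, omega: float, target_divergence: float,
                 seed: int = 0) -> tuple[tuple[SequenceRecord, SequenceRecord],
                                         TruthRecord]:
    """A codon-sequence pair diverged from a common ancestor at planted omega.

    ``target_divergence`` is the total expected number of fixed
    substitutions per nucleotide site across both branches.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if not 0 <= target_divergence < 0.75:
        raise ValueError("target_divergence must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    ancestor = _random_cds(n_codons, rng)
    per_branch = round(target_divergence * 3 * n_codons / 2)
    if omega == 0:
        # nonsynonymous rate exactly zero: only synonymous changes allowed
        a = _evolve_cds_syn_only(ancestor, per_branch, rng)
        b = _evolve_cds_syn_only(ancestor, per_branch, rng)
    else:
        a = _evolve_cds(ancestor, per_branch, omega, rng)
        b = _evolve_cds(ancestor, per_branch, omega, rng)
    recs = (
        SequenceRecord(id="cds_a", residues="".join(a), alphabet=Alphabet.dna),
        SequenceRecord(id="cds_b", residues="".join(b), alphabet=Alphabet.dna),
    )
    truth = TruthRecord(scenario="cds_pair", parameters={
        "seed": seed, "n_codons": n_codons, "omega": omega,
        "target_divergence": target_divergence,
        "substitutions_per_branch": per_branch,
    })
    return recs, truth


def _evolve_cds_syn_only(codons: list[str], n_subs: int,
                         rng: np.random.Generator) -> list[str]:
    out = list(codons)
    done = tries = 0
    while done < n_subs and tries < 10 ** 7:
        tries += 1
        k = rng.integers(len(out))
        pos = rng.integers(3)
        cur = out[k]
        base = _BASES[rng.integers(4)]
        if base == cur[pos]:
            continue
        nxt = cur[:pos] + base + cur[pos + 1:]
        if nxt in _STOPS or _CODON_TABLE[nxt] != _CODON_TABLE[cur]:
            continue
        out[k] = nxt
        done += 1
    return out


def _expand_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC_DNA[ch][rng.integers(len(IUPAC_DNA[ch]))] for ch in pattern)


def gen_promoter_set(n_background: int,
                     length: int = 1000,
                     base_composition: tuple[float, float, float, float] =
                     (0.25, 0.25, 0.25, 0.25),
                     planted: tuple[MotifPattern, int, int] | None = None,
                     seed: int = 0,
                     ) -> tuple[list[SequenceRecord], list[SequenceRecord],
                                TruthRecord]:
    """Background promoters plus targets with a planted motif.

    Returns ``(background, targets, truth)``.  ``planted`` is
    ``(motif, copies, n_targets)``: each target promoter receives ``copies``
    concrete instances of the motif at non-overlapping random positions.
    """
    if n_background < 2:
        raise ValueError("need at least 2 background promoters")
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)

    def draw(n: int) -> str:
        return "".join(_BASES[i] for i in rng.choice(4, size=n, p=comp))

    background = [
        SequenceRecord(id=f"bg_{i + 1}", residues=draw(length),
                       alphabet=Alphabet.dna)
        for i in range(n_background)
    ]
    targets: list[SequenceRecord] = []
    planted_info = None
    if planted is not None:
        motif, copies, n_targets = planted
        if copies * len(motif) > length:
            raise ValueError("cannot place that many copies")
        positions_by_target = []
        for t in range(n_targets):
            seq = list(draw(length))
            positions: list[int] = []
            tries = 0
            while len(positions) < copies:
                tries += 1
                if tries > 10000:
                    raise ValueError("could not place motif copies")
                pos = int(rng.integers(0, length - len(motif) + 1))
                if any(abs(pos - q) < len(motif) for q in positions):
                    continue
                seq[pos:pos + len(motif)] = _expand_iupac(motif.pattern, rng)
                positions.append(pos)
            targets.append(SequenceRecord(
                id=f"target_{t + 1}", residues="".join(seq),
                alphabet=Alphabet.dna))
            positions_by_target.append(sorted(p + 1 for p in positions))
        planted_info = {
            "motif_name": motif.name, "pattern": motif.pattern,
            "copies": copies, "n_targets": n_targets,
            "positions_1based": positions_by_target,
        }
    truth = TruthRecord(scenario="promoter_set", parameters={
        "seed": seed, "n_background": n_background, "length": length,
        "base_composition": comp.tolist(), "planted": planted_info,
    })
    return background, targets, truth
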