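"""TPR repeat detection, internal-duplication score matrices and APC motifs.

The detector scans a protein with a 34-column position weight profile
(packaged as a versioned TSV fixture, see ``data/tpr_profile.tsv``), selects
non-overlapping windows greedily by descending score, and reports the
surviving windows N-terminal to C-terminal.  Repeat units have a fixed
length of 34 residues and no internal indels, which keeps all-vs-all score
matrices index-comparable between proteins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from apctools.align import AlignmentParams, AlignMode, align_local
from apctools.seqio import Alphabet, SequenceRecord

__all__ = [
    "TPR_UNIT_LENGTH",
    "TprProfile",
    "RepeatDomain",
    "DomainScoreMatrix",
    "DuplicationBlock",
    "ProteinMotifReport",
    "load_default_profile",
    "detect_tpr",
    "extract_domains",
    "build_matrix",
    "find_blocks",
    "scan_protein_motifs",
]

TPR_UNIT_LENGTH = 34
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

C_BOX_RE = re.compile(r"DR[FY]IP.R")
KEN_BOX_RE = re.compile(r"KEN")
D_BOX_RE = re.compile(r"(?=R..L)")  # overlapping RxxL matches


@dataclass(frozen=True)
class TprProfile:
    """A 34 x 20 position weight model for one repeat unit.

    ``weights[i, j]`` scores amino acid ``_AA_ORDER[j]`` at unit position
    ``i``.  ``default_threshold`` is the calibrated per-window score cut.
    """

    weights: np.ndarray
    default_threshold: float
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if self.weights.shape != (TPR_UNIT_LENGTH, len(_AA_ORDER)):
            raise ValueError(
                f"profile must be {TPR_UNIT_LENGTH}x{len(_AA_ORDER)}, "
                f"got {self.weights.shape}"
            )

    @property
    def consensus(self) -> str:
        return "".join(_AA_ORDER[j] for j in self.weights.argmax(axis=1))

    def score_window(self, window: str) -> float:
        if len(window) != TPR_UNIT_LENGTH:
            raise ValueError("window must be 34 residues")
        idx = [_AA_ORDER.find(c) for c in window]
        # unknown residues (X) contribute the column mean
        return float(sum(
            self.weights[i, j] if j >= 0 else self.weights[i].mean()
            for i, j in enumerate(idx)
        ))

    def scan(self, residues: str) -> np.ndarray:
        """Score of every 34-residue window (empty if sequence too short)."""
        n = len(residues) - TPR_UNIT_LENGTH + 1
        if n <= 0:
            return np.empty(0)
        col = np.full(256, np.nan)
        for j, aa in enumerate(_AA_ORDER):
            col[ord(aa)] = j
        codes = col[np.frombuffer(residues.encode(), dtype=np.uint8)]
        means = self.weights.mean(axis=1)
        scores = np.zeros(n)
        for i in range(TPR_UNIT_LENGTH):
            c = codes[i:i + n]
            known = ~np.isnan(c)
            scores[known] += self.weights[i, c[known].astype(int)]
            scores[~known] += means[i]
        return scores

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TprProfile":
        version = "unversioned"
        threshold = None
        rows: list[list[float]] = []
        header: list[str] | None = None
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if line.startswith("# version:"):
                    version = line.split(":", 1)[1].strip()
                elif line.startswith("# default_threshold:"):
                    threshold = float(line.split(":", 1)[1])
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            rows.append([float(x) for x in parts[1:]])
        if header is None or threshold is None:
            raise ValueError(f"malformed profile file: {path}")
        w = np.array(rows)
        order = [header.index(a) for a in _AA_ORDER]
        return cls(weights=w[:, order], default_threshold=threshold,
                   version=version)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# version: {self.version}",
                 f"# default_threshold: {self.default_threshold}",
                 "pos\t" + "\t".join(_AA_ORDER)]
        for i in range(TPR_UNIT_LENGTH):
            lines.append(f"{i + 1}\t" + "\t".join(
                f"{x:.4f}" for x in self.weights[i]))
        Path(path).write_text("\n".join(lines) + "\n")


def load_default_profile() -> TprProfile:
    """Load the packaged, calibrated repeat profile."""
    ref = resources.files("apctools").joinpath("data/tpr_profile.tsv")
    with resources.as_file(ref) as path:
        return TprProfile.from_tsv(path)


@dataclass(frozen=True)
class RepeatDomain:
    """One detected 34-residue repeat unit (1-based inclusive coordinates)."""

    parent_id: str
    index: int
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != TPR_UNIT_LENGTH:
            raise ValueError("repeat unit must span exactly 34 residues")
        if self.start < 1:
            raise ValueError("coordinates are 1-based")


def detect_tpr(protein: SequenceRecord,
               profile: TprProfile | None = None,
               threshold: float | None = None) -> list[RepeatDomain]:
    """Greedy best-first selection of non-overlapping scoring windows.

    Proteins shorter than one unit yield an empty list.  Ties in window
    score are broken toward the leftmost start for determinism.
    """
    if profile is None:
        profile = load_default_profile()
    if threshold is None:
        threshold = profile.default_threshold
    scores = profile.scan(protein.residues)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    taken: list[tuple[int, float]] = []
    occupied = np.zeros(len(protein.residues), dtype=bool)
    for i in order:
        if scores[i] < threshold:
            break
        if occupied[i:i + TPR_UNIT_LENGTH].any():
            continue
        occupied[i:i + TPR_UNIT_LENGTH] = True
        taken.append((i, float(scores[i])))
    taken.sort()
    return [
        RepeatDomain(parent_id=protein.id, index=k + 1,
                     start=i + 1, end=i + TPR_UNIT_LENGTH, score=s)
        for k, (i, s) in enumerate(taken)
    ]


def extract_domains(protein: SequenceRecord,
                    domains: list[RepeatDomain]) -> list[SequenceRecord]:
    """Cut each detected unit out as a 34-residue record."""
    out = []
    for dom in domains:
        if dom.end > len(protein.residues):
            raise ValueError(
                f"domain {dom.index} of {dom.parent_id} out of bounds")
        out.append(SequenceRecord(
            id=f"{dom.parent_id}/unit{dom.index}",
            residues=protein.residues[dom.start - 1:dom.end],
            alphabet=Alphabet.protein,
            description=f"{dom.parent_id} repeat unit {dom.index} "
                        f"{dom.start}-{dom.end}",
        ))
    return out


@dataclass
class DomainScoreMatrix:
    """All-vs-all local-alignment scores between two sets of repeat units."""

    rows_parent: str
    cols_parent: str
    scores: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    @property
    def is_self(self) -> bool:
        return self.rows_parent == self.cols_parent

    @property
    def shading(self) -> np.ndarray:
        """Min-max normalized intensities in [0, 1], monotone in score."""
        lo, hi = self.scores.min(), self.scores.max()
        if hi == lo:
            return np.ones_like(self.scores)
        return (self.scores - lo) / (hi - lo)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t" + "\t".join(self.col_ids)]
        for rid, row in zip(self.row_ids, self.scores):
            lines.append(rid + "\t" + "\t".join(f"{x:g}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


def build_matrix(domains_a: list[SequenceRecord],
                 domains_b: list[SequenceRecord],
                 params: AlignmentParams | None = None) -> DomainScoreMatrix:
    """Score every unit of one set against every unit of the other."""
    if not domains_a or not domains_b:
        raise ValueError("need at least one repeat unit on each side")
    if params is None:
        params = AlignmentParams(mode=AlignMode.local)
    scores = np.zeros((len(domains_a), len(domains_b)))
    for i, da in enumerate(domains_a):
        for j, db in enumerate(domains_b):
            scores[i, j] = align_local(da, db, params).score
    return DomainScoreMatrix(
        rows_parent=domains_a[0].id.rsplit("/", 1)[0],
        cols_parent=domains_b[0].id.rsplit("/", 1)[0],
        scores=scores,
        row_ids=[d.id for d in domains_a],
        col_ids=[d.id for d in domains_b],
    )


@dataclass(frozen=True)
class DuplicationBlock:
    """A diagonal run of high-scoring cells (1-based unit ordinals)."""

    row_range: tuple[int, int]
    col_range: tuple[int, int]
    mean_score: float

    def __post_init__(self) -> None:
        rlen = self.row_range[1] - self.row_range[0] + 1
        clen = self.col_range[1] - self.col_range[0] + 1
        if rlen != clen:
            raise ValueError("row and column ranges must have equal length")
        if rlen < 2:
            raise ValueError("a block spans at least 2 units")


def find_blocks(matrix: DomainScoreMatrix,
                score_quantile: float = 0.75,
                min_run: int = 2) -> list[DuplicationBlock]:
    """Maximal diagonal runs of cells above a per-matrix score quantile.

    For self-comparisons the main diagonal is excluded both from the
    quantile estimate and from the runs; only the upper triangle is
    reported (the matrix is symmetric).
    """
    s = matrix.scores
    n_rows, n_cols = s.shape
    if matrix.is_self:
        mask = ~np.eye(n_rows, n_cols, dtype=bool)
        pool = s[mask]
        offsets = range(1, n_cols)
    else:
        pool = s.ravel()
        offsets = range(-(n_rows - 1), n_cols)
    if pool.size == 0:
        return []
    cut = float(np.quantile(pool, score_quantile))

    blocks: list[DuplicationBlock] = []
    for off in offsets:
        cells = [(i, i + off) for i in range(n_rows)
                 if 0 <= i + off < n_cols]
        run: list[tuple[int, int]] = []
        for i, j in cells + [(-1, -1)]:  # sentinel flushes the last run
            if i >= 0 and s[i, j] > cut:
                run.append((i, j))
                continue
            if len(run) >= min_run:
                blocks.append(DuplicationBlock(
                    row_range=(run[0][0] + 1, run[-1][0] + 1),
                    col_range=(run[0][1] + 1, run[-1][1] + 1),
                    mean_score=float(np.mean([s[a, b] for a, b in run])),
                ))
            run = []
    blocks.sort(key=lambda b: -b.mean_score)
    return blocks


@dataclass(frozen=True)
class ProteinMotifReport:
    """Short linear APC motifs found in one protein sequence."""

    parent_id: str
    has_c_box: bool
    c_box_position: int | None  # 1-based start, first match
    has_ir_tail: bool
    ken_boxes: tuple[int, ...]
    d_boxes: tuple[int, ...]


def scan_protein_motifs(protein: SequenceRecord) -> ProteinMotifReport:
    """Scan for C-box (DR[FY]IPxR), IR tail, KEN boxes and D boxes (RxxL)."""
    seq = protein.residues
    c_box = C_BOX_RE.search(seq)
    return ProteinMotifReport(
        parent_id=protein.id,
        has_c_box=c_box is not None,
        c_box_position=c_box.start() + 1 if c_box else None,
        has_ir_tail=seq.endswith("IR"),
        ken_boxes=tuple(m.start() + 1 for m in KEN_BOX_RE.finditer(seq)),
        d_boxes=tuple(m.start() + 1 for m in D_BOX_RE.finditer(seq)),
    )
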