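"""Protein-family sequence comparison: identity/similarity, trees, TM scan.

Pairwise global alignment (Needleman-Wunsch/Gotoh affine gaps, BLOSUM62),
percent identity and strong-group percent similarity under two denominator
conventions, neighbor-joining trees on alignment-derived p-distances, and a
Kyte-Doolittle hydropathy scan for candidate transmembrane segments --
the quantities used to situate a tetraspan membrane protein within its
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "STRONG_GROUPS",
    "ProteinRecord",
    "PairwiseAlignment",
    "read_fasta",
    "write_fasta",
    "global_align",
    "percent_identity",
    "percent_similarity",
    "percent_table",
    "p_distance_matrix",
    "build_tree",
    "HydropathyScan",
    "hydropathy_segments",
]

#: the standard strong-similarity residue groups used in alignment shading
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")

#: sense strand of the 21-nt shRNA hairpin used to knock down pasiflora2
PASIFLORA2_SHRNA_SENSE = "TACAATGTGATTATGGTGCTC"

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (20-letter alphabet plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairwiseAlignment:
    """Two gapped strings of equal length plus the alignment score."""

    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")
        if not self.aligned_a:
            raise ValueError("zero-length alignment")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    @property
    def gap_count(self) -> int:
        return self.aligned_a.count("-") + self.aligned_b.count("-")

    def column_pairs(self) -> Iterable[tuple[str, str]]:
        """Residue pairs of gap-free columns."""
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x != "-" and y != "-":
                yield x, y

    def write_fasta(self, path: str | Path) -> None:
        Path(path).write_text(
            f">{self.a_id}\n{self.aligned_a}\n>{self.b_id}\n{self.aligned_b}\n"
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    Gap penalties are the classic protein defaults (open 10, extend 0.1 per
    residue, applied to terminal gaps as well).  Among co-optimal alignments
    the aligner's deterministic first traceback is returned.
    """
    if isinstance(a, str):
        a = ProteinRecord("a", a)
    if isinstance(b, str):
        b = ProteinRecord("b", b)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    return PairwiseAlignment(
        a_id=a.id,
        b_id=b.id,
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
    )


def _denominator(aln: PairwiseAlignment, convention: str) -> int:
    if convention == "alignment":
        return aln.length
    if convention == "shorter":
        return min(len(aln.seq_a), len(aln.seq_b))
    raise ValueError("denominator convention must be 'alignment' or 'shorter'")


def percent_identity(aln: PairwiseAlignment, denominator: str = "alignment") -> float:
    """100 x identical columns / denominator.

    ``denominator``: ``"alignment"`` (gapped alignment length) or
    ``"shorter"`` (length of the shorter input sequence).
    """
    matches = sum(1 for x, y in aln.column_pairs() if x == y)
    return 100.0 * matches / _denominator(aln, denominator)


def _strongly_similar(x: str, y: str) -> bool:
    if x == y:
        return True
    return any(x in g and y in g for g in STRONG_GROUPS)


def percent_similarity(aln: PairwiseAlignment, denominator: str = "alignment") -> float:
    """100 x (identical or strong-group) columns / denominator."""
    similar = sum(1 for x, y in aln.column_pairs() if _strongly_similar(x, y))
    return 100.0 * similar / _denominator(aln, denominator)


def percent_table(records: Sequence[ProteinRecord], denominator: str = "shorter",
                  **align_kwargs) -> pd.DataFrame:
    """Tidy table of pairwise identity/similarity percentages."""
    rows = []
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            aln = global_align(a, b, **align_kwargs)
            rows.append({
                "a": a.id,
                "b": b.id,
                "identity_pct": percent_identity(aln, denominator),
                "similarity_pct": percent_similarity(aln, denominator),
                "score": aln.score,
            })
    return pd.DataFrame(rows)


def p_distance_matrix(records: Sequence[ProteinRecord], **align_kwargs) -> DistanceMatrix:
    """Pairwise p-distances 1 - identical/aligned-columns from global alignments.

    Taxa are ordered lexicographically by id so the matrix (and any tree
    built from it) is independent of input order.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    ordered = sorted(records, key=lambda r: r.id)
    n = len(ordered)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(ordered[i], ordered[j], **align_kwargs)
            pairs = list(aln.column_pairs())
            matches = sum(1 for x, y in pairs if x == y)
            d = 1.0 - matches / len(pairs) if pairs else 1.0
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=[r.id for r in ordered])


def build_tree(records: Sequence[ProteinRecord], method: str = "nj", **align_kwargs):
    """Neighbor-joining tree on p-distances; returns a scikit-bio TreeNode.

    Requires >= 3 sequences with unique ids; serialize with
    ``str(tree)`` / ``tree.write`` (Newick).
    """
    if method != "nj":
        raise ValueError("only neighbor joining is implemented")
    if len(records) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    dm = p_distance_matrix(records, **align_kwargs)
    return nj(dm)


@dataclass
class HydropathyScan:
    """Candidate TM segments as 0-based half-open (start, end) spans."""

    segments: list[tuple[int, int]]
    window: int
    threshold: float
    too_short: bool = False


def hydropathy_segments(
    record: ProteinRecord | str, window: int = 19, threshold: float = 1.6
) -> HydropathyScan:
    """Kyte-Doolittle sliding-window scan for hydrophobic segments.

    Window means above ``threshold`` mark candidate transmembrane cores; each
    maximal run of qualifying windows is reported as the full residue span it
    covers.  A window of 19 with threshold 1.6 is the classic setting for
    membrane-spanning helices.  Sequences shorter than the window yield an
    empty scan flagged ``too_short``.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    if len(seq) < window:
        return HydropathyScan([], window, threshold, too_short=True)
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means > threshold
    segments: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start, i - 1 + window))
            start = None
    if start is not None:
        segments.append((start, len(above) - 1 + window))
    return HydropathyScan(segments, window, threshold)
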