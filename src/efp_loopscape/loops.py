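"""Locating and classifying the seven-residue β3Ωβ4 loop window.

Each curated sequence is mapped onto a reference EF-P (E. coli numbering by
default, residues 31-37) either through a supplied multiple alignment or
through reference-anchored global pairwise alignment. Windows that require a
gap — a deletion in the query inside the window, or a query-only insertion
strictly within it — are rejected, because they break the 7-column homology
the downstream statistics assume. Accepted windows are classified by the
residue at the loop tip (position 34 equivalent: K = lysine-type,
R = arginine-type) and by the presence of proline at the −2 position
(position 32 equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "PairwiseAlignment",
    "LoopAssignment",
    "LoopRejection",
    "LoopClass",
    "DEFAULT_WINDOW",
    "align_pair",
    "extract_loop",
    "extract_loops_pairwise",
    "extract_loops_msa",
    "classify_loop",
    "loops_to_frame",
    "read_msa",
]

DEFAULT_WINDOW = (31, 37)  # 1-based inclusive reference residue interval

# window-internal positions, 1-based within the 7-mer
_MINUS2_POS = 2  # reference residue 32
_TIP_POS = 4  # reference residue 34


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of one query against the reference."""

    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class LoopAssignment:
    """The 7-residue window of one protein, with tip and −2 identified."""

    protein_id: str
    loop_seq: str
    minus2_residue: str
    tip_residue: str
    source: str  # "msa" or "pairwise"

    def __post_init__(self):
        if len(self.loop_seq) < _TIP_POS:
            raise ValueError("loop window too short to carry tip and -2 positions")
        if "-" in self.loop_seq:
            raise ValueError("loop_seq must be gap-free")
        if self.loop_seq[_MINUS2_POS - 1] != self.minus2_residue:
            raise ValueError("minus2_residue must equal window position 2")
        if self.loop_seq[_TIP_POS - 1] != self.tip_residue:
            raise ValueError("tip_residue must equal window position 4")


@dataclass(frozen=True)
class LoopRejection:
    protein_id: str
    reason: str  # e.g. "gap-in-window"


@dataclass(frozen=True)
class LoopClass:
    protein_id: str
    loop_type: str  # "lysine-type", "arginine-type", or "other(<residue>)"
    has_P_minus2: bool


def _aligner(substitution_matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0):
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        substitution_matrices.load("BLOSUM62") if substitution_matrix is None else substitution_matrix
    )
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def align_pair(
    query: str,
    reference: str,
    substitution_matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    reference_id: str = "reference",
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring (Gotoh).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. Residues
    outside the substitution matrix alphabet are scored as X. Deterministic:
    among co-optimal alignments the aligner's canonical first traceback is
    returned; the score is the DP optimum either way.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(substitution_matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    q = _sanitize(query, alphabet)
    r = _sanitize(reference, alphabet)
    alignment = aligner.align(q, r)[0]
    return PairwiseAlignment(
        query_id=query_id,
        reference_id=reference_id,
        aligned_query=str(alignment[0]),
        aligned_reference=str(alignment[1]),
        score=float(alignment.score),
    )


def extract_loop(
    aligned_query: str,
    aligned_reference: str,
    protein_id: str,
    reference_window=DEFAULT_WINDOW,
    source: str = "pairwise",
):
    """Read the query residues homologous to reference residues 31-37.

    Reference residues are counted over non-gap reference characters
    (1-based, inclusive window). Returns a :class:`LoopAssignment`, or a
    :class:`LoopRejection` tagged ``gap-in-window`` when the query has a gap
    in any window column or an insertion (reference-gap column) strictly
    inside the window.
    """
    lo, hi = reference_window
    if hi - lo + 1 < _TIP_POS:
        raise ValueError("window too short to contain the tip position")
    n_ref = sum(1 for c in aligned_reference if c != "-")
    if n_ref < hi:
        raise ValueError(f"reference has {n_ref} residues; window needs {hi}")

    cols = []  # alignment column of each window reference residue
    pos = 0
    for col, c in enumerate(aligned_reference):
        if c != "-":
            pos += 1
            if lo <= pos <= hi:
                cols.append(col)
            if pos == hi:
                break

    window_chars = [aligned_query[c] for c in cols]
    if "-" in window_chars:
        return LoopRejection(protein_id=protein_id, reason="gap-in-window")
    # query-only insertion columns strictly inside the window
    for col in range(cols[0] + 1, cols[-1]):
        if aligned_reference[col] == "-":
            return LoopRejection(protein_id=protein_id, reason="gap-in-window")

    loop = "".join(window_chars)
    return LoopAssignment(
        protein_id=protein_id,
        loop_seq=loop,
        minus2_residue=loop[_MINUS2_POS - 1],
        tip_residue=loop[_TIP_POS - 1],
        source=source,
    )


def classify_loop(assignment: LoopAssignment) -> LoopClass:
    """Classify a loop by its tip residue and −2 proline."""
    tip = assignment.tip_residue
    if tip == "K":
        loop_type = "lysine-type"
    elif tip == "R":
        loop_type = "arginine-type"
    else:
        loop_type = f"other({tip})"
    return LoopClass(
        protein_id=assignment.protein_id,
        loop_type=loop_type,
        has_P_minus2=assignment.minus2_residue == "P",
    )


def extract_loops_pairwise(
    records,
    reference_sequence: str,
    reference_window=DEFAULT_WINDOW,
    **align_kwargs,
):
    """Align every record against the reference and extract its window.

    Returns ``(assignments, rejections)``.
    """
    assignments, rejections = [], []
    for rec in records:
        aln = align_pair(rec.sequence, reference_sequence, query_id=rec.protein_id, **align_kwargs)
        result = extract_loop(
            aln.aligned_query, aln.aligned_reference, rec.protein_id, reference_window, source="pairwise"
        )
        (assignments if isinstance(result, LoopAssignment) else rejections).append(result)
    return assignments, rejections


def read_msa(path) -> dict:
    """Read an aligned FASTA into {sequence id: aligned string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_loops_msa(
    msa: dict,
    reference_id: str,
    reference_window=DEFAULT_WINDOW,
    ids=None,
):
    """Extract windows from a precomputed MSA containing the reference row."""
    if reference_id not in msa:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref_row = msa[reference_id]
    assignments, rejections = [], []
    for pid, row in msa.items():
        if pid == reference_id:
            continue
        if ids is not None and pid not in ids:
            continue
        result = extract_loop(row, ref_row, pid, reference_window, source="msa")
        (assignments if isinstance(result, LoopAssignment) else rejections).append(result)
    return assignments, rejections


def loops_to_frame(assignments, rejections=()):
    """Tabulate assignments (+ classifications) and rejections."""
    import pandas as pd

    rows = []
    for a in assignments:
        c = classify_loop(a)
        rows.append(
            {
                "protein_id": a.protein_id,
                "loop_seq": a.loop_seq,
                "minus2": a.minus2_residue,
                "tip": a.tip_residue,
                "loop_type": c.loop_type,
                "has_P32": int(c.has_P_minus2),
                "source": a.source,
                "status": "ok",
            }
        )
    for r in rejections:
        rows.append(
            {
                "protein_id": r.protein_id,
                "loop_seq": "",
                "minus2": "",
                "tip": "",
                "loop_type": "",
                "has_P32": "",
                "source": "",
                "status": r.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "loop_seq", "minus2", "tip", "loop_type", "has_P32", "source", "status"],
    )
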