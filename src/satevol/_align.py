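"""Shared pairwise-alignment utilities.

Scoring convention used throughout the package: a gap of length ``L`` costs
``gap_open + L * gap_extend`` (both negative), i.e. the first gapped position
pays both the opening and the extension penalty.  Defaults: match +2,
mismatch -3, gap open -8, gap extend -1.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP_OPEN = -8
DEFAULT_GAP_EXTEND = -1

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=16)
def _aligner(mode, match, mismatch, gap_open, gap_extend):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gap position only;
    # fold the per-position extension into it to get open + L*extend.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    ref: str,
    seq: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Global affine-gap alignment; returns (gapped_ref, gapped_seq, score)."""
    aligner = _aligner("global", match, mismatch, gap_open, gap_extend)
    aln = aligner.align(ref, seq)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def local_align(
    query: str,
    target: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
):
    """Local affine-gap alignment.

    Returns ``(q_aln, t_aln, q_start, q_end, t_start, t_end, score)`` with
    gapped strings covering the aligned region only, or ``None`` when the
    optimal local score is not positive.
    """
    aligner = _aligner("local", match, mismatch, gap_open, gap_extend)
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
    return str(aln[0]), str(aln[1]), q_start, q_end, t_start, t_end, float(aln.score)


def identity(gapped_a: str, gapped_b: str) -> float:
    """Fraction of identical columns; gap columns count as mismatches."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings differ in length")
    if not gapped_a:
        return 0.0
    matches = sum(
        1
        for x, y in zip(gapped_a, gapped_b)
        if x == y and x != "-" and x != "N"
    )
    return matches / len(gapped_a)
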