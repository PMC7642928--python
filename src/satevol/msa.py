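"""Reference-anchored (star) multiple alignment, site-coverage masking and
consensus building for satellite monomers.

Monomers of one family are near-identical, so each sequence is globally
aligned to a reference and the pairwise alignments are merged on reference
columns.  This is deterministic given inputs and parameters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    global_align,
)

#: maps a sorted tuple of bases to its IUPAC ambiguity code
_IUPAC = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "C"): "M", ("A", "G"): "R", ("A", "T"): "W",
    ("C", "G"): "S", ("C", "T"): "Y", ("G", "T"): "K",
    ("A", "C", "G"): "V", ("A", "C", "T"): "H",
    ("A", "G", "T"): "D", ("C", "G", "T"): "B",
    ("A", "C", "G", "T"): "N",
}


class EmptyAlignmentError(ValueError):
    """Raised when masking removes every column."""


@dataclass
class Alignment:
    """A gapped multiple alignment with an optional column mask.

    ``mask[j]`` is True when column ``j`` is kept.  De-gapping any row
    recovers the corresponding input sequence verbatim.
    """

    labels: list[str]
    rows: list[str]
    mask: np.ndarray = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.mask is None:
            self.mask = np.ones(self.length, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.length,):
                raise ValueError("mask length does not match alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def kept_rows(self) -> list[str]:
        """Rows restricted to kept (unmasked) columns."""
        idx = np.flatnonzero(self.mask)
        return ["".join(row[j] for j in idx) for row in self.rows]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def align_monomers(
    monomers: list[str],
    reference: str,
    labels: list[str] | None = None,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Star-align ``monomers`` against ``reference``.

    Each monomer is globally aligned to the reference with affine gaps; the
    pairwise alignments are merged on reference columns.  Insertions relative
    to the reference are left-justified within their inter-reference slot.
    """
    if not monomers:
        raise ValueError("no monomers to align")
    if labels is None:
        labels = [f"seq{i}" for i in range(len(monomers))]
    ref = reference.upper()
    n_ref = len(ref)

    # Per sequence: list over reference slots 0..n_ref of inserted strings,
    # plus the character matched to each reference position ('-' if deleted).
    per_seq_inserts: list[list[str]] = []
    per_seq_chars: list[list[str]] = []
    for mono in monomers:
        a_ref, a_seq, _ = global_align(
            ref, mono.upper(), match, mismatch, gap_open, gap_extend
        )
        inserts = [""] * (n_ref + 1)
        chars = []
        ref_pos = 0
        for rc, sc in zip(a_ref, a_seq):
            if rc == "-":
                inserts[ref_pos] += sc
            else:
                chars.append(sc)
                ref_pos += 1
        per_seq_inserts.append(inserts)
        per_seq_chars.append(chars)

    slot_width = [
        max(len(ins[s]) for ins in per_seq_inserts) for s in range(n_ref + 1)
    ]

    rows = []
    for inserts, chars in zip(per_seq_inserts, per_seq_chars):
        parts = []
        for s in range(n_ref):
            parts.append(inserts[s].ljust(slot_width[s], "-"))
            parts.append(chars[s])
        parts.append(inserts[n_ref].ljust(slot_width[n_ref], "-"))
        rows.append("".join(parts))

    return Alignment(
        labels=list(labels),
        rows=rows,
        provenance={
            "reference": ref,
            "match": match,
            "mismatch": mismatch,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
        },
    )


def site_coverage_mask(alignment: Alignment, min_cov: float = 0.85) -> Alignment:
    """Flag columns whose non-gap fraction is below ``min_cov`` as removed.

    Masking is idempotent: already-removed columns stay removed.
    """
    n = alignment.n_rows
    cov = np.empty(alignment.length)
    for j in range(alignment.length):
        cov[j] = sum(1 for row in alignment.rows if row[j] != "-") / n
    mask = alignment.mask & (cov >= min_cov)
    if not mask.any():
        raise EmptyAlignmentError(
            f"site-coverage mask at {min_cov} removed every column"
        )
    out = Alignment(
        labels=list(alignment.labels),
        rows=list(alignment.rows),
        mask=mask,
        provenance=dict(alignment.provenance),
    )
    out.provenance["min_site_coverage"] = min_cov
    return out


def consensus(alignment: Alignment, tie_policy: str = "iupac") -> str:
    """Majority-rule consensus over kept columns.

    Ties map to the IUPAC ambiguity code of the tied set (``tie_policy=
    "iupac"``) or to the alphabetically first base (``"first"``).  Columns
    with a gap majority are omitted.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    if tie_policy not in ("iupac", "first"):
        raise ValueError(f"unknown tie policy: {tie_policy!r}")
    out = []
    idx = np.flatnonzero(alignment.mask)
    for j in idx:
        col = [row[j] for row in alignment.rows]
        n_gap = col.count("-")
        if n_gap * 2 > len(col):
            continue
        counts = Counter(c for c in col if c in "ACGT")
        if not counts:
            out.append("N")
            continue
        top = max(counts.values())
        winners = tuple(sorted(b for b, c in counts.items() if c == top))
        if len(winners) == 1 or tie_policy == "first":
            out.append(winners[0])
        else:
            out.append(_IUPAC[winners])
    return "".join(out)
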