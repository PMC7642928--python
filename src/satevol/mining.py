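"""Detection of tandem satellite arrays and extraction of phased monomers.

Three complementary detectors are provided: a periodicity scan over exact
k-mer recurrences (:func:`find_tandem_arrays`), a seed-and-extend local
search against a consensus query (:func:`search_by_consensus`), and a
windowed match-density boundary refiner (:func:`dotplot_boundaries`).
:func:`extract_monomers` phases an array against a reference and emits its
repeat units.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._align import local_align, revcomp

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")


class PhaseError(ValueError):
    """Array period is irreconcilable with the reference length."""


@dataclass
class SatArray:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str
    period: int
    n_copies: float
    mean_identity_to_query: float = 1.0
    low_confidence: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid array interval")
        if self.period < 10:
            raise ValueError("period must be >= 10")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Monomer:
    id: str
    array_id: str
    species: str
    sequence: str
    phase_offset: int
    full_length: bool


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)[:5]}")
    return seq


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y and x != "N") / n


def find_tandem_arrays(
    sequence: str,
    min_period: int = 10,
    max_period: int = 2000,
    min_copies: int = 2,
    scaffold: str = "seq",
    k: int = 12,
    identity_floor: float = 0.65,
) -> list[SatArray]:
    """Detect tandem arrays from the spacing distribution of repeated k-mers.

    Positions whose k-mer recurs at a spacing within [min_period,
    max_period] are clustered into regions; each region's period is the
    modal spacing.  Array boundaries are extended outward while per-copy
    identity to the boundary unit stays above ``identity_floor``.  Returns
    maximal non-overlapping arrays sorted by coordinate.
    """
    if min_period < 10:
        raise ValueError("min_period must be >= 10")
    if max_period > 2000:
        raise ValueError("max_period must be <= 2000")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    if not sequence:
        return []
    seq = _check_sequence(sequence)

    positions: dict[str, int] = {}
    evidence: list[tuple[int, int]] = []  # (position, spacing)
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        prev = positions.get(km)
        if prev is not None and min_period <= i - prev <= max_period:
            evidence.append((prev, i - prev))
        positions[km] = i
    if not evidence:
        return []

    evidence.sort()
    regions: list[list[tuple[int, int]]] = [[evidence[0]]]
    for pos, spacing in evidence[1:]:
        if pos - regions[-1][-1][0] > max_period:
            regions.append([])
        regions[-1].append((pos, spacing))

    arrays = []
    for region in regions:
        spacings = [s for _, s in region]
        period = Counter(spacings).most_common(1)[0][0]
        near = [s for s in spacings if abs(s - period) <= max(2, period // 20)]
        period = int(np.median(near))
        support = [p for p, s in region if abs(s - period) <= max(2, period // 20)]
        if len(support) < max(10, period // 4):
            continue
        start = min(support)
        end = max(support) + period + k
        end = min(end, len(seq))

        # extend boundaries copy by copy while identity holds up
        unit_left = seq[start : start + period]
        while start - period >= 0 and _ungapped_identity(
            seq[start - period : start], unit_left
        ) >= identity_floor:
            start -= period
            unit_left = seq[start : start + period]
        unit_right = seq[end - period : end]
        while end + period <= len(seq) and _ungapped_identity(
            seq[end : end + period], unit_right
        ) >= identity_floor:
            end += period
            unit_right = seq[end - period : end]

        n_copies = (end - start) / period
        if n_copies < min_copies:
            continue
        arrays.append(
            SatArray(
                scaffold=scaffold,
                start=start,
                end=end,
                strand="+",
                period=period,
                n_copies=n_copies,
            )
        )

    # keep maximal non-overlapping arrays, longest first
    arrays.sort(key=lambda a: (-(a.length), a.start))
    chosen: list[SatArray] = []
    for arr in arrays:
        if all(arr.end <= c.start or c.end <= arr.start for c in chosen):
            chosen.append(arr)
    chosen.sort(key=lambda a: a.start)
    return chosen


def _collect_hits(
    query: str,
    genome: str,
    min_identity: float,
    min_coverage: float,
    k: int,
) -> list[tuple[int, int, float, float]]:
    """Seed-and-extend hits of ``query`` (one strand) on ``genome``:
    (start, end, identity, coverage)."""
    qlen = len(query)
    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(0, qlen - k + 1):
        km = query[i : i + k]
        if "N" not in km:
            kmer_pos[km].append(i)

    seed_positions = []
    for g in range(len(genome) - k + 1):
        if genome[g : g + k] in kmer_pos:
            seed_positions.append(g)
    if not seed_positions:
        return []

    # cluster seeds into candidate windows
    windows = []
    w_start = seed_positions[0]
    prev = seed_positions[0]
    for g in seed_positions[1:]:
        if g - prev > qlen:
            windows.append((w_start, prev + k))
            w_start = g
        prev = g
    windows.append((w_start, prev + k))

    hits: list[tuple[int, int, float, float]] = []

    def recurse(seg_start: int, seg_seq: str, depth: int = 0):
        if len(seg_seq) < 0.3 * qlen or depth > 200:
            return
        res = local_align(query, seg_seq)
        if res is None:
            return
        q_aln, t_aln, qs, qe, ts, te, _ = res
        matches = sum(1 for x, y in zip(q_aln, t_aln) if x == y and x != "-")
        ident = matches / max(len(q_aln), 1)
        cov = (qe - qs) / qlen
        if ident >= min_identity and cov >= min_coverage:
            hits.append((seg_start + ts, seg_start + te, ident, cov))
            recurse(seg_start, seg_seq[:ts], depth + 1)
            recurse(seg_start + te, seg_seq[te:], depth + 1)

    for ws, we in windows:
        lo = max(0, ws - qlen)
        hi = min(len(genome), we + qlen)
        recurse(lo, genome[lo:hi])
    return hits


def search_by_consensus(
    genome: str,
    query: str,
    min_identity: float = 0.65,
    min_coverage: float = 0.70,
    scaffold: str = "seq",
    k: int = 11,
    merge_gap_frac: float = 0.5,
) -> list[SatArray]:
    """Seed-and-extend local search of a consensus query on both strands.

    Identity is matches over aligned columns (gap columns count as
    mismatches); coverage is the aligned query span over the query length.
    Same-strand hits separated by at most ``merge_gap_frac * len(query)``
    are merged into arrays.
    """
    if len(query) < 50:
        raise ValueError("query must be at least 50 bp")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if not genome:
        return []
    genome = _check_sequence(genome)
    query = _check_sequence(query)
    if query.count("N") > 0.1 * len(query):
        logger.warning("query has more than 10%% N")

    qlen = len(query)
    stranded_hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for start, end, ident, cov in _collect_hits(
            q, genome, min_identity, min_coverage, k
        ):
            stranded_hits.append((start, end, strand, ident, cov))
    if not stranded_hits:
        return []
    stranded_hits.sort()

    merged: list[list] = []
    max_gap = merge_gap_frac * qlen
    for start, end, strand, ident, cov in stranded_hits:
        if (
            merged
            and merged[-1][2] == strand
            and start - merged[-1][1] <= max_gap
        ):
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][3].append((ident, end - start))
        else:
            merged.append([start, end, strand, [(ident, end - start)]])

    arrays = []
    for start, end, strand, scored in merged:
        weight = sum(w for _, w in scored)
        mean_ident = sum(i * w for i, w in scored) / weight
        arrays.append(
            SatArray(
                scaffold=scaffold,
                start=start,
                end=end,
                strand=strand,
                period=qlen,
                n_copies=max(1.0, (end - start) / qlen),
                mean_identity_to_query=mean_ident,
            )
        )

    # resolve overlaps across strands: keep the higher-identity array
    arrays.sort(key=lambda a: (-(a.length * a.mean_identity_to_query), a.start))
    chosen: list[SatArray] = []
    for arr in arrays:
        if all(arr.end <= c.start or c.end <= arr.start for c in chosen):
            chosen.append(arr)
    chosen.sort(key=lambda a: a.start)
    return chosen


def dotplot_boundaries(
    region: str,
    consensus: str,
    hint: tuple[int, int] | None = None,
    k: int = 8,
    smooth: int = 21,
) -> tuple[int, int, bool]:
    """Refine array boundaries from windowed match density to the consensus.

    Per-position match indicators (k-mer present in the consensus on either
    strand) are smoothed; boundaries are where the density drops below half
    the in-array plateau.  Returns ``(start, end, low_confidence)``; when no
    plateau is found the input boundaries are returned flagged
    low-confidence.
    """
    region = _check_sequence(region)
    consensus = _check_sequence(consensus)
    fallback = hint if hint is not None else (0, len(region))
    if len(region) < k or len(consensus) < k:
        return (*fallback, True)

    ckmers = set()
    for i in range(len(consensus) - k + 1):
        km = consensus[i : i + k]
        ckmers.add(km)
        ckmers.add(revcomp(km))
    match = np.zeros(len(region))
    for i in range(len(region) - k + 1):
        if region[i : i + k] in ckmers:
            match[i : i + k] = 1.0

    kernel = np.ones(smooth) / smooth
    density = np.convolve(match, kernel, mode="same")
    plateau = float(np.percentile(density, 90))
    if plateau < 0.3:
        return (*fallback, True)
    half = plateau / 2.0
    mid = int(np.argmax(density)) if hint is None else (hint[0] + hint[1]) // 2
    mid = min(max(mid, 0), len(region) - 1)
    if density[mid] < half:
        mid = int(np.argmax(density))
    start = mid
    while start > 0 and density[start - 1] >= half:
        start -= 1
    end = mid + 1
    while end < len(region) and density[end] >= half:
        end += 1
    return (start, end, False)


def estimate_period(
    seq: str,
    min_period: int = 50,
    max_period: int = 600,
    min_identity: float = 0.60,
    tolerance: float = 0.05,
) -> int | None:
    """Estimate the repeat period of a sequence by self-match at each lag.

    Returns the smallest lag whose self-identity is within ``tolerance`` of
    the best lag (avoids harmonics), or None when no lag reaches
    ``min_identity`` or the sequence holds fewer than two periods.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best_p, best_f = None, 0.0
    scores = {}
    hi = min(max_period, len(seq) // 2)
    for p in range(min_period, hi + 1):
        f = float((arr[:-p] == arr[p:]).mean())
        scores[p] = f
        if f > best_f:
            best_p, best_f = p, f
    if best_p is None or best_f < min_identity:
        return None
    for p in range(min_period, hi + 1):
        if scores[p] >= best_f - tolerance:
            return p
    return best_p


def merge_arrays(arrays: list[SatArray]) -> list[SatArray]:
    """Union overlapping same-scaffold arrays (e.g. hits from several
    queries); the merged interval keeps the attributes of the
    highest-identity contributor."""
    out: list[SatArray] = []
    for arr in sorted(arrays, key=lambda a: (a.scaffold, a.start)):
        prev = out[-1] if out else None
        if prev is not None and prev.scaffold == arr.scaffold and arr.start < prev.end:
            keep = prev if prev.mean_identity_to_query >= arr.mean_identity_to_query else arr
            merged = SatArray(
                scaffold=keep.scaffold,
                start=min(prev.start, arr.start),
                end=max(prev.end, arr.end),
                strand=keep.strand,
                period=keep.period,
                n_copies=max(1.0, (max(prev.end, arr.end) - min(prev.start, arr.start)) / keep.period),
                mean_identity_to_query=keep.mean_identity_to_query,
            )
            out[-1] = merged
        else:
            out.append(arr)
    return out


def _best_rotation(array_prefix: str, reference: str) -> int:
    """Rotation r of the reference maximizing ungapped identity with the
    array prefix; ties resolved by the smallest offset."""
    ref2 = reference + reference
    best_r, best_score = 0, -1
    for r in range(len(reference)):
        rot = ref2[r : r + len(reference)]
        score = sum(
            1 for x, y in zip(array_prefix, rot) if x == y and x != "N"
        )
        if score > best_score:
            best_r, best_score = r, score
    return best_r


def _lexicographically_minimal_rotation(s: str) -> int:
    return min(range(len(s)), key=lambda r: s[r:] + s[:r])


def extract_monomers(
    sequence: str,
    array: SatArray,
    reference: str | None = None,
    species: str = "sim",
    full_length_frac: float = 0.75,
    max_n_frac: float = 0.20,
) -> list[Monomer]:
    """Partition an array into phased monomers on the canonical strand.

    With a reference, the phase is the maximal-identity rotation of the
    reference against the array start; without one, the phase making the
    first full unit the lexicographically minimal rotation is used.
    Terminal units shorter than ``full_length_frac`` of the expected size
    are emitted with ``full_length=False``.
    """
    seq = _check_sequence(sequence)[array.start : array.end]
    if array.strand == "-":
        seq = revcomp(seq)
    period = array.period

    if reference is not None:
        reference = _check_sequence(reference)
        if abs(len(reference) - period) / period > 0.5:
            raise PhaseError(
                f"reference length {len(reference)} vs array period {period}"
            )
        expected = len(reference)
        rot = _best_rotation(seq[:expected], reference)
        first_start = (expected - rot) % expected
        unit = expected
    else:
        unit = period
        first_unit = seq[:period] if len(seq) >= period else seq
        rot = _lexicographically_minimal_rotation(first_unit)
        first_start = rot % period if period <= len(seq) else 0
        expected = period

    cuts = list(range(first_start, len(seq) + 1, unit))
    if first_start > 0:
        cuts = [0] + cuts
    if cuts[-1] < len(seq):
        cuts.append(len(seq))

    array_id = f"{array.scaffold}:{array.start}-{array.end}"
    monomers = []
    dropped_n = 0
    for i in range(len(cuts) - 1):
        piece = seq[cuts[i] : cuts[i + 1]]
        if not piece:
            continue
        if piece.count("N") > max_n_frac * len(piece):
            dropped_n += 1
            continue
        full = len(piece) >= full_length_frac * expected
        monomers.append(
            Monomer(
                id=f"{array_id}|{i}",
                array_id=array_id,
                species=species,
                sequence=piece,
                phase_offset=(expected - first_start) % expected if first_start else 0,
                full_length=full,
            )
        )
    if dropped_n:
        logger.info("dropped %d monomers with >%.0f%% N", dropped_n, 100 * max_n_frac)
    return monomers
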