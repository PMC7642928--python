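"""Genomic-distribution summaries: satellite density in fixed windows,
strand-aware gene proximity, read quality filtering and read-cluster
genomic-proportion estimation.
"""

from __future__ import annotations

import bisect
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._align import local_align, revcomp

logger = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    scaffold: str
    window: int
    counts: np.ndarray  # satellite bp per window

    @property
    def total_bp(self) -> int:
        return int(self.counts.sum())


def density_profile(
    intervals: list[tuple[int, int]],
    scaffold: str,
    scaffold_length: int,
    window: int = 100_000,
) -> DensityProfile:
    """Apportion interval bp into non-overlapping windows tiling the
    scaffold; the final partial window is kept.  Window sums conserve total
    interval length exactly."""
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = max(1, -(-scaffold_length // window))
    counts = np.zeros(n_windows, dtype=np.int64)
    for start, end in intervals:
        if not (0 <= start < end <= scaffold_length):
            raise ValueError(
                f"interval [{start},{end}) outside scaffold {scaffold} "
                f"of length {scaffold_length}"
            )
        w0, w1 = start // window, (end - 1) // window
        for w in range(w0, w1 + 1):
            lo = max(start, w * window)
            hi = min(end, (w + 1) * window)
            counts[w] += hi - lo
    return DensityProfile(scaffold=scaffold, window=window, counts=counts)


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]


@dataclass
class ProximityHit:
    array_id: str
    gene_id: str
    category: str  # upstream | downstream | intronic | exonic
    distance: int
    identity: float = 1.0
    coverage: float = 1.0


def gene_proximity(
    hits: list[tuple[str, str, int, int]],
    genes: list[GeneModel],
    flank: int = 5000,
    min_id: float = 0.65,
    min_cov: float = 0.70,
    hit_scores: dict[str, tuple[float, float]] | None = None,
) -> list[ProximityHit]:
    """Classify satellite hits relative to gene models, strand-aware.

    ``hits`` are (array_id, scaffold, start, end).  Containment is decided by
    the hit midpoint (exonic/intronic); otherwise upstream/downstream when
    within ``flank`` bp of the TSS/TES.  One hit may match several genes;
    duplicates per (hit, gene, category) are collapsed.  ``hit_scores`` maps
    array_id -> (identity, coverage) for consensus-guided hits; hits without
    scores are treated as truth-planted and bypass the gates.
    """
    by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for gene in genes:
        if not gene.exons:
            logger.warning("gene %s has no exons; skipped", gene.gene_id)
            continue
        by_scaffold[gene.scaffold].append(gene)

    out = []
    seen = set()
    for array_id, scaffold, start, end in hits:
        if hit_scores is not None and array_id in hit_scores:
            ident, cov = hit_scores[array_id]
            if ident < min_id or cov < min_cov:
                continue
        else:
            ident, cov = 1.0, 1.0
        mid = (start + end) // 2
        for gene in by_scaffold.get(scaffold, ()):
            category = None
            distance = 0
            if gene.start <= mid < gene.end:
                in_exon = any(s <= mid < e for s, e in gene.exons)
                category = "exonic" if in_exon else "intronic"
            else:
                if gene.strand == "+":
                    up_lo, up_hi = gene.tss - flank, gene.tss
                    dn_lo, dn_hi = gene.tes, gene.tes + flank
                else:
                    up_lo, up_hi = gene.tss, gene.tss + flank
                    dn_lo, dn_hi = gene.tes - flank, gene.tes
                if up_lo <= mid < up_hi:
                    category = "upstream"
                    distance = gene.tss - mid if gene.strand == "+" else mid - gene.tss
                elif dn_lo <= mid < dn_hi:
                    category = "downstream"
                    distance = mid - gene.tes if gene.strand == "+" else gene.tes - mid
            if category is None:
                continue
            key = (array_id, gene.gene_id, category)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ProximityHit(
                    array_id=array_id,
                    gene_id=gene.gene_id,
                    category=category,
                    distance=distance,
                    identity=ident,
                    coverage=cov,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class FilterStats:
    kept: int = 0
    dropped_quality: int = 0
    dropped_short: int = 0


def quality_filter_reads(
    reads: list[tuple[str, str, list[int]]],
    trim_to: int = 100,
    q_floor: int = 30,
    max_low_frac: float = 0.10,
    min_len: int = 50,
    mode: str = "fraction",
) -> tuple[list[tuple[str, str, list[int]]], FilterStats]:
    """Trim reads to ``trim_to`` bp and drop low-quality ones.

    Default interpretation ("fraction"): drop when more than ``max_low_frac``
    of bases score below ``q_floor``.  The alternative "mean" mode drops when
    the mean quality is more than ``max_low_frac`` below ``q_floor``.
    Reads shorter than ``min_len`` after trimming are dropped separately.
    """
    if mode not in ("fraction", "mean"):
        raise ValueError(f"unknown mode: {mode!r}")
    kept = []
    stats = FilterStats()
    for rid, seq, quals in reads:
        seq = seq[:trim_to]
        quals = quals[:trim_to]
        if len(seq) < min_len:
            stats.dropped_short += 1
            continue
        if mode == "fraction":
            low = sum(1 for q in quals if q < q_floor)
            bad = low / len(quals) > max_low_frac
        else:
            bad = (sum(quals) / len(quals)) < q_floor * (1 - max_low_frac)
        if bad:
            stats.dropped_quality += 1
            continue
        kept.append((rid, seq, quals))
        stats.kept += 1
    logger.info(
        "quality filter: %d kept, %d dropped (quality), %d dropped (short)",
        stats.kept,
        stats.dropped_quality,
        stats.dropped_short,
    )
    return kept, stats


@dataclass
class ReadCluster:
    cluster_id: int
    read_count: int
    proportion: float
    representative: str


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _reads_similar(a: str, b: str, min_sim: float, min_span: float) -> bool:
    """True when a local alignment covers >= min_span of the shorter read at
    >= min_sim identity (gap columns count as mismatches); both strands."""
    shorter = min(len(a), len(b))
    for bb in (b, revcomp(b)):
        res = local_align(a, bb)
        if res is None:
            continue
        q_aln, t_aln, qs, qe, ts, te, _ = res
        span = min(qe - qs, te - ts)
        if span < min_span * shorter:
            continue
        matches = sum(
            1 for x, y in zip(q_aln, t_aln) if x == y and x != "-"
        )
        if matches / max(len(q_aln), 1) >= min_sim:
            return True
    return False


def estimate_genomic_proportion(
    reads: list[tuple[str, str, list[int]]],
    min_sim: float = 0.90,
    min_span: float = 0.65,
    report_floor: float = 1e-4,
    max_reads: int = 50_000,
    seed: int = 0,
    kmer: int = 15,
    min_shared_kmers: int = 3,
    max_candidates: int = 12,
) -> list[ReadCluster]:
    """Cluster reads by sequence similarity and report genomic proportions.

    Reads are linked when a shared-k-mer screen plus a local alignment shows
    >= ``min_sim`` identity over >= ``min_span`` of the shorter read;
    connected components are clusters and proportion = component size /
    retained reads.  Clusters below ``report_floor`` are suppressed from the
    report (totals unaffected).  At most ``max_reads`` reads are retained via
    a seeded subsample; the result is input-order invariant.
    """
    if not reads:
        raise ValueError("no reads supplied")
    if len(reads) < 1000:
        logger.warning("fewer than 1000 reads; proportion estimates are noisy")
    reads = sorted(reads, key=lambda r: r[0])
    if len(reads) > max_reads:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=max_reads, replace=False)
        reads = [reads[i] for i in sorted(idx)]
    n = len(reads)
    seqs = [r[1].upper() for r in reads]

    index: dict[str, list[int]] = defaultdict(list)
    canon_kmers = []
    for i, s in enumerate(seqs):
        kms = set()
        for j in range(0, len(s) - kmer + 1):
            km = s[j : j + kmer]
            if "N" in km:
                continue
            kms.add(min(km, revcomp(km)))
        canon_kmers.append(kms)
        for km in kms:
            index[km].append(i)

    uf = _UnionFind(n)
    for i in range(n):
        shared: dict[int, int] = defaultdict(int)
        for km in canon_kmers[i]:
            bucket = index[km]
            if len(bucket) > 200:
                # ultra-frequent k-mer: only look at nearby bucket entries
                # (keeps dense clusters chained without quadratic blowup)
                pos = bisect.bisect_right(bucket, i)
                neighbours = bucket[pos : pos + 5]
            else:
                neighbours = bucket
            for j in neighbours:
                if j > i:
                    shared[j] += 1
        cands = sorted(
            (j for j, c in shared.items() if c >= min_shared_kmers),
            key=lambda j: -shared[j],
        )
        checked = 0
        for j in cands:
            if checked >= max_candidates:
                break
            if uf.find(i) == uf.find(j):
                continue
            checked += 1
            if _reads_similar(seqs[i], seqs[j], min_sim, min_span):
                uf.union(i, j)

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)
    ordered = sorted(components.values(), key=lambda m: (-len(m), m[0]))

    def medoid(members: list[int]) -> int:
        """Member sharing the most k-mers with the rest (capped sample)."""
        if len(members) <= 2:
            return members[0]
        sample = members[:30]
        return max(
            sample,
            key=lambda i: sum(
                len(canon_kmers[i] & canon_kmers[j]) for j in sample if j != i
            ),
        )

    clusters = []
    for cid, members in enumerate(ordered):
        prop = len(members) / n
        if prop < report_floor:
            continue
        clusters.append(
            ReadCluster(
                cluster_id=cid,
                read_count=len(members),
                proportion=prop,
                representative=seqs[medoid(members)],
            )
        )
    return clusters
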