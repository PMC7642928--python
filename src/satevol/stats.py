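"""Summary statistics: intra/interspecific divergence tables, Tajima's D,
a concerted-evolution index, and conserved-motif detection on consensus
alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa import Alignment
from .phylo import k2p_distance, p_distance


@dataclass
class DivergenceTable:
    """Mean pairwise divergences: within-species on the diagonal,
    between-species off it.  NaN diagonal marks species with one sequence."""

    species: list[str]
    means: np.ndarray
    counts: np.ndarray
    model: str

    def to_tsv(self) -> str:
        lines = ["\t".join(["species"] + self.species)]
        for i, sp in enumerate(self.species):
            cells = []
            for j in range(len(self.species)):
                v = self.means[i, j]
                cells.append("NA" if math.isnan(v) else f"{v:.6f}")
            lines.append("\t".join([sp] + cells))
        return "\n".join(lines) + "\n"


def _pair_dist(row_i: str, row_j: str, model: str, gamma_shape):
    if model == "p":
        return p_distance(row_i, row_j)
    if model == "k2p":
        return k2p_distance(row_i, row_j, gamma_shape)
    raise ValueError(f"unknown model: {model!r}")


def divergence_table(
    alignment: Alignment,
    species_of: dict[str, str],
    model: str = "p",
    gamma_shape: float | None = None,
) -> DivergenceTable:
    """Average pairwise distance within and between species.

    Distances are taken over the alignment's kept columns with pairwise
    deletion; undefined (saturated/incomparable) pairs are excluded from the
    averages but included in nothing else.
    """
    rows = alignment.kept_rows()
    species = sorted({species_of[lab] for lab in alignment.labels})
    idx = {sp: k for k, sp in enumerate(species)}
    n_sp = len(species)
    sums = np.zeros((n_sp, n_sp))
    counts = np.zeros((n_sp, n_sp), dtype=int)
    for i in range(len(rows)):
        si = idx[species_of[alignment.labels[i]]]
        for j in range(i + 1, len(rows)):
            sj = idx[species_of[alignment.labels[j]]]
            d = _pair_dist(rows[i], rows[j], model, gamma_shape)
            if math.isnan(d):
                continue
            a, b = min(si, sj), max(si, sj)
            sums[a, b] += d
            counts[a, b] += 1
    means = np.full((n_sp, n_sp), math.nan)
    for a in range(n_sp):
        for b in range(a, n_sp):
            if counts[a, b] > 0:
                means[a, b] = means[b, a] = sums[a, b] / counts[a, b]
            counts[b, a] = counts[a, b]
    tag = model if gamma_shape is None or model == "p" else f"k2p+g{gamma_shape}"
    return DivergenceTable(species=species, means=means, counts=counts, model=tag)


def tajimas_d(sequences: list[str]) -> float:
    """Tajima's D with complete deletion of gap/N-containing columns.

    Returns NaN when fewer than 4 sequences or no segregating site.
    """
    n = len(sequences)
    if n < 4:
        return math.nan
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be aligned (equal length)")
    cols = [
        [s[j] for s in sequences]
        for j in range(length)
        if all(s[j] in "ACGT" for s in sequences)
    ]
    if not cols:
        return math.nan

    seg = sum(1 for col in cols if len(set(col)) > 1)
    if seg == 0:
        return math.nan

    # mean pairwise differences
    n_pairs = n * (n - 1) // 2
    pi = 0.0
    for col in cols:
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        same = sum(v * (v - 1) // 2 for v in counts.values())
        pi += (n_pairs - same) / n_pairs

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * seg + e2 * seg * (seg - 1)
    if var <= 0:
        return math.nan
    return (pi - seg / a1) / math.sqrt(var)


def concerted_evolution_index(table: DivergenceTable) -> dict[str, float]:
    """Per-species CEI = intraspecific mean / mean interspecific divergence.

    Values below 1 indicate within-species homogenization (concerted
    evolution).  Species with an undefined diagonal get NaN.
    """
    if len(table.species) < 2:
        raise ValueError("need at least 2 species")
    out = {}
    for i, sp in enumerate(table.species):
        intra = table.means[i, i]
        inter = [
            table.means[i, j]
            for j in range(len(table.species))
            if j != i and not math.isnan(table.means[i, j])
        ]
        if math.isnan(intra) or not inter:
            out[sp] = math.nan
            continue
        denom = float(np.mean(inter))
        out[sp] = 0.0 if denom == 0 and intra == 0 else intra / denom
    return out


# ---------------------------------------------------------------------------
# Conserved motifs
# ---------------------------------------------------------------------------


@dataclass
class Motif:
    """A conserved block on consensus-alignment coordinates (kept columns)."""

    start: int
    end: int
    score: float  # mean per-column information content, bits
    p_value: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _column_ic(alignment: Alignment) -> np.ndarray:
    """Per kept column: information content 2 - H (bits); gap-majority
    columns score 0."""
    idx = np.flatnonzero(alignment.mask)
    ic = np.zeros(len(idx))
    n = alignment.n_rows
    for k, j in enumerate(idx):
        col = [row[j] for row in alignment.rows]
        counts = np.array([col.count(b) for b in "ACGT"], dtype=float)
        total = counts.sum()
        if total < 0.5 * n or total == 0:
            continue
        freqs = counts[counts > 0] / total
        entropy = -(freqs * np.log2(freqs)).sum()
        ic[k] = 2.0 - entropy
    return ic


def find_conserved_motifs(
    alignment: Alignment,
    wmin: int = 10,
    wmax: int = 200,
    alpha: float = 1e-6,
    n_null: int = 100_000,
    rng: np.random.Generator | None = None,
) -> list[Motif]:
    """Detect conserved blocks of ``wmin``..``wmax`` columns.

    Candidate windows are maximal runs of columns whose information content
    exceeds the alignment-wide mean.  Significance is the probability, under
    random draws of equal-length column sets from this alignment (Gaussian
    tail beyond the permutation resolution), of a mean IC at least as large;
    it is Bonferroni-corrected by the number of possible window starts so
    that reported p-values are conservative under selection.  Motifs with
    ``p < alpha`` are reported greedily non-overlapping by descending score.
    """
    if alignment.n_rows < 3:
        raise ValueError("need at least 3 rows")
    if rng is None:
        rng = np.random.default_rng(0)
    ic = _column_ic(alignment)
    n_cols = len(ic)
    if n_cols < wmin:
        return []

    floor = float(ic.mean())
    above = ic > floor
    runs = []
    start = None
    for j in range(n_cols + 1):
        flag = above[j] if j < n_cols else False
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            runs.append((start, j))
            start = None

    mu, sigma = float(ic.mean()), float(ic.std())
    multiplicity = max(1, n_cols - wmin + 1)
    candidates = []
    for s, e in runs:
        if e - s < wmin:
            continue
        if e - s > wmax:
            # keep the best wmax-wide sub-window
            means = np.convolve(ic[s:e], np.ones(wmax) / wmax, mode="valid")
            off = int(np.argmax(means))
            s, e = s + off, s + off + wmax
        length = e - s
        obs = float(ic[s:e].mean())
        null_means = (
            rng.choice(ic, size=(n_null, length), replace=True).mean(axis=1)
            if n_null * length <= 5_000_000
            else None
        )
        if null_means is not None:
            p_raw = (1 + int((null_means >= obs).sum())) / (n_null + 1)
            if p_raw <= 2.0 / (n_null + 1) and sigma > 0:
                from scipy.stats import norm

                p_gauss = float(norm.sf((obs - mu) / (sigma / math.sqrt(length))))
                p_raw = min(p_raw, max(p_gauss, 0.0))
        else:
            from scipy.stats import norm

            p_raw = float(norm.sf((obs - mu) / (sigma / math.sqrt(length)))) \
                if sigma > 0 else 1.0
        p_adj = min(1.0, p_raw * multiplicity)
        candidates.append(Motif(start=s, end=e, score=obs, p_value=p_adj))

    candidates.sort(key=lambda m: (-m.score, m.start))
    reported: list[Motif] = []
    for cand in candidates:
        if cand.p_value >= alpha:
            continue
        if any(cand.start < m.end and m.start < cand.end for m in reported):
            continue
        reported.append(cand)
    reported.sort(key=lambda m: m.start)
    return reported
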