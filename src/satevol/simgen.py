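"""Synthetic multi-species genomes with satellite arrays evolving under a
concerted-evolution model, plus reads, gene annotations and truth tables.

The simulator plants heterochromatic tandem arrays (homogenized within each
species by gene-conversion-like events) and independently diverging dispersed
euchromatic copies on gene-bearing scaffolds, with a derived subfamily
carrying a contiguous internal deletion.  All randomness flows from one
seeded generator, so identical configurations produce byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from ._align import revcomp
from .annotate import GeneModel
from .io import write_bed, write_fasta, write_fastq, write_gff3

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one simulation run.  Rates are per branch-length unit
    of the (substitutions/site-scaled) species tree."""

    tree: str = "(A:0.5,B:0.5);"
    mu: float = 0.05  # substitutions per site per branch unit
    kappa: float = 2.0  # transition/transversion bias of the site model
    homog_rate: float = 1.0  # homogenization events per monomer per unit
    n_het_arrays: int = 6
    het_copies: tuple[int, int] = (5, 12)
    n_eu_copies: int = 8
    eu_homog_rate: float = 0.0
    eu_offset: float = 0.1  # divergence of the euchromatic founder lineage
    monomer_len: int = 360
    del_len: int = 170
    del_center: float = 0.5
    subfam_fraction: float = 0.3
    n_genes: int = 6
    chrom_len: int = 0  # target total genome length per species (0 = auto)
    burn_in_diversity: float = 0.05
    read_len: int = 100
    coverage: float = 1.0
    indel_rate: float = 0.0
    seq_error_rate: float = 0.0
    q_low_frac: float = 0.02  # fraction of read bases below Q30
    rev_frac: float = 0.3  # fraction of planted arrays reverse-complemented
    seed: int = 0

    def validate(self) -> None:
        for name in ("mu", "homog_rate", "eu_homog_rate", "burn_in_diversity",
                     "indel_rate", "seq_error_rate", "q_low_frac"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.del_len >= self.monomer_len:
            raise ConfigError("del_len must be smaller than monomer_len")
        if not 0 <= self.subfam_fraction <= 1:
            raise ConfigError("subfam_fraction must be in [0, 1]")
        if not 0 <= self.del_center <= 1:
            raise ConfigError("del_center must be in [0, 1]")
        if self.het_copies[0] < 1 or self.het_copies[1] < self.het_copies[0]:
            raise ConfigError("het_copies must be a nondecreasing positive range")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(**{k: tuple(v) if k == "het_copies" else v for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class TruthArray:
    array_id: str
    species: str
    scaffold: str
    start: int  # 0-based half-open, set at assembly
    end: int
    strand: str
    domain: str  # het | eu
    subfamily: str  # F360 | F190
    monomer_ids: list[str]
    monomer_seqs: list[str]  # canonical orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    arrays: list[TruthArray] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)  # declared non-satellite repeats
    proximity: list[tuple[str, str, str, int]] = field(default_factory=list)  # array, gene, category, distance
    ancestor_360: str = ""
    ancestor_190: str = ""
    deletion_interval: tuple[int, int] = (0, 0)
    params: dict = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for arr in self.arrays:
            length = self.scaffold_lengths[arr.scaffold]
            if not 0 <= arr.start < arr.end <= length:
                raise AssertionError(f"array {arr.array_id} out of bounds")
            if arr.domain not in ("het", "eu") or arr.subfamily not in ("F360", "F190"):
                raise AssertionError(f"array {arr.array_id} has bad labels")
            by_scaffold.setdefault(arr.scaffold, []).append((arr.start, arr.end))
        for ivs in by_scaffold.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise AssertionError("overlapping truth arrays")

    def satellite_bp(self) -> int:
        return sum(a.length for a in self.arrays)

    def arrays_tsv(self) -> str:
        lines = ["array_id\tspecies\tscaffold\tstart\tend\tstrand\tdomain\tsubfamily\tn_monomers"]
        for a in self.arrays:
            lines.append(
                f"{a.array_id}\t{a.species}\t{a.scaffold}\t{a.start}\t{a.end}"
                f"\t{a.strand}\t{a.domain}\t{a.subfamily}\t{len(a.monomer_ids)}"
            )
        return "\n".join(lines) + "\n"

    def proximity_tsv(self) -> str:
        lines = ["array_id\tgene_id\tcategory\tdistance"]
        for row in self.proximity:
            lines.append("\t".join(str(x) for x in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _substitute_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    if base not in _TRANSITION:
        return base
    w_total = kappa + 2.0
    if rng.random() < kappa / w_total:
        return _TRANSITION[base]
    others = [b for b in _BASES if b != base and b != _TRANSITION[base]]
    return others[int(rng.integers(2))]


def _mutate(seq: str, p_site: float, kappa: float, rng: np.random.Generator) -> str:
    """Each site mutates with probability p_site to a kappa-weighted
    different base (at most one hit per site per call)."""
    if p_site <= 0:
        return seq
    n = rng.binomial(len(seq), min(p_site, 1.0))
    if n == 0:
        return seq
    sites = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for i in sites:
        chars[i] = _substitute_base(chars[i], kappa, rng)
    return "".join(chars)


def _apply_indels(seq: str, p_site: float, rng: np.random.Generator) -> str:
    if p_site <= 0:
        return seq
    n = rng.binomial(len(seq), min(p_site, 1.0))
    for _ in range(n):
        i = int(rng.integers(len(seq)))
        if rng.random() < 0.5 and len(seq) > 20:
            seq = seq[:i] + seq[i + 1 :]
        else:
            seq = seq[:i] + seq[i] + seq[i:]
    return seq


@dataclass
class _ArrayState:
    array_id: str
    subfamily: str
    copies: list[str]


@dataclass
class SpeciesMonomers:
    species: str
    het_arrays: list[_ArrayState]
    eu_copies: list[str]


def evolve_monomers(config: SimConfig) -> tuple[dict[str, SpeciesMonomers], dict]:
    """Evolve the ancestral monomer pool down the species tree.

    Heterochromatic copies exchange sequence within the species-wide pool of
    their subfamily at ``homog_rate`` (concerted evolution); euchromatic
    copies evolve independently (``eu_homog_rate`` default 0).  Returns
    per-leaf monomer sets plus a truth fragment with the ancestral
    consensuses and deletion interval.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    try:
        tree = dendropy.Tree.get(data=config.tree, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable newick tree: {exc}") from exc
    leaves = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")

    ancestor = _random_seq(config.monomer_len, rng)
    center = config.del_center * config.monomer_len
    del_start = int(round(center - config.del_len / 2.0))
    del_start = max(0, min(del_start, config.monomer_len - config.del_len))
    del_end = del_start + config.del_len
    ancestor_del = ancestor[:del_start] + ancestor[del_end:]

    n_del = int(round(config.subfam_fraction * config.n_het_arrays))
    del_idx = set(
        rng.choice(config.n_het_arrays, size=n_del, replace=False).tolist()
    ) if n_del else set()

    burn = config.burn_in_diversity / 2.0
    root_arrays = []
    for a in range(config.n_het_arrays):
        subfam = "F190" if a in del_idx else "F360"
        seed_seq = ancestor_del if subfam == "F190" else ancestor
        n_copies = int(rng.integers(config.het_copies[0], config.het_copies[1] + 1))
        copies = [
            _mutate(seed_seq, burn, config.kappa, rng) for _ in range(n_copies)
        ]
        root_arrays.append(_ArrayState(array_id=f"het{a}", subfamily=subfam, copies=copies))
    eu_founder = _mutate(ancestor, config.eu_offset, config.kappa, rng)
    root_eu = [
        _mutate(eu_founder, burn, config.kappa, rng)
        for _ in range(config.n_eu_copies)
    ]

    results: dict[str, SpeciesMonomers] = {}

    def evolve_branch(arrays: list[_ArrayState], eu: list[str], t: float):
        arrays = [
            _ArrayState(
                a.array_id,
                a.subfamily,
                [
                    _apply_indels(
                        _mutate(c, config.mu * t, config.kappa, rng),
                        config.indel_rate * t,
                        rng,
                    )
                    for c in a.copies
                ],
            )
            for a in arrays
        ]
        eu = [
            _apply_indels(
                _mutate(c, config.mu * t, config.kappa, rng),
                config.indel_rate * t,
                rng,
            )
            for c in eu
        ]
        # species-wide homogenization within each subfamily pool
        pool = [
            (ai, ci)
            for ai, a in enumerate(arrays)
            for ci in range(len(a.copies))
        ]
        if pool and config.homog_rate > 0 and t > 0:
            n_events = rng.poisson(config.homog_rate * t * len(pool))
            by_subfam: dict[str, list[tuple[int, int]]] = {}
            for ai, ci in pool:
                by_subfam.setdefault(arrays[ai].subfamily, []).append((ai, ci))
            for _ in range(n_events):
                ai, ci = pool[int(rng.integers(len(pool)))]
                same = by_subfam[arrays[ai].subfamily]
                dj, cj = same[int(rng.integers(len(same)))]
                arrays[ai].copies[ci] = arrays[dj].copies[cj]
        if eu and config.eu_homog_rate > 0 and t > 0:
            n_events = rng.poisson(config.eu_homog_rate * t * len(eu))
            for _ in range(n_events):
                i = int(rng.integers(len(eu)))
                j = int(rng.integers(len(eu)))
                eu[i] = eu[j]
        return arrays, eu

    def descend(node, arrays, eu):
        t = node.edge.length or 0.0
        if t > 0:
            arrays, eu = evolve_branch(arrays, eu, t)
        if node.is_leaf():
            sp = node.taxon.label.replace(" ", "_")
            results[sp] = SpeciesMonomers(species=sp, het_arrays=arrays, eu_copies=eu)
        else:
            for child in node.child_nodes():
                descend(child, arrays, eu)

    descend(tree.seed_node, root_arrays, root_eu)
    results = {sp: results[sp] for sp in leaves}

    truth_fragment = {
        "ancestor_360": ancestor,
        "ancestor_190": ancestor_del,
        "deletion_interval": (del_start, del_end),
        "params": asdict(config),
    }
    return results, truth_fragment


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def assemble_genomes(
    monomers: dict[str, SpeciesMonomers],
    config: SimConfig,
    truth_fragment: dict,
) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Embed the evolved monomers into per-species scaffolds.

    Heterochromatic arrays become tandem runs separated by declared repeat
    filler on a repeat-dense scaffold; euchromatic copies land singly on a
    gene-bearing scaffold at planted upstream/intronic/downstream/distal
    positions.  Coordinates are recorded exactly in the returned TruthTable.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthTable(
        ancestor_360=truth_fragment["ancestor_360"],
        ancestor_190=truth_fragment["ancestor_190"],
        deletion_interval=tuple(truth_fragment["deletion_interval"]),
        params=truth_fragment["params"],
    )
    genomes: dict[str, dict[str, str]] = {}

    for sp, state in monomers.items():
        genomes[sp] = {}

        # --- heterochromatic scaffold: [filler][array][filler]...[filler]
        het_name = f"{sp}_het"
        parts = []
        cursor = 0

        def emit(seq: str):
            nonlocal cursor
            parts.append(seq)
            cursor += len(seq)

        emit(_random_seq(1200, rng))
        for arr in state.het_arrays:
            array_seq = "".join(arr.copies)
            strand = "-" if rng.random() < config.rev_frac else "+"
            start = cursor
            emit(array_seq if strand == "+" else revcomp(array_seq))
            array_id = f"{sp}_{arr.array_id}"
            truth.arrays.append(
                TruthArray(
                    array_id=array_id,
                    species=sp,
                    scaffold=het_name,
                    start=start,
                    end=cursor,
                    strand=strand,
                    domain="het",
                    subfamily=arr.subfamily,
                    monomer_ids=[f"{array_id}|{i}" for i in range(len(arr.copies))],
                    monomer_seqs=list(arr.copies),
                )
            )
            filler_start = cursor
            emit(_random_seq(int(rng.integers(700, 1100)), rng))
            truth.repeats.append((het_name, filler_start, cursor))
        # leading filler is also a declared repeat
        truth.repeats.insert(0, (het_name, 0, 1200))
        genomes[sp][het_name] = "".join(parts)
        truth.scaffold_lengths[het_name] = cursor

        # --- euchromatic scaffold: genes with planted satellite insertions
        eu_name = f"{sp}_eu"
        parts = []
        cursor = 0
        categories = ["upstream", "intronic", "downstream", "distal"]
        plan = [
            (m % max(config.n_genes, 1), categories[m % 4])
            for m in range(len(state.eu_copies))
        ]
        by_gene: dict[int, dict[str, int]] = {}
        for m, (g, cat) in enumerate(plan):
            by_gene.setdefault(g, {})[cat] = m
        distal = [m for m, (_, cat) in enumerate(plan) if cat == "distal"]

        def emit_eu_monomer(m: int, gene: GeneModel | None, category: str):
            mono = state.eu_copies[m]
            strand = "-" if rng.random() < config.rev_frac else "+"
            start = cursor
            emit(mono if strand == "+" else revcomp(mono))
            array_id = f"{sp}_eu{m}"
            truth.arrays.append(
                TruthArray(
                    array_id=array_id,
                    species=sp,
                    scaffold=eu_name,
                    start=start,
                    end=cursor,
                    strand=strand,
                    domain="eu",
                    subfamily="F360",
                    monomer_ids=[f"{array_id}|0"],
                    monomer_seqs=[mono],
                )
            )
            return array_id, start

        for g in range(config.n_genes):
            emit(_random_seq(int(rng.integers(2500, 3500)), rng))
            gene_strand = "+" if rng.random() < 0.5 else "-"
            slots = by_gene.get(g, {})

            pending_up = None
            m_before = slots.get("upstream" if gene_strand == "+" else "downstream")
            if m_before is not None:
                cat = "upstream" if gene_strand == "+" else "downstream"
                array_id, a_start = emit_eu_monomer(m_before, None, cat)
                gap = int(rng.integers(400, 2400))
                emit(_random_seq(gap, rng))
                pending_up = (array_id, a_start, cat)

            gene_start = cursor
            gid = f"{sp}_gene{g}"
            emit(_random_seq(300, rng))  # exon 1
            exon1 = (gene_start, cursor)
            intron_start = cursor
            m_intron = slots.get("intronic")
            emit(_random_seq(300, rng))
            if m_intron is not None:
                array_id, _ = emit_eu_monomer(m_intron, None, "intronic")
                truth.proximity.append((array_id, gid, "intronic", 0))
            emit(_random_seq(400, rng))
            exon2_start = cursor
            emit(_random_seq(300, rng))
            exon2 = (exon2_start, cursor)
            gene_end = cursor
            gene = GeneModel(
                gene_id=gid,
                scaffold=eu_name,
                start=gene_start,
                end=gene_end,
                strand=gene_strand,
                exons=[exon1, exon2],
            )
            truth.genes.append(gene)
            if pending_up is not None:
                array_id, a_start, cat = pending_up
                arr = next(a for a in truth.arrays if a.array_id == array_id)
                mid = (arr.start + arr.end) // 2
                anchor = gene.tss if cat == "upstream" else gene.tes
                truth.proximity.append((array_id, gid, cat, abs(anchor - mid)))

            m_after = slots.get("downstream" if gene_strand == "+" else "upstream")
            if m_after is not None:
                cat = "downstream" if gene_strand == "+" else "upstream"
                gap = int(rng.integers(400, 2400))
                emit(_random_seq(gap, rng))
                array_id, a_start = emit_eu_monomer(m_after, None, cat)
                arr = truth.arrays[-1]
                mid = (arr.start + arr.end) // 2
                anchor = gene.tes if cat == "downstream" else gene.tss
                truth.proximity.append((array_id, gid, cat, abs(mid - anchor)))
            emit(_random_seq(6000, rng))

        for m in distal:
            emit(_random_seq(7000, rng))
            emit_eu_monomer(m, None, "distal")
        emit(_random_seq(6500, rng))
        genomes[sp][eu_name] = "".join(parts)
        truth.scaffold_lengths[eu_name] = cursor

        # --- optional padding scaffold to reach a target genome length
        if config.chrom_len:
            current = sum(len(s) for s in genomes[sp].values())
            if current > config.chrom_len:
                raise ConfigError(
                    f"planted content ({current} bp) exceeds chrom_len for {sp}"
                )
            pad = config.chrom_len - current
            if pad > 0:
                pad_name = f"{sp}_pad"
                genomes[sp][pad_name] = _random_seq(pad, rng)
                truth.scaffold_lengths[pad_name] = pad

    truth.validate()
    return genomes, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(
    genomes: dict[str, dict[str, str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, list[int]]]:
    """Uniform-start shotgun reads with a two-level quality model.

    Read count per scaffold is Poisson with mean coverage * length /
    read_len; a ``q_low_frac`` fraction of bases gets Q20, the rest Q38.
    Scaffolds shorter than the read length are skipped with a warning.
    """
    if config.coverage <= 0:
        raise ConfigError("coverage must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    reads = []
    for sp, scaffolds in genomes.items():
        for name, seq in scaffolds.items():
            if len(seq) < config.read_len:
                import logging

                logging.getLogger(__name__).warning(
                    "scaffold %s shorter than read length; skipped", name
                )
                continue
            n = int(rng.poisson(config.coverage * len(seq) / config.read_len))
            starts = rng.integers(0, len(seq) - config.read_len + 1, size=n)
            for i, s in enumerate(sorted(starts.tolist())):
                frag = seq[s : s + config.read_len]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                if config.seq_error_rate > 0:
                    frag = _mutate(frag, config.seq_error_rate, 1.0, rng)
                low = rng.random(config.read_len) < config.q_low_frac
                quals = np.where(low, 20, 38).tolist()
                reads.append((f"{name}|r{i}", frag, quals))
    return reads


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate(config: SimConfig, outdir) -> TruthTable:
    """Run the full simulation and write FASTA/GFF3/FASTQ/truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    monomers, fragment = evolve_monomers(config)
    genomes, truth = assemble_genomes(monomers, config, fragment)
    reads = simulate_reads(genomes, config)

    for sp, scaffolds in genomes.items():
        write_fasta(outdir / f"{sp}.fasta", scaffolds)
    write_gff3(outdir / "genes.gff3", truth.genes)
    write_fastq(outdir / "reads.fastq", reads)
    write_bed(
        outdir / "truth_arrays.bed",
        [
            (a.scaffold, a.start, a.end, a.array_id, 0, a.strand)
            for a in truth.arrays
        ],
    )
    write_bed(outdir / "repeats.bed", [(s, b, e) for s, b, e in truth.repeats])
    (outdir / "truth_arrays.tsv").write_text(truth.arrays_tsv())
    (outdir / "truth_proximity.tsv").write_text(truth.proximity_tsv())
    write_fasta(
        outdir / "ancestor.fasta",
        {"ancestor_360": truth.ancestor_360, "ancestor_190": truth.ancestor_190},
    )
    (outdir / "params.json").write_text(
        json.dumps(truth.params, indent=2, default=list) + "\n"
    )
    return truth
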