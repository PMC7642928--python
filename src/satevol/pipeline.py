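"""End-to-end orchestration: simulate -> mine -> align -> tree -> classify ->
summarize, with a checksummed run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import annotate, classify, io, mining, msa, phylo, simgen, stats

logger = logging.getLogger(__name__)

STAGES = ("simulate", "mine", "align", "tree", "classify", "stats", "density",
          "proximity", "proportion")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def mine_genome(
    genome: dict[str, str],
    queries: dict[str, str],
    species: str,
    min_identity: float = 0.65,
    min_coverage: float = 0.70,
) -> tuple[list[mining.SatArray], list[mining.Monomer]]:
    """Consensus-guided search with all queries, merged, period-confirmed,
    and phased into monomers."""
    arrays: list[mining.SatArray] = []
    for name, seq in genome.items():
        per_scaffold = []
        for query in queries.values():
            per_scaffold.extend(
                mining.search_by_consensus(
                    seq, query, min_identity, min_coverage, scaffold=name
                )
            )
        arrays.extend(mining.merge_arrays(per_scaffold))

    monomers = []
    for arr in arrays:
        region = genome[arr.scaffold][arr.start : arr.end]
        period = mining.estimate_period(region) or arr.period
        arr.period = period
        arr.n_copies = max(1.0, arr.length / period)
        reference = min(
            queries.values(), key=lambda q: abs(len(q) - period)
        )
        try:
            monos = mining.extract_monomers(
                genome[arr.scaffold], arr, reference=reference, species=species
            )
        except mining.PhaseError:
            monos = mining.extract_monomers(
                genome[arr.scaffold], arr, reference=None, species=species
            )
        monomers.extend(monos)
    return arrays, monomers


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in dependency order.

    ``config`` holds a ``seed``, a ``stages`` list (default: all), a
    ``simulate`` section (SimConfig fields) and optional per-stage parameter
    sections.  Returns the manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    enabled = config.get("stages", list(STAGES))
    manifest: dict = {"stages": {}, "seed": master_seed}
    (outdir / "resolved_config.json").write_text(json.dumps(config, indent=2, default=str))

    sim_dir = outdir / "sim"
    truth = None
    genomes: dict[str, dict[str, str]] = {}
    queries: dict[str, str] = {}
    arrays_by_sp: dict[str, list[mining.SatArray]] = {}
    monomers_by_sp: dict[str, list[mining.Monomer]] = {}

    def record(stage: str, files: list[Path]):
        manifest["stages"][stage] = {
            "outputs": {str(f.relative_to(outdir)): _sha256(f) for f in files}
        }

    try:
        if "simulate" in enabled:
            sim_cfg = dict(config.get("simulate", {}))
            sim_cfg.setdefault("seed", _stage_seed(master_seed, "simulate"))
            cfg = simgen.SimConfig.from_dict(sim_cfg)
            truth = simgen.simulate(cfg, sim_dir)
            record("simulate", sorted(sim_dir.iterdir()))
            for sp in {a.species for a in truth.arrays}:
                genomes[sp] = io.read_fasta(sim_dir / f"{sp}.fasta")
            queries = io.read_fasta(sim_dir / "ancestor.fasta")

        if "mine" in enabled:
            mine_dir = outdir / "mine"
            mine_dir.mkdir(exist_ok=True)
            files = []
            for sp in sorted(genomes):
                arrays, monomers = mine_genome(genomes[sp], queries, sp)
                arrays_by_sp[sp] = arrays
                monomers_by_sp[sp] = monomers
                bed = mine_dir / f"{sp}.arrays.bed"
                io.write_bed(
                    bed,
                    [
                        (
                            a.scaffold,
                            a.start,
                            a.end,
                            f"{a.scaffold}:{a.start}-{a.end}",
                            round(100 * a.mean_identity_to_query),
                            a.strand,
                        )
                        for a in arrays
                    ],
                )
                fasta = mine_dir / f"{sp}.monomers.fasta"
                io.write_fasta(
                    fasta,
                    {
                        f"{m.species}|{m.array_id}|{i}|{'full' if m.full_length else 'partial'}": m.sequence
                        for i, m in enumerate(monomers)
                    },
                )
                files += [bed, fasta]
            record("mine", files)

        alignment = None
        if "align" in enabled and monomers_by_sp:
            full = [
                m
                for sp in sorted(monomers_by_sp)
                for m in monomers_by_sp[sp]
                if m.full_length
            ]
            ref = queries.get("ancestor_360") or next(iter(queries.values()))
            labels = [f"{m.species}|{m.array_id}|{m.id}" for m in full]
            alignment = msa.align_monomers([m.sequence for m in full], ref, labels=labels)
            alignment = msa.site_coverage_mask(alignment, 0.85)
            aln_path = outdir / "monomers.aln.fasta"
            io.write_fasta(aln_path, dict(zip(alignment.labels, alignment.rows)))
            mask_path = outdir / "monomers.mask.tsv"
            removed = np.flatnonzero(~alignment.mask)
            mask_path.write_text("\n".join(str(i) for i in removed) + "\n")
            record("align", [aln_path, mask_path])

        if "tree" in enabled and alignment is not None and alignment.n_rows >= 3:
            dm = phylo.distance_matrix(alignment, model="k2p", gamma_shape=1.0)
            finite = ~np.isnan(dm.matrix).any(axis=1)
            if not finite.all():
                keep = np.flatnonzero(finite)
                dm = phylo.DistanceMatrix(
                    labels=[dm.labels[i] for i in keep],
                    matrix=dm.matrix[np.ix_(keep, keep)],
                    model=dm.model,
                )
            tree = phylo.nj_tree(dm)
            tree_path = outdir / "monomers.nwk"
            tree_path.write_text(tree.to_newick() + "\n")
            dm_path = outdir / "distances.tsv"
            dm_path.write_text(dm.to_tsv())
            record("tree", [tree_path, dm_path])

        if "classify" in enabled and alignment is not None:
            ref = queries.get("ancestor_360") or next(iter(queries.values()))
            calls = [
                classify.call_subfamily(lab, alignment.degapped(i), ref)
                for i, lab in enumerate(alignment.labels)
            ]
            sub_path = outdir / "subfamilies.tsv"
            sub_path.write_text(
                "monomer\tlabel\tdeletion\tcanonical\n"
                + "\n".join(
                    f"{c.monomer_id}\t{c.label}\t{c.deletion}\t{c.canonical_deletion}"
                    for c in calls
                )
                + "\n"
            )
            record("classify", [sub_path])

        if "stats" in enabled and alignment is not None:
            species_of = {lab: lab.split("|")[0] for lab in alignment.labels}
            if len(set(species_of.values())) >= 2:
                table = stats.divergence_table(alignment, species_of, model="p")
                tsv = outdir / "divergence.tsv"
                tsv.write_text(table.to_tsv())
                cei = stats.concerted_evolution_index(table)
                cei_path = outdir / "cei.json"
                cei_path.write_text(json.dumps(cei, indent=2) + "\n")
                record("stats", [tsv, cei_path])

        if "density" in enabled and truth is not None:
            dens_path = outdir / "density.tsv"
            lines = ["scaffold\tstart\tend\tsat_bp"]
            for scaffold, length in truth.scaffold_lengths.items():
                ivs = [
                    (a.start, a.end) for a in truth.arrays if a.scaffold == scaffold
                ]
                prof = annotate.density_profile(ivs, scaffold, length)
                for w, count in enumerate(prof.counts):
                    lines.append(
                        f"{scaffold}\t{w * prof.window}"
                        f"\t{min((w + 1) * prof.window, length)}\t{count}"
                    )
            dens_path.write_text("\n".join(lines) + "\n")
            record("density", [dens_path])

        if "proximity" in enabled and truth is not None:
            hits = [
                (a.array_id, a.scaffold, a.start, a.end) for a in truth.arrays
            ]
            prox = annotate.gene_proximity(hits, truth.genes)
            prox_path = outdir / "proximity.tsv"
            prox_path.write_text(
                "array\tgene\tcategory\tdistance\n"
                + "\n".join(
                    f"{h.array_id}\t{h.gene_id}\t{h.category}\t{h.distance}"
                    for h in prox
                )
                + "\n"
            )
            record("proximity", [prox_path])

        if "proportion" in enabled and truth is not None:
            reads = io.read_fastq(sim_dir / "reads.fastq")
            kept, _ = annotate.quality_filter_reads(reads)
            clusters = annotate.estimate_genomic_proportion(
                kept, seed=_stage_seed(master_seed, "proportion")
            )
            prop_path = outdir / "clusters.tsv"
            prop_path.write_text(
                "cluster\treads\tproportion\n"
                + "\n".join(
                    f"{c.cluster_id}\t{c.read_count}\t{c.proportion:.6f}"
                    for c in clusters
                )
                + "\n"
            )
            record("proportion", [prop_path])
    except Exception:
        manifest["status"] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["status"] = "complete"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
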