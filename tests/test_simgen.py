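import filecmp
import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from oracles import expected_p_distance
from satevol.io import read_fasta, read_gff3
from satevol.phylo import p_distance
from satevol.simgen import (
    ConfigError,
    SimConfig,
    assemble_genomes,
    evolve_monomers,
    simulate,
    simulate_reads,
)


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(mu=-0.1).validate()

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(homog_rate=float("inf")).validate()

    def test_deletion_longer_than_monomer_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(del_len=400, monomer_len=360).validate()

    def test_bad_subfam_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(subfam_fraction=1.5).validate()

    def test_unparseable_newick_raises(self):
        with pytest.raises(ValueError):
            evolve_monomers(SimConfig(tree="(A:1,B:1"))


class TestEvolveMonomers:
    def test_zero_rates_identity(self):
        cfg = SimConfig(
            seed=1, mu=0.0, homog_rate=0.0, burn_in_diversity=0.0,
            eu_offset=0.0, subfam_fraction=0.0, n_het_arrays=2,
            het_copies=(3, 3), n_eu_copies=2,
        )
        monomers, frag = evolve_monomers(cfg)
        anc = frag["ancestor_360"]
        for state in monomers.values():
            for arr in state.het_arrays:
                assert all(c == anc for c in arr.copies)
            assert all(c == anc for c in state.eu_copies)

    def test_deletion_length(self):
        cfg = SimConfig(seed=2, subfam_fraction=1.0, n_het_arrays=2)
        monomers, frag = evolve_monomers(cfg)
        assert len(frag["ancestor_190"]) == 360 - 170
        for state in monomers.values():
            for arr in state.het_arrays:
                assert arr.subfamily == "F190"
                assert all(len(c) == 190 for c in arr.copies)

    def test_interspecific_p_distance_matches_site_model(self):
        """Mean leaf-vs-leaf p-distance agrees with the analytic expectation
        of the per-branch substitution process within 3 SE (>=500 pairs)."""
        cfg = SimConfig(
            seed=4, tree="(A:0.5,B:0.5);", mu=0.05, kappa=2.0,
            homog_rate=0.0, burn_in_diversity=0.0, eu_offset=0.0,
            n_het_arrays=0, n_eu_copies=600, subfam_fraction=0.0,
        )
        monomers, _ = evolve_monomers(cfg)
        dists = [
            p_distance(a, b)
            for a, b in zip(monomers["A"].eu_copies, monomers["B"].eu_copies)
        ]
        expected = expected_p_distance([0.025, 0.025], kappa=2.0)
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(np.mean(dists) - expected) <= 3 * se

    def test_homogenization_monotonically_reduces_diversity(self):
        """Spearman rho < 0 (p < 0.01) between homog_rate and mean
        intraspecific heterochromatic p-distance."""
        rates = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
        means = []
        for rate in rates:
            cfg = SimConfig(
                seed=5, tree="(A:10,B:10);", mu=0.003, homog_rate=rate,
                n_het_arrays=4, het_copies=(6, 6), n_eu_copies=0,
                burn_in_diversity=0.15, subfam_fraction=0.0,
            )
            monomers, _ = evolve_monomers(cfg)
            copies = [
                c for a in monomers["A"].het_arrays for c in a.copies
            ]
            dists = [
                p_distance(x, y) for x, y in itertools.combinations(copies, 2)
            ]
            means.append(np.mean(dists))
        rho, p = spearmanr(rates, means)
        assert rho < 0
        assert p < 0.01

    def test_domain_contrast(self):
        """Euchromatic intraspecific divergence exceeds heterochromatic when
        heterochromatin is homogenized and ancestral diversity is high."""
        cfg = SimConfig(
            seed=6, tree="(A:10,B:10);", mu=0.003, homog_rate=1.0,
            eu_homog_rate=0.0, n_het_arrays=4, het_copies=(6, 6),
            n_eu_copies=12, burn_in_diversity=0.25, eu_offset=0.0,
            subfam_fraction=0.0,
        )
        monomers, _ = evolve_monomers(cfg)
        het = [c for a in monomers["A"].het_arrays for c in a.copies]
        eu = monomers["A"].eu_copies
        het_div = np.mean(
            [p_distance(x, y) for x, y in itertools.combinations(het, 2)]
        )
        eu_div = np.mean(
            [p_distance(x, y) for x, y in itertools.combinations(eu, 2)]
        )
        assert eu_div > het_div


class TestAssembleGenomes:
    def test_truth_interval_lengths(self, small_sim):
        _, _, truth, _ = small_sim
        for arr in truth.arrays:
            assert arr.length == sum(len(s) for s in arr.monomer_seqs)

    def test_satellite_bp_conservation(self, small_sim):
        _, genomes, truth, _ = small_sim
        total = truth.satellite_bp()
        by_extraction = 0
        for arr in truth.arrays:
            sp_genome = genomes[arr.species]
            by_extraction += len(sp_genome[arr.scaffold][arr.start : arr.end])
        assert by_extraction == total

    def test_planted_sequence_matches_genome(self, small_sim):
        from satevol._align import revcomp

        _, genomes, truth, _ = small_sim
        for arr in truth.arrays:
            region = genomes[arr.species][arr.scaffold][arr.start : arr.end]
            expected = "".join(arr.monomer_seqs)
            if arr.strand == "-":
                expected = revcomp(expected)
            assert region == expected

    def test_truth_validation_passes(self, small_sim):
        _, _, truth, _ = small_sim
        truth.validate()

    def test_oversized_content_rejected(self):
        cfg = SimConfig(seed=1, chrom_len=1000)
        monomers, frag = evolve_monomers(cfg)
        with pytest.raises(ConfigError):
            assemble_genomes(monomers, cfg, frag)


class TestSimulateReads:
    def test_expected_read_count(self):
        cfg = SimConfig(seed=7, coverage=2.0, read_len=100)
        genomes = {"A": {"chr": "ACGT" * 25000}}  # 100 kb
        reads = simulate_reads(genomes, cfg, np.random.default_rng(0))
        lam = 2.0 * 100_000 / 100
        assert abs(len(reads) - lam) <= 3 * np.sqrt(lam)

    def test_zero_coverage_rejected(self):
        cfg = SimConfig(coverage=0.0)
        with pytest.raises(ConfigError):
            simulate_reads({"A": {"chr": "ACGT" * 100}}, cfg)

    def test_error_free_reads_are_genome_substrings(self):
        from satevol._align import revcomp

        cfg = SimConfig(seed=8, coverage=0.5, seq_error_rate=0.0)
        genome = "".join(
            np.random.default_rng(1).choice(list("ACGT"), size=20000)
        )
        reads = simulate_reads({"A": {"chr": genome}}, cfg)
        for _, seq, _ in reads[:200]:
            assert seq in genome or revcomp(seq) in genome

    def test_short_scaffold_skipped(self):
        cfg = SimConfig(seed=9, coverage=1.0, read_len=100)
        reads = simulate_reads({"A": {"tiny": "ACGT" * 10}}, cfg)
        assert reads == []


class TestDeterminismAndRoundTrip:
    def test_identical_seeds_identical_bytes(self, tmp_path):
        cfg = dict(
            seed=21, n_het_arrays=2, het_copies=(3, 4), n_eu_copies=3,
            n_genes=2, coverage=0.2,
        )
        simulate(SimConfig(**cfg), tmp_path / "run1")
        simulate(SimConfig(**cfg), tmp_path / "run2")
        files1 = sorted(p.name for p in (tmp_path / "run1").iterdir())
        files2 = sorted(p.name for p in (tmp_path / "run2").iterdir())
        assert files1 == files2
        for name in files1:
            assert filecmp.cmp(
                tmp_path / "run1" / name, tmp_path / "run2" / name, shallow=False
            ), name

    def test_fasta_gff_roundtrip_matches_truth(self, tmp_path):
        cfg = SimConfig(
            seed=22, n_het_arrays=2, het_copies=(3, 4), n_eu_copies=4,
            n_genes=2, coverage=0.1,
        )
        truth = simulate(cfg, tmp_path)
        from satevol._align import revcomp

        genomes = {
            sp: read_fasta(tmp_path / f"{sp}.fasta") for sp in ("A", "B")
        }
        for scaffold, length in truth.scaffold_lengths.items():
            sp = scaffold.split("_")[0]
            assert len(genomes[sp][scaffold]) == length
        for arr in truth.arrays:
            region = genomes[arr.species][arr.scaffold][arr.start : arr.end]
            expected = "".join(arr.monomer_seqs)
            if arr.strand == "-":
                expected = revcomp(expected)
            assert region == expected
        genes = read_gff3(tmp_path / "genes.gff3")
        by_id = {g.gene_id: g for g in genes}
        assert len(genes) == len(truth.genes)
        for gene in truth.genes:
            got = by_id[gene.gene_id]
            assert (got.start, got.end, got.strand) == (
                gene.start,
                gene.end,
                gene.strand,
            )
            assert sorted(got.exons) == sorted(gene.exons)
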