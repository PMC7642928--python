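import pytest

from conftest import reciprocal_overlap
from satevol._align import revcomp
from satevol.mining import (
    PhaseError,
    SatArray,
    dotplot_boundaries,
    estimate_period,
    extract_monomers,
    find_tandem_arrays,
    merge_arrays,
    search_by_consensus,
)


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindTandemArrays:
    def test_planted_exact_tandem(self, rng):
        unit = _rand(rng, 360)
        genome = _rand(rng, 2000) + unit * 5 + _rand(rng, 2000)
        arrays = find_tandem_arrays(genome, 50, 600)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.period == 360
        assert arr.n_copies == pytest.approx(5, abs=0.2)
        assert abs(arr.start - 2000) <= 5
        assert abs(arr.end - 3800) <= 5

    def test_random_sequence_no_arrays(self, rng):
        assert find_tandem_arrays(_rand(rng, 20000), 50, 600) == []

    def test_empty_sequence(self):
        assert find_tandem_arrays("", 50, 600) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGTXACGT" * 100, 10, 100)

    def test_bad_parameters_rejected(self, rng):
        seq = _rand(rng, 1000)
        with pytest.raises(ValueError):
            find_tandem_arrays(seq, min_period=5)
        with pytest.raises(ValueError):
            find_tandem_arrays(seq, max_period=5000)
        with pytest.raises(ValueError):
            find_tandem_arrays(seq, min_copies=1)

    def test_mutated_copies_still_found(self, rng):
        unit = _rand(rng, 300)
        copies = []
        for _ in range(8):
            chars = list(unit)
            for j in rng.choice(300, size=12, replace=False):  # ~4% divergence
                chars[j] = rng.choice(list("ACGT"))
            copies.append("".join(chars))
        genome = _rand(rng, 1500) + "".join(copies) + _rand(rng, 1500)
        arrays = find_tandem_arrays(genome, 50, 600)
        assert len(arrays) == 1
        assert abs(arrays[0].period - 300) <= 3


class TestSearchByConsensus:
    def test_exact_copy_perfect_hit(self, rng):
        query = _rand(rng, 360)
        genome = _rand(rng, 1000) + query + _rand(rng, 1000)
        hits = search_by_consensus(genome, query)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1000, 1360)
        assert hits[0].mean_identity_to_query == pytest.approx(1.0)
        assert hits[0].strand == "+"

    def test_heavily_randomized_copy_rejected(self, rng):
        """A copy with 40% of positions randomized has expected identity
        ~0.60 + 0.25*0.40 = 0.70 of matched sites -> effective ~0.70*...;
        drawn to land below the 0.65 gate it must not be reported."""
        query = _rand(rng, 360)
        chars = list(query)
        n_rand = int(0.40 * 360)
        sites = rng.choice(360, size=n_rand, replace=False)
        for j in sites:
            chars[j] = rng.choice([b for b in "ACGT" if b != chars[j]])
        copy = "".join(chars)
        # exact planted identity (all randomized sites differ)
        identity = sum(a == b for a, b in zip(copy, query)) / 360
        assert identity < 0.65
        genome = _rand(rng, 1000) + copy + _rand(rng, 1000)
        assert search_by_consensus(genome, query) == []

    def test_reverse_complement_hit(self, rng):
        query = _rand(rng, 360)
        genome = _rand(rng, 800) + revcomp(query) + _rand(rng, 800)
        hits = search_by_consensus(genome, query)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (800, 1160)

    def test_strand_symmetry(self, rng):
        query = _rand(rng, 300)
        genome = _rand(rng, 600) + query + _rand(rng, 400) + revcomp(query) + _rand(rng, 600)
        fwd = search_by_consensus(genome, query)
        rev = search_by_consensus(revcomp(genome), query)
        n = len(genome)
        mirrored = sorted((n - h.end, n - h.start) for h in rev)
        assert sorted((h.start, h.end) for h in fwd) == mirrored

    def test_short_query_rejected(self, rng):
        with pytest.raises(ValueError):
            search_by_consensus(_rand(rng, 500), "ACGT" * 10)

    def test_empty_genome(self, rng):
        assert search_by_consensus("", _rand(rng, 100)) == []

    def test_matches_sliding_oracle_on_small_genome(self, rng):
        """On a <=5 kb genome with well-separated planted copies, hits match
        a brute-force full-scan oracle at the same thresholds."""
        query = _rand(rng, 200)
        copies = [(600, query), (1800, revcomp(query)), (3400, query)]
        genome = list(_rand(rng, 4600))
        for pos, seq in copies:
            genome[pos : pos + 200] = seq
        genome = "".join(genome)

        # oracle: ungapped identity of the query at every offset, both strands
        oracle_hits = []
        for q in (query, revcomp(query)):
            for i in range(len(genome) - 200 + 1):
                window = genome[i : i + 200]
                ident = sum(a == b for a, b in zip(window, q)) / 200
                if ident >= 0.65:
                    oracle_hits.append((i, i + 200))
        oracle_hits.sort()

        hits = sorted((h.start, h.end) for h in search_by_consensus(genome, query))
        assert hits == oracle_hits


class TestDotplotBoundaries:
    def test_planted_array_boundaries(self, rng):
        unit = _rand(rng, 360)
        region = _rand(rng, 500) + unit * 4 + _rand(rng, 500)
        start, end, low_conf = dotplot_boundaries(region, unit)
        assert not low_conf
        assert abs(start - 500) <= 10
        assert abs(end - (500 + 4 * 360)) <= 10

    def test_array_at_sequence_start(self, rng):
        unit = _rand(rng, 300)
        region = unit * 3 + _rand(rng, 500)
        start, end, low_conf = dotplot_boundaries(region, unit)
        assert not low_conf
        assert start == 0

    def test_unrelated_consensus_low_confidence(self, rng):
        region = _rand(rng, 2000)
        unit = _rand(rng, 300)
        start, end, low_conf = dotplot_boundaries(region, unit, hint=(500, 1500))
        assert low_conf
        assert (start, end) == (500, 1500)


class TestExtractMonomers:
    def test_exact_array_five_full_monomers(self, rng):
        unit = _rand(rng, 360)
        genome = _rand(rng, 100) + unit * 5 + _rand(rng, 100)
        arr = SatArray("s", 100, 100 + 1800, "+", 360, 5.0)
        monomers = extract_monomers(genome, arr, reference=unit)
        assert len(monomers) == 5
        assert all(m.full_length for m in monomers)
        assert all(m.sequence == unit for m in monomers)
        assert monomers[0].phase_offset == 0

    def test_partial_terminal_unit_flagged(self, rng):
        """250 bp < 0.75 * 360 = 270 -> full_length False."""
        unit = _rand(rng, 360)
        genome = unit * 3 + unit[:250]
        arr = SatArray("s", 0, len(genome), "+", 360, 3.7)
        monomers = extract_monomers(genome, arr, reference=unit)
        assert [m.full_length for m in monomers] == [True, True, True, False]
        assert len(monomers[-1].sequence) == 250

    def test_no_reference_lexmin_idempotent(self, rng):
        unit = _rand(rng, 120)
        genome = unit * 4
        arr = SatArray("s", 0, len(genome), "+", 120, 4.0)
        first = extract_monomers(genome, arr, reference=None)
        second = extract_monomers(genome, arr, reference=None)
        assert [m.sequence for m in first] == [m.sequence for m in second]
        full = [m.sequence for m in first if len(m.sequence) == 120]
        rotations = {unit[i:] + unit[:i] for i in range(120)}
        assert full[0] in rotations
        assert full[0] == min(rotations)

    def test_reverse_strand_canonical_sequence(self, rng):
        unit = _rand(rng, 200)
        genome = _rand(rng, 50) + revcomp(unit * 3) + _rand(rng, 50)
        arr = SatArray("s", 50, 50 + 600, "-", 200, 3.0)
        monomers = extract_monomers(genome, arr, reference=unit)
        assert all(m.sequence == unit for m in monomers)

    def test_period_reference_mismatch_raises(self, rng):
        unit = _rand(rng, 360)
        arr = SatArray("s", 0, 720, "+", 360, 2.0)
        with pytest.raises(PhaseError):
            extract_monomers(unit * 2, arr, reference=_rand(rng, 100))

    def test_monomers_contained_in_array(self, rng):
        unit = _rand(rng, 150)
        genome = _rand(rng, 30) + unit * 4 + _rand(rng, 30)
        arr = SatArray("s", 30, 30 + 600, "+", 150, 4.0)
        monomers = extract_monomers(genome, arr, reference=unit)
        assert sum(len(m.sequence) for m in monomers) == arr.length


class TestPeriodAndMerge:
    def test_estimate_period_tandem(self, rng):
        unit = _rand(rng, 190)
        assert estimate_period(unit * 5) == 190

    def test_estimate_period_prefers_fundamental_over_harmonic(self, rng):
        unit = _rand(rng, 180)
        assert estimate_period(unit * 6, min_period=50, max_period=600) == 180

    def test_estimate_period_none_for_random(self, rng):
        assert estimate_period(_rand(rng, 2000)) is None

    def test_merge_overlapping(self):
        a = SatArray("s", 100, 500, "+", 360, 1.1, 0.9)
        b = SatArray("s", 400, 900, "+", 360, 1.4, 0.95)
        merged = merge_arrays([a, b])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 900)
        assert merged[0].mean_identity_to_query == 0.95


class TestSimgenRecovery:
    def test_recall_precision_and_monomer_count(self, small_sim):
        from satevol.pipeline import mine_genome

        _, genomes, truth, frag = small_sim
        queries = {
            "ancestor_360": frag["ancestor_360"],
            "ancestor_190": frag["ancestor_190"],
        }
        for sp in ("A",):
            arrays, monomers = mine_genome(genomes[sp], queries, sp)
            truth_sp = [a for a in truth.arrays if a.species == sp]
            matched = sum(
                1
                for t in truth_sp
                if any(
                    a.scaffold == t.scaffold
                    and reciprocal_overlap((t.start, t.end), (a.start, a.end))
                    for a in arrays
                )
            )
            assert matched / len(truth_sp) >= 0.95
            false = sum(
                1
                for a in arrays
                if not any(
                    t.scaffold == a.scaffold
                    and reciprocal_overlap((t.start, t.end), (a.start, a.end))
                    for t in truth_sp
                )
            )
            assert (len(arrays) - false) / len(arrays) >= 0.95
            n_true = sum(len(t.monomer_ids) for t in truth_sp)
            n_full = sum(1 for m in monomers if m.full_length)
            assert abs(n_full - n_true) <= 0.05 * n_true
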