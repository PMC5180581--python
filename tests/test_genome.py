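"""Genome layer: initialization, gene scanning, binding, mutation operators."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from grnswarm.genome import (
    ArtificialGenome, GeneLayout, GeneLocus, GenomeError, MutationRates,
    binds, complement_mismatches, decode, init_genome, load_genome,
    replicate_genome, save_genome, scan_genes,
)

LAYOUT = GeneLayout()  # promoter 0101 | type 2 | site 5 | payload 9


def brute_force_scan(genome: ArtificialGenome, layout: GeneLayout) -> list[tuple]:
    """Independent string-based scanner: left-to-right, non-overlapping genes."""
    out = []
    prom = layout.promoter
    glen = layout.gene_len
    for ci in range(genome.n_chromosomes):
        seq = genome.chromosome_str(ci)
        pos = 0
        while True:
            hit = seq.find(prom, pos)
            if hit < 0 or hit + glen > len(seq):
                break
            t0 = hit + len(prom)
            tval = 0
            for ch in seq[t0 : t0 + layout.type_len]:
                tval = tval * len(genome.alphabet) + genome.alphabet.index(ch)
            b0 = t0 + layout.type_len
            out.append(
                (
                    ci,
                    hit,
                    hit + glen,
                    ("signalling", "regulatory", "structural")[tval % 3],
                    seq[b0 : b0 + layout.binding_len],
                    seq[b0 + layout.binding_len : b0 + layout.binding_len + layout.payload_len],
                )
            )
            pos = hit + glen
    return out


class TestInitGenome:
    def test_default_dimensions(self):
        g = init_genome(0)
        assert g.n_chromosomes == 10
        assert g.lengths == (10_000,) * 10

    def test_same_seed_is_bit_identical(self):
        a = init_genome(7, 1, 20, "01")
        b = init_genome(7, 1, 20, "01")
        assert a == b

    def test_different_seeds_differ(self):
        assert init_genome(1) != init_genome(2)

    def test_character_frequencies_uniform(self):
        g = init_genome(99, 2, 50_000, "0123")
        counts = np.bincount(np.concatenate(g.chromosomes), minlength=4)
        # chi-square goodness of fit against the uniform distribution
        _, p = stats.chisquare(counts)
        assert p > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chromosomes=0),
            dict(chrom_length=0),
            dict(alphabet="0"),
        ],
    )
    def test_invalid_arguments_raise(self, kwargs):
        with pytest.raises(GenomeError):
            init_genome(0, **{"n_chromosomes": 2, "chrom_length": 10, "alphabet": "01", **kwargs})


class TestScanGenes:
    def test_no_promoter_yields_empty(self):
        # chromosome of all '2' cannot contain the promoter 0101
        g = ArtificialGenome.from_strings(["2" * 200], "0123")
        assert scan_genes(g, LAYOUT) == []

    def test_single_promoter_at_offset_13(self):
        body = "2" * 13 + LAYOUT.promoter + "2" * (LAYOUT.gene_len - len(LAYOUT.promoter)) + "33"
        g = ArtificialGenome.from_strings([body], "0123")
        loci = scan_genes(g, LAYOUT)
        assert len(loci) == 1
        assert loci[0].promoter_offset == 13
        assert loci[0].start == 13 and loci[0].end == 13 + LAYOUT.gene_len

    def test_promoter_too_close_to_end_is_dropped(self):
        g = ArtificialGenome.from_strings(["2" * 30 + LAYOUT.promoter + "2" * 3], "0123")
        assert scan_genes(g, LAYOUT) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_chromosomes(self, seed):
        g = init_genome(seed, n_chromosomes=2, chrom_length=1000, alphabet="0123")
        got = [
            (l.chromosome, l.start, l.end, l.gene_type, l.binding_site, l.payload)
            for l in scan_genes(g, LAYOUT)
        ]
        assert got == brute_force_scan(g, LAYOUT)

    def test_scanning_is_pure_and_repeatable(self):
        g = init_genome(5, 1, 1000, "0123")
        before = [c.copy() for c in g.chromosomes]
        first = scan_genes(g, LAYOUT)
        second = scan_genes(g, LAYOUT)
        assert first == second
        assert all(np.array_equal(a, b) for a, b in zip(before, g.chromosomes))

    def test_loci_sorted_and_in_bounds(self):
        g = init_genome(11, 3, 800, "0123")
        loci = scan_genes(g, LAYOUT)
        keys = [(l.chromosome, l.start) for l in loci]
        assert keys == sorted(keys)
        for l in loci:
            assert 0 <= l.start < l.end <= g.lengths[l.chromosome]


class TestBinds:
    def test_perfect_complement_binds_at_zero_tolerance(self):
        # complement of 0123 under c -> 3 - c is 3210
        assert binds("3210", "0123", "0123", tolerance=0)

    def test_identity_is_not_complement(self):
        assert not binds("0123", "0123", "0123", tolerance=0)

    def test_length_mismatch_raises(self):
        with pytest.raises(GenomeError):
            binds("01", "012", "0123")

    def test_exhaustive_enumeration_matches_mismatch_oracle(self):
        alphabet = "0123"
        comp = {a: alphabet[len(alphabet) - 1 - i] for i, a in enumerate(alphabet)}
        import itertools

        seqs = ["".join(s) for s in itertools.product(alphabet, repeat=4)]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(seqs), size=60, replace=False)
        for tol in (0, 1, 2):
            for i in idx:
                for j in idx:
                    sig, site = seqs[i], seqs[j]
                    mism = sum(a != comp[b] for a, b in zip(sig, site))
                    assert binds(sig, site, alphabet, tol) == (mism <= tol)
                    assert complement_mismatches(sig, site, alphabet) == mism


class TestReplicateGenome:
    def test_zero_rates_give_identical_child(self):
        parent = init_genome(3, 2, 500, "0123")
        child = replicate_genome(parent, MutationRates(0.0, 0.0), np.random.default_rng(0))
        assert child == parent

    def test_forced_point_mutation_changes_every_character(self):
        parent = init_genome(4, 1, 300, "0123")
        child = replicate_genome(parent, MutationRates(1.0, 0.0), np.random.default_rng(0))
        assert np.all(child.chromosomes[0] != parent.chromosomes[0])
        assert child.lengths == parent.lengths

    def test_point_mutation_count_within_binomial_ci(self):
        parent = init_genome(5, 1, 100_000, "0123")
        rate = 0.001
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(200):
            child = replicate_genome(parent, MutationRates(rate, 0.0), rng)
            counts.append(int(np.count_nonzero(child.chromosomes[0] != parent.chromosomes[0])))
        n, p = 100_000, rate
        se = np.sqrt(n * p * (1 - p) / len(counts))
        assert abs(np.mean(counts) - n * p) < 2.576 * se  # 99% CI

    def test_duplication_inserts_recoverable_segment(self):
        parent = init_genome(6, 1, 400, "0123")
        child = replicate_genome(parent, MutationRates(0.0, 1.0), np.random.default_rng(7))
        pc, cc = parent.chromosomes[0], child.chromosomes[0]
        extra = len(cc) - len(pc)
        assert extra >= 1
        recovered = any(
            np.array_equal(np.concatenate([cc[:i], cc[i + extra:]]), pc)
            for i in range(len(pc) + 1)
        )
        assert recovered

    def test_mutation_count_bookkeeping(self):
        parent = init_genome(8, 1, 1000, "0123")
        child = replicate_genome(parent, MutationRates(0.01, 0.0), np.random.default_rng(1))
        assert child.mutation_count >= parent.mutation_count


class TestPersistence:
    def test_round_trip_is_bit_exact(self, tmp_path):
        g = init_genome(12, 3, 777, "0123")
        path = tmp_path / "genome.txt"
        save_genome(g, str(path))
        g2 = load_genome(str(path))
        assert g2 == g
        assert g2.seed == g.seed
        assert g2.mutation_count == g.mutation_count

    def test_rejects_non_genome_file(self, tmp_path):
        path = tmp_path / "bogus.txt"
        path.write_text("not a genome\n")
        with pytest.raises(GenomeError):
            load_genome(str(path))
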