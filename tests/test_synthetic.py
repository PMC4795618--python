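"""Generator contracts: repeat structure, variant insertion, read placement."""

import numpy as np
import pytest

from varthesaurus import (ReadSimParams, build_repeat_reference, derive_child,
                          derive_tumor, insert_variants, mix_samples,
                          simulate_reads)


def _repeat_bases(genome):
    return sum(f.length * f.copy_number for f in genome.repeat_map)


class TestRepeatReference:
    def test_zero_fraction_gives_empty_repeat_map(self):
        g = build_repeat_reference(1, 100_000, 0.0, 2, seed=7)
        assert g.repeat_map == []
        assert g.length("chr1") == 100_000

    def test_repeat_intervals_total_requested_fraction(self):
        g = build_repeat_reference(1, 100_000, 0.1, 2, seed=7)
        assert _repeat_bases(g) == 10_000

    def test_copies_are_identical_and_disjoint(self):
        g = build_repeat_reference(1, 100_000, 0.1, 3, seed=3)
        seen = []
        for fam in g.repeat_map:
            seq = g.haplotypes[fam.contig][0]
            src = seq[fam.starts[0]:fam.starts[0] + fam.length]
            for s in fam.starts[1:]:
                assert np.array_equal(src, seq[s:s + fam.length])
            seen.extend((s, s + fam.length) for s in fam.starts)
        seen.sort()
        for (a0, a1), (b0, b1) in zip(seen, seen[1:]):
            assert a1 <= b0  # non-overlapping

    def test_deterministic_fasta_output(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        build_repeat_reference(1, 50_000, 0.1, 2, seed=7).write_fasta(p1)
        build_repeat_reference(1, 50_000, 0.1, 2, seed=7).write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unplaceable_repeats_raise(self):
        with pytest.raises(ValueError, match="without overlap"):
            build_repeat_reference(1, 3_000, 0.9, 3, seed=0)


class TestInsertVariants:
    def test_zero_rate_is_identity(self):
        g = build_repeat_reference(1, 10_000, 0.0, 2, seed=1).to_diploid()
        out, truth = insert_variants(g, 0.0, "germline", seed=2)
        assert len(truth) == 0
        for c in g.contigs:
            for h in range(2):
                assert np.array_equal(g.haplotypes[c][h], out.haplotypes[c][h])

    def test_event_count_matches_binomial_expectation(self):
        g = build_repeat_reference(1, 1_000_000, 0.0, 2, seed=1).to_diploid()
        _, truth = insert_variants(g, 1e-3, "germline", seed=5)
        # mean 1000, sd ~31.6; 4 sd band
        assert 1000 - 4 * 32 <= len(truth) <= 1000 + 4 * 32

    def test_heterozygous_records_have_af_half_and_alter_one_haplotype(self):
        g = build_repeat_reference(1, 50_000, 0.0, 2, seed=1).to_diploid()
        out, truth = insert_variants(g, 2e-3, "germline", seed=3)
        assert len(truth) > 0
        for r in truth:
            assert r.expected_af == 0.5
            pos0 = r.position - 1
            changed = out.haplotypes[r.contig][r.haplotype][pos0]
            other = out.haplotypes[r.contig][1 - r.haplotype][pos0]
            assert "ACGT"[changed] == r.alt
            assert "ACGT"[other] == r.ref

    def test_input_genome_unmodified(self):
        g = build_repeat_reference(1, 20_000, 0.0, 2, seed=1).to_diploid()
        before = g.haplotypes["chr1"][0].copy()
        insert_variants(g, 5e-3, "germline", seed=3)
        assert np.array_equal(g.haplotypes["chr1"][0], before)

    def test_invalid_rate_rejected(self):
        g = build_repeat_reference(1, 1_000, 0.0, 2, seed=1).to_diploid()
        with pytest.raises(ValueError):
            insert_variants(g, 1.5, "germline")
        with pytest.raises(ValueError, match="diploid"):
            insert_variants(build_repeat_reference(1, 1_000, 0.0, 2, seed=1),
                            1e-3, "germline", zygosity="heterozygous")


class TestDeriveTumor:
    def test_zero_rate_gives_identical_genome(self):
        normal, _ = insert_variants(
            build_repeat_reference(1, 10_000, 0.0, 2, seed=1).to_diploid(),
            1e-3, "germline", seed=2)
        tumor, som = derive_tumor(normal, 0.0, seed=3)
        assert len(som) == 0
        for h in range(2):
            assert np.array_equal(normal.haplotypes["chr1"][h],
                                  tumor.haplotypes["chr1"][h])

    def test_somatic_count_and_no_germline_overwrite(self):
        # very high rates force many collisions; none may overwrite
        normal, germ = insert_variants(
            build_repeat_reference(1, 5_000, 0.0, 2, seed=1).to_diploid(),
            0.2, "germline", seed=2)
        tumor, som = derive_tumor(normal, 0.2, seed=3)
        germ_pos = {r.position for r in germ}
        som_pos = {r.position for r in som}
        assert germ_pos.isdisjoint(som_pos)
        assert all(r.origin == "somatic" for r in som)
        # germline alleles still intact in the tumor
        for r in germ:
            assert "ACGT"[tumor.haplotypes[r.contig][r.haplotype][r.position - 1]] == r.alt

    def test_somatic_rate_expectation(self):
        normal, _ = insert_variants(
            build_repeat_reference(1, 1_000_000, 0.0, 2, seed=1).to_diploid(),
            0.0, "germline", seed=2)
        _, som = derive_tumor(normal, 5e-4, seed=9)
        assert 500 - 4 * 23 <= len(som) <= 500 + 4 * 23  # sd ~22.4


class TestDeriveChild:
    @pytest.fixture()
    def parents(self):
        ref = build_repeat_reference(2, 40_000, 0.0, 2, seed=1)
        mother, _ = insert_variants(ref.to_diploid(), 2e-3, "germline", seed=2)
        father, _ = insert_variants(ref.to_diploid(), 2e-3, "germline", seed=3)
        return mother, father

    def test_zero_rate_child_is_pure_transmission(self, parents):
        mother, father = parents
        child, denovo = derive_child(mother, father, 0.0, seed=4)
        assert len(denovo) == 0
        parent_keys = {(r.contig, r.position, r.alt)
                       for p in parents for r in p.truth}
        for r in child.truth:
            assert (r.contig, r.position, r.alt) in parent_keys

    def test_denovo_records_heterozygous_and_disjoint_from_parents(self, parents):
        mother, father = parents
        child, denovo = derive_child(mother, father, 1e-3, seed=4)
        parent_pos = {(r.contig, r.position) for p in parents for r in p.truth}
        for r in denovo:
            assert r.expected_af == 0.5
            assert r.origin == "denovo"
            assert (r.contig, r.position) not in parent_pos

    def test_denovo_count_expectation(self):
        ref = build_repeat_reference(1, 1_000_000, 0.0, 2, seed=1)
        mother, _ = insert_variants(ref.to_diploid(), 0.0, "germline", seed=2)
        father, _ = insert_variants(ref.to_diploid(), 0.0, "germline", seed=3)
        _, denovo = derive_child(mother, father, 1e-4, seed=5)
        assert 100 - 4 * 10 <= len(denovo) <= 100 + 4 * 10

    def test_contig_mismatch_raises(self, parents):
        mother, _ = parents
        other = insert_variants(
            build_repeat_reference(1, 40_000, 0.0, 2, seed=9).to_diploid(),
            1e-3, "germline", seed=2)[0]
        with pytest.raises(ValueError, match="contig"):
            derive_child(mother, other, 1e-4, seed=1)


class TestSimulateReads:
    def test_pair_count_matches_coverage_arithmetic(self):
        g = build_repeat_reference(1, 10_000, 0.0, 2, seed=1)  # haploid
        reads = simulate_reads(g, ReadSimParams())
        assert len(reads) == 1000  # 10000 * 20 / (2 * 100)

    def test_doubling_coverage_doubles_pairs(self):
        g = build_repeat_reference(1, 10_000, 0.0, 2, seed=1)
        n20 = len(simulate_reads(g, ReadSimParams(target_coverage=20)))
        n40 = len(simulate_reads(g, ReadSimParams(target_coverage=40)))
        assert n40 == 2 * n20

    def test_mean_coverage_within_two_percent(self):
        g = build_repeat_reference(1, 100_000, 0.0, 2, seed=1).to_diploid()
        reads = simulate_reads(g, ReadSimParams())
        realized = 2 * 100 * len(reads) / 100_000
        assert abs(realized - 20.0) / 20.0 < 0.02

    def test_error_free_reads_match_source_haplotype(self):
        g, _ = insert_variants(
            build_repeat_reference(1, 20_000, 0.0, 2, seed=1).to_diploid(),
            1e-3, "germline", seed=2)
        reads = simulate_reads(g, ReadSimParams())
        r1, r2 = reads.pair_sequences()
        from varthesaurus._seq import revcomp

        for i in range(0, len(reads), 97):
            hap = g.haplotypes[reads.contig_names[reads.contig_idx[i]]][reads.haplotype[i]]
            s = reads.start[i]
            assert np.array_equal(r1[i], hap[s:s + 100])
            assert np.array_equal(revcomp(r2[i]), hap[s + 300:s + 400])

    def test_contig_shorter_than_fragment_raises(self):
        g = build_repeat_reference(1, 300, 0.0, 2, seed=1)
        with pytest.raises(ValueError, match="shorter than fragment"):
            simulate_reads(g, ReadSimParams())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ReadSimParams(insert_size=150)
        with pytest.raises(ValueError):
            ReadSimParams(target_coverage=0)


class TestMixSamples:
    @pytest.fixture()
    def pair_reads(self):
        ref = build_repeat_reference(1, 100_000, 0.0, 2, seed=1)
        normal, _ = insert_variants(ref.to_diploid(), 1e-3, "germline", seed=2)
        tumor, som = derive_tumor(normal, 2e-3, seed=3)
        p = ReadSimParams()
        return simulate_reads(normal, p), simulate_reads(tumor, p), som

    def test_pure_fractions_reproduce_inputs(self, pair_reads):
        rn, rt, _ = pair_reads
        mixed = mix_samples(rt, rn, 1.0, seed=5)
        assert np.array_equal(mixed.start, rt.start)
        assert np.all(np.asarray(mixed.source_idx) == 0)
        mixed0 = mix_samples(rt, rn, 0.0, seed=5)
        assert np.array_equal(mixed0.start, rn.start)

    def test_half_mixture_dilutes_somatic_af_to_quarter(self, pair_reads):
        """50% purity x heterozygous somatic -> expected mutation AF 0.25."""
        rn, rt, som = pair_reads
        mixed = mix_samples(rt, rn, 0.5, seed=5)
        covering = supporting = 0
        for r in som:
            pos0 = r.position - 1
            m1 = (mixed.start <= pos0) & (pos0 < mixed.start + 100)
            m2 = (mixed.start + 300 <= pos0) & (pos0 < mixed.start + 400)
            cov = m1 | m2
            # tumor-origin reads on the mutated haplotype carry the variant
            carry = cov & (mixed.source_idx == 0) & (mixed.haplotype == r.haplotype)
            covering += int(cov.sum())
            supporting += int(carry.sum())
        af = supporting / covering
        assert abs(af - 0.25) < 0.03

    def test_empty_collection_rejected(self, pair_reads):
        rn, rt, _ = pair_reads
        empty = mix_samples(rt, rn, 0.5, seed=1)
        empty.start = empty.start[:0]
        with pytest.raises(ValueError):
            mix_samples(empty, rn, 0.5, seed=1)
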