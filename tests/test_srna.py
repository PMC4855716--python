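"""Read cleaning, tag collapsing, genome mapping (with a brute-force
oracle), ncRNA filtering, known-miRNA matching and novel prediction."""

from __future__ import annotations

import numpy as np
import pytest

from gonadmir._seq import revcomp
from gonadmir.config import DEFAULT_ADAPTER
from gonadmir.srna import (LibraryStats, ReadTag, annotate_known,
                           clean_reads, collapse_tags, filter_ncrna,
                           length_filter, library_report, map_tags,
                           mirna_counts, predict_novel)

from conftest import make_hairpin, random_seq

HI_Q = "I" * 50


def _reads(seqs):
    return [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestCleanReads:
    def test_adapter_trimmed_at_exact_match(self):
        insert = "TGAGGTAGTAGGTTGTATAGTT"
        out, raw, clean = clean_reads(
            _reads([insert + DEFAULT_ADAPTER[:14]]), DEFAULT_ADAPTER)
        assert out == [insert] and (raw, clean) == (1, 1)

    def test_one_adapter_mismatch_tolerated(self):
        insert = "TGAGGTAGTAGGTTGTATAGTT"
        adapter = list(DEFAULT_ADAPTER[:14])
        adapter[3] = "A" if adapter[3] != "A" else "C"
        out, _, _ = clean_reads(
            _reads([insert + "".join(adapter)]), DEFAULT_ADAPTER)
        assert out == [insert]

    def test_reads_with_n_or_low_quality_discarded(self):
        reads = [("r0", "N" * 30, "I" * 30),
                 ("r1", "ACGT" * 8, "#" * 32)]  # phred 2
        out, raw, clean = clean_reads(reads, DEFAULT_ADAPTER)
        assert out == [] and raw == 2 and clean == 0

    def test_read_without_adapter_discarded(self):
        out, _, clean = clean_reads(_reads(["ACGT" * 9]), DEFAULT_ADAPTER)
        assert out == [] and clean == 0

    def test_nothing_removed_when_all_reads_clean(self):
        rng = np.random.default_rng(0)
        seqs = [random_seq(rng, 22) + DEFAULT_ADAPTER[:14] for _ in range(20)]
        out, raw, clean = clean_reads(_reads(seqs), DEFAULT_ADAPTER)
        assert raw == clean == 20 and len(out) == 20

    def test_malformed_record_raises_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            clean_reads([("r0", "ACGT", "IIII"), ("r1", "ACGT", "III")],
                        DEFAULT_ADAPTER)


class TestLengthFilterAndCollapse:
    @pytest.mark.parametrize("length,kept", [
        (17, False), (18, True), (32, True), (33, False)])
    def test_boundary_lengths(self, length, kept):
        assert bool(length_filter(["A" * length])) is kept

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_counts_preserved_and_order_independent(self):
        a = ["ACGTACGTACGTACGTAC"] * 3 + ["TTTTACGTACGTACGTAC"]
        b = ["ACGTACGTACGTACGTAC"]
        tags = collapse_tags(a, b)
        assert [(t.sequence, t.count_a, t.count_b) for t in tags] == [
            ("ACGTACGTACGTACGTAC", 3, 1), ("TTTTACGTACGTACGTAC", 1, 0)]
        assert sum(t.count_a + t.count_b for t in tags) == len(a) + len(b)
        shuffled = collapse_tags(a[::-1], b)
        assert [(t.sequence, t.count_a, t.count_b) for t in shuffled] == \
            [(t.sequence, t.count_a, t.count_b) for t in tags]


class TestMapping:
    def _brute_force(self, tag, genome, max_mm=1):
        """Naive Hamming scan over every position and strand."""
        loci = []
        for chrom in sorted(genome):
            text = genome[chrom]
            for query, strand in ((tag, "+"), (revcomp(tag), "-")):
                for pos in range(len(text) - len(query) + 1):
                    mm = sum(a != b for a, b in
                             zip(query, text[pos:pos + len(query)]))
                    if mm <= max_mm:
                        loci.append((chrom, strand, pos, mm))
        return sorted(loci)

    def test_exact_and_one_mismatch_loci(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": random_seq(rng, 3000)}
        tag_exact = genome["chr1"][100:122]
        mutated = list(genome["chr1"][500:522])
        mutated[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[10]]
        tags = [ReadTag(tag_exact, 1, 0), ReadTag("".join(mutated), 1, 0)]
        map_tags(tags, genome)
        assert ("chr1", "+", 100, 0) in tags[0].genome_loci
        assert ("chr1", "+", 500, 1) in tags[1].genome_loci

    def test_oracle_equivalence_on_random_tags(self):
        """Pigeonhole-seeded mapping equals the full Hamming scan."""
        rng = np.random.default_rng(2)
        genome = {"chr1": random_seq(rng, 4000), "chr2": random_seq(rng, 1000)}
        tags = []
        for _ in range(60):
            if rng.random() < 0.5:  # planted (possibly mutated) tag
                pos = int(rng.integers(0, 3970))
                seq = list(genome["chr1"][pos:pos + 22])
                if rng.random() < 0.5:
                    p = int(rng.integers(0, 22))
                    seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
                tags.append(ReadTag("".join(seq), 1, 0))
            else:
                tags.append(ReadTag(random_seq(rng, int(rng.integers(18, 33))),
                                    1, 0))
        map_tags(tags, genome)
        for tag in tags:
            assert sorted(tag.genome_loci) == \
                self._brute_force(tag.sequence, genome)


class TestAnnotation:
    MATURES = {"aaa-mir-21": "TAGCTTATCAGACTGATGTTGA",
               "aaa-mir-9": "TCTTTGGTTATCTAGCTGTATGA"}

    def test_exact_match(self):
        tags = [ReadTag(self.MATURES["aaa-mir-21"], 5, 0)]
        annotate_known(tags, self.MATURES)
        assert tags[0].annotation == "known_miRNA"
        assert tags[0].matched_id == "aaa-mir-21"
        assert tags[0].match_mismatches == 0

    def test_two_mismatches_rejected(self):
        seq = list(self.MATURES["aaa-mir-21"])
        seq[0] = "C"
        seq[10] = "C" if seq[10] != "C" else "G"
        tags = [ReadTag("".join(seq), 1, 0)]
        annotate_known(tags, self.MATURES)
        assert tags[0].annotation == "unannotated"

    def test_isomir_overhang_matched(self):
        mat = self.MATURES["aaa-mir-21"]
        for variant in (mat[:-1], mat[1:], mat + "GA"):
            tags = [ReadTag(variant, 1, 0)]
            annotate_known(tags, self.MATURES)
            assert tags[0].annotation == "known_miRNA", variant

    def test_three_nt_overhang_rejected(self):
        tags = [ReadTag(self.MATURES["aaa-mir-21"] + "GAT", 1, 0)]
        annotate_known(tags, self.MATURES)
        assert tags[0].annotation == "unannotated"

    def test_tie_broken_lexicographically(self):
        mature = "TAGCTTATCAGACTGATGTTGA"
        knowns = {"aaa-mir-5": mature, "aaa-mir-3": mature}
        tags = [ReadTag(mature, 1, 0)]
        annotate_known(tags, knowns)
        assert tags[0].matched_id == "aaa-mir-3"

    def test_per_mirna_counts_sum_tag_counts(self):
        mat = self.MATURES["aaa-mir-21"]
        tags = [ReadTag(mat, 3, 1), ReadTag(mat[:-1], 2, 2),
                ReadTag(random_seq(np.random.default_rng(3), 22), 9, 9)]
        annotate_known(tags, self.MATURES)
        counts = mirna_counts(tags)
        row = counts[counts.mirna_id == "aaa-mir-21"].iloc[0]
        assert (row.count_a, row.count_b) == (5, 3)


class TestNcrnaFilter:
    def test_blacklist_fragment_marked(self):
        rng = np.random.default_rng(4)
        rrna = random_seq(rng, 100)
        tags = [ReadTag(rrna[10:36], 4, 0), ReadTag(random_seq(rng, 26), 1, 1)]
        filter_ncrna(tags, {"rRNA-1": rrna})
        assert tags[0].annotation == "ncRNA"
        assert tags[1].annotation == "unannotated"

    def test_empty_blacklist_removes_nothing(self):
        tags = [ReadTag("ACGT" * 6, 1, 0)]
        filter_ncrna(tags, {})
        assert tags[0].annotation == "unannotated"

    def test_ncrna_excluded_from_mirna_annotation(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 22)
        tags = [ReadTag(seq, 1, 0)]
        filter_ncrna(tags, {"rRNA-1": seq + random_seq(rng, 40)})
        annotate_known(tags, {"aaa-mir-x": seq})
        assert tags[0].annotation == "ncRNA"
        assert tags[0].matched_id is None


class TestNovelPrediction:
    def test_planted_hairpin_tag_recovered(self):
        """A tag from a hairpin arm that drifted beyond one mismatch from
        every known mature comes back as a novel candidate."""
        rng = np.random.default_rng(6)
        hairpin = make_hairpin(rng, arm=28)
        chrom = random_seq(rng, 800) + hairpin + random_seq(rng, 800)
        tag_seq = hairpin[2:24]  # inside the 5' arm
        tags = [ReadTag(tag_seq, 6, 1)]
        map_tags(tags, {"chr1": chrom})
        assert len(tags[0].genome_loci) == 1
        novel = predict_novel(tags, {"chr1": chrom})
        assert len(novel) == 1
        assert tags[0].annotation == "novel_candidate"
        assert novel[0].source == "novel"
        assert novel[0].start <= 802 and novel[0].end >= 824

    def test_random_background_tags_rejected(self):
        rng = np.random.default_rng(7)
        genome = {"chr1": random_seq(rng, 6000)}
        rejected = 0
        for _ in range(100):
            pos = int(rng.integers(0, 5978))
            tags = [ReadTag(genome["chr1"][pos:pos + 22], 1, 0)]
            map_tags(tags, genome)
            tags = [t for t in tags if len(t.genome_loci) == 1]
            if not tags or not predict_novel(tags, genome):
                rejected += 1
        assert rejected >= 95

    def test_tag_spanning_the_loop_rejected(self):
        rng = np.random.default_rng(8)
        hairpin = make_hairpin(rng, arm=28, loop=8)
        chrom = random_seq(rng, 600) + hairpin + random_seq(rng, 600)
        tag_seq = hairpin[20:42]  # covers the terminal loop
        tags = [ReadTag(tag_seq, 2, 0)]
        map_tags(tags, {"chr1": chrom})
        assert predict_novel(tags, {"chr1": chrom}) == []
        assert tags[0].annotation == "unannotated"

    def test_annotated_and_multimapping_tags_excluded(self):
        rng = np.random.default_rng(9)
        hairpin = make_hairpin(rng)
        chrom = random_seq(rng, 400) + hairpin + random_seq(rng, 400)
        known_tag = ReadTag(hairpin[0:22], 3, 3)
        known_tag.annotation = "known_miRNA"
        multi = ReadTag(hairpin[0:22], 1, 0)
        multi.genome_loci = [("chr1", "+", 400, 0), ("chr1", "+", 900, 1)]
        map_tags([known_tag], {"chr1": chrom})
        assert predict_novel([known_tag, multi], {"chr1": chrom}) == []


class TestLibraryReport:
    def test_published_scale_percentages(self):
        """Percent fields reproduce half-up rounding at realistic depths:
        11,065,356 / 11,946,840 -> 92.6 % and 8,203,487 -> 68.67 %."""
        stats = LibraryStats("a", raw_reads=12_175_326,
                             clean_reads=11_946_840,
                             genome_mapped=11_065_356,
                             mirbase_mapped=8_203_487)
        assert stats.genome_mapped_pct == "92.6"
        assert stats.mirbase_mapped_pct == "68.67"

    def test_zero_clean_reads_reports_na(self):
        stats = LibraryStats("a")
        assert stats.genome_mapped_pct == "NA"
        assert stats.mirbase_mapped_pct == "NA"

    def test_counts_and_histogram(self):
        t1 = ReadTag("A" * 20, 3, 1)
        t1.genome_loci = [("chr1", "+", 0, 0)]
        t1.annotation = "known_miRNA"
        t1.matched_id = "aaa-mir-1"
        t2 = ReadTag("C" * 22, 2, 0)
        t2.genome_loci = [("chr1", "+", 50, 1)]
        t3 = ReadTag("G" * 20, 0, 4)  # unmapped
        stats, hist = library_report([t1, t2, t3], raw_a=10, clean_a=6,
                                     raw_b=9, clean_b=5)
        assert stats["a"].genome_mapped == 5
        assert stats["b"].genome_mapped == 1
        assert stats["a"].mirbase_mapped == 3
        assert hist.set_index("length").loc[20, "count_a"] == 3
        assert hist.set_index("length").loc[20, "count_b"] == 5
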