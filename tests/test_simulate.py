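"""The synthetic-data generator: determinism, planted structure, database
divergence, read composition and the mRNA panel."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from gonadmir._seq import revcomp
from gonadmir.config import SimulationConfig
from gonadmir.fold import fold_hairpin
from gonadmir.simulate import (make_blacklist, make_databases, make_genome,
                               simulate_mrna, simulate_reads)
from gonadmir.targets import UTRRecord, seed_match


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(seed=5, chrom_lengths=[12_000] * 3,
                premirna_per_chrom=[0, 3, 2], n_chrom=3, n_premirna=5,
                n_de=2, library_size_a=4_000, library_size_b=4_000,
                n_genes=16)
    base.update(overrides)
    return SimulationConfig(**base)


class TestMakeGenome:
    def test_quota_respected_per_chromosome(self):
        genome, truth = make_genome(tiny_config())
        per_chrom = {c: 0 for c in genome}
        for locus in truth.planted_loci:
            per_chrom[locus.chrom] += 1
        assert per_chrom == {"chr1": 0, "chr2": 3, "chr3": 2}

    def test_planted_sequence_matches_genome_slice(self):
        genome, truth = make_genome(tiny_config())
        for locus in truth.planted_loci:
            slice_ = genome[locus.chrom][locus.start:locus.end]
            expected = truth.premirna_seqs[locus.premirna_id]
            if locus.strand == "-":
                expected = revcomp(expected)
            assert slice_ == expected

    def test_planted_hairpins_pass_the_folder(self):
        _genome, truth = make_genome(tiny_config())
        for pre_id, seq in truth.premirna_seqs.items():
            assert fold_hairpin(seq).verdict, pre_id

    def test_mature_is_substring_of_hairpin(self):
        _genome, truth = make_genome(tiny_config())
        for mirna_id, (mature, arm) in truth.mature_seqs.items():
            pre = truth.premirna_seqs[truth.mature_of[mirna_id]]
            assert mature in pre
            assert 20 <= len(mature) <= 24
            assert arm in ("5p", "3p")

    def test_determinism_identical_config(self):
        g1, t1 = make_genome(tiny_config())
        g2, t2 = make_genome(tiny_config())
        assert g1 == g2
        assert [(l.chrom, l.start, l.strand) for l in t1.planted_loci] == \
            [(l.chrom, l.start, l.strand) for l in t2.planted_loci]

    def test_chromosome_too_short_raises(self):
        with pytest.raises(ValueError, match="chr2"):
            make_genome(tiny_config(chrom_lengths=[12_000, 500, 12_000]))

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            tiny_config(premirna_per_chrom=[1, 3, 2])  # sum != n_premirna
        with pytest.raises(ValueError):
            tiny_config(de_fold=1.5)
        with pytest.raises(ValueError):
            tiny_config(error_rate=0.2)


class TestMakeDatabases:
    def test_zero_divergence_reproduces_planted(self):
        _genome, truth = make_genome(tiny_config())
        pre, mat, _bl = make_databases(truth, 0.0, 0.0, seed=5)
        for key, seq in pre.items():
            assert seq == truth.premirna_seqs[key.removeprefix("aaa-")]
        for key, seq in mat.items():
            assert seq == truth.mature_seqs[key.removeprefix("aaa-")][0]

    def test_divergence_matches_binomial_expectation(self):
        """Mean substitutions over many draws ~ len * rate (within 0.3)."""
        _genome, truth = make_genome(tiny_config())
        pre_id, pre_seq = next(iter(truth.premirna_seqs.items()))
        n, rate = len(pre_seq), 0.05
        subs = []
        for seed in range(300):
            pre, _mat, _bl = make_databases(truth, rate, seed=seed)
            subs.append(sum(a != b for a, b in
                            zip(pre[f"aaa-{pre_id}"], pre_seq)))
        assert np.mean(subs) == pytest.approx(n * rate, abs=0.3)

    def test_matures_at_most_one_substitution(self):
        _genome, truth = make_genome(tiny_config())
        _pre, mat, _bl = make_databases(truth, 0.05, 0.10, seed=7)
        for key, seq in mat.items():
            true_seq = truth.mature_seqs[key.removeprefix("aaa-")][0]
            assert sum(a != b for a, b in zip(seq, true_seq)) <= 1

    def test_blacklist_shares_no_18mer_with_matures(self):
        _genome, truth = make_genome(tiny_config())
        blacklist = make_blacklist(truth, seed=5)
        mature_kmers = {m[i:i + 18]
                        for m, _arm in truth.mature_seqs.values()
                        for i in range(len(m) - 17)}
        for seq in blacklist.values():
            kmers = {seq[i:i + 18] for i in range(len(seq) - 17)}
            assert not kmers & mature_kmers

    def test_divergence_out_of_range_raises(self):
        _genome, truth = make_genome(tiny_config())
        with pytest.raises(ValueError):
            make_databases(truth, 0.5)


class TestSimulateReads:
    def test_error_free_reads_start_with_planted_insert(self):
        """With no sequencing errors, every miRNA read is a mature (+-1 nt
        3' variability) followed by the adapter."""
        cfg = tiny_config(error_rate=0.0, ncrna_fraction=0.0)
        _genome, truth = make_genome(cfg)
        inserts = set()
        for mirna_id, (mature, _arm) in truth.mature_seqs.items():
            pre = truth.premirna_seqs[truth.mature_of[mirna_id]]
            off = truth.mature_offset[mirna_id]
            inserts |= {mature, mature[:-1],
                        pre[off:off + len(mature) + 1]}
        for _title, seq, qual in simulate_reads(truth, cfg, "a"):
            assert len(seq) == cfg.read_length == len(qual)
            assert any(seq.startswith(ins + cfg.adapter[:4])
                       for ins in inserts), seq

    def test_fold_change_realized_in_counts(self):
        """a_up miRNAs show ~de_fold more reads in library a (mean over
        replicates within 15 %)."""
        cfg = tiny_config(library_size_a=12_000, library_size_b=12_000,
                          error_rate=0.0, ncrna_fraction=0.0, de_fold=4.0)
        _genome, truth = make_genome(cfg)
        a_up = [m for m, (lab, _f) in truth.de_labels.items() if lab == "a_up"]
        assert a_up
        ratios = []
        for seed in range(12):
            cfg_i = tiny_config(seed=seed + 100, library_size_a=12_000,
                                library_size_b=12_000, error_rate=0.0,
                                ncrna_fraction=0.0, de_fold=4.0)
            counts = {lib: dict.fromkeys(truth.mature_seqs, 0)
                      for lib in "ab"}
            for lib in "ab":
                for title, _seq, _qual in simulate_reads(truth, cfg_i, lib):
                    origin = title.split("|", 1)[1]
                    if origin in counts[lib]:
                        counts[lib][origin] += 1
            for m in a_up:
                if counts["b"][m]:
                    ratios.append(counts["a"][m] / counts["b"][m])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.15)

    def test_ncrna_fraction_of_reads(self):
        cfg = tiny_config(ncrna_fraction=0.10)
        _genome, truth = make_genome(cfg)
        reads = simulate_reads(truth, cfg, "a")
        n_nc = sum(t.split("|", 1)[1] == "ncRNA" for t, _s, _q in reads)
        assert sps.binomtest(n_nc, len(reads), 0.10).pvalue > 1e-4

    def test_empty_library(self):
        cfg = tiny_config(library_size_a=0)
        _genome, truth = make_genome(cfg)
        assert simulate_reads(truth, cfg, "a") == []

    def test_byte_identical_reruns(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        assert simulate_reads(truth, cfg, "a") == simulate_reads(truth, cfg, "a")

    def test_counts_match_multinomial_expectation(self):
        """Chi-square goodness of fit of per-miRNA read counts against the
        planted weights is not rejected at alpha = 0.001 (aggregated over
        seeds to control flakiness)."""
        from gonadmir.simulate import _library_weights, _rng

        pvals = []
        for seed in range(10):
            cfg = tiny_config(seed=seed, ncrna_fraction=0.0, error_rate=0.0,
                              library_size_a=6_000)
            _genome, truth = make_genome(cfg)
            ids, w_a, _w_b = _library_weights(truth, _rng(cfg, 1000))
            counts = dict.fromkeys(ids, 0)
            for title, _s, _q in simulate_reads(truth, cfg, "a"):
                counts[title.split("|", 1)[1]] += 1
            observed = np.array([counts[m] for m in ids])
            expected = w_a / w_a.sum() * observed.sum()
            pvals.append(sps.chisquare(observed, expected).pvalue)
        assert min(pvals) > 0.001 / len(pvals)


class TestSimulateMrna:
    def test_planted_edge_gene_bias_is_opposite(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        simulate_mrna(truth, cfg)
        for mirna_id, gene_id, _off, _cls in truth.target_edges:
            label, _fold = truth.de_labels[mirna_id]
            expected_gene = "b_up" if label == "a_up" else "a_up"
            assert truth.gene_bias[gene_id] == expected_gene

    def test_planted_site_detected_at_recorded_offset(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        utrs, _gff, _fpkm = simulate_mrna(truth, cfg)
        for mirna_id, gene_id, offset, seed_class in truth.target_edges:
            mature, _arm = truth.mature_seqs[mirna_id]
            sites = seed_match(mature, UTRRecord(gene_id, utrs[gene_id]))
            assert any(s.utr_start == offset and s.seed_class == seed_class
                       for s in sites)

    def test_fpkm_classes_exercise_filter_and_undefined_rule(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        _utrs, _gff, fpkm = simulate_mrna(truth, cfg)
        low = fpkm[(fpkm.fpkm_female < 0.5) & (fpkm.fpkm_male < 0.5)]
        assert len(low) >= cfg.n_low_genes
        undef = fpkm[((fpkm.fpkm_female > 0.5) & (fpkm.fpkm_male == 0)) |
                     ((fpkm.fpkm_male > 0.5) & (fpkm.fpkm_female == 0))]
        assert len(undef) == cfg.n_undefined_genes

    def test_gff3_features_cover_all_genes(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        _utrs, gff, fpkm = simulate_mrna(truth, cfg)
        utr_feats = [f for f in gff if f["type"] == "three_prime_UTR"]
        assert len(utr_feats) == cfg.n_genes == len(fpkm)
        for feat in utr_feats:
            assert feat["end"] - feat["start"] + 1 == cfg.utr_length

    def test_utr_too_short_raises(self):
        cfg = tiny_config()
        _genome, truth = make_genome(cfg)
        cfg.utr_length = 10
        with pytest.raises(ValueError):
            simulate_mrna(truth, cfg)
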