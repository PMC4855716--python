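"""Synthetic data generator with a machine-readable ground truth.

Emulates the full input bundle of the pipeline: a genome with planted
pre-miRNA hairpins at uneven chromosomal density, known pre-miRNA / mature
databases from a slightly diverged "related species", an Rfam-style ncRNA
blacklist, two adapter-ligated small-RNA libraries with a planted
differential-expression contrast, and an mRNA panel (3'UTR FASTA + GFF3 +
per-sex FPKM table) whose biased genes carry seed sites for the planted-DE
miRNAs in the inverse direction.

Library "a" plays the female (XX) pool and "b" the male (XY) pool.  All
randomness flows from ``SimulationConfig.seed`` through per-stage child
generators, so identical configurations produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import DNA, revcomp
from .config import SimulationConfig
from . import io

_BASES = np.array(list(DNA))

# stage tags used to derive independent child RNGs from the one config seed
_STAGE_GENOME, _STAGE_DB, _STAGE_READS_A, _STAGE_READS_B, _STAGE_MRNA = range(5)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs point substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        chars[pos] = rng.choice([b for b in DNA if b != chars[pos]])
    return "".join(chars)


@dataclass
class PlantedLocus:
    chrom: str
    start: int           # 0-based half-open on the forward strand
    end: int
    strand: str
    premirna_id: str


@dataclass
class TruthTable:
    """Everything the generator planted, for truth-vs-called comparisons."""

    planted_loci: list[PlantedLocus] = field(default_factory=list)
    premirna_seqs: dict[str, str] = field(default_factory=dict)   # hairpin sense
    mature_seqs: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (seq, arm)
    mature_offset: dict[str, int] = field(default_factory=dict)   # offset in hairpin
    mature_of: dict[str, str] = field(default_factory=dict)       # mirna_id -> premirna_id
    de_labels: dict[str, tuple[str, float]] = field(default_factory=dict)  # mirna -> (label, fold)
    target_edges: list[tuple[str, str, int, str]] = field(default_factory=list)
    gene_bias: dict[str, str] = field(default_factory=dict)       # gene -> a_up/b_up/unbiased/low

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for locus in self.planted_loci:
            if not 0 <= locus.start < locus.end <= chrom_lengths[locus.chrom]:
                raise ValueError(f"locus {locus.premirna_id} outside {locus.chrom}")
        for mirna_id, (seq, _arm) in self.mature_seqs.items():
            pre = self.premirna_seqs[self.mature_of[mirna_id]]
            if seq not in pre:
                raise ValueError(f"mature {mirna_id} not a substring of its hairpin")
        gene_ids = set(self.gene_bias)
        for mirna_id, gene_id, _off, _cls in self.target_edges:
            if mirna_id not in self.mature_seqs or gene_id not in gene_ids:
                raise ValueError("target edge references unknown miRNA or gene")


def _build_hairpin(rng: np.random.Generator) -> tuple[str, int, int]:
    """One planted pre-miRNA: arm + loop + (reverse complement of arm, <=2 mм).

    Returns (sequence, arm_length, loop_length); total 60-90 nt.
    """
    arm_len = int(rng.integers(27, 37))       # 2*27+6=60 .. 2*36+12=84 nt
    loop_len = int(rng.integers(6, 13))
    arm = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len)
    # 1-2 arm mismatches: a perfect palindrome would leave the locus strand
    # genuinely ambiguous to any aligner
    arm2 = _mutate(rng, revcomp(arm), int(rng.integers(1, 3)))
    return arm + loop + arm2, arm_len, loop_len


def make_genome(config: SimulationConfig) -> tuple[dict[str, str], TruthTable]:
    """Background genome with planted hairpins; records all truth fields
    except the mRNA side (filled in by :func:`simulate_mrna`)."""
    config.validate()
    rng = _rng(config, _STAGE_GENOME)
    truth = TruthTable()
    genome: dict[str, str] = {}
    margin, spacing = 150, 120
    idx = 0
    for c, (length, quota) in enumerate(
            zip(config.chrom_lengths, config.premirna_per_chrom)):
        chrom = f"chr{c + 1}"
        seq = list(_random_seq(rng, length))
        # non-overlapping slots, kept clear of chromosome ends
        needed = quota * (90 + spacing) + 2 * margin
        if quota and length < needed:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) too short for "
                f"{quota} planted hairpins (needs >= {needed} bp)")
        if quota:
            usable = length - 2 * margin - quota * (90 + spacing)
            offsets = np.sort(rng.choice(usable + 1, size=quota, replace=False)) \
                if usable >= quota else np.arange(quota)
            pos = margin
            starts = []
            for q in range(quota):
                starts.append(pos + int(offsets[q]))
                pos += 90 + spacing
            for start in starts:
                idx += 1
                pre_id = f"mir-{idx}"
                hairpin, arm_len, _loop_len = _build_hairpin(rng)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = hairpin if strand == "+" else revcomp(hairpin)
                seq[start:start + len(hairpin)] = list(inserted)
                truth.planted_loci.append(
                    PlantedLocus(chrom, start, start + len(hairpin), strand, pre_id))
                truth.premirna_seqs[pre_id] = hairpin
                # mature resides in one arm, 20-24 nt, small 5' offset
                arm = "5p" if rng.random() < 0.5 else "3p"
                m_len = int(rng.integers(20, 25))
                if arm == "5p":
                    off = int(rng.integers(0, 3))
                else:
                    off = len(hairpin) - m_len - int(rng.integers(0, 3))
                mirna_id = f"{pre_id}-{arm}"
                truth.mature_seqs[mirna_id] = (hairpin[off:off + m_len], arm)
                truth.mature_offset[mirna_id] = off
                truth.mature_of[mirna_id] = pre_id
        genome[chrom] = "".join(seq)
    # plant the DE contrast: alternate a_up / b_up over the first n_de miRNAs
    mirna_ids = sorted(truth.mature_seqs)
    de_ids = [mirna_ids[i * len(mirna_ids) // max(config.n_de, 1)]
              for i in range(config.n_de)] if config.n_de else []
    for i, mirna_id in enumerate(mirna_ids):
        if mirna_id in de_ids:
            label = "a_up" if de_ids.index(mirna_id) % 2 == 0 else "b_up"
            truth.de_labels[mirna_id] = (label, config.de_fold)
        else:
            truth.de_labels[mirna_id] = ("neutral", 1.0)
    truth.validate({c: len(s) for c, s in genome.items()})
    return genome, truth


SPECIES_PREFIX = "aaa"  # stand-in related-species code used in database ids


def make_databases(
    truth: TruthTable,
    divergence: float,
    mature_divergence: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Known pre-miRNA / mature databases from an emulated related species,
    plus an ncRNA blacklist sharing no 18-mer with any mature.

    Pre-miRNA backbones receive per-base substitutions at rate ``divergence``;
    matures (far more conserved in practice) receive at most one substitution,
    drawn at rate ``mature_divergence``.
    """
    if not 0 <= divergence <= 0.15:
        raise ValueError("divergence must lie in [0, 0.15]")
    if not 0 <= mature_divergence <= 0.15:
        raise ValueError("mature_divergence must lie in [0, 0.15]")
    rng = np.random.default_rng([seed, _STAGE_DB])
    known_pre, known_mat = {}, {}
    for pre_id, seq in sorted(truth.premirna_seqs.items()):
        n_subs = int(rng.binomial(len(seq), divergence))
        known_pre[f"{SPECIES_PREFIX}-{pre_id}"] = _mutate(rng, seq, n_subs)
    for mirna_id, (seq, _arm) in sorted(truth.mature_seqs.items()):
        n_subs = min(1, int(rng.binomial(len(seq), mature_divergence)))
        known_mat[f"{SPECIES_PREFIX}-{mirna_id}"] = _mutate(rng, seq, n_subs)
    blacklist = make_blacklist(truth, seed)
    return known_pre, known_mat, blacklist


def make_blacklist(truth: TruthTable, seed: int, n_records: int = 8) -> dict[str, str]:
    """Rfam-style contaminant sequences sharing no 18-mer with any mature.

    Drawn from an RNG keyed only on (seed, stage) so the blacklist written
    to disk and the one the read simulator samples from always agree.
    """
    rng = np.random.default_rng([seed, _STAGE_DB, 7])
    mature_18mers = {
        seq[i:i + 18]
        for seq, _arm in truth.mature_seqs.values()
        for i in range(len(seq) - 17)
    }
    blacklist = {}
    families = ["rRNA", "tRNA", "snoRNA", "snRNA"]
    for k in range(n_records):
        while True:
            seq = _random_seq(rng, int(rng.integers(60, 121)))
            kmers = {seq[i:i + 18] for i in range(len(seq) - 17)}
            if not kmers & mature_18mers:
                break
        blacklist[f"{families[k % len(families)]}-{k + 1}"] = seq
    return blacklist


def _library_weights(truth: TruthTable, rng: np.random.Generator
                     ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-miRNA expected abundance weights for libraries a and b."""
    mirna_ids = sorted(truth.mature_seqs)
    base = rng.lognormal(mean=0.0, sigma=0.6, size=len(mirna_ids))
    w_a, w_b = base.copy(), base.copy()
    for i, mirna_id in enumerate(mirna_ids):
        label, fold = truth.de_labels[mirna_id]
        if label == "a_up":
            w_a[i] *= fold
        elif label == "b_up":
            w_b[i] *= fold
    return mirna_ids, w_a, w_b


def simulate_reads(
    truth: TruthTable,
    config: SimulationConfig,
    library: str,
) -> list[tuple[str, str, str]]:
    """One adapter-ligated FASTQ library as (title, seq, qual) tuples.

    Reads are a mature sequence with +-1 nt of 3' trimming variability,
    the 3' adapter appended, truncated to ``read_length`` and subjected to
    uniform substitution errors; ``ncrna_fraction`` of reads are blacklist
    fragments instead.  Counts follow one multinomial draw whose expected
    values realize the planted fold changes.
    """
    if library not in ("a", "b"):
        raise ValueError("library must be 'a' or 'b'")
    config.validate()
    stage = _STAGE_READS_A if library == "a" else _STAGE_READS_B
    rng = _rng(config, stage)
    lib_size = config.library_size_a if library == "a" else config.library_size_b
    if lib_size == 0:
        return []
    mirna_ids, w_a, w_b = _library_weights(truth, _rng(config, _STAGE_GENOME + 1000))
    weights = w_a if library == "a" else w_b
    probs = weights / weights.sum() * (1.0 - config.ncrna_fraction)
    probs = np.append(probs, config.ncrna_fraction)
    counts = rng.multinomial(lib_size, probs)

    blacklist = make_blacklist(truth, config.seed)
    blacklist_seqs = [blacklist[k] for k in sorted(blacklist)]

    inserts: list[str] = []
    origins: list[str] = []  # recorded in read titles for truth evaluation
    for i, mirna_id in enumerate(mirna_ids):
        n = int(counts[i])
        if n == 0:
            continue
        mature, _arm = truth.mature_seqs[mirna_id]
        pre = truth.premirna_seqs[truth.mature_of[mirna_id]]
        off = truth.mature_offset[mirna_id]
        extended = pre[off:off + len(mature) + 1]  # one extra 3' genomic nt
        variants = rng.choice(3, size=n, p=[0.7, 0.15, 0.15])
        for v in variants:
            if v == 1 and len(mature) > 20:
                inserts.append(mature[:-1])
            elif v == 2 and len(extended) > len(mature):
                inserts.append(extended)
            else:
                inserts.append(mature)
            origins.append(mirna_id)
    for _ in range(int(counts[-1])):
        src = blacklist_seqs[int(rng.integers(len(blacklist_seqs)))]
        frag_len = int(rng.integers(18, 29))
        start = int(rng.integers(0, len(src) - frag_len + 1))
        inserts.append(src[start:start + frag_len])
        origins.append("ncRNA")

    order = rng.permutation(len(inserts))
    read_len = config.read_length
    reads_mat = np.empty((len(inserts), read_len), dtype="S1")
    for row, k in enumerate(order):
        full = inserts[k] + config.adapter
        while len(full) < read_len:  # short inserts: pad with adapter copies
            full += config.adapter
        reads_mat[row] = np.frombuffer(full[:read_len].encode(), dtype="S1")
    if config.error_rate > 0:
        bases = np.frombuffer(b"ACGT", dtype="S1")
        err = rng.random(reads_mat.shape) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err)
            base_idx = np.searchsorted(bases, reads_mat[err])
            reads_mat[err] = bases[(base_idx + shift) % 4]
    qual = "I" * read_len
    return [(f"{library}_{row + 1:07d}|{origins[k]}",
             reads_mat[row].tobytes().decode(), qual)
            for row, k in enumerate(order)]


def _seed_site(mature: str) -> str:
    """A perfect 8mer site: reverse complement of miRNA positions 1-8 with
    an A opposite position 1 (target 5'->3')."""
    return revcomp(mature[1:8]) + "A"


def simulate_mrna(
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[dict[str, str], list[dict], pd.DataFrame]:
    """3'UTR panel: (utr_fasta, gff3 features, fpkm table).

    For ``planted_target_fraction`` of the DE miRNAs, a perfect 8mer seed
    site is written into the UTR of a gene whose FPKM bias opposes the
    miRNA's; a configurable tail of genes exercises the low-expression
    filter (FPKM < 0.5) and the undefined-bias rule (> 0.5 vs exactly 0).
    Fills ``truth.target_edges`` and ``truth.gene_bias`` in place.
    """
    config.validate()
    if config.utr_length < 20:
        raise ValueError("utr_length too short to host a seed site")
    rng = _rng(config, _STAGE_MRNA)
    n = config.n_genes
    gene_ids = [f"gene_{i + 1:04d}" for i in range(n)]
    utrs = {g: _random_seq(rng, config.utr_length) for g in gene_ids}

    de_mirnas = sorted(m for m, (label, _f) in truth.de_labels.items()
                       if label in ("a_up", "b_up"))
    n_planted = int(round(config.planted_target_fraction * len(de_mirnas)))
    n_special = config.n_low_genes + config.n_undefined_genes
    if n_planted + n_special > n:
        raise ValueError("n_genes too small for planted targets plus "
                         "filter-exercising genes")
    truth.target_edges = []
    truth.gene_bias = {}
    for i, mirna_id in enumerate(de_mirnas[:n_planted]):
        gene_id = gene_ids[i]
        label, _fold = truth.de_labels[mirna_id]
        gene_label = "b_up" if label == "a_up" else "a_up"
        truth.gene_bias[gene_id] = gene_label
        mature, _arm = truth.mature_seqs[mirna_id]
        site = _seed_site(mature)
        offset = int(rng.integers(0, config.utr_length - len(site) + 1))
        seq = utrs[gene_id]
        utrs[gene_id] = seq[:offset] + site + seq[offset + len(site):]
        truth.target_edges.append((mirna_id, gene_id, offset, "8mer"))
    # remaining ordinary genes: a mix of biased and unbiased backgrounds
    for gene_id in gene_ids[n_planted:n - n_special]:
        u = rng.random()
        truth.gene_bias[gene_id] = ("a_up" if u < 0.2 else
                                    "b_up" if u < 0.4 else "unbiased")
    for k, gene_id in enumerate(gene_ids[n - n_special:]):
        truth.gene_bias[gene_id] = "low" if k < config.n_low_genes else (
            "a_up" if k % 2 == 0 else "b_up")

    # FPKM values: biased classes separated ~4-fold around a log-normal base
    rows = []
    special_start = n - n_special
    undefined_start = special_start + config.n_low_genes
    for k, gene_id in enumerate(gene_ids):
        bias = truth.gene_bias[gene_id]
        if k >= undefined_start:  # undefined-bias pattern: > 0.5 vs exactly 0
            level = float(rng.uniform(0.6, 3.0))
            f, m = (level, 0.0) if bias == "a_up" else (0.0, level)
        elif k >= special_start:  # below the FPKM floor
            f = float(rng.uniform(0.05, 0.45))
            m = float(rng.uniform(0.05, 0.45))
        else:
            base = max(float(rng.lognormal(np.log(20.0), 0.5)), 1.5)
            jf = float(np.exp(rng.normal(0.0, 0.15)))
            jm = float(np.exp(rng.normal(0.0, 0.15)))
            if bias == "a_up":
                f, m = base * 2 * jf, base / 2 * jm
            elif bias == "b_up":
                f, m = base / 2 * jf, base * 2 * jm
            else:
                f, m = base * jf, base * jm
        rows.append((gene_id, round(f, 4), round(m, 4)))
    fpkm = pd.DataFrame(rows, columns=["gene_id", "fpkm_female", "fpkm_male"])

    # gene models laid head-to-tail on one mRNA scaffold (GFF3 is 1-based)
    features = []
    pos = 1
    for gene_id in gene_ids:
        end = pos + config.utr_length - 1
        features.append(dict(seqid="mrna_scaffold", source="gonadmir_sim",
                             type="gene", start=pos, end=end, strand="+",
                             attributes=f"ID={gene_id}"))
        features.append(dict(seqid="mrna_scaffold", source="gonadmir_sim",
                             type="three_prime_UTR", start=pos, end=end,
                             strand="+", attributes=f"Parent={gene_id}"))
        pos = end + 101
    return utrs, features, fpkm


def simulate_all(config: SimulationConfig, outdir: str) -> TruthTable:
    """Generate and write the complete input bundle plus truth tables."""
    io.ensure_dir(outdir)
    genome, truth = make_genome(config)
    known_pre, known_mat, blacklist = make_databases(
        truth, config.divergence, config.mature_divergence, seed=config.seed)
    utrs, gff_features, fpkm = simulate_mrna(truth, config)

    io.write_fasta(genome, f"{outdir}/genome.fa")
    io.write_fasta(known_pre, f"{outdir}/known_premirnas.fa")
    io.write_fasta(known_mat, f"{outdir}/known_matures.fa")
    io.write_fasta(blacklist, f"{outdir}/ncrna_blacklist.fa")
    io.write_fasta(utrs, f"{outdir}/utrs.fa")
    io.write_gff3(gff_features, f"{outdir}/genes.gff3")
    io.write_tsv(fpkm, f"{outdir}/fpkm.tsv")
    for lib in ("a", "b"):
        io.write_fastq(simulate_reads(truth, config, lib),
                       f"{outdir}/reads_{lib}.fastq")

    loci = pd.DataFrame(
        [(l.chrom, l.start, l.end, l.strand, l.premirna_id)
         for l in truth.planted_loci],
        columns=["chrom", "start", "end", "strand", "premirna_id"])
    io.write_tsv(loci, f"{outdir}/truth_loci.tsv")
    de = pd.DataFrame(
        [(m, lab, fold) for m, (lab, fold) in sorted(truth.de_labels.items())],
        columns=["mirna_id", "label", "fold"])
    io.write_tsv(de, f"{outdir}/truth_de.tsv")
    edges = pd.DataFrame(truth.target_edges,
                         columns=["mirna_id", "gene_id", "utr_offset", "seed_class"])
    io.write_tsv(edges, f"{outdir}/truth_edges.tsv")
    bias = pd.DataFrame(sorted(truth.gene_bias.items()),
                        columns=["gene_id", "bias"])
    io.write_tsv(bias, f"{outdir}/truth_gene_bias.tsv")
    return truth
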