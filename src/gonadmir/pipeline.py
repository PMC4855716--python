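"""End-to-end orchestration: discovery -> annotation -> DE -> targets ->
integration, with optional synthetic-data generation and truth evaluation.

``run_pipeline`` works from files on disk (the formats the CLI documents);
``--simulate`` first writes a complete synthetic bundle and then runs the
same file-based pipeline over it, so the simulation path exercises every
reader and writer a real dataset would.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import discovery, expression, integrate, io, simulate, srna, targets
from .config import SimulationConfig
from .discovery import DistributionTest, PreMiRNACandidate
from .expression import DECall
from .integrate import GeneExpression, NetworkSummary, RegulatoryEdge
from .srna import LibraryStats, ReadTag
from .targets import TargetPrediction


@dataclass
class PipelineResult:
    candidates: list[PreMiRNACandidate]
    distribution: DistributionTest | None
    tags: list[ReadTag]
    novel: list[PreMiRNACandidate]
    stats: dict[str, LibraryStats]
    length_hist: pd.DataFrame
    de_calls: list[DECall]
    predictions: list[TargetPrediction]
    raw_target_counts: pd.DataFrame
    genes: list[GeneExpression]
    edges: list[RegulatoryEdge]
    summary: NetworkSummary
    truth_metrics: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    genome_path: str,
    known_premirnas_path: str,
    known_matures_path: str,
    blacklist_path: str,
    fastq_a_path: str,
    fastq_b_path: str,
    utr_fasta_path: str,
    fpkm_path: str,
    outdir: str,
    adapter: str = "GCCTTGGCACCCGAGAATTCCA",
    e_cutoff: float = 0.001,
    discovery_flank: int = 30,
    novel_flank: int = 50,
    min_target_score: int = targets.MIN_SCORE,
    config: SimulationConfig | None = None,
) -> PipelineResult:
    """Run every stage over files on disk and write all reports to outdir."""
    import os

    for path in (genome_path, known_premirnas_path, known_matures_path,
                 blacklist_path, fastq_a_path, fastq_b_path,
                 utr_fasta_path, fpkm_path):
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input file: {path}")
    io.ensure_dir(outdir)

    genome = io.read_fasta(genome_path)
    known_pre = io.read_fasta(known_premirnas_path)
    known_mat = io.read_fasta(known_matures_path)
    blacklist = io.read_fasta(blacklist_path)

    # --- stage 1: conserved pre-miRNA discovery -------------------------
    candidates, dist = discovery.discover(
        known_pre, genome, e_cutoff=e_cutoff, flank=discovery_flank)
    io.write_tsv(discovery.candidates_to_frame(candidates),
                 f"{outdir}/premirna_candidates.tsv")
    io.write_gff3(discovery.candidates_to_gff3(candidates),
                  f"{outdir}/premirna_candidates.gff3")
    counts_per_chrom = {c: 0 for c in genome}
    for cand in candidates:
        counts_per_chrom[cand.chrom] += 1
    with open(f"{outdir}/chrom_distribution.txt", "w") as fh:
        fh.write("chrom\tn_premirna\n")
        for chrom in sorted(counts_per_chrom):
            fh.write(f"{chrom}\t{counts_per_chrom[chrom]}\n")
        if dist is not None:
            fh.write(f"# chi2={dist.chi2:.4f} df={dist.df} "
                     f"p={dist.p_value:.6g}\n")

    # --- stage 2: small-RNA library annotation --------------------------
    reads_a = list(io.iter_fastq(fastq_a_path))
    reads_b = list(io.iter_fastq(fastq_b_path))
    clean_a, raw_a, n_clean_a = srna.clean_reads(reads_a, adapter)
    clean_b, raw_b, n_clean_b = srna.clean_reads(reads_b, adapter)
    filt_a = srna.length_filter(clean_a)
    filt_b = srna.length_filter(clean_b)
    tags = srna.collapse_tags(filt_a, filt_b)
    srna.map_tags(tags, genome)
    mapped_tags = [t for t in tags if t.genome_loci]
    srna.filter_ncrna(tags, blacklist)
    srna.annotate_known(tags, known_mat)
    novel = srna.predict_novel(mapped_tags, genome, flank=novel_flank)
    stats, length_hist = srna.library_report(
        tags, raw_a, n_clean_a, raw_b, n_clean_b)
    io.write_tsv(srna.tags_to_frame(tags), f"{outdir}/tags.tsv")
    io.write_tsv(pd.DataFrame([{
        "library": s.library, "raw_reads": s.raw_reads,
        "clean_reads": s.clean_reads, "genome_mapped": s.genome_mapped,
        "genome_mapped_pct": s.genome_mapped_pct,
        "mirbase_mapped": s.mirbase_mapped,
        "mirbase_mapped_pct": s.mirbase_mapped_pct,
    } for s in stats.values()]), f"{outdir}/library_stats.tsv")
    io.write_tsv(length_hist, f"{outdir}/length_histogram.tsv")
    io.write_tsv(discovery.candidates_to_frame(novel),
                 f"{outdir}/novel_candidates.tsv")
    io.write_gff3(discovery.candidates_to_gff3(novel),
                  f"{outdir}/novel_candidates.gff3")

    # --- stage 3: expression / DE ---------------------------------------
    counts_df = srna.mirna_counts(tags)
    counts = {row.mirna_id: (row.count_a, row.count_b)
              for row in counts_df.itertuples(index=False)}
    expr = expression.tpm_normalize(counts, n_clean_a, n_clean_b) \
        if counts else []
    de_calls = expression.call_de(expr, n_clean_a, n_clean_b) if expr else []
    io.write_tsv(expression.calls_to_frame(de_calls), f"{outdir}/de_calls.tsv")

    # --- stage 4: target prediction -------------------------------------
    utrs = targets.utrs_from_fasta(utr_fasta_path)
    de_matures = {c.mirna_id: known_mat[c.mirna_id] for c in de_calls
                  if c.status != "not_de" and c.mirna_id in known_mat}
    if de_matures:
        predictions, raw_counts = targets.predict_targets(
            de_matures, utrs, min_score=min_target_score)
    else:
        predictions, raw_counts = [], pd.DataFrame(
            columns=["mirna_id", "n_target_genes", "n_sites"])
    io.write_tsv(targets.predictions_to_frame(predictions),
                 f"{outdir}/target_predictions.tsv")
    io.write_tsv(raw_counts, f"{outdir}/raw_target_counts.tsv")

    # --- stage 5: integration -------------------------------------------
    fpkm = io.read_tsv(fpkm_path)
    genes = integrate.classify_gene_table(fpkm)
    edges = integrate.integrate(de_calls, predictions, genes)
    summary = integrate.summarize_network(
        predictions, edges, sorted(de_matures))
    multi_mirna, multi_gene = integrate.multi_target_report(edges)
    io.write_tsv(integrate.genes_to_frame(genes), f"{outdir}/gene_bias.tsv")
    io.write_tsv(integrate.edges_to_frame(edges), f"{outdir}/edges.tsv")
    io.write_tsv(multi_mirna, f"{outdir}/multi_target_mirnas.tsv")
    io.write_tsv(multi_gene, f"{outdir}/multi_mirna_genes.tsv")
    summary_df = pd.DataFrame([{
        "mirna_id": m,
        "raw_targets": summary.per_mirna_raw.get(m, 0),
        "integrated_targets": summary.per_mirna_integrated.get(m, 0),
    } for m in sorted(summary.per_mirna_raw)])
    io.write_tsv(summary_df, f"{outdir}/network_summary.tsv")

    result = PipelineResult(
        candidates=candidates, distribution=dist, tags=tags, novel=novel,
        stats=stats, length_hist=length_hist, de_calls=de_calls,
        predictions=predictions, raw_target_counts=raw_counts,
        genes=genes, edges=edges, summary=summary)

    with open(f"{outdir}/run_log.yaml", "w") as fh:
        yaml.safe_dump({
            "python": platform.python_version(),
            "adapter": adapter, "e_cutoff": e_cutoff,
            "discovery_flank": discovery_flank, "novel_flank": novel_flank,
            "min_target_score": min_target_score,
            "n_candidates": len(candidates), "n_tags": len(tags),
            "n_de": sum(c.status in ("a_up", "b_up") for c in de_calls),
            "n_edges": len(edges),
            "reduction_factor": None if summary.mean_integrated == 0
            else round(summary.reduction_factor, 3),
        }, fh, sort_keys=False)
    return result


def run_simulated(
    config: SimulationConfig,
    outdir: str,
) -> tuple[PipelineResult, simulate.TruthTable]:
    """Generate a synthetic bundle, run the file-based pipeline over it and
    score every stage against the planted truth."""
    datadir = io.ensure_dir(f"{outdir}/data")
    resultdir = io.ensure_dir(f"{outdir}/results")
    truth = simulate.simulate_all(config, datadir)
    result = run_pipeline(
        genome_path=f"{datadir}/genome.fa",
        known_premirnas_path=f"{datadir}/known_premirnas.fa",
        known_matures_path=f"{datadir}/known_matures.fa",
        blacklist_path=f"{datadir}/ncrna_blacklist.fa",
        fastq_a_path=f"{datadir}/reads_a.fastq",
        fastq_b_path=f"{datadir}/reads_b.fastq",
        utr_fasta_path=f"{datadir}/utrs.fa",
        fpkm_path=f"{datadir}/fpkm.tsv",
        outdir=resultdir,
        adapter=config.adapter,
        config=config,
    )
    result.truth_metrics = evaluate_against_truth(
        result, truth, config, f"{datadir}/reads_a.fastq",
        f"{datadir}/reads_b.fastq")
    io.write_tsv(pd.DataFrame([result.truth_metrics]),
                 f"{resultdir}/truth_metrics.tsv")
    return result, truth


def evaluate_against_truth(
    result: PipelineResult,
    truth: simulate.TruthTable,
    config: SimulationConfig,
    fastq_a_path: str,
    fastq_b_path: str,
) -> dict[str, float]:
    """Truth-vs-called comparison across all stages.

    Returns recovery/sensitivity metrics on the scale [0, 1] except where
    noted.  Mature-read annotation attributes each read through the origin
    recorded in its FASTQ title by the simulator.
    """
    metrics: dict[str, float] = {}

    # planted locus recovery: accepted candidate overlapping the locus on
    # the same strand, named after the planted family
    recovered = named = 0
    for locus in truth.planted_loci:
        overlapping = [
            c for c in result.candidates
            if c.chrom == locus.chrom and c.strand == locus.strand
            and not (c.end <= locus.start or c.start >= locus.end)]
        if overlapping:
            recovered += 1
            if any(c.ortholog_id == locus.premirna_id for c in overlapping):
                named += 1
    n_loci = len(truth.planted_loci)
    metrics["locus_recovery"] = recovered / n_loci if n_loci else 1.0
    metrics["locus_named_recovery"] = named / n_loci if n_loci else 1.0

    # mature-derived read annotation rate
    tags_by_seq = {t.sequence: t for t in result.tags}
    total = annotated = 0
    for path in (fastq_a_path, fastq_b_path):
        for title, seq, _qual in io.iter_fastq(path):
            origin = title.split("|", 1)[1] if "|" in title else ""
            if not origin.startswith("mir"):
                continue
            total += 1
            pos = srna._find_adapter(seq.upper(), config.adapter)
            if pos < srna.MIN_TAG_LEN or pos > srna.MAX_TAG_LEN:
                continue
            tag = tags_by_seq.get(seq[:pos].upper())
            if tag is not None and tag.annotation == "known_miRNA":
                annotated += 1
    metrics["mature_read_annotation"] = annotated / total if total else 1.0

    # DE sensitivity / false-positive rate among neutral miRNAs
    call_by_id = {discovery.strip_species_prefix(c.mirna_id): c
                  for c in result.de_calls}
    n_true_de = n_found = n_neutral = n_false = 0
    for mirna_id, (label, _fold) in truth.de_labels.items():
        call = call_by_id.get(mirna_id)
        if label in ("a_up", "b_up"):
            n_true_de += 1
            if call is not None and call.status == label:
                n_found += 1
        elif label == "neutral":
            n_neutral += 1
            if call is not None and call.status in ("a_up", "b_up"):
                n_false += 1
    metrics["de_sensitivity"] = n_found / n_true_de if n_true_de else 1.0
    metrics["de_fpr"] = n_false / n_neutral if n_neutral else 0.0

    # integrated edge recovery and the opposite-bias invariant
    edge_set = {(discovery.strip_species_prefix(e.mirna_id), e.gene_id)
                for e in result.edges}
    planted = {(m, g) for m, g, _off, _cls in truth.target_edges}
    metrics["edge_recovery"] = (
        len(planted & edge_set) / len(planted) if planted else 1.0)
    gene_up = {"female_up": "a", "undefined_bias_female": "a",
               "male_up": "b", "undefined_bias_male": "b"}
    mirna_up = {"a_up": "a", "a_exclusive": "a",
                "b_up": "b", "b_exclusive": "b"}
    metrics["same_direction_edges"] = float(sum(
        gene_up.get(e.gene_bias) == mirna_up.get(e.mirna_bias)
        for e in result.edges))
    metrics["reduction_factor"] = result.summary.reduction_factor
    if result.distribution is not None:
        metrics["chrom_distribution_p"] = result.distribution.p_value
    return metrics
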