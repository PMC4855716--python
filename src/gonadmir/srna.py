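"""Small-RNA library processing: trim, filter, collapse, map, annotate.

Raw FASTQ reads are adapter-trimmed and quality-filtered, restricted to the
18-32 nt insert range, collapsed to unique tags with per-library counts,
mapped to the genome tolerating one mismatch (pigeonhole-seeded exact
halves, so completeness is guaranteed), cleared of ncRNA contaminants via a
blacklist, matched to known mature miRNAs (<= 1 mismatch, small terminal
isomiR overhangs allowed), and leftover uniquely-mapping tags are folded
with genomic flanks to nominate novel miRNA precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from ._seq import revcomp, to_dna
from .discovery import PreMiRNACandidate, fold_candidate

MIN_TAG_LEN, MAX_TAG_LEN = 18, 32


@dataclass
class ReadTag:
    """A collapsed unique small-RNA sequence with per-library counts."""

    sequence: str
    count_a: int = 0
    count_b: int = 0
    genome_loci: list[tuple[str, str, int, int]] = field(default_factory=list)
    annotation: str = "unannotated"   # known_miRNA | ncRNA | novel_candidate | unannotated
    matched_id: str | None = None
    match_mismatches: int | None = None


@dataclass
class LibraryStats:
    library: str
    raw_reads: int = 0
    clean_reads: int = 0
    genome_mapped: int = 0
    mirbase_mapped: int = 0

    @staticmethod
    def _pct(numerator: int, denominator: int, decimals: int) -> str:
        if denominator == 0:
            return "NA"
        q = Decimal(1).scaleb(-decimals)
        value = Decimal(100 * numerator) / Decimal(denominator)
        return str(value.quantize(q, rounding=ROUND_HALF_UP))

    @property
    def genome_mapped_pct(self) -> str:
        """Percent of clean reads mapped to the genome, 1 decimal."""
        return self._pct(self.genome_mapped, self.clean_reads, 1)

    @property
    def mirbase_mapped_pct(self) -> str:
        """Percent of clean reads matched to known matures, 2 decimals."""
        return self._pct(self.mirbase_mapped, self.clean_reads, 2)


def _find_adapter(seq: str, adapter: str) -> int:
    """Position where the 3' adapter begins, or -1 if absent.

    The leftmost exact match of the adapter's first 10 nt wins; a single
    mismatch in that prefix is tolerated as a fallback, then the longest
    suffix-prefix overlap (>= 6 nt) at the read end.
    """
    probe = adapter[:10]
    pos = seq.find(probe)
    if pos >= 0:
        return pos
    if len(probe) == 10:
        for i in range(len(seq) - len(probe) + 1):
            window = seq[i:i + len(probe)]
            if sum(a != b for a, b in zip(window, probe)) <= 1:
                return i
    max_k = min(len(adapter) - 1, len(seq), 9)
    for k in range(max_k, 5, -1):
        if seq.endswith(adapter[:k]):
            return len(seq) - k
    return -1


def clean_reads(
    reads: list[tuple[str, str, str]],
    adapter: str,
    min_q: int = 20,
) -> tuple[list[str], int, int]:
    """Trim adapters and drop low-quality reads.

    Returns (trimmed insert sequences, raw count, clean count).  Reads are
    discarded when the mean Phred quality falls below ``min_q``, when they
    contain N, or when no adapter can be located (insert ran past the read).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    raw = 0
    out: list[str] = []
    for idx, record in enumerate(reads):
        try:
            _title, seq, qual = record
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}") from exc
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {idx}: "
                             "sequence/quality length mismatch")
        raw += 1
        seq = seq.upper()
        if "N" in seq:
            continue
        if qual and np.mean([ord(c) - 33 for c in qual]) < min_q:
            continue
        pos = _find_adapter(seq, adapter)
        if pos < 0:
            continue
        insert = seq[:pos]
        if insert:
            out.append(insert)
    return out, raw, len(out)


def length_filter(reads: list[str],
                  min_len: int = MIN_TAG_LEN,
                  max_len: int = MAX_TAG_LEN) -> list[str]:
    """Keep inserts of 18-32 nt inclusive."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse_tags(reads_a: list[str], reads_b: list[str]) -> list[ReadTag]:
    """Merge identical sequences into tags with per-library counts,
    sorted by sequence for determinism."""
    counts: dict[str, list[int]] = {}
    for seq in reads_a:
        counts.setdefault(seq, [0, 0])[0] += 1
    for seq in reads_b:
        counts.setdefault(seq, [0, 0])[1] += 1
    return [ReadTag(seq, a, b) for seq, (a, b) in sorted(counts.items())]


def _occurrences(pattern: str, text: str) -> list[int]:
    out, pos = [], text.find(pattern)
    while pos >= 0:
        out.append(pos)
        pos = text.find(pattern, pos + 1)
    return out


def _near_matches(tag: str, text: str, max_mm: int) -> list[tuple[int, int]]:
    """All (position, mismatches) of ``tag`` in ``text`` with <= max_mm
    substitutions, via pigeonhole seeding on two exact halves."""
    half = len(tag) // 2
    starts: set[int] = set()
    for seed, offset in ((tag[:half], 0), (tag[half:], half)):
        for pos in _occurrences(seed, text):
            start = pos - offset
            if 0 <= start <= len(text) - len(tag):
                starts.add(start)
    hits = []
    for start in sorted(starts):
        window = text[start:start + len(tag)]
        mm = sum(a != b for a, b in zip(tag, window))
        if mm <= max_mm:
            hits.append((start, mm))
    return hits


def map_tags(
    tags: list[ReadTag],
    genome: dict[str, str],
    max_mm: int = 1,
) -> list[ReadTag]:
    """Record every genomic locus within ``max_mm`` substitutions of each
    tag (both strands, full-length).  Loci are (chrom, strand, forward-strand
    start, mismatches)."""
    genome = {c: to_dna(s) for c, s in genome.items()}
    for tag in tags:
        loci: list[tuple[str, str, int, int]] = []
        rc = revcomp(tag.sequence)
        for chrom in sorted(genome):
            text = genome[chrom]
            for pos, mm in _near_matches(tag.sequence, text, max_mm):
                loci.append((chrom, "+", pos, mm))
            for pos, mm in _near_matches(rc, text, max_mm):
                loci.append((chrom, "-", pos, mm))
        tag.genome_loci = loci
    return tags


def filter_ncrna(tags: list[ReadTag], blacklist: dict[str, str],
                 max_mm: int = 1) -> list[ReadTag]:
    """Mark tags matching any blacklist sequence (substring, <= 1 mismatch)
    as ncRNA; they stay in the tag table but leave the miRNA stream."""
    for tag in tags:
        if tag.annotation == "ncRNA":
            continue
        for seq in blacklist.values():
            if len(tag.sequence) <= len(seq) and \
                    _near_matches(tag.sequence, to_dna(seq), max_mm):
                tag.annotation = "ncRNA"
                break
    return tags


def annotate_known(
    tags: list[ReadTag],
    known_matures: dict[str, str],
    max_mm: int = 1,
    max_overhang: int = 2,
) -> list[ReadTag]:
    """Match tags to known mature miRNAs.

    A tag matches a mature when they align with <= ``max_mm`` substitutions
    at equal length, or as substring/superstring with at most
    ``max_overhang`` unaligned terminal nucleotides (isomiR trimming).
    Ties go to (fewest mismatches, lexicographically smallest id).
    """
    matures = {mid: to_dna(seq) for mid, seq in known_matures.items()}
    # pigeonhole prefilter: an 18+ nt alignment with <= 1 substitution always
    # contains an exact run of >= 9 aligned bases, i.e. a shared 9-mer
    k = 9
    kmer_to_ids: dict[str, set[str]] = {}
    for mid, mat in matures.items():
        for i in range(len(mat) - k + 1):
            kmer_to_ids.setdefault(mat[i:i + k], set()).add(mid)
    for tag in tags:
        if tag.annotation == "ncRNA":
            continue
        best: tuple[int, str] | None = None
        seq = tag.sequence
        candidate_ids: set[str] = set()
        for probe_start in range(max(len(seq) - k + 1, 1)):
            candidate_ids |= kmer_to_ids.get(seq[probe_start:probe_start + k], set())
        for mid in sorted(candidate_ids):
            mat = matures[mid]
            short, long_ = (seq, mat) if len(seq) <= len(mat) else (mat, seq)
            if len(long_) - len(short) > max_overhang:
                continue
            for off in range(len(long_) - len(short) + 1):
                mm = sum(a != b for a, b in
                         zip(short, long_[off:off + len(short)]))
                if mm <= max_mm and (best is None or mm < best[0]):
                    best = (mm, mid)
        if best is not None:
            tag.annotation = "known_miRNA"
            tag.match_mismatches, tag.matched_id = best
    return tags


def predict_novel(
    tags: list[ReadTag],
    genome: dict[str, str],
    flank: int = 50,
    **fold_kwargs,
) -> list[PreMiRNACandidate]:
    """Fold unannotated, uniquely-mapping tags with genomic flanks and keep
    proper stem-loops where the tag lies wholly within one arm."""
    genome = {c: to_dna(s) for c, s in genome.items()}
    candidates: list[PreMiRNACandidate] = []
    seen_loci: set[tuple[str, str, int]] = set()
    for tag in tags:
        if tag.annotation != "unannotated" or len(tag.genome_loci) != 1:
            continue
        chrom, strand, pos, _mm = tag.genome_loci[0]
        locus = (chrom, strand, pos)
        if locus in seen_loci:
            continue
        seen_loci.add(locus)
        chrom_seq = genome[chrom]
        start = max(0, pos - flank)
        end = min(len(chrom_seq), pos + len(tag.sequence) + flank)
        window = chrom_seq[start:end]
        # tag offset inside the (strand-oriented) window
        tag_off = pos - start
        if strand == "-":
            window = revcomp(window)
            tag_off = len(window) - (pos - start) - len(tag.sequence)
        cand = PreMiRNACandidate(
            id=f"novel|{chrom}:{start}-{end}({strand})",
            chrom=chrom, strand=strand, start=start, end=end,
            sequence=window, source="novel",
            left_clipped=pos - flank < 0,
            right_clipped=pos + len(tag.sequence) + flank > len(chrom_seq))
        fold_candidate(cand, **fold_kwargs)
        if not cand.accepted:
            continue
        loop = cand.fold.loop_span
        tag_end = tag_off + len(tag.sequence)
        if loop is not None and (tag_end <= loop[0] or tag_off >= loop[1]):
            tag.annotation = "novel_candidate"
            candidates.append(cand)
    return candidates


def mirna_counts(tags: list[ReadTag]) -> pd.DataFrame:
    """Per-miRNA counts: sum of counts of all tags matched to each id."""
    rows: dict[str, list[int]] = {}
    for tag in tags:
        if tag.annotation == "known_miRNA" and tag.matched_id:
            acc = rows.setdefault(tag.matched_id, [0, 0])
            acc[0] += tag.count_a
            acc[1] += tag.count_b
    return pd.DataFrame(
        [(mid, a, b) for mid, (a, b) in sorted(rows.items())],
        columns=["mirna_id", "count_a", "count_b"])


def library_report(
    tags: list[ReadTag],
    raw_a: int, clean_a: int, raw_b: int, clean_b: int,
) -> tuple[dict[str, LibraryStats], pd.DataFrame]:
    """Per-library pipeline statistics plus a count-weighted tag length
    histogram."""
    stats = {
        "a": LibraryStats("a", raw_reads=raw_a, clean_reads=clean_a),
        "b": LibraryStats("b", raw_reads=raw_b, clean_reads=clean_b),
    }
    hist: dict[int, list[int]] = {}
    for tag in tags:
        mapped = len(tag.genome_loci) > 0
        known = tag.annotation == "known_miRNA"
        if mapped:
            stats["a"].genome_mapped += tag.count_a
            stats["b"].genome_mapped += tag.count_b
        if known:
            stats["a"].mirbase_mapped += tag.count_a
            stats["b"].mirbase_mapped += tag.count_b
        acc = hist.setdefault(len(tag.sequence), [0, 0])
        acc[0] += tag.count_a
        acc[1] += tag.count_b
    hist_df = pd.DataFrame(
        [(length, a, b) for length, (a, b) in sorted(hist.items())],
        columns=["length", "count_a", "count_b"])
    return stats, hist_df


def tags_to_frame(tags: list[ReadTag]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sequence": t.sequence, "count_a": t.count_a, "count_b": t.count_b,
        "annotation": t.annotation, "matched_id": t.matched_id or "NA",
        "match_mismatches": -1 if t.match_mismatches is None else t.match_mismatches,
        "n_loci": len(t.genome_loci),
        "loci": ";".join(f"{c}:{s}{p}:{m}" for c, s, p, m in t.genome_loci) or "NA",
    } for t in tags])
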