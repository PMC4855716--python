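"""Conserved pre-miRNA discovery: homology search, flank extension,
hairpin validation, reciprocal orthology naming and a chromosomal
distribution test.

The homology search is a seeded, ungapped local aligner: exact 11-mer word
hits are extended in both directions under a +1/-2 match/mismatch scheme
with an X-drop of 10, and scored hits are converted to E-values with the
ungapped Karlin-Altschul statistics E = K * m * n * exp(-lambda * S)
(K = 0.711, lambda = 1.37).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from collections import defaultdict

import pandas as pd
from scipy import stats

from ._seq import revcomp, to_dna
from .fold import FoldResult, fold_hairpin

WORD_SIZE = 11
MATCH, MISMATCH = 1, -2
XDROP = 10
KARLIN_K = 0.711
KARLIN_LAMBDA = 1.37


@dataclass
class HomologyHit:
    query_id: str
    chrom: str
    strand: str
    start: int       # 0-based half-open, forward-strand coordinates
    end: int
    identity: float
    score: int
    e_value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must precede end")


@dataclass
class PreMiRNACandidate:
    id: str
    chrom: str
    strand: str
    start: int       # 0-based half-open, flank-extended
    end: int
    sequence: str
    structure: str | None = None
    n_pairs: int = 0
    paired_fraction: float = 0.0
    n_hairpin_loops: int = 0
    fold_energy: float = 0.0
    ortholog_id: str | None = None
    source: str = "conserved"
    left_clipped: bool = False
    right_clipped: bool = False
    fold: FoldResult | None = None

    @property
    def accepted(self) -> bool:
        return self.fold is not None and self.fold.verdict


@dataclass
class DistributionTest:
    counts_per_chrom: dict[str, int]
    expected_per_chrom: dict[str, float]
    chi2: float
    df: int
    p_value: float


def _kmer_index(genome: dict[str, str], k: int = WORD_SIZE) -> dict[str, list]:
    index: dict[str, list] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            word = seq[i:i + k]
            if "N" not in word:
                index[word].append((chrom, i))
    return index


def _extend(query: str, target: str, qpos: int, tpos: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of an exact word match.

    Returns (q_start, q_end, score, matches) with q_end exclusive;
    target coordinates follow from the shared diagonal.
    """
    score = best = WORD_SIZE * MATCH
    matches = WORD_SIZE
    # right extension
    q, t = qpos + WORD_SIZE, tpos + WORD_SIZE
    q_end, best_matches_r = q, 0
    run_matches = 0
    while q < len(query) and t < len(target):
        score += MATCH if query[q] == target[t] else MISMATCH
        run_matches += query[q] == target[t]
        q += 1
        t += 1
        if score > best:
            best, q_end, best_matches_r = score, q, run_matches
        elif best - score > XDROP:
            break
    score = best
    # left extension
    q, t = qpos - 1, tpos - 1
    q_start, best_matches_l = qpos, 0
    run_matches = 0
    cur = score
    while q >= 0 and t >= 0:
        cur += MATCH if query[q] == target[t] else MISMATCH
        run_matches += query[q] == target[t]
        if cur > score:
            score, q_start, best_matches_l = cur, q, run_matches
        elif score - cur > XDROP:
            break
        q -= 1
        t -= 1
    matches += best_matches_r + best_matches_l
    return q_start, q_end, score, matches


def e_value(score: int, query_len: int, db_len: int) -> float:
    return KARLIN_K * query_len * db_len * math.exp(-KARLIN_LAMBDA * score)


def homology_search(
    known: dict[str, str],
    genome: dict[str, str],
    e_cutoff: float = 0.001,
) -> list[HomologyHit]:
    """Seeded ungapped search of every known pre-miRNA against both strands.

    Overlapping hits of the same query on the same strand are merged keeping
    the best score; hits with E-value above ``e_cutoff`` are dropped.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    genome = {c: to_dna(s) for c, s in genome.items()}
    db_len = sum(len(s) for s in genome.values())
    index = _kmer_index(genome)
    hits: list[HomologyHit] = []
    for query_id, raw_query in known.items():
        query_fwd = to_dna(raw_query)
        if re.search(r"[^ACGT]", query_fwd):
            import warnings
            warnings.warn(f"query {query_id} contains non-ACGT characters; skipped")
            continue
        for strand, query in (("+", query_fwd), ("-", revcomp(query_fwd))):
            seen_diagonals: set[tuple[str, int]] = set()
            best_by_span: dict[tuple, HomologyHit] = {}
            for qpos in range(len(query) - WORD_SIZE + 1):
                word = query[qpos:qpos + WORD_SIZE]
                for chrom, tpos in index.get(word, ()):
                    diag = (chrom, tpos - qpos)
                    if diag in seen_diagonals:
                        continue
                    seen_diagonals.add(diag)
                    q_start, q_end, score, matches = _extend(
                        query, genome[chrom], qpos, tpos)
                    ev = e_value(score, len(query), db_len)
                    if ev > e_cutoff:
                        continue
                    t_start = tpos - (qpos - q_start)
                    t_end = t_start + (q_end - q_start)
                    hit = HomologyHit(
                        query_id, chrom, strand, t_start, t_end,
                        identity=matches / (q_end - q_start),
                        score=score, e_value=ev)
                    key = (chrom,)
                    merged = False
                    for span, old in list(best_by_span.items()):
                        if span[0] == chrom and not (
                                t_end <= old.start or t_start >= old.end):
                            if score > old.score:
                                best_by_span.pop(span)
                                best_by_span[(chrom, t_start, t_end)] = hit
                            merged = True
                            break
                    if not merged:
                        best_by_span[(chrom, t_start, t_end)] = hit
            hits.extend(best_by_span.values())
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.query_id))
    return hits


def extend_flanks(
    hit: HomologyHit,
    genome: dict[str, str],
    flank: int = 30,
) -> PreMiRNACandidate:
    """Add ~``flank`` bp of genomic context on both sides (clipped at
    chromosome bounds); minus-strand candidates carry the reverse
    complement of the forward-strand slice."""
    chrom_seq = to_dna(genome[hit.chrom])
    start = max(0, hit.start - flank)
    end = min(len(chrom_seq), hit.end + flank)
    seq = chrom_seq[start:end]
    if hit.strand == "-":
        seq = revcomp(seq)
    return PreMiRNACandidate(
        id=f"{hit.query_id}|{hit.chrom}:{start}-{end}({hit.strand})",
        chrom=hit.chrom, strand=hit.strand, start=start, end=end,
        sequence=seq,
        left_clipped=hit.start - flank < 0,
        right_clipped=hit.end + flank > len(chrom_seq),
    )


def fold_candidate(candidate: PreMiRNACandidate, **fold_kwargs) -> PreMiRNACandidate:
    result = fold_hairpin(candidate.sequence, **fold_kwargs)
    candidate.fold = result
    candidate.structure = result.structure
    candidate.n_pairs = result.n_pairs
    candidate.paired_fraction = result.paired_fraction
    candidate.n_hairpin_loops = result.n_hairpin_loops
    candidate.fold_energy = result.fold_energy
    return candidate


_FAMILY_STEMS = {"mir", "let", "lin", "lsy", "bantam"}


def strip_species_prefix(name: str) -> str:
    """Database names carry a 3-4 letter species code ("dre-mir-21");
    family stems like "mir"/"let" are never treated as species codes."""
    m = re.match(r"^([a-z]{3,4})-(.+)$", name)
    if m and m.group(1) not in _FAMILY_STEMS:
        return m.group(2)
    return name


def _best_hits(queries: dict[str, str], targets: dict[str, str]) -> dict[str, str]:
    """query id -> best-scoring target id (ties: lexicographically first)."""
    best: dict[str, tuple[int, str]] = {}
    if not queries or not targets:
        return {}
    hits = homology_search(queries, targets, e_cutoff=10.0)
    for hit in hits:
        cur = best.get(hit.query_id)
        cand = (hit.score, hit.chrom)
        if cur is None or hit.score > cur[0] or \
                (hit.score == cur[0] and hit.chrom < cur[1]):
            best[hit.query_id] = cand
    return {q: t for q, (_s, t) in best.items()}


def reciprocal_annotate(
    candidates: list[PreMiRNACandidate],
    known: dict[str, str],
) -> list[PreMiRNACandidate]:
    """Assign orthologous names by reciprocal best hit against the known set.

    A candidate is named after a known pre-miRNA (species prefix stripped)
    iff each is the other's best-scoring partner.
    """
    cand_seqs = {c.id: c.sequence for c in candidates}
    fwd = _best_hits(cand_seqs, known)
    rev = _best_hits(known, cand_seqs)
    for cand in candidates:
        partner = fwd.get(cand.id)
        if partner is not None and rev.get(partner) == cand.id:
            cand.ortholog_id = strip_species_prefix(partner)
        else:
            cand.ortholog_id = None
    return candidates


def distribution_test(
    counts_per_chrom: dict[str, int],
    chrom_lengths: dict[str, int],
    model: str = "length_weighted",
) -> DistributionTest:
    """Chi-square goodness of fit of per-chromosome hairpin counts against a
    uniform or chromosome-length-proportional expectation."""
    if len(chrom_lengths) < 2:
        raise ValueError("need at least two chromosomes")
    chroms = sorted(chrom_lengths)
    obs = [counts_per_chrom.get(c, 0) for c in chroms]
    total = sum(obs)
    if total < 1:
        raise ValueError("need at least one candidate")
    if model == "uniform":
        exp = [total / len(chroms)] * len(chroms)
    elif model == "length_weighted":
        total_len = sum(chrom_lengths.values())
        if any(chrom_lengths[c] == 0 for c in chroms):
            raise ValueError("zero-length chromosome under length_weighted model")
        exp = [total * chrom_lengths[c] / total_len for c in chroms]
    else:
        raise ValueError(f"unknown model {model!r}")
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    df = len(chroms) - 1
    p = float(stats.chi2.sf(chi2, df))
    return DistributionTest(
        counts_per_chrom=dict(zip(chroms, obs)),
        expected_per_chrom=dict(zip(chroms, exp)),
        chi2=float(chi2), df=df, p_value=p)


def discover(
    known: dict[str, str],
    genome: dict[str, str],
    e_cutoff: float = 0.001,
    flank: int = 30,
    distribution_model: str = "length_weighted",
    **fold_kwargs,
) -> tuple[list[PreMiRNACandidate], DistributionTest | None]:
    """Full discovery pass: search, extend, fold, accept, name, test.

    Returns all accepted candidates (deduplicated by locus) and the
    chromosomal distribution test (None when nothing was accepted).
    """
    hits = homology_search(known, genome, e_cutoff)
    # deduplicate overlapping hits across queries AND strands, keeping the
    # best score (a hairpin locus is near-palindromic, so the reverse
    # strand often also scores; the true strand aligns better)
    hits_by_locus: list[HomologyHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.strand, h.query_id)):
        if any(h.chrom == hit.chrom
               and not (hit.end <= h.start or hit.start >= h.end)
               for h in hits_by_locus):
            continue
        hits_by_locus.append(hit)
    candidates = [fold_candidate(extend_flanks(h, genome, flank), **fold_kwargs)
                  for h in sorted(hits_by_locus,
                                  key=lambda h: (h.chrom, h.start, h.strand))]
    accepted = [c for c in candidates if c.accepted]
    reciprocal_annotate(accepted, known)
    dist = None
    if accepted:
        counts: dict[str, int] = defaultdict(int)
        for cand in accepted:
            counts[cand.chrom] += 1
        dist = distribution_test(
            counts, {c: len(s) for c, s in genome.items()}, distribution_model)
    return accepted, dist


def candidates_to_frame(candidates: list[PreMiRNACandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": c.id, "chrom": c.chrom, "strand": c.strand,
        "start": c.start, "end": c.end, "sequence": c.sequence,
        "structure": c.structure, "n_pairs": c.n_pairs,
        "paired_fraction": round(c.paired_fraction, 4),
        "n_hairpin_loops": c.n_hairpin_loops,
        "fold_energy": c.fold_energy, "ortholog_id": c.ortholog_id,
        "source": c.source,
    } for c in candidates])


def candidates_to_gff3(candidates: list[PreMiRNACandidate]) -> list[dict]:
    return [dict(seqid=c.chrom, source="gonadmir", type="pre_miRNA",
                 start=c.start + 1, end=c.end, strand=c.strand,
                 attributes=f"ID={c.id};ortholog={c.ortholog_id or 'NA'}")
            for c in candidates]
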