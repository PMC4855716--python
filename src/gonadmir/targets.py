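"""miRNA target prediction in 3'UTRs: canonical seed matching plus a
duplex-stability score.

Sites are anchored on perfect Watson-Crick complementarity to the miRNA
seed (positions 2-7) and classified by the canonical taxonomy:

* ``8mer``    - seed match + position-8 match + A opposite position 1
* ``7mer-m8`` - seed match + position-8 match
* ``7mer-A1`` - seed match + A opposite position 1
* ``6mer``    - seed match only

Duplex stability extends pairing from the seed toward the miRNA 3' end
against the upstream UTR context (ungapped walk, G:U wobbles allowed) and
scores pairs as G:C = 3, A:U = 2, G:U = 1, the same weights the hairpin
folder uses; ``delta_g`` is the negated score.  Sites below ``min_score``
(default 14, roughly a strong seed plus some 3' support) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp, to_dna, validate_alphabet
from .fold import pair_weight

MIN_SCORE = 14
MIN_MATURE_LEN, MAX_MATURE_LEN = 19, 25


@dataclass
class UTRRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty UTR for {self.gene_id}")
        validate_alphabet(self.sequence)
        self.sequence = to_dna(self.sequence)


@dataclass
class TargetSite:
    mirna_id: str
    gene_id: str
    utr_start: int    # 0-based: base pairing miRNA position 8 (or 7)
    seed_class: str
    pair_score: int = 0
    delta_g: float = 0.0


@dataclass
class TargetPrediction:
    mirna_id: str
    gene_id: str
    sites: list[TargetSite]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def best_delta_g(self) -> float:
        return min(s.delta_g for s in self.sites)


def seed_match(mirna: str, utr: UTRRecord) -> list[TargetSite]:
    """All canonical seed sites of one miRNA in one UTR (unscored).

    ``utr_start`` is the UTR position pairing miRNA position 8 for 8mer /
    7mer-m8 sites, and the position pairing position 7 otherwise.
    """
    mirna = to_dna(mirna)
    validate_alphabet(mirna)
    if not MIN_MATURE_LEN <= len(mirna) <= MAX_MATURE_LEN:
        raise ValueError(f"mature length {len(mirna)} outside "
                         f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]")
    core = revcomp(mirna[1:7])   # target-sense match for miRNA positions 2-7
    seq = utr.sequence
    sites = []
    pos = seq.find(core)
    while pos >= 0:
        has_m8 = pos > 0 and seq[pos - 1] == revcomp(mirna[7])
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            seed_class, start = "8mer", pos - 1
        elif has_m8:
            seed_class, start = "7mer-m8", pos - 1
        elif has_a1:
            seed_class, start = "7mer-A1", pos
        else:
            seed_class, start = "6mer", pos
        sites.append(TargetSite("", utr.gene_id, start, seed_class))
        pos = seq.find(core, pos + 1)
    return sites


def score_duplex(mirna: str, utr: UTRRecord, site: TargetSite) -> TargetSite:
    """Weighted-pair duplex score for one site.

    Pairing is walked ungapped outward from the seed: miRNA positions 2-7
    are paired by construction; positions 8, 9, ... pair successively more
    5' UTR bases while complementary (G:U allowed), and position 1 pairs the
    opposing base when complementary.  ``delta_g = -pair_score``.
    """
    mirna_rna = to_dna(mirna).replace("T", "U")
    seq_rna = utr.sequence.replace("T", "U")
    # UTR position of the base opposite miRNA position 7 (core 5'-most match
    # sits at core_start; miRNA position p pairs seq[core_start + 6 - (p-1)])
    core_start = site.utr_start + 1 if site.seed_class in ("8mer", "7mer-m8") \
        else site.utr_start

    def w(i: int) -> int:
        utr_pos = core_start + 6 - i
        if not 0 <= utr_pos < len(seq_rna):
            return 0
        return pair_weight(mirna_rna[i], seq_rna[utr_pos])

    score = sum(w(i) for i in range(1, 7))  # the seed core, paired by construction
    for i in range(7, len(mirna_rna)):      # walk toward the miRNA 3' end
        wi = w(i)
        if wi == 0:
            break
        score += wi
    score += w(0)  # miRNA position 1 against the opposing base, if it pairs
    site.pair_score = score
    site.delta_g = -float(score)
    return site


def predict_targets(
    matures: dict[str, str],
    utrs: list[UTRRecord],
    min_score: int = MIN_SCORE,
) -> tuple[list[TargetPrediction], pd.DataFrame]:
    """All (miRNA, gene) pairs with at least one surviving site.

    Returns predictions ordered by (mirna_id, gene_id, utr_start) and a
    per-miRNA raw target count table (genes and sites).
    """
    if not matures or not utrs:
        raise ValueError("matures and utrs must be non-empty")
    predictions: list[TargetPrediction] = []
    raw_counts = []
    for mirna_id in sorted(matures):
        mature = matures[mirna_id]
        n_genes = n_sites = 0
        for utr in sorted(utrs, key=lambda u: u.gene_id):
            sites = [score_duplex(mature, utr, s)
                     for s in seed_match(mature, utr)]
            sites = [s for s in sites if s.pair_score >= min_score]
            if not sites:
                continue
            for s in sites:
                s.mirna_id = mirna_id
            sites.sort(key=lambda s: s.utr_start)
            predictions.append(TargetPrediction(mirna_id, utr.gene_id, sites))
            n_genes += 1
            n_sites += len(sites)
        raw_counts.append((mirna_id, n_genes, n_sites))
    counts = pd.DataFrame(raw_counts,
                          columns=["mirna_id", "n_target_genes", "n_sites"])
    return predictions, counts


def utrs_from_fasta(path: str) -> list[UTRRecord]:
    from . import io

    return [UTRRecord(gene_id, seq)
            for gene_id, seq in io.read_fasta(path).items()]


def utrs_from_gff3(gff3_path: str, genome: dict[str, str]) -> list[UTRRecord]:
    """Extract three_prime_UTR sequences (GFF3 is 1-based inclusive)."""
    from . import io

    df = io.read_gff3(gff3_path)
    utr_rows = df[df["type"] == "three_prime_UTR"]
    records = []
    for _, row in utr_rows.iterrows():
        attrs = io.parse_gff3_attributes(row["attributes"])
        gene_id = attrs.get("Parent") or attrs.get("ID") or "unknown"
        seq = genome[row["seqid"]][row["start"] - 1:row["end"]]
        if row["strand"] == "-":
            seq = revcomp(seq)
        records.append(UTRRecord(gene_id, seq))
    return records


def predictions_to_frame(predictions: list[TargetPrediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna_id": p.mirna_id, "gene_id": p.gene_id, "n_sites": p.n_sites,
        "site_offsets": ";".join(str(s.utr_start) for s in p.sites),
        "seed_classes": ";".join(s.seed_class for s in p.sites),
        "pair_scores": ";".join(str(s.pair_score) for s in p.sites),
        "best_delta_g": p.best_delta_g,
    } for p in predictions])
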