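"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GFF3 is written directly (the feature set
is tiny: gene / three_prime_UTR / pre_miRNA records, 1-based inclusive
coordinates per the GFF3 spec); tables are pandas TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        path, "fasta")


def iter_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples; malformed records raise."""
    with open(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as handle:
        for title, seq, qual in reads:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


GFF3_COLUMNS = ["seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes"]


def write_gff3(features: Iterable[dict], path: str) -> None:
    """Write GFF3 from dicts carrying the nine standard columns.

    ``start``/``end`` must already be 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write("\t".join(str(feat.get(c, ".")) for c in GFF3_COLUMNS) + "\n")


def read_gff3(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", names=GFF3_COLUMNS,
                     dtype={"start": int, "end": int})
    return df


def parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            key, value = field.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
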