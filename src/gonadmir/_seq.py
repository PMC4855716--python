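"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as T; output uses DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_alphabet(seq: str, extra: str = "") -> None:
    allowed = set("ACGTU" + extra)
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
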