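"""RNA secondary-structure prediction for hairpin (pre-miRNA) validation.

Two complementary views of a candidate precursor are computed:

* A weighted maximum-pairing dynamic program (Nussinov-style) scores every
  admissible nested structure as the sum of its base-pair weights
  (G:C = 3, A:U = 2, G:U = 1; minimum hairpin loop of 3 unpaired nt) and
  recovers one optimum by traceback into a dot-bracket string.  The negated
  weighted-pair sum serves as a stability score ("fold energy", arbitrary
  units; more negative = more stable).

* A gapped stem alignment — a local alignment of the sequence against its
  own reverse complement with mismatch and gap penalties — locates the
  substantive helices.  Because the pairing model above carries no loop or
  bulge penalties, random sequence happily closes dozens of scattered pairs,
  so the topology of the maximum-pairing structure alone cannot distinguish
  a genuine stem-loop from background; a contiguous, lightly interrupted
  helix can.  ``n_hairpin_loops`` counts disjoint stems whose alignment
  score reaches ``min_stem_score``.

A candidate is accepted (``verdict``) when exactly one substantive stem
exists and the structure meets the pairing thresholds: at least ``min_pairs``
base pairs and at least half of all nucleotides paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import to_rna, validate_alphabet

#: weight of each admissible pair; everything else cannot pair
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a pair

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 500

STEM_MISMATCH = -4.0
STEM_GAP = -8.0


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def _weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(n):
            w[i, j] = pair_weight(seq[i], seq[j])
    return w


def _fill(w: np.ndarray) -> np.ndarray:
    """M[i, j] = best weighted-pair score of subsequence [i, j) (half-open)."""
    n = w.shape[0]
    m = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            # last base (index j-1) unpaired, or paired with some k
            best = m[i, j - 1]
            ks_hi = j - 1 - (MIN_LOOP + 1)  # max k that may pair j-1
            if ks_hi >= i:
                vals = m[i, i:ks_hi + 1] + m[i + 1:ks_hi + 2, j - 1] \
                    + w[i:ks_hi + 1, j - 1]
                v = vals.max()
                if v > best:
                    best = v
            m[i, j] = best
    return m


def _traceback(m: np.ndarray, w: np.ndarray) -> list[tuple[int, int]]:
    """Recover one optimal structure as a list of (i, j) pairs (0-based).

    Among co-optimal decompositions the outermost (smallest k) pairing is
    preferred, which favours long-range nesting over fragmenting the
    structure into additional hairpins.
    """
    pairs: list[tuple[int, int]] = []
    stack = [(0, m.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 2 or m[i, j] == 0:
            continue
        target = m[i, j]
        found = False
        for k in range(i, j - 1 - MIN_LOOP):
            wk = w[k, j - 1]
            if wk and m[i, k] + m[k + 1, j - 1] + wk == target:
                pairs.append((k, j - 1))
                stack.append((i, k))
                stack.append((k + 1, j - 1))
                found = True
                break
        if not found:
            stack.append((i, j - 1))
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def count_terminal_loops(pairs: list[tuple[int, int]]) -> int:
    """Number of hairpin (terminal) loops in a nested pair list."""
    n_loops = 0
    for i, j in pairs:
        if not any(i < p < q < j for p, q in pairs if (p, q) != (i, j)):
            n_loops += 1
    return n_loops


@dataclass
class Stem:
    """A gapped helix: 5' arm [arm5_start, arm5_end) pairs 3' arm (reversed)."""

    arm5_start: int
    arm5_end: int
    arm3_start: int
    arm3_end: int
    score: float


def _stem_alignment(seq: str, blocked: np.ndarray) -> Stem | None:
    """Best local alignment of ``seq`` against its own reverse complement.

    Cell (i, k) aligns seq[i] with revcomp(seq)[k], i.e. proposes the pair
    (i, n-1-k); only cells with i + k <= n - 2 - MIN_LOOP are admissible so
    a hairpin loop always separates the two arms.  Positions flagged in
    ``blocked`` cannot pair (used to mask out stems already found).
    """
    n = len(seq)
    sub = np.full((n, n), STEM_MISMATCH, dtype=np.float64)
    for i in range(n):
        for k in range(n):
            # cell (i, k) proposes the pair (seq[i], seq[n-1-k])
            w = pair_weight(seq[i], seq[n - 1 - k])
            if w and not blocked[i] and not blocked[n - 1 - k]:
                sub[i, k] = w
    # forbid arm overlap / too-small loop
    ii, kk = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    admissible = (ii + kk) <= (n - 2 - MIN_LOOP)

    h = np.zeros((n + 1, n + 1), dtype=np.float64)
    idx = np.arange(n)
    for i in range(1, n + 1):
        diag = h[i - 1, :-1] + sub[i - 1]
        up = h[i - 1, 1:] + STEM_GAP
        row = np.maximum(0.0, np.maximum(diag, up))
        row[~admissible[i - 1]] = 0.0
        # close left gaps with a prefix-max scan (linear gap penalty)
        scan = np.maximum.accumulate(row - STEM_GAP * idx)
        row = np.maximum(row, scan + STEM_GAP * idx)
        row[~admissible[i - 1]] = 0.0
        h[i, 1:] = row
    best = float(h.max())
    if best <= 0:
        return None
    i, k = np.unravel_index(int(h.argmax()), h.shape)
    # traceback to the start of the alignment
    i2, k2 = i, k
    while h[i, k] > 0:
        v = h[i, k]
        if i > 0 and k > 0 and np.isclose(v, h[i - 1, k - 1] + sub[i - 1, k - 1]):
            i, k = i - 1, k - 1
        elif i > 0 and np.isclose(v, h[i - 1, k] + STEM_GAP):
            i -= 1
        elif k > 0 and np.isclose(v, h[i, k - 1] + STEM_GAP):
            k -= 1
        else:
            break
    # seq arm: [i, i2); revcomp arm [k, k2) maps to seq [n-k2, n-k)
    return Stem(i, i2, len(seq) - k2, len(seq) - k, best)


def find_stems(sequence: str, min_stem_score: float, max_stems: int = 4) -> list[Stem]:
    """Iteratively locate disjoint helices scoring at least ``min_stem_score``."""
    seq = to_rna(sequence)
    blocked = np.zeros(len(seq), dtype=bool)
    stems: list[Stem] = []
    for _ in range(max_stems):
        stem = _stem_alignment(seq, blocked)
        if stem is None or stem.score < min_stem_score:
            break
        stems.append(stem)
        blocked[stem.arm5_start:stem.arm5_end] = True
        blocked[stem.arm3_start:stem.arm3_end] = True
    return stems


@dataclass
class FoldResult:
    """Optimal structure of one sequence plus hairpin acceptance verdict."""

    sequence: str
    structure: str
    n_pairs: int
    fold_energy: float          # -(weighted pair sum); lower = more stable
    n_hairpin_loops: int        # substantive stem-loops (strong helices)
    n_terminal_loops: int       # terminal loops of the max-pairing structure
    paired_fraction: float
    verdict: bool
    pairs: list[tuple[int, int]] = field(repr=False, default_factory=list)
    main_stem: Stem | None = None

    @property
    def loop_span(self) -> tuple[int, int] | None:
        """[start, end) of the terminal loop of the main stem, if any."""
        if self.main_stem is None:
            return None
        return (self.main_stem.arm5_end, self.main_stem.arm3_start)


def fold_hairpin(
    sequence: str,
    min_pairs: int = 18,
    min_paired_fraction: float = 0.5,
    min_stem_score: float = 32.0,
) -> FoldResult:
    """Fold one sequence and judge whether it is a proper stem-loop.

    Parameters
    ----------
    sequence
        RNA or DNA string, length ``MIN_FOLD_LEN``–``MAX_FOLD_LEN``.
    min_pairs
        Minimum base pairs in the optimal structure for acceptance.
    min_paired_fraction
        Minimum fraction ``2 * n_pairs / len`` of paired nucleotides.
    min_stem_score
        Minimum gapped-stem alignment score for a helix to count as a
        substantive hairpin (roughly a dozen contiguous pairs).

    Returns
    -------
    FoldResult with ``verdict`` true iff exactly one substantive stem-loop
    exists and the pairing thresholds are met.
    """
    seq = to_rna(sequence)
    validate_alphabet(seq)
    n = len(seq)
    if not MIN_FOLD_LEN <= n <= MAX_FOLD_LEN:
        raise ValueError(
            f"sequence length {n} outside foldable range "
            f"[{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    w = _weight_matrix(seq)
    m = _fill(w)
    pairs = _traceback(m, w)
    structure = pairs_to_dotbracket(pairs, n)
    score = int(m[0, n])
    stems = find_stems(seq, min_stem_score)
    n_pairs = len(pairs)
    paired_fraction = 2.0 * n_pairs / n
    verdict = (
        len(stems) == 1
        and n_pairs >= min_pairs
        and paired_fraction >= min_paired_fraction
    )
    return FoldResult(
        sequence=seq,
        structure=structure,
        n_pairs=n_pairs,
        fold_energy=-float(score),
        n_hairpin_loops=len(stems),
        n_terminal_loops=count_terminal_loops(pairs),
        paired_fraction=paired_fraction,
        verdict=verdict,
        pairs=pairs,
        main_stem=stems[0] if stems else None,
    )
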