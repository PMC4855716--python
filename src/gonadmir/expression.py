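"""TPM normalization and sex-biased differential-expression calling.

Two pooled libraries without biological replicates are compared per miRNA
with a two-sided Fisher's exact test on the 2x2 table
[(count_a, clean_a - count_a), (count_b, clean_b - count_b)], the exact
analogue of asking whether a tag is over-represented in one library.  A
miRNA is called sex-biased when |log2 ratio| >= 1 (on TPM + 0.01 pseudocount)
and p < 0.01; detection in only one library is tracked separately as
sex-exclusivity, flagged high-confidence above 15 reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT_TPM = 0.01
LOG2_RATIO_MIN = 1.0
P_CUTOFF = 0.01
MIN_EXCLUSIVE_READS = 15

#: relative tolerance when selecting tables "as or more extreme" than the
#: observed one (minimum-likelihood rule), mirroring common exact-test usage
_REL_EPS = 1e-7


@dataclass
class MiRNAExpression:
    mirna_id: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float


@dataclass
class DECall:
    mirna_id: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    log2_ratio: float
    p_value: float
    q_value: float
    status: str          # a_up | b_up | not_de | a_exclusive | b_exclusive
    ratio_class: str     # gt2 | mid | le_half
    high_confidence_exclusive: bool = False


def tpm_normalize(
    counts: dict[str, tuple[int, int]],
    clean_a: int,
    clean_b: int,
) -> list[MiRNAExpression]:
    """TPM = count / total clean reads * 1e6, exactly, no pseudocount."""
    if clean_a <= 0 or clean_b <= 0:
        raise ValueError("clean read totals must be positive")
    out = []
    for mirna_id in sorted(counts):
        ca, cb = counts[mirna_id]
        if ca < 0 or cb < 0:
            raise ValueError("negative counts")
        out.append(MiRNAExpression(
            mirna_id, ca, cb,
            tpm_a=1e6 * ca / clean_a,
            tpm_b=1e6 * cb / clean_b))
    return out


def de_test(count_a: int, count_b: int, clean_a: int, clean_b: int) -> float:
    """Two-sided Fisher's exact test, minimum-likelihood rule.

    Computed in log space by summing hypergeometric point probabilities of
    all tables (with the observed margins) no more likely than the observed
    one, so deeply sequenced libraries do not underflow.
    """
    if min(count_a, count_b) < 0:
        raise ValueError("negative counts")
    if count_a > clean_a or count_b > clean_b:
        raise ValueError("count exceeds clean total")
    n = count_a + count_b
    if n == 0:
        return 1.0
    total = clean_a + clean_b
    support = np.arange(max(0, n - clean_b), min(n, clean_a) + 1)
    logpmf = stats.hypergeom.logpmf(support, total, clean_a, n)
    observed = logpmf[np.searchsorted(support, count_a)]
    keep = logpmf <= observed + np.log1p(_REL_EPS)
    if keep.all():
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def _ratio_class(ratio: float) -> str:
    if ratio > 2:
        return "gt2"
    if ratio <= 0.5:
        return "le_half"
    return "mid"


def call_de(
    expressions: list[MiRNAExpression],
    clean_a: int,
    clean_b: int,
    min_exclusive_reads: int = MIN_EXCLUSIVE_READS,
    log2_ratio_min: float = LOG2_RATIO_MIN,
    p_cutoff: float = P_CUTOFF,
) -> list[DECall]:
    """Classify each miRNA as sex-biased, sex-exclusive or unchanged.

    A pseudocount of 0.01 TPM enters the expression ratio only when one
    library has zero counts (keeping exclusive ratios finite); exclusivity
    itself stays count-based.  Benjamini-Hochberg q-values are reported
    alongside the raw p-values used for calling.
    """
    pvals = [de_test(e.count_a, e.count_b, clean_a, clean_b)
             for e in expressions]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    calls = []
    for expr, p, q in zip(expressions, pvals, qvals):
        if expr.count_a > 0 and expr.count_b > 0:
            ratio = expr.tpm_a / expr.tpm_b
        else:  # pseudocount keeps exclusive ratios finite
            ratio = (expr.tpm_a + PSEUDOCOUNT_TPM) / (expr.tpm_b + PSEUDOCOUNT_TPM)
        log2_ratio = float(np.log2(ratio))
        high_conf = False
        if expr.count_a >= 1 and expr.count_b == 0:
            status = "a_exclusive"
            high_conf = expr.count_a > min_exclusive_reads
        elif expr.count_b >= 1 and expr.count_a == 0:
            status = "b_exclusive"
            high_conf = expr.count_b > min_exclusive_reads
        elif log2_ratio >= log2_ratio_min and p < p_cutoff:
            status = "a_up"
        elif log2_ratio <= -log2_ratio_min and p < p_cutoff:
            status = "b_up"
        else:
            status = "not_de"
        calls.append(DECall(
            mirna_id=expr.mirna_id,
            count_a=expr.count_a, count_b=expr.count_b,
            tpm_a=expr.tpm_a, tpm_b=expr.tpm_b,
            log2_ratio=log2_ratio, p_value=p, q_value=float(q),
            status=status, ratio_class=_ratio_class(ratio),
            high_confidence_exclusive=high_conf))
    n_a_up = sum(c.status == "a_up" for c in calls)
    n_b_up = sum(c.status == "b_up" for c in calls)
    n_de = sum(c.status in ("a_up", "b_up") for c in calls)
    assert n_a_up + n_b_up == n_de, "DE set size identity violated"
    return calls


def calls_to_frame(calls: list[DECall]):
    import pandas as pd

    return pd.DataFrame([{
        "mirna_id": c.mirna_id, "count_a": c.count_a, "count_b": c.count_b,
        "tpm_a": round(c.tpm_a, 4), "tpm_b": round(c.tpm_b, 4),
        "log2_ratio": round(c.log2_ratio, 4),
        "p_value": c.p_value, "q_value": c.q_value,
        "status": c.status, "ratio_class": c.ratio_class,
        "high_confidence_exclusive": c.high_confidence_exclusive,
    } for c in calls])
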