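"""miRNA-mRNA integration: expression filtering, per-gene sex bias, and
inverse-expression network construction.

Genes are filtered at FPKM 0.5 with one carve-out: a gene above 0.5 in one
sex and exactly zero in the other is kept as an "undefined bias" favoring
the expressed sex.  Sex-biased miRNAs are then intersected with their
predicted targets, keeping only pairs where the target's bias opposes the
miRNA's (a miRNA up in females may only regulate male-up genes, and vice
versa); sex-exclusive miRNAs participate as their sex's "up".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .expression import DECall
from .targets import TargetPrediction

FPKM_MIN = 0.5
GENE_FOLD_THRESHOLD = 2.0

# library a = female (XX), library b = male (XY)
_MIRNA_SEX = {"a_up": "female", "a_exclusive": "female",
              "b_up": "male", "b_exclusive": "male"}
_GENE_UP_SEX = {"female_up": "female", "undefined_bias_female": "female",
                "male_up": "male", "undefined_bias_male": "male"}


@dataclass
class GeneExpression:
    gene_id: str
    fpkm_female: float
    fpkm_male: float
    bias: str


@dataclass
class RegulatoryEdge:
    mirna_id: str
    gene_id: str
    mirna_bias: str
    gene_bias: str
    n_sites: int
    best_delta_g: float


@dataclass
class NetworkSummary:
    per_mirna_raw: dict[str, int]
    per_mirna_integrated: dict[str, int]
    mean_raw: float
    mean_integrated: float
    reduction_factor: float   # inf when integration keeps nothing


def classify_gene_bias(
    fpkm_female: float,
    fpkm_male: float,
    fold_threshold: float = GENE_FOLD_THRESHOLD,
    fpkm_min: float = FPKM_MIN,
) -> str:
    """Bias label for one gene from its two FPKM values.

    Rule order: the undefined-bias carve-out (> fpkm_min in one sex, zero in
    the other) precedes the joint expression filter (min < fpkm_min ->
    excluded), then a ``fold_threshold`` ratio decides the direction.
    """
    if fpkm_female < 0 or fpkm_male < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_female > fpkm_min and fpkm_male == 0:
        return "undefined_bias_female"
    if fpkm_male > fpkm_min and fpkm_female == 0:
        return "undefined_bias_male"
    if min(fpkm_female, fpkm_male) < fpkm_min:
        return "excluded"
    if fpkm_female / fpkm_male >= fold_threshold:
        return "female_up"
    if fpkm_male / fpkm_female >= fold_threshold:
        return "male_up"
    return "unbiased"


def classify_gene_table(fpkm: pd.DataFrame, **kwargs) -> list[GeneExpression]:
    return [GeneExpression(row.gene_id, row.fpkm_female, row.fpkm_male,
                           classify_gene_bias(row.fpkm_female, row.fpkm_male,
                                              **kwargs))
            for row in fpkm.itertuples(index=False)]


def integrate(
    de_calls: list[DECall],
    predictions: list[TargetPrediction],
    genes: list[GeneExpression],
) -> list[RegulatoryEdge]:
    """Emit an edge for every predicted (miRNA, target) pair whose expression
    biases point to opposite sexes; same-direction pairs are dropped."""
    import warnings

    gene_bias = {g.gene_id: g.bias for g in genes}
    mirna_sex = {c.mirna_id: _MIRNA_SEX[c.status]
                 for c in de_calls if c.status in _MIRNA_SEX}
    mirna_status = {c.mirna_id: c.status for c in de_calls}
    edges = []
    for pred in predictions:
        sex = mirna_sex.get(pred.mirna_id)
        if sex is None:
            continue
        if pred.gene_id not in gene_bias:
            warnings.warn(f"prediction references unknown gene {pred.gene_id}; skipped")
            continue
        g_bias = gene_bias[pred.gene_id]
        gene_up = _GENE_UP_SEX.get(g_bias)
        if gene_up is None or gene_up == sex:
            continue
        edges.append(RegulatoryEdge(
            mirna_id=pred.mirna_id, gene_id=pred.gene_id,
            mirna_bias=mirna_status[pred.mirna_id], gene_bias=g_bias,
            n_sites=pred.n_sites, best_delta_g=pred.best_delta_g))
    edges.sort(key=lambda e: (e.mirna_id, e.gene_id))
    return edges


def summarize_network(
    predictions: list[TargetPrediction],
    edges: list[RegulatoryEdge],
    mirna_ids: list[str] | None = None,
) -> NetworkSummary:
    """Per-miRNA target counts before/after integration and the fold by
    which integration shrinks the predicted network.

    ``mirna_ids`` restricts the summary (typically to the sex-biased
    miRNAs that were eligible for integration); defaults to every miRNA
    appearing in an edge.
    """
    raw: dict[str, int] = {}
    for pred in predictions:
        raw[pred.mirna_id] = raw.get(pred.mirna_id, 0) + 1
    integrated: dict[str, int] = {}
    for edge in edges:
        integrated[edge.mirna_id] = integrated.get(edge.mirna_id, 0) + 1
    if mirna_ids is None:
        mirna_ids = sorted(integrated)
    per_raw = {m: raw.get(m, 0) for m in mirna_ids}
    per_int = {m: integrated.get(m, 0) for m in mirna_ids}
    mean_raw = sum(per_raw.values()) / len(mirna_ids) if mirna_ids else 0.0
    mean_int = sum(per_int.values()) / len(mirna_ids) if mirna_ids else 0.0
    factor = mean_raw / mean_int if mean_int > 0 else math.inf
    return NetworkSummary(per_raw, per_int, mean_raw, mean_int, factor)


def multi_target_report(edges: list[RegulatoryEdge]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNAs regulating >= 2 genes, and genes regulated by >= 2 miRNAs."""
    df = edges_to_frame(edges)
    if df.empty:
        empty = pd.DataFrame(columns=["id", "n", "partners"])
        return empty, empty.copy()
    by_mirna = df.groupby("mirna_id")["gene_id"].agg(["count", lambda s: ";".join(sorted(s))])
    by_mirna.columns = ["n", "partners"]
    by_gene = df.groupby("gene_id")["mirna_id"].agg(["count", lambda s: ";".join(sorted(s))])
    by_gene.columns = ["n", "partners"]
    multi_mirna = by_mirna[by_mirna["n"] >= 2].reset_index().rename(
        columns={"mirna_id": "id"})
    multi_gene = by_gene[by_gene["n"] >= 2].reset_index().rename(
        columns={"gene_id": "id"})
    return multi_mirna, multi_gene


def edges_to_frame(edges: list[RegulatoryEdge]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna_id": e.mirna_id, "gene_id": e.gene_id,
        "mirna_bias": e.mirna_bias, "gene_bias": e.gene_bias,
        "n_sites": e.n_sites, "best_delta_g": e.best_delta_g,
    } for e in edges], columns=["mirna_id", "gene_id", "mirna_bias",
                                "gene_bias", "n_sites", "best_delta_g"])


def genes_to_frame(genes: list[GeneExpression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": g.gene_id, "fpkm_female": g.fpkm_female,
        "fpkm_male": g.fpkm_male, "bias": g.bias,
    } for g in genes])
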