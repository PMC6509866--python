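"""Differential expression / methylation / miRNA screening and the diff-gene union.

Expression and miRNA matrices (log2 scale) are screened with a two-sided
Welch t-test per gene plus a log2 fold change computed as the difference
of class means; p-values are Benjamini-Hochberg adjusted and a gene is
selected when ``|log2FC| >= logfc_cut`` and ``FDR <= fdr_cut``.
Methylation beta matrices are screened on the raw t-test p-value and the
mean beta difference (``p <= p_cut`` and ``|diff_mean| >= diffmean_cut``).
Targets of differential miRNAs qualify when their in-degree from
differential miRNAs exceeds a cut (strictly).  A gene differential in any
of the three channels is a diff-gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, SampleLabels, TypedEdgeList

__all__ = [
    "DiffGeneSet",
    "bh_adjust",
    "dea_expression",
    "dea_methylation",
    "mirna_target_genes",
    "union_diff_genes",
]

#: Provenance channel names.
DEG, DMET, MIRNA_TARGET = "DEG", "Dmet", "miRNA-target"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-equivariant; output clipped to <= 1 and monotone in the ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_by_class(
    matrix: ExpressionMatrix, labels: SampleLabels
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene Welch t-test and class mean difference (tumor - normal).

    A gene with zero variance in both classes has an undefined statistic;
    its p is set to 1 and it is flagged.
    """
    labels = labels.aligned_to(matrix)
    labels.require_both_classes()
    if labels.n_positive < 2 or labels.n_negative < 2:
        raise ValueError("need at least 2 samples per class")
    tum = matrix.values[:, labels.y == 1]
    nor = matrix.values[:, labels.y == 0]
    delta = tum.mean(axis=1) - nor.mean(axis=1)
    degenerate = (tum.var(axis=1) == 0) & (nor.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate rows handled below
        t, p = stats.ttest_ind(tum, nor, axis=1, equal_var=False)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return np.asarray(t), np.asarray(p), delta, degenerate


def dea_expression(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    logfc_cut: float = 1.0,
    fdr_cut: float = 0.01,
) -> pd.DataFrame:
    """Differential expression table on a log2-scale matrix.

    Returns a frame indexed by gene with columns ``log2_fc``, ``t_stat``,
    ``p_value``, ``fdr``, ``degenerate`` and ``selected``; selection uses
    inclusive thresholds (``|log2FC| >= logfc_cut`` and ``fdr <= fdr_cut``).
    """
    t, p, delta, degenerate = _welch_by_class(matrix, labels)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2_fc": delta,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "degenerate": degenerate,
        },
        index=pd.Index(matrix.gene_ids, name="feature_id"),
    )
    out["selected"] = (np.abs(out["log2_fc"]) >= logfc_cut) & (out["fdr"] <= fdr_cut)
    return out


def dea_methylation(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    p_cut: float = 0.01,
    diffmean_cut: float = 0.35,
) -> pd.DataFrame:
    """Differential methylation table on a beta-value matrix in [0, 1].

    Selection is on the raw t-test p (``p <= p_cut``) and the mean beta
    difference (``|diff_mean| >= diffmean_cut``), both inclusive.
    """
    if np.any(matrix.values < 0) or np.any(matrix.values > 1):
        raise ValueError("methylation beta values must lie in [0, 1]")
    t, p, delta, degenerate = _welch_by_class(matrix, labels)
    out = pd.DataFrame(
        {
            "diff_mean": delta,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "degenerate": degenerate,
        },
        index=pd.Index(matrix.gene_ids, name="feature_id"),
    )
    out["selected"] = (np.abs(out["diff_mean"]) >= diffmean_cut) & (out["p_value"] <= p_cut)
    return out


def mirna_target_genes(
    demirnas: set[str], target_edges: TypedEdgeList, degree_cut: int = 2
) -> set[str]:
    """Target genes regulated by strictly more than ``degree_cut`` differential miRNAs.

    Only ``mirna_target`` edges whose miRNA endpoint is in ``demirnas``
    contribute to a gene's in-degree.
    """
    if not demirnas:
        return set()
    counts: dict[str, int] = {}
    for mirna, gene, etype in target_edges.of_type("mirna_target"):
        if mirna in demirnas:
            counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c > degree_cut}


@dataclass(frozen=True)
class DiffGeneSet:
    """The union of the three differential channels with per-gene provenance."""

    degs: frozenset[str]
    dmet_genes: frozenset[str]
    demirna_target_genes: frozenset[str]

    @property
    def diff_genes(self) -> frozenset[str]:
        return self.degs | self.dmet_genes | self.demirna_target_genes

    def provenance(self, gene: str) -> frozenset[str]:
        out = set()
        if gene in self.degs:
            out.add(DEG)
        if gene in self.dmet_genes:
            out.add(DMET)
        if gene in self.demirna_target_genes:
            out.add(MIRNA_TARGET)
        return frozenset(out)

    def intersection_counts(self) -> dict[str, int]:
        """Sizes of the channel sets and all their intersections (upset-style)."""
        a, b, c = self.degs, self.dmet_genes, self.demirna_target_genes
        return {
            "DEG": len(a),
            "Dmet": len(b),
            "miRNA-target": len(c),
            "DEG&Dmet": len(a & b),
            "DEG&miRNA-target": len(a & c),
            "Dmet&miRNA-target": len(b & c),
            "DEG&Dmet&miRNA-target": len(a & b & c),
            "union": len(a | b | c),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "provenance": ",".join(sorted(self.provenance(g)))}
            for g in sorted(self.diff_genes)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "provenance"])


def union_diff_genes(
    degs: set[str], dmet_genes: set[str], demirna_target_genes: set[str]
) -> DiffGeneSet:
    """Combine the three differential channels into the diff-gene set."""
    return DiffGeneSet(
        degs=frozenset(degs),
        dmet_genes=frozenset(dmet_genes),
        demirna_target_genes=frozenset(demirna_target_genes),
    )
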