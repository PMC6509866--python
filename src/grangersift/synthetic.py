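"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generators emulate the pipeline's real inputs at desk scale: a
two-class log2 expression matrix with planted differential genes, a
methylation beta matrix with planted hyper-methylated genes, a miRNA
matrix plus a random miRNA->target edge list, a typed gene-gene
interaction edge list, and a VAR(1) time series with planted directed
couplings.  Every generator is a pure function of its spec (including
the seed), and each returns the planted truth alongside the data.

The default spec is the package's standard study condition: 40 genes,
60 tumor / 60 normal samples, 150 time points, three strongly
discriminative genes (2.5 sd class separation) that are also the sources
of the planted causal edges, and a band of moderately differential genes
around them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    ExpressionMatrix,
    SampleLabels,
    TimeSeriesMatrix,
    TypedEdgeList,
    UNDIRECTED_TYPES,
    canonical_edge,
)

__all__ = [
    "SyntheticSpec",
    "default_spec",
    "simulate_expression",
    "simulate_methylation",
    "simulate_mirna",
    "simulate_var_timeseries",
    "simulate_interactions",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a synthetic study.

    Effect sizes: ``planted_deg_effects`` are additive log2 shifts in the
    tumor class; ``planted_discriminative`` separations are in units of
    ``noise_sd``; ``planted_dmet_effects`` are beta-value shifts;
    ``planted_causal_edges`` maps directed gene pairs to VAR coupling
    coefficients (the coupling matrix must stay stable, spectral
    radius < 1).
    """

    n_genes: int = 40
    n_tumor: int = 60
    n_normal: int = 60
    n_timepoints: int = 150
    planted_deg_effects: dict[str, float] = field(default_factory=dict)
    planted_discriminative: dict[str, float] = field(default_factory=dict)
    planted_dmet_effects: dict[str, float] = field(default_factory=dict)
    planted_causal_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    n_mirnas: int = 30
    planted_demirna_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    base_mean: float = 8.0
    var_self_coeff: float = 0.5
    seed: int = 0

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i:03d}" for i in range(self.n_genes))

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(f"mir-{i:03d}" for i in range(self.n_mirnas))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"T{i:03d}" for i in range(self.n_tumor)) + tuple(
            f"N{i:03d}" for i in range(self.n_normal)
        )

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        planted = (
            set(self.planted_deg_effects)
            | set(self.planted_discriminative)
            | set(self.planted_dmet_effects)
            | {g for e in self.planted_causal_edges for g in e}
        )
        stray = planted - universe
        if stray:
            raise ValueError(f"planted genes outside the gene universe: {sorted(stray)}")
        if set(self.planted_demirna_effects) - set(self.mirna_ids):
            raise ValueError("planted miRNAs outside the miRNA universe")
        radius = np.max(np.abs(np.linalg.eigvals(self.coupling_matrix())))
        if radius >= 1:
            raise ValueError(f"unstable VAR coupling matrix (spectral radius {radius:.3f})")

    def coupling_matrix(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        A = np.eye(self.n_genes) * self.var_self_coeff
        for (src, dst), coeff in self.planted_causal_edges.items():
            A[idx[dst], idx[src]] = coeff
        return A


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The standard 40-gene study condition with three planted markers.

    Exactly three genes carry discriminative signal (2.5 sd tumor/normal
    separation); they double as the causal sources, each driving two
    target genes.  The targets are differential through the methylation
    channel only, so they enter the diff-gene network without carrying
    classifier signal — mirroring regulated genes whose expression change
    is not itself diagnostic.  Two further moderate DEGs keep the
    expression screen non-trivial.
    """
    genes = [f"G{i:03d}" for i in range(40)]
    sources = genes[:3]
    targets = genes[3:9]
    causal = {}
    for i, s in enumerate(sources):
        causal[(s, targets[2 * i])] = 0.7
        causal[(s, targets[2 * i + 1])] = 0.7
    return SyntheticSpec(
        planted_deg_effects={genes[9]: 1.2, genes[10]: 1.2},
        planted_discriminative={g: 2.5 for g in sources},
        planted_dmet_effects={g: 0.5 for g in targets},
        planted_demirna_effects={f"mir-{i:03d}": 2.0 for i in range(5)},
        planted_causal_edges=causal,
        seed=seed,
    )


def _labels(spec: SyntheticSpec) -> SampleLabels:
    y = np.r_[np.ones(spec.n_tumor, dtype=int), np.zeros(spec.n_normal, dtype=int)]
    return SampleLabels(sample_ids=spec.sample_ids, y=y)


def simulate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleLabels, dict]:
    """Two-class log2 expression with planted tumor shifts.

    Planted differential genes are shifted by their log2 effect; planted
    discriminative genes by ``separation * noise_sd``.  The truth record
    lists both planted sets.
    """
    rng = np.random.default_rng(spec.seed)
    vals = spec.base_mean + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_tumor + spec.n_normal)
    )
    idx = {g: i for i, g in enumerate(spec.gene_ids)}
    for g, eff in spec.planted_deg_effects.items():
        vals[idx[g], : spec.n_tumor] += eff
    for g, sep in spec.planted_discriminative.items():
        vals[idx[g], : spec.n_tumor] += sep * spec.noise_sd
    matrix = ExpressionMatrix(
        gene_ids=spec.gene_ids, sample_ids=spec.sample_ids, values=vals
    )
    truth = {
        "planted_degs": sorted(spec.planted_deg_effects),
        "planted_discriminative": sorted(spec.planted_discriminative),
    }
    return matrix, _labels(spec), truth


def simulate_methylation(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleLabels, dict]:
    """Beta-value matrix in [0, 1]; planted genes hyper-methylated in tumors."""
    rng = np.random.default_rng(spec.seed + 1)
    vals = 0.3 + 0.05 * rng.standard_normal((spec.n_genes, spec.n_tumor + spec.n_normal))
    idx = {g: i for i, g in enumerate(spec.gene_ids)}
    for g, eff in spec.planted_dmet_effects.items():
        vals[idx[g], : spec.n_tumor] += eff
    vals = np.clip(vals, 0.001, 0.999)
    matrix = ExpressionMatrix(
        gene_ids=spec.gene_ids, sample_ids=spec.sample_ids, values=vals
    )
    return matrix, _labels(spec), {"planted_dmet_genes": sorted(spec.planted_dmet_effects)}


def simulate_mirna(
    spec: SyntheticSpec, targets_per_mirna: int = 8
) -> tuple[ExpressionMatrix, SampleLabels, TypedEdgeList, dict]:
    """miRNA log2 matrix plus a random miRNA->target edge list.

    Each miRNA regulates ``targets_per_mirna`` genes drawn uniformly;
    planted differential miRNAs are shifted in the tumor class.
    """
    rng = np.random.default_rng(spec.seed + 2)
    vals = spec.base_mean + spec.noise_sd * rng.standard_normal(
        (spec.n_mirnas, spec.n_tumor + spec.n_normal)
    )
    idx = {m: i for i, m in enumerate(spec.mirna_ids)}
    for m, eff in spec.planted_demirna_effects.items():
        vals[idx[m], : spec.n_tumor] += eff
    matrix = ExpressionMatrix(
        gene_ids=spec.mirna_ids, sample_ids=spec.sample_ids, values=vals
    )
    rows = []
    for m in spec.mirna_ids:
        targets = rng.choice(spec.n_genes, size=min(targets_per_mirna, spec.n_genes), replace=False)
        for t in targets:
            rows.append((m, spec.gene_ids[t], "mirna_target"))
    edges = TypedEdgeList.build(rows)
    truth = {"planted_demirnas": sorted(spec.planted_demirna_effects)}
    return matrix, _labels(spec), edges, truth


def simulate_var_timeseries(spec: SyntheticSpec) -> tuple[TimeSeriesMatrix, dict]:
    """Stationary VAR(1) series ``x_t = A x_{t-1} + eps_t`` with burn-in.

    ``A`` has ``var_self_coeff`` on the diagonal and the planted coupling
    coefficients off-diagonal; 50 burn-in steps are discarded; values are
    offset by ``base_mean``.  Time points are half-hour steps.
    """
    A = spec.coupling_matrix()
    rng = np.random.default_rng(spec.seed + 3)
    burn_in = 50
    n_total = burn_in + spec.n_timepoints
    x = np.zeros((spec.n_genes, n_total))
    eps = rng.standard_normal((spec.n_genes, n_total))
    x[:, 0] = eps[:, 0]
    for t in range(1, n_total):
        x[:, t] = A @ x[:, t - 1] + eps[:, t]
    ts = TimeSeriesMatrix(
        gene_ids=spec.gene_ids,
        time_points=tuple(0.5 * t for t in range(spec.n_timepoints)),
        values=spec.base_mean + x[:, burn_in:],
    )
    truth = {"planted_causal_edges": sorted(spec.planted_causal_edges)}
    return ts, truth


def simulate_interactions(
    spec: SyntheticSpec, edge_density: float = 0.15
) -> TypedEdgeList:
    """Random typed undirected edges covering all planted causal pairs.

    Each unordered gene pair is linked with probability ``edge_density``;
    a linked pair gets one uniformly drawn interaction type plus each of
    the remaining types with probability 0.2.  The unordered version of
    every planted causal edge is always present, so the directing cascade
    has the chance to recover it.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(spec.seed + 4)
    genes = spec.gene_ids
    forced = {tuple(sorted(p)) for p in spec.planted_causal_edges}
    rows: list[tuple[str, str, str]] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = (genes[i], genes[j])
            linked = pair in forced or rng.random() < edge_density
            if not linked:
                continue
            primary = UNDIRECTED_TYPES[rng.integers(len(UNDIRECTED_TYPES))]
            rows.append((*pair, primary))
            for t in UNDIRECTED_TYPES:
                if t != primary and rng.random() < 0.2:
                    rows.append((*pair, t))
    return TypedEdgeList.build(rows)


def write_fixture_set(spec: SyntheticSpec, outdir: str | Path, edge_density: float = 0.15) -> dict:
    """Write the full synthetic input set (TSVs + truth JSON) to ``outdir``."""
    from . import core_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, labels, truth_e = simulate_expression(spec)
    meth, _, truth_m = simulate_methylation(spec)
    mirna, _, target_edges, truth_mi = simulate_mirna(spec)
    ts, truth_t = simulate_var_timeseries(spec)
    interactions = simulate_interactions(spec, edge_density)
    core_io.write_expression(expr, outdir / "expression.tsv")
    core_io.write_labels(labels, outdir / "labels.tsv")
    core_io.write_expression(meth, outdir / "methylation.tsv")
    core_io.write_expression(mirna, outdir / "mirna.tsv")
    core_io.write_edge_list(target_edges, outdir / "mirna_targets.tsv")
    core_io.write_timeseries(ts, outdir / "timeseries.tsv")
    core_io.write_edge_list(interactions, outdir / "interactions.tsv")
    truth = {**truth_e, **truth_m, **truth_mi, **truth_t, "seed": spec.seed}
    truth["planted_causal_edges"] = [list(e) for e in truth["planted_causal_edges"]]
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
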