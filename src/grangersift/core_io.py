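"""Shared domain types and TSV readers/writers.

Every on-disk format the pipeline touches is plain TSV (tab-separated,
UTF-8, ``.`` decimal, no quoting): expression / methylation / time-series
matrices with gene rows and sample (or time-point) columns, two-column
sample label files, typed interaction edge lists, and directed causal
networks with per-edge test diagnostics.  Reader/writer pairs are exact
round-trips on valid files; identifier matching is case-sensitive and a
mismatch is always an error, never a silent drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "SampleLabels",
    "TimeSeriesMatrix",
    "TypedEdgeList",
    "DirectedEdge",
    "CausalNetwork",
    "ConfusionMatrix",
    "MetricsReport",
    "PipelineConfig",
    "UNDIRECTED_TYPES",
    "INTERACTION_TYPES",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_timeseries",
    "write_timeseries",
    "read_edge_list",
    "write_edge_list",
    "read_causal_network",
    "write_causal_network",
    "load_config",
    "save_config",
]

#: Undirected gene-gene interaction categories (evidence channels).
UNDIRECTED_TYPES = ("colocation", "physical", "shared_domain")
#: All recognised interaction types; ``mirna_target`` edges are directed
#: miRNA -> gene regulation pairs.
INTERACTION_TYPES = UNDIRECTED_TYPES + ("mirna_target",)

POSITIVE_LABEL = "TP"  # tumor
NEGATIVE_LABEL = "NT"  # normal


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix (log2-scale expression or beta values).

    ``gene_ids`` and ``sample_ids`` are ordered, unique, case-sensitive
    strings; ``values`` is a finite float array of shape ``(d, n)`` with
    ``d`` genes and ``n`` samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def d(self) -> int:
        """Number of genes."""
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        """Number of samples."""
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(map(str, df.index)),
            sample_ids=tuple(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
        )

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene identifier: {gene_id!r}") from None
        return self.values[i]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes``, preserving the requested order."""
        idx = []
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        for g in genes:
            if g not in pos:
                raise KeyError(f"unknown gene identifier: {g!r}")
            idx.append(pos[g])
        return ExpressionMatrix(
            gene_ids=tuple(genes),
            sample_ids=self.sample_ids,
            values=self.values[idx],
        )


@dataclass(frozen=True)
class SampleLabels:
    """Binary class labels aligned to an :class:`ExpressionMatrix`.

    ``y`` holds 1 for the positive class (tumor, ``TP``) and 0 for the
    negative class (normal, ``NT``).
    """

    sample_ids: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "y", y)
        _check_unique(self.sample_ids, "sample")
        if y.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match sample_ids")
        if not np.all(np.isin(y, [0, 1])):
            raise ValueError("labels must be binary (0=normal, 1=tumor)")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.y) - self.y.sum())

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError("both tumor and normal samples are required")

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleLabels":
        """Reorder to the matrix sample order; IDs must match exactly."""
        if set(self.sample_ids) != set(matrix.sample_ids):
            extra = set(self.sample_ids) - set(matrix.sample_ids)
            missing = set(matrix.sample_ids) - set(self.sample_ids)
            raise ValueError(
                f"label/matrix sample mismatch: unknown {sorted(extra)}, "
                f"unlabeled {sorted(missing)}"
            )
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in matrix.sample_ids]
        return SampleLabels(sample_ids=matrix.sample_ids, y=self.y[order])

    def class_names(self) -> np.ndarray:
        return np.where(self.y == 1, POSITIVE_LABEL, NEGATIVE_LABEL)


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Genes x ordered time points (hours), for causality testing."""

    gene_ids: tuple[str, ...]
    time_points: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "time_points", tuple(float(t) for t in self.time_points))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.gene_ids, "gene")
        tp = np.asarray(self.time_points)
        if len(tp) and np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        if vals.shape != (len(self.gene_ids), len(self.time_points)):
            raise ValueError("matrix shape does not match gene/time-point counts")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite value in time-series matrix")

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def series(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene identifier: {gene_id!r}") from None
        return self.values[i]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def canonical_edge(a: str, b: str, etype: str) -> tuple[str, str, str]:
    """Canonical key of a typed edge; undirected types are sorted."""
    if etype in UNDIRECTED_TYPES and b < a:
        a, b = b, a
    return (a, b, etype)


@dataclass(frozen=True)
class TypedEdgeList:
    """Set of typed interaction edges.

    The three gene-gene channels (colocation, physical, shared_domain) are
    undirected and stored with the lexicographically smaller gene first;
    ``mirna_target`` edges are directed miRNA -> gene pairs and keep their
    orientation.  Self-edges are never stored; ``n_self_dropped`` counts
    how many were discarded during construction.
    """

    edges: frozenset[tuple[str, str, str]]
    n_self_dropped: int = 0

    @classmethod
    def build(
        cls, rows: Iterable[tuple[str, str, str]], *, strict_types: bool = True
    ) -> "TypedEdgeList":
        edges: set[tuple[str, str, str]] = set()
        dropped = 0
        for a, b, t in rows:
            a, b, t = str(a), str(b), str(t)
            if t not in INTERACTION_TYPES:
                if strict_types:
                    raise ValueError(f"unknown interaction type: {t!r}")
                continue
            if a == b:
                dropped += 1
                continue
            edges.add(canonical_edge(a, b, t))
        return cls(edges=frozenset(edges), n_self_dropped=dropped)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def of_type(self, etype: str) -> "TypedEdgeList":
        return TypedEdgeList(
            edges=frozenset(e for e in self.edges if e[2] == etype),
            n_self_dropped=0,
        )

    def undirected_pairs(self) -> set[tuple[str, str]]:
        """Unique unordered gene pairs, regardless of type multiplicity."""
        return {(a, b) for a, b, t in self.edges if t in UNDIRECTED_TYPES}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out


@dataclass(frozen=True)
class DirectedEdge:
    """A Granger-directed edge with the diagnostics of the test cascade."""

    source: str
    target: str
    interaction_type: str
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    cointegration_p: float = float("nan")
    granger_p_forward: float = float("nan")
    granger_p_reverse: float = float("nan")
    lag_used: int = 1


@dataclass(frozen=True)
class CausalNetwork:
    """Directed causal network over feature genes.

    ``nodes`` includes every gene carried into the directing step, also
    those that received no directed edge (isolated nodes matter for the
    downstream independence screen).
    """

    nodes: frozenset[str]
    directed_edges: tuple[DirectedEdge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        edges = tuple(
            sorted(
                self.directed_edges,
                key=lambda e: (e.source, e.target, e.interaction_type),
            )
        )
        object.__setattr__(self, "directed_edges", edges)
        for e in edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(
                    f"edge {e.source}->{e.target} references a gene outside nodes"
                )

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.directed_edges}

    def indegree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for s, t in self.edge_pairs():
            deg[t] += 1
        return deg


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; tumor is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, sensitivity, specificity, Matthews correlation, optional AUC."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {"acc": self.acc, "sn": self.sn, "sp": self.sp, "mcc": self.mcc, "auc": self.auc}


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, YAML-serialisable.

    Defaults follow the published analysis settings where those are
    stated (|log2FC| >= 1 with FDR <= 0.01 for expression and miRNA;
    p <= 0.01 with |diff-mean| >= 0.35 for methylation beta values;
    miRNA-target in-degree > 2; Pearson alpha 0.01 and 0.05 for the
    stationarity/cointegration/Granger tests; 500 trees with sqrt(p)
    features per split).
    """

    # differential analysis
    logfc_cut: float = 1.0
    fdr_cut: float = 0.01
    meth_p_cut: float = 0.01
    diffmean_cut: float = 0.35
    # network
    feature_degree_cut: int | None = 120
    feature_top_k: int | None = None
    target_degree_cut: int = 2
    # causality cascade
    alpha_pearson: float = 0.01
    alpha_tests: float = 0.05
    max_lag: int = 3
    lag_selection: str = "fixed"  # fixed | information_criterion
    # stepwise selection
    epsilon: float = 0.005
    n_trees: int = 500
    k_folds: int = 5
    n_repeats: int = 10
    max_iterations: int = 100
    removal_semantics: str = "prose"  # prose | pseudocode
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_cut", "meth_p_cut", "alpha_pearson", "alpha_tests"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        for name in ("n_trees", "k_folds", "n_repeats", "max_iterations"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.lag_selection not in ("fixed", "information_criterion"):
            raise ValueError(f"unknown lag_selection: {self.lag_selection!r}")
        if self.removal_semantics not in ("prose", "pseudocode"):
            raise ValueError(f"unknown removal_semantics: {self.removal_semantics!r}")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_frame(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    _check_unique(ids, f"{what} row")
    _check_unique(cols, f"{what} column")
    try:
        body = df.astype(float)
    except ValueError:
        for r, row in df.iterrows():
            for c, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {r!r}, column {c!r}: {cell!r}"
                    ) from None
        raise
    body.index = ids
    body.columns = cols
    return body


def read_expression(
    path: str | Path, labels_path: str | Path | None = None
) -> ExpressionMatrix | tuple[ExpressionMatrix, SampleLabels]:
    """Read a genes x samples TSV; optionally a (sample_id, class) label TSV.

    With ``labels_path`` the labels are reordered to the matrix sample
    order and both are returned; class values must be ``TP``/``NT`` or
    ``1``/``0``.
    """
    mat = ExpressionMatrix.from_frame(_read_matrix_frame(path, "gene"))
    if labels_path is None:
        return mat
    labels = read_labels(labels_path).aligned_to(mat)
    return mat, labels


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_labels(path: str | Path) -> SampleLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns (sample_id, class)")
    sample_ids = tuple(df.iloc[:, 0].astype(str))
    mapping = {POSITIVE_LABEL: 1, NEGATIVE_LABEL: 0, "1": 1, "0": 0}
    try:
        y = np.array([mapping[str(v)] for v in df.iloc[:, 1]], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}; expected TP/NT or 1/0") from None
    return SampleLabels(sample_ids=sample_ids, y=y)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.sample_ids), "class": labels.class_names()}
    ).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    df = _read_matrix_frame(path, "gene")
    try:
        tp = tuple(float(c) for c in df.columns)
    except ValueError:
        raise ValueError("time-series column headers must be numeric time points") from None
    return TimeSeriesMatrix(
        gene_ids=tuple(df.index), time_points=tp, values=df.to_numpy(dtype=float)
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    pd.DataFrame(
        ts.values, index=list(ts.gene_ids), columns=["%.17g" % t for t in ts.time_points]
    ).to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_edge_list(path: str | Path) -> TypedEdgeList:
    """Read a (gene_a, gene_b, interaction_type) TSV.

    Undirected edges are canonicalized; self-edges are dropped and counted
    in the returned list's ``n_self_dropped``; an unknown type is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_a", "gene_b", "interaction_type"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"edge list must have columns {required}, got {list(df.columns)}")
    return TypedEdgeList.build(df[required].itertuples(index=False, name=None))


def write_edge_list(edges: TypedEdgeList, path: str | Path) -> None:
    pd.DataFrame(sorted(edges.edges), columns=["gene_a", "gene_b", "interaction_type"]).to_csv(
        path, sep="\t", index=False
    )


_CAUSAL_COLS = [
    "source",
    "target",
    "interaction_type",
    "pearson_r",
    "pearson_p",
    "cointegration_p",
    "granger_p_forward",
    "granger_p_reverse",
    "lag_used",
]


def write_causal_network(net: CausalNetwork, path: str | Path) -> None:
    """Write edges and diagnostics as TSV; nodes go to a `.nodes` sidecar.

    The sidecar preserves isolated nodes so that read-back reproduces the
    network exactly.
    """
    rows = [
        {
            "source": e.source,
            "target": e.target,
            "interaction_type": e.interaction_type,
            "pearson_r": e.pearson_r,
            "pearson_p": e.pearson_p,
            "cointegration_p": e.cointegration_p,
            "granger_p_forward": e.granger_p_forward,
            "granger_p_reverse": e.granger_p_reverse,
            "lag_used": e.lag_used,
        }
        for e in net.directed_edges
    ]
    pd.DataFrame(rows, columns=_CAUSAL_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    nodes_path = Path(str(path) + ".nodes")
    nodes_path.write_text("".join(f"{v}\n" for v in sorted(net.nodes)))


def read_causal_network(path: str | Path) -> CausalNetwork:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"source": str, "target": str, "interaction_type": str},
        float_precision="round_trip",
    )
    if list(df.columns) != _CAUSAL_COLS:
        raise ValueError(f"causal network file must have columns {_CAUSAL_COLS}")
    edges = tuple(
        DirectedEdge(
            source=r.source,
            target=r.target,
            interaction_type=r.interaction_type,
            pearson_r=float(r.pearson_r),
            pearson_p=float(r.pearson_p),
            cointegration_p=float(r.cointegration_p),
            granger_p_forward=float(r.granger_p_forward),
            granger_p_reverse=float(r.granger_p_reverse),
            lag_used=int(r.lag_used),
        )
        for r in df.itertuples(index=False)
    )
    nodes_path = Path(str(path) + ".nodes")
    if nodes_path.exists():
        nodes = frozenset(l for l in nodes_path.read_text().splitlines() if l)
    else:
        nodes = frozenset(x for e in edges for x in (e.source, e.target))
    return CausalNetwork(nodes=nodes, directed_edges=edges)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg.__dict__), fh, sort_keys=True)


def write_metrics_json(report: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
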