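"""Predictor validation (metrics, ROC/AUC, cross-dataset runs) and the pipeline runner.

``run_pipeline`` chains the whole method — differential screening, the
diff-gene union, the multi-interaction network, Granger directing, the
independence screen, stepwise selection and final evaluation — writing
every intermediate as TSV/JSON plus a provenance log, so each stage can
be re-run from its persisted inputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import core_io
from .core_io import (
    CausalNetwork,
    ExpressionMatrix,
    MetricsReport,
    PipelineConfig,
    SampleLabels,
    TimeSeriesMatrix,
    TypedEdgeList,
)
from .causality import CausalityConfig, direct_network
from .diffexpr import dea_expression, dea_methylation, mirna_target_genes, union_diff_genes
from .independent_screen import screen_independent
from .network import build_network, induced_subnetwork, select_by_degree, select_top_k
from .stepwise_select import CvConfig, cv_score, make_rf_scorer, rank_candidates, stepwise_select

__all__ = [
    "RocResult",
    "ValidationReport",
    "PipelineError",
    "PipelineResult",
    "roc_auc",
    "oof_scores",
    "cross_validate_predictors",
    "run_pipeline",
]


@dataclass(frozen=True)
class RocResult:
    """ROC curve (threshold sweep over unique scores) and trapezoid AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def roc_auc(scores, labels: SampleLabels) -> RocResult:
    """ROC by sweeping the unique score values; AUC by the trapezoid rule.

    Scores are positive-class probabilities or votes; tied scores are
    grouped on a single sweep point.  The curve starts at (0, 0) and ends
    at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(labels.sample_ids),):
        raise ValueError("scores must align with labels")
    labels.require_both_classes()
    fpr, tpr, thr = roc_curve(labels.y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=tuple(fpr), tpr=tuple(tpr), thresholds=tuple(thr), auc=auc)


def oof_scores(
    genes,
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    cfg: CvConfig | None = None,
) -> np.ndarray:
    """Out-of-fold positive-class vote fractions from one stratified CV pass.

    The score of a sample is the fraction of trees voting tumor in the
    forest trained on the folds that exclude it.
    """
    cfg = cfg or CvConfig()
    labels = labels.aligned_to(matrix)
    X = matrix.subset_genes(tuple(genes)).values.T
    y = labels.y
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed % (2**31 - 1))
    out = np.empty(len(y), dtype=float)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features="sqrt",
            random_state=(cfg.seed + fold + 1) % (2**31 - 1),
            n_jobs=1,
        )
        clf.fit(X[tr], y[tr])
        out[te] = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
    return out


@dataclass(frozen=True)
class ValidationReport:
    """Per-dataset CV performance of a fixed predictor panel."""

    dataset_id: str
    metrics: MetricsReport
    roc: RocResult
    dropped_genes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            **self.metrics.as_dict(),
            "roc_auc": self.roc.auc,
            "dropped_genes": list(self.dropped_genes),
        }


def cross_validate_predictors(
    predictors,
    datasets: list[tuple[str, ExpressionMatrix, SampleLabels]],
    cfg: CvConfig | None = None,
    *,
    strict: bool = True,
) -> list[ValidationReport]:
    """Evaluate a predictor panel within each validation dataset by CV.

    The panel is re-fit inside each dataset (stratified k-fold).  A
    dataset missing a predictor gene raises in strict mode; otherwise the
    missing genes are dropped and flagged in the report.
    """
    cfg = cfg or CvConfig()
    predictors = tuple(predictors)
    reports = []
    for dataset_id, matrix, labels in datasets:
        present = [g for g in predictors if g in matrix.gene_ids]
        missing = tuple(g for g in predictors if g not in matrix.gene_ids)
        if missing and strict:
            raise KeyError(
                f"dataset {dataset_id!r} is missing predictor genes {list(missing)}"
            )
        if not present:
            raise ValueError(f"dataset {dataset_id!r} contains no predictor genes")
        labels = labels.aligned_to(matrix)
        metrics = cv_score(present, matrix, labels, cfg)
        roc = roc_auc(oof_scores(present, matrix, labels, cfg), labels)
        reports.append(
            ValidationReport(
                dataset_id=dataset_id, metrics=metrics, roc=roc, dropped_genes=missing
            )
        )
    return reports


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """End-to-end run summary with all stage outputs in memory."""

    diff_genes: frozenset[str]
    feature_genes: frozenset[str]
    causal_network: CausalNetwork
    independent_genes: tuple[str, ...]
    predictors: tuple[str, ...]
    p_acc: float
    metrics: MetricsReport
    roc: RocResult
    per_type_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    stages: tuple[str, ...] = ()
    outdir: Path | None = None


def _versions() -> dict[str, str]:
    import networkx
    import sklearn
    import statsmodels

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(
    config: PipelineConfig,
    *,
    expression: ExpressionMatrix,
    labels: SampleLabels,
    timeseries: TimeSeriesMatrix,
    interactions: TypedEdgeList,
    methylation: ExpressionMatrix | None = None,
    mirna: ExpressionMatrix | None = None,
    mirna_targets: TypedEdgeList | None = None,
    feature_genes: set[str] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run dea -> union -> network -> direct -> screen -> select -> evaluate.

    ``feature_genes`` skips the differential and degree-screening stages
    and directs the induced interaction network of the given list
    instead.  With ``outdir`` every intermediate is persisted as TSV/JSON
    together with a provenance log naming the stages, config and library
    versions.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def run_stage(name, fn):
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(name, exc) from exc
        stages.append(name)
        return result

    labels = labels.aligned_to(expression)

    if feature_genes is None:
        def _dea():
            table = dea_expression(expression, labels, config.logfc_cut, config.fdr_cut)
            degs = set(table.index[table["selected"]])
            dmet: set[str] = set()
            if methylation is not None:
                mt = dea_methylation(
                    methylation,
                    labels.aligned_to(methylation),
                    config.meth_p_cut,
                    config.diffmean_cut,
                )
                dmet = set(mt.index[mt["selected"]])
                if out is not None:
                    mt.to_csv(out / "dea_methylation.tsv", sep="\t")
            targets: set[str] = set()
            if mirna is not None and mirna_targets is not None:
                mi = dea_expression(
                    mirna, labels.aligned_to(mirna), config.logfc_cut, config.fdr_cut
                )
                demirnas = set(mi.index[mi["selected"]])
                targets = mirna_target_genes(demirnas, mirna_targets, config.target_degree_cut)
                if out is not None:
                    mi.to_csv(out / "dea_mirna.tsv", sep="\t")
            if out is not None:
                table.to_csv(out / "dea_expression.tsv", sep="\t")
            return degs, dmet, targets

        degs, dmet, targets = run_stage("dea", _dea)
        diffset = run_stage("union", lambda: union_diff_genes(degs, dmet, targets))
        diff_genes = set(diffset.diff_genes)
        if out is not None:
            diffset.to_frame().to_csv(out / "diff_genes.tsv", sep="\t", index=False)

        def _network():
            net = build_network(diff_genes, interactions)
            if config.feature_top_k is not None:
                feats = select_top_k(net, config.feature_top_k)
            else:
                feats = select_by_degree(net, config.feature_degree_cut or 0)
            return net, feats

        diff_net, feats = run_stage("network", _network)
        feature_net = induced_subnetwork(diff_net, feats)
        if out is not None:
            diff_net.degree_frame().to_csv(out / "diff_gene_degrees.tsv", sep="\t", index=False)
            core_io.write_edge_list(feature_net.edges, out / "feature_edges.tsv")
    else:
        diff_genes = set(feature_genes)
        feats = set(feature_genes)
        feature_net = run_stage("network", lambda: build_network(feats, interactions))
        if out is not None:
            core_io.write_edge_list(feature_net.edges, out / "feature_edges.tsv")

    cascade_cfg = CausalityConfig(
        alpha_pearson=config.alpha_pearson,
        alpha_tests=config.alpha_tests,
        max_lag=config.max_lag,
        lag_selection=config.lag_selection,
    )
    directing = run_stage("direct", lambda: direct_network(feature_net, timeseries, cascade_cfg))
    if out is not None:
        core_io.write_causal_network(directing.network, out / "causal_network.tsv")
        pd.DataFrame(
            [
                {"interaction_type": t, "causal_edges": c, "feature_edges": n}
                for t, (c, n) in sorted(directing.per_type_counts.items())
            ]
        ).to_csv(out / "causal_edge_summary.tsv", sep="\t", index=False)

    screen = run_stage("screen", lambda: screen_independent(directing.network))
    independent = tuple(sorted(screen.independent_genes))
    if out is not None:
        screen.to_frame().to_csv(out / "independent_genes.tsv", sep="\t", index=False)

    cv_cfg = CvConfig(
        k_folds=config.k_folds,
        n_trees=config.n_trees,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )

    def _select():
        candidates = [g for g in independent if g in expression.gene_ids]
        if not candidates:
            raise ValueError("no independent genes present in the expression matrix")
        scorer = make_rf_scorer(expression, labels, cv_cfg)
        ranked = [g for g, _ in rank_candidates(candidates, scorer=scorer)]
        return stepwise_select(
            ranked,
            epsilon=config.epsilon,
            scorer=scorer,
            removal_semantics=config.removal_semantics,
            max_iterations=config.max_iterations,
        )

    selection = run_stage("select", _select)
    if out is not None:
        pd.DataFrame({"gene_id": list(selection.predictors)}).to_csv(
            out / "predictors.tsv", sep="\t", index=False
        )
        core_io.write_metrics_json(
            {"trace": list(selection.trace), "p_acc": selection.p_acc},
            out / "selection_trace.json",
        )

    def _evaluate():
        metrics = cv_score(selection.predictors, expression, labels, cv_cfg)
        roc = roc_auc(oof_scores(selection.predictors, expression, labels, cv_cfg), labels)
        return metrics, roc

    metrics, roc = run_stage("evaluate", _evaluate)
    if out is not None:
        core_io.write_metrics_json(metrics.as_dict(), out / "predictor_metrics.json")
        pd.DataFrame(
            {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
        ).to_csv(out / "roc_points.csv", index=False, float_format="%.17g")
        provenance = {
            "stages": stages,
            "config": dict(config.__dict__),
            "versions": _versions(),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
        )

    return PipelineResult(
        diff_genes=frozenset(diff_genes),
        feature_genes=frozenset(feats),
        causal_network=directing.network,
        independent_genes=independent,
        predictors=selection.predictors,
        p_acc=selection.p_acc,
        metrics=metrics,
        roc=roc,
        per_type_counts=directing.per_type_counts,
        stages=tuple(stages),
        outdir=out,
    )
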