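"""Stepwise character selection over cross-validated Random-Forest accuracy.

The selector reduces the globally independent genes to a minimal
predictor panel.  Starting from the single best gene it repeats a
forward-add step (adopt the candidate whose addition maximises CV
accuracy) followed by a conditional backward step (return to the
candidate pool every current member whose removal strictly improves
accuracy), while the accuracy does not fall by more than a tolerance
``epsilon`` relative to the previous round and candidates remain.

Classification accuracy is measured with a Random Forest (default 500
trees, ``sqrt(p)`` features per split) under stratified 5-fold
cross-validation, repeated with distinct fold seeds and averaged.  Any
deterministic scorer mapping a gene set to a :class:`MetricsReport` can
be injected in place of the Random Forest, which makes the algorithm a
pure function of its score table — the property the unit tests exploit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core_io import ConfusionMatrix, ExpressionMatrix, MetricsReport, SampleLabels

__all__ = [
    "CvConfig",
    "SelectionResult",
    "confusion_metrics",
    "cv_score",
    "make_rf_scorer",
    "rank_candidates",
    "stepwise_select",
]

Scorer = Callable[[tuple[str, ...]], MetricsReport]


@dataclass(frozen=True)
class CvConfig:
    """Random-Forest cross-validation settings.

    ``mtry`` follows the sqrt(p) rule; folds are stratified by class and
    re-drawn per repeat from seeds derived deterministically from ``seed``.
    """

    k_folds: int = 5
    n_trees: int = 500
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be positive")


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """ACC, SN, SP and MCC of a binary confusion matrix.

    ACC = (TP+TN)/(TP+FP+FN+TN); SN = TP/(TP+FN); SP = TN/(FP+TN);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(FP+TN)(TN+FN)), defined
    as 0 when any marginal factor vanishes; SN (resp. SP) is reported as
    0 when its own denominator is 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    acc = (tp + tn) / cm.total
    sn = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    sp = tn / (fp + tn) if (fp + tn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (fp + tn) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc)


def _repeat_seed(seed: int, repeat: int) -> int:
    return int((seed * 100003 + 7919 * repeat + 1) % (2**31 - 1))


def cv_score(
    genes: Sequence[str],
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    cfg: CvConfig | None = None,
) -> MetricsReport:
    """Repeated stratified k-fold Random-Forest CV metrics for a gene set.

    Within each repeat the out-of-fold predictions are pooled into one
    confusion matrix; metrics (and AUC from the out-of-fold tree-vote
    fractions) are then averaged over repeats.
    """
    cfg = cfg or CvConfig()
    genes = tuple(genes)
    if not genes:
        raise ValueError("gene set must be nonempty")
    labels = labels.aligned_to(matrix)
    labels.require_both_classes()
    if min(labels.n_positive, labels.n_negative) < cfg.k_folds:
        raise ValueError(
            f"a class has fewer than k_folds={cfg.k_folds} samples; use smaller k"
        )
    X = matrix.subset_genes(genes).values.T  # samples x genes
    y = labels.y
    reports = []
    aucs = []
    for rep in range(cfg.n_repeats):
        rs = _repeat_seed(cfg.seed, rep)
        skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=rs)
        pred = np.empty_like(y)
        score = np.empty(len(y), dtype=float)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            clf = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                max_features="sqrt",
                random_state=(rs + fold) % (2**31 - 1),
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            pos = list(clf.classes_).index(1)
            prob = clf.predict_proba(X[te])[:, pos]
            score[te] = prob
            pred[te] = (prob >= 0.5).astype(int)
        cm = ConfusionMatrix(
            tp=int(np.sum((pred == 1) & (y == 1))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            tn=int(np.sum((pred == 0) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))),
        )
        reports.append(confusion_metrics(cm))
        aucs.append(float(roc_auc_score(y, score)))
    if not np.all(np.isfinite([r.acc for r in reports])):
        raise ValueError("non-finite accuracy from cross-validation")
    return MetricsReport(
        acc=float(np.mean([r.acc for r in reports])),
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean(aucs)),
    )


def make_rf_scorer(
    matrix: ExpressionMatrix, labels: SampleLabels, cfg: CvConfig | None = None
) -> Scorer:
    """Memoized gene-set scorer backed by :func:`cv_score`."""
    cfg = cfg or CvConfig()
    cache: dict[frozenset[str], MetricsReport] = {}

    def score(genes: tuple[str, ...]) -> MetricsReport:
        key = frozenset(genes)
        if key not in cache:
            cache[key] = cv_score(sorted(key), matrix, labels, cfg)
        return cache[key]

    return score


def rank_candidates(
    G: Sequence[str],
    matrix: ExpressionMatrix | None = None,
    labels: SampleLabels | None = None,
    cfg: CvConfig | None = None,
    scorer: Scorer | None = None,
) -> list[tuple[str, MetricsReport]]:
    """Rank genes by single-predictor CV accuracy (descending).

    Ties break on higher MCC, then lexicographic gene ID.
    """
    if not G:
        raise ValueError("candidate list must be nonempty")
    if scorer is None:
        scorer = make_rf_scorer(matrix, labels, cfg)
    scored = [(g, scorer((g,))) for g in G]
    scored.sort(key=lambda gr: (-gr[1].acc, -gr[1].mcc, gr[0]))
    return scored


@dataclass(frozen=True)
class SelectionResult:
    """Final predictor panel with its accuracy and full decision trace."""

    predictors: tuple[str, ...]
    p_acc: float
    report: MetricsReport
    trace: tuple[dict, ...]
    hit_iteration_cap: bool = False


def _argbest(
    options: list[tuple[str, MetricsReport]], rank_of: dict[str, int]
) -> tuple[str, MetricsReport]:
    # highest ACC, then higher MCC, then earlier initial rank, then lexicographic
    return min(
        options,
        key=lambda gr: (-gr[1].acc, -gr[1].mcc, rank_of.get(gr[0], len(rank_of)), gr[0]),
    )


def stepwise_select(
    G: Sequence[str],
    matrix: ExpressionMatrix | None = None,
    labels: SampleLabels | None = None,
    epsilon: float = 0.005,
    cfg: CvConfig | None = None,
    scorer: Scorer | None = None,
    removal_semantics: str = "prose",
    max_iterations: int = 100,
) -> SelectionResult:
    """Run stepwise character selection over the ranked gene list ``G``.

    The loop runs while ``P_ACC - ACC_max > -epsilon`` and candidates
    remain (``ACC_max`` is the accuracy snapshot from the previous round,
    initially minus infinity so that the first round always runs).  Each
    round adopts the best single addition unconditionally, then — if the
    tolerance condition still holds — evaluates leaving each member out
    against the pre-removal accuracy.

    ``removal_semantics``:

    - ``"prose"`` (default): members whose removal *strictly improves*
      accuracy are returned to the candidate pool (drop the harmful).
    - ``"pseudocode"``: the literal set-builder reading — keep exactly the
      members whose leave-out accuracy exceeds ``P_ACC`` and return the
      rest; kept for comparison since it discards the best members.

    Returns the final panel, its accuracy and a trace that reconstructs
    every decision; if the iteration cap is hit (or the panel empties
    under the pseudocode semantics) the best panel seen so far is
    returned with a warning.
    """
    if not G:
        raise ValueError("candidate list must be nonempty")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if removal_semantics not in ("prose", "pseudocode"):
        raise ValueError(f"unknown removal_semantics: {removal_semantics!r}")
    if scorer is None:
        scorer = make_rf_scorer(matrix, labels, cfg)
    rank_of = {g: i for i, g in enumerate(G)}

    trace: list[dict] = []
    singles = [(g, scorer((g,))) for g in G]
    first, first_rep = _argbest(singles, rank_of)
    P: list[str] = [first]
    C: list[str] = [g for g in G if g != first]
    p_acc = first_rep.acc
    if not np.isfinite(p_acc):
        raise ValueError("non-finite accuracy")
    trace.append({"action": "init", "gene": first, "acc_before": None, "acc_after": p_acc})

    best_panel = (tuple(P), p_acc)
    acc_max = -math.inf
    hit_cap = False
    iteration = 0
    while p_acc - acc_max > -epsilon and C:
        iteration += 1
        if iteration > max_iterations:
            warnings.warn("stepwise selection hit the iteration cap; returning best panel")
            hit_cap = True
            break
        acc_max = p_acc

        # forward add: adopt the best extension unconditionally
        options = [(c, scorer(tuple(P) + (c,))) for c in C]
        gene, rep = _argbest(options, rank_of)
        acc_before = p_acc
        P.append(gene)
        C.remove(gene)
        p_acc = rep.acc
        trace.append(
            {"action": "add", "gene": gene, "acc_before": acc_before, "acc_after": p_acc}
        )
        if p_acc > best_panel[1]:
            best_panel = (tuple(P), p_acc)

        # conditional backward remove (leave-one-out against pre-removal P_ACC)
        if p_acc - acc_max > -epsilon and len(P) > 1:
            loo = {p: scorer(tuple(x for x in P if x != p)).acc for p in P}
            improvers = [p for p in P if loo[p] > p_acc]
            if removal_semantics == "prose":
                removed = improvers
            else:
                removed = [p for p in P if p not in improvers]
            if removed:
                for p in removed:
                    trace.append(
                        {
                            "action": "remove",
                            "gene": p,
                            "acc_before": p_acc,
                            "acc_after": loo[p],
                        }
                    )
                P = [p for p in P if p not in removed]
                C.extend(removed)
                if not P:
                    warnings.warn(
                        "pseudocode removal emptied the panel; returning best panel"
                    )
                    hit_cap = True
                    break
                p_acc = scorer(tuple(P)).acc  # Step 2.4 re-evaluation
        if not np.isfinite(p_acc):
            raise ValueError("non-finite accuracy")
        if p_acc > best_panel[1]:
            best_panel = (tuple(P), p_acc)

    if hit_cap:
        final = list(best_panel[0])
        p_acc = best_panel[1]
    else:
        final = P
    report = scorer(tuple(final))
    return SelectionResult(
        predictors=tuple(final),
        p_acc=p_acc,
        report=report,
        trace=tuple(trace),
        hit_iteration_cap=hit_cap,
    )
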