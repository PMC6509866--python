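"""Edge-restricted Granger-causality cascade for directing interaction edges.

For every *interacting* feature-gene pair (never for arbitrary pairs) the
cascade runs, in fixed order, on the two genes' time-series expression:

1. Pearson correlation — a pair without significant correlation
   (``p >= alpha_pearson``) is dismissed before any time-series test.
2. Augmented Dickey-Fuller unit-root test on each series — levels first,
   then first differences — establishing integration order 0 or 1.
3. Engle-Granger cointegration when both series are integrated of order 1;
   a non-cointegrated I(1) pair is not testable on levels and is dropped
   (optionally differenced instead, see ``stationarity_protocol``).
4. Pairwise Granger F-tests in both directions.  A directed edge is
   emitted only when one direction is significant and the other is not:
   the source must help predict the target while the target must not
   appreciably help predict the source.

All thresholds are raw per-test alphas (no cross-pair correction by
default), with Pearson at 0.01 and the three time-series tests at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller, coint, grangercausalitytests
from statsmodels.tsa.api import VAR

from .core_io import CausalNetwork, DirectedEdge, TimeSeriesMatrix, UNDIRECTED_TYPES
from .network import MultiNetwork

__all__ = [
    "CausalityConfig",
    "PairTestResult",
    "pearson_test",
    "unit_root_test",
    "cointegration_test",
    "granger_test",
    "direct_edge",
    "direct_network",
]

NOT_TESTABLE = "not_testable"


@dataclass(frozen=True)
class CausalityConfig:
    """Thresholds and lag policy for the directing cascade."""

    alpha_pearson: float = 0.01
    alpha_tests: float = 0.05
    max_lag: int = 3
    lag_selection: str = "fixed"  # fixed (lag 1) | information_criterion (AIC <= max_lag)
    stationarity_protocol: str = "gate"  # gate | difference

    def __post_init__(self) -> None:
        if not 0 < self.alpha_pearson < 1 or not 0 < self.alpha_tests < 1:
            raise ValueError("alphas must lie in (0, 1)")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.lag_selection not in ("fixed", "information_criterion"):
            raise ValueError(f"unknown lag_selection: {self.lag_selection!r}")
        if self.stationarity_protocol not in ("gate", "difference"):
            raise ValueError(f"unknown stationarity_protocol: {self.stationarity_protocol!r}")


@dataclass(frozen=True)
class PairTestResult:
    """Full diagnostics of the cascade on one unordered gene pair."""

    gene_a: str
    gene_b: str
    verdict: str  # a_causes_b | b_causes_a | bidirectional | none | not_correlated | not_testable
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    adf_p_a: float = float("nan")
    adf_p_b: float = float("nan")
    integration_order_a: int | None = None
    integration_order_b: int | None = None
    coint_p: float = float("nan")
    granger_p_ab: float = float("nan")
    granger_p_ba: float = float("nan")
    lag_used: int = 1

    def swapped(self) -> "PairTestResult":
        """The same result viewed from the (b, a) argument order."""
        verdict = {"a_causes_b": "b_causes_a", "b_causes_a": "a_causes_b"}.get(
            self.verdict, self.verdict
        )
        return PairTestResult(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            verdict=verdict,
            pearson_r=self.pearson_r,
            pearson_p=self.pearson_p,
            adf_p_a=self.adf_p_b,
            adf_p_b=self.adf_p_a,
            integration_order_a=self.integration_order_b,
            integration_order_b=self.integration_order_a,
            coint_p=self.coint_p,
            granger_p_ab=self.granger_p_ba,
            granger_p_ba=self.granger_p_ab,
            lag_used=self.lag_used,
        )


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p; zero variance raises ``ValueError``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be one-dimensional, equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def unit_root_test(
    x, alpha: float = 0.05, max_lag: int | None = None
) -> tuple[float, float, int | None]:
    """ADF unit-root test on levels, then on first differences.

    Returns ``(adf_stat, p_levels, integration_order)`` where the order is
    0 when the levels reject a unit root at ``alpha``, 1 when only the
    first differences do, and ``None`` (not testable) otherwise — also for
    constant or too-short series.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("unit-root test needs at least 10 observations")
    if np.std(x) == 0:
        return float("nan"), float("nan"), None
    kw = {"autolag": "AIC"}
    if max_lag is not None:
        kw["maxlag"] = max_lag
    try:
        stat, p = adfuller(x, **kw)[:2]
    except (ValueError, np.linalg.LinAlgError):
        return float("nan"), float("nan"), None
    if p < alpha:
        return float(stat), float(p), 0
    dx = np.diff(x)
    if np.std(dx) == 0:
        return float(stat), float(p), None
    try:
        _, p_diff = adfuller(dx, **kw)[:2]
    except (ValueError, np.linalg.LinAlgError):
        return float(stat), float(p), None
    if p_diff < alpha:
        return float(stat), float(p), 1
    return float(stat), float(p), None


def cointegration_test(x, y) -> float:
    """Engle-Granger cointegration p-value for two I(1) series.

    A (near-)perfect level relationship, where the residuals of the level
    regression are numerically zero, is reported as p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("cointegration test requires non-constant series")
    # residual scale of the level regression of y on x
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    scale = np.std(y) if np.std(y) > 0 else 1.0
    if np.std(resid) / scale < 1e-10:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p, _ = coint(y, x)
    return float(p)


def granger_test(x, y, lag: int = 1) -> float:
    """F-test p-value for "x Granger-causes y" at the given lag.

    Compares the restricted AR(lag) model of ``y`` against the unrestricted
    regression that adds ``lag`` past values of ``x``.  The series are
    assumed already prepared (stationary levels or differences).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(y) - lag <= 2 * lag + 1:
        raise ValueError("series too short for the requested lag")
    data = np.column_stack([y, x])  # column 2 tested as a cause of column 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = grangercausalitytests(data, maxlag=[lag], verbose=False)
    p = res[lag][0]["ssr_ftest"][1]
    return float(p)


def _choose_lag(x: np.ndarray, y: np.ndarray, cfg: CausalityConfig) -> int:
    if cfg.lag_selection == "fixed":
        return 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = VAR(np.column_stack([x, y])).select_order(maxlags=cfg.max_lag)
    lag = sel.aic if sel.aic is not None else 1
    return max(1, int(lag))


def direct_edge(
    pair: tuple[str, str], ts: TimeSeriesMatrix, cfg: CausalityConfig | None = None
) -> PairTestResult:
    """Run the full cascade on one interacting pair.

    Verdict rules: ``not_correlated`` if the Pearson gate fails (no
    time-series test is attempted); ``not_testable`` if stationarity
    cannot be established, the orders are mixed, or an I(1) pair is not
    cointegrated (under the default gate protocol); ``a_causes_b`` /
    ``b_causes_a`` when exactly one Granger direction is significant;
    ``bidirectional`` when both are (no edge is emitted downstream);
    ``none`` otherwise.
    """
    cfg = cfg or CausalityConfig()
    a, b = pair
    x = ts.series(a)
    y = ts.series(b)

    try:
        r, p_r = pearson_test(x, y)
    except ValueError:
        return PairTestResult(gene_a=a, gene_b=b, verdict=NOT_TESTABLE)
    if p_r >= cfg.alpha_pearson:
        return PairTestResult(
            gene_a=a, gene_b=b, verdict="not_correlated", pearson_r=r, pearson_p=p_r
        )

    _, adf_p_a, order_a = unit_root_test(x, alpha=cfg.alpha_tests)
    _, adf_p_b, order_b = unit_root_test(y, alpha=cfg.alpha_tests)
    base = dict(
        gene_a=a,
        gene_b=b,
        pearson_r=r,
        pearson_p=p_r,
        adf_p_a=adf_p_a,
        adf_p_b=adf_p_b,
        integration_order_a=order_a,
        integration_order_b=order_b,
    )
    if order_a is None or order_b is None:
        return PairTestResult(verdict=NOT_TESTABLE, **base)

    coint_p = float("nan")
    xg, yg = x, y
    if order_a == 0 and order_b == 0:
        pass  # test on levels
    elif order_a == 1 and order_b == 1:
        coint_p = cointegration_test(x, y)
        base["coint_p"] = coint_p
        if coint_p >= cfg.alpha_tests:
            if cfg.stationarity_protocol == "gate":
                return PairTestResult(verdict=NOT_TESTABLE, **base)
            xg, yg = np.diff(x), np.diff(y)
        # cointegrated pairs are tested on levels
    else:  # mixed integration orders
        if cfg.stationarity_protocol == "gate":
            return PairTestResult(verdict=NOT_TESTABLE, **base)
        xg = np.diff(x) if order_a == 1 else x[1:]
        yg = np.diff(y) if order_b == 1 else y[1:]
    if "coint_p" not in base:
        base["coint_p"] = coint_p

    lag = _choose_lag(xg, yg, cfg)
    try:
        p_ab = granger_test(xg, yg, lag)  # a -> b
        p_ba = granger_test(yg, xg, lag)  # b -> a
    except ValueError:
        return PairTestResult(verdict=NOT_TESTABLE, lag_used=lag, **base)
    if not (np.isfinite(p_ab) and np.isfinite(p_ba)):
        return PairTestResult(verdict=NOT_TESTABLE, lag_used=lag, **base)

    sig_ab = p_ab < cfg.alpha_tests
    sig_ba = p_ba < cfg.alpha_tests
    if sig_ab and not sig_ba:
        verdict = "a_causes_b"
    elif sig_ba and not sig_ab:
        verdict = "b_causes_a"
    elif sig_ab and sig_ba:
        verdict = "bidirectional"
    else:
        verdict = "none"
    return PairTestResult(
        verdict=verdict, granger_p_ab=p_ab, granger_p_ba=p_ba, lag_used=lag, **base
    )


@dataclass(frozen=True)
class DirectingReport:
    """Outcome of directing a feature network."""

    network: CausalNetwork
    results: tuple[PairTestResult, ...]
    n_pairs_skipped: int  # pairs with a gene absent from the time series
    per_type_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def verdict_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.results:
            out[r.verdict] = out.get(r.verdict, 0) + 1
        return out


def direct_network(
    feature_net: MultiNetwork, ts: TimeSeriesMatrix, cfg: CausalityConfig | None = None
) -> DirectingReport:
    """Direct every interacting pair of the feature network.

    Each unordered pair is tested once regardless of how many interaction
    channels link it; an emitted directed edge is replicated per channel
    so that per-type causal/total counts can be tabulated.  Bidirectional
    pairs are recorded but emit no edge.  Genes missing from the time
    series are skipped (and counted); they remain nodes of the returned
    network so the independence screen can treat them as isolated.
    """
    cfg = cfg or CausalityConfig()
    pair_types: dict[tuple[str, str], list[str]] = {}
    for a, b, t in feature_net.edges:
        if t in UNDIRECTED_TYPES:
            pair_types.setdefault((a, b), []).append(t)

    results: list[PairTestResult] = []
    edges: list[DirectedEdge] = []
    skipped = 0
    causal_by_type: dict[str, int] = {t: 0 for t in UNDIRECTED_TYPES}
    total_by_type: dict[str, int] = {t: 0 for t in UNDIRECTED_TYPES}
    for a, b, t in feature_net.edges:
        if t in UNDIRECTED_TYPES:
            total_by_type[t] += 1

    for (a, b) in sorted(pair_types):
        if a not in ts or b not in ts:
            skipped += 1
            continue
        res = direct_edge((a, b), ts, cfg)
        results.append(res)
        if res.verdict not in ("a_causes_b", "b_causes_a"):
            continue
        src, dst = (a, b) if res.verdict == "a_causes_b" else (b, a)
        p_fwd = res.granger_p_ab if res.verdict == "a_causes_b" else res.granger_p_ba
        p_rev = res.granger_p_ba if res.verdict == "a_causes_b" else res.granger_p_ab
        for etype in sorted(pair_types[(a, b)]):
            causal_by_type[etype] += 1
            edges.append(
                DirectedEdge(
                    source=src,
                    target=dst,
                    interaction_type=etype,
                    pearson_r=res.pearson_r,
                    pearson_p=res.pearson_p,
                    cointegration_p=res.coint_p,
                    granger_p_forward=p_fwd,
                    granger_p_reverse=p_rev,
                    lag_used=res.lag_used,
                )
            )

    net = CausalNetwork(nodes=frozenset(feature_net.nodes), directed_edges=tuple(edges))
    per_type = {t: (causal_by_type[t], total_by_type[t]) for t in UNDIRECTED_TYPES}
    return DirectingReport(
        network=net, results=tuple(results), n_pairs_skipped=skipped, per_type_counts=per_type
    )
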