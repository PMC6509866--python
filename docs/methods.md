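# Methods

`grangersift` extracts a minimal gene-predictor panel for a two-class
(tumor/normal) study from four kinds of input: a log2 expression matrix
with sample labels, a methylation beta matrix, a miRNA expression matrix
with a miRNA→target edge list, an undirected typed gene–gene interaction
edge list, and a time-series expression matrix. The method is a five-stage
cascade; this note records the model behind each stage, the tunable
parameters, the numerical choices, and what the synthetic studies do and
do not demonstrate.

## 1. Differential screening and the diff-gene union

Each omics channel is screened per feature with a two-sided Welch
(unequal-variance) t-test between classes. Welch is used because the
discovery cohorts this method targets are strongly unbalanced (hundreds
of tumors vs tens of normals), making pooled variance inappropriate.

* Expression and miRNA (log2 scale): log2 fold change is the difference
  of class means; p-values are Benjamini–Hochberg adjusted; a feature is
  differential when `|log2FC| >= logfc_cut` (default 1.0) and
  `FDR <= fdr_cut` (default 0.01), both inclusive.
* Methylation (beta values in [0, 1]): selection on the raw p-value
  (`p <= 0.01`) and the mean beta difference (`|diff_mean| >= 0.35`).
* miRNA targets: a gene qualifies when strictly more than
  `target_degree_cut` (default 2) *differential* miRNAs regulate it.
  Counting regulation by differential miRNAs only (rather than all
  miRNAs in the target network) is a deliberate choice, exposed as the
  `demirnas` argument; the degree comparison is strict because the cut
  is phrased as "greater than".

A gene differential in any channel is a **diff-gene**; per-gene
provenance (DEG / Dmet / miRNA-target) is retained, and all pairwise and
triple intersection counts are reported.

## 2. Multi-interaction network and feature genes

The three undirected interaction channels (co-location, physical,
shared protein domain) form a multigraph on the diff-genes: a pair
linked by two channels contributes two edges, and degree counts that
multiplicity — the channels are treated as independent lines of
evidence. A unique-neighbor degree is available as an option.
**Feature genes** are the nodes with degree strictly greater than
`feature_degree_cut`; because any absolute cut is tied to the density of
a particular interaction database, a `feature_top_k` alternative (top-k
by degree, ties kept) is provided. On the synthetic studies below the
cut is 0 (every connected diff-gene is a feature gene) since the
simulated interaction graphs are far sparser than curated human
networks.

## 3. Directing edges: the Granger cascade

Only interacting feature-gene pairs are tested — the interaction network
restricts the hypothesis space, which is the point of the design. The
cascade per pair, in fixed gate order on the time-series expression:

1. **Pearson correlation**, two-sided, `alpha_pearson = 0.01`. A pair
   that is not contemporaneously correlated is dismissed
   (`not_correlated`) and never reaches a time-series test.
2. **Augmented Dickey–Fuller** unit-root test on each series (levels,
   then first differences; AIC lag choice), `alpha = 0.05`. Integration
   order 0 (levels stationary) or 1 (differences stationary); anything
   else — including constant series — is `not_testable`.
3. **Engle–Granger cointegration** when both series are I(1). A
   cointegrated pair is tested on levels; a non-cointegrated I(1) pair
   is `not_testable` under the default *gate* protocol. The alternative
   *difference* protocol first-differences such pairs instead. Pairs of
   mixed order (one I(0), one I(1)) are `not_testable` under the gate
   protocol, since no balanced level regression exists.
4. **Granger F-tests** in both directions at lag 1 (default; AIC
   selection up to `max_lag = 3` optional — 26-point series, the typical
   length of public dynamic expression sets, cannot support deep lags).
   A directed edge `a -> b` is emitted only when `p(a->b) < 0.05` *and*
   `p(b->a) >= 0.05`: the source must help predict the target while the
   target must not appreciably help predict the source. Pairs
   significant in both directions are recorded as `bidirectional` and
   emit no edge (optionally they could be treated as 2-gene feedback
   loops; off by default).

No multiple-testing correction is applied across pairs: each gate uses
its raw per-test alpha. This matches the per-edge decision framing; a
BH option across pairs would change the edge set's global error rate
and is left to the caller via the recorded per-pair p-values.

Directed edges replicate per underlying interaction channel so that
causal-vs-total counts per channel can be tabulated.

## 4. Globally independent genes

On the directed network, a gene is **globally independent** when its
in-degree is 0 — a source of a feed-forward subnetwork or a completely
isolated node — or when it belongs to a *feedback subnetwork*,
formalised as a nontrivial strongly connected component (or a
self-loop). Equivalently: in-degree 0 or on a directed cycle. Feature
genes none of whose pairs survived the cascade are isolated nodes and
therefore independent by default (`include_isolated=False` drops them).
These genes are the candidate dominant regulators.

## 5. Stepwise character selection

Candidates are ranked by single-gene accuracy under stratified 5-fold
Random-Forest cross-validation (default 500 trees, `sqrt(p)` features
per split, repeated with fresh fold seeds and averaged; out-of-fold
predictions are pooled into one confusion matrix per repeat). The
selector then loops:

* **while** `P_ACC − ACC_max > −ε` and candidates remain (`ACC_max` is
  the previous round's accuracy snapshot, initialised to −∞ so the
  first round always runs):
  * snapshot `ACC_max ← P_ACC`; **add** the candidate whose inclusion
    maximises CV accuracy (adopted unconditionally);
  * if the tolerance still holds, **remove**: every current member whose
    leave-one-out accuracy strictly exceeds the panel's accuracy is
    returned to the candidate pool, and the panel is re-scored.

Ties in every argmax break on higher MCC, then earlier initial rank,
then lexicographic gene ID — determinism requires a rule and this one
prefers the better-calibrated gene.

Two readings of the removal step exist: *remove the improvers* (the
default, matching the verbal description "abandon predictors whose
removal leads to higher accuracy") and the literal set-builder *keep
only the improvers* (`removal_semantics="pseudocode"`), which can
discard the panel's best members and even empty the panel; the
implementation then returns the best panel seen, with a warning. An
iteration cap (`max_iterations`, default 100) guards the add/remove
cycle that a static accuracy plateau can produce; gene-set scores are
memoized, so revisited panels cost nothing.

**Tolerance ε.** ε is the accuracy loss tolerated per round. With a
plateaued accuracy the loop condition only fails on a *drop* larger
than ε, so a generous ε lets the panel absorb weakly informative
candidates indefinitely. The library default is ε = 0.005; the
package's own synthetic studies use ε = 0 — the strictest "stop unless
the round strictly improved accuracy" reading — which is what keeps the
panel minimal. Injecting any deterministic scorer turns the selector
into a pure function of the score table, which is how the algorithm's
traces are verified against hand simulation.

## 6. Evaluation

ACC, SN, SP and MCC come from the pooled out-of-fold confusion matrix
(MCC is defined as 0 when a marginal vanishes). ROC curves sweep the
unique out-of-fold tree-vote fractions (ties grouped); AUC is the
trapezoid integral, which equals the tie-corrected Mann–Whitney
statistic. Validation datasets re-fit the fixed panel internally by CV
(each validation cohort is scored on its own folds); a transfer mode
would instead apply the discovery forest directly and is intentionally
not the default, since cross-platform expression scales differ.

## The synthetic studies

`synthetic.default_spec` defines the standard study: 40 genes, 60 tumor
and 60 normal samples, 150 half-hour time points. Exactly three genes
carry discriminative signal (tumor shift of 2.5 sd of the within-class
noise, sd = 1.0 on the log2 scale — a strong but realistic marker
effect); they double as the sources of six planted causal couplings
(VAR(1) coefficient 0.7 with self-coefficient 0.5, spectral radius
< 1, 50 burn-in steps discarded). The six coupling targets are
differential through the methylation channel only (beta shift 0.5) —
regulated genes whose expression change is not itself diagnostic — so
they join the network without adding classifier signal. Two further
moderate DEGs (1.2 log2 shift) keep the expression screen non-trivial,
and five differential miRNAs (2.0 log2 shift) feed the target channel.
Interaction edges are random at density 0.15 with every planted causal
pair guaranteed present. All generators are pure functions of
(spec, seed).

Study-scale pipeline settings: feature degree cut 0, 100 trees, 2 CV
repeats, ε = 0, iteration cap 40. With these conditions the pipeline
recovers a panel of ≤ 6 genes containing the planted markers with CV
accuracy above 0.95 across seeds; the directing cascade recovers a
planted 0.9-coefficient coupling in ≥ 90 % of runs and emits a directed
edge on white noise in well under 10 %.

What the synthetic studies do **not** show: the generators use Gaussian
class-conditional expression with independent genes (no correlation
structure, batch effects, or heavy tails), unimodal methylation betas
(real betas are bimodal), linear VAR(1) dynamics, and Erdős–Rényi-style
interaction graphs (no hubs or modules). Passing them demonstrates the
statistical machinery is calibrated and the algorithmic contracts hold;
it does not certify performance on real cohorts, where the degree cut,
lag policy and ε all need data-driven choices.

## Numerical and degenerate-input choices

* Matrices must be finite; missing values are rejected, not imputed.
* Zero-variance genes get t undefined → p = 1 and a `degenerate` flag.
* Constant series are `not_testable` at the Pearson gate.
* A numerically perfect level relationship (residual sd / response sd
  < 1e-10) is reported as cointegration p = 0 rather than passed to the
  Engle–Granger regression, which is singular there.
* BH-adjusted values are clipped to 1 and monotone in rank.
* CV fold seeds derive deterministically from (seed, repeat); the same
  config and seed reproduce byte-identical pipeline outputs.
* All identifier matching is exact and case-sensitive; mismatches are
  errors, never silent drops.
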