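# Methods

## Problem setting

A missense mutation is one amino-acid substitution in a protein, written
(protein, position, wild-type residue, mutant residue) with 1-based
positions. Predictors assign each substitution a binary functional class —
*deleterious* (impairs function / disease-associated) or *neutral* — plus
a confidence on a tool-specific scale that may be continuous (e.g. an
alignment score) or categorical (e.g. low/medium/high). Tools also differ
in coverage: a tool may return nothing for a mutation whose sequence
context it cannot process. The package combines such heterogeneous
predictors into one consensus classifier and quantifies the gain.

## Confidence calibration

Raw confidences are incomparable across tools, so each is transformed to
its *observed accuracy*: the empirical probability that the tool is
correct given its predicted class and confidence level, estimated on a
labeled benchmark. The relationship between confidence and accuracy can
differ between the two predicted classes (a tool may be overconfident only
when calling deleterious), so transformation functions are fitted per
(tool, predicted class) stratum.

* **Categorical scores** — observed accuracy is `correct / total` per
  category token within the stratum. Categories never seen in fitting are
  absent from the map; looking one up later raises a domain error rather
  than guessing.
* **Continuous scores** — records are sorted ascending by raw confidence
  (stable sort, mutation key as tie-breaker), partitioned into
  `n_bins = 60` equal-count bins, and the per-bin fraction correct is
  smoothed by a centered moving average over `smooth_window = 5` bins.
  Each bin is represented by the mean raw confidence of its members.
  Evaluation interpolates linearly between representatives and clamps to
  the terminal bin values outside the fitted range.

Numerical details, all deterministic:

* When the record count does not divide evenly, the first `n mod bins`
  bins take one extra record.
* The smoothing window truncates at the curve ends (the first bin of a
  5-window fit averages three bins) and weights by bin size where merging
  has made sizes unequal.
* Adjacent bins with identical representative confidence (possible only
  under heavy ties in the raw scale) are merged, count-weighted, so the
  curve remains a strictly increasing function of confidence.
* Small strata reduce the bin count to `min(n_bins, n // min_per_bin)`
  (at least 1) instead of failing; `min_per_bin` defaults to 5.
* Fitted curves are *not* forced monotone. Monotonicity is a property of
  well-behaved tools, verified in tests for simulated ensembles, not an
  assumption baked into the estimator.

PolyPhen-1-style three-class output is folded to the binary scheme at
parse time: *possibly deleterious* becomes a deleterious call with the
categorical token `"0.5"` (its nominal confidence on the tool's 0–1
scale), which then passes through categorical calibration like any other
category.

## Consensus vote

For one mutation, every non-missing tool contributes `sign * C` where
`sign` is +1 for a deleterious and −1 for a neutral call and `C` its
calibrated confidence. The consensus score is the mean over the `N`
contributing tools, hence bounded by [−1, +1] and by `max C` in magnitude.
Scores in [−1, 0] are classified neutral — the boundary belongs to the
neutral side — and (0, +1] deleterious. Renormalizing by the available
tools rather than the full ensemble size is what gives the consensus 100%
coverage despite constituent missingness; with at least one covering tool
per mutation the consensus always answers.

|score| is the consensus' own confidence. It is calibrated to observed
accuracy by exactly the continuous-tool procedure, with |score| as the raw
confidence, per consensus class, under the pseudo-tool name `consensus`.

Selective prediction (`select_top_confident`) keeps the
`ceil(fraction * n)` results of largest |score|, ties broken by mutation
key. This trades coverage for accuracy and mirrors the behaviour of
reject-option classifiers.

## Evaluation metrics

Benchmarks have unequal class counts, so threshold metrics are computed on
a *class-normalized* confusion matrix: each true-class row is rescaled so
positives and negatives carry half the total mass. This preserves
sensitivity and specificity exactly; normalized accuracy is therefore the
balanced accuracy (sensitivity + specificity)/2. MCC uses the standard
formula with the 0-on-zero-denominator convention. AUC is the rank
(Mann–Whitney) statistic with mid-rank ties — reweighting classes does not
change class-conditional score distributions, so AUC is computed once on
raw scores; the emitted ROC curve (one point per distinct threshold, via
scikit-learn) integrates to the same value by trapezoid, which the tests
check. Constituent tools, whose native scales may point either way, are
oriented for ROC analysis by the signed calibrated confidence
`sign * C`. Metrics are computed only over mutations a predictor actually
evaluated; coverage is reported separately.

Inter-tool agreement is the phi coefficient (Pearson correlation of
binary call vectors, deleterious = 1) over mutations both tools
evaluated; a tool constant on the shared set makes phi undefined and NaN
is returned. Residue-composition bias compares observed wild-type and
mutant residue counts with expectation under supplied background
frequencies, pooling the 40 observed/expected pairs into one Pearson
coefficient; exactly matching constant vectors return r = 1 (correlation
is otherwise undefined there).

## Leakage-free dataset construction

Stages, in order, each idempotent where meaningful:

1. **Conflict purge** — any mutation key labeled both neutral and
   deleterious across sources is removed entirely.
2. **Deduplication** — one record per key; the survivor records the
   sorted union of contributing sources. Output sorted by key, making the
   build independent of source concatenation order.
3. **Overlap removal** — a query position is *overlapping* when some
   alignment fragment with e-value ≤ 1e−10 and identity ≥ 0.5 (boundary
   inclusive) maps it, as a non-gap/non-gap column, onto a position
   mutated in the reference set; identical identifiers overlap directly at
   identical positions. Records at overlapping positions are dropped,
   first against training references, then against held-out references.

Identity is matched columns over total alignment columns, gaps included.
Position correspondence is by alignment column, not fragment containment:
a position inside a qualifying fragment is removed only if it actually
pairs with a mutated reference position.

Alignment fragments come from a pluggable producer. The BLAST tabular
adapter consumes the standard 12-column format; since that format carries
no alignment path, gapless HSPs (equal spans) map linearly, and gapped
HSPs are re-aligned from supplied sequences or rejected. The built-in
`PairwiseLocalAligner` is Smith–Waterman with BLOSUM62, gap open 11 /
extend 1; lacking Karlin–Altschul statistics it replaces the e-value gate
with a minimum fragment length of 30 alignment columns (emitted e-value
0.0). On unrelated random 200-mers this produces no qualifying fragment,
which the tests verify; it is an approximation adequate for desk-scale
inputs, not a BLAST replacement for genome-scale screens.

PMD-style activity annotations label records: `=` alone is neutral, any
other token set is deleterious, and a set containing `=` plus a change
token is excluded as self-contradictory. Quantitative activity changes
label deleterious strictly above a 0.5 relative-change threshold.

## Simulator

`generate_mutations` draws labels by a neutral-fraction parameter
(default 0.5) and residues from background database frequencies,
resampling the mutant until it differs from the wild type; keys are
de-duplicated deterministically. `simulate_tool` draws a confidence `c`
per mutation from the profile's (optionally class-conditional)
distribution, is correct with probability `a(c)` — constant, identity, or
logistic families — and missing with the profile's missing rate. Since a
wrong call on a labeled binary task is necessarily the opposite class,
the `class_bias` parameter (probability of calling deleterious when
wrong) only affects unlabeled inputs.

Correlation between tools uses one shared uniform *latent difficulty* per
mutation: with probability ρ a tool thresholds the shared draw instead of
a private one. Marginal accuracy is exactly `E[a(c)]` for any ρ, tools
are conditionally independent given the label at ρ = 0 (where the
pairwise phi has a closed form used as a test oracle), and ρ > 0 induces
positive correlation through shared successes on easy mutations. Every
tool consumes a stream sub-seeded by its name, so adding a tool never
perturbs the others, and all output is bit-reproducible given (spec,
seed).

The default ensemble has six tools with marginal accuracies between 0.65
and 0.75, informative confidences for five of them (one reports an
uninformative uniform confidence at constant accuracy), two categorical
tools, missingness 0–0.4 with one full-coverage member, and ρ = 0.2.
These defaults emulate the regime in which consensus prediction of
variant effects operates — several moderately accurate, weakly correlated
predictors — and they are the fixed study conditions of the test suite.
What the simulator deliberately does not model: the real tools' score
distributions, sequence-dependent error structure, shared evolutionary
inputs beyond the single latent knob, or any specific published tool.
Passing tests therefore demonstrate correctness of calibration, voting
and evaluation machinery under controlled conditions, not performance on
real proteomes.

## Problem sizes

The end-to-end experiments run at n = 20,000 mutations with a half split
(calibrate on 10,000, evaluate on 10,000) — large enough that binomial
noise on an accuracy is ~0.005 and the consensus-versus-best-tool gap
(~0.1) is unambiguous. Calibration-curve recovery uses n = 60,000 for a
~250-record stratum per bin. The whole suite and the acceptance script
each complete in well under a minute on one CPU.

## Known limitations

* The built-in aligner's length-for-e-value substitution is heuristic;
  for genuine benchmark construction, precomputed BLAST tabular output is
  the intended path.
* Calibration curves are estimated independently per stratum; no
  information is shared across classes or tools, and no isotonic
  correction is applied, so curves from small strata are noisy.
* The consensus assumes calibrated confidences are comparable across
  tools, which holds by construction here but only approximately when
  tools were calibrated on different benchmarks.
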