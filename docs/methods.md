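# Methods

## Problem and model

`essnet` classifies genes as essential or non-essential from functional
context alone: a gene is represented not by its sequence or expression but by
how strongly its interaction neighborhood is enriched in each annotation
gene set (GO terms, KEGG pathways). The premise is that essentiality is
concentrated in a limited set of core functions (ribosome biogenesis,
RNA processing, core complexes), so the neighborhoods of essential genes are
enriched in a recognizable subset of terms.

### Enrichment score

For gene *g* with neighborhood G(g) = {g} ∪ neighbors(g) (size *n*), term
*T* with *M* members in a background universe of *N* genes, and overlap
*m* = |G(g) ∩ T|, the feature is

    S(g, T) = −log10 P[X ≥ m],   X ~ Hypergeometric(N, M, n),

the upper tail including k = m. Conventions:

* **G(g) includes g itself.** An isolated gene has n = 1 and a well-defined
  (nearly all-zero) profile.
* **Background universe.** Defaults to the union of network nodes, all
  annotation members and the labeled genes; an explicit integer *N* (e.g.
  ~20,000 for the human genome) can override the count while keeping the
  membership universe for intersections. Term members and neighborhoods are
  intersected with the universe before counting.
* **Underflow cap.** When the tail probability underflows to zero the score
  is clamped at 320 (just beyond −log10 of the smallest positive double);
  the cap is configurable. m = 0 gives p = 1 and score 0 exactly.
* **No multiple-testing correction** — the scores are classifier features,
  not hypothesis tests.
* **Availability filter.** A labeled gene is dropped iff it is absent from
  the interaction network: without a neighborhood no enrichment profile
  exists. A present-but-isolated gene is kept (its vector is defined); a
  flag additionally drops genes whose entire score row is zero.

The feature vector is ordered with all GO columns before all KEGG columns;
tooling (the KEGG-only ablation, per-namespace reporting) relies on the
block layout.

### mRMR ranking

Mutual information is estimated with the discrete plug-in estimator after
per-feature discretization into three bins with edges at mean ± σ
(population σ), the convention of the original mRMR software. Values at or
below the low edge code 0 and at or above the high edge code 2: the worked
three-bin example (0,0,0,10,10,10) → (0,0,0,2,2,2) fixes boundary values to the
outer bins, and a constant column maps entirely to the middle bin. The class
label enters the estimator raw (binary). Logarithms are base 2; the greedy
D − R ordering is invariant to the base because relevance and redundancy
rescale together (property-tested). Ties on D − R, and on D for the MaxRel
list, break to the lower feature index so both lists are fully
deterministic. Exact mathematical ties between *different* joint tables are
resolved by floating-point rounding; the oracle tests treat such ties as
equivalent orderings.

The greedy loop is exact (no approximation): the first pick maximizes
relevance (R defined as 0 while nothing is selected), and each later pick
maximizes D − R with R the mean MI to all already-selected features.
Redundancy sums are accumulated incrementally — after selecting feature *s*
only MI(s, ·) against the remaining candidates is computed — which is
algebraically identical to recomputing R from scratch and is what the
brute-force oracle tests verify.

### IFS and the classifier

Prefixes F_k of the mRMR list are swept over k = k_min..k_max (defaults
5..500 step 1, i.e. 496 feature sets). All prefixes share one stratified
ten-fold partition: per class, sample indices are shuffled with the seed and
dealt round-robin, so fold class counts differ by at most one and every k is
scored on identical splits. Confusion counts are pooled (micro-averaged)
across the ten held-out folds — one SN/SP/ACC/MCC quadruple per k — rather
than averaging per-fold metrics, since pooled counts are well-defined even
when a fold lacks predicted positives. The optimal k is the smallest k
attaining the maximum MCC (parsimony on ties).

The default classifier mirrors an SMO-trained SVM at default settings:
`SVC(kernel="linear", C=1.0)` behind a `StandardScaler` fit on training
folds only. The classifier is pluggable (`ClassifierSpec`: `svm-linear`,
`linear-svc`, `logreg`) since IFS itself is classifier-agnostic. A training
split containing a single class is a hard error, not a silent skip.
MCC with any zero denominator factor is reported as 0 with an
`mcc_defined=False` flag; SN/SP are NaN when the corresponding class is
empty. Metrics are rounded to three decimals in outputs.

## Synthetic benchmark

The generator emulates the pipeline's three inputs with a planted, known
ground truth. Defaults (the package's study conditions): 1000 genes, 200
positives / 800 negatives (~1:4 imbalance, matching curated human
essentiality gold standards), 500 GO terms (cycled over BP/CC/MF) + 50 KEGG
pathways, 20 informative terms, term sizes uniform on 6..12, background edge
probability 0.005, planted wiring probability 0.5, seed 1.

Construction, in order, from one seeded generator:

1. Labeled genes are sampled; term members are drawn only from non-positive
   genes, so any enrichment a positive shows is mediated by its wiring, not
   its own membership.
2. The 20 informative terms draw their members first, and those members are
   excluded from the other 530 terms' draws. This is an identifiability
   choice: a background term overlapping an informative term's membership
   inherits its planted edges and becomes a genuinely class-correlated
   feature, and with unconstrained overlap such "aggregator" terms
   (containing members of several informative terms) dominate the relevance
   ranking and the planted terms are unrecoverable at any term size.
3. The background network is Erdős–Rényi over all gene pairs — a simple
   null; degree-distribution realism is a non-goal.
4. Each positive is assigned 1–3 informative terms, dealt from a shuffled
   cyclic queue so every informative term covers an equal share (~10%) of
   the positives, and is wired to each member of its terms with probability
   0.5. Negatives and unlabeled genes receive only background wiring.

Term sizes 6–12 are the scaled-down analogue of mid-size annotation sets: at
1000 genes (~1/20 of a genome) they correspond to real sets of roughly
120–240 genes. They also balance two failure modes observed at the extremes:
much larger terms inflate positive degrees until every term becomes weakly
class-informative, while much smaller terms (2–4 genes) leave a positive
assigned a single term with up to a 25% chance of drawing no planted edge at
all, capping attainable sensitivity.

**What passing on this benchmark shows — and does not.** The generator
exercises the enrichment arithmetic, the ranking, and the selection loop
under realistic imbalance and dimensionality, with a recoverable ground
truth. It does not mimic the GO DAG (no nested or overlapping terms), STRING
confidence-score distributions, scale-free degree structure, or annotation
noise; real-data performance claims cannot be read off these tests. In
particular, published headline numbers obtained on real STRING/GO/KEGG
snapshots (a specific optimal feature count, a specific MCC, specific top
terms) are outside what this package can or tries to reproduce.

## Numerical and design notes

* Hypergeometric tails come from `scipy.stats.hypergeom.sf(m−1, N, M, n)`,
  vectorized per gene over all terms; tests verify them to 1e−9 in p against
  explicit enumeration on instances up to N = 50.
* Edge-score thresholds (STRING-style 0–1000 confidence) default to 0 (keep
  all edges); duplicate edges collapse to the maximum score; self-loop rows
  are dropped with a warning but threshold-dropped edges still contribute
  their endpoints as nodes.
* Gene identity is the raw case-sensitive symbol; no alias resolution.
  GMT is the gene-set format with the namespace supplied per file (so KEGG
  ids like `hsa03013` need no parsing); matrix TSV headers carry
  `term_id|namespace` so a written matrix round-trips losslessly at six
  significant digits.
* Determinism: every stochastic step (generator, fold assignment) is
  driven by an explicit integer seed; rerunning any stage with identical
  inputs and seed reproduces results bit-for-bit.
* Default problem sizes in the test-suite and acceptance script —
  IFS bookkeeping on 100 samples × 600 features (full 5..500 step-1 sweep)
  and parameter recovery on the 1000-gene default config with k swept
  5..100 in steps of 5 — were chosen so the planted-signal regime (optimal
  k ≈ 20–40) is comfortably covered while a full run stays in the tens of
  seconds on one CPU.

## Known limitations

* The discrete MI estimator is the plug-in estimator without bias
  correction; with 3×2 tables and ≥100 samples the bias is far below the
  decision margins involved, but very small sample sizes would need care.
* Greedy mRMR is the exact textbook procedure, O(N²) MI evaluations; for
  feature counts far beyond ~10⁴ an approximate or chunked variant would be
  needed.
* The filter for unavailable genes is network-membership only; genes absent
  from the annotation universe but present in the network are kept (their
  rows are informative zeros).
* `FittedModel` persistence uses joblib and is not portable across major
  scikit-learn versions.
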