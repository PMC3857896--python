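# Methods

## The separability statistic

Every selection decision in this package reduces to one quantity: the
separability M of the two-class problem induced by a gene set.  For the n
samples restricted to the set, build the n × n kernel matrix, bring its
diagonal to 1 (column normalization for the linear kernel; automatic for
the Gaussian RBF kernel K(x, y) = exp(−‖x − y‖²/σ)), and score each column
*j* by

S_j = (mean_same − mean_opp) / (sd_same + sd_opp),

where the two populations are column *j*'s entries split by whether the
row sample shares sample *j*'s class; the self-similarity entry K_jj = 1
belongs to the same-class population.  M = Σ_j S_j.

Choices inside the statistic, and why:

* **Sum of standard deviations in the denominator, not a pooled
  variance.**  With unit self-similarity the same-class population of a
  non-trivial problem always carries spread, so the sum cannot vanish for
  well-posed inputs and no additive epsilon is needed.  The truly
  degenerate case (both populations constant — e.g. a constant gene under
  the RBF kernel, or a zeroed linear column) returns S_j = 0 with the
  column flagged and a warning logged, rather than aborting a pipeline.
  The statistic lives in one function (`kernels.column_separability`, with
  the vectorized equivalent `kernels._per_sample_scores` on hot paths) so
  an alternative rendering could be swapped in one place.
* **n−1 standard deviations** (t-statistic convention), configurable via
  `ddof`; a singleton population contributes spread 0.
* **RBF parameterization** K = exp(−‖x − y‖²/σ) with σ the tuned value.
  Any monotone re-parameterization (σ², 2σ²) merely relabels the tuning
  grid, so nothing downstream depends on the choice.
* **Column normalization of the linear kernel** divides column *j* by
  K_jj; the result need not be symmetric, and columns with K_jj below
  1e-12 are zeroed and recorded as degenerate.

## Selectors

**KMGS** scores each gene independently as a one-dimensional problem and
ranks by M (descending; exact ties go to the lower gene index so traces
are reproducible).  Gene evaluations are independent, and results are
identical regardless of evaluation order.

**KMSFS** starts from an empty set and a zero n × n accumulator A.  The
accumulated pairwise statistic is additive over genes in both kernels —
inner products for linear, squared distances for RBF — so a candidate
gene's joint problem is A plus a rank-one contribution, converted to Gram
entries by column normalization (linear) or exp(−·/σ) (RBF) and scored by
M.  The argmax joins the set (ties → lower index) and A absorbs its
contribution.  This is the only reading of the update that makes one step
O(m · n²) for both kernels; the test suite pins the trace to a naive
oracle that rebuilds every candidate Gram from scratch.

**Fisher's ratio** (μ⁺ − μ⁻)²/(s⁺² + s⁻²) is the baseline filter and the
prescreen used before heavy runs.  When both class variances vanish the
score is +∞ for differing means and 0 otherwise.

## Preprocessing

Normalized two-channel-style data go through row-then-column z-scoring:
samples first, then genes, so every gene ends exactly mean-0 / sd-1 —
the orientation that gene-wise kernel scoring consumes.  Raw
Affymetrix-style intensities go through the Dudoit pipeline: clamp to
[100, 16000], drop genes with max/min ≤ 5 or max − min ≤ 500 across
samples, then log10.  All four numbers are parameters with those
defaults.  Label recoding maps the first-seen class to +1.

## Error estimation

Gene selection is evaluated by the **external B.632+ bootstrap**: B
resampled sets (default 200), each of size n drawn with replacement, with
the *balanced* constraint that every sample occurs exactly B times across
the B sets (the plan permutes n·B index copies and cuts blocks; blocks
with empty out-of-bag or single-class in-bag trigger a bounded
re-permutation, and the plan is deterministic given its seed).  Selection
runs inside each in-bag set only; a linear SVM (scikit-learn SVC,
regularization C) trained on the in-bag top-g genes is scored on the
out-of-bag samples for g = 1..G (default 100).  err1 averages each
sample's out-of-bag misclassification rate over the sets where it is
out-of-bag; samples never out-of-bag (vanishingly rare under the balanced
design) are excluded with a warning.  The apparent error ērr and the
no-information rate γ = Σ_k p_k(1 − q_k) come from the full-dataset
pipeline, recomputed per gene count (the conservative choice).  The blend
is the standard .632+ rule: err1′ = min(err1, γ),
R = (err1′ − ērr)/(γ − ērr) clipped to [0, 1] (0 when undefined),
w = 0.632/(1 − 0.368R), estimate (1 − w)·ērr + w·err1′.

## Parameter tuning

Grid search over σ ∈ {10⁻⁵ … 10⁵} (RBF selectors) × C ∈ {10⁻³ … 10³},
all settings sharing one bootstrap plan so the G per-gene-count errors are
paired.  The G × k error matrix feeds the Friedman rank-sum test (ranks
ascending within each block, average ranks on ties, statistic
(12N/(k(k+1)))Σ(R̄_j − (k+1)/2)², chi-square with k−1 df).  If it rejects
at α (default 0.05), a best-vs-rest Holm step-down with
z = (R̄_j − R̄_best)/√(k(k+1)/(6N)) and two-sided normal p-values keeps the
best setting plus every setting not significantly worse; the reported
winner is the best-ranked member of that set, ties broken toward smaller
σ, then smaller C.  Best-vs-rest (k−1 comparisons) rather than all-pairs
is a documented design choice — the question asked is whether one setting
beats the rest, not the full ordering.

## Synthetic data

`generate_dataset` draws Gaussian class-conditional genes: null genes are
standard normal in both classes; *linear* DEGs shift the class means by
±δ/2 (δ in within-class sd units); *nonlinear* DEGs keep equal means but
scale one class's spread by ρ.  Gene positions are shuffled so planted
genes gain nothing from index tie-breaking, and the matrix passes through
the same row/column standardization as real data.  Defaults mirror the
study conditions exercised throughout the tests: n = 30 + 30 samples,
205 genes with 5 linear DEGs; δ = 1.5 for the moderate-recovery runs and
3 for the strong-signal error-curve runs; ρ = 3 for the variance-shift
probe.  The generator deliberately omits gene–gene correlation, batch
effects and heavy-tailed noise, so passing recovery tests demonstrate the
machinery on clean class-conditional structure, not performance on real
microarrays.

## Problem sizes and tolerances

Oracle-equivalence tests run 20–50 random instances at n ≤ 10, m ≤ 6 with
agreement at 1e-10 (1e-12 where arithmetic is exact); the end-to-end
recovery experiment uses n = 60, 205 genes, B = 50, G = 10 — sizes chosen
so the whole suite and the acceptance script finish in a few seconds on
one CPU while keeping every pipeline stage (selection inside bootstrap,
SVM scoring, .632+ blending) genuinely exercised.  The frozen recovery
floor (mean top-5 recovery ≥ 0.8 at δ = 1.5 over seeds 1–20) was
calibrated once with the independent naive scorer and left untouched.

## Known limitations

* Only two-class problems; multi-class extension is out of scope.
* Only linear and Gaussian RBF kernels are wired through the selectors.
* KMSFS cost grows as O(T · m · n²); for m in the thousands a Fisher
  prescreen (as in the standard protocol: top 1000) is the intended entry
  point.
* The printed-count check for the published leukemia matrix requires the
  original 72 × 7129 archive at `data/leukemia.mat`, which cannot be
  redistributed with the package.
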