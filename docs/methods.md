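# Methods

This note documents the statistical models, defaults and numerical
choices behind `cytoscreen`, and what the synthetic-data tests do and do
not establish about real cohorts.

## Data model and conventions

A cohort is a patients × variables matrix of continuous marker
expressions with a binary phenotype coded 0/1, 1 being the case class;
all downstream metrics assume this coding. Patients with any missing
value are dropped at load time — the pipeline never imputes, mirroring
the complete-case convention of the clinical setting it targets.
Training/validation splitting is simple random by default (a stratified
option exists); the reference scale throughout is 119 patients split
79/40. Standardization (z-scores, n−1 denominator for the SD) is always
fitted on training data; validation cohorts and subgroup members are
z-scored with training parameters, never their own.

## Conditional-inference forest

Split-variable selection is separated from split-point selection. At
each node, `mtry` candidate variables are drawn uniformly; each is scored
by the linear statistic T = Σᵢ xᵢyᵢ standardized by its permutation
moments (E[T] = n₁x̄, Var[T] = n₁n₀σ²ₓ/(n−1)), with a two-sided normal
p-value. The node splits only if the minimal Bonferroni-adjusted p-value
over the candidates is below `alpha` (default 0.05); otherwise it becomes
a leaf carrying its class-1 fraction. This is a concrete instantiation of
the conditional-inference framework: an asymptotic normal approximation
to the exact permutation test, with an optional Monte-Carlo permutation
p-value (`exact_split_test`, 999 shuffles) for nodes of ≤ 30 samples
where the approximation is weakest. The split point is the observed value
maximizing the standardized two-sample statistic of the induced
partition, with the left branch taking values strictly below it. A
consequence of splitting at observed values worth knowing: in perfectly
separated data the cut lands on the smallest in-bag case value, so the
single most extreme case patient can be misrouted when out-of-bag.

Defaults: `ntree=1000`, `mtry=5` (5 and 11 are the exercised settings),
`min_node=20` as the minimal size eligible for splitting with child
nodes of at least `min_node // 3`, bootstrap resampling of size n with
replacement (0.632·n subsampling without replacement behind a flag).
These stopping parameters are not prescribed by the source methodology
and are exposed in `ForestConfig`.

Variable importance is **unconditional** OOB permutation importance: per
tree, OOB accuracy at the 0.5 probability cut minus OOB accuracy after
permuting one variable's values among that tree's OOB rows; a variable
unused by a tree contributes exactly 0 for it. Conditional permutation is
deliberately not implemented — extensive testing in the source analysis
found it indistinguishable from the unconditional scheme at much higher
cost. Because single-forest importances are stochastic, the ranking of
record is the mean over `n_runs=20` independently seeded forests, sorted
descending with lexicographic name tie-breaks for reproducibility.

The tree growth and importance loops are numba kernels; each tree and
each importance pass is seeded from a `SeedSequence` chain, so forests
are bit-identical across runs for a fixed master seed.

## Feature-set enrichment

The ranked list is the Pearson (default) or Spearman correlation of each
variable with the 0/1 phenotype, sorted descending — signed mode — or by
absolute value. For a binary phenotype the Spearman case reduces to
Pearson on rank-transformed columns (the rank transform of a 0/1 vector
is affine), which is how it is computed. Ties are broken
lexicographically by variable name, making permutation p-values
order-independent.

The walk adds √((N−G)/G) at members and subtracts √(G/(N−G)) elsewhere;
algebraically the final sum is 0 and the supremum lies in
[0, √(G(N−G))], attained iff the members occupy the top G ranks. The ES
is the **signed supremum** of the running sum (so a set concentrated at
the bottom of the list scores 0, as the geometry implies); a max-|sum|
variant is available behind `absolute_es`. The best set size is the
ES-maximizing G, ties toward smaller G (parsimony).

Significance uses class-label randomization with full re-ranking: each
of `n_perm` (default 10,000) permutations shuffles the labels,
recomputes all N correlations, re-sorts, and re-runs the walk for the
*fixed* set. p = #{ES_perm > ES_obs}/n_perm by the strict counting
definition; an add-one smoothed estimate is behind a flag. Because ES is
a discrete function of member ranks, ties between permuted and observed
ES occur with positive probability and the strict count is slightly
liberal; on 200 null cohorts the p-values are nonetheless
indistinguishable from uniform by a Kolmogorov–Smirnov test. The
permutation loop is vectorized (one matrix product and one row-argsort
per chunk of permutations), so 10,000 permutations over ~100 variables
cost well under a second. Note the p-value is valid for a *pre-specified*
set; the p-value attached to the ES-maximizing G of the same data is
optimistically biased by selection, as the scan's null calibration test
illustrates.

## Randomized screening tools

A tool's thresholds live in standardized training units with ℓ_v < 0 <
u_v; the decision rule is "any member variable strictly outside its
bounds ⇒ case". Values exactly on a threshold count as in-bounds — an
arbitrary but fixed convention. Threshold draws are uniform on
(0, zmax_v] and [zmin_v, 0), the standardized training extremes,
anchoring the "positive upper / negative lower" reading of the rule; a
variable entirely one-sided after standardization (impossible for
self-standardized training data, possible for externally supplied
parameters) is widened to ±ε with a warning.

The search enumerates subsets lexicographically (sizes 3–6 by default;
the exact counts for a 27-variable pool are verified in the tests),
draws `realizations` (default 1000) threshold vectors per subset from a
generator keyed by (master seed, subset index) — so distributed
execution over subset ranges reproduces the serial result — and keeps
the global best under (OMR, −TPR, tool hash), retaining every co-optimal
tool. Each realization consumes one contiguous block of 2k uniforms, so
the first R draws coincide for any larger R (best OMR is monotone in the
budget, for nested seeds). Of the four historical candidate metrics,
metric (1) — predicted-positive count over (TP+FN) — is computed and
reported but never drives selection, because its original wording is
ambiguous; the two-level OMR/TPR policy is the selector.

A structural limitation, measured honestly by the planted-rule tests:
with 2k thresholds per tool, the best of K uniform draws has total
misclassification roughly proportional to K^(−1/2k), so a 4-variable
rule (8 thresholds) plateaus around OMR 0.10–0.15 at a few thousand
realizations per subset. Matching moderate planted thresholds to within
a few percent total error is beyond a desk-scale uniform search — which
is precisely why the source methodology resorted to HPC-scale search and
to CART pre-partitioning.

## CART pre-partitioning

The Gini tree considers every (variable, observed value) pair, left
branch strictly below the value; impurity decreases within 1e−12 are
treated as tied and broken by (variable name, value), so the fitted
split is reproducible against a brute-force oracle despite float
summation-order effects. Depth is capped by configuration; there is no
cost-complexity pruning — pruning happens implicitly by selecting the
pre-partitioning level with minimal validation OMR.

A "level" is tree depth; groups at level L are the depth-L nodes with
members of earlier-stopped nodes carried down, so every level partitions
the full cohort. Per-group searches re-fit standardization within the
group (dropping pool variables that are constant there); a group whose
governing parent group reached OMR = 0 inherits the parent's tool, as do
degenerate (< 2 patient) groups. A freshly searched group falls back to
its parent's tool if the parent tool scores better on the group — this
guarantees the training level curve is non-increasing in depth, which
the un-guarded search (a worse random draw at a deeper level) would not.
Validation never refits anything: patients are routed through the
training tree and scored with training-derived parameters and tools.

## Synthetic cohorts

The generator emulates two features of gated flow-cytometry panels:
block correlation (variables derived from the same staining panel are
highly correlated) via single-latent-factor equicorrelated blocks,
x_j = √ρ·f_b + √(1−ρ)·ε_j; and coordinated mixed-sign association via
per-variable shifts of `effect × phenotype` in SD units, so planted
signals survive standardization unchanged. The alternative mechanism
generates the phenotype *from* a planted any-out-of-bounds rule, making
the screening search's target exactly realizable. Defaults mirror the
motivating study's scale: 119 patients, 112 variables, prevalence 0.48.

What the generator does not emulate: non-Gaussian marginals (real gated
percentages are bounded and skewed), hierarchical parent/child gate
dependencies beyond pairwise equicorrelation, batch effects, and
label noise in the clinical phenotype. Passing recovery tests therefore
demonstrates correctness of the algorithms under a clean, favorable
signal model — not expected field performance on real cytometry data.

## Evaluation

The mean-only baseline predicts the training prevalence p for everyone;
in-sample its MSE is exactly p(1−p) and MAE exactly 2p(1−p), useful as
closed-form anchors. Forest probability errors (MAE/MSE against 0/1
labels) are reported both in-sample and out-of-bag, since the two can
differ dramatically — a forest can fit training data almost perfectly
while its OOB discrimination is near chance, which is exactly the regime
that motivates a separate screening-tool stage. ROC/AUC uses the
standard threshold sweep with trapezoidal integration (equal to the
normalized Mann–Whitney statistic). The end-to-end pipeline derives
every stage seed from one master seed through named spawn keys and logs
them, so any stage can be replayed in isolation; artifacts are
byte-identical across reruns of the same configuration.

Problem sizes used in the shipped tests and acceptance script (null
uniformity at 200×500 permutations on 60×30 cohorts; VIL recovery at
n=300, 50 variables, 20×20×500 trees; screening recovery at the
119-patient study scale; end-to-end at n=400, 40 variables) were chosen
to make the whole suite run in a few minutes on one CPU while keeping
each check statistically meaningful at its stated tolerance.
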