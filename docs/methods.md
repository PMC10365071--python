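# Methods

This note documents the models, numerical choices and simulation design
behind `unbgcn`, in the order the pipeline runs them.

## Biomarker construction

**Covariate adjustment.** Thickness at every vertex is adjusted by a
per-vertex OLS model on centered age and a centered gender dummy. Two
fitting policies are used, matching the two downstream paths:

- *Group-pattern path:* the model is fitted on the pooled AD+CU sample with
  diagnostic group retained as additional (centered) dummies, so age and
  gender coefficients are estimated while the group contrast — the signal
  of interest — is not regressed away.
- *Individual path:* the model is fitted on the CU reference only and then
  applied, with the reference's covariate centering, to every subject (and,
  for longitudinal data, to the follow-up visit unchanged). This treats the
  reference group as defining "normal aging" and measures each subject
  against it.

Because covariates are centered on the fitting sample, the adjusted values
are thickness evaluated at the sample-mean age/gender; the intercept and
group effects survive. A rank-deficient design (e.g. a single gender in the
fitting sample) raises `DegenerateDesignError` rather than silently
dropping a column.

**t → z transform.** `z = Φ⁻¹(F_t(t; df))` — the probit of the Student-t
CDF — evaluated through the survival function on the positive branch so
that |t| up to ~40 stays finite. The transform is exact, strictly monotone
and sign-preserving; the degrees of freedom used are recorded on the
pattern object.

**Atrophy patterns.** The group pattern is the pooled-variance two-sample
t statistic per vertex (AD minus CU; df = n_AD + n_CU − 2) mapped through
t→z; negative z means the AD group is thinner. The individual pattern uses
`t = (x − mean_CU) / (sd_CU · √(1 + 1/n_CU))` with df = n_CU − 1 — the
prediction-interval standard error, treating the subject as a new draw from
the reference population. Under that null the scores are exactly standard
normal, which the test suite verifies by Kolmogorov–Smirnov at 10,000
vertices. A vertex with zero reference (or pooled) variance raises an error
naming the vertex.

**UNB.** Per region, the inner product of the two z-maps divided by the
fixed constant 100. The divisor only sets the feature scale and is not
configurable. Concordant thinning (both maps negative) contributes
positively, so larger UNB = more AD-like; a reference-like subject scores
near zero on unaffected regions. The score is linear in each pattern
(scaling one map by c scales every UNB by c), which the suite checks, and
equals a naive double loop to ≤ 1e−12 relative error.

**Longitudinal UNBs.** For baseline/24-month pairs, the group pattern, the
CU reference distribution and the covariate model all come from the
baseline visit; the follow-up is adjusted with the baseline-fitted
coefficients and scored against the baseline reference. A moving reference
would absorb exactly the change the longitudinal statistics measure.

## Population graph

Edge weights count matching phenotypes: `W(m,n) = Σ_l α_l(m,n)` with α the
Kronecker delta for categorical phenotypes and the strict unit step
`|a − b| < θ` for numeric ones (a difference of exactly θ scores 0). The
default specification is gender (categorical) plus age and APOE ε4 allele
count (numeric, θ = 2). APOE is treated as numeric by default; a
categorical match is one configuration flag away. Entries are integers in
[0, P], the diagonal is zero, and the matrix equals the naive O(N²P) pair
loop exactly.

Two propagation operators are provided:

- the symmetric normalized Laplacian `L = I − D^{−1/2} W D^{−1/2}`
  (isolated nodes get the 0/0 → identity limit; eigenvalues in [0, 2]);
- the self-loop-renormalized averaging operator
  `S = D̃^{−1/2}(W + I)D̃^{−1/2}` (spectral radius ≤ 1).

**The network propagates with L by default.** Phenotype-count graphs are
dense — any two subjects share a gender with probability ~1/2 — and on a
dense graph the averaging operator contracts every node toward the global
mean at a per-hop rate of roughly (w_within − w_between)/(w_within +
w_between), which is near zero when the phenotype contrast between classes
is weak. Three such hops erase the node-level feature signal entirely,
making classification impossible regardless of training. L acts instead as
a difference (high-pass) filter — on a near-complete graph it approximates
mean-centering — and preserves the between-subject signal. The averaging
operator remains available (`ModelConfig.propagation = "renormalized"`) and
is the natural choice for sparse graphs.

## GCN with attention

Architecture: optional attention refinement of the input features, K = 3
hidden layers `H^(k+1) = relu(P H^(k) Θ^(k))` of width 16, a linear GCN
output layer, and a row-wise softmax. Whole-graph (transductive) training:
all nodes propagate, the masked cross-entropy sees labeled nodes only. The
suite verifies the transductive contract by corrupting held-out labels and
asserting bit-identical trained weights.

**Attention module.** Pairwise node dot products `Y = X Xᵀ` are
row-standardized (raw inner products scale with the feature dimension M and
would saturate the softmax), passed through a linear map `R^N → R^M`, and
softmaxed over the feature axis, giving a weight map A with nonnegative
rows summing to 1; refined features are `Z = X ⊙ A`. The network consumes
`M·Z`, so the uniform map A = 1/M — the zero-parameter initial state — is
exactly the identity and the module starts as a no-op; the constant is
absorbed into the first-layer weights and does not change the function
class. Disabling the module reproduces the plain GCN bit for bit.

**Optimization.** GCN weights: Adam (lr 0.01, weight decay 5e−4, 200
epochs), Glorot-uniform init, dropout 0.3 on the input of every hidden
layer during training only. Attention parameters: plain gradient descent
with step `attention_lr` (default 0.05) from zero init. Adam is
deliberately *not* used for the attention map: its per-coordinate step
normalization turns small noisy gradients into full-size steps, so the map
executes a random walk that drowns the systematic feature-relevance signal;
un-normalized descent accumulates gradients in proportion to their
magnitude, which is exactly what an interpretable relevance map needs.

**Interpretation vs. accuracy.** With dropout active, the per-epoch mask
noise dominates the attention gradient; the default small step keeps the
module conservative (accuracy-neutral). For feature-attribution analyses —
ranking regions by attention — train with `dropout=0` and a larger step
(e.g. `attention_lr=0.5`): gradients are then deterministic and the
informative features rise to the top of the ranking, which the suite
verifies on a fixture whose class signal lives in a single column.

**Ranking.** `rank_roi_attention` reports the column means of A normalized
to sum to 1, sorted descending; entries below the 0.05 display threshold
are flagged rather than removed. Prediction ties break to the lowest class
index. Node-permutation equivariance holds exactly when dropout is off
(dropout masks are drawn per array position, not per subject identity).

**Evaluation protocol.** `cross_validate` runs repeated stratified splits
(default 10 × 90/10); each repeat keeps held-out nodes in the graph as
unlabeled. Splits and per-repeat model seeds derive deterministically from
the master seed. The published protocol describes both "10-fold CV" and
"repeated 90/10 splits"; the repeated-split reading is implemented (k-fold
is a special case of the same machinery via `test_fraction`). `grid_search`
scores every combination by mean accuracy, breaking ties toward the smaller
model, then grid order.

## Evaluation statistics

- Minimum sample size `N = ceil(C σ²/(m−b)²)`, with σ the SD (ddof = 1) of
  per-subject 24-month change and m−b its mean. The constant C is not
  standardized in the source literature for this biomarker; the default
  `C = (z_0.975 + z_0.80)² ≈ 7.849` (80% power, two-sided α = 0.05) is the
  textbook convention and is configurable. Comparisons between biomarkers
  or groups are invariant to C; absolute values are not.
- Paired two-sided t-test; paired Cohen's d = mean(diff)/sd(diff).
- ROC AUC by the rank (Mann–Whitney) formulation, ties counted 1/2; 95% CI
  by stratified bootstrap (2000 resamples, seeded) since the analytic CI
  choice is not determined by the problem; curve points via scikit-learn.
- Confusion-matrix ACC/SEN/SPE with their defining identities
  property-tested over random labelings.
- ICV adjustment: volume/ICV, elementwise.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, not
the imaging physics. Per subject in group g, vertex v:

```
thickness = base(v) + age_slope·(age − mean age) + gender_offset·1[male]
            − effect_g·1[v ∈ affected ROI] + subject_offset + noise
```

with a 24-month follow-up subtracting a per-subject global decline
(group mean + heterogeneity) and redrawing the measurement noise. Defaults,
chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| group sizes | 84 / 102 / 132 (AD/MCI/CU) | typical amyloid-positive longitudinal cohort proportions |
| ROIs × vertices | 34 × 100 | left-hemisphere Desikan-Killiany; vertex count is a fixture scale, not an anatomical estimate |
| atrophy effects | 0.30 / 0.15 mm (AD/MCI) | typical temporoparietal thinning magnitudes |
| affected fraction | 0.3 (~10 ROIs) | AD signature is regional, not global |
| noise_sd | 0.20 mm | scan-rescan thickness variability scale |
| subject_sd | 0.05 mm | global thickness trait heterogeneity |
| age slope | −0.01 mm/yr | healthy-aging thinning rate |
| 24-mo decline | 0.10 / 0.05 / 0.02 mm | graded progression AD > MCI > CU |
| decline_sd | 0.06 mm | between-subject progression heterogeneity; without it longitudinal change is near-deterministic and minimum sample sizes degenerate to 1 |

APOE ε4 allele counts are drawn group-enriched (AD most); amyloid status is
a label only. What the generator does **not** emulate: spatial correlation
between vertices, registration error, hemispheric asymmetry, site effects,
non-Gaussian noise, or realistic effect-size/noise ratios — so passing
tests demonstrate the pipeline's correctness and qualitative behavior
(orderings, nulls, power trends), not clinical performance levels. The
cross-validated accuracies on synthetic cohorts are higher than one should
expect on real data.

`planted_feature_graph` is a separate sanity fixture for the classifier:
two Gaussian classes a configurable Euclidean distance apart, on a
phenotype graph that is only weakly class-correlated (mildly enriched APOE;
age and gender class-independent). The weak homophily is deliberate: the
graph must not carry enough class information to classify by itself,
otherwise the zero-separation null would sit above chance.

## Determinism and degenerate inputs

Every stochastic component (cohort draw, weight init, dropout, splits,
bootstrap) derives from an explicit integer seed through
`numpy.random.default_rng`; identical config + seed gives bit-identical
cohorts, training histories and artifacts. Degenerate inputs — zero
variance at a vertex, single-gender designs, empty masks, single-class
training sets, zero baseline in a change rate, non-positive ICV — raise
typed errors naming the offending element rather than propagating NaNs.

## Known limitations

- The attention linear map has N×M parameters on typically a few hundred
  labeled subjects; with aggressive steps it overfits, which is why the
  default step is conservative and the attribution configuration is
  separate.
- Whole-graph dense linear algebra: fine for cohorts of hundreds to a few
  thousand subjects, not engineered for biobank scale.
- The k-fold reading of the published protocol and inductive (graph
  rebuilt without test nodes) evaluation are not implemented; evaluation is
  transductive throughout.
- Real FreeSurfer inputs must be converted to the documented TSV layout;
  no direct `.thickness`/annot parsing is included.
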