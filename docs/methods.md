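# Methods

## Model overview

`targetox` treats drug toxicity as a property of the *network location* of
the drug's bound proteins (intended targets plus off-targets). The pipeline
is: scored protein network → diffusion state distances → learned reference
(landmark) proteins → per-drug feature vector → gradient-boosted binary
classifier → interpretation (SHAP, proteome-wide annotation).

## Diffusion state distance

For a connected undirected graph with binary adjacency A and degree matrix
D, the walk transition matrix is T = D⁻¹A and the stationary distribution
is πᵢ = deg(i)/2|E|. With P the matrix whose every row is π,

DSD(u, v) = ‖(bᵤᵀ − bᵥᵀ)(I − T + P)⁻¹‖₁.

Implementation notes:

* The inverse is obtained by one dense LU factorization and solve (never an
  explicit inverse loop); pairwise L1 distances between rows of the solve
  give an exactly symmetric matrix with a zero diagonal.
* Edge confidence scores act only as a filter (default ≥ 200 on the
  0–1000 scale); the walk itself runs on the unweighted graph. There is no
  evidence the original construction used weighted walks, and binary
  adjacency makes the stationary distribution exact and cheap.
* `dsd_iterative` implements the defining truncated series
  He^k(u) = Σ_{i≤k} bᵤᵀTⁱ and serves as an independent oracle for the
  closed form. Because (bᵤ − bᵥ)ᵀP = 0 and TP = PT = P, the series equals
  the Neumann expansion of the closed form term by term, and converges
  geometrically *when the walk is aperiodic*. On bipartite graphs the
  series oscillates for node pairs on opposite sides of the bipartition
  (same-side pairs still converge); convergence tests therefore sample
  non-bipartite graphs. Real protein networks are never bipartite.
* A disconnected input raises an error directing the caller to
  `main_component`; size ties between components break to the component
  containing the lexicographically smallest node.
* Node ordering is lexicographic everywhere, and every distance matrix
  carries its id index, so serialization (binary matrix + text id sidecar,
  or long-format TSV) is unambiguous.
* The discretized shortest-path variant maps hops < 3 to 1 and hops ≥ 3 to
  0. Its diagonal is 1 (0 hops < 3); self-distances are never consumed
  downstream, so this choice is inert.

## Reference-point selection

Candidates are all network nodes; each is scored by the one-sided
hypergeometric tail probability of the drug-binding-protein count inside
its neighborhood (all nodes within a DSD radius, the center included).
The hypergeometric test is the natural "enrichment" reading and matches
the Fisher's-exact convention used elsewhere in the pipeline. No
multiple-testing correction is applied at this step: the p-values rank and
gate candidates for clustering, they are not inferential claims.

Significant centers (p ≤ cutoff) are clustered by average-linkage
hierarchical clustering of their DSD row-vectors (Euclidean), cut at the
requested number of clusters; clustering in the same metric space the
features live in keeps each landmark representative of a distinct region.
Each cluster contributes the center of its *densest* neighborhood — most
drug-binding members, ties by smaller p, then lexicographic id — making
the output invariant to permutation of the candidate list.

The three free parameters are the radius (specified in DSD units, usually
derived from a distance quantile), the p cutoff and the cluster count.
`tune_reference_parameters` grid-searches them against 5-fold CV AUC;
infeasible cells (too few significant centers) are recorded, not fatal.
Pipeline defaults are the 1% distance quantile, p ≤ 10⁻³ and 12 landmarks;
12 matches the size at which the landmark encoding saturates on networks
with a handful of binding-protein concentrations.

## Functional impact

Annotations are propagated along `is_a` edges only: `part_of` and other
relations are excluded to keep the closure conservative and reproducible.
Information content uses natural log over propagated unique entity–term
pairs, IC(t) = −ln(|k_t|/|k|); propagated (not direct) counts are used
because inheritance is defined before the IC computation. FI of a protein
set is Σ IC(t) over the leaf frontier of the set's propagated term union —
terms with no proper descendant also in the union. Only the
biological-process namespace is used by default (configurable). Evidence
codes are not filtered by default; an allow-list is available. Proteins
missing from the corpus contribute nothing; a fully unannotated set warns
and scores 0.

## Classifier

A LightGBM binary-logistic ensemble with defaults of 500 rounds, depth 6
(63 leaves), learning rate 0.05, single-threaded and deterministic per
seed. Missing covariates stay NaN end to end — the trees route missing
values natively, so "missing" is distinct from any observed value
(tri-state route indicators: 1 / 0 / NaN). Boosted trees are
scale-invariant, so features are not standardized. Scores are raw margins
(log-odds); they are not calibrated to probabilities.

Evaluation: stratified 80/20 split; 5-fold stratified CV on the training
side with out-of-fold scores pooled into one ROC; AUC by the rank statistic
(ties count ½, verified in tests against exhaustive pair counting); the
optimal trade-off point maximizes sensitivity + specificity (Youden).
Leave-one-out scoring retrains without each drug in turn and is used for
group-level score comparisons.

SHAP attributions come from the ensemble's exact TreeSHAP computation and
satisfy additivity (attributions + expected value = raw score). Group
contrasts per feature use the unpaired two-sided Mann–Whitney rank-sum
test — the statistically appropriate form for two independent drug groups
— alongside a per-group allocation table of positive-attribution shares.

## Proteome annotation

Every protein of a druggable list becomes a simulated single-target
parenteral drug: real distances to the reference points, its own FI, and
all other covariates missing. After scoring, exactly ⌈0.1·n⌉ proteins form
the top decile (score descending, ties by lexicographic id). Their
reference-distance vectors are clustered with a Gaussian mixture fitted by
EM; the component count is selected by BIC over 1–10 unless fixed, and a
degenerate full covariance falls back to diagonal with a warning. Each
cluster × BP term with ≥ 2 annotated cluster members is tested by the
one-sided hypergeometric (Fisher) test against the supplied druggable list
as background — the annotation question is about the druggable genome, not
the whole proteome — with Benjamini–Hochberg correction across all tests.

## Synthetic benchmark

The generator emulates the structural premises of the method with known
ground truth:

* **Network**: planted-partition graph, default 600 proteins in 6 equal
  communities (within-community edge probability 0.08, between 0.004).
  Each community contains a denser core (20% of its nodes wired at 0.5)
  around a planted center; drug-binding proteins are the core nodes
  closest to the center. This mirrors the observation that drug-binding
  proteins concentrate in a few distinctive network regions, and it is
  what makes the planted centers recoverable by neighborhood enrichment.
  Edge scores are uniform over 200–999, plus 2% decoy edges scored below
  200 that the standard filter must remove. Smaller test configurations
  raise the core density to 0.8: a smaller graph needs a proportionally
  stronger planted signal at the same core-pair quantile.
* **Drugs**: 200 by default, 1–5 targets each. Every target comes from the
  home community's binding pool with probability `community_bias` (default
  0.9) and uniformly from the whole component otherwise, so bias 1.0
  plants perfectly compact bound sets and bias 0.0 yields the uniform null
  used by the compactness test. A drug is truly toxic iff it binds at
  least one protein of a hot-spot community (2 of 6 by default), and the
  emitted label flips that truth with probability 0.05. The flip is
  independent of all features, so the hot-spot indicator is the Bayes
  score and `oracle_bayes_auc` is an upper bound no classifier can
  systematically beat.
* **Ontology**: a rooted `is_a` tree (depth 4, branching 3; an optional
  multi-parent mode adds second parents so the frontier logic is exercised
  on true DAGs). Each community preferentially annotates into one depth-1
  subtree (bias 0.7), giving the cluster-enrichment stage real signal.
* **Covariates**: routes and plasma-protein binding are uninformative
  noise with 30%/40% missingness — only network position and FI carry
  label signal, which the SHAP tests exploit.

What the generator does *not* emulate: real degree distributions
(protein networks are heavy-tailed, not planted-partition), realistic GO
term counts and depths, correlated covariates (real route and binding data
do carry some toxicity signal), and multi-protein combination effects —
the generative rule is an OR over targets, so a single-target drug can
reach the top score, unlike real data where the highest risks arise from
combined effects of several proteins. Passing tests therefore validate the
machinery and its statistical behavior, not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script use the 600-protein default bundle for
end-to-end checks and 120–240-protein bundles elsewhere; dense DSD on
these sizes takes well under a second, and the full suite runs in a few
seconds. The walk-series oracle uses k = 10⁴ steps against a 10⁻⁶
agreement tolerance. Hypergeometric p-values are checked against exhaustive
enumeration at 10⁻¹², AUC against pair counting at 10⁻¹², SHAP additivity
at 10⁻⁶. Wilcoxon's signed-rank test with all-zero differences is defined
as statistic 0, p = 1 (no evidence of any difference). GMM fits use three
EM restarts and a 10⁻⁶ covariance regularizer.

## Known limitations

* The DSD solve is dense (O(n³) time, O(n²) memory): adequate into the
  low tens of thousands of nodes, but a full 16k-protein STRING component
  is near the practical ceiling on a laptop.
* Reference selection assumes the binding proteins are spatially
  concentrated; on a network where they are uniform, no neighborhood is
  enriched and selection correctly reports infeasibility rather than
  returning arbitrary landmarks.
* Raw scores are comparable within one trained model only; no calibration
  across models or datasets is attempted.
* The leave-one-out trainer refits one model per drug, which is the
  dominant cost for large drug sets; pass smaller tree counts through
  `hyper_params` when exploring.
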