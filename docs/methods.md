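# Methods

This note documents the models, defaults and numerical choices behind
`scsnf`, and what the synthetic-data generator does and does not
emulate.

## Similarity network fusion

Each standardized modality block yields a subject–subject Euclidean
distance matrix. Similarities use a locally adaptive Gaussian kernel

    W(i,j) = exp( −d(i,j)² / (2 (μ ε(i,j))²) ),
    ε(i,j) = ( m_K(i) + m_K(j) + d(i,j) ) / 3,

where m_K(i) is subject i's mean distance to its K nearest neighbours
(self excluded). We deliberately use the Gaussian-density form of the
kernel (bandwidth μ·ε inside a square) rather than the variant that
divides d² by μ·ε directly: the latter has a distance-scaled exponent,
and on standardized high-dimensional blocks (typical d ≈ √(2F) ≈ 40–70)
it concentrates all affinity on single nearest neighbours, which makes
spectral clustering of the resulting graph unstable. The density form
keeps the exponent scale-free (≈ −1/(2μ²) at typical distances) and is
what the fusion method's reference implementation computes.

Two normalizations feed the diffusion:

* full: P(i,i) = ½, P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)) — rows sum to
  1 with half the mass pinned on the diagonal;
* kNN: S is W restricted to each row's K nearest neighbours (self
  excluded; ties broken by lower index), row-normalized.

The cross-diffusion update replaces each modality's status matrix by
S_v · mean_{u≠v}(P_u) · S_vᵀ; after every iteration the matrix is
re-symmetrized and the P-form (diagonal ½) restored, so each status
matrix remains a proper random-walk smoothing target throughout. Variants
that skip the per-iteration renormalization exist; we restore it because
it keeps the T → ∞ behaviour bounded and matches the reference
convention. The fused network is the average of the final status
matrices, symmetrized. It is dense; at cohort sizes of a few hundred
subjects there is no reason to sparsify.

Defaults K = 20, μ = 0.5, T = 20 follow the reference implementation's
recommended ranges; no cohort-specific tuning is attempted, and all
three are exposed in `SNFParams` and the CLI config. For cohorts with
n < 3K the CLI clamps K to n/3.

## Consensus spectral clustering and model selection

Spectral clustering uses the symmetric-normalized Laplacian, the k
eigenvectors of smallest eigenvalue (dense `eigh`, exact at these n),
row-normalization of the embedding, and k-means with 25 seeded restarts.
Labels are canonicalized so cluster 1 contains the lexicographically
smallest subject identifier, making reports stable across runs; for
cross-run agreement the package additionally provides optimal label
matching (Hungarian assignment on the confusion matrix).

Consensus clustering draws ⌊0.8 n⌋ subjects without replacement for each
of 100 iterations, clusters the restricted affinity, and accumulates
co-cluster and co-sample counts; the consensus entry is their ratio. A
subject pair never co-sampled (probability ≈ (1 − 0.64)^100 per pair) is
an error advising more iterations. Final labels are obtained by spectral
clustering the consensus-proportion matrix itself at the same k — the
consensus matrix is a bona fide affinity, and reusing one clustering
engine avoids a second algorithm (the common alternative is a
hierarchical cut of the consensus tree).

The number of clusters is selected over k = 2…10 by mean silhouette with
dissimilarity 1 − consensus(i,j), each k scored on its own consensus
run; ties go to the smaller k. Computing silhouettes on the consensus
matrix rather than on the fused network rewards *stability* of a
partition under subsampling, which is the quantity consensus clustering
is designed to expose.

NMI between labelings uses the geometric-mean normalization
MI/√(H(a)H(b)); the degenerate case of two single-cluster labelings is
defined as 1 (vacuous agreement). Modality contribution re-runs the
identical consensus procedure on each modality's own kernel at the
selected k and reports NMI against the fused labels.

## Survival analysis

Two composite endpoints per subject, times in months (days / 30.4375):

* transplant-free: earliest of lung transplant and death;
* progression-free: earliest of the first post-enrollment FVC %
  predicted value ≥ 10 *percentage points* below the enrollment value
  (an absolute decline, not 10% relative), transplant, and death.

Subjects without an event are censored at last follow-up. Hazard ratios
come from lifelines' Cox partial likelihood (Efron ties, Wald 95% CIs).
Adjusted models add CPI and antifibrotic treatment status; antifibrotic
enters as a 3-level category (nintedanib / pirfenidone / neither,
reference "neither"), with a binary any-vs-none switch in the config.
Degenerate small-sample designs (complete separation, constant
covariates) are handled by dropping constant covariates and, if the
partial likelihood still diverges, refitting with a light ridge
(penalizer 0.1, then 1.0) — logged, and irrelevant at cohort scale.

CPI = 91.0 − 0.65·DLco% − 0.53·FVC% + 0.34·FEV1% (higher = more
severe). The baseline-characteristics table uses Kruskal–Wallis for
continuous variables and chi-square for categorical ones, with Yates
continuity correction for 2×2 tables only — the convention of standard
statistical software, and the one that reproduces published tables
computed the same way.

Agreement with an external binary risk grouping uses Cohen's kappa from
the 2×2 contingency table with the Fleiss–Cohen–Everitt asymptotic
variance for the 95% CI. Because the pairing of two unrelated binary
alphabets is arbitrary, the kappa under the agreement-maximizing
orientation is reported alongside the raw value.

## Classifier

Subtype classification uses protein + miRNA features only (the toRNA
block is excluded by default, configurable), 5-fold stratified CV, and
within each training fold: a random forest (500 trees) ranks all
features, the top 50 are kept, a second forest is refit on the screened
set, and the held-out fold is scored by ROC AUC of the predicted
subtype-1 probability. The reported ledger lists features screened in at
least 3 of 5 folds with the mean and SD of their refit importances
(Gini-based), flagging features present in all 5. "Iterations" are the
five CV folds, not repeats of the whole CV. The screening is strictly
training-fold-local; the suite contains a leak test that plants label
information only in held-out rows and verifies chance-level AUC.

Clinical consistency re-fits per-fold Cox models of the predicted labels
in the training and validation subsets for both endpoints; folds with no
events or a single predicted class yield an undefined cell rather than
aborting.

## Differential expression and enrichment

Per feature, OLS of expression on a subtype-1 indicator (optional
covariates behind a flag; unadjusted by default), two-sided t-test on
the subtype coefficient, BH adjustment *within each modality* (the
analyses report per-modality significant counts), significance at
q < 0.05, direction = sign of the subtype-1 − subtype-2 estimate.
Zero-variance features are skipped with a log line.

Significant miRNAs expand to the union of their validated target genes
(up- and down-regulated separately) through a user-supplied two-column
map. Over-representation of a query gene set in each pathway of a GMT
collection uses the right-tail hypergeometric probability
P(X ≥ k) for X ~ HG(N, K, m), BH-adjusted across the collection; the
default universe is the union of all pathway genes, overridable with a
measured background. Venn-region counts summarize overlap among
enriched-pathway sets.

## Synthetic-data generator

The generator is the package's stand-in for restricted registry data and
defines the conditions under which the pipeline is tested:

* **Omics blocks.** Gaussian on the post-normalization scale (the
  pipeline consumes already-normalized matrices; count-level simulation
  belongs to upstream QC, which is out of scope). Default 232 subjects
  in a 45/55 split; 1300 protein / 750 miRNA / 1600 toRNA features;
  informative fractions 0.10 / 0.15 / 0 (the toRNA block carries no
  subtype signal by construction); informative features' subtype means
  differ by effect_size × noise_sd = 2 SD, with alternating sign across
  features.
* **Clinical table.** Baseline FVC/DLco/FEV1 % predicted are Gaussian
  with subtype-1 shifted lower by ≈ 5–6 points (a severity gradient on
  the scale seen in IPF cohorts); CPI follows from its formula, so the
  subtype–severity confounding the adjusted models must handle is
  present. Antifibrotic category (0.18/0.36/0.46) and the demographic
  variables are independent of subtype, so adjustment changes nothing
  under the null.
* **Events.** Death and transplant are exponential clocks whose hazards
  multiply exp(log 1.8) for subtype 1 and exp(0.04·(CPI − 52));
  administrative censoring at 48 months plus exponential dropout
  (0.004/month). Longitudinal FVC sits on a fixed 4-monthly visit grid
  with subject-specific linear slopes (means −6.5 vs −2.5 %/year by
  subtype, SD 2) and visit noise (SD 2), the simplest structure that
  exercises the first-decline rule; visits stop at death, transplant or
  censoring. Admin censoring of 0 months is allowed as the degenerate
  everyone-censored case; only negative values are errors.
* **Risk grouping.** A severity-driven median split of CPI + N(0, 8)
  noise, so the external grouping tracks transplant-free survival but is
  only loosely tied to the molecular subtypes.
* **Not emulated:** missing visits and informative missingness, batch
  effects, count-level sequencing noise, aptamer chemistry, and any
  realistic gene–pathway biology (the GMT and miRNA-target resources the
  simulator writes are random and exist so the enrichment stage runs
  end-to-end). Passing tests therefore demonstrate correct and stable
  *machinery* under the planted model, not performance on real cohorts.

All randomness flows from one seed through fixed, CRC-keyed
derivations, so identical configs reproduce identical bytes on disk and
any pipeline stage can be re-run in isolation.

## Problem sizes used in the test suite

Planted-structure recovery runs ten full 232-subject fits with default
consensus settings; hazard-ratio recovery uses 100 replicates of 300
subjects; DE error control uses 2000 null features at n = 200 and a
1500/500 null/signal mix at n = 120; the consensus
standard-error-shrinkage and k-selection properties run on 24–60-subject
fixtures. These sizes were chosen to make the Monte-Carlo assertions
sharp (binomial/KS bounds at conventional α) while keeping the default
test run fast.

## Known limitations

* The fusion hyperparameters (K, μ, T) and the distance metric are
  method-level defaults; no claim is made that they match any specific
  cohort analysis, whose hyperparameters are generally unpublished.
* Competing risks (transplant vs death) are not modelled; both count as
  events in composite endpoints, as defined.
* The external risk signature's internal scoring is consumed as
  precomputed labels; a median-split plug-in is provided for users with
  their own scores.
* BH-FDR assumes feature-level independence or positive dependence;
  strongly correlated blocks can make the realized FDR conservative.
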