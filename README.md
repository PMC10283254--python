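# scsnf

Multi-omics molecular subtyping of patient cohorts by **S**pectral
**c**lustering on **S**imilarity **N**etwork **F**usion, with the full
downstream characterization a translational study needs: composite
survival endpoints and proportional-hazards models, agreement with
external risk signatures, a cross-validated subtype classifier, and
differential-expression / pathway over-representation analysis.

The package targets blood multi-omics studies of idiopathic pulmonary
fibrosis (IPF) — plasma proteomics, plasma miRNA and whole-blood total
RNA ("toRNA") profiles over the same subjects — but nothing in the
machinery is lung-specific: any set of subjects × features matrices
sharing a subject list can be fused and subtyped.

## Method

Given modality matrices X_v (subjects × features, standardized per
feature), the pipeline is:

1. **Affinity kernels.** Per modality, Euclidean distances d(i,j) are
   converted to similarities with a locally adaptive Gaussian kernel
   W(i,j) = exp(−d²(i,j) / (2·(μ·ε(i,j))²)), where ε(i,j) averages the
   two subjects' mean distances to their K nearest neighbours and
   d(i,j) itself.
2. **Similarity network fusion.** Each modality's full-normalized
   status matrix P_v (diagonal ½, off-diagonal row mass ½) is diffused
   through its K-nearest-neighbour transition matrix S_v against the
   average of the other modalities: P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ,
   re-symmetrized and re-normalized each of T iterations. The fused
   network is the average of the final status matrices.
3. **Consensus spectral clustering.** The fused network is clustered by
   normalized-cut spectral clustering (bottom eigenvectors of
   L_sym = I − D^{-1/2} W D^{-1/2}, row-normalized embedding, seeded
   k-means). One hundred subsampled runs (80% of subjects each)
   accumulate a co-clustering consensus matrix; final labels come from
   spectral-clustering the consensus matrix itself. The number of
   clusters k ∈ {2,…,10} is chosen by the mean silhouette computed on
   the dissimilarity 1 − consensus(i,j).
4. **Characterization.** Modality contribution by normalized mutual
   information (NMI) between single-modality and fused clusterings;
   Kaplan–Meier / Cox models (unadjusted and CPI + antifibrotic-adjusted)
   of transplant-free and progression-free survival, where progression is
   the first ≥ 10 percentage-point absolute decline in FVC % predicted,
   transplant, or death; Cohen's kappa against an external high/low risk
   grouping; a 5-fold cross-validated random-forest classifier with a
   ≥ 3-of-5 feature-selection ledger; per-feature OLS differential
   expression with Benjamini–Hochberg control per modality; and
   right-tail hypergeometric pathway over-representation of DE proteins
   and miRNA target genes.

Because real registry data of this kind are typically access-restricted,
the package ships a first-class synthetic-study generator
(`scsnf.simulate`) that plants a two-subtype structure in the protein and
miRNA blocks (none in toRNA), a severity gradient in baseline lung
function (hence in the composite physiologic index, CPI), and
subtype-dependent censored event times — so every stage is testable
end-to-end without any download.

## Worked example

```python
from scsnf import SimulationConfig, simulate_study, MultiOmicsSubtypeModel
from scsnf.snf import SNFParams

study = simulate_study(SimulationConfig(
    n_subjects=80, n_features={"protein": 120, "mirna": 80, "torna": 150},
    seed=11))
model = MultiOmicsSubtypeModel.from_blocks(
    list(study.blocks.values()), k_range=range(2, 6),
    consensus_iterations=50)
model.snf_params = SNFParams(K_nn=15)
res = model.fit(seed=0)
res.modality_contribution()
print(res.summary())
```

prints

```
Multi-omics subtype model (SNF + consensus spectral clustering)
===============================================================
subjects: 80    modalities: protein, mirna, torna
SNF: K_nn=15, mu=0.5, T=20
consensus: 50 iterations, ratio 0.8
selected k: 2
subtype sizes: 1: 40 (50.0%), 2: 40 (50.0%)
mean silhouette by k: 2: 1.000, 3: 0.774, 4: 0.635, 5: 0.506
modality contribution (NMI vs fused): protein: 1.000, mirna: 1.000, torna: 0.002
```

The silhouette profile peaks at k = 2 (the planted number of subtypes),
the labels split the cohort into the two planted groups, and the NMI
attribution shows that the protein and miRNA networks drive the fused
clustering while the toRNA network (no planted signal) contributes
essentially nothing.

The same analysis runs from the shell, one stage per subcommand:

```bash
scsnf --seed 7 --outdir run all        # simulate → cluster → … → report
scsnf --seed 7 --outdir run report     # re-collate headline numbers
```

Each stage writes plain TSV/JSON outputs plus a `run_manifest.json` with
SHA-256 digests; re-running with the same seed reproduces identical
digests.

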