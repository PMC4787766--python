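# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limitations of `pip3scope`.

## Study design

Five conditions of one epithelial cell background: WT, A66 (PI3Kα
inhibitor + EGF), A66 without EGF, PTEN knockout, and PIK3CA H1047R;
EGF stimulation time points 0/15/40/90/180/300 min (the no-EGF inhibitor
arm has a single 300-min group); triplicate libraries — 25 groups, 75
samples. Seven named contrasts drive the set logic:

| name | design | contrast | α |
|---|---|---|---|
| basal_pi3k | pairwise | A66_noEGF 300′ vs WT 0′ | 0.05 |
| induced_pi3k | interaction | A66 vs WT over the time course | 0.01 |
| egf_dep_wt | time course | WT across all six time points | 0.01 |
| chronic_pten | pairwise | PTEN_KO 0′ vs WT 0′ | 0.05 |
| chronic_pik3ca | pairwise | PIK3CA H1047R 0′ vs WT 0′ | 0.05 |
| induced_pten | interaction | PTEN_KO vs WT over the time course | 0.01 |
| induced_pik3ca | interaction | PIK3CA H1047R vs WT over the time course | 0.01 |

## Differential expression

Counts are modelled as NB(μ, α) with log link and per-sample offsets
log s_j, where s_j are median-of-ratios size factors (median over
all-positive genes of count/geometric-mean; a positive-entry fallback is
available for matrices without all-positive genes). The GLM is fitted by
iteratively reweighted least squares, vectorized across genes (shared
design matrix, batched weighted solves), converged when the relative
deviance change is < 1e-8, capped at 100 iterations, with the linear
predictor clipped to ±30 for numerical safety. All designs are tested by
likelihood ratio against the nested reduced model (pairwise included,
for uniformity across designs), with χ² p-values on the difference in
parameter counts and Benjamini–Hochberg adjustment (NaNs propagated).
Time is a categorical factor throughout.

Direction for LRT designs is the sign of the maximal-magnitude log2
coefficient across the tested levels (the non-reference condition and
interaction terms for interaction designs, the time levels for time
courses); pairwise designs report the single condition coefficient, with
`condition_a` as the tested condition and `condition_b` the baseline.

**Dispersion.** Per-gene maximum-likelihood α given fitted means
(method-of-moments initialization, two alternating IRLS/profile cycles,
bounded to [1e-8, 10]), with a Cox–Reid adjustment (−½ log det XᵀWX)
available to debias small-sample estimates. For inference, per-gene
CR-adjusted estimates feed a mean–dispersion trend α(μ) = a/μ + b fitted
by non-negative least squares with one outlier-trimming pass; a gene's
working dispersion is the trend value whenever the design leaves fewer
than 30 residual degrees of freedom (every triplicate design in this
study), and the per-gene estimate otherwise. This choice is deliberate:
with ≤ 3 replicates per group, raw per-gene ML dispersions are biased
low and make the LRT anticonservative, while the trend pools thousands
of genes. No shrinkage toward the trend, Cook's-distance outlier
handling, or independent filtering is performed — the stage trades those
refinements for transparency and is pluggable.

## Gene-set logic

`venn_regions` computes the exact 2ⁿ−1 region partition of any named
set system. The labelled mappings are configuration with defaults:

* set1 = (basal ∩ egf_dep) \ induced; set2 = basal only;
  set3 = basal ∩ induced (regardless of EGF dependence — the prose
  description does not constrain it); set4 = (induced ∩ egf_dep) \ basal.
* A/B = chronic in both mutants, C/D = PIK3CA-only, E/F = PTEN-only,
  G/H = no chronic effect but in the combined induced set; the first of
  each pair is the EGF-dependent half.

The full region partition is always emitted alongside the labels, so any
alternative reading can be recovered. The coherence filter retains genes
significant in all six contrasts with signs (+, +, −, −, +, +) over
(chronic_pten, chronic_pik3ca, a66_vs_wt, a66_noegf, induced_pten,
induced_pik3ca) — up in both activating mutants and down under the
inhibitor — or the exact mirror.

## Cluster stability

Profiles are z-scored per gene (population SD; constant rows map to
zeros and are flagged) and clustered by PAM on Euclidean dissimilarity
(on z-scores this is equivalent to a correlation distance up to an
affine map). PAM runs BUILD + best-improvement SWAP plus a small number
of seeded random restarts (default 2; tests of global optimality on tiny
instances use 4) — SWAP alone is a local search and the restarts make it
reliable at negligible cost. Stability: 100 resamples of the gene list
with replacement; duplicated rows are kept during re-clustering and each
reference cluster records its best Jaccard similarity against the
resample's clusters over the distinct genes present in the resample.
Stable ⇔ median ≥ 0.75 and SD ≤ 10% of the mean. The optimal k is the
largest k of the first contiguous all-stable run starting at k = 2 (a
"max stable k" rule is available); the first-run rule operationalizes
the caveat that Jaccard values trivially recover at large k. Default
k_max is min(10, n/20). Resampling the whole gene set (not per cluster)
follows the standard clusterwise-bootstrap scheme.

## Motif activity

Expression per promoter is log(size-factor-normalized count + 1); with
gene-level counts every promoter of a gene inherits the gene's
expression. After row- and column-centering E and column-centering the
site matrix N, activities per sample solve the ridge problem
A·s = (ÑᵀÑ + λI)⁻¹ÑᵀE·s and are centered per motif across samples.
λ defaults to 5-fold promoter-wise cross-validation on a logarithmic
grid (scaled by the promoter count), with a fixed fold-assignment seed.
Standard errors come from the ridge covariance diagonal times per-sample
residual variance (residual df = P − tr(H)); z_m = √(mean_s (A_ms/σ_ms)²).

S_pm is the increase in residual sum of squares when motif m's sites are
removed from promoter p with activities held fixed — in closed form
2·N_pm·(r_p·A_m) + N_pm²·‖A_m‖², clipped at zero, zero exactly when
N_pm = 0, and divided by the mean residual variance to be dimensionless.
S_m(gene) is the maximum S_pm over the gene's promoters (one score per
target). The strongly-regulated table keeps motifs with z ≥ 2 and genes
with S_m strictly > 20; because the score scale depends on the data
scale, the threshold is a parameter and a quantile can be supplied
instead when comparing across datasets.

## Comparison and enrichment statistics

S_m distributions of a motif's targets (S_m > 0) in two gene sets are
compared with the two-sample KS test (asymptotic p, effective
n = n_a·n_b/(n_a+n_b)) and the Mann–Whitney test (normal approximation
with tie correction and continuity correction — set sizes here are tens
to hundreds; exact enumeration serves only as a test oracle). Motifs
with fewer than 5 targets per set are skipped with a note; results sort
by descending D. Both tests are reported; no combination rule is
applied. Term enrichment is the classical one-sided hypergeometric
upper tail, significant at raw p < 0.05 (BH-adjusted values are provided
as columns but not used for the default call — fidelity to the classical
procedure over rigor, by design). QC provides the Pearson correlation
matrix of samples (NaN for zero-variance columns) and PCA by SVD of the
double-centered matrix.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions. Per-gene categories (largest-remainder rounding of the
configured fractions, then shuffled): 51% null, 10% + 10% + 8% chronic
(PTEN / PIK3CA / both, random sign, ±effect_log2fc = 2 at all time
points), 7% + 7% EGF-responsive (impulse-like rise–peak–decay shapes
peaking at 15–40 or 180–300 min, shared by all EGF-stimulated
conditions), 2% basal-PI3K (shift only in the no-EGF inhibitor arm),
2% induced-PI3K (EGF response attenuated by 80% under A66), and
1.5% + 1.5% coherent (up in both mutants, down under the inhibitor, and
mirrored). The proportions put chronic remodelling at the
thousands-of-genes scale, acute PI3K effects at the hundreds scale, and
the coherent core at ~3% of genes, matching the qualitative "butterfly"
structure the pipeline is meant to expose at a 4000-gene problem size.

Counts: μ_gs = L_s · softmax_g(baseline + planted log2 effects + motif
term), with baseline log2 abundances N(0, 1), library sizes log-normal
(mean 5e5, CV 0.1; each column is normalized to its drawn total, a
factor absorbed exactly by size factors), and NB noise with
α(μ) = 1/μ + 0.05.

Motifs: 20 motifs, 4 active. Active motifs carry mutually orthogonal
smooth activity programs over the six time points (QR decomposition of a
random 6×6 matrix, anchored at the unstimulated state, unit
peak-to-trough range, scaled by amplitude 0.5 in log2 units); the no-EGF
arm keeps the t = 0 activity, making the programs EGF-driven.
Orthogonality matters: correlated programs leak one motif's signal into
another's target scores. Targets (15% of eligible genes per active
motif; the first active motif instead targets 60% of the
`chronic_both` category and is that category's *only* active regulator,
giving the comparison stage its planted Fig-8-like contrast) receive
1 + Poisson(1.5) functional sites on **all** of the gene's promoters —
expression is gene-level, so a promoter without the gene's regulatory
content would carry unexplained signal. All promoters additionally get
Poisson(0.5) non-functional background sites, making the emitted site
matrix noisy evidence of regulation, as real site annotations are.
Genes whose planted logic requires the *absence* of an EGF response
(basal-PI3K, induced-PI3K) are excluded from motif targeting.

Annotation terms: one designated term per non-null category drawn with
20× the background odds (background inclusion probability 0.05 per
term).

**What the generator does not emulate:** batch effects, GC/length bias,
isoform structure, promoter-level quantification, correlated gene–gene
noise, outlier samples, and realistic motif libraries. Passing the
recovery tests therefore demonstrates that the pipeline's logic and
estimators are correct under the declared noise model — not that the
thresholds (S_m > 20, z ≥ 2, Jaccard 0.75) are optimal for any real
dataset.

## Numerical choices and problem sizes

All randomness flows from explicit seeds (numpy `default_rng`); the
pipeline is byte-reproducible under a fixed config. Degenerate inputs:
all-zero genes get NA p-values; constant profile rows are flagged;
rank problems in the ridge are handled by the penalty; bounded
dispersion optimization snaps to a boundary when the boundary is as
good as the interior optimum. Test and acceptance runs use 400–4000
genes, 100 bootstrap resamples, and 3–10 seeds per stochastic check —
sizes chosen so the whole suite exercises every stage end to end in a
few minutes while leaving comfortable statistical margins.

## Known limitations

* The NB-GLM stage is intentionally simpler than mature DE packages (no
  shrinkage, no outlier refitting); on real low-count data its error
  control depends on the trend fit.
* The S_pm/S_m score scale is dataset-dependent; the absolute threshold
  of 20 is kept for interface fidelity and should be replaced by a
  quantile when scales differ.
* With gene-level counts, multi-promoter genes cannot be resolved at the
  promoter level; the max rule makes S_m insensitive to this, but
  promoter-specific regulation is out of reach.
* The A66-no-EGF baseline is the WT 0-min group (no 0-min library exists
  for that arm); the comparison is configurable.
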