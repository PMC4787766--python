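# pip3scope

Analysis pipeline for bulk RNA-seq time courses probing **PI3K/PIP3
signalling**: how chronic pathway activation (PTEN knockout, PIK3CA
H1047R) and acute pharmacological inhibition (the PI3Kα inhibitor A66,
with or without EGF stimulation) remodel the mRNA landscape of an
epithelial cell line over an EGF time course (0/15/40/90/180/300 min,
triplicate libraries, 25 condition×time groups, 75 samples).

It is written for computational biologists who want the full chain of
that study design as tested, reusable components:

1. **Differential expression** — negative-binomial GLM with log link and
   median-of-ratios size-factor offsets. Three designs: *pairwise*
   (single condition/time factor, likelihood-ratio test, adjusted
   p < 0.05), *time course* (time factor vs intercept, adjusted
   p < 0.01), and *interaction* (condition + time + condition:time vs
   time only, adjusted p < 0.01), with Benjamini–Hochberg correction.
   The per-gene dispersion α follows the trend α(μ) = a/μ + b fitted
   across genes.
2. **Gene-set logic** — Venn regions of the basal-PI3K, induced-PI3K and
   EGF-dependent sets (sets 1–4), the chronic × induced × EGF-dependence
   regions (sets A–H), and the *direction-coherence filter*: genes up in
   both activating mutants and down under the inhibitor (or the exact
   mirror) across all six contrasts.
3. **Cluster stability** — PAM (k-medoids) on z-scored profiles with a
   bootstrap Jaccard criterion: a cluster is stable when its median
   Jaccard over 100 gene resamples is ≥ 0.75 with SD ≤ 10% of the mean;
   the optimal k is the largest k of the first contiguous all-stable run
   from k = 2.
4. **Motif activity** — a MARA-style linear model E_ps ≈ Σ_m N_pm·A_ms
   (promoter expression from motif site counts times sample-wise motif
   activities), fitted by ridge regression with promoter-wise
   cross-validated penalty; per-motif z-values; per-promoter strength of
   regulation S_pm (increase in misfit when a motif's sites are removed
   from a promoter) and per-gene S_m via the max-over-promoters rule;
   filters z ≥ 2 and S_m > 20.
5. **Comparison statistics** — two-sample Kolmogorov–Smirnov and
   Mann–Whitney tests on S_m distributions between gene sets (sorted by
   the KS D statistic), classical Fisher (hypergeometric) term
   enrichment, and sample-level QC (Pearson correlation matrix, PCA).

A first-class **synthetic-data generator** emulates the study design
with planted structure (chronic shifts, impulse-like EGF responses,
PI3K-dependent subsets, coherent genes, motif-driven expression), so the
entire pipeline is exercised and tested without any external data.

## Worked example

```bash
pip3scope run-all --seed 1 --out demo_run
```

runs simulate → de → sets → cluster → motifs → compare → enrich → qc on
a 4000-gene synthetic dataset and finishes in well under a minute. The
log and `summary.json` of that run show, among others:

```
de:chronic_pten   design=pairwise    alpha=0.05  n_significant=877
de:induced_pi3k   design=interaction alpha=0.01  n_significant=198
"butterfly_ratio": 6.59
"set_sizes": {"set2": 86, "set3": 116, "set4": 77, "A": 223, "B": 222,
              "coherent_up": 54, "coherent_down": 58, ...}
"top_motif_by_d": "M00"
```

Reading these numbers: the chronic PTEN-knockout contrast changes ~4×
more genes than the acute inhibitor contrast at matched thresholds (the
union over both mutants gives the `butterfly_ratio` of 6.6) — a single
chronic pathway mutation remodels the transcriptome far more broadly
than acute inhibition. Only ~112 genes (coherent_up + coherent_down)
change coherently with the directional PIP3 logic across all six
contrasts, the candidate direct targets. The motif comparison stage
ranks `M00` — the planted regulator of the chronically affected genes —
first by KS D (D = 0.84, p ≈ 8e-31), with the Mann–Whitney test
agreeing, mirroring how a motif that specifically drives one gene set
surfaces from the S_m score distributions.

Every stage can also be run standalone on a run directory
(`pip3scope de|sets|cluster|motifs|compare|enrich|qc --run-dir demo_run`),
and a YAML config can replace the flags (`pip3scope run-all --config
config.yaml`). Re-running with the same seed reproduces every output
file byte for byte (`MANIFEST.tsv` carries SHA-256 checksums).

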