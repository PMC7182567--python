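# phlike

Targeted RNA-Seq classification of **BCR-ABL1-like (Ph-like) B-cell acute
lymphoblastic leukemia**, with the clinical association and competing-risks
outcome analysis that goes with it.

Ph-like B-ALL lacks the t(9;22) *BCR-ABL1* fusion but shares its
gene-expression signature and its poor prognosis. Identifying it from
full-transcriptome profiling is expensive; a 42-gene targeted panel
(38 signature genes plus the control genes *GUSB*, *JUN*, *PBGD*, *TBP*)
makes the call affordable for routine diagnostics. This package implements
the complete desk side of that workflow for hematology research groups:

1. **Panel normalization** — raw amplicon counts → reads-per-million
   (RPM, each sample scaled to 10⁶ panel reads) → gene/sample QC →
   intra-patient normalization by the best housekeeping gene. The
   housekeeping gene is chosen as the candidate *h* maximizing the mean
   pairwise inter-sample Spearman ρ of the *h*-normalized profiles.
2. **Signature classification** — unsupervised hierarchical clustering of
   samples with one-minus-Pearson-correlation distance, *d(i,j) = 1 −
   r(xᵢ, xⱼ)*, and average linkage (UPGMA); the tree is cut into *k*
   clusters (default 2) and the cluster overexpressing the up-markers
   *ECM1*, *ENAM*, *IGJ*, *CRLF2* while underexpressing *MDFIC* is labeled
   `PH_LIKE`.
3. **Molecular features** — *CRLF2* qPCR positivity by 2^−ΔΔCt against
   *GAPDH* (positive at ≥ 0.1%), IKZF1/CDKN2A/B deletion and codeletion
   status from MLPA calls, per-gene mutation flags.
4. **Association tests** — Fisher's exact test (two-sided,
   point-probability rule), Pearson χ² without continuity correction,
   Mood's median test, and the conventional chooser (Fisher when any
   expected count < 5).
5. **Outcome analysis** — Kaplan–Meier with Greenwood variance and
   log-log CIs, the log-rank test, the Aalen–Johansen cumulative incidence
   of relapse with death-without-relapse as a competing risk
   (CIF₁(t) = Σ_{tᵢ≤t} Ŝ(tᵢ⁻) d₁ᵢ/nᵢ), Gray's two-sample test on the
   subdistribution hazard, and univariable Cox regression (Efron ties).
6. **Synthetic cohorts** — a seeded generator of complete cohorts
   (negative-binomial panel counts with a planted 25% Ph-like subgroup,
   qPCR Cts, lesion/mutation flags, competing-risks outcomes) so that
   every stage can be exercised and calibrated without patient data.

## Worked example

Generate a synthetic cohort of 80 patients, classify it, and compare
outcomes by signature label:

```bash
phlike simulate --seed 17 --out ex/
# wrote cohort of 80 samples (20 planted Ph-like) to ex

phlike classify --counts ex/counts.tsv --panel ex/panel.json --out ex/cls/
# 80 samples classified; 20 PH_LIKE -> ex/cls
```

`ex/cls/signature_calls.tsv` holds one call per sample:

```
sample_id  cluster  label        marker_score
P001       0        NON_PH_LIKE  -1.0402726710885795
P002       1        PH_LIKE       3.1208180132657195
P003       1        PH_LIKE       3.1208180132657195
```

`marker_score` is the mean z-scored log₂ expression of the up-markers
minus that of *MDFIC* for the sample's cluster; the cluster with the
highest score is the Ph-like one. The directory also contains the RPM and
normalized matrices, QC report, Newick dendrograms for samples and genes,
a heatmap-ready matrix ordered by both trees, and per-marker Mood's
median tests.

```bash
phlike outcome --calls ex/cls/signature_calls.tsv --clinical ex/clinical.tsv \
               --mutations ex/mutations.tsv --out ex/oc/
```

prints (excerpt) the log-rank and Gray's test comparisons by label:

```
"dfs": { "logrank_p": 0.0536, ... }
"cir": { "gray_p": 0.495, "gray_stat": 0.465,
         "cif_at_horizons": { "NON_PH_LIKE": {"4.0": 0.450, ...},
                              "PH_LIKE":     {"4.0": 0.611, ...} } }
```

i.e. the planted group's 4-year cumulative incidence of relapse is 61%
versus 45%, with Gray's test not significant at this sample size.
Subgroup analyses are one flag away, e.g.
`--subset mrd_induction=negative` restricts the comparison to
MRD-negative patients.

Single contingency tables can be tested directly:

```bash
phlike stats table --table 9,5,3,25
# method=fisher_exact statistic=NA p=0.000628246
```

## Library use

```python
from phlike import (SimulationConfig, simulate_cohort, compute_rpm,
                    filter_genes, select_housekeeping,
                    normalize_to_housekeeping, classify_samples, DEFAULT_PANEL)

cohort = simulate_cohort(SimulationConfig(), seed=1)
rpm = compute_rpm(cohort.counts)
rpm, qc = filter_genes(rpm, DEFAULT_PANEL)       # drops SCHIP1, IFITM1
hk, scores = select_housekeeping(rpm, panel=DEFAULT_PANEL)
calls, tree = classify_samples(normalize_to_housekeeping(rpm, hk), DEFAULT_PANEL)
```

See `docs/methods.md` for the statistical methods, default parameters and
their rationale, and known limitations.
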