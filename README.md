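# kmscreen

Transcriptome-wide prognostic biomarker screening for (serous) ovarian
cancer expression cohorts: multi-cohort integration with scaling
normalization, an exhaustive quartile-bounded cutoff-scan survival screen,
multivariate Cox adjustment, PFS/OS significance concordance, and
hypergeometric over-representation analysis — together with a synthetic
multi-cohort generator with planted hazard effects so the whole pipeline can
be validated end to end without any patient data.

## Who this is for

Researchers who want to rank genes by how strongly a dichotomized expression
level separates survival curves across pooled microarray cohorts, and who
need the screen's every step (normalization, cutoff choice, multiplicity
correction, filters) to be explicit, tested and reproducible.

## The method

For each gene with expression values *x₁ … xₙ* and right-censored survival
times, the screen:

1. takes every distinct observed value *c* with *Q₁ ≤ c < Q₃* (lower/upper
   quartiles, linear interpolation) as a candidate cutoff;
2. splits samples into low (*x ≤ c*) and high (*x > c*) groups and computes
   the two-group log-rank statistic χ²(c) = (O−E)²/V and its p-value at
   every candidate (this equals the Cox score test for the binary split);
3. applies the Benjamini–Hochberg step-up FDR across the gene's cutoff
   series and selects the cutoff with the lowest FDR — ties broken by the
   highest Cox hazard ratio (Efron tie handling), then by the smallest
   cutoff;
4. estimates HR (high vs low) with its Wald 95% CI at the selected cutoff.

Study-level filters affect ranking only: genes whose selected cutoff is
below 200 intensity units (twice the ~100-unit array background) are
deprioritized, and risk-direction genes (HR > 1: higher expression, worse
prognosis) rank before protective ones. Before merging, each array is
rescaled so that its mean over the probe panel shared by all platforms is
exactly 1000. Significant genes can then be adjusted for stage, grade,
debulking and optional cell-type scores in a multivariate Cox model,
compared across the PFS and OS endpoints with a 2×2 chi-square, and tested
for gene-set over-representation with the hypergeometric upper tail.

## Worked example

```python
from kmscreen import (PlantedEffect, SimConfig, simulate_study,
                      merge_cohorts, screen)

cfg = SimConfig(
    n_cohorts=1, samples_per_cohort=(600,),
    n_genes_total=200, n_shared_genes=200,
    planted_effects=(PlantedEffect("G0001", 0.5, 2.0, "both"),),
    seed=11,
)
study = simulate_study(cfg)
merged = merge_cohorts(study.cohorts, study.probe_map)
table = screen(merged, endpoint="os").table
print(table.head(1)[["selected_cutoff", "fdr", "hr", "direction"]])
print("true cutoff:", round(study.truth["realized_cutoff"].iloc[0], 1))
```

prints

```
       selected_cutoff           fdr        hr direction
gene
G0001       518.687378  3.534132e-10  2.095059      risk
true cutoff: 504.3
```

The planted risk gene (true HR 2.0, cutoff at the median of its intensity
distribution) is ranked first out of 200 genes; its selected cutoff lands
within ~3% of the latent truth and the estimated hazard ratio of 2.09 sits
inside the sampling error of the planted effect.

The same pipeline is scriptable from the shell:

```bash
kmscreen simulate --out study/ --seed 11 --planted G0001:0.5:2.0:both
kmscreen screen --data-dir study/ --endpoint os --out results/
kmscreen report --data-dir study/ --out results/
```

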