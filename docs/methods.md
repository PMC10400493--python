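# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that make
results deterministic.

## Cutoff-scan survival screen

**Candidate cutoffs.** For a gene's expression vector the candidates are
the distinct observed values `v` with `Q1 <= v < Q3`, where the quartiles
use linear interpolation between order statistics (the numpy default).
Restricting to the interquartile range guarantees both groups hold at least
a quarter of the samples; using observed values makes the scan invariant to
any strictly increasing transform of the expression scale. A constant
vector has no candidates and the gene is skipped (its row is kept with
missing statistics so the gene universe is preserved). The boundary is
half-open — a value exactly at `Q3` is not a candidate; since `x > c`
defines the high group, a cutoff at `Q3` would duplicate the split of the
largest candidate below it in most configurations anyway.

**Scan statistic.** Each split low = {x <= c}, high = {x > c} is tested with
the standard two-group log-rank statistic, χ² = (Σ d1ⱼ − Σ dⱼ n1ⱼ/nⱼ)² /
Σ dⱼ (n1ⱼ/nⱼ)(1 − n1ⱼ/nⱼ)(nⱼ − dⱼ)/(nⱼ − 1), summing over distinct event
times. The production path evaluates all cutoffs of a gene at once (suffix
sums of a cutoff × sample indicator matrix give at-risk counts; segment
sums give tied-event counts). A deliberately naive per-risk-table
implementation (`logrank_two_group`) is kept as the independent reference;
the two agree to ~1e-12 and the suite additionally cross-checks against
lifelines' `logrank_test`. With no tied event times the statistic equals
the Cox score test for the binary covariate exactly.

**Multiplicity and selection.** The Benjamini–Hochberg step-up FDR is
applied *within a gene, across its cutoff series*; a gene's headline FDR is
the minimum over cutoffs, and cross-gene significance compares that best
FDR to the 1% default threshold. The alternative reading — BH across genes —
is not used because the selection rule ("the cutoff with the lowest FDR")
couples the correction to the per-gene series; the per-gene best FDR is
anti-conservative under the null *as a gene-level error rate* (the
min-over-cutoffs selection), which is why the null inflation is measured
and reported (about 1–2% of null genes reach best-FDR < 0.05 in the shipped
configuration) rather than assumed away. Ties in the best FDR are broken by
the largest Cox hazard ratio — literally the largest HR, not the largest
|log HR|, so for protective genes this prefers the weakest effect; the rule
is kept as stated because the screen's ranking preference is for risk
genes, where the two readings coincide — and remaining ties by the smallest
cutoff, which makes selection a total order.

**Hazard ratio estimation.** At the selected cutoff (and at every tied
cutoff during tie-breaking) the HR is the exponentiated coefficient of a
univariate Cox fit with Efron handling of tied event times, Newton-iterated
with step-halving to gradient ≤ 1e-8. The solver is specialized to a
binary covariate; for the tie-break it runs as a numba kernel over all tied
cutoffs, and the scalar implementation is verified against lifelines'
`CoxPHFitter` to ~1e-7 in the tests. A fit drifting beyond |β| > 15
log-hazard units is declared separated and replaced by the log-rank O/E
estimate (O1/E1)/(O0/E0), flagged in the output. Reported p-values are
floored at 1e-300.

**Filters and ranking.** The cutoff floor (selected cutoff > 200 intensity
units, i.e. twice the ~100-unit array background) and the
risk-direction-first preference affect ranking and top-gene selection only,
never the per-gene statistics. Full ranking: floor-passing genes first,
risk before protective, ascending FDR, descending HR, gene symbol.

## Normalization and QC

Every sample is rescaled by `f = 1000 / mean(shared probes)` applied to all
of its probes, so the mean over the shared panel is exactly 1000 (relative
tolerance 1e-9). Restricting the mean to the probe panel present on all
platforms prevents the larger platform's extra probes from shifting the
common scale. The operation is per-sample, hence idempotent and permutation-
equivariant. QC checks the standard array metrics (background, noise,
percent present calls, bioB spike, GAPDH/ACTB 3'/5' ratio) against
config-exposed thresholds (defaults: present calls >= 25%, 3'/5' ratio <=
3.0, bioB required when reported — platform conventions, since no canonical
values exist); failing samples are flagged with reasons and only excluded
when explicitly requested, because no principled default exclusion rule is
available.

## Multivariate adjustment

The gene enters as the high/low indicator at its screen-selected cutoff;
stage and grade enter as ordinal numerics (one coefficient each — matching
single-df reporting; factor coding can be swapped in by passing dummy
columns as cell scores), debulking as optimal=0/suboptimal=1. Analysis is
complete-case with the dropped count reported, since imputation assumptions
are not defensible for these registries. Fitting delegates to lifelines
(Efron ties, Newton-Raphson with step-halving); exact duplicates or an
ill-conditioned design raise a named collinearity warning, and a
non-convergent fit returns a flagged diagnostic result rather than raising.

## Endpoint concordance

Genes of a common universe are classified per endpoint by best-cutoff
p < 0.01 (the simplified cross-endpoint analysis uses the raw p, not the
FDR; FDR classification is a flag), and the 2×2 counts are tested with the
Pearson chi-square, 1 df, no continuity correction by default (counts in
the thousands; a Yates flag exists). Expected overlap is
(PFS-sig)(OS-sig)/total.

## Over-representation

For each gene set: p = P(X >= k) with X hypergeometric(N = |universe|,
K = |set ∩ universe|, n = |list|), BH across sets. The universe defaults to
all screened genes — the measurable universe — rather than all genes in the
collection; sets disjoint from the universe are skipped with a note. Two
separate runs (risk list, protective list) are the intended usage.

## Synthetic studies

The generator emulates the structure the screen assumes, not any particular
dataset:

- **Intensities** are background + log-normal: `100 + exp(N(6 + g + s, 1))`
  with a per-gene offset g ~ N(0, 0.3²) shared across cohorts and a small
  per-cohort shift s ~ N(0, 0.1²). Typical values are then a few hundred
  units over a background of 100, so the cutoff floor of 200 is a
  meaningful discriminator.
- **Platforms:** the first ceil(n/2) cohorts (even indices) carry the full
  gene panel ("GPL570"-like), the others only the shared subset
  ("GPL96"-like), mirroring the nested probe-set relationship of the U133
  arrays.
- **Survival** is exponential with mean 40 months for OS and 24 months for
  PFS (typical ovarian-cancer follow-up scales); each planted effect
  multiplies the hazard by its HR for samples above the gene's realized
  cutoff (the requested quantile of the pooled simulated values), so the
  truth is exactly the dichotomous model the screen fits. A log-linear
  effect mode exists for robustness checks.
- **Censoring** is administrative and independent: C = τ·U with U uniform
  and τ bisected on the realized draws to hit the target censoring fraction
  (default 40%); a zero target yields fully observed data.
- **Clinical covariates** are drawn from pooled category frequencies
  typical of integrated ovarian databases (serous ≈ 93%, stage 3 ≈ 74%,
  optimal debulking ≈ 60%) with 10% per-field missingness in the
  categorical fields.
- **Determinism:** one root seed fans out through `SeedSequence.spawn` into
  per-cohort, per-purpose substreams; identical configs give bit-identical
  studies, and the writers emit full-precision (`%.17g`) TSVs that
  round-trip exactly.

Not emulated: probe-level noise and cross-hybridization, batch effects
beyond cohort-level intensity shifts, informative censoring, competing
risks, and correlated co-expression structure. Passing recovery tests
therefore show that the screen finds the effects it models, on data that
satisfy its assumptions — not that those assumptions hold in any given real
cohort.

## Validation experiments and problem sizes

The shipped checks use: 50 genes × n=150 for scan-vs-naive equivalence
(every candidate cutoff, tolerance 1e-8); 1000 null genes × n=200 at a
prespecified median split for null calibration (KS against Uniform(0,1));
and 50 replicates of 200 genes × n=600 with one planted HR=2.0 effect at
the median for recovery (rank-1 fraction and median estimated HR). The
recovery screen runs on the raw simulated cohort: with a single cohort the
per-sample rescaling is exercised separately by the normalization contract
and would only perturb group membership near the cutoff without changing
what recovery measures. These sizes give stable pass/fail behaviour on a
single core in a few minutes; the same experiments rerun at any seed via
`scripts/acceptance.py`.

## Known limitations

- The min-FDR-over-cutoffs statistic is not a calibrated gene-level FDR;
  treat cross-gene significance calls as a ranking device, not an error
  rate (measured inflation is reported by the acceptance script).
- Proportional hazards is assumed throughout; only a Schoenfeld-style
  diagnostic hook, not a formal test, is provided.
- Gene symbols are matched case-sensitively; aliasing/updating is the
  mapping file's responsibility.
- Cohort deduplication is limited to detecting sample-ID collisions.
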