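# survscreen

Genome-wide **optimal survival-cutpoint screening** for expression biomarkers.

Prognostic biomarker studies routinely dichotomize a continuous marker — an
mRNA expression z-score, an immunohistochemistry H-score — into "high" and
"low" groups and compare recurrence-free survival between them. Choosing the
threshold by hand ("z ≥ 1 means overexpression") is arbitrary; choosing the
threshold that *best separates* the survival curves and then quoting the
ordinary log-rank p-value is worse, because the selection inflates the type-I
error several-fold. `survscreen` implements the principled middle ground used
in high-risk prostate-cancer biomarker work: per gene, pick the cutoff
maximizing the log-rank separation, but test it with the **maximally selected
rank statistic**, whose null distribution is the supremum of an absolute
Brownian bridge.

## The statistic

For a marker *x* with candidate cutoffs *c* (midpoints of consecutive
distinct values, with a minimum group size per side), let

S(c) = Σᵢ ( dᵢ⁺ − dᵢ · rᵢ⁺ / rᵢ )

be the log-rank O−E score of the above-cutoff group over the ordered event
times. The selected cutoff is c\* = argmax |S(c)|, and the standardized
supremum statistic is

Q = max |S(c)| / ( s·√(D−1) ),  s² = (1/(D−1)) Σᵢ₌₁..D ( 1 − Σⱼ₌₁..ᵢ 1/(D−j+1) )²,

with D the total event count (the Contal–O'Quigley standardization). The
selection-corrected p-value is the Brownian-bridge supremum tail

p = 2 Σⱼ≥₁ (−1)ʲ⁺¹ exp(−2 j² Q²).

A univariate Cox proportional-hazards fit on the selected dichotomy supplies
the hazard ratio (HR) with Wald 95% CI; a multivariate fit adjusts for
clinical covariates (age, Gleason score, T category, initial PSA) with
Bonferroni-adjusted p-values. The genome-wide screen keeps genes with
p < 0.05 and then bands them by the cutoff's z-score location: c\* ≥ 1
("overexpression" genes — only high expressers are separated) or c\* ≤ −1
("under-expression" genes), partitioning them into shorter- and
longer-survival lists by which side of the cutoff carries the excess hazard.

The package also covers the validation arm of such studies: per-field IHC
**H-scores** (Σₖ k·100·fractionₖ over staining intensity categories 0–3,
range 0–300, highest-of-three-fields rule), PSA-based recurrence rules per
therapy (surgery / radiotherapy / hormonal therapy), Pearson mRNA–protein
correlation, and a generic Fisher overrepresentation + activation z-score for
pathway analysis — plus a synthetic-cohort generator with planted cutpoint
effects under proportional hazards so the whole pipeline is testable without
any data download.

## Worked example

Simulate a 200-patient, 50-gene cohort with one planted effect (gene
`G00000`: patients above expression z = 0.8 carry a 5-fold hazard), screen
it, and report the planted gene:

```bash
survscreen simulate --n-samples 200 --n-genes 50 --planted 0:0.8:5.0 \
    --seed 7 --out-expr expr.tsv --out-clinical clinical.tsv
survscreen screen --expr expr.tsv --clinical clinical.tsv --out screen.tsv
survscreen report --expr expr.tsv --clinical clinical.tsv \
    --gene G00000 --out-prefix G00000
```

which logs

```
cascade: 50 genes analyzed -> 4 associated (p < 0.05) -> 0 banded (z >= 1 or z <= -1)
         -> 0 shorter / 0 longer survival
G00000: cutoff=0.4914 HR=2.637 (95% CI 1.769-3.932) logrank p=8.07e-07;
        mean time to event high=11.67 low=29.89 months
```

Reading this: the screen recovers the planted gene as survival-associated
(its corrected cutpoint p is 0.0031, one of the 4 genes past the p filter);
the selected cutoff 0.49 sits below the z = 1 band, so under the strict
overexpression definition the gene is not "banded" — the cutoff estimate is
noisy and biased toward the cohort median, which is exactly why the band
filter is aggressive (see `docs/methods.md`). The per-gene report shows the
dichotomy's effect: patients above the cutoff recur on average at 11.7
months versus 29.9 months below it, HR ≈ 2.6, and the covariate-adjusted
Cox table (`G00000.cox_adjusted.tsv`) confirms the gene as an independent
prognostic factor (adjusted HR 2.65, Bonferroni p = 1.6e-05) while age,
Gleason score, T category and iPSA are null, as simulated.

Screening a real cBioPortal z-score export works the same way: pass the
expression TSV (`Hugo_Symbol` + one column per sample) and a clinical TSV
(`sample_id`, `time` in months, `event` 0/1, covariates) to
`survscreen screen`.

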