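# Methods

## Model and procedure

The package addresses a screening problem from survival biomarker discovery
in high-risk (Gleason ≥ 8) prostate cancer: given a gene-by-sample matrix of
expression z-scores and recurrence-free survival (months, 0/1 event), find
genes whose *dichotomized* expression predicts recurrence, without choosing
the dichotomy by hand.

Per gene, the candidate cutoffs are midpoints between consecutive distinct
observed values, restricted so that each side retains at least `min_group`
subjects (default `max(10, 10% of n)`; unconstrained extremes produce
degenerate groups and unstable hazard ratios — the floor is configurable
down to 1). The selected cutoff maximizes the absolute log-rank score
S(c) of the above-cutoff group. Inference uses the standardized supremum

Q = max|S| / (s√(D−1)), s² = (1/(D−1)) Σᵢ₌₁..D (1 − Σⱼ₌₁..ᵢ 1/(D−j+1))²,

referred to the supremum law of an absolute Brownian bridge,
p = 2Σⱼ(−1)ʲ⁺¹exp(−2j²Q²) (Contal–O'Quigley construction). The scale s
depends only on the event count D. Argmax ties break toward the candidate
closest to the median marker value (maximal stability), then first-in-order.

The per-candidate scores are computed vectorized: with risk/event indicator
matrices over the ordered distinct event times, S(c) and the per-candidate
hypergeometric variances V(c) come from two matrix products; the
implementation is verified against a direct per-event-time O−E summation and
an exhaustive-split oracle (exact to 1e-10), and the analytic p-value against
a label-permutation oracle.

The genome-wide screen applies, in order, the association filter
(corrected p < α, default 0.05, uncorrected across genes by design — a
Benjamini–Hochberg column is emitted for users but not used in the filter)
and the z-band filter (cutoff z ≥ 1 → "overexpression" gene, ≤ −1 →
"under-expression" gene, band edges inclusive). Banded genes split into
shorter/longer-survival lists by the survival direction of the banded
expression class: an overexpression gene is "shorter survival" when the
above-cutoff HR exceeds 1, an under-expression gene when the HR is below 1
(the low group carries the excess hazard). An alternative reading — the band
sign alone decides the direction — is available as
`direction_rule="band"`; the HR-based rule is the default because it makes
"overexpression linked to shorter survival" equivalent to HR > 1 for the
high group.

## Survival core

Kaplan–Meier, the two-group log-rank test (hypergeometric variance) and Cox
proportional hazards are implemented from scratch so the cutpoint statistic
on top of them is fully auditable. The Cox fit maximizes the partial
likelihood by Newton–Raphson from β = 0 with step-halving, gradient-norm
tolerance 1e-9 (plus a 1e-10 step-size criterion for the float64 plateau
where the gradient cannot shrink further on log-likelihoods of magnitude
~1e3), maximum 50 iterations; Efron tie handling by default, Breslow
available. Non-convergence is flagged, never silent; monotone likelihood
(separation) is detected via |β| > 15 and warned. Inference is Wald
(HR = exp(β), 95% CI exp(β ± z₀.₉₇₅·se)), matching the HR (95% CI)
presentation standard in clinical tables; the Bonferroni column multiplies
each Wald p by the number of covariates in the model, capped at 1.
Cross-checks: score test at β = 0 equals the log-rank χ² on untied data
(to 1e-6), and coefficients agree with an independent reference
implementation to |Δβ| < 1e-6 on random fixtures.

"Average time to recurrence" is the arithmetic mean of observed times among
subjects with an event, per group — the quantity is not otherwise
well-defined under censoring; groups without events yield a missing value
with a warning. Restricted-mean or median-KM alternatives can be computed
from the exported curves.

## Synthetic cohorts: what they emulate, and what not

`SimulationConfig` defaults emulate a TCGA-style high-risk prostatectomy
sub-cohort: n = 201 samples; per-gene i.i.d. standard-normal expression (so
"z-scores" are self-consistent); exponential baseline hazard 0.02/month and
independent exponential censoring 0.015/month truncated at 120 months of
follow-up, giving ~60–70% events and mean recurrence times in the 12–32
month range typical of this disease setting; age ≈ N(62.4, 7.5²) clipped to
44–78, Gleason score {8, 9, 10} with probabilities (0.30, 0.665, 0.035),
ordinal T category {2, 3, 4} with (0.135, 0.83, 0.035), log-normal initial
PSA (median 10 ng/mL). Planted effects multiply the hazard by `true_hr` for
samples above `true_cutoff_z`, preserving proportional hazards per gene.
Options add an equicorrelated gene block, covariate effects on the hazard,
and a gene–covariate confounder for exercising multivariate adjustment.

Not emulated: gene–gene correlation structure beyond the optional block,
non-proportional hazards, informative censoring, batch effects, and the
RSEM quantification upstream of the z-scores. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's own
assumptions, not robustness to real-data violations of them.

IHC fields are multinomial draws over the four staining categories;
per-patient H-scores follow the highest-of-three-fields rule. The
grayscale-histogram binning (zones high 0–60, positive 61–120, low 121–180,
negative 181–255, darker = stronger staining) is a configurable convenience
and explicitly not a calibrated reproduction of any specific image-analysis
plugin. PSA recurrence rules: after prostatectomy, first PSA > 0.2 ng/mL
that is also rising; after radiotherapy, first PSA > nadir + 2; under
hormonal therapy, first rising PSA at castrate testosterone (< 50).
"Rising" means strictly greater than the immediately preceding measurement
(the first measurement can never qualify); a criterion met exactly at the
last visit counts as an event at that time, otherwise the series censors at
the last visit.

## Numerical choices

* p-value series: summed until |term| < 1e-12 (cap 100 terms), clipped to
  [0, 1]; below Q = 0.15 the alternating series converges too slowly and the
  tail probability is 1 to within ~1e-23, so 1.0 is returned directly.
* Candidate variance terms guard r ≤ 1 risk sets; missing expression values
  are dropped per gene (pairwise deletion), mirroring per-gene screening.
* Duplicate gene symbols on load keep the row with fewest missing values
  (ties: first occurrence) — cBioPortal exports contain duplicates.
* Textual T categories map to ordinal 2/3/4 (pT2\* → 2, pT3\* → 3, pT4 → 4,
  configurable), so the Cox model treats T as a single trend covariate.
* All randomness flows through explicit seeds; no global random state.

## Validation design and known limitations

Validation is property-based on synthetic cohorts (the acceptance script
recomputes every quantity from scratch): exhaustive-oracle equivalence,
null calibration of the corrected p-value (false-positive rate ≈ 0.05 on
500 null genes, versus ≈ 0.45 for the naive minimum-p scan over the same
candidates — the selection correction is not optional), planted-effect
recovery (median cutoff error ≈ 0.16–0.19 z-units at n = 300, HR = 3), and
HR confidence-interval coverage evaluated on the *known true* dichotomy
(92–98%).

Two limitations of the maximally selected approach deserve emphasis,
because the package's own measurements quantify them:

1. **Selection bias at the estimated cutoff.** The HR fitted on the
   *selected* dichotomy is biased and its CI covers the true HR only
   ~60–70% of the time under a planted effect; the acceptance script
   reports this diagnostic alongside the true-split coverage. Hazard
   ratios at data-driven cutoffs should be read as descriptive, not as
   unbiased effect estimates.
2. **Power profile over cutoff location.** The supremum of the
   *unstandardized* log-rank score inherits the Brownian bridge's u(1−u)
   variance profile: sensitivity is greatest for mid-range cutpoints and
   drops sharply toward the tails, and the argmax is median-biased.
   Consequently genes whose true threshold sits in the z ≥ 1 tail are
   detected with modest probability even at large hazard ratios, and a
   detected gene's estimated cutoff falls below the band 15–25% of the
   time. The screen's z-band stage is therefore a high-specificity,
   low-sensitivity filter; screen-recovery counts reported by the
   acceptance script reflect this honestly.

The fixed analytic anchors: the supremum p-value at the classical 5%
critical value 1.358 evaluates to 0.0500; the one-sided hypergeometric tail
for overlap 4 between a 5-gene list and a 5-gene set in a 20-gene universe
is 76/15504 ≈ 0.004902; the H-score of a 40/30/20/10% composition is 100.
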