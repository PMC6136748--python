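# Methods

## Scope and design

`digitstat` implements the statistical pipeline of a summary-table-driven
digit-ratio study: morphometry (duplicate-measurement averaging, ratio
computation, reliability), frequentist group comparisons computable from
(mean, SD, n) summaries, Bayes-factor and sensitivity-power evidence,
Holm–Bonferroni correction, a Monte-Carlo rejection-proportion bootstrap,
covariate-adjusted (ANCOVA-style) scaling checks, and a synthetic cohort
generator that stands in for raw data that such studies rarely deposit.
The summary-statistic route is the primary design constraint: every
two-group statistic is defined on (mean, SD, n) triples, and the raw-vector
entry points are exact wrappers over those (a property the test suite
enforces to 12 significant digits).

## Morphometry and reliability

Each digit is measured twice; the working length is the repeat mean.
2D:4D = mean(D2)/mean(D4) per hand, 2D:5D analogously. Missing duplicate
pairs propagate: a ratio is undefined if either contributing cell is
missing, so per-ratio sample sizes vary naturally across a cohort.

Reliability is reported per (hand, digit) cell as the Pearson correlation
between first and second measurements and as the intraclass correlation.
The ICC variant is **ICC(C,1)** — two-way random effects, single measure,
consistency — computed from the subject × repeat ANOVA decomposition:
ICC = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error). This is the
standard choice for duplicate measurements by a single observer, where a
fixed offset between first and second passes should not count against
reliability. The implementation is cross-checked against pingouin's
ICC(C,1) in the tests. Cells with fewer than 3 complete pairs are flagged
undefined rather than estimated.

Normality is screened with a one-sample Kolmogorov–Smirnov test against a
normal with the sample mean and SD. No Lilliefors correction is applied
for the estimated parameters, so the p-value is conservative; it is used
as a screen, not as a decision rule. Levene's test uses mean-centering
(the SPSS default) rather than the Brown–Forsythe median variant; constant
input leaves it undefined and flagged instead of raising, so batch
pipelines continue.

## Two-group and k-group inference

Welch's t is used throughout for two-group contrasts (robust to the
strongly unbalanced group sizes this design produces, e.g. 17 vs 241),
with Welch–Satterthwaite df and two-tailed p-values.

Cohen's d uses the **unweighted average-variance denominator**
√((s1²+s2²)/2). This is deliberate: with group SDs 0.033/0.029 and n
241/17 the n-weighted pooled denominator gives d = 0.73 where the
average-variance form gives 0.74, and the latter is what the widely used
web effect-size calculators (Becker) produce. The choice is pinned by a
test.

One-way ANOVA is reconstructed from group summaries (SS_between from group
means and sizes, SS_within from group SDs) with Cohen's f =
√(SS_between/SS_within). With k = 2 the F statistic equals the square of
the pooled-variance t, which the tests verify against raw-data oracles.

## Sensitivity power analysis (MDES)

The minimum detectable effect size solves Power(d) = 1−β for the two-sided
two-sample t-test, where the power function uses the noncentral t with
df = n1+n2−2 and noncentrality d/√(1/n1+1/n2). The root is bracketed and
solved with Brent's method to |ΔPower| < 1e−8. The far-tail noncentral-t
CDF underflows to NaN in scipy for large noncentrality; those terms are
exactly the negligible ones and are clamped to zero. At α = 0.05 and
power 0.80 the 17/241 design gives d_min = 0.706, the 192/51 design 0.44.

## JZS Bayes factor

The two-sample Jeffreys–Zellner–Siow Bayes factor follows the Rouder
construction: effective sample size N = n1·n2/(n1+n2), df ν = n1+n2−2, a
Cauchy(0, r) prior on the standardized effect expressed as an
inverse-gamma(½, r²/2) mixture over the variance hyperparameter g, and

BF10 = ∫₀^∞ (1+Ng)^(−1/2) (1 + t²/(ν(1+Ng)))^(−(ν+1)/2) π(g) dg
       ÷ (1 + t²/ν)^(−(ν+1)/2).

The integral is evaluated with adaptive quadrature on the half-line
(relative tolerance 1e−10; the integrand is computed in log space to avoid
under/overflow; non-convergence raises with diagnostics rather than
returning a number). The default scale r = √2/2 is the "medium" prior of
the standard calculators; it is exposed as a parameter. The df fed to the
Bayes factor is the pooled ν even when the t statistic came from a Welch
test — mirroring how practitioners feed Welch t values into the standard
JZS calculators — and this mild mismatch is accepted deliberately. The
implementation is cross-checked against pingouin's independent JZS
routine.

## Holm–Bonferroni

Adjusted p-values are the running maximum of (m−rank+1)·p over the raw
ranks, capped at 1, mapped back to input order. The family size m is an
explicit parameter (default: the number of p-values supplied) because
corrections are sometimes declared over a larger family than the p-values
at hand. The tests verify elementwise dominance by plain Bonferroni,
permutation equivariance, and decision-equivalence with the classical
step-down rejection rule at arbitrary α.

## Rejection-proportion bootstrap

The bootstrap asks: if we repeatedly drew balanced subsamples from the two
observed pools, how often would an unpooled t-test at level α reject? Per
outer replicate, n_boot iterations each draw `pairs_per_sample` pairs of
subsamples (each side `subsample_n` draws **with replacement** from its
pool, re-balancing the minority group's size), run a two-tailed Welch test
on each pair, and record rejections; the replicate's value is the mean
indicator over n_boot × pairs_per_sample tests. The outer loop (n_outer
replicates) yields the overall mean and a 2.5/97.5 empirical-percentile
95% interval. Defaults are 1000 iterations × 12 pairs × size 17 × 100
outer replicates; the denominator convention (n_boot × pairs) and all
counts are configuration parameters, since alternative readings of this
procedure differ only in those counts. Degenerate resamples with zero
variance on both sides count as non-rejections. Reproducibility: a root
seed spawns one independent child stream per outer replicate
(`numpy` SeedSequence), so results are bit-identical across runs and
outer replicates are order-independent.

Test sizing: the suite exercises the bootstrap at n_boot = 100–1000 and
n_outer = 5–20, which keeps Monte-Carlo error around a percentage point —
adequate for the calibration (5% type-I under a shared pool), monotonicity
and CI-shrinkage properties being checked.

## Adjusted models

`fit_linear` is ordinary least squares (statsmodels under the hood) with
its per-term tests reported SPSS-GLM-style: Wald χ² = (B/SE)² on 1 df,
95% CI = B ± 1.95996·SE, plus a joint Wald χ² over the non-intercept
terms. The joint statistic is a Wald (not likelihood-ratio) form; with a
Gaussian likelihood and identity link the two agree asymptotically and the
Wald form matches the per-term convention. A saturated (zero-residual) fit
is guarded: SEs collapse to ~0 and p-values to 0 instead of dividing by
zero. Rank-deficient designs raise an error naming the collinear columns
found by a greedy rank-building pass.

`ancova_scaling_check` regresses ratio on [intercept, group, mean finger
length]. If a group's apparent ratio difference were pure allometry
(bigger hands → different ratios), the covariate absorbs it and the group
coefficient collapses toward zero; the tests construct exactly that
confound and verify the collapse, as well as unbiased recovery of a
genuine injected gap.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
person's data:

- **Cohort composition**: 77 non-athletes, 103 varsity, 78 club (258
  women); each athlete gets one college sport from a fixed roster of 16
  sports (softball 10, water polo 1, … track & field 24); 6 non-athletes
  additionally played softball in high school, for 17 overhand throwers
  in total. Starter/reserve is Bernoulli(0.79) among sport players;
  ancestry is Bernoulli(12/258) non-European.
- **Digit lengths**: one 6-vector per subject (2 hands × digits 2/4/5)
  from a multivariate normal; means 73.9/75.6/61.2 mm, SDs 4.6/4.7/4.3 mm.
  The correlation matrix is the Kronecker product of an inter-hand block
  (r = 0.6) and a within-hand equicorrelation across digits (r = 0.85).
  The digit correlation is the load-bearing parameter: with these CVs it
  implies a 2D:4D SD of ≈ 0.033–0.034, matching the ≈ 0.035 scale such
  cohorts report. All correlations are configurable.
- **Duplicates**: measured value = true length + N(0, 0.5 mm) per repeat.
  With a 4.6 mm between-subject SD this gives ICC ≈ σ²_b/(σ²_b+σ²_e) =
  21.16/21.41 ≈ 0.988, comfortably above the 0.97 reliability benchmark.
- **Overhand effect**: injected as an additive shift on the *lengths* of
  digits 4 and 5 (both hands), sized so the expected ratio difference
  equals `overhand_effect_d` (default 0.75) ratio SDs. The shift is
  closed-form from a first-order delta-method approximation of the ratio
  SD: Δ = m2/(r0 − δ) − m4 with δ = d·σ_ratio. The delta-method SD
  underestimates the exact ratio-of-normals SD by ≈ 0.6% at these CVs
  (verified against a large Monte-Carlo oracle in the tests), which
  biases the realized d by well under the ±0.15 recovery tolerance; no
  further numeric correction is applied. Injecting on lengths, not
  ratios, means throwers get slightly longer 4th/5th digits — so the
  ANCOVA scaling check faces a genuine, mildly group-correlated covariate
  instead of a vacuous one.

What the generator does **not** emulate: non-normal tails, left/right
asymmetries beyond a symmetric correlation, ethnicity substructure beyond
the binary flag, multi-sport athletes, or any subject-level association
between sport choice and digit ratio other than the injected overhand
effect. Passing tests therefore demonstrate that the pipeline's machinery
is correct and calibrated under its own assumptions — not that those
assumptions hold in any particular real cohort.

## Sport coding

The 16 canonical sports map to five binary attributes (team, contact,
ball, overhand, judged) through a fixed table; names are case-insensitive
and trimmed, cross-country is merged into track & field, and unknown names
raise (no fuzzy matching, no silent default). Multi-sport subjects are
pooled attribute-wise by OR — a subject counts in a category if any sport
she played has the attribute — which is monotone (adding a sport never
removes an attribute). Swimming is coded as an individual, non-team sport.

In the pipeline, the overhand contrast compares throwers against the
entire remainder of the cohort (a woman who never played a sport certainly
never threw overhand competitively); all other attribute contrasts are
defined only among women who played an organized sport, since e.g.
"non-contact" is meaningless for someone with no sport.

## Numerical conventions and edge cases

- Two-tailed p-values everywhere; rejection at p ≤ α.
- Group summaries require n ≥ 2 and finite SD ≥ 0; both SDs zero makes t
  and d undefined (error), as does zero within-group variance for F.
- Rendering rounds ratios to 3 dp and t/d/mdes/BF to 2 dp; stored values
  keep full precision, and the JSON report serializes the unrounded
  numbers.
- The full pipeline is deterministic given (cohort, options, seed); rerun
  output is byte-identical.

## Limitations

- Summary-statistic inference cannot reproduce quantities that depend on
  raw data (exact bootstrap CIs, regression coefficients, ICCs of a
  specific historical sample); for those the package offers calibrated
  synthetic-data checks instead.
- The KS normality screen is conservative without the Lilliefors
  correction.
- The JZS Bayes factor inherits the pooled-df convention of the standard
  calculators even for Welch t inputs.
- The ANCOVA reproduces SPSS-style Wald output from an OLS fit; it is not
  a general GLM front-end.
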