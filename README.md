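# digitstat

Statistical toolkit for 2D:4D / 2D:5D digit-ratio cohort studies.

The ratio of the second to the fourth finger length (2D:4D), and its 2D:5D
analogue, are widely used anthropometric proxies for prenatal testosterone
exposure; lower values are male-typical. Studies in this area typically
compare digit ratios between behaviorally defined groups (e.g. women who
played overhand-throwing sports vs those who did not) and publish only
summary tables — mean ± SD (n) per group plus test statistics — rather than
raw data. `digitstat` makes that entire analysis workflow reusable and
testable, and treats **printed summary statistics as first-class inputs**:
every two-group inference is computable from (mean, SD, n) triples alone,
so published tables can be re-analyzed directly.

## What it computes

For a two-group contrast with summaries $(m_1, s_1, n_1)$ and
$(m_2, s_2, n_2)$:

- **Welch's t** (unequal variances):
  $t = (m_1 - m_2)/\sqrt{s_1^2/n_1 + s_2^2/n_2}$ with Welch–Satterthwaite
  df and a two-tailed p.
- **Cohen's d** with the unweighted average-variance denominator
  $d = (m_1 - m_2)/\sqrt{(s_1^2 + s_2^2)/2}$ (the form the common web
  effect-size calculators report).
- **Minimum detectable effect size** (sensitivity power analysis): the $d$
  solving $\mathrm{Power}(d;\alpha, n_1, n_2) = 1-\beta$ on the
  noncentral-t power curve.
- **JZS Bayes factor**: the Jeffreys–Zellner–Siow BF10 for the t contrast,
  with a Cauchy(0, r) prior on the standardized effect (default
  $r=\sqrt{2}/2$), evaluated by adaptive quadrature over the
  inverse-gamma(½, r²/2) mixture representation.
- **Holm–Bonferroni** sequentially rejective adjusted p-values with an
  explicit family size.

Raw-cohort stages add duplicate-measurement reliability (test–retest r and
ICC(C,1)), KS normality and Levene checks, one-way ANOVA across
athlete-status groups, a **rejection-proportion bootstrap** (the fraction of
subsampled Welch tests rejecting the null, with percentile confidence
limits from an outer replication loop), and an **ANCOVA scaling check**
(ratio ~ group + mean finger length) that asks whether a ratio difference
is an allometric artifact of overall hand size. A synthetic-cohort
generator produces 258-subject cohorts with the same statistical structure
(group sizes, sport roster, ~0.035 ratio SDs, 0.5 mm duplicate-measurement
noise, a configurable overhand-throwing effect injected on digit lengths)
so every stage runs without access to any raw data.

## Worked example

Re-analyze printed summary rows (columns: label, mean1, sd1, n1, mean2,
sd2, n2):

```bash
$ digitstat summary-table table2.csv
overhand_right_2d4d: t(18.33)=3.07, p=0.006, d=0.77, mdes=0.71, BF10=14.40 [alternative]
overhand_left_2d4d: t(19.05)=3.13, p=0.005, d=0.74, mdes=0.71, BF10=16.74 [alternative]
individual_right_2d4d: t(111.64)=1.16, p=0.248, d=0.17, mdes=0.41, BF10=0.30 [null]
```

Reading the first row: non-throwers (0.978 ± 0.035, n=241) vs throwers
(0.951 ± 0.035, n=17) differ by t = 3.07 on 18.33 df (p = 0.006); the
standardized difference d = 0.77 is large and exceeds the smallest effect
the design could detect at 80% power (mdes = 0.71); the Bayes factor ≈ 14
favors a real group difference. The third row shows the opposite pattern:
d = 0.17 is far below the detectable 0.41 and BF10 = 0.30 (BF01 = 3.3)
actively supports the null.

The same numbers fall out of a full synthetic cohort:

```bash
$ digitstat synth --seed 0 -o cohort.csv
wrote 258 subjects to cohort.csv
$ digitstat analyze cohort.csv --no-bootstrap
$ digitstat bootstrap cohort.csv --ratio right_2d4d --n-boot 200 --outer 20 --seed 0
right_2d4d: mean rejection 76.79% (95% CI 75.72-77.96%)
```

The Python API mirrors the CLI:

```python
from digitstat import GroupSummary, welch_from_summary, cohens_d, jzs_bf, mdes

g_non, g_thrower = GroupSummary(0.978, 0.035, 241), GroupSummary(0.951, 0.035, 17)
welch_from_summary(g_non, g_thrower).t     # 3.074
cohens_d(g_non, g_thrower).d               # 0.771
mdes(0.05, 0.80, 17, 241).d_min            # 0.706
jzs_bf(3.07, 17, 241).bf10                 # 14.249
```

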