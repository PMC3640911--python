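# Methods

## The corrected-ratio statistic

A HUMARA lane pair yields four band intensities: the two CAG alleles before
and after methylation-sensitive digestion. With `r_pre = a/b` before and
`r_post = a/b` after digestion, the corrected ratio is
`CR = r_post / r_pre`, replaced by its reciprocal when below 1 so that
`CR >= 1` always. Because any allele-preferential amplification factor beta
multiplies both lanes identically, it cancels exactly; so does any per-lane
densitometry scale. `CR` maps bijectively to the majority-allele cell
fraction `f = CR/(1+CR)` (CR 1 -> 0.5, CR 3 -> 0.75, CR 10 -> 10/11). SXCI
is called at `CR >= 3` (moderate) and `CR >= 10` (stringent), inclusive.

Degenerate inputs: a single absent post-digestion band is complete skewing
and returns `CR = +inf` (reported as ">= 100", the display cap, and counted
as SXCI at every threshold); an absent pre-digestion band, or both post
bands absent, are assay failures and raise distinct errors rather than
producing a number. Uninformative (CAG-homozygous or gel-unresolvable)
subjects carry no CR and enter no tabulation.

## Population model

**Inborn skewing.** X inactivation is fixed when a pool of `N` embryonic
precursor cells each silences one X at random; the blood-cell inactivation
fraction is `p0 = K/N`, `K ~ Binomial(N, 1/2)`. The default `N = 16` puts
the inborn tail `P(max(p0, 1-p0) >= 0.75) = 5034/65536 ≈ 7.7%`, bracketing
observed neonate (~4%) and younger-adult (~8%) SXCI frequencies at CR >= 3.
`N` is exposed in `PopulationConfig`.

**Acquired skewing.** Adult skewing accumulates with age through selection
and drift among haematopoietic clones. No quantitative rate is available in
the source data, so the model is the simplest process that (a) is exact at
age 0, (b) keeps `p` inside (0, 1), and (c) gives tail mass monotone in age:
a Gaussian random walk on the logit,

    logit(p) = logit(p0) + Normal(0, sigma^2 * max(0, age - a0)),

with onset `a0 = 15` years (the cohorts contain nobody between 29 days and
16 years, so the onset inside that gap is unidentifiable; 15 y marks the end
of it). Fractions 0 and 1 are absorbing and returned unchanged.

**Calibration of sigma.** The drift scale is the one free parameter. It is
pinned — deterministically, no Monte Carlo — by requiring the elderly
stratum (ages uniform on 51–96 y) to reach 25.7% SXCI at the moderate
threshold, the frequency reported for that stratum in the survey the
package reproduces. The expectation

    P(skewed) = E_age sum_K Binom(K; N, 1/2) *
                [ Phi_bar((c - m)/s) + Phi((-c - m)/s) ],
    m = logit(K/N), s = sigma*sqrt(age - a0), c = logit(0.75)

is evaluated on an age grid and solved for sigma by Brent's method
(`xskew.calibrate.calibrate_drift_sd`); the result, sigma = 0.1068 logit
units per sqrt(year), is frozen as `DEFAULT_DRIFT_SD`. With it, the same
closed form predicts 7.7% for neonates (pure inborn) and 11.6% for ages
16–50 on the true fractions; assay noise moves the realised call
frequencies slightly (see below).

**Demographics.** Ages are uniform within recruitment bands. The default
control structure mirrors the reproduced survey: 52 neonates (2–28 days),
and adult bands 16–50 y and 51–96 y weighted 187:162 so that ~90%
informativeness leaves ≈46/166/144 informative subjects. Patients are 35–83
y with AJCC stages drawn 92:13:10:16:12. CAG repeats are uniform on 10–35;
a subject is heterozygous with probability 0.90 by default.

**RNG streams.** The population and the assay use independent seeded
`numpy` Generator streams (per-stream seeds derived from the run seed via
`SeedSequence` with a CRC of the stream name), so re-running the assay
never perturbs the cohort.

## Assay model

Noiseless template amounts for inactive-allele fraction `p`, amplification
bias `beta` and digestion efficiency `d`:

    pre:  T_a = beta,                      T_b = 1
    post: T_a = beta*(p + (1-d)(1-p)),     T_b = (1-p) + (1-d)*p

(methylated/inactive templates survive digestion; active templates survive
only the undigested fraction `1-d`). Each band is the template amount times
a per-lane scale and an independent unit-mean lognormal factor with
coefficient of variation `noise_cv` (default 0.10 — silver-stain
densitometry noise is multiplicative). At `noise_cv = 0`, `d = 1` the
pipeline CR equals `max(p,1-p)/min(p,1-p)` to machine precision for any
`beta`. Defaults: `d = 1` (wet protocols certify complete digestion with
no-enzyme controls; `d < 1` biases CR toward 1 and is available for
sensitivity analyses), `beta` drawn per subject log-uniformly on
[0.7, 1.4]. A CV of 0.10 keeps the false-SXCI rate at `p = 0.5` well below
1% (the log-CR noise SD is ~0.2, against a log-3 threshold distance of
1.1). Alleles closer than `min_repeat_diff` repeats co-migrate into one
merged band and the subject is uninformative, like a true homozygote.

Not modelled: PCR saturation (intensities are linear in template),
background subtraction, gel-image analysis, duplicate-run reconciliation.

## What the simulator does and does not show

The generator reproduces the *structure* the analysis assumes — binomial
inborn skew, monotone age effect, ~90% informativeness, multiplicative
densitometry noise — so passing recovery tests shows the pipeline correctly
inverts its own generative model at realistic sample sizes. It does not
establish anything about mechanisms in real cohorts: the acquired-drift
form is a modelling choice, the case-control contrast in young patients has
an unknown mechanism and is deliberately *not* a simulation target (it is
covered only by the printed-count reproduction), and informativeness is
treated as independent of age and case status.

## Statistics

Tabulations count SXCI/non-SXCI per age bin (three-group, five-group, or a
<=40 / >40 split restricted to an explicit eligibility window, default
16–83 y, matching how the reproduced case-control table excludes neonates
and the oldest controls). Percentages are rounded half-up to one decimal.
Subjects outside every bin (the 29 d – 15 y recruitment gap) are excluded
with a logged count. Inference: Pearson chi-square (Yates continuity
correction, `(|O-E|-0.5)+` floored at zero, only on 2x2 and only on
request), the likelihood-ratio G-test `G = 2*sum O*ln(O/E)` for age-group
heterogeneity, Fisher's exact test for small tables, and Welch's t for mean
ages; all two-tailed. Which test headlines a 2x2 comparison is decided by
the expected counts: Fisher when any expected cell is below 5, otherwise
uncorrected Pearson. (On the reproduced young-patient contrast
[[5,9],[13,157]] these give 0.006 vs 0.0007 — the published 0.006 is
consistent with the exact test, and all three variants are always
reported.) No multiple-testing correction is applied, matching the survey
design being reproduced.

Numerical notes: tables with a zero margin raise a degeneracy error instead
of NaNs; `O = 0` cells contribute zero to G; the Fisher statistic is the
cross-product odds ratio with 0/inf for empty diagonals; CR comparisons at
thresholds are inclusive.

## Problem sizes in the test suite

Monte-Carlo checks use 1e5 draws for distributional oracles (binomial tail,
drift variance), 1e4 replicates for the type-I-error calibration, 25
replicates of cohort-sized (46–144 subject) strata for frequency recovery
and 40 full-cohort replicates for the mean-age direction check; these sizes
put the Monte-Carlo error well inside each test's stated tolerance.

## Known limitations

- The drift rate is calibrated to one elderly stratum; other cohorts would
  need recalibration (`calibrate_drift_sd` is public).
- Uniform ages within bands understate the youth of the real younger-adult
  stratum (median 41 y vs uniform 33 y); only bin-level frequencies are
  calibrated.
- No X-linked selection by genotype, no twin or autoimmune structure, no
  HhaI-site alternative assay.
- The simulator treats informativeness as independent of age and cohort.
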