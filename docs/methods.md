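# Methods

`dup15q` estimates the epidemiology of a rare, strongly deleterious copy
number variant whose effect depends on parental origin — the motivating case
is the interstitial duplication of 15q11.2-q13.3, which spans an imprinted
gene cluster, so a maternally and a paternally derived copy are distinct
exposures.  Everything downstream is driven by a single input: per-study
carrier counts by cohort class (schizophrenia cohorts, developmental-
delay/autism/congenital-anomaly referral cohorts, controls) and parental
origin, plus de novo / inherited tallies for carriers whose parents were
tested.  No genotype-level data are touched; carrier status is an input, not
a call.

## Prevalence

Cohort prevalence pools raw counts across studies: the numerator sums
carriers of the requested origin and the denominator sums cohort sizes over
studies flagged usable (a study that reported carriers but no cohort size
cannot enter a prevalence and only informs the origin ratio).  No
heterogeneity weighting or random-effects synthesis is attempted — the
counts are sparse enough (0–10 carriers per study) that only the pooled
binomial proportion is defensible.

Confidence bounds are Wilson score intervals: the set of p for which
|p̂ − p|·√(n/(p(1−p))) ≤ z.  The closed form is used, with `z = 1.96`
exactly at the 95% level (the convention of the published tables this
package reproduces; any other level uses the exact normal quantile), and is
unit-tested against numeric inversion of the score test by bisection.  At
p̂ = 0 the lower bound is exactly 0.  Fractional numerators are accepted
because of the extrapolation step below; the score formula is applied to
them unchanged.

**Origin-ratio extrapolation.**  Referral-cohort carriers are often only
partially origin-typed.  The origin-specific prevalence of such a class is
obtained by splitting the systematically ascertained carrier total T in
proportion to the origin-typed counts (m, p), which may come from a larger
superset of cohorts including ratio-only studies:
`T_maternal = T·m/(m+p)`.  The split is exact (the two parts sum to T) and
fractional; when every usable carrier is origin-typed the rule reduces to
the raw origin-specific pool, so the same code path serves all three
classes.  In the shipped tables the DD/ASD/MCA split is 53 carriers at a
50:10 ratio → 44.17 maternal / 8.83 paternal over 51,001 screened.

A prevalence can be re-expressed as a "1 in N" denominator triple
(1/p̂, 1/upper, 1/lower); note the bound order inverts.

## General-population frequency and penetrance

The general population is a three-stratum mixture — controls (weight 0.95),
SZ (0.01), DD/ASD/MCA (0.04); the weights are population frequencies of the
outcome classes, with the affected strata treated as mutually exclusive
single-ascertainment classes.  The carrier frequency of a given origin is
the weighted stratum-prevalence sum

    q = 0.95·p_control + 0.01·p_SZ + 0.04·p_DD,

and penetrance follows by Bayes inversion,

    P(outcome | carrier, origin) = p_outcome_cohort · w_outcome / q,

truncated at 1 with an explicit `capped` flag.  Confidence limits are
propagated by combining extremes: the upper penetrance limit divides the
upper Wilson bound of the case-cohort prevalence by the lower bound of q
(itself the weighted sum of stratum lower bounds), and conversely.  Pairing
two opposite 95% extremes makes these limits deliberately conservative
rather than calibrated: in the package's own parameter-recovery experiments
their empirical coverage is ≈99–100%, not 95%.  They should be read as
plausibility envelopes, which is how the source analyses use them.

**Rounding policies.**  `FULL_PRECISION` (default) carries pooled
prevalences through unrounded.  `PRINTED_PRECISION` first rounds every
stratum prevalence, point and bounds, to two significant figures before the
mixture and ratio steps.  The published table this package reproduces was
evidently computed from two-significant-figure intermediate values (with
full precision the maternal SZ penetrance is 12.4% rather than the printed
12.3%), so printed-precision mode is the reproduction surface while
full-precision mode is the statistically cleaner default.  The exact final
rounding of the published interval ends is not fully consistent — two bound
cells differ by one unit in the last printed digit from any propagation
pathway we tried — so reproduction tests compare point cells exactly at
printed precision and bound cells to within one final-digit unit.

**Sensitivity preset.**  Because referral cohorts may over-represent severe
cases, a preset with halved affected-stratum weights (0.975/0.005/0.02) is
provided; penetrance is monotone in the outcome weight, so every estimate
drops under this preset, but the maternal DD/ASD/MCA penetrance remains
above 20%.

## Selection and mutation rate

For a variant at mutation–selection balance, the population frequency obeys
q = μ/s.  Two estimators follow:

* **Selection coefficient:** in an unbiased carrier sample the de novo influx
  equals the selective outflow, so s ≈ de novo/(de novo + inherited).  The
  pooled shipped tallies give s = 29/53 = 0.55 (maternal) and 7/12 = 0.58
  (paternal).  No confidence interval is attached by default (none is
  conventional for this approximation); an optional Wilson interval on the
  de novo fraction is exposed as a labelled extension.
* **Mutation rate:** μ = q·s, per newborn, not per gamete — the newborn rate
  already reflects selection acting before birth, which for this CNV class
  is known to be strong (the sperm-level rate is orders of magnitude
  higher).  Reciprocals are reported as "1 per N newborns"; the shipped
  tables give ≈1:26,500 maternal and ≈1:52,200 paternal, which we regard as
  agreeing with the published "≈1 per 27,000 / 50,000" framings to within
  their stated approximation (±10%).

## Synthetic populations and parameter recovery

The generator (`dup15q.simulate`) produces exactly the structure the
estimators assume, no more:

* **Balance process:** carriers of one parental-origin class evolve as
  C_{t+1} = Binomial(C_t, 1−s) + Poisson(μN).  The stationary mean is μN/s,
  embodying q = μ/s; the stationary de novo fraction among carriers is s,
  embodying the selection estimator.  Burn-in from an empty population mixes
  on a ~1/s-generation timescale; defaults (N = 10⁶, 300 burn-in, 100
  recorded generations) are chosen for statistical stability — the source
  analysis implies no particular census size or generation count.
  Validation runs use 2,000 recorded generations, giving ≥10⁴ carrier-
  generations so the de novo fraction is resolved to well under the 0.03
  tolerance tested.
* **Ascertainment:** each carrier develops SZ with probability pen_sz,
  DD/ASD/MCA with pen_dd, else none (one categorical draw — outcomes
  mutually exclusive).  Cohort carrier counts are binomial at the
  Bayes-forward prevalences q·pen/w; sampled carriers are labelled de novo
  at the *realized* de novo fraction of the equilibrium state, so the
  downstream s estimator is validated against the process rather than
  against its own input parameter.  Default cohort sizes are the pooled
  published ones (28,138 / 51,001 / 149,780) and the default truth is the
  published maternal operating point (q = 6.9×10⁻⁵, s = 0.55,
  pen_sz = 0.123, pen_dd = 0.505), under which the expected carrier counts
  are ≈24 / 44 / 4.
* **Recovery:** `recovery_experiment` repeats simulate→sample→estimate and
  reports bias, RMSE and interval coverage for q, both penetrances and s.
  At the default truth with 500 replicates the point estimates are unbiased
  to within Monte Carlo error (|bias(s)| < 0.01) and the propagated
  penetrance intervals cover the truth in ≈100% of replicates — the
  conservativeness noted above, measured rather than assumed.

What the generator does **not** emulate: diploid genetics, pedigree
structure, origin flipping on transmission through a parent of the other
sex, sex-biased fecundity, comorbidity between outcome classes, or
study-level heterogeneity in ascertainment.  Passing recovery therefore
shows the estimators are self-consistent under their own assumptions, not
that those assumptions hold in any particular real cohort.

## Numerical and interface choices

* All proportions are kept as fractions internally; percent formatting (two
  significant figures for prevalences, one decimal for penetrances) lives
  only in the report renderer.
* Randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical seeds give identical
  study sets bit-for-bit.
* Degenerate inputs fail loudly and specifically: empty usable-record
  selections, origin requests where every carrier is untyped, zero carrier
  tallies (the published table's own "n/a" cell), q = 0 divisions, and
  configurations whose implied cohort prevalence exceeds 1.
* Validation is eager: a `StudyRecord` cannot be constructed with a carrier
  sum exceeding its cohort size, and file readers report the first
  offending row by number.

## Known limitations

The mixture treats stratum membership as fixed and known; uncertainty in
the weights themselves is explored only through presets, not propagated.
The bound-propagation intervals are conservative by construction.  The
selection estimator assumes unbiased carrier ascertainment of de novo
status, which referral cohorts may violate.  Mutation rates inherit all
uncertainty in q and s multiplicatively and carry no interval.
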