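# Methods

`tcrstrat` quantifies a statistical argument about germline T cell
receptor (TCR) susceptibility alleles in autoimmune disease: if a risk
variant in a TRAV/TRBV gene acts only in carriers of a particular
high-risk HLA class II diplotype, its case-control odds ratio measured
over an unstratified cohort is diluted toward 1 and the study is
underpowered, whereas restricting cases to the relevant diplotype
restores both the odds ratio and the power. This note documents the
models, the numerical choices, and what the synthetic-data checks do and
do not establish.

## Odds-ratio dilution model

Let `f` be the fraction of cases carrying the risk diplotype and
`OR_s` the odds ratio of the candidate allele within that stratum. The
linear dilution model used throughout is

    OR_all = f * OR_s + (1 - f),

with the inversion `OR_s = (OR_all - (1 - f)) / f` defined whenever
`OR_all > 1 - f`. For the reference scenario — `OR_all = 1.1`,
`f = 0.076` (DR3/3 homozygotes among type 1 diabetes cases) — the
inversion gives `OR_s = 2.32`, reported as 2.3 at the package's default
two-significant-figure presentation. At `f = 0.38`
(DR3/4-DQB1\*03:02) it gives 1.26.

The linear mixture of odds ratios is a stated model, not an identity.
The generative truth of a cohort in which risk-stratum cases carry the
allele at frequency `p1` and everyone else at `p0` is frequency mixing:
the pooled case frequency is `pc = f*p1 + (1-f)*p0` and the exact cohort
OR is `odds(pc)/odds(p0)`. Because `p -> p/(1-p)` is convex, the exact
cohort OR never exceeds the linear prediction for `OR_s >= 1`; at the
reference scenario the gap is 1.1 (linear) vs 1.089 (exact), and it
vanishes toward the null. Both forms are exposed (`dilute_or` vs
`mixing_or`) so the approximation error is always inspectable, and the
simulator's parameter-recovery tests are asserted against `mixing_or`,
which is what a simulated cohort actually converges to.

A multi-stratum extension `OR_all = sum(f_i * OR_i) + (1 - sum(f_i))`
is provided with `sum(f_i) <= 1` enforced; the residual cohort carries a
null OR.

## Exact power of Fisher's exact test

Power is computed for the unconditional two-binomial sampling model with
the conditional Fisher rejection rule: carrier counts are
`a ~ Binomial(n1, p1)` in cases and `c ~ Binomial(n2, p0)` in controls,
and the design rejects when the Fisher exact p-value of the observed 2x2
table is at or below `alpha`. This is the construction standard power
software uses for the "Fisher exact" procedure. The two-sided Fisher
p-value follows the minimum-likelihood convention (sum of point
probabilities not exceeding the observed one, with a relative tie slack
of 1e-7); a mid-p variant is deliberately not offered so that all powers
refer to the same, conservative test.

Implementation: all hypergeometric and binomial mass is handled as
cached log-factorials with log-sum-exp accumulation, stable to group
sizes well beyond 10^4. The double sum over outcomes is organised by the
conditional margin `s = a + c`; within a margin the hypergeometric point
probabilities are unimodal, so the rejection region is the union of two
outer tails `{a <= a_lo(s)} u {a >= a_hi(s)}` located once per margin.
Each binomial is restricted to a central window carrying all but
`tail_mass_tolerance` (default 1e-12, required to sit below `alpha/100`)
of its mass. Exactness is verified against full double-binomial
enumeration with an independent Fisher implementation for group sizes up
to 25, to 1e-10.

Because the conditional test is conservative under binomial sampling,
its exact size is below alpha (0.044 at 2000 per group, alpha 0.05) and
its exact power sits below the two-proportion z-approximation; the
package ships the z-power (pooled variance under the null, unpooled
under the alternative) as a cross-check, and the two agree within 0.03
on all reference scenarios.

### Converting an odds ratio to a case frequency

Two conventions are implemented:

* **odds scale** (`case_freq_from_or`): `p1 = OR*p0 / (1 - p0 + OR*p0)`,
  the conversion consistent with the OR's definition;
* **multiplicative** (`scaled_case_freq`): `p1 = OR * p0`, i.e. the
  effect applied as a frequency ratio.

At `p0 = 0.10`, `OR = 1.1` these give `p1 = 0.1089` vs `0.11`, and exact
powers of 0.139 vs 0.165 at 2000 per group. The published figure for
this design is 16%: it is reproduced to the percent by the
multiplicative convention (and only by it), indicating that the original
power analysis entered the scaled frequency directly into its software.
The reproduction pipeline (`run_paper_scenarios`, `tcrstrat
reproduce-paper`, `scripts/acceptance.py`) therefore defaults to the
multiplicative convention, while library calls default to the odds-scale
conversion; every report records which convention produced it. The
stratified DR3/3 design has essentially full power (rounds to 100%)
under either convention. The companion published figure of 75% for the
DR3/4-DQB1\*03:02 stratum is not exactly recoverable from the stated
inputs under any convention implemented here (multiplicative gives 73%,
odds-scale 66%); no reported target depends on it.

"Background allele frequency of 10%" is read as a per-subject carrier
frequency (one binomial trial per subject), which is the reading under
which the published design reproduces; an allele-count mode (2n trials
per group) is available behind `mode="allele"`.

The stratified power keeps the full 2000-case count — a design enriched
to the stratum — which is the reading that reproduces the published
100%; `reduce_cases=True` instead analyses the `round(f*n)` stratum
cases of a fixed cohort, which at DR3/3 frequencies has visibly lower
power.

## LD attenuation

For an indirect test typed at a tag SNP with squared correlation `r2` to
the causal variant, power is computed at effective sample sizes
`floor(r2 * n)` per group (floored at one subject; `r2 = 0` returns
`alpha` by convention). The `n_eff = r2 * n` mapping is the standard
formalisation of the proportionality between LD and association power;
it is this module's modelling choice, not an estimated quantity.
Coverage lists of `r2` values are summarised by their mean and the
fraction at or above a threshold (default 0.8); the package never
queries LD resources itself and never imputes missing values.

## Synthetic cohort generator

`simulate_cohort` draws, conditional on case/control status: stratum
membership `Bernoulli(f)` for cases (and, for labelling only, for
controls), then carrier status `Bernoulli(p1)` for risk-stratum cases
and `Bernoulli(p0)` for everyone else, with
`p1 = case_freq_from_or(p0, or_stratum)`. Defaults mirror the reference
study conditions: `f = 0.076`, `p0 = 0.10`, 2000 cases and 2000 controls
in the power-validation scenarios. Disease prevalence is deliberately
absent — the design conditions on status, so prevalence is
unidentifiable and the argument is framed entirely in case/control
frequencies. Randomness uses NumPy's default generator; replicate `r`
of a Monte-Carlo run draws from `default_rng([seed, r])`, so any
replicate can be reproduced in isolation.

What the generator emulates: a binary marker with stratum-contingent
enrichment under exact binomial sampling. What it does not emulate:
diploid genotypes, haplotype phase, LD between the marker and other
loci, population stratification, genotyping error, or covariates.
Passing tests therefore show that the analytic engine is correct for its
own sampling model, not that real cohorts meet that model's
assumptions.

Monte-Carlo checks (fixed seeds, 3-standard-error bands): empirical
rejection rates match the exact power engine; the null design's
rejection rate respects alpha; cohort and stratum OR estimates recover
`mixing_or` and `or_stratum`; and the stratum-enriched DR3/3 design
rejects in >= 99% of replicates, consistent with its ~100% exact power.

## Polymorphism catalog

The packaged TSV transcribes the compiled set of nonsynonymous germline
TRAV/TRBV variants at pMHC-contacting regions (N-terminus, CDR1, CDR2
extended one residue N-terminally, HV4), IMGT residue numbering, one
record per substitution. Source rows list substitutions and genes as
separate, unequal-length sets without an explicit mapping, so each
record carries its row's full gene list; the distinct-position and
distinct-gene counts are invariant to that choice. The catalog spans 19
distinct (chain, region, position) triples and 21 distinct gene names by
direct count. Provenance distinguishes the reference allele catalog
from supplementary-literature additions.

## Numerical and degenerate-input conventions

* Odds ratio of a table with `b*c = 0`: `inf` if `a*d > 0`, `nan` if
  both cross products vanish; Haldane-Anscombe +0.5 correction only via
  an explicit flag.
* Fisher test on a table with an empty row or column: p = 1 with a
  warning (no information), never an exception.
* Dilution inversion at `OR_all <= 1 - f` raises a dedicated error;
  curve generation skips such grid points with a logged notice.
* Presentation rounding (two significant figures for ORs, whole percent
  for powers) is applied only in human-readable output; TSV/JSON outputs
  carry full precision.

## Problem sizes

The reference power computations run at 2000 subjects per group (a few
hundred margins of support a few hundred wide; well under a second
each). Monte-Carlo validation uses 2000 replicates at the reference
design, 500 for the near-saturated stratified design, 100 cohorts of
20000 per group for parameter recovery, and single cohorts of 2x10^5 to
4x10^5 subjects per group for large-sample recovery of the mixing OR.

## Known limitations

* The linear OR-dilution model is taken as given (it is the published
  model); its derivation is not re-examined, and the exact mixing OR is
  provided alongside precisely because the two diverge for large
  stratum effects.
* The one worked p-value printed as 0.03 in the source experiments
  corresponds to the one-sided Fisher test (0.0349; two-sided 0.0698);
  the original sidedness is not stated, and the package reproduces the
  printed value via the one-sided computation.
* Sample-size solving, covariate-adjusted power, multiple-testing
  correction across variants, and haplotype-level genetics are out of
  scope.
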