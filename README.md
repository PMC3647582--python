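# tcrstrat

**HLA-stratified case-control power analysis for germline TCR
susceptibility alleles.**

Germline variation in the T cell receptor V genes (TRAV/TRBV) touches
the loops that contact peptide-MHC, and animal models of type 1
diabetes show MHC-dependent TCR effects — yet human association studies
have found nothing at these loci. `tcrstrat` implements the statistical
explanation: a risk allele whose effect is contingent on one high-risk
HLA diplotype is *diluted* in an unstratified cohort, and the diluted
odds ratio can sit below the detection threshold of a well-powered
study. The package is for statistical geneticists and epidemiologists
who want to quantify that dilution, compute exact power for stratified
and unstratified designs, and validate both by simulation.

## The model

With `f` the fraction of cases carrying the risk diplotype and `OR_s`
the within-stratum odds ratio of the candidate allele, the cohort-level
odds ratio under the linear dilution model is

    OR_all = f · OR_s + (1 − f),      inverted as  OR_s = (OR_all − (1 − f)) / f.

At `OR_all = 1.1` and `f = 0.076` (DR3/3 homozygotes among cases) the
hidden stratum OR is **2.3**. The package pairs this with the exact
carrier-frequency mixing OR (the generative truth of its simulator), an
**exact power engine for Fisher's exact test** — unconditional binomial
sampling, conditional rejection rule, full enumeration in log space —
an LD attenuation model (`n_eff = r²·n`), a synthetic stratified-cohort
generator, and a catalog of germline TRAV/TRBV interface polymorphisms
(19 distinct IMGT positions).

## Worked example

```sh
$ tcrstrat reproduce-paper --out-dir outputs
DR3/3                    unstratified  OR   1.1 power  16%
DR3/3                    stratified    OR   2.3 power 100%
DR3/4-DQB1*03:02         unstratified  OR   1.1 power  16%
DR3/4-DQB1*03:02         stratified    OR   1.3 power  73%
poly I:C induction, anti-Vb13 vs control OR   0.02 p (two-sided) 2.1e-08
KRV trigger, anti-Vb13 vs control        OR   0.11 p (less) 0.035
full-precision outputs in outputs/
```

Reading the output: a cohort-wide OR of 1.1 at a 10% background carrier
frequency gives a 2000-vs-2000 study only 16% power (two-tailed Fisher
exact test, α = 0.05). Stratifying cases to the DR3/3 diplotype
concentrates the same signal to OR 2.3 and lifts power to 100%; the
commoner DR3/4-DQB1\*03:02 stratum concentrates it to 1.3 and 73%. The
last two lines are the rat Vβ13-depletion experiments that motivate the
stratum-contingent hypothesis, recomputed from their 2×2 outcome counts
(2/20 vs 34/40 diabetic, and 3/10 vs 8/10). Full-precision TSV/JSON
reports land in `outputs/`, including the stratified-vs-unstratified OR
curve over cohort ORs in [1.0, 2.0].

The same pieces are available as a library:

```python
from tcrstrat import (PowerSpec, concentrate_or, fisher_power_exact,
                      scaled_case_freq)

or_s = concentrate_or(1.1, f=0.076)            # 2.3158
spec = PowerSpec(n_cases=2000, n_controls=2000, alpha=0.05)
fisher_power_exact(spec, 0.10, scaled_case_freq(0.10, 1.1))   # 0.1647
fisher_power_exact(spec, 0.10, scaled_case_freq(0.10, or_s))  # 1.0000
```

Other subcommands: `tcrstrat stratify` (dilute/concentrate ORs, OR
curves), `tcrstrat power` (scenario power reports), `tcrstrat attenuate`
(LD-reduced power and r² coverage summaries), `tcrstrat simulate`
(synthetic cohorts and Monte-Carlo power), `tcrstrat catalog`
(polymorphism counts). See `docs/methods.md` for the models,
conventions and their rationale — including the two odds-ratio→case-
frequency conversions and why the reproduction pipeline defaults to the
multiplicative one.

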