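# virosnap

Week-96 virologic-outcome analysis for a two-arm switch trial of long-acting
injectable HIV therapy (cabotegravir + rilpivirine every 8 weeks) versus
continued daily oral therapy, built for biostatisticians and trialists who
need the full outcome pipeline — not just the final confidence interval — to
be reproducible and testable.

The package implements, as an installable library with a CLI and a set of
numbered analysis drivers:

- **Modified FDA snapshot classification** of the week-96 outcome into
  suppressed / nonsuppressed / no-virologic-data, using the weeks 84–102
  window (inclusive, days 588–714), per-participant window extensions, and
  three modifications to the treatment-switch rule: temporary changes ≤ 31
  days, oral bridging of the long-acting drugs with return to injections, and
  within-class changes in the oral arm are not switches. A prior switch *for
  virological failure* is assigned nonsuppressed regardless of later values.
- **Analysis populations**: intention-to-treat exposed (≥ 1 dose of assigned
  intervention), per-protocol (excluding, in precedence order, withdrawal or
  death before week 96; an injection more than 14 days late after subtracting
  oral-bridged days; more than 7 missed oral-treatment days at any visit),
  and complete case.
- **Confirmed virological failure (CVF)**: two consecutive viral loads
  ≥ 200 copies/ml, with arm-specific monitoring rules (retest 4–6 weeks after
  a ≥ 200 result on long-acting therapy; 10–16 weeks after a ≥ 1,000 result on
  oral therapy) and explicit adjudication records for single unconfirmed
  values.
- **APOBEC-aware resistance filtering**: drug-resistance mutation calls in
  the 14 APOBEC-context positions of RT/IN are disregarded when the carrying
  proviral sequence shows evidence of APOBEC hypermutation (a signature
  mutation or a stop codon); prevalence is reported with and without the
  filter.
- **Noninferiority statistics**: the Miettinen–Nurminen (MN) score interval
  for a difference of proportions, its Cochran–Mantel–Haenszel-weighted
  stratified form, Wald intervals for safety tables, a CMH-weighted
  homogeneity test, margin-based noninferiority decisions, and the standard
  sample-size formula for noninferiority of two proportions.
- **A synthetic-trial generator** (seeded, bit-reproducible) and a
  **deterministic reference fixture** whose pipeline outputs equal the
  trial's reported marginal tables, so every stage runs without any external
  data.

## The core statistic

For events/totals $x_1/n_1$ (long-acting) and $x_2/n_2$ (oral), the MN
100(1−α)% bounds for $\delta = p_1 - p_2$ are the roots of

$$z(\delta) = \frac{\hat p_1 - \hat p_2 - \delta}
  {\sqrt{\left(\frac{\tilde p_1 \tilde q_1}{n_1} +
  \frac{\tilde p_2 \tilde q_2}{n_2}\right)\frac{N}{N-1}}} = \pm z_{1-\alpha/2},$$

where $(\tilde p_1, \tilde p_2)$ are the maximum-likelihood estimates
restricted to $\tilde p_1 - \tilde p_2 = \delta$ (closed-form cubic solution)
and $N = n_1 + n_2$. The $N/(N-1)$ inflation distinguishes MN from
Farrington–Manning. The statistic is monotone in $\delta$, so each bound is
found by bisection to $10^{-10}$; the interval is finite and informative even
with zero events in one arm, which the Wald interval is not. Stratified
analyses pool stratum differences with CMH weights $n_{1k} n_{2k} / (n_{1k} +
n_{2k})$; noninferiority holds when the lower bound exceeds −10 percentage
points (suppression) or the upper bound stays below +4 (CVF).

## Worked example

```sh
python analysis/01_generate_cohort.py
python analysis/04_virological_failure.py
```

prints, for the reference cohort:

```
failures with the adjudicated case: 4/255 vs 0/257
failures without the adjudicated case: 3/255 vs 0/257
risk difference 1.6 pp (95% MN CI 0.1 to 4.0); 4 pp upper-bound criterion met
```

Three participants had two consecutive viral loads ≥ 200 copies/ml and one
further death 9 days after a 44,984 copies/ml result carries an adjudication
record, giving 4/255 failures in the long-acting arm versus 0/257 on oral
therapy. The MN interval for that difference is (0.1, 4.0) percentage
points: positive on the left (failure was genuinely more frequent on
long-acting therapy) and, by this computation, just inside the 4-point
margin. The remaining drivers (`02`, `03`, `05`, `06`) print the snapshot
tables (247/255 vs 250/257 suppressed at < 50 copies/ml), the per-protocol
reconstruction 255−4−22−5 = 224 and 257−5−37 = 215, the resistance
prevalences 14/208 (7%) filtered vs 25/208 (12%) unfiltered, and the full
stratified statistics block with the 119-per-group design calculation.

Equivalent CLI:

```sh
virosnap generate --fixture --out data/ref
virosnap report data/ref --out report/
virosnap stats --counts 4 255 0 257 --margin 4 --bound upper
```

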