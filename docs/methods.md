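# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic data do and do not emulate, and the design
decisions taken where more than one reading was defensible.

## Time axis and data model

All timing is integer study days with randomization at day 0; nominal week
*w* is day 7·*w*. Viral loads censored at the assay's lower limit ("<50") are
stored as `below_lloq=True` with `copies_per_ml=0`, and every threshold
comparison consults the flag before the value, so no sentinel value can leak
into arithmetic. Tables are comma-separated UTF-8 with header rows; aligned
amino-acid sequences travel as FASTA with record ids
`participant_id|timepoint|gene`, one character per reference position and
mixtures bracketed (`[NS]`) so that reference numbering survives mixtures.

## Snapshot classification

The week-96 outcome window is weeks 84–102 read inclusively (days 588–714),
with per-participant extensions for deliberately delayed tests (the
reference cohort carries four, extended to week 109). When several
measurements fall in a window the one closest in days to day 672 is used,
ties resolved toward the later measurement — standard practice for snapshot
analyses; the rule only matters when two measurements are equidistant, which
scheduled visits make rare. Three kinds of regimen change
are not treatment switches: temporary changes of at most 31 days, oral
dosing of the long-acting agents bridging a delayed injection with a
subsequent return to injections (recognized from bridge dose events, the
single source of truth for bridging intervals), and within-class changes in
the oral arm. A disqualifying switch whose reason is virological failure
forces `nonsuppressed` regardless of any in-window value; any other switch
leaves classification to the in-window measurement — consistent with a
no-data block containing only withdrawals and deaths. Among participants
without an in-window value the reported reason follows the precedence death
> withdrawal > missing-in-window, purely for deterministic reporting.

## Populations

ITT-exposed is everyone with at least one administered dose of assigned
intervention. Per-protocol exclusions are evaluated in a fixed precedence
(withdrew or died before week 96, then unbridged injection delay > 14 days,
then > 7 missed oral-treatment days at a visit) so each excluded participant
carries exactly one reason and the arm sizes reconstruct additively
(255−4−22−5 = 224; 257−5−37 = 215 on the reference cohort). Injection delay
is measured against the randomization-anchored target date (weeks 4, 8, 16,
…), not the previous actual injection, and bridged days overlapping the
delay interval are subtracted; a partially bridged delay therefore counts
only its uncovered days, a choice this note records because the source rule
specifies only that bridged days are excluded. The missed-oral rule is
evaluated per dispensing interval via the recorded missed-day streak.

## Confirmed virological failure

Failure is two *consecutive measurements* in the participant's day-sorted
series both ≥ 200 copies/ml, regardless of their spacing: the arm-specific
retest windows (4–6 weeks after ≥ 200 on long-acting therapy; 10–16 weeks
after ≥ 1,000 on oral therapy, leaving room for adherence counselling)
govern when measurements are generated, not how failure is defined. A single
qualifying value can be an adjudicated unconfirmed failure only through an
explicit adjudication record — never inferred — and is counted as failure
only when the pipeline is configured to do so (the default, matching the
reported counts). An oral-arm participant with two consecutive values in
[200, 1000) would be counted: the definition is measurement-based even where
the monitoring rule would never have triggered a retest; the generator does
not produce this ambiguous case by default.

## APOBEC-context resistance filtering

Host APOBEC3 editing of proviral DNA creates G→A hypermutants that are
usually replication-incompetent; resistance mutations attributable to that
process overstate the archived-resistance prevalence. A call is disregarded
iff (gene, position, one of its observed mutants) belongs to the 14-entry
APOBEC-context set {RT 67N, 138K, 184I, 190E, 190S, 230I; IN 118R, 138K,
140R, 140S, 163K, 163R, 232N, 263K} *and* the carrying sequence shows
APOBEC evidence: at least one signature mutation or at least one stop codon
(both kinds implemented; signature matches take precedence in the reported
evidence kind). Mixtures match if any observed mutant matches, the
conservative reading. Parsing follows the standard `RefAA?PosObs(/Obs)*`
notation, dropping a reference residue repeated inside a mixture
(`M230M/L` → {L}). The full signature reference lists (154 RT / 95 IN
positions in the public Stanford database) are deliberately user-supplied
data files; the shipped `apobec_signatures_synthetic.csv` is a synthetic
stand-in used by the simulator and tests, so all correctness guarantees are
independent of any particular transcription. The shipped DRM list is a
working subset covering the mutations this analysis encounters.
Susceptibility levels are out of scope: they require an external scoring
engine and enter only through user-supplied lookup tables.

## Noninferiority statistics

The Miettinen–Nurminen score interval uses the restricted-MLE variance with
the N/(N−1) inflation (the feature distinguishing it from
Farrington–Manning); the restricted MLE is the closed-form trigonometric
root of the constrained-likelihood cubic, and bounds are found by bisection
(Brent) on the monotone statistic with tolerance 10⁻¹⁰ over (−1, 1). The
stratified form pools stratum differences with CMH weights n₁ₖn₂ₖ/(n₁ₖ+n₂ₖ)
and solves the weighted score equation with per-stratum restricted MLEs; a
single stratum delegates to the unstratified routine so the two are equal to
the bit. Strata with an empty arm are excluded with a warning. The
homogeneity statistic is the CMH-weighted least-squares chi-square: squared
deviations of level differences about their CMH-weighted mean, each scaled
by the level's unrestricted variance estimate, with df = levels − 1 (the
exact form is not pinned down by the source and is recorded here as this
package's choice; its type-I error is verified by simulation in the test
suite). Noninferiority decisions use strict inequalities (a bound exactly at
the margin fails). Sample size is
⌈(z₁₋α/₂+z_power)²·(p₁q₁+p₂q₂)/(margin−|p₁−p₂|)²⌉ — 119 per group at p=0.94,
margin 0.10, α=0.05, power 0.90. Reported values are rounded half away from
zero to one decimal in percentage points, matching table conventions.

Cross-checks: a vectorized 10⁻⁶-step grid search over the score statistic is
the precision oracle for the MN bounds; statsmodels'
`confint_proportions_2indep(method="score", correction=True)` solves the
same equation and agrees to ~10⁻⁴ on zero-cell tables, though its coarser
root search can sit at |z| ≈ 1.92 on mid-sized tables, so that comparison is
held at 3·10⁻³.

## Synthetic data

`generate_trial` draws permuted-block 1:1 allocation within third-drug-class
strata (NNRTI fraction 0.08), visit-structured dosing (injections at weeks
4, 8, then 8-weekly to 96; oral dispensing 12-weekly), viral loads every 24
weeks, a per-visit rebound hazard that, once triggered, keeps values ≥ 200
until a simulated failure switch (making consecutive-pair detection
exercisable), retests placed mid-window by the arm's monitoring rule,
injection-delay categories (0 / 1–7 / 8–14 / ≥ 15 days) with probability
0.12 that a long delay is bridged, withdrawal/death hazards per 24-week
interval, per-participant adverse-event draws, and baseline sequences
carrying either a retained DRM or an APOBEC-context DRM on an
evidence-bearing sequence. Defaults are calibrated to the reported marginal
frequencies (97% suppression; long-acting failure hazard 0.0053 per
monitoring visit ≈ 1.6% cumulative; 10% of long-acting participants with a
> 14-day delay; 14% of oral participants missing > 7 days; 12% unfiltered /
7% filtered rilpivirine prevalence); where only a summary percentage is
reported the per-event probability was back-calculated once from the number
of opportunities and is not revisited. The generator does not model
pharmacokinetics, correlated adverse-event/viral-load processes beyond the
switch-on-failure link, calendar time, or sequence evolution — so passing
tests demonstrate the pipeline's rules and statistics, not biological
realism of trajectories.

`make_fixture` is the complementary instrument: outcomes are *assigned*, not
sampled, so pipeline outputs reproduce a specified marginal table exactly
and with no randomness. The reference fixture encodes the reported week-96
marginals (snapshot 247/4/4 and 250/2/5; failures 4 vs 0 including one
adjudicated death; per-protocol 224/215; complete case 251/252; resistance
14/208 vs 25/208 unfiltered). A variant
(`threshold200_fixture_spec`) redistributes one assigned failure to an
observed low-level value because the published < 200 row (249/251
suppressed) is arithmetically incompatible with three assigned failures
plus four no-data participants; the < 50 marginals are unchanged.

## Known limitations

- The reported CVF interval in the source tables, (0.4, 4.2), is not
  reproduced by the Miettinen–Nurminen equation on 4/255 vs 0/257 (which
  gives 0.1 and 4.0 at one decimal, confirmed by the grid oracle, by
  statsmodels, and by exact unconditional computation); this package reports
  the computed values. The associated noninferiority decision for failure on
  the reference cohort is therefore "met" (upper bound 3.97 < 4).
- The homogeneity test's exact weighting is this package's documented
  choice, simulation-calibrated rather than source-specified.
- Problem sizes in tests (10,000-participant recovery runs, 1,000-rep null
  simulations, 1,000 filter-oracle instances) were chosen to keep
  Monte-Carlo error well below the asserted tolerances while running in
  seconds.
- Nucleotide-level hypermutation statistics, subtype assignment,
  questionnaire scoring, body-composition and sensitivity regression
  analyses are out of scope.
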