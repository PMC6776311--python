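# Methods

## Sampling model

The sampling unit is the scat. Each scat carries a set of prey taxa
(presence only: a taxon identified twice in one scat counts once), a river,
and a collection year; rivers × years form the analysis groups. Aggregate
identification categories ("Catfish", "Unknown", "Unknown Insects", …) are
ordinary taxon codes: the niche-breadth indices are defined over recorded
diet categories, not over resolved species, and dropping the aggregates
would change every index. A `contaminated` flag excludes a scat from
isotope analyses only — contamination (mud, wood, termite nest) spoils the
fecal matrix used for mass spectrometry, not the identifiable hard remains.

Two occurrence summaries are kept side by side because the literature's
"percentage of occurrence" is ambiguous between them: %S (share of scats
containing the taxon; sums above 100) and %R (the taxon's share of all
prey records; sums to 100). %R is the vector used downstream, both as the
p_j of Levin's index and as the diet-composition DC_ij of the trophic
computation, because only %R is a probability vector. Percentages are
always computed from raw counts and rounded to one decimal only for
display.

## Niche breadth

Levin's index B = 1/Σp_j² (inverse Simpson concentration) and its
standardized form B_a = (B−1)/(n−1), with n the number of categories
actually recorded (count ≥ 1). A single-category diet has B_a ≡ 0. The
interpretive labels (generalist above 0.6, specialist below 0.4) are
attached to results but never alter a computation.

Confidence intervals resample scats — not individual records — with
replacement to the original group size, re-tabulate, and recompute the
statistic; bounds are the 2.5 %/97.5 % empirical percentiles of 1000
replicates by default, reported sorted ascending. n is recomputed on each
replicate, so replicates that lose rare taxa have a smaller denominator.
This gives the replicate distribution of B_a a slight upward bias relative
to the plug-in estimate in very evenly spread collections; percentile
intervals therefore need not bracket the point estimate exactly, though
any excursion is orders of magnitude smaller than the interval width.
Replicates on which a statistic is undefined (e.g., an all-empty resample)
are dropped with a warning; more than half missing is an error. No
bias-corrected (BCa) adjustment is applied — the interval is the plain
quantile pair.

## Species accumulation

The sample-based expected-richness curve uses the closed form
τ(h) = S_obs − Σ_j α_jh·S_j, α_jh = (H−h)!(H−j)!/((H−h−j)!H!), where S_j
counts taxa occurring in exactly j of the H scats. α_jh is the probability
that a taxon present in j scats is missed by a random h-scat subset, so
τ(h) is *exactly* the mean richness over all C(H, h) subsets (verified
against exhaustive enumeration in the tests). α_jh is defined as 0 when
j > H − h, where the factorial form is undefined; this is also what forces
τ(H) = S_obs. Factorial ratios are evaluated in log-gamma space and the
result clamped to [0, 1]: the largest study group has H = 117 scats, far
beyond naive factorials.

The closed form carries no distribution-free uncertainty; the band
reported is a scat-bootstrap percentile band, chosen for consistency with
the rest of the package. It is conditional on the observed collection and
is not comparable to unconditional variance estimators used by some
rarefaction software.

## Trophic level

The consumer's fractional trophic level is FTL_i = 1 + Σ_j FTL_j·DC_ij
(one level above the diet-weighted mean of prey levels). DC_ij is the
group's %R/100 vector; taxa without a reference FTL (unidentified
categories, the one cichlid and the prawn lacking published values) are
excluded and DC renormalized over the remainder, with exclusions reported
on the result. Whether diet proportions should be %R- or %S-based is a
genuine design fork; %R is the default because it is the normalized
composition vector, and the counts-in/proportions-out API makes the
alternative a one-line caller change. Bootstrap intervals delegate to the
same scat-resampling machinery.

Prey FTL values ship as a versioned CSV (no live database access), with
realistic trophic levels for the regional fish fauna and, for the
freshwater crab, the mean of values reported for similar species; the
source is recorded per row. Published group-level FTL point estimates
cannot be reproduced exactly without the original lookup values, so the
packaged table is a fixture: the pipeline's five group FTLs are regression
checks against this table, with the scientific assertion being the
documented band [3.0, 4.0] and the invasion-driven decline pattern, not
the third decimal. The trophic-enrichment constants (3.4 ‰ ± 1.0 per level
for δ¹⁵N, 0.4 ‰ ± 1.3 for δ¹³C) convert between δ¹⁵N differences and
trophic shifts: shift = Δδ¹⁵N / 3.4.

## Isotope statistics

Group variances (unbiased, ddof = 1) of δ¹⁵N and δ¹³C serve as isotopic
niche widths. Homoscedasticity is tested with Levene's statistic — the
one-way ANOVA F on absolute deviations from the group center — with the
center configurable between mean (classical, the default) and median
(Brown–Forsythe); the choice is recorded on every result. Mean δ¹⁵N is
compared with a two-factor river × year ANOVA with interaction, sequential
(Type-I) sums of squares, on natural-log-transformed values (all δ¹⁵N in
this system are positive; δ¹³C, always negative, is never
log-transformed). Post-hoc contrasts are two-sample t-tests with
p-values multiplied by the number of contrasts (capped at 1). The
equal-variance policy is "auto" by default: Welch when a pairwise Levene
test rejects at 0.05, pooled otherwise — the reported degrees of freedom
in this study match pooled tests for homoscedastic pairs and
Welch–Satterthwaite for the heteroscedastic one, which is what "auto"
produces. Shapiro–Wilk checks (3 ≤ n ≤ 5000) are advisory: they log a
verdict and never gate a computation.

## Synthetic data

The diet generator draws, per scat, an item count K = 1 + Poisson(mean−1)
truncated to the number of available taxa, then K distinct taxa by
weighted sampling without replacement. Without-replacement draws make the
induced per-record taxon shares differ from the nominal weights whenever
scats hold several items (dominant taxa are capped at one record per
scat). Rather than pretending the nominal weights are the truth, the
module computes the induced shares exactly — inclusion probabilities by
dynamic programming over drawn subsets (feasible to 18 taxa), marginalized
over the truncated item-count distribution — and defines the scenario's
analytic B_a and FTL from them. Parameter-recovery tests target these
exact values (B_a within 0.01 and FTL within 0.02 at 10⁴ scats; group
variances within 5 % at n = 10⁴).

The isotope generator draws group-wise normals; an optional coupling sets
a group's mean δ¹⁵N to a baseline minus TEF × (invader share) × (prey FTL
gap), encoding the mechanism by which eating a low-trophic-level invader
lowers the consumer's δ¹⁵N. Default scenarios use the study's group sizes
(36/34/20/55 uncontaminated scats in the invaded-river groups, 31 in the
uninvaded river), reported variances (δ¹⁵N 2.45/1.80/4.83/1.73; δ¹³C
3.65/6.49/2.04/7.09), and δ¹⁵N means anchored so the across-year mean
differences equal the reported 1.88 ‰ and 2.78 ‰ within the reported
overall range; δ¹³C means are plausible lowland-river values (means were
not reported and nothing downstream depends on them).

What the generator does *not* emulate: latrine-level clustering (scats
from a shared latrine are not independent; no latrine IDs exist), seasonal
or spatial structure, differential digestibility between prey types, and
isotope-value dependence on individual identity. Passing recovery tests
therefore show the estimators are consistent for the generating process,
not that field scats satisfy its independence assumptions.

## Study fixture

The packaged occurrence counts (records per taxon per river-year plus
scats per group) expand into a scat-level collection by a fixed rule: a
running offset assigns each taxon's c records to c distinct scats, round
robin modulo the group size. Re-tabulating the expansion reproduces the
record counts, %R and %S exactly. The assignment itself is
underdetermined by the marginals; the round-robin rule is maximally even,
which slightly understates between-scat variance relative to real, clumped
collections — bootstrap widths on the fixture are order-of-magnitude
comparable to, not equal to, the study's printed quantile gaps.

## Pipeline conventions

Years collapse to early/late eras (default: 2009–2010 early) for the
comparison scheme: within-river across eras for rivers sampled in both,
across rivers within an era. The ANOVA includes only rivers sampled in
both eras (a 2 × 2 design; with the study's group sizes its residual df is
141). Output tables are plain CSV, byte-identical across runs at equal
config and seed; per-group bootstrap streams are spawned from the single
seed so group order cannot leak randomness between groups. Exit codes: 0
success, 2 input-schema error, 3 no runnable stage.

## Problem sizes

Default verification runs use 10⁴–10⁵ synthetic scats for recovery checks,
200 outer simulations × 1000 bootstrap replicates for interval coverage
(the vectorized incidence-matrix bootstrap makes this cheap), 200
replicates for Levene power, and exhaustive subset enumeration up to H = 8
scats for the accumulation oracle. These sizes put Monte Carlo noise well
below each test's tolerance.

## Known limitations

* Occurrence-based diet proportions ignore biomass: abundant, identifiable
  hard remains over-represent some prey regardless of mass consumed.
* The accumulation band and the niche/FTL intervals are conditional
  bootstrap bands; they do not model detection failure or latrine
  dependence.
* Prey FTL values are fixture values, not a maintained taxonomic database;
  group FTL third decimals move with the lookup table.
* The isotope module assumes δ values arrive calibrated from the
  instrument; `delta_value` exists for completeness and synthesis, not for
  reprocessing raw ratios, and no baseline or drift correction is applied.
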