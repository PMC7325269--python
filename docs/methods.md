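# Methods

## Model

`rhoclock` dates the most recent common ancestor of a clade from a rooted tree
whose branch lengths are whole-molecule mutation counts. The tree is assumed
homoplasy-free (multiple hits resolved upstream, each branch mutation a
distinct site) and mutations are modelled as independent Poisson processes per
lineage with rate μ (mutations per year on the whole molecule).

**Coalescent periods.** Internal nodes are coalescent events; period *i* is
the interval during which exactly *i* ancestral lineages exist. Writing
γ<sub>i</sub> for the mutations accumulated across all lineages during period
*i*, the per-period rho is ρ<sub>i</sub> = γ<sub>i</sub>/i (the mean per
extant lineage) and the modified rho is ρ<sub>m</sub> = Σ ρ<sub>i</sub>.
Since each period's duration is estimated by ρ<sub>i</sub>/μ and periods tile
the root-to-tip interval, the unscaled age is ρ<sub>m</sub>/μ. Because a sum
of independent Poisson counts is Poisson, ρ<sub>m</sub> inherits a compound
Poisson structure; this motivates the uncertainty convention below.

**Time-dependent scaling.** The number of extant lineages falls stepwise
going backward — a proxy for a shrinking effective population size. Under
neutrality the substitution rate in a population whose size changes between
consecutive generations is Ɵ = (N₁/N₀)·μ, with neutral fixation probability
q = (N₁/N₀)·(1/N₀) (both exposed as `fluctuating_substitution_rate` and
`fixation_probability`; q is clamped to 1 with a warning for extreme growth,
the relation being first-order). Counteracting that dependence backward in
time, the rate in each internal period *i* is scaled by i/(i+1), the tip
period (i = n) keeping the unscaled germline rate. Equivalently the age is

    age = (1/μ) · ( ρ_n + Σ_{i=2}^{n-1} (i+1)/i · ρ_i ) .

Only the single-step size relation is implemented; compounding over multiple
generations (which telescopes to N_final/N_initial) is deliberately out of
scope.

## Period decomposition of a tree

A cladogram orders coalescences only partially (a parent cannot precede its
child). Within that constraint nodes are ranked from recent to ancient by
(1) mean mutation-count distance to descendant tips, ascending; (2) number of
descendant tips, ascending; (3) smallest descendant tip label — a
deterministic convention, invariant to the child order of the input Newick.
It is one defensible ordering, not the only one; for published period tables
the TSV input route is authoritative and bypasses the ordering entirely.
A multifurcation with c children drops the lineage count by c−1 in one event,
so intermediate period indices can be skipped (no zero-mutation periods are
fabricated for them).

A branch whose end events are not consecutive spans several periods. Its
mutations are apportioned across the spanned periods in proportion to the
mutation totals of the *internode* branches (those confined to a single
spanned period), as exact `Fraction`s, so Σ γ<sub>i</sub> equals the tree's
total branch mutations exactly. When all internode weights are zero the
mutations are spread uniformly (logged); conservation is never violated.
Re-integerising apportioned counts would break conservation, so fractional
γ<sub>i</sub> are kept. A tip branch confined to one period that carries more
than 5 mutations triggers a plausibility warning (under a Poisson process one
period rarely accumulates more per lineage); nothing is filtered — the window
is documentation, not an action.

## Rounding modes

* `table` (default) freezes the reference arithmetic chain: scale factor
  rounded to 2 decimals → scaled rate = factor·μ rounded to 3 significant
  figures → years-per-mutation = round(1/scaled rate) → period years =
  round(ρ_i · years-per-mutation), all half-up. This reproduces the worked
  example digit for digit (10,416 + 12,422 + 2,907 + 4,651 = 30,396 years).
* `exact` does the same computation in exact rational arithmetic
  (30,425.29 years on the same table, within 0.5% of table mode).

All interior rounding is half-up (ties away from zero), not banker's.

## Uncertainty

The default rule treats the age in kiloyears as a Poisson mean:
sd = √(1000 · age_years), rounded to the nearest year; the 95% interval is
age ± 1.96 · sd using the *rounded* sd (the rounded-first convention is what
reproduces the reference interval bounds exactly; using the unrounded sd
shifts some bounds by one year). A statistically explicit alternative,
`compound_poisson_uncertainty`, propagates per-period Poisson variance,
Var(years_i) = γ_i · (years-per-mutation_i / i)², and is labelled as an
alternative in reports; it is never used for the reference intervals. The
kiloyear rule's implied variance has no per-datum derivation — it is a
reverse-engineered convention validated against five independent printed
intervals — which is why both are exposed.

## Rate configuration

`RateModel` defaults: one whole-molecule mutation per **4651 years**
(equivalently μ ≈ 1.3 × 10⁻⁸ per site per year over 16,569 sites of human
mtDNA); generation time 20 years is carried as metadata (the rate scalar is
already in years). Per-site Newick branch lengths can be converted with the
sequence length (`--per-site-lengths`). Dating runs entirely on
years-per-mutation.

## Simulator

`simulate_kingman_tree` draws a haploid (mtDNA-style) Kingman coalescent:
with *i* lineages and current effective (female) size N the total coalescence
rate is i(i−1)/2 · (1/N) per generation (pairwise rate 1/N), so E[T₂] = N
generations and E[TMRCA] = 2N(1−1/n) under constant size. Piecewise-constant
size schedules are handled by advancing to the next schedule change whenever a
drawn waiting time crosses it. Branch mutation counts are Poisson with mean
duration_years / years-per-mutation. Defaults emulate a human-mtDNA-like
setting: N = 5000, generation time 20 y, one mutation per 4651 years — under
which a 10-tip sample has E[TMRCA] = 180,000 years and roughly 40 mutations
per root-to-tip path.

What the simulator does *not* emulate: homoplasy and mutation-rate
heterogeneity among sites or lineages, sequence-level errors, selection,
sampling structure, or any specific inferred human demography. Passing
recovery tests therefore show that the estimator behaves as designed under its
own model assumptions, not that real mtDNA trees satisfy those assumptions.

`recovery_experiment` simulates, decomposes and dates each replicate twice —
unscaled (ρ<sub>m</sub>/μ) and scaled (exact mode) — reporting mean bias,
RMSE and empirical coverage of the Poisson-kiloyear interval against the true
TMRCA. Under constant size the unscaled estimator is unbiased
(E[γ<sub>i</sub>] = i·μ·E[duration<sub>i</sub>]); the scaled age is strictly
larger whenever any internal period carries a mutation. Test problem sizes
(2000 replicates at n = 10; a few thousand replicates for the analytic-mean
checks) keep Monte-Carlo error at the 3-standard-error tolerance the tests
assert.

## Bundled example data

`rhoclock/data/five_lineage_tree.nwk` is a synthetic 5-tip tree constructed so
that its decomposition reproduces the worked example's period table exactly
(γ = {2:3, 3:6, 4:2, 5:5}). The genealogy it stands in for is not
machine-readable, and the period table does not determine branch-level
mutation placement, so the fixture's classic rho (7.8) is not the source
genealogy's (≈4.79, as implied by its classic-rho age of 22,277 years at 4651
years/mutation); this is documented rather than forced. All dating arithmetic
operates on the period table, which is exact.

## Numerical and design choices

* All mutation bookkeeping uses `fractions.Fraction`; conversion from Newick
  float lengths goes through `repr` so decimal tokens are exact.
* Unifurcations are collapsed on input (branch counts summed); a root branch
  length is ignored with a warning; missing branch lengths are an error rather
  than silently zero.
* Sample size n for dating a period table is the largest period index.
* Reported reference-style output (reports, CLI) defaults to table mode and
  the Poisson-kiloyear rule; `--no-timestamp` makes reports byte-identical.
* Known limitations: the event-ordering convention can differ from the
  (unstated) ordering used to build any published period table — feed period
  tables directly when reproducing published numbers; the kiloyear uncertainty
  rule is a convention, not a likelihood-based interval; ages from trees with
  heavy multifurcation near the root lean on the apportionment rule where the
  data are least informative.
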