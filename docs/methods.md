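# Methods notes

This note records the modeling choices, conventions, default parameters and
known limitations behind each analysis stage, in the spirit of a statistical
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Time and age conventions

All internal times are days. Day 0 is the day embryos were laid; lifespans
are integer days on that scale, and "adult lifespan" subtracts a
species-specific development offset (2 d for *C. elegans* and the *fog-2*
control, 4 d for *C. inopinata*, configurable in `Config.adult_offset_days`).
Hourly hatching observations are converted to days (hours/24) at read time
so a single unit flows through every stage. In life tables, offspring
counted on adult day d contribute at calendar age maturation_day + d, using
the same offsets as the adult-lifespan transform — the only age anchors the
assays provide.

## Milestone attainment

Attainment-versus-time records are modeled as independent Bernoulli draws
with logit-linear probability in time; observations are not binned, and
worms that never reached a milestone during the assay are dropped at read
time (with a logged count), because they carry no information about
attainment *time* and the assays stopped scoring them.

Fitting is maximum likelihood via IRLS (statsmodels GLM, binomial family),
relative log-likelihood tolerance 1e-10, 100 iterations. The median time is
t50 = −β₀/β₁; its CI uses the delta method on the coefficient covariance
(gradient [−1/β₁, β₀/β₁²]). Step-like data (hatching checked hourly) can be
perfectly separated; that case is detected exactly (every status-0 time
precedes every status-1 time, or the IRLS slope diverges past 1e4) and
reported as the midpoint of the empirical transition interval with an
infinite-slope flag instead of failing.

The species comparison is a 2-df likelihood-ratio test: pooled intercept +
slope versus that model plus a species indicator and species × time
interaction. Two degrees of freedom is the only structure consistent with
testing both a level and a rate difference at once. Probit or
complementary-log-log links and plate-level random effects are out of scope.

## Survivorship and proportional hazards

Kaplan–Meier curves, medians, and the Cox comparison are implemented
directly (the product-limit estimator and the one-covariate Efron partial
likelihood are a few dozen lines each) so the package can promise contracts
a wrapper cannot: the Newton solver drives the partial-likelihood score
below 1e-10, label swaps negate the log hazard ratio to within 1e-10, and
the curve object exposes the at-risk and death counts entering every
factor. lifelines remains in the dependency set purely as an independent
cross-check in the test suite, where both routes must agree.

Ties are handled with the Efron correction — daily scoring makes ties the
rule, not the exception. Censoring is supported (an optional `censored`
column defaulting to false); the lifespan assays followed every worm to
death, so the default path is uncensored. Monotone likelihoods (e.g. all
deaths in one group preceding the other) drive the estimate to infinity;
because the score also decays to zero out there, detection combines a
non-vanishing score with an implausible magnitude (|log HR| > 10) and
returns a flagged infinite estimate rather than raising.

The published lifespan comparisons used a mixed proportional-hazards model
whose random-effect structure is not recoverable from the text; this
package deliberately fits the fixed-effect model and treats published
z-values as directional checks only. With idealized Weibull cohorts the
fixed-effect z is considerably larger than the published mixed-model
values, as expected when between-plate variance is not absorbed.

## Rank-sum and Fisher tests

Both tests are implemented from first principles because the package's
comparisons hinge on their exact conventions.

Rank-sum: the statistic is the Mann–Whitney U of the *first* sample
(pairs with x > y plus half the ties), identical to the W that R's
`wilcox.test(x, y)` prints; both orderings are reported since U₁ + U₂ =
n₁n₂. The exact two-sided p doubles the smaller tail of the full null
distribution (built by the standard counting recursion, O(n₁n₂(n₁+n₂))) and
applies when both samples have n < 50 and no ties; otherwise a normal
approximation with tie-corrected variance and continuity correction 0.5 is
used — the same switchover rule as R's default. scipy's "exact" method
silently ignores ties, so cross-checks against scipy use tie-free inputs.

Fisher: the two-sided p sums conditional hypergeometric probabilities of
all tables at most as probable as the observed one (the
probability-at-most-observed rule, not tail doubling), and the odds ratio
is the conditional MLE — the ψ solving E_ψ[a] = a_obs for the noncentral
hypergeometric distribution, found by Brent's method on log ψ with the mean
computed via log-sum-exp. Observed counts on the edge of their support give
OR 0 or ∞ with a flag; a zero margin gives p = 1 with the OR undefined.
On the published failed-cross counts (10 of 30 vs 5 of 30) this machinery
yields OR = 2.46, p = 0.23 to the printed precision, which the acceptance
suite verifies.

## Life tables and the Euler–Lotka equation

Survivorship l_x starts at 1, declines linearly to the embryo-to-adult
viability at the maturation day (the assays say nothing about the shape of
pre-adult mortality; a ramp is the least-structured monotone choice), and
thereafter equals viability × the adult survival curve — the lifespan assay
follows worms that did mature, so its survival is conditional on
maturation. Fecundity m_x is the mean embryos laid per female still under
observation on that day; females already dead or finished laying leave the
denominator, and females that failed to reproduce at all remain in it.
The `daughters_half` option halves m_x for strict female-counting in
gonochoristic cohorts; the default counts all offspring.

r is the unique real root of Σ e^(−r·x) l_x m_x = 1 (the left side is
strictly decreasing in r whenever reproduction occurs at positive ages),
found by bisection from a geometrically expanded [−10, 10]/day bracket to
|f(r)| < 1e-13; negative r (declining cohorts) is handled symmetrically,
and R0 = 1 returns r = 0 exactly. The simulator's `analytic_r` solves the
same equation on the *expected* schedule with an independent root finder
(scipy Brent), giving a dual-route check that the tests exploit.

Confidence intervals use a seeded percentile bootstrap (default B = 1000,
`Config.bootstrap_reps`) resampling individuals — females with their whole
schedules, worms with their death days, plates with their viabilities —
because per-day resampling would destroy the within-female correlation of
laying. Resamples with zero net reproduction are recorded as failures and
the estimate is flagged when they exceed 10%. The percentile method is the
least-assumption default; nothing in the published analyses pins down a
different construction.

## Phenotype-set intersections

Term matching is exact on whole tokens (case-insensitive, trimmed) against
both the mutant-phenotype and RNAi-phenotype columns, with comma, semicolon
and pipe accepted as list delimiters; substring matches are rejected so
"long" never fires on "elongated". Genes with empty or "N.A." phenotype
cells count toward the gene total with all-false flags. Intersection counts
are exclusive (a gene's flag set must equal the subset exactly), which is
what an UpSet matrix plot displays. Ontology-graph expansion (descendant
terms) is deliberately not performed.

## The simulator and what it does not emulate

Per worm: a latent milestone time from a logistic distribution (location
t50, scale 0.25 d; 0.05 d for near-step hatching) so the attainment GLM is
correctly specified and recovery isolates estimator error from
misspecification (a normal-latent mode exists behind `latent_family` to
probe the latter); a death day ceil(Weibull(shape 5, species scale)); daily
embryo counts negative-binomial around a mean profile (size k = 2 —
strongly overdispersed, as worm daily counts are; k = ∞ gives Poisson and
k = 0 is a deterministic sentinel), truncated at death, and zeroed entirely
for failed crosses; plates with Poisson(60) embryos (min 5) and binomial
maturation.

Preset parameters are the published study conditions wherever the papers
state them: milestone medians (2.7/6.7 d reproductive onset at 20 °C),
median total lifespans at 25 °C (16/19/20 d — Weibull scales 16.7/19.9/21.0
chosen so the discretized median lands centrally on those values),
successful-brood totals under continuous mating (145/65, front-loaded over
four adult days for *C. elegans*, spread over six for *C. inopinata*),
cross-failure rates (1/3 and 1/6), *C. inopinata* viability medians by
temperature (0.63/0.84/0.79/0.88), and maturation offsets (2/4 d). Values
the papers do not print — Weibull shape, profile shape within the stated
total and duration, NB dispersion, *C. elegans* viability (set high,
0.93–0.95, consistent with its being reported only as "higher") — were
fixed once at field-realistic values and are not calibration knobs.

What the simulator does **not** emulate: plate effects and any other shared
environment (so mixed-model z-values are not reproducible), between-female
heterogeneity in lifetime fecundity beyond NB day noise, male dynamics,
density dependence, larval-stage mortality structure (the l_x ramp), and
measurement error in milestone scoring. Passing recovery tests therefore
demonstrates estimator correctness under the stated generative model, not
robustness to these real-data features.

## Problem sizes and numerical defaults

The test suite and acceptance script run simulations at the published
sample sizes where those are small (n = 30 fecundity crosses, 10–18
viability plates, 263–444 lifespan worms, 380–677 milestone worms) and at
a few hundred individuals per cohort elsewhere; bootstrap replicates are
100–200 in tests (default 1000 in the API), and the bootstrap-coverage
simulation uses 120 cohorts of 60 females with 120 replicates each. These
sizes were chosen so the whole suite completes in well under a minute per
module while keeping Monte-Carlo error far below every asserted tolerance.

Numerical defaults in one place: IRLS tolerance 1e-10 (100 iterations);
Cox Newton score tolerance 1e-10 with steps clipped to ±5; Euler–Lotka
bisection |f| < 1e-13; Fisher CMLE Brent tolerance 1e-12 on log ψ;
brood-fraction normalization checked to 1e-12; all RNG through
`numpy.random.default_rng` with every consumer seeded explicitly.

## Known limitations

- The fixed-effect Cox model is a deliberate simplification of the
  published mixed fits; published z-values are matched in direction only.
- The day-8 brood-fraction style comparisons exclude females with no
  observation that day (dead or finished); treating them as zeros is a
  defensible alternative the package logs but does not default to.
- Life-table construction assumes lifespan, fecundity and viability were
  measured on the same population under the same conditions; it cannot
  detect cohort mismatches beyond species/temperature metadata checks.
- The exact rank-sum null is computed only below n = 50 per sample and
  without ties; beyond that the tie-corrected normal approximation is
  standard but approximate at extreme tails.
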