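# wormlife

Comparative life-history analysis for *Caenorhabditis* cohort data.

`wormlife` turns the four classic bench assays of nematode life history —
developmental-milestone checks, lifespan scoring, daily egg counts, and
plate-level embryo-to-adult viability — into the quantities comparative
biologists argue about: median milestone times, survivorship curves and
median lifespans, brood-size distributions, and above all the intrinsic
rate of natural increase *r*, the composite fitness measure that weighs
*when* a female reproduces as heavily as *how much*. It was built for the
comparison of the outsized, slow-developing fig-dwelling *C. inopinata*
with *C. elegans* (wild-type N2 and the obligate-outcrossing *fog-2*
pseudo-female control), but every stage works on any long-format cohort
table.

## The models at the core

**Milestone timing.** Each worm is scored 0/1 for having reached a
milestone (hatching, L4, young adulthood, onset of reproduction) at each
observation time. A binomial GLM with logit link,
P(status = 1 | t) = expit(β₀ + β₁t), turns these into an attainment curve;
the median milestone time is t₅₀ = −β₀/β₁, with a delta-method CI. Species
are compared with a 2-df likelihood-ratio test (species main effect +
species × time interaction).

**Survivorship.** Kaplan–Meier product-limit curves over integer days
since egg lay (day 0 = egg laid); median lifespan is the first day with
S(t) ≤ 0.5. Adult lifespan subtracts each species' development time
(2 d *C. elegans*, 4 d *C. inopinata*). Groups are compared with a
fixed-effect Cox proportional-hazards model using the Efron tie
correction, fitted by Newton iteration on the partial likelihood.

**Fecundity.** Per-female daily embryo counts give lifetime broods,
per-day brood fractions, and group medians with or without failed crosses.
Comparisons use a self-implemented Wilcoxon rank-sum test (exact null
distribution below n = 50 without ties; tie-corrected normal approximation
otherwise) and Fisher's exact test with the conditional-MLE odds ratio,
matching R's `wilcox.test`/`fisher.test` conventions.

**Demography.** A life table pairs survivorship l_x (viability ramp to the
maturation day, then viability × adult survival) with per-capita daily
fecundity m_x. The intrinsic rate of increase solves the Euler–Lotka
equation

    Σ_x e^(−r·x) · l_x · m_x = 1

by bracketed bisection; confidence intervals come from a seeded percentile
bootstrap over individuals (females, worms, plates).

**Phenotype sets.** A WormBase simplemine export is scanned for exact-token
membership in four life-history phenotype terms ("long", "slow growth",
"extended life span", "reduced brood size"), and exclusive (UpSet-style)
intersections are counted.

**Simulator.** `wormlife.simulate` generates all four observation tables
from known parameters (logistic latent milestone times, Weibull deaths,
negative-binomial daily counts, binomial plate viability) together with the
analytic *r* of the generative model, so every estimator can be checked by
parameter recovery.

## Worked example

Simulate a *C. elegans*-like cohort and estimate its rate of increase:

```
$ wormlife simulate --species C_elegans --n 200 --seed 17 --outdir demo
analytic r = 1.3167
$ wormlife demography --lifespan demo/lifespan.tsv \
    --fecundity demo/fecundity.tsv --viability demo/viability.tsv \
    --reps 200 --seed 17 --out demo/rates.tsv
  species        r        R0   ci_low  ci_high  seed  reps
C_elegans 1.344512 97.542988 1.302896 1.392099    17   200
$ wormlife lifespan --input demo/lifespan.tsv --out demo/surv.tsv
C_elegans	n=200	median=16.0
```

The simulated cohort's estimated intrinsic rate (r = 1.34/day, 95% CI
1.30–1.39) brackets the generative model's analytic value (1.3167): a
population with this schedule grows e^1.34 ≈ 3.8-fold per day once its age
structure stabilizes. R0 ≈ 98 is the expected lifetime offspring per
individual after viability losses, and the Kaplan–Meier median total
lifespan of 16 days matches the Weibull the cohort was drawn from. The same
commands run unchanged on real observation tables; `wormlife run --inputs
<dir> --out <dir>` executes every stage whose input table is present and
writes a seeded `manifest.json` with input checksums for reproducibility.

In Python, the milestone model is a scikit-learn-style estimator:

```python
from wormlife import LogisticAttainment
model = LogisticAttainment().fit(times_days, status01)
model.t50_          # median milestone time, days
model.predict_proba([2.0, 3.0])
```

## Layout

- `src/wormlife/io.py` — TSV schemas, validation, alias maps
- `src/wormlife/milestones.py` — logistic attainment model, t₅₀, species LRT
- `src/wormlife/survival.py` — Kaplan–Meier, medians, Cox comparison
- `src/wormlife/fecundity.py` — broods, exact rank-sum and Fisher tests
- `src/wormlife/demography.py` — life tables, Euler–Lotka, bootstrap CIs
- `src/wormlife/phenotypes.py` — simplemine parsing, UpSet intersections
- `src/wormlife/simulate.py` — cohort simulator and analytic ground truth
- `src/wormlife/pipeline.py`, `cli.py` — orchestration and the `wormlife` CLI
- `docs/methods.md` — modeling assumptions, conventions, and limitations
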