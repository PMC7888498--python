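# Methods

## The model

`ltam` estimates genetic parameters for four sow traits analysed jointly:
litter size (number born alive) at parities 1–3 — NBA1, NBA2, NBA3,
treated as continuous — and stayability from first to fourth farrowing
(STAY14), a binary trait modelled through a Gaussian liability with a
threshold at 0. The linear-threshold animal model is

    y = Xβ + Za + e,

where `y` stacks the observed litter sizes and, for STAY14, the latent
liability; `β` holds the fixed effects — a contemporary-group (CG) factor
defined as herd × year × season of first farrowing, plus age at first
farrowing (AFF, days, centred) as a linear covariate on every trait;
`a ~ N(0, A ⊗ G)` are additive genetic effects for every pedigree animal
with `A` the numerator relationship matrix; `e ~ N(0, I ⊗ R)`. Because a
binary outcome carries no scale information, the STAY14 residual variance
is fixed to exactly 1 and the threshold to 0 in every cycle; its
heritability is therefore `h² = σ²ₐ/(σ²ₐ + 1)` on the liability scale.

Seasons follow the tropical three-season calendar: summer (Mar–Jun),
rainy (Jul–Oct), winter (Nov–Feb). Editing rules: sows missing a birth
date, farrowing date or parity are dropped, as are sows with AFF < 280 d
or > 460 d (strict inequalities; 280 and 460 are retained). A sow that
reached a fourth farrowing is coded STAY14 = 1, a sow with a removal date
and no fourth farrowing 0, and a sow still present at the end of data
collection without a fourth-parity opportunity is right-censored
(missing); censoring is the only reading under which stayability can have
fewer observations than NBA1, as herd datasets of this kind show.

## Pedigree machinery

Pedigrees are renumbered topologically (parents before offspring;
referenced-but-unlisted parents become founders, logged). Inbreeding uses
the Meuwissen–Luo L-row recursion; `A` itself is built densely by the
tabular method only as a small-pedigree oracle (guard n ≤ 5,000), while
the sampler consumes the sparse `A⁻¹` assembled with Henderson's
parent–offspring rules and inbreeding-corrected Mendelian-sampling
variances d = ½ − ¼(F_s + F_d), with an unknown parent entering as F = −1
(founder variance). Unknown parents are unrelated base-population draws;
there are no genetic groups.

## Gibbs sampler

Single-site Gibbs with full data augmentation; each cycle updates, in
order: (1) liabilities, drawn from the residual conditional given the
record's other current residuals under `R`, truncated to the side of 0
matching the observed category (inverse-CDF draws with a tail clamp so
category consistency is exact); (2) missing continuous cells (litters
never farrowed) as unconstrained conditional-normal draws, so every
record is complete; (3) location effects — all levels of a CG factor at
once (levels share no records, so the joint draw equals single-site
updating) and the AFF slope per trait; (4) animal effects animal-by-animal
through the sparse `A⁻¹` (compiled loop); (5) `G` from its
inverted-Wishart full conditional with scale `a'A⁻¹a` plus the prior
scale; (6) `R` under the pinned-variance constraint: the continuous
residual block from its marginal inverted Wishart, then the regression of
the liability residual on the continuous residuals from its normal
conditional (its scale drawn from the regression SSE), covariances
rebuilt with the STAY14 variance held at exactly 1. Rescaling an
unconstrained draw after the fact would change the stationary law and is
not used; the decomposition sampler is itself an approximation to the
exact constrained conditional (the conditional variance depends on the
regression coefficients), validated by recovery of a known residual
correlation in a two-trait test.

All randomness flows through one numpy Generator seeded by the chain
seed; the compiled sweep consumes pre-drawn normals, so runs are bitwise
reproducible. The default protocol is a single chain of 250,000 cycles,
50,000 burn-in, thinning 50 — exactly 4,000 stored samples.

### Priors

Location effects of the continuous traits carry flat priors. Liability-
scale location effects carry a diffuse proper N(0, 1) prior: the binary
likelihood depends on location effects only through effect/√(1+σ²ₐ), so
jointly rescaling all liability location effects and the genetic standard
deviation leaves it nearly unchanged, and integrating flat priors over
~100 CG effects multiplies the marginal posterior of σ²ₐ(liability) by
roughly (1+σ²ₐ)^(n_groups/2) — an improper ridge along which the chain
demonstrably diverges. On the probit scale ±2 SD of this prior spans
group stay rates from 2% to 98%, far beyond anything a herd shows, so
identified effects are essentially unshrunk. `G` and the free part of `R`
default to minimally informative inverted Wisharts (df = dimension + 1,
scale 0.01·I); flat (df 0, zero scale) is available and is what the
conjugate closed-form checks use.

Contemporary groups in which every observed STAY14 value falls in one
category (or none is observed) leave the group's liability effect without
a finite maximum — the extreme-category-subclass problem. Such levels are
pooled into one merged level of the binary trait's own CG coding
(continuous traits keep full resolution); the edit is logged and
switchable.

### Initialisation and warm-up

Chains start from CG-level trait means, liabilities drawn consistent with
their categories, and a (G, R) pair that splits the empirical phenotypic
covariance 25/75 while keeping the observed cross-trait correlation
structure in both matrices; animal effects start at their BLUP solution
(the mixed-model equations solved once at the starting covariances), and
the first 500 cycles update only the location/augmentation state with
(G, R) fixed. These choices do not alter the stationary distribution —
they shorten the transient in which covariance must otherwise flow
between R and G through the slowly mixing animal effects.

### Mixing at desk scale — an honest account

The partition of (co)variance between `G` and `R` is the slow direction
of single-site Gibbs in this model class: with one record per animal it
is identified only through family resemblance. Cross-checks performed
while developing the package (a closed-form oracle for the animal sweep;
an exact-likelihood REML fit of the Gaussian sub-model via the
eigendecomposition of `A`; an independently written naive Gibbs; an
ensemble sampler on the fully marginalised posterior) show the
conditionals are correct, but that at small herd sizes the chain — any
single-site chain — makes long excursions toward boundary configurations
(genetic correlations near ±1) whose decay can take tens of thousands of
cycles. This is why the production protocol for this model family uses
hundreds of thousands of cycles. Posterior means of genetic correlations
from short desk-scale chains should be read with that in mind; the
package's recovery tests average three seeds at 20,000 cycles and
document the achieved accuracy rather than asserting more than the chain
delivers.

## Synthetic herds

`HerdSimulator` generates the study-shaped data every test runs on:

- **Pedigree**: unrelated founder sires and dams; each dam mated to a
  random sire, a fixed number of daughters per dam; default 150 sires,
  1,000 dams, 3 daughters — 3,000 recorded sows, matching the real
  population's sows-per-sire (~26) and sows-per-dam (~3.5) ratios at
  desk scale.
- **Breeding values** by gene dropping: founders ~ N(0, G); offspring =
  parent average + Mendelian deviation with variance d·G.
- **Phenotypes**: intercepts (9.4, 10.0, 10.6) for NBA1–3 — litter size
  rising with parity — and 0.7 for the liability (stay incidence
  Φ(0.7) ≈ 0.758); CG effects drawn per herd-year-season label (SD 0.3
  litter, 0.2 liability); AFF ~ truncated normal 367 ± 26 d on
  [280, 460]; small negative AFF slopes; residuals from `R`. Defaults:
  σ²ₚ = 6.5 with h² = 0.30 for litter traits, σ²ₐ = 1/3 (h² = 0.25) on
  the liability, genetic correlations 0.6, residual correlations 0.1.
  Litter sizes are simulated Gaussian (matching the model's assumption);
  a rounding switch exists for realism experiments.
- **Calendar**: births uniform over 2010–2013, first farrowing at AFF,
  ~155-day farrowing intervals, data end 2015-12-31. This reproduces the
  study's contemporary-group size (~70–100 sows per herd-year-season)
  at the scaled-down herd; a natural minority of late sows is
  right-censored. Spreading the same sows over many more cohort years
  would create group sizes the study did not have.
- **Culling**: sows with a negative liability are removed before parity
  4; in the default liability-linked mode the lowest-liability culled
  sows leave earliest (thirds by default), producing the informative
  sequential missingness — NBA records after the removal parity are
  deleted — that motivates joint analysis. A random-culling mode breaks
  the link for unit tests.

What the generator does **not** emulate: litter sizes are Gaussian rather
than counts, farrowing intervals are independent of litter size, removal
reasons are not modelled, and herds/seasons have purely random effects.
Passing tests therefore show the estimator recovers parameters under the
model's own assumptions plus realistic missingness — not that the model
is robust to every feature of field data.

## Numerical choices

- Truncated normals by inverse CDF with probabilities clipped at 1e-14
  and draws clamped to the truncation side (exact category consistency
  even when a bound sits many SDs from the mean).
- 4×4 Cholesky factorisations hand-rolled inside the compiled animal
  sweep; a non-positive pivot raises a numerical error naming the cycle.
- Posterior summaries derive h², r_g, r_p per stored draw and then
  average (mean of the ratio, never ratio of means); reports round to 2
  decimals, a machine-readable sidecar keeps full precision; the bracketed
  dispersion is the posterior SD.
- Stored-sample count is exact by construction: (cycles − burn-in) must
  be divisible by the thinning interval.

## Known limitations

- One binary trait per analysis; multi-threshold ordinal traits are out
  of scope.
- The constrained `R` update is an approximate decomposition sampler (see
  above).
- Genetic-correlation posteriors from short chains at desk scale carry
  transient bias toward boundary values; production-length protocols are
  advised for real analyses.
- No convergence diagnostics beyond trace export; the sample store is
  plain text for external tooling.
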