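# Methods

This note documents the models implemented in `nivalis`, the assumptions
they make, the defaults of the synthetic-data generator, and the
numerical choices that matter when interpreting output. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The scientific problem

In a wild rodent population monitored over ~9 years, heavier individuals
survive and reproduce better, yet the population can nevertheless evolve
toward *lower* body mass. The resolution is that the phenotypic
covariance between mass and fitness mixes two different things: a causal
(genetic) association and a non-causal environmental one (good sites
make animals both heavy and successful). Splitting the trait–fitness
covariance into additive-genetic and environmental parts — which
requires a pedigree — can reverse the apparent direction of selection.
`nivalis` implements that decomposition end to end, plus the
growth-curve analysis that identifies the proximate agent of selection:
overwinter viability selection on *potential adult mass* in years with a
short snow-free season.

## Pedigree algebra

The additive relationship matrix **A** is built by the tabular method
(founders: diagonal 1; offspring row = half the sum of the parent rows;
diagonal `1 + F`, with `F` half the parents' relatedness). Its sparse
inverse uses Henderson's rules with the inbreeding-adjusted Mendelian
sampling variance `d_i = 1/2 − (F_s + F_d)/4` (single known parent:
`3/4 − F_p/4`; founders: 1). Unknown parents are treated as unique,
unrelated, non-inbred founders; there are no genetic groups. Pedigree
validation topologically sorts records (Kahn's algorithm, ties broken by
cohort then id, so every matrix is reproducible), rejects cycles,
sex-inconsistent parentage and parents born after their offspring, and
permits same-cohort parentage (females can breed in their year of
birth). Generation time is the mean over parent–offspring links of the
cohort difference, and converts per-generation rates to per-year rates.

## The animal model

Phenotypes follow a Gaussian mixed model with fixed effects (age class,
sex, their interaction, centred/scaled Julian date and its square, an
age×date interaction, and the inbreeding coefficient) and random
effects: breeding values `a ~ N(0, A ⊗ G)`, maternal, permanent-
environment and year effects (each i.i.d. across levels with its own
k×k covariance), and a residual. Relative fitness can be included as an
additional Gaussian response whose residual variance is fixed to
`1e-8 ×` its observed variance (an exact zero breaks the conditional
updates); its repeatable non-additive variance is then carried by the
permanent-environment term, which makes the additive and
permanent-environment covariances with a trait directly the genetic and
environmental components of the selection differential. Binary
responses (annual survival) can instead be attached as probit-liability
("threshold") traits with unit residual variance; covariances involving
them are reported on the liability scale, which is the flagged
latent-scale variant of the component decomposition.

Sampling is Gibbs. All location effects are drawn *jointly* from their
multivariate-normal full conditional using the simulation solver of
García-Cortés & Sorensen: simulate pseudo-effects and pseudo-records
from the current covariances, solve the mixed-model equations once for
the difference between real and pseudo data, and shift. This requires
one sparse factorization per iteration (SuperLU, symmetric
minimum-degree ordering, diagonal pivoting — the coefficient matrix is
symmetric positive definite) and no explicit posterior Cholesky. Each
covariance matrix is then drawn from its conditional inverse-Wishart
with prior scale `V·ν` (defaults `V = I`, `ν = 0.002`). Residual
covariances are estimated per "residual group"; traits never observed in
the same capture (e.g. a juvenile-mass/adult-mass split) sit in
different groups with their cross-covariance fixed at zero, and
missing-trait residuals inside a group are imputed by their Gaussian
conditional each sweep. Degrees of freedom for conditional
inverse-Wishart draws are floored just above `k − 1` so terms with fewer
levels than traits (e.g. a 4-trait year term over 4 years) stay
numerically proper.

Parameter expansion is not implemented, but each iteration includes a
"scale move" per random term — a joint Metropolis rescaling of the
term's effects and covariance (`u' = e^{eps/2} u`, `V' = e^eps V`),
whose acceptance reduces to likelihood x inverse-Wishart prior x a
Jacobian because the effect-prior term cancels — which traverses the
near-absorbing direction at small variances where plain Gibbs lingers.
Residual slow mixing between confounded components (e.g. additive vs
permanent-environment) remains visible as lag-1 autocorrelation of the
variance chains, reported in the posterior metadata so thinning can be
judged. The chain preset used
throughout the tests is deliberately short (thousands of iterations);
`MCMCSettings.long()` provides the heavy preset (1.3M iterations, 300k
burn-in, thinning 1000) appropriate for real analyses.

Point estimates are posterior modes of a Gaussian-kernel density
estimate (Scott bandwidth, 512-point grid); intervals are 95%
highest-posterior-density intervals; `p_MCMC` is twice the smaller tail
probability, floored at `1/n_samples`.

Heritability divides the additive variance by the sum of all random-term
variances plus the residual. Whether the year variance belongs in the
denominator is a definitional choice; both versions are available
(`include_year`), the inclusive one being the default.

## Selection decomposition and response predictions

The selection differential for trait `z` is the per-sample sum of the
additive, maternal, permanent-environment and residual covariances with
relative fitness; the year-level covariance is excluded because
year-level covariation does not act among individuals (and cohort-wise
fitness standardization drives it to zero anyway). The decomposition
`σ_P = σ_A + σ_E` therefore holds *exactly* per posterior sample, by
construction. Relative fitness is lifetime reproductive success divided
by its sex-and-cohort mean (annual components: sex-and-year means).

Gradients are `β = (G′ + P′ + R′)⁻¹ S` with the fitness row/column
removed from each matrix; whether the maternal covariance belongs in the
denominator is ambiguous, so it is excluded by default and an
`include_maternal` switch reports the alternative. Response predictions:
univariate breeder's equation `h²S`; multivariate `G′β`; the
correlation-free variant `(G′ ∘ I)β` (off-diagonals of `G′` zeroed); and
the secondary-theorem (Robertson–Price) estimate `σ_A(z, ω)`, which is
also the retrospective estimate of realized genetic change. All are
reported per generation and per year (divided by generation time, per
sample).

"Significance" of selection is a posterior tail probability, optionally
cross-checked by a nonparametric bootstrap of the raw covariance
(individuals resampled, 1,000 replicates by default — the resampling
unit and count are package choices).

## Realized genetic change and the drift null

The breeding-value trend regresses cohort means of the sampled breeding
values on cohort year *within each posterior sample*; computing a trend
on posterior-mean breeding values would ignore both their sampling
variance and their non-independence. The drift null drops neutral
breeding values down the *observed* pedigree (founders `N(0, V_A)`,
offspring mid-parent plus Mendelian noise), one replicate per posterior
`V_A` draw, paired so that posterior uncertainty in `V_A` propagates
into the null; the exceedance probability is one-tailed in the observed
direction by default with a two-tailed option. Rates convert to Darwins
as `|ln((z̄ + rate)/z̄)| × 1e6` for a one-year step; the formula is
stated in output metadata because conventions differ.

## The growth / viability-selection model

Juvenile mass records follow a monomolecular curve
`m(t) = a_i (1 − e^(−k_i (t − t0)))` anchored at the litter's latent
onset `t0` (the projected zero-mass date); `a_i` is the predicted adult
mass. Litter-mates share `t0` — the identifying assumption — with at
most five litters per mother-year, at least 20 days apart, and slots
kept date-ordered (which resolves label switching). Measurement error is
fixed at SD 2.05 g. Overwinter survival is a within-model logistic
regression on sex, `a_i`, days from `t0` to the first snowfall, and the
mass×days interaction; survival information feeds back into the growth
parameters. Coefficients are sampled on centred covariates and reported
on the raw scale by exact back-transformation.

**Identifiability.** The joint posterior of (onset, rate, asymptote) has
a structural soft spot: with three or fewer captures a monomolecular
curve can interpolate the records exactly, so earlier onsets with slower
growth and larger asymptotes fit almost as well as the truth, and the
integrated posterior can genuinely prefer them. Three modelling choices
close this gap, and they are assumptions to be aware of:

1. *Capture-protocol information.* Juveniles are trappable from about 25
   days after onset, and the trapping protocol catches a trappable
   animal at a session with high probability (default 0.995, matching a
   monitoring design whose seasonal capture probability is effectively
   complete). Every pre-first-capture session at which a juvenile would
   have been trappable therefore contributes `log(1 − p_det)`. This
   bounds each litter's onset within roughly one inter-session interval.
2. *Weakly informative anchors* on the population mean growth rate
   (`log k ~ N(log 0.023, 0.04)` — the population growth-rate scale is
   treated as known to a few percent; this is the strongest identifying
   assumption and is exposed in the configuration) and mean asymptote (`N(41, 2)` g — the mean adult mass
   is directly observable in the trapping data).
3. *A hierarchical onset-lag prior*: each mother-year's first-litter
   date is snowmelt + lag with `lag ~ N(λ, τ²)` and λ, τ estimated from
   the data (vague hyperpriors), so the onset lag is inferred, not
   assumed; later litter slots carry an exponential spacing prior that
   also compacts unoccupied trailing slots. The hyperparameters are
   informed only by occupied first slots, so empty bookkeeping slots
   cannot drag the hierarchy.

The sampler is Metropolis-within-Gibbs with several extra moves that
matter in practice: an exact Gaussian conditional refresh of `a_i`
(the curve is linear in `a`; the weak survival term enters through an
accept step), a "ridge move" that perturbs `log k_i` while rescaling
`a_i` to keep the fitted mass at the individual's mean capture age
unchanged (unit Jacobian after the log-scale correction), and
label-compaction moves that delete an empty leading litter slot (or
reinsert one) with the likelihood invariant. Step sizes adapt during
burn-in only. Convergence is summarized by split-R̂ across chains for
the survival coefficients.

Posterior-predictive checks replicate masses (sum of squared
standardized residuals) and survival outcomes (Bernoulli deviance) from
the stored draws and report tail probabilities.

**Phenology.** The onset-of-reproduction analysis regresses the earliest
inferred birth date per year on snowmelt date. A minimum over ~10²
noisily-estimated litter dates is biased early by roughly one posterior
SD; the slope on snowmelt is robust (≈1 when snowmelt drives onset), but
the absolute lag estimate should be read with that bias in mind. The
package therefore reports both the per-year-minimum statistic and the
hierarchical mean lag λ.

**Group-specific selection.** The viability-selection gradient on
predicted adult mass for a group of years averages
`b_mass + b_interaction × days_i` over that group's juveniles per
posterior sample; survival-vs-mass curves are evaluated at the group's
mean covariates. The population-level consequence of a shift Δa in
predicted adult mass integrates the fitted survival curve over the
observed covariate distribution, shifted, per sample.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which every estimator is verified by parameter
recovery. Defaults emulate the study system: ~70 founders and 9 yearly
cohorts giving ~1,000–2,000 individuals with generation time ~1.3–1.4 y;
adult mass ~41.7 g (SD ~4.7); additive variance 4.34 g² (h² ≈ 0.20) with
genetic correlations 0.79/0.40/0.56 among mass, body length and tail
length; additive variance 0.10 for relative fitness (h² ≈ 0.06) with
σ_A(mass, ω) = −0.35 and a permanent-environment covariance of +1.21 so
the phenotypic differential is +0.86 g; five trapping sessions per
season; monomolecular growth from litter onsets placed on average 40 d
(+ exponential jitter) after snowmelt, litters ≥ 20 d apart, measurement
error SD 2.05 g; and overwinter survival of juveniles following the
logistic model with mass slope −0.33, days slope −0.09 and interaction
+0.0025, so selection against large potential adult mass operates only
when the first snowfall comes early (the last seven of nine seasons).
A +0.15 g/y trend in the mass year effects emulates the plastic increase
that partially masks the genetic decline at the phenotypic level.
Litter-count and litter-size distributions are not reported quantities
for the study system; the defaults (0–2 litters per female-year, mean
size ~2.2, capped at 6) are assumptions chosen to give a stationary
population at the study's scale.

Relative fitness is generated directly as a Gaussian trait
(`ω = 1 + a_ω + pe_ω`), matching the analysis convention — so the
`lrs` column emulates relative fitness on the analysis scale, not an
integer offspring count, and can occasionally be negative. A
"demographic" mode instead takes lifetime reproductive success from the
realized pedigree, with optional fecundity-selection channels acting on
mass breeding values (causal selection) and on mass
permanent-environment deviations (a site-quality channel that creates a
non-causal positive mass-fitness association). The demographic mode is
what the secondary-theorem forward-consistency and sign-pattern checks
use, because there fitness and demography are the same process — in
Gaussian mode, real viability selection coexists with an independently
drawn fitness trait, which is internally inconsistent and distorts
genetic-covariance estimates. The final simulated cohort has
right-censored (all-zero) lifetime reproductive success in demographic
mode and is dropped before fitness standardization. What the generator deliberately does *not* emulate: capture
failure (detection is complete), count-valued fitness with its
overdispersion, age-dependent fecundity, immigration, and environmental
autocorrelation beyond the year effects. Passing recovery tests
therefore demonstrates estimator correctness under the stated model, not
robustness to these real-data complications.

One fixed seed drives named substreams per stage, so adding a stage
never perturbs earlier draws and outputs are byte-identical across runs.

## Problem sizes and tolerances in the test suite

The suite runs everything at reduced scale as a deliberate design choice
for a simulation study: pedigrees of ~100–500, chains of 1–6 thousand
iterations, 5–20 replicates per property. Exact invariants
(decomposition closure, litter constraints, zero-variance drift) are
asserted to machine precision; Monte-Carlo quantities use 3–4 standard
error bounds; coverage checks use the nominal level minus five points,
which is also about where the frequentist coverage of Bayesian HPD
intervals lands at these sizes, because the realized genetic variance of
a small founder population deviates from the base-population parameter.
The acceptance script (`scripts/acceptance.py`) re-runs the full
pipeline at a somewhat larger scale (~600–900 individuals, 5 cohorts)
and reports its computed quantities; values for stochastic posterior
summaries land near, not exactly on, the generating values.

## Known limitations

* No REML path, no non-Gaussian fitness families (Gaussian fitness is a
  deliberate convention, not an oversight), no dominance/epistatic
  terms, no genetic groups, no genomic relatedness.
* The animal-model sampler's variance components mix slowly when a trait
  has little replication per individual (no parameter expansion).
* The growth model's onset dates are identified by the capture-protocol
  term and the hierarchical lag prior; with genuinely incomplete
  detection, `detection_prob` must be lowered and onset uncertainty
  grows accordingly.
* The parent–offspring-conflict style analysis (plugging posterior-mean
  predicted adult masses into a second model as data) understates
  uncertainty; intervals from such plug-in fits are indicative only.
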