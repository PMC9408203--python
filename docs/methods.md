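# Methods

## Scope and data flow

`mixlr` starts from *called* peak tables (sample, marker, allele, size,
height), never raw capillary signal. A panel definition fixes the locus
set and allele ladders; only autosomal loci are admitted. The pipeline
is: (1) calibrate a variance model from replicated single-source
profiles; (2) deconvolve a mixture into per-locus weighted genotype
sets by MCMC; (3) compute likelihood ratios for queried contributors
under configurable propositions; (4) optionally replay an internal
validation design on synthetic data.

## Peak-height likelihood

Conditional on genotypes, mixture proportions `φ` and a per-locus
amplitude `A_l`, expected heights are linear in template shares
(`ν_a = A_l Σ_k φ_k n_ka`) with backward stutter *reallocating* (never
creating) a fraction `ξ_l` of each allele's expectation to the
one-repeat-shorter position. Observed heights are modeled Gamma with
mean `ν` and variance `VF·ν`; this single dispersion parameter `VF` is
what the protocol dataset estimates, so calibration and inference use
the same statistic. Dropout is the Gamma CDF below the analytical
threshold (AT), which makes the dropout probability closed-form and
monotone in template. Drop-in peaks are Poisson with
population-frequency allele labels and AT-shifted exponential heights;
the validated protocol observed none, so the default drop-in base rate
is 0 and the drop-in coefficient merely scales that base. An observed
peak with no expected source then renders a genotype set impossible,
which is exactly the admissibility rule the set enumerator applies
(carried, stutter-of-carried, or drop-in).

The virtual allele Q aggregates all unobserved alleles: it contributes
expected height like any allele but its observation term is always the
dropout CDF, and it generates no stutter.

## Priors and sampling

The genotype-set prior during MCMC is uniform over admissible sets;
population genotype probabilities enter only at the LR stage, where the
weights are multiplied by `Pr(S|H)`. Applying them in both places would
count them twice. `φ` has a uniform prior on the simplex (sampled via a
logistic-normal random walk with the ALR Jacobian), `A_l` a log-uniform
prior on a wide bounded range (lognormal random walk).

Proposals mix single-contributor genotype moves, joint two-contributor
moves at one locus (needed to hop between genotype configurations whose
single moves pass through impossible states), `φ` and `A_l` random
walks, and an always-accepted relabeling swap of two unknown positions
(the likelihood is exactly exchangeable in them). Eight chains, 20%
burn-in, thin 1 by default; iteration defaults grow with the number of
contributors (5000/chain at N=2 up to 20000/chain at N=4–5).

**Preprocessing** seeds the chains by structured likelihood ascent: a
set of candidate mixture proportions (Dirichlet draws plus ordered
spreads) is each given a height-matched genotype assignment — required
alleles are assigned to the unknown whose expected height best fits the
peak — polished by greedy coordinate sweeps; the best joint candidate is
refined by alternating sweeps, amplitude rescaling to match total
observed signal, and a nonnegative least-squares refit of `φ`. The
proportion and the genotype partition are strongly coupled, and random
walks essentially never cross between their joint modes, so good
seeding is what makes eight moderate-length chains sufficient. The
configured `preprocessing_steps` is the total ascent budget; the
remainder after the structured stage is spent on randomized greedy
polish per chain.

**Weight estimation.** Where a locus's admissible-set space is small
(bounded enumeration), weights are recorded by Rao–Blackwellization:
at regular intervals the exact conditional posterior over all admissible
sets given the current `(φ, A_l)` is accumulated, integrating out the
genotype dimension. Elsewhere visited point masses are counted with
run-length bookkeeping. Pooled weights over exchangeable unknown
positions are additionally symmetrized (an exact symmetry of the
model). A parallel "canonical" record keeps unknown positions ordered
largest-contributor-first at sampling time; deconvolved-profile export
and the reported mixture ratio read that ordering, matching the
reporting convention that unknown 1 is the largest contributor.

## The oracle

`oracle_posterior` computes the same posterior exactly for small
instances (N ≤ 3) by enumerating every admissible genotype set per locus
and summing the likelihood over a discrete grid: `φ` on a uniform
simplex grid (step 0.02 by default) and `A_l` on a log-spaced grid
centered at half the total observed locus signal. Priors match the
sampler, so the two are estimates of the same distribution; the test
suite requires total-variation distance < 0.05 on toy instances
covering allele sharing, dropout, and a conditioned known.

## Likelihood ratios

Simple (sub-source) and Overall (sub-sub-source) LRs follow the
weighted-genotype formulas given in the README. Design choices the
formulas leave open:

- **Position prior (Simple LR).** Uniform `1/U` over the `U` unknown
  positions per locus, independently across loci. This makes N=1 reduce
  to 1/RMP and a single-locus Simple LR equal the Overall LR.
- **Ordering form.** The factorial-order form of the Overall LR and the
  position-sum form coincide for unrelated unknowns; both are
  implemented independently and asserted equal to 1e-12 relative.
- **Q matching.** A set genotype containing Q denotes the POI if its
  real alleles are the POI's and every Q stands for a POI allele *not*
  observed at the locus (Q aggregates unobserved alleles, with
  frequency `1 − Σ observed frequencies`, clamped to the minimum
  frequency if non-positive). Conditioned knowns match on full
  genotypes only.
- **No absolute exclusions.** LRs accumulate in log space with no lower
  cutoff. A locus numerator with no sampled mass is floored at one
  pseudo-sample times the POI's own genotype probability, so a
  non-contributor's LR is small but finite rather than zero.
- **LR-stage frequencies** use the published column values directly;
  alleles absent from the table are priced at the `5/(2N)` floor
  *without* renormalizing, so the H2 denominator matches a hand RMP on
  the same table exactly. (Renormalization applies only when reading
  casework frequency files, per the minimum-frequency convention.)

Genotype probability models: Hardy–Weinberg, NRC II recommendation 4.1
(homozygote `p² + p(1−p)θ`, heterozygote `2p_i p_j`) and recommendation
4.2 (the conditional Balding–Nichols match probabilities with the
`(1+θ)(1+2θ)` denominator). The co-ancestry forms are conservative
match probabilities, not sampling distributions: their total mass over
a locus exceeds 1 for θ > 0 (for 4.1 by exactly `θ Σ p(1−p)`), which
the tests assert rather than hide. θ defaults to 0.01 on the combined
population column.

## Synthetic data generator

The generator exists to emulate the conditions of a laboratory
validation study, not any particular instrument:

- **Design grid.** Two- to five-person mixtures over 24 ratio
  conditions (two-person 1:1 … 1:10; three-person 1:1:1 … 1:3:5;
  four/five-person up to 1:2:2:5:10), largest undiluted contributor
  ~500 pg, serial dilutions 1:2/1:4/1:8, triplicate amplification —
  96 conditions, 288 profiles. Analytical thresholds follow the study
  protocol: 50 RFU for two-person mixtures and three-person mixtures
  except their 1:8 dilutions, 30 RFU otherwise.
- **Defaults.** Gain γ = 3 RFU/pg, dispersion VF = 40, stutter
  ξ = 0.07, drop-in rate 0. These place a ~6 pg contributor (the most
  dilute minor in the grid) deep in the stochastic regime at a 30 RFU
  threshold while a 500 pg contributor essentially never drops —
  matching the qualitative dropout behavior the validation design is
  built to probe. VF = 40 at γ = 3 gives heterozygote peak CVs of
  ~16% at 500 pg and ~50% at 50 pg.
- **Protocol dataset.** Ten donors × (500, 250, 125) pg × five
  replicates = 150 single-source profiles for calibration.
- **What it does not model.** Forward or −2 stutter, pull-up, dye
  baselines, degradation (a hook exists but defaults off), inhibition,
  or inter-locus amplification imbalance (efficiencies default to 1 and
  are configurable). Passing tests therefore demonstrate internal
  consistency of engine and model on data that honor the modeled
  effects — not performance on real casework electropherograms.

## Calibration estimators

- **VF** is method-of-moments: the mean over allele positions of
  `Var(h)/Mean(h)` across replicates, using positions observed in every
  replicate of a group (avoiding censoring bias from partially dropped
  positions). Recovery of the generator's VF = 40 within ±15% from 150
  profiles is part of the acceptance suite.
- **Stutter** is a pooled signal ratio per locus, `Σs / Σ(s+p)` over
  isolated parent/stutter position pairs, where a stutter peak censored
  by the AT contributes zero while its parent still counts. Excluding
  censored pairs entirely would inflate the estimate far beyond the
  ±0.015 recovery band at these noise levels (only the upper tail of
  the stutter distribution survives a 30 RFU threshold); counting them
  as zero under-corrects slightly and stays within the band. Pairs
  whose stutter position coincides with a true allele are excluded as
  confounded.
- **Heterozygote balance** (log peak ratio vs expected height) is
  emitted as a table for plotting; it is diagnostic only.

## Problem sizes and numerical choices

The validation harness and acceptance computations run reduced
versions of the study: an 8-locus sub-panel for calibration, toy
3-locus instances for oracle equivalence, and a 24-condition, ≥40-test
sensitivity grid on the full 22-locus panel at one tenth of the default
iteration counts — sizes chosen so the entire replay completes on a
single CPU while leaving every qualitative conclusion (recovery bands,
error rates, precision) intact. Gamma log-densities use `gammaln`
directly; log-CDF terms floor the regularized incomplete gamma at
1e-300; per-locus LR terms accumulate in log space. Degenerate inputs:
a locus with no surviving peaks yields the all-Q genotype set with
weight 1; an all-zero-template simulation yields an empty profile; a
locus where the required alleles cannot fit in `2N` slots raises a
constraint error naming the locus (the harness records it as a failed
row rather than crashing a grid).

## Known limitations

- The likelihood is a declared stand-in with the same inputs, outputs
  and validation behavior as commercial fully continuous engines; no
  claim of numerical agreement with any proprietary implementation is
  made, and published casework LR tables are not reproducible without
  the underlying electropherograms.
- Replicate amplifications are analyzed independently; joint
  multi-replicate likelihoods are out of scope.
- Kinship/relative propositions and degradation curves are not
  implemented (hooks and errors, respectively).
- Chains seeded from a common preprocessing mode can understate
  genuinely multimodal posteriors at loci outside the
  Rao–Blackwellized regime; the Gelman–Rubin diagnostic on the mixture
  proportions is the intended guard.
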