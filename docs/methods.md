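# Methods

This note documents the models implemented in `hybridzone`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Local ancestry: a diploid single-pulse HMM

Ancestry along each chromosome is modelled as the product of two independent
haploid Markov chains, each describing a genome that received a single pulse
of admixture *t* generations ago with genome-wide fraction *m* of the
introgressing (N) ancestry. Over a genetic distance *d* (Morgans) a haplotype
retains its current ancestry with probability e^(−t·d) and otherwise redraws
it from the stationary distribution (1−m, m); collapsing the ordered pair of
haplotypes onto N-dosage gives the 3×3 diploid kernel over {GG, GN, NN}.
Genetic distances are physical distances multiplied by a single genome-wide
recombination rate, default 3.9×10⁻⁸ M/bp (a 14.7 M map over a 375 Mb
genome); no map-file dialects are supported because the target data are
low-coverage and a uniform rate is what the inference needs.

Emissions integrate over the unobserved genotype: given ancestry state and
the panel allele frequencies (f_G, f_N) the genotype is binomial within each
ancestry, and each read reports the true allele with probability 1−ε
(default ε = 0.01). A site with zero reads has emission likelihood 1 in
every state, so uncovered sites are smoothed by their neighbours — the
low-coverage regime this package is built for. Posteriors come from scaled
forward–backward, vectorised across samples; hard calls require a posterior
of **at least** 0.9 (inclusive, as are all thresholds here), and samples with
fewer than 25,000 called sites are dropped before any downstream analysis.

Two free parameters matter:

- `pulse_time` *t* (default 8 generations): sets the length scale of ancestry
  blocks (mean block ≈ 1/(t·r) bp ≈ 3.2 Mb at the defaults). Estimates of HI
  are insensitive to moderate misspecification of *t* because the emissions
  dominate wherever there is coverage.
- `admixture` *m*: stationary mixing weight. By default it is estimated per
  sample by weighted least squares on the raw allele read fractions
  (E[count_a] = n·(f_G + m·(f_N − f_G))), clipped to [0.01, 0.99]; samples
  are then grouped by m rounded to 0.01 so each group shares transition
  matrices. Supplying a scalar or per-sample mapping overrides this. Joint
  maximum-likelihood estimation of (t, m) is deliberately out of scope.

Per-sample summaries are the hybrid index HI = (n_NN + n_GN/2)/n_called and
ancestry heterozygosity AH = n_GN/n_called, which always satisfy
AH/2 ≤ HI ≤ 1 − AH/2. Cohort cutoffs (configurable) are HI < 0.15
(*guttatus*-like), 0.15–0.8 (admixed), > 0.95 (*nasutus*-like), with the
(0.8, 0.95] gap left unassigned. A sample with HI ∈ [0.4, 0.6] and AH > 0.85
is flagged as an F1-or-allopolyploid candidate; offspring that retain
AH > 0.85 indicate fixed heterozygosity (allopolyploid), selfed offspring
whose AH drops to ≈ 0.5 (below 0.7) indicate a diploid F1, and candidates
without offspring stay unresolved.

## Family QC

For each maternal–offspring pair the incompatibility ratio is the number of
sites where the two are hard-called homozygous for opposite ancestries
divided by the number of homozygous maternal sites with any offspring call.
Heterozygous maternal sites are uninformative for incompatibility and enter
neither numerator nor denominator; the offspring call in the denominator may
be heterozygous. Offspring with a ratio ≥ 5% (inclusive) or with no evaluable
sites are excluded, and a family is dropped when strictly more than half of
its offspring — counting the excluded ones — are excluded. The filter is
idempotent and order-independent.

## Mating-system inference

This module is an explicit, closed-form surrogate for Bayesian progeny-array
mating-system estimators: there is no MCMC, no maternal inbreeding-history
model, and no tuning chain. Per thinned site (one site per 10-kb window,
chosen uniformly under the run seed), the selfing likelihood takes the
offspring genotype from a Mendelian self of the maternal genotype, and the
outcrossing likelihood from one maternal gamete plus one allele drawn at the
population frequency; read likelihoods are binomial with the same ε. Maternal
genotypes enter as probability triples — posteriors from the mother's own
reads under a Hardy–Weinberg prior at the estimated population frequencies,
optionally sharpened by her ancestry calls and the panel frequencies.
Population allele frequencies are estimated once, from the maternal samples.
Per-site likelihoods multiply across sites; the posterior uses a configurable
prior P(selfed) = 0.5. Calls require posterior ≥ 0.9 for selfed or ≤ 0.1 for
outcrossed; everything else is ambiguous and excluded from rates.

Sibship posteriors for outcrossed pairs in a fruit compare one shared father
(genotype integrated over Hardy–Weinberg frequencies, the two paternal
gametes conditionally independent given it) against two independent paternal
gametes, prior 0.5; a pair is half-sib if P > 0.5, full-sib if P < 0.5,
missing at exactly 0.5. A fruit with ≥ 2 outcrossed offspring is flagged
multi-paternal when any pair is called half-sib.

Two caveats are inherent to the surrogate. First, sites are treated as
independent, but ancestry blocks make nearby sites strongly correlated; the
posterior magnitudes are therefore overconfident, and reliable classification
needs many independently segregating blocks — in practice a full-scale genome
(tens of chromosome arms), not a toy one. Second, the outcross model draws
pollen from a single allele-frequency pool, so when flowering phenology makes
the pollen pool cohort-structured the model should be fitted per cohort (as
the pipeline tests and the README example do); pooling strongly diverged
cohorts biases calls toward selfing for the less admixed cohort. Exact
numerical agreement with any particular MCMC implementation is not claimed.
The forward-read-only convention some pipelines use to avoid double-counting
overlapping read pairs is represented by the `halve_depth` option of the read
simulator rather than read-level logic.

## Reproductive isolation

All three indices run from −1 (complete disassortative mating) through 0
(random mating) to 1 (complete assortative mating).

- RI_M equals the ovule cohort's selfing rate: a selfing event isolates the
  maternal plant completely, an outcrossing event not at all. It is the same
  for every pollen-cohort partner, and reduced pollen export by selfers is
  deliberately not modelled.
- RI_P = 1 − 2P from plot-level flower censuses, with plots assigned to
  cohorts (plots spanning cohorts are excluded explicitly). For each focal
  flower on day *d*, A and B are the same-day open flowers in the same and
  the opposing cohort; per-flower probabilities A/(A+B), B/(A+B) are summed
  count-weighted over the season (exact and O(days), no flower
  materialisation) into totals whose ratio is P. The focal flower is removed
  from A by default — a flower is not its own potential mate; self-mating is
  RI_M's job — but `include_focal=True` restores the other convention, and
  with plot-scale counts the difference is negligible. A focal flower alone
  on its day contributes nothing; if the ovule cohort never flowers (or no
  flower has any potential mate) the value is missing; if the pollen cohort
  never overlaps, RI_P = 1. The model assumes every open flower contributes
  equally to the pollen pool and ignores distance.
- RI_combined = RI_M + (1 − RI_M)·RI_P: sequential action of two barriers,
  order-independent, equal to 1 whenever RI_M = 1, monotone nondecreasing and
  at least max(RI_M, RI_P) on [0,1]². Negative RI_P is allowed and propagates
  when RI_M < 1. Displayed values are rounded half-up to 3 decimals; internal
  values are never rounded.

## Offspring-based assortative mating

Per fruit, the mean of (offspring HI − maternal HI) is computed separately
for selfed and outcrossed offspring (ambiguous offspring excluded). Selfed
deviations reflect meiotic sampling only and centre on zero; outcrossed
deviations have expectation (pollen-pool mean HI − maternal HI)/2, producing
regression toward the pollen-pool mean. Yearly shifts are fruit-level means
with a fruit-level standard error (labelled as such; single-fruit groups get
a missing SE). For cross-cohort attribution the implied pollen-parent hybrid
index is 2·HI_offspring − HI_mother (unbiased under Mendelian expectation,
clipped to [0,1]); implied parents falling in the unassigned HI gap are
excluded from cross-cohort counts but retained in denominators.

## The synthetic-data generator

The generator produces exactly the structures the inference assumes:

- **Genomes.** Haplotypes are two-state Markov paths with stationary N
  probability m and switch rates t·r·m / t·r·(1−m) (exponential block
  lengths) — the Markov approximation to a t-generation pulse, matching the
  HMM's own model class, rather than a forward-in-time genealogy; it is
  O(blocks) and makes truth/inference discrepancies attributable to data, not
  model mismatch. Blocks tile each chromosome exactly. Haplotype alleles at
  panel sites are independent Bernoulli draws given local ancestry.
- **Phenology.** Each individual flowers on the integer days (day-of-year) of
  its cohort window [peak − w, peak + w] with independent Poisson(intensity)
  open flowers per day; plot censuses are sums over resident individuals. Any
  unimodal window would do; this one keeps the parameters explicit.
- **Mating.** Per ovule: selfed with the cohort probability s, otherwise the
  father is drawn among all other individuals' open flowers on the fruit's
  day, proportional to counts. The mother's own flowers are excluded from her
  outcross pool (geitonogamy is represented only through s). An outcross
  attempt with no eligible same-day pollen falls back to selfing and is
  flagged in the pedigree so realized rates stay auditable. Gametes are
  produced by meiosis with Poisson crossovers at r per bp, transmitting both
  ancestry blocks and alleles, so offspring are exactly Mendelian-consistent
  with their recorded parents.
- **Reads.** Site depth is Poisson(λ); each read picks one haplotype
  uniformly and reports its allele flipped with probability ε. `halve_depth`
  emulates forward-read-only extraction.

All randomness flows from one seed through named per-stage generators
(`rng_for(seed, stage)`), so fixtures are bit-reproducible while stages stay
independent.

Default parameters are chosen as study-like conditions for a
*guttatus*/*nasutus* mosaic zone: genome 14 × 26.8 Mb (≈375 Mb),
r = 3.9×10⁻⁸ M/bp, 208,560-site panels with parental allele-frequency
difference ≥ 0.8 (panel size is set per run; tests use smaller panels over
the same genome), pulse time t = 8, λ = 1, ε = 0.01, cohorts
m = {0.08, 0.30, 0.99} with selfing s = {0.14, 0.20, 1.0} and flowering
peaks {142, 130, 115} (half-width 10 d, intensity 2 flowers/day): the selfer
cohort flowers earliest and the least admixed cohort latest.

What the generator does **not** emulate: within-ancestry linkage
disequilibrium (alleles are independent given ancestry), selection and
inbreeding depression, seed and pollen dispersal kernels and distance decay,
organellar genomes, read-pair and alignment artifacts, and year-structured
environments. Passing tests therefore demonstrate internal statistical
correctness and parameter recovery under the assumed model class — not
robustness to the ways real field data violate it.

## Numerical choices and problem sizes

- Forward–backward is scaled (not log-space); posteriors are renormalised per
  site. Likelihood ratios in the mating module are summed in log space and
  mapped through a logistic, so extreme products neither overflow nor
  underflow. A pair with zero likelihood under both mate-type models yields a
  missing posterior (ambiguous).
- Threshold comparisons are inclusive throughout (≥ 0.9 posterior, ≥ 25,000
  sites, ≥ 5% incompatibility).
- Test problem sizes were chosen so the suite exercises study-like regimes
  while staying lightweight: hybrid-index recovery runs 20 samples at the
  full 200,000-site panel (median |HI error| < 0.02 at λ = 1, ε = 0.01);
  the pipeline-recovery fixture runs 200 mothers × 10 ovules (≈2,200 samples)
  over a 20,000-site panel on the full 375 Mb genome, which leaves ≈19,000
  sites after 10-kb thinning. Unit fixtures use 2-chromosome toy genomes
  where only arithmetic, not calibration, is at stake.
- The `unassigned` cohort gap and all missing values propagate as NaN and are
  preserved in output tables rather than silently dropped.
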