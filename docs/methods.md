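# Methods

This note documents the models, estimators and design choices behind
`dmpkit`, in the order data flow through the pipeline.

## Data model and GENEPOP dialect

Genotypes are multilocus microsatellite records; allele labels are fragment
sizes in base pairs (positive integers).  Because samples mix haploid males
(one gene copy per locus), diploid males and diploid females, ploidy is a
first-class attribute of each individual.  GENEPOP text has no haploid
notation, so ploidy and sex travel in a sidecar TSV
(`id, population, sex, ploidy[, habitat, year]`), which is authoritative; on
export, haploid alleles are either duplicated (`104` → `104104`, the
convention diploid-only software expects) or merged pairwise into
pseudo-diploid "false diploid" records.  Pair merging is deterministic
(lexicographic by id, sequential pairing); the choice of pairing cannot
affect allele frequencies, and a deterministic order makes round-trip and
conservation tests exact.  An odd male is dropped and logged.  Allele labels
that do not fit GENEPOP's 3-digit code space are remapped through a lookup
TSV written next to the file; labels ≤ 999 are written verbatim.

## Ploidy calling and the mis-scoring model

A male heterozygous at ≥ 1 typed locus must carry two gene copies and is
called diploid; an all-homozygous male is called haploid.  Males typed at
fewer than `min_typed` loci are excluded.  The default `min_typed = 8` (of a
10-locus panel) follows the source study's stated rule; that study elsewhere
implies a ≥ 9-locus cutoff, so the threshold is a parameter rather than a
constant.

The only error mode is a diploid male homozygous at every typed locus.  With
`F` the kinship of his parents (the probability his two alleles are
identical by descent) and `p_{li}` the allele frequencies at locus *l*,

P(all homozygous) = ∏_l [ F + (1 − F) · Σ_i p_{li}² ],

treating loci as independent.  Σp² may be supplied from raw frequencies or
as 1 − He when only expected heterozygosities are available; both paths are
exposed because published tables typically print He, not frequencies.  `F`
defaults to the haplodiploid brother–sister kinship, computed by exhaustive
enumeration of transmission paths in the four-member pedigree (mother,
haploid father, sister, brother); the same engine handles arbitrary small
pedigrees and is cross-checked in tests against a forward Monte-Carlo
simulation of the pedigree.  For the brother–sister pedigree the closed form
per locus is exact: the offspring's two alleles trace to the same founder
copy with probability 1/4, otherwise they are independent draws, giving
1/4 + 3/4·Σp².

Evaluated on the bundled 10-locus reference He values with F = 1/4 the
panel value is ≈ 1.7 × 10⁻³.  The reference analysis reported 0.0023 from an
appendix whose exact inputs (raw frequencies vs He, population pooling) are
not recoverable; the package therefore treats only the order of magnitude as
reproducible, and the acceptance checks assert the value lies in
[10⁻³, 10⁻²].

DMP is `n_diploid / (n_diploid + n_haploid)` over non-excluded calls, with
binomial SE and an exact 95% CI.  Clopper–Pearson is the default because it
reproduces the reference study's printed interval (5.0–9.2% on the pooled
counts); Wilson is available (it gives 5.1% on the same data).

## Diversity statistics

* **Ho** is defined over typed diploids only; a haploid's heterozygosity is
  undefined and haploids never enter Ho, HW or LD computations.
* **He** uses Nei's unbiased correction on gene copies,
  `n/(n−1) · (1 − Σp̂²)`, matching the convention of the standard GENEPOP
  software that produced the reference tables.
* **Hardy–Weinberg** is the exact probability test: conditional on allele
  counts, a genotype table has probability
  `n! ∏a_i! 2^h / (2n)! ∏f_ij!` (Levene), and the p-value is the mass of
  tables no more probable than the observed one.  Tables are enumerated
  recursively when their count is ≤ the enumeration cap (default 10⁶);
  beyond that, gene copies are randomly re-paired `n_mc` times and
  `p = (k+1)/(n_mc+1)`.  The enumeration path is verified against an
  independent biallelic het-count formula; the MC path against enumeration.
* **Linkage disequilibrium** uses the log-likelihood-ratio G statistic on
  the genotype × genotype table, with a permutation null (one locus's
  genotypes shuffled across individuals) and the same `(k+1)/(n+1)`
  estimator, which floors p at `1/(n_perm+1)`.  Combination across
  populations uses Fisher's method; because MC p-values are floored, the
  combined χ² is always finite (an infinite χ² from a literal zero p-value,
  as sometimes printed, is deliberately not reproducible).
* **Null alleles** follow the standard EM for a single non-amplifying
  allele at frequency r under Hardy–Weinberg: apparent homozygotes i/i pool
  true i/i with i/null, blanks (diploids typed elsewhere but not here) are
  null/null; the E-step apportions counts with current frequencies, the
  M-step renormalizes gene-copy counts.  At the r = 0 boundary the
  likelihood is flat to first order and EM crawls sublinearly, so
  convergence is declared on likelihood plateau as well as parameter change,
  followed by an explicit boundary comparison that snaps to r = 0 when the
  boundary likelihood is no worse.  The estimator is verified against a
  brute-force grid maximization of the same likelihood.
* **Allelic richness** is rarefaction to g gene copies,
  `Σ_i [1 − C(N−N_i, g)/C(N, g)]`, with exact integer binomials.  The base
  g defaults to the per-locus minimum across populations (not a per-dataset
  constant), which is how the standard per-locus standardization behaves and
  keeps every population comparable at each locus.
* **Private alleles** count, per population, alleles observed nowhere else.

`population_summary` assembles all of the above; in `males_merged_pairs`
mode it first calls ploidy, merges called haploids pairwise, and keeps
called diploids as-is.  HW p-values are BH-adjusted across the
loci × populations grid.  Within the summary the per-test Monte-Carlo sizes
default lower (n_mc 10⁴, cap 5 × 10⁴) than the single-test defaults, a
throughput choice for the full grid; both are parameters.

## The habitat model

Per-population counts `(n_diploid, n_haploid)` follow a binomial GLM with
logit link.  The design is habitat indicator intercepts plus habitat-nested
slopes for overall allelic richness and private-allele count.  Nesting makes
aliasing generic rather than exceptional: a covariate constant within a
habitat yields a zero column; a two-population stratum is saturated by its
intercept and one slope.  Columns are therefore screened greedily in column
order (a column is kept iff it raises the design rank) and every dropped
column is reported — on the bundled reference records the captive
private-allele column (all zeros) and the island private-allele column
(saturated stratum) are dropped, which reproduces the reference df pattern
(2, 2, 1) exactly.  The likelihood is maximized by IRLS (statsmodels GLM);
complete separation is flagged, not hidden.

Terms are tested by type-II analysis of deviance respecting marginality: a
term is tested by the deviance difference between the model containing every
term that does not contain it, with and without the tested term; df is the
number of surviving columns removed.  On the reference records the habitat
term gives LR χ² = 7.071 (df 2, p = 0.029), matching the published value to
all printed digits.  The covariate-term χ² values differ somewhat from the
published ones (1.75 and 0.22 vs 2.49 and 0.51): the exact design matrix
behind those rows is not reconstructible from the published material, so the
package documents its own design fully and treats only the habitat row and
the df pattern as reproducible.

Supporting statistics: Kruskal–Wallis uses midranks with the tie-correction
divisor `1 − Σ(t³−t)/(N³−N)` (all-identical data returns H = 0 by
convention); Cohen's d uses the pooled SD, with the conventional magnitude
bands (negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large); the
two-proportion test applies the Yates correction with `(|O−E|−0.5)`
truncated at zero; Welch's t uses the Satterthwaite df; FDR adjustment is
Benjamini–Hochberg step-up.

## The forward simulator

The simulator is the package's synthetic-data generator and the testbed
linking diversity to DMP.  Mechanism per generation:

1. Each female mates exactly once (monoandry).  With probability α
   (`sibmating_rate`) she takes a brother when one exists, else a uniform
   random male.  Diploid males may be chosen as mates
   (`sterile_sons_only`, the default — their mates produce only sons,
   i.e. all eggs develop unfertilized) or excluded entirely.
2. Clutch sizes are Poisson with mean `mean_clutch` (default 8).  Each egg
   of a haploid-mated female is fertilized with probability φ
   (`fertilization_prob`, default 0.5).
3. Fertilized eggs inherit one maternal csd allele and the paternal allele:
   heterozygous → female, homozygous → diploid male.  Unfertilized eggs are
   hemizygous haploid males.
4. Offspring adults are truncated uniformly at random to the carrying
   capacity; with migration, a Bernoulli fraction of adults is replaced by
   individuals drawn from the founder allele pool (dispersal is treated as
   a diffuse external source, not spatially explicit).
5. Markers are inherited Mendelianly.  Null alleles are heritable: an extra
   allele at founder frequency `null_allele_rate` per locus that is
   invisible at genotyping (one null → apparent homozygote, two nulls or a
   haploid null → missing), so downstream EM estimates a real population
   parameter.  Independent per-genotype dropout is applied on top.

All randomness flows from a single seed through one generator; runs are
bit-reproducible.  If a generation has no males or no females the population
is flagged extinct and the run stops.

Defaults emulate the study system: 10 loci with 2–12 alleles per locus (the
validated panel's allele counts), founder frequencies Dirichlet(1) (giving
He roughly in the 0.45–0.9 range), k = 20 equal-frequency csd alleles
(typical of csd surveys in large Hymenoptera populations), φ = 0.5,
α = 0 — sib-mating avoidance is reported for this species but no rate was
quantified, so panmixia is the default and α is a parameter.  Presets:
mainland (200 foundresses, capacity 1000, 5% migration, 10 generations),
island (50, 300, closed, 20), captive_large (120 foundresses, capacity 200,
25 closed generations) and captive_small (11 foundresses, capacity 150,
18 closed generations) mirror the documented founding histories of the
studied populations.  Capacity values for captive cultures reflect a
mass-rearing protocol cycling on the order of a hundred breeding adults.

Under panmixia with k equal-frequency alleles, a mother is heterozygous, a
random sperm matches one of her alleles with probability 2/k, and the
offspring is then homozygous with probability 1/2 — so the diploid-male
fraction among fertilized eggs is 1/k.  This closed form is the simulator's
primary correctness check (k ∈ {2, 5, 10} in the acceptance suite).

What the generator does **not** emulate: spatial structure and
kairomone-biased trapping, overlapping generations, allele-size mutation,
thelytokous lineages, and selection other than csd.  Passing tests on
simulated data therefore validate estimator logic and the
diversity → DMP mechanism, not field sampling artifacts.

## Problem sizes and numerical choices

The default test-and-acceptance runs use deliberately moderate sizes chosen
as adequate for their error bars: 20 replicates for simulator laws (the 1/k
check compares against 3 Monte-Carlo SEs), 10⁵ pedigrees for the mis-scoring
oracle, n = 500 diploids × 20 replicates for EM recovery, 8 simulated
populations × 80 sampled males for the captive-vs-mainland contrast.
Rarefaction uses exact integer binomials; HW enumeration caps at 10⁶ tables
before switching to Monte Carlo; probability ties in exact tests are
compared with a 10⁻⁹ log-scale tolerance; GLM IRLS runs to statsmodels'
deviance convergence with a 10⁻¹⁰ tolerance and rank decisions use a
relative 10⁻⁹ threshold.

## Known limitations

- The published covariate-term χ² values and the appendix mis-scoring
  probability cannot be reproduced exactly (inputs not recoverable); both
  are checked qualitatively instead, as described above.
- The EM null-allele model attributes all blanks to null homozygotes;
  technical dropout inflates r̂ unless modeled separately.
- Richness comparisons assume the per-locus rarefaction base; datasets with
  loci missing entirely in one population yield NaN richness for that locus.
- The simulator's migration pool is the founder frequency distribution, so
  long-run mainland diversity equilibrates to the founder pool rather than
  to a mutation–drift balance.
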