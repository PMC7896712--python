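# Methods

## The question the package addresses

Inbreeding depression (ID) — the decline of a quantitative trait's mean with
inbreeding — is usually estimated by regressing individual phenotypes on an
inbreeding coefficient *F* inferred from dense SNP data. Several genomic *F*
measures are in routine use and they disagree in well-documented ways:
SNP-by-SNP measures that weight rare alleles heavily (the GCTA `--ibc`
statistic F^III, a.k.a. F_UNI/F_GRM/F_alt) versus excess-homozygosity
measures (F^II, PLINK's F_HOM) versus runs-of-homozygosity measures (F_ROH
at various minimum segment lengths). `idbench` builds the whole comparison
as a tested pipeline: a forward simulator in which the true inbreeding load
is known exactly, marker extraction, all the estimators, the ID regression,
and the bias/RMSE/correlation bookkeeping across replicates.

## Simulation model

A diploid monoecious Wright-Fisher population of constant size N evolves in
discrete generations with random mating (selfing permitted — the two parents
of an offspring are independent fitness-proportional draws with
replacement). The genome is a single linear sequence of L = 100 Mb with
per-adjacent-bp recombination rate c = 1e-8, i.e. a 1 Morgan map — one
expected crossover per gamete, Poisson-distributed with uniform positions
and no interference (Haldane). Mutation is infinite-sites on the discrete bp
lattice (collisions with segregating sites are redrawn; no back mutation) at
rate U per haploid genome per generation.

A fraction `prop_causal` = 5% of mutations are QTLs with pleiotropic
effects: genotypic values 1 / 1+sh / 1+s for fitness (multiplicative across
loci, per-locus values floored at 0, i.e. 1+s < 0 is lethal) and 0 / ah / a
for the trait (additive, no environmental noise). |s| is gamma distributed
with mean 0.03 and shape beta = 1 (exponential); with the default rho = 1
the trait effect is proportional to the fitness effect (a =
trait_scale * s); for rho < 1 the two gamma marginals are coupled by a
Gaussian copula whose correlation is solved numerically so the Pearson
correlation of |a| and |s| equals rho. Dominance is h = 0.2 by default
(partial recessivity, hence directional dominance and a positive inbreeding
load); the variable-dominance variant draws h ~ Uniform[0, exp(-k|s|)] with
k solved in closed form so that E[h] matches the target mean (k =
((0.5/h̄)^(1/beta) − 1)·beta/|mean_s|).

Runs start from a genome devoid of variation and last 10N generations (5N
at N = 10,000). Sites fixed or lost are swept from the state each
generation; fixed trait effects only shift the phenotypic mean, which no
downstream regression uses (a counter records the sweep). For experiments
that measure inbreeding against a stored reference generation,
`drop_fixed=False` retains fixed columns so reference-frequency estimators
see them.

### Calibration

Two scenario constants are tuned, once, by `calibrate_rates`:

* **U** starts from the neutral Watterson expectation
  E[S] = 4N(0.95·U)·Σ 1/i solved for 30,000 neutral SNPs (13.44 at N=100)
  and is refined multiplicatively by full-length pilot replicates, because
  selection at linked QTLs depresses neutral diversity slightly below the
  neutral expectation. The frozen default is **U = 13.87**, which yields
  ~29-31k neutral SNPs in the final generation at N=100.
* **trait_scale** multiplies every a so that the expected load B = Σ 2dpq
  (d = a(h−1/2)) is about 1 — one haploid lethal equivalent. Because the
  trait has no feedback on fitness, the scale is solved exactly from the
  pilots' unscaled loads (scale = target / mean unscaled B) instead of
  iteratively; the frozen default is **trait_scale = 0.875**. Proportional
  deviations of estimated ID and all correlations are invariant to this
  scale, so it affects only the reporting units.

## True inbreeding load

B = Σ 2dpq over segregating QTLs, with d = a(h−1/2) > 0 under the default
parameters. An independent route forces every individual to complete
homozygosity in expectation — each heterozygous QTL value ah is replaced by
(0+a)/2, removing Monte-Carlo noise from the allele-picking that a literal
implementation would add — and measures the drop in the population mean.
Under exact Hardy-Weinberg proportions the two routes coincide
algebraically; on simulated populations they agree to a few per cent. The
baseline mean F of the population (~−1/2N) is treated as zero when reading
the drop as a per-unit-F rate; at N = 100 this is a 0.5% distinction, far
below replicate noise.

## Estimators

The marker panel contains all N individuals at every segregating neutral
SNP (QTLs removed, no MAF pruning), recoded to minor-allele dosage with the
current-generation frequencies (ties at 0.5 count the derived allele).
F^I, F^II, F^III (GCTA `--ibc` Fhat1-3) and F_HOM (PLINK `--het`) are the
standard per-individual formulas; with panel frequencies the population
means of F^I-F^III are algebraically identical and average ≈ −1/2N across
neutral replicates, while with stored reference-generation frequencies the
same formulas estimate identity by descent accumulated since that
generation, ≈ 1−(1−1/2N)^t under drift (both are tested). F^III is also
computed through its homozygote-weight (delta) reformulation as a
cross-check at 1e-12 tolerance.

F_ROH reproduces PLINK 1.9 `--homozyg` defaults: 50-SNP scanning windows
with at most 1 heterozygote, per-SNP hit-rate threshold 5%, minimum 100
SNPs per segment, at most 50 kb/SNP density, segments split at >1 Mb gaps;
minimum segment lengths 0.1/1/5 Mb replace PLINK's default 1000 kb, and the
caller is run once at the smallest cut with longer cuts obtained by
filtering (exact, because length enters only as a final filter). Before
calling, SNPs in high LD are thinned (`--indep-pairwise 50 5 0.9`
equivalent); within a flagged pair the smaller-MAF SNP is dropped, ties
drop the downstream SNP — PLINK's own choice is version-dependent, so the
rule is pinned here. Segment span is last-SNP minus first-SNP bp and the
F_ROH denominator is the configured genome length L.

## Evaluation

Estimated ID is minus the OLS slope of phenotype on each F measure across
all N individuals (no sampling of individuals, no phenotype noise, so any
deviation from the true load reflects the F measure itself). Per replicate
the proportional deviation is (EstID − TrueID)/TrueID; across replicates
the pipeline reports mean deviations with empirical 2.5-97.5% intervals,
RMSE = sqrt(mean squared deviation) with a nonparametric bootstrap SE
(1,000 resamples — the SE method is unstated in the sources the defaults
mirror, so bootstrap is the package's choice), means and within-replicate
variances of each F, and entrywise-averaged Pearson correlation matrices
among {F measures, phenotype, HML, HML_MAF, HML_QTL}. RMSE is computed on
the proportional scale; with the true load calibrated to ~1 this coincides
numerically with the absolute scale.

The homozygous mutation load counts loci homozygous for the *derived*
(mutant) allele — not the minor allele — per individual; HML_MAF restricts
to SNPs with minor-allele frequency ≤ 0.05 (inclusive boundary), where
derived and minor nearly always coincide.

One sign convention is worth spelling out. With trait values 0/ah/a and
a < 0, raw phenotypes *decrease* with mutational burden, so corr(Phe, HML)
would print negative while the conventional tabulation of phenotype-load
and phenotype-F correlations is on the burden scale (larger = more
depressed) — and the small-N ordering corr(Phe, HML) > corr(Phe, HML_MAF)
only makes sense there. The correlation table therefore uses the
depression score −Phe; the ID regression keeps the raw phenotype and takes
minus the slope, so both outputs are positive when inbreeding depresses
the trait.

## Problem sizes and what the tests show

The default benchmark is N = 100 for 1,000 generations (~30,000 SNPs); one
replicate takes ~15 s to simulate and ~3 s to analyse with the vectorised
uint8 haplotype representation (a CSR index over derived alleles makes
gamete assembly sparse in the allele count rather than the site count).
Acceptance-level checks run 30-32 replicates; three-standard-error
tolerances are used for all stochastic comparisons, combined with the
published standard errors where those are available. Replicate counts in
the hundreds would narrow the intervals but not move the means.

Neutral-theory unit tests use a 5 Mb genome at c = 2e-7 — the same
1 Morgan map in a smaller site budget. An early version used 5 Mb at the
default c and produced wild replicate scatter: with a 0.05 Morgan map the
whole genome is effectively one linked block and genome-wide means have
enormous sampling variance. Map length, not physical length, is the
quantity that controls this.

Large-N claims (the shrinking F^III bias and growing F_ROH underestimation
toward N = 10,000) are outside the default test scale: a single N = 1,000
replicate is 10,000 generations. The configuration space supports them
(`default_scenario(N=...)` plus `calibrate_rates`), and the variant
scenario presets (recombination x10 up/down, quarter SNP density, 10%
QTLs, s = −0.1, beta = 0.1/2, h = 0, rho = 0.5, variable dominance) are
exposed but not asserted against published values.

## What the generator does not emulate

Real data features deliberately out of scope: environmental noise on
phenotypes, separate sexes and non-random mating, population structure and
migration, multiple chromosomes, heterogeneous recombination and mutation
rates along the genome, genotyping error and missingness (the PED/MAP
reader rejects missing codes because the estimator formulas assume
complete data), and ascertainment bias of SNP panels. Conclusions from
passing tests therefore concern the statistical behaviour of the F
measures under idealised Wright-Fisher conditions, not their field
performance on any particular organism.

## Known limitations

* The PED/MAP text format cannot carry the derived-vs-minor orientation
  flag; panels read back from disk support the F estimators but not the
  derived-allele load counts (HML requires an in-memory panel).
* With tight linkage (map length << 1 Morgan) genome-wide means are
  dominated by a handful of genealogies and converge very slowly in
  replicates; calibration targets are set for the 1 Morgan default.
* `ld_prune` follows the pinned removal rule; other PLINK versions can
  retain a different member of a high-LD pair, which perturbs ROH edges
  slightly (but not the F_ROH fractions at the tested tolerances).
* The bivariate-gamma copula solve assumes rho in (0, 1]; negative
  pleiotropic correlations are rejected by config validation.
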