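# Methods

This note records the models implemented, the numerical and design
choices made where the literature leaves room, and what the synthetic
data generator does and does not emulate.

## Pedigree algebra

Kinship uses the standard tabular recursion over a topological order:
C(i,j) = ½[C(sire_i,j) + C(dam_i,j)], C(i,i) = ½(1 + C(sire_i,dam_i)),
with unknown parents contributing zero.  Founders (both parents
unknown) are the base population: non-inbred and mutually unrelated.
Individuals with one known parent inherit half of that parent's row.
Duplicated ids, ancestry cycles, dangling parent references, sex-
inconsistent parents and parents not older than their offspring are
hard errors — silent repair would corrupt every downstream estimate.

Pedigree depth is the equivalent complete generations
t_i = Σ_parents (1 + t_parent)/2; a fully known k-generation pedigree
gives t = k exactly.  Filial classification is strict: F1 requires two
founder parents, F(k) two F(k−1) parents, anything else (including one
unknown parent) is OVERLAPPED; founders themselves are labelled
FOUNDER.  Classes beyond F5 are supported — the ladder depth is a
property of the data, not of the labels.

Cohort grouping supports discrete filial classes, yearly birth cohorts
and sliding contiguous year windows (span 2 = biannual, 3 = triennial);
an individual belongs to every window containing its birth year, so
adjacent windows overlap by construction.

## Genealogical Ne

ΔF_i = 1 − (1 − F_i)^(1/(t_i − 1)).  The t − 1 exponent reflects the
absence of self-fertilization: in a dioecious population inbreeding
lags coancestry by one generation.  Individuals with t ≤ 1 have no
defined rate and are excluded from the average (and counted in an
exclusion report); pairs enter ΔC as all unordered non-self pairs of
the reference subset, with kinship and depth computed on the full
pedigree.  Ne_Fi = 1/(2·mean ΔF), Ne_Cij = 1/(2·mean ΔC).  The mean is
the arithmetic mean of per-individual (per-pair) increases, not the
formula evaluated at mean F and t.  Standard errors propagate the
dispersion of the increases through the inversion by a first-order
delta method: SE(Ne) = SD(Δ)/(2·Δ̄²·√n).  On simulated dioecious
discrete-generation populations of census 20 the estimator recovers
the census within sampling error (median over 50 replicates within
±20%), which is the regime the t − 1 exponent is designed for.

## LD effective size

For each pair of retained loci, each retained allele pair contributes
the squared Pearson correlation of the two dosage vectors (0/1/2
copies) over pairwise-complete individuals.  This equals the Burrows
composite Δ² normalized by (p(1−p) + D_A)(q(1−q) + D_B), where D is
the within-locus Hardy–Weinberg departure — the phase-free convention
appropriate for unphased microsatellites.  It is bounded in [0, 1] and
reaches 1 under perfect association.  Per-pair r² is the unweighted
mean over allele pairs; the pooled mean weights locus pairs by their
number of allele-pair comparisons, and S is the matching weighted
harmonic mean of per-pair sample sizes.

Pcrit screening masks alleles below the frequency threshold (the
individuals stay); loci left with fewer than two retained alleles are
excluded and reported.  Screening applies to the LD estimator only.

The Waples bias-corrected inversion subtracts the sampling expectation
1/S + 3.19/S² and solves the quadratic drift relation
Ne = (1/3 + √(1/9 − 2.76·r²drift))/(2·r²drift), the random-mating,
S ≥ 30 calibration.  Those constants are calibrated for the Burrows
statistic carrying an (S/(S−1))² small-sample factor, so the inversion
is applied to r²·(S/(S−1))²; note S²/(S−1)³ ≈ 1/S + 3.19/S² to three
significant figures at S = 50, which is what makes the correction
consistent.  Non-positive corrected drift — and a negative
discriminant — are reported as an infinite-Ne flag rather than a
number.  On ideal simulated populations (N = 50, 17 loci, 8 founder
alleles, S = 50) the median estimate over 100 replicates is within a
few percent of the census.

Confidence intervals use a delete-one-locus jackknife: every locus
pair involving the deleted locus is removed, the pooled r² is
recomputed, the jackknife variance is formed on the r² scale (where
the statistic is approximately normal) and the interval endpoints are
mapped through the inversion.  The jackknife unit is the locus, not
the individual or the locus pair: locus-level deletion keeps the
replicates interpretable as independent marker subsets.  Empirical
coverage of the nominal 95% interval on ideal populations is ~94%.

## Molecular-coancestry Ne

Per pair and locus, f_ij,l = (I_ac + I_ad + I_bc + I_bd)/4; corrected
terms (f − s_l)/(1 − s_l) are combined across loci with weights
w_l = (1 − s_l)²/[s_l(1 − s_l)] (monomorphic loci drop out), averaged
over the n(n−1)/2 non-self pairs, and inverted as Ne(M) = 1/(2·f̂).
Pairs with no commonly typed locus are dropped.  The CI is a
delete-one-locus jackknife, for symmetry with the LD module.

One property of this estimator deserves emphasis: when the reference
homozygosity s_l = Σp̂² is computed from the same sample, the mean of
the raw coancestry over all ordered pairs including self-pairs equals
Σp̂² *exactly*, so the corrected non-self mean is ≈ −1/(2(n−1))
regardless of population history — a centring, not a size signal.
Meaningful absolute values therefore require reference frequencies
from a base population (`base_frequencies=`); in simulations the
founder generation provides them, and f̂ then tracks pedigree
coancestry (rank correlation ≈ 0.7 on simulated herds).  Excluding
self-coancestries keeps f̂ below the full-matrix mean f, so Ne(M)
always exceeds the founder-genome-equivalents diagnostic Ng = 1/(2f),
which is also provided.

## Temporal effective size

Per locus, Fs has numerator Σ(x_i − y_i)² and denominator
Σ z_i(1 − z_i) over the union of the two samples' alleles; pooling is
the ratio of summed numerators to summed denominators (the unbiased
pooling), never the mean of per-locus ratios.  A halved-denominator
variant is available behind a flag for comparison with the alternative
convention.  The plan-I correction is
Fs′ = [Fs(1 − 1/(4ñ)) − 1/ñ + 1/N]/[(1 + Fs/4)(1 − 1/(2n_y))] with ñ
the harmonic mean sample size and N the census at first sampling; the
inversion Ne = elapsed_years/(2·Fs′) accumulates one unit of per-year
drift per elapsed year.  Fs is symmetric in the samples, Fs′ is not
(it uses n_y); Fs′ ≤ 0 yields an infinite-Ne flag.  On ideal
populations sampled one generation apart (N = 30, S = 30, 17 loci)
the median estimate over 100 replicates is within ~10% of the census.

In the pipeline, the census defaults to the pedigree count of
individuals born within the parental age cap (five years) of the first
sampling year — the pedigree records no deaths, so the cap bounds
lifespan — and can be overridden per cohort.

## Demographic models

The age-structured Nb/Ne model takes per-sex schedules of survival
s_x and birth rates b_x over age classes 1..ω, rescales fecundities to
stationarity (Σ l_x b_x = 2 per sex, assumption: every recruit reaches
its first birthday), and assumes yearly breeding, independence of
survival and fecundity across years, and within-age Poisson offspring
variance.  Lifetime offspring variance per sex is

  V = Σ_x [l_x b_x + l_x b_x² − (l_x b_x)²] + 2 Σ_{x<y} b_x b_y l_y (1 − l_x),

the Poisson within-age term plus the survival-induced covariance of
contributions at different ages.  Per-generation effective size is
Hill's Ne = 4·N1·T/(V̄ + 2) with T the mean age of parents and V̄ the
equal-sex-ratio average of the per-sex variances.  The single-cohort
Nb applies the variance formula Nb_s = N·k̄/(k̄ − 1 + V_k/k̄) to one
season's eligible breeders per sex (ages with b_x > 0, zero producers
included) and combines sexes as 4·Nbm·Nbf/(Nbm + Nbf).  The Nb/Ne
ratio is invariant to the recruit cohort size N1.  A semelparous
schedule collapses to Nb = Ne = N1 exactly.  Against an
individual-based gene-dropping oracle run under the same assumptions
the ratio agrees within a few percent on disparate tables.  Note that
the ratio may exceed 1: with symmetric sexes and mildly declining
fecundity the season's breeders are effectively more numerous than a
generation's; strongly skewed schedules push it below 1.

Factor C is computed from a deterministic recursion on the
standardized variance/covariance matrix of age-class cohort allele
frequencies: each year a newborn cohort draws 2·N1 gene copies
binomially from parental age classes weighted by l_i·b_i (adding
1/(2N1) variance plus the parental covariance mixture), and each
cohort thins hypergeometrically from N1·l_i to N1·l_{i+1} individuals
as it ages.  At the stationary increment, C = f(1)/λ, the ratio of the
one-year cohort-to-cohort standardized drift to the asymptotic
per-year accumulation rate, and the per-generation effective size
implied by the recursion is 1/(2λG).  Both noise sources scale as
1/N1, so C is size-free; the semelparous limit gives C = G = 1
exactly, and the recursion's f(k) predictions match the
individual-based simulator within a few percent.  C applies exactly to
consecutive-cohort (one-year) comparisons; for a t-year span the
implied factor decays as (C − 1 + t)/t toward 1, which is why
long-span temporal estimates adjusted by the full C/G drift upward.

Adjustments: cohort LD estimates are multiplied by Nb/Ne (division
available behind a flag); per-year temporal estimates are multiplied
by C/G.  The G used for C/G defaults to the recursion's own generation
interval but accepts the pedigree-observed value, which is usually the
better-grounded number.

## Synthetic data generator

Defaults emulate a herd recovery scenario: six founders (three boars,
three sows), 17 unlinked loci with eight founder alleles drawn from a
symmetric Dirichlet (microsatellite-like polymorphism), yearly
breeding over a five-age-class pig-like life table (survival 0.8, 0.7,
0.6, 0.5, 0; birth rates 1.5, 1.2, 0.8, 0.5, 0.3; generation interval
≈ 1.8 years; parents capped at five years), Poisson litters of mean 6
with sire and dam drawn with probability proportional to their
age-class birth rates, a mating policy rejecting pairs above a
pairwise-coancestry threshold (threshold 1 = random mating), and a
fixed number of recruits per cohort (the stationarity assumption of
the demographic model).  With litter mean ≤ 1 every recruit draws its
parents independently, which reproduces the within-age Poisson
variance the deterministic models assume — that mode is the oracle
substrate for the demographic validation.  The litter-size
distribution is a modeling choice, not an inference from data.

The discrete-ladder mode breeds each generation exclusively from the
previous one, so classification recovers exact F1..Fk classes; the
Wright–Fisher mode (constant N, random union of gametes, selfing
allowed) is the ideal population with Ne = N used for parameter
recovery.

Realized truth: drift Ne comes from regressing the standardized
squared change of newborn-cohort allele frequencies on the year span —
the regression slope removes the cohort-level offset (factor-C effect)
— via Ne = 1/(2·slope·T); inbreeding Ne from the rise of mean pedigree
inbreeding converted to a per-generation rate.  Realized Nb applies
the variance formula to each year's realized offspring counts among
eligible breeders and combines years harmonically.

What the generator does not emulate: mutation, migration, selection,
genotyping error, linked loci, population growth or decline (recruit
cohorts are fixed), and missing genotype data in generated files.
Passing tests therefore demonstrate correctness of the estimators
under their own model assumptions and the qualitative mechanisms
(age-structure bias, relatedness-driven covariation of r² and f̂),
not robustness to those real-data complications.

## Problem sizes in the test suite

Oracle comparisons run on pedigrees of up to 12 individuals (where
exhaustive path counting is exact and fast) and 20 × 5 genotype
matrices.  Parameter-recovery checks use 100 replicates of N = 50
(LD) and N = 30 (temporal) ideal populations; the demographic
validation uses six 45-year runs per life table at 60 recruits/year;
the discrete-vs-yearly stability comparison uses 50 replicates of each
design at a matched sample size of 40.  These sizes give Monte-Carlo
error comfortably inside the asserted tolerances while keeping the
default test run in tens of seconds.

## Known limitations

- Within-sample molecular-coancestry estimates carry no absolute size
  signal (see above); the module is faithful to the published formulas
  but honest use requires a base reference.
- The printed r² columns of marker-based studies depend on software
  conventions (weighting, allele screening, sample-size factors) that
  cannot be reconstructed from formulas alone; this implementation
  documents its conventions and validates them against its own oracles
  instead of chasing printed values.
- The factor-C recursion models frequencies at the cohort level;
  individual-level persistence of exceptional breeders beyond the
  Poisson model (e.g., strong litter clustering) inflates realized
  drift slightly relative to the model.
- The temporal estimator's sampling correction assumes samples much
  smaller than the cohorts they are drawn from; complete-census cohort
  samples over-subtract and can drive Fs′ to zero in large populations.
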