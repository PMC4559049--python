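# Methods

This note documents the models behind `snpdispersal`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter when reading
the code or its output.

## The estimation problem

Natal dispersal — the distance between where an animal was born and
where it settles — is measured here without ever observing a birth:
noninvasive fecal genotypes identify individuals, a likelihood
parentage analysis links mothers to offspring, fecal sample locations
proxy each animal's home-range center, and the mother–offspring
center-to-center Euclidean distance is the dispersal estimate. Because
every stage (genotyping error, sex calling, pedigree inference, center
estimation, cub exclusion) can distort the final distances, the
package ships a generator that produces populations with known truth
at the study's scale, and the test suite validates each stage against
that truth or against closed-form oracles.

## Synthetic-data generator

**Population.** Founders (default 120 females + 120 males) form
generation 0; each mother draws Poisson(2.2) offspring and, per
litter, one father uniformly from the same generation's males
(polygamy allowed; the field system is unconstrained mating, and no
mating-system detail is available to emulate). Three non-overlapping
generations yield ≈ 810 individuals, of which 53 % (433/810) are
"sampled" — genotyped and located. There is no age structure or
mortality; generations are a modelling device, not cohorts.

**Space.** The study region is a 214 × 214 km rectangle (≈ 45,000 km²).
Founder centers are uniform; each non-cub offspring center is its
mother's center plus an isotropic displacement whose magnitude is
exponential with sex-specific mean (female 12.9 km, male 33.8 km;
half-normal available as an option). Only means and SDs of dispersal
are available to calibrate against, and the exponential is the
simplest heavy-tailed single-parameter choice consistent with them.
Displacements leaving the rectangle are truncated to the boundary,
which biases realized male distances below the kernel mean — the same
direction as the real study's acknowledged loss of long-distance male
dispersers beyond its borders.

**Panel and genotypes.** 87 autosomal + 3 X + 2 Y + 4 mtDNA-diagnostic
loci. Autosomal minor-allele frequencies are 0.5·Beta with
concentration 30, mean 0.37, clipped to [0.01, 0.5]. Founders are
Hardy–Weinberg draws; offspring inherit one allele per parent; males
are hemizygous at X loci (reported as homozygotes) and carry both Y
markers; females have no Y calls; the mtDNA haplotype
(south/middle/north, founder proportions 0.96/0.03/0.01) is copied
matrilineally and encoded in the four diagnostic loci. Observed
(per-sample) genotypes first lose one allele of a heterozygote with
probability `dropout_rate` (default 0.01, a typical fecal-DNA value),
then each allele flips with probability `epsilon` (default 3.8 × 10⁻⁴),
then calls go missing (0.0035) or are invalidated (0.003); haploid
loci are left error-free, matching error-rate conventions that score
diploid loci only.

**Fecal sampling.** Per-individual sample counts follow the study's
published frequency table over 1–19 (mean ≈ 2.2, two-thirds
singletons). Sites scatter isotropically (σ = 3 km per axis) around
the true center. That scale is a compromise: the real data show a
15.6 km mean spread between same-individual sites, but that figure
mixes home-range size with excursions, and as i.i.d. noise it would
drown the female dispersal signal that the real median-center workflow
evidently preserves; 3 km keeps center error (~2 km for two samples)
subordinate to the 12.9 km female kernel while still exercising the
median-center machinery. Families with dependent cubs travel as a
unit over a restricted range, so cub-litter offspring *and their
mothers* use a tight σ = 0.2 km — without this co-movement the 1-km
cub rule could never fire, whereas the real study detected cubs with
it. A fraction of final-generation litters (`cub_litter_prob` = 0.15)
are such pre-dispersal families, sitting at the mother's center.

**What the generator does not emulate:** landscape heterogeneity and
resistance, age structure and mortality, non-uniform volunteer
sampling effort, linkage between loci, and null alleles. Passing
tests therefore demonstrate correctness of the estimators under the
stated statistical model, not robustness to those field realities.

## Genotype QC

Replicates of one individual are consolidated by per-locus strict
majority among valid calls (ties → missing); a group with > 20 %
pairwise autosomal mismatch is dropped as a probable sample mixture.
Error rates come from replicate concordance at diploid loci: a
comparison is a replicate pair at a locus with both calls valid and at
least one heterozygous; the mismatch error rate is the discordant
fraction of those comparisons (the convention behind the published
3/7825 = 0.00038 arithmetic), and allelic dropout divides the same
het→hom count by twice the comparisons, since either of a
heterozygote's alleles could have dropped. Sex calling requires
unanimity: calls at *all* Y loci ⇒ male, provided no X heterozygote;
missing at all Y loci ⇒ female (an X heterozygote confirms);
everything else is undetermined. The probability of identity uses the
plain HWE form ∏(p⁴ + 4p²q² + q⁴) with no sibling correction, since a
single PID bound is all that is quoted for the panel.

## Lynch–Ritland relatedness

The regression estimator with reference individual x at locus l is

    r̂ₓ(l) = [p_a(S_bc+S_bd) + p_b(S_ac+S_ad) − 4 p_a p_b]
            / [(1+S_ab)(p_a+p_b) − 4 p_a p_b]

with locus weight wₓ(l) = denominator / (2 p_a p_b); the multilocus
value is Σ w r̂ / Σ w and the reported coefficient averages the two
reciprocal references (Lynch & Ritland's symmetrization). Loci missing
in either member, or monomorphic, are excluded from sums and weights;
a direction whose total weight is zero (e.g. a lone heterozygous
reference at p = 0.5 — the denominator vanishes identically) is
uninformative and the other direction is used alone. Allele
frequencies are estimated from all consolidated individuals with no
small-sample correction and no exclusion of the focal pair, matching
common estimator-package defaults; the functions accept any frequency
vector, so a corrected variant is a caller-side change. Expectations:
0.5 for parent–offspring and full sibs, 0.25 for half sibs and
grandparent–grandchild, 0 for unrelated pairs; the estimator is
unbiased but individual values range well outside [0, 1].

## Parentage

**Likelihoods.** Per locus, a symmetric per-allele miscall rate ε
(default 1.538 × 10⁻⁴, the typing error a parentage run would be given)
defines a 3×3 genotype confusion matrix; Mendelian transmission gives
P(offspring | parents); parents' true genotypes carry HWE priors. The
triad likelihood is P(g_offspring | g_mother, g_father) with all true
genotypes marginalized; the dyad likelihood integrates the unsampled
co-parent's transmitted allele over population frequencies; the
unrelated baseline is the HWE marginal. Likelihoods are *conditional*
on the candidates' observed genotypes — their own marginals are common
to all hypotheses for a focal individual and cancel in the posterior
(this is also what makes the single-locus dyad value for an A/A
offspring with an A/A parent equal exactly p). Missing calls
contribute a factor that marginalizes out. Only autosomal loci enter;
mtDNA is a post-hoc maternity check that flags, never rejects.

**Posterior.** For each focal individual the hypothesis set is: every
screened (positive dyad log-likelihood-ratio) mother × father pair,
every single sampled parent with an unsampled partner, and both
parents unsampled. Priors count candidates: each sampled candidate has
weight 1 and the unsampled-parent mass is N_max − n_sampled per sex
(N_f^max = 663, N_m^max = 516 by default, taken from the study's
census-derived pool sizes; the census/pool-size tension in the source
material is left as two independent knobs). Posteriors normalize over
this set; an assignment is reported when the best hypothesis names at
least one sampled parent with posterior ≥ 0.95.

**Assembly.** Ages are unknown, so a sampled offspring is
genotypically as plausible a "parent" of its own parent as the
reverse, and a founder's best-supported hypothesis is often built from
its descendants. A marginal per-focal decision cannot resolve this;
full pedigree-space MCMC is out of scope by design. The deterministic
middle path implemented here: (1) keep a pool of up to 8 hypotheses
per focal within 12 log-units of its best; (2) insert greedily —
triads before dyads, because a triad fixes its own direction through
allele sharing while a pairwise dyad likelihood is symmetric — ordered
by the prior-free log Bayes factor against the unrelated hypothesis,
rejecting anything that creates a cycle, a second same-sex parent, or
a second assignment for one focal; (3) repair sweeps that remove an
accepted hypothesis when the blocked alternatives it excludes carry a
larger summed Bayes factor (this is what dissolves inverted-family
configurations: explaining two children as children beats explaining
one founder by its children); (4) conditional reassignment passes that
re-score still-unassigned individuals with their pedigree descendants
excluded from the candidate pools; and (5) a final filter keeping only
assignments whose *conditional* posterior still clears 0.95. Dyads
whose direction is not forced by the surrounding structure are demoted
to unoriented parent–offspring links and excluded from dispersal.

On error-free, fully sampled populations of ~50–70 individuals this
recovers the true pedigree exactly in 39 of 40 seeds; the one failure
is a configuration in which a full-sibling-as-mother plus an inverted
founder triad jointly outscore the truth in likelihood — a finite-data
identifiability limit, not an assembly artifact. For fully sampled
populations the candidate-pool maxima are set to the sampled sex
counts (the coherent reading of a "maximum number of candidates" when
everyone is genotyped); self-consistency runs also hand the likelihood
the panel's generating allele frequencies, because frequencies
re-estimated from a ~50-animal, family-structured toy sample are
biased enough to flip true-parent likelihood ratios, which is a
property of the toy size, not of the method (the full-scale analysis
estimates frequencies from all 433 individuals).

## Spatial statistics

Home-range centers are coordinate-wise medians of an individual's
sample sites (robust to excursions; a single site is used as-is; this
is the "median center" of the cited tooling, distinct from the
geometric median). Distances are planar Euclidean on projected meter
coordinates, reported in km. The Mantel statistic is the Pearson
correlation of upper-triangle entries with the null built by jointly
permuting rows and columns of one matrix; p = (1 + #extreme)/(n_perm + 1)
with 999 permutations by default, one-sided in the direction of the
observed sign (the cited test's convention; two-sided and exact
full-enumeration modes are available, the latter for n ≤ 8).
Individuals with missing relatedness entries are dropped listwise per
stratum. Opposite-sex pairs form a rectangular matrix, so only a
Pearson correlation is reported there.

## Dispersal

An offspring is excluded as a pre-dispersal cub iff it has a full
sibling, the two sibling centers are mutually within `delta_sib_km`,
and each is within `delta_mother_km` of the mother's center (both
default 1 km; the sibling tolerance is not pinned down by the source
description, and 1 km is the only scale it supplies). Distances of
zero are retained — short-distance dispersal is information, not an
artifact. Summaries report N, median, mean, SE = sample SD (n−1)
/ √n, and max per group, rounded to one decimal in written reports.
The sex comparison is a two-sided Wilcoxon rank-sum test (exact for
small untied samples, normal approximation with tie and continuity
corrections otherwise), with W in the first-sample U convention.
Offspring linked to a mother only through an unoriented dyad are
excluded (conservative, per the directionality argument above).

## Calibration experiments and problem sizes

The experiment layer (`snpdispersal.experiments`) fixes the problem
sizes used by the tests and the acceptance script: 2,000 pairs × 87
loci for estimator calibration; three seeds of ~50-individual
populations for pedigree self-consistency plus 500 triples for
orientation; 40 replicates of 38 female + 25 male mother–offspring
pairs for sex-bias recovery (these replicates place mothers on an
unbounded plane, isolating estimator behaviour from boundary
truncation, and condition on the study's group sizes); 200 null runs
of n = 30 with 99 permutations for Mantel calibration. These sizes
make every stochastic check tight relative to its tolerance while the
whole suite stays interactive.

## Known limitations

* Dyad orientation is conservative: without age data, symmetric
  parent–offspring links are dropped from dispersal rather than
  guessed, so partially sampled populations yield fewer distance
  records than an MCMC sampler that commits to directions.
* Boundary truncation plus sub-sampling biases realized male
  dispersal below the kernel mean in full-study simulations, and a
  single simulated study can fail to reject the sex-difference test —
  mirroring the marginal significance such designs produce in the
  field.
* The cub filter depends on center co-location and misses cub
  families whose centers are noisy; undetected cubs bias dispersal
  means downward, a bias the source design shares.
* The error model is symmetric per-allele miscall plus one-allele
  dropout; systematic cluster-calling artifacts are represented only
  as invalidated calls.
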