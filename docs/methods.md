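# Methods

## Statistics and site policy

All statistics operate on haplotype alignments over {A,C,G,T,N,-} with
males already collapsed to one row at X-linked loci. The default site
policy is complete deletion: any column containing N (or a gap, since
gaps are treated as missing by default) in any retained sequence is
excluded before counting, reproducing the behaviour of classic
sequence-analysis software. A pairwise-deletion mode is available, in
which each pair is compared over its jointly called sites and the
per-pair proportions are averaged.

- π is the mean pairwise difference proportion, Σ<sub>i&lt;j</sub>d<sub>ij</sub> / (C(n,2)·sites).
- D<sub>XY</sub> is the same quantity over between-group pairs,
  Σ<sub>i∈A,j∈B</sub>d<sub>ij</sub> / (n<sub>A</sub>n<sub>B</sub>·sites).
- F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub> with
  H<sub>w</sub> = (π<sub>A</sub>+π<sub>B</sub>)/2 and H<sub>b</sub> = D<sub>XY</sub>,
  all three computed on the joint usable-site set so
  H<sub>w</sub> = (1−F<sub>ST</sub>)·H<sub>b</sub> holds exactly.
  The sequence-based F<sub>ST</sub> family varies across software
  versions; this Hudson–Slatkin–Maddison form is the one the relative-
  vs-absolute-divergence argument is usually stated in, and the
  Lynch–Crease N<sub>ST</sub> variant — (π<sub>T</sub> − π<sub>S</sub>)/π<sub>T</sub>
  with π<sub>S</sub> the sample-size-weighted within-group mean — is
  exposed as an option. Negative values are reported as-is, never
  clipped; group medians are robust to them.
- Tajima's D uses the count form of π̂ (not per site) over usable sites
  with the 1989 constants; it is flagged undefined (NaN) when n < 4 or
  S = 0, never silently zero.

Counts are accumulated as integers (per-column allele counts give
Σ pair differences without enumerating pairs) and divided once, so the
vectorised path agrees with brute-force pairwise enumeration to 1e−12,
which the test suite asserts on 1000 random alignments.

Two finite-sample identities are worth noting because they differ from
the asymptotic intuition: comparing a group of n sequences against an
identical copy of itself gives D<sub>XY</sub> = π(n−1)/n (the n
self-pairs contribute zero) and hence F<sub>ST</sub> = −1/(n−1), not 0.
The "F<sub>ST</sub> ≈ 0 under panmixia" behaviour holds in expectation
over independent samples and is checked that way in the simulator tests.

## Genotype calling and sexing

A site is called when total coverage ≥ 8 reads (the threshold is a
parameter; the inclusive reading of "minimum depth of 8" is used) and
heterozygous when the second-most-frequent base carries ≥ 25% of reads
(a tie at exactly 25% counts as heterozygous). Modal ties break by the
fixed order A<C<G<T for determinism. Individual/locus combinations
whose fraction of called sites falls below a configurable floor
(default 0.5) are flagged for exclusion; the floor is a convention, not
an inference about the original study's unstated criterion.

Sex inference counts heterozygous sites across the five X-linked
screening loci with the highest mean called fraction (a coverage
proxy). At most 3 heterozygous sites — tolerating sequencing error —
means male; fewer than 5 screened loci means unknown. When pileups are
available, a heterozygous consensus site whose own pileup does not
support a confident heterozygote at the calling thresholds is
discounted first; this is the mechanical analogue of manually checking
each polymorphism's allele quality and frequency. Whether "3 or fewer
polymorphisms" should count sites or loci is ambiguous; sites are
counted and both the threshold and the discount are exposed. Collapsing
removes copy 2 of every male at X loci only; a male whose two X rows
disagree at called sites keeps copy 1 with a machine-readable warning.

## Phasing

Downstream statistics are functions of per-site allele counts, so phase
is irrelevant to them; heterozygous consensus sites are therefore split
into haplotypes with a seeded random phase rather than a statistical
phasing model, and the phase seed is recorded in the run manifest
because the four-gamete trimmer (alone) does depend on phase. The test
suite verifies that π, D<sub>XY</sub>, F<sub>ST</sub> and Tajima's D
are bit-identical across phase seeds.

## Resampling

Category contrasts use a permutation test on the difference of group
medians (medians because the reported summaries are medians; a
difference-of-means statistic is available). Whole loci are
reallocated; when C(n<sub>A</sub>+n<sub>B</sub>, n<sub>A</sub>) ≤ 20,000
every relabeling is enumerated and the p-value is exact, otherwise
p = (1 + #extreme)/(B+1) over B random reallocations (default 10,000),
so the smallest reportable p is 1/(B+1). Two-sided by default; the
alternative is an option. No multiple-testing correction is applied;
p-values are reported per contrast as-is.

BCa intervals follow Efron: z₀ = Φ⁻¹(fraction of bootstrap replicates
below the point estimate), acceleration from jackknife skewness,
adjusted quantiles α<sub>k</sub> = Φ(z₀ + (z₀+z<sub>k</sub>)/(1 − a(z₀+z<sub>k</sub>))).
A sample with zero range collapses to a flagged point interval; a
bootstrap distribution entirely on one side of the estimate falls back
to the percentile interval with a degeneracy flag. Spearman ρ uses
mid-ranks for ties; its bootstrap p is 2·min(P(ρ*≤0), P(ρ*≥0)) over
case resamples, floored at 1/(B+1).

## Calibration and trimming

The calibration chain applies D = 2μt twice: mitochondrial divergence
at 0.0115 subs/site/My (pairwise arthropod COI clock) dates each
outgroup split, then each locus's divergence to that outgroup at that
date gives a per-locus nuclear rate; rates from the two outgroups are
averaged when both exist, and loci with no outgroup get none.
Divergence between species consensus sequences defaults to the
uncorrected p-distance with a Jukes–Cantor option (−(3/4)ln(1−4p/3));
at divergences below 0.08 the two differ by under 6%, and both are
reported rather than hidden. Consensus ties (two bases at equal
majority) are emitted as IUPAC codes and excluded from divergence
sites, since a tie carries no majority signal. Generation time is fixed
at one year (univoltine, diapause-egg overwintering), so rates per year
and per generation coincide.

The four-gamete trimmer finds the longest contiguous window containing
no pair of biallelic, fully called sites exhibiting all four gametes;
ties resolve leftmost, and with no segregating sites the whole locus is
kept. Sites with missing data or more than two alleles are ignored for
pair compatibility, since the four-gamete logic is defined for
biallelic complete pairs. This is site-window trimming only: unlike
tools that also delete sequences to enlarge the retained region, no
rows are dropped, which keeps the operation deterministic and
oracle-checkable (the suite compares it with exhaustive window
enumeration on 500 random alignments). The IM writer emits a title
line, population count and names, a (0,1):2 population tree, and one
locus block per alignment with the infinite-sites model token, the
inheritance scalar (1.0 autosomal, 0.75 X) and the per-locus rate when
calibrated; a bundled parser round-trips the format for testing.
Running any isolation-with-migration MCMC on that file is out of scope.

## Synthetic data generator

The simulator is a continuous-time two-deme structured coalescent:
within a deme, k lineages coalesce at rate k(k−1)/2 / (2N<sub>e,eff</sub>);
lineages migrate between demes at per-lineage backward rate m; at the
split time both demes merge into an ancestral deme. Continuous time was
chosen over discrete generations because it makes the closed-form
expectations exact — E[π] = 4N<sub>e</sub>μ per site in one deme, and
E[D<sub>XY</sub>] = 2μT + 4N<sub>e,anc</sub>μ under pure isolation —
and the test suite checks both to within 3 Monte-Carlo standard errors,
plus a direct cross-check of mean D<sub>XY</sub> against msprime under
the same demography.

Mutations are Poisson on branches (infinite sites), each assigned a
distinct position drawn uniformly without replacement from the finite
locus; a locus drawing more mutations than sites falls back to
placement with replacement and a multi-hit warning. X linkage enters
twice: X loci use (3/4)N<sub>e</sub>, and sampled males contribute one
lineage (X0 males). A sweep is modelled as a local N<sub>e</sub>
multiplier on the affected loci's daughter demes — one parameter that
produces the diversity-reduction footprint without an explicit
trajectory; the ancestral deme is left unscaled so D<sub>XY</sub> is
unaffected, which is precisely the contrast the sweep scenario exists
to exhibit. Loci are single non-recombining gene trees; recombination
is available only as a two-tree concatenation mode used to exercise the
trimmer.

Study-scale defaults mirror the empirical design: 48 loci (21
autosomal, 27 X-linked; barrier/background cell counts 13+22 / 8+5) of
5 kb; 96 individuals, 48 per species with sex ratios 25:23 and 30:18,
split across four population labels per species (panmictic within
species — the analyses pool populations by species, and no
within-species structure estimates exist to calibrate against).
Demographic defaults are chosen to land in the empirically observed
ranges: N<sub>e</sub> = 125,000 and μ = 4.05×10⁻⁹/site/generation give
θ ≈ 0.002 (the observed π scale), T = 800,000 generations at one
generation per year gives D<sub>XY</sub> ≈ 0.008 and isolation
F<sub>ST</sub> ≈ 0.75. The `semi_permeable` scenario gives background
loci 4N<sub>e</sub>m = 1 and seals barrier loci; `no_flow_sweeps` seals
everything and applies a 0.25 N<sub>e</sub> multiplier to
barrier-category loci. Pileup simulation draws Poisson(coverage) reads
per site, split binomially between the two haplotypes, each read
miscalled to a uniform different base with the error probability
(defaults 30× and 0.2%).

What the generator does not emulate: alignment error and indel
polymorphism (gaps appear only if injected), within-species population
structure, linked selection beyond the local-N<sub>e</sub> sweep proxy,
recurrent mutation (outside the multi-hit fallback), and real read
artefacts (mapping bias, base-quality structure). Passing tests
therefore demonstrate correctness of the estimators and the pipeline's
logic under the model's assumptions, not robustness to those real-data
complications.

## Seeding and determinism

One master seed drives every run. A `numpy SeedSequence` is spawned per
locus in locus order (so any locus regenerates independently), and the
pipeline spawns separate child streams for phase assignment, pileup
simulation and permutation tests. Identical config + seed reproduces
every output file byte for byte; the manifest records the config
snapshot, input digests, child seeds and all machine-readable warnings.

## Problem sizes in the checks

The verification scripts use sizes chosen to make Monte-Carlo bands
tight while staying desk-scale: 1000 random alignments for the
statistic oracles, 500 for the trimmer, 1000 replicate datasets for the
permutation null calibration, 400–1500 coalescent replicates for the
expectation checks, and the full 48-locus / 96-individual design for
the scenario contrasts.
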