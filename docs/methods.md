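# Methods

This note records the statistical and modelling choices behind the
package: what each component assumes, the defaults and their units, what
the synthetic generator does and does not emulate, and where behavior is
known to be scale- or parameter-sensitive.

## Genotype data model and filters

Genotypes are biallelic SNP dosages in {0, 1, 2} with −1 for missing;
multiallelic and indel records are dropped on read (not split), and any
VCF genotype containing a missing allele — including half-calls like
`./1` — is treated as missing. Internal coordinates are 0-based
half-open; conversion to and from the VCF's 1-based positions happens
only at I/O. Minor-allele frequency is computed over non-missing alleles
pooled across the whole cohort (per-dataset, not per-group: the standard
behavior of VCF tooling, and the natural choice when group labels are
themselves an inference target). Missingness filters act on the fraction
of missing calls per site. Window grids tile each chromosome with the
last window allowed to be short; with step = size every base is covered
exactly once.

## Windowed statistics

Per-site nucleotide diversity uses the unbiased pairwise estimator
π = n/(n−1) · 2p(1−p) over the n non-missing chromosomes, which equals
the mean pairwise difference among chromosomes; d<sub>XY</sub> =
p₁(1−p₂) + p₂(1−p₁) equals the mean difference across groups. Window
F<sub>ST</sub> is Hudson's estimator as a **ratio of averages**:
1 − mean(H<sub>w</sub>)/mean(H<sub>b</sub>), H<sub>w</sub> the average
of the two groups' per-site π and H<sub>b</sub> the per-site
d<sub>XY</sub>, using only sites with at least two chromosomes in every
group (`n_sites` is reported per window). The Hudson form was chosen
over Weir–Cockerham for its robustness to small and unequal sample
sizes; outputs state the estimator. Negative estimates are reported
unclipped — note the estimator's finite-sample behavior: two samples
drawn from identical frequencies give E[F<sub>ST</sub>] ≈ −1/(n−1) per
site, and ≈0 only when both samples estimate a common population.

Observed heterozygosity of a sample set over a region is simply the
fraction of non-missing calls equal to dosage 1. This is the quantity
whose contrast (middle cluster ≈ 2× the outer clusters) diagnoses the
inversion; an absolute comparison against any particular published value
depends on the site-frequency spectrum retained by upstream filters.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors (composite
genotype LD) over pairwise-complete samples — appropriate for unphased
data and the default of common tooling. Decay curves bin all
within-region pairs by inter-site distance (1-based position
difference); bin width (default 1 kb) and maximum distance (default
100 kb) are reporting choices with no empirical anchor. For n unrelated
individuals the finite-sample null is E[r²] ≈ 1/n, which is the floor
the background curves approach.

## Inversion genotyping

PCA runs on the per-site mean-imputed, centered dosage matrix of the
target region after a 40% MAF cutoff (the cutoff concentrates the
signal on sites near fixation between arrangements). PC1 is clustered
by deterministic 1-D k-means (k = 3, centers initialized at the 1/6,
3/6, 5/6 quantiles, Lloyd iterations to convergence) so results carry no
RNG dependence. Because a principal component's sign is arbitrary, PC1
is oriented so the largest cluster sits leftmost, and clusters are
labeled AA/AB/BB left to right; the orientation is recorded. The
labeling is then audited: the middle cluster's observed heterozygosity
must exceed both outer clusters' — if not (e.g., no real inversion
signal in the region), the calls are returned with `het_check_passed =
False` rather than raising.

The association scan is a per-site linear trend test (slope t-test of
phenotype on dosage). It deliberately replaces the kinship-aware mixed
models used on real cohorts: the synthetic cohorts here carry no
relatedness structure, so the trend test achieves near-nominal type-I
error (verified on null cohorts); it must not be applied to structured
samples without correction. Significance uses a fixed p < α threshold
(default α = 1e−5), which is a per-test cutoff, not an FDR procedure.
The latitude trend is Kendall tau-b between arrangement dosage and
latitude with a two-sided permutation p (10,000 seeded permutations);
the additivity check reports genotype-group phenotype means with
bootstrap CIs and flags strict monotonicity.

## ABBA-BABA and topology weighting

D is computed from population allele frequencies,
D = Σ[(1−p₁)p₂p₃(1−p₄) − p₁(1−p₂)p₃(1−p₄)] / Σ[… + …],
with significance from a weighted delete-one block jackknife over
contiguous site blocks (default 100 sites — a synthetic-scale choice),
blocks weighted by site count, Z = D/SE and p = 2Φ(−|Z|). Calibration:
with ≥50 blocks the null Z has unit variance; with ~30 blocks the SE is
underestimated by ~10%, so block counts below 50 should be interpreted
cautiously (the implementation refuses fewer than 10).

Topology weighting enumerates all (2g−5)!! unrooted binary topologies
on g taxon groups (3 ≤ g ≤ 7) by edge insertion with canonical-form
deduplication. The weight of a topology for a window tree is the
fraction of one-tip-per-group subsamples whose induced tree matches it;
matching is by nontrivial-split sets, exact mode enumerates up to 10,000
combinations, Monte-Carlo mode samples with a seed (observed exact-vs-MC
discrepancy < 0.02 at 10,000 subsamples). Rooted sister relationships
are read as cherries in the unrooted topology, since the outgroup is
itself one of the groups.

## Synthetic cohorts

The generator plants the statistical structure of an inversion
polymorphism without simulating demography:

- background sites draw one allele frequency per site from
  Beta(0.8, 0.8) shared by all samples — a genome homogenized by gene
  flow, giving near-zero background F<sub>ST</sub> and a weak PC1;
- inversion sites carry two haplotype-pool frequencies differing by
  exactly *d* per site (default d = 0.8); each individual draws two
  independent haplotypes per its genotype, so recombination suppression
  is implicit (no within-pool linkage);
- modifier sites on a second chromosome differentiate the lesser
  ecotype (frequency difference 0.8 — an arbitrary default, since no
  quantitative effect size is available for these loci);
- phenotype = dosage·1.0 + 0.25·(modifier score) + N(0, 0.25²);
- latitude = 55° + 5°·dosage + N(0, 3²), clipped to [−90, 90].

Defaults are 72 samples (25 common / 33 hoary / 14 lesser) with exact
genotype counts 37 AA : 7 AB : 28 BB, 2000 background + 500 inversion
SNPs on a 1-Mb chromosome with the inversion at [400 kb, 600 kb), and
20 modifier SNPs. What passing tests on these cohorts do **not** show:
robustness to LD within haplotype pools, to kinship, to missingness
structure of real call sets, or to site-frequency spectra shaped by
variant-calling pipelines.

Window trees are built by expanding each leaf of a stated taxon-level
topology into a random binary clade of that group's tips; a `scatter`
parameter regrafts tips onto uniformly random edges to mimic incomplete
lineage sorting.

## Spatial forward models

Both models are individual-based, diploid, hermaphroditic and
non-overlapping. Each individual carries two haplotypes of a 100-kb
chromosome with a 50-kb central inversion ([25, 75] kb) whose B-dosage
g sets an additive phenotype φ = g/2, plus neutral loci (default 20,
mutation 1e−5 per locus per gamete, recombination 1e−6 per bp, with
crossovers rejected inside the inversion in heterozygotes). Fitness is
linear in the mismatch between φ and the position along the selection
gradient: w = max(0, 1 − s·|y − φ|). Model 1 additionally divides
fitness by (1 + c·neighbors within radius r<sub>c</sub>) and weights
mate choice by (1−a)^|Δg|; model 2 places two demes on separate unit
squares with the gradient continued across them (deme 0 optimum at low
phenotype, deme 1 at high) and migrates each offspring with probability
m, redrawing its position in the destination. Mothers are sampled in
proportion to fitness **within each deme** (N offspring per deme each
generation — soft regulation, per the population-size contract); each
mother picks a mate within `mate_search_radius` of her position.
Iterations stop at the generation where one arrangement fixes, since no
new inversion mutations arise and the outcome is decided; reported
counts and positions are from that generation.

Spatial kernel defaults — dispersal σ = 0.03, mate radius 0.5,
competition radius 0.05 with strength c = 1.0 (all in unit-square
units) — were fixed once after an exploration of the model's regime
structure, to place the three qualitative outcomes of interest
(drift loss, low-heterozygote balanced polymorphism, spatial
stratification) inside the default selection grids. That structure is
worth stating because it constrains what any parameterization of this
model family can show:

- Under weak assortment the polymorphism is protected whenever selection
  is strong enough, because with imperfect spatial sorting the
  intermediate phenotype φ = 0.5 has the smallest average mismatch — a
  marginal heterozygote advantage of order s/4. At desk scale (N = 200,
  2,000 generations) the drift-loss regime therefore lives at
  s ≲ 0.1, and the default model-1 grid is s ∈ {0.02, 0.05, 0.10} ×
  a ∈ {0.05, 0.5, 0.95}.
- Strong assortment stabilizes two spatially segregated arrangement
  clusters (each regulated by local competition) once s ≳ 0.1; stable
  cells then hold almost no heterozygotes (AB fraction < 1%) and
  genotype mean-y positions order AA < AB < BB. A sweep cell is called
  stable when at least half its iterations retain both haplotypes.
- Model 2 with per-deme soft regulation is a Levene-type system:
  divergent selection between demes protects the polymorphism even at
  high migration (m = 0.25), with well-mixed genotypes and no
  stratification, while very low migration (m = 5e−4) gives stability
  by near-fixation of opposite arrangements in the two demes. A
  high-migration *loss* regime exists only where drift dominates
  (s ≲ 0.05 at 200 total diploids), and it cannot coexist on one grid
  with low-migration stability at the same scale — a structural
  property of soft selection, not a tuning artifact. The default
  model-2 grid is s ∈ {0.05, 0.10, 0.15} × m ∈ {0.25, 0.01, 5e−4},
  run with 100 diploids per deme at desk scale.

Scaled test settings (N = 200 or 2×100, 2,000 generations, 20
iterations per cell, with the full scale of 1,000 diploids / 10,000
generations / 50 iterations as the config default) are the package's
desk-scale study conditions; thresholds sit near regime boundaries, so
individual grid cells at the boundary (e.g., strong assortment at
s = 0.10, ~55% stable) are seed-sensitive.

The genotype-ratio score compares a cell's mean stable counts with the
observed cohort ratio 37:7:28 as a signed difference of heterozygote
proportions (positive = excess simulated heterozygotes); balanced cells
of both models score ≈ −0.07 to −0.10 (fewer heterozygotes than
observed), consistent with strict assortment or isolation overshooting
the observed intermediate heterozygote count — relaxed mixing regimes
land nearer the observed ratio.

## Numerical and degenerate-input conventions

Sites with fewer than two chromosomes in a group are skipped (NaN) in
π; windows with no usable site hold NaN and n_sites = 0. Monomorphic
sites give undefined r² (NaN, excluded from bins) and p = 1 in the
association scan. k-means quantile initialization falls back to an
equispaced grid under ties and errors if fewer than k distinct values
exist. The jackknife reports p at the float floor with a warning when
all blocks are identical. Genotype-matrix equality is exact (ids,
variants, calls), which the VCF round-trip tests rely on.

## Known limitations

Synthetic cohorts have no within-pool LD, so LD inside the planted
inversion is flat in distance rather than decaying; only the
inside-vs-outside contrast is meaningful. The association surrogate is
invalid under kinship. The simulator's mating system (fitness-weighted
mothers with replacement, shared fathers within a radius) makes
effective population size smaller than census N, so drift-based
timescales are ~10–40% faster than 2N-based closed forms. Model
geometry, kernels, and grids are one defensible instantiation of the
verbal model description; alternative fitness forms can be swapped in
behind `simulate.fitness`.
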