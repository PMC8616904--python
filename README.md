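# supergene

A desk-scale toolkit for detecting, genotyping, and modelling
chromosomal-inversion supergenes in diploid genotype cohorts.

Polymorphic inversions suppress recombination between their two
arrangements (call them A and B), so a cohort segregating for one shows a
distinctive joint signature: a localized block of elevated F<sub>ST</sub>
and linkage disequilibrium, three clusters on PC1 of the genotype matrix
(AA, AB, BB), roughly doubled heterozygosity in the middle cluster, and —
when the arrangement is under spatially varying selection — clines in
arrangement frequency. This package implements that whole analysis chain
for population geneticists who want to test the machinery, teach it, or
prototype against realistic synthetic data before touching a real
call set:

- **`supergene.io`** — VCF 4.x input/output (biallelic SNPs, dosage
  coding, half-calls treated as missing), MAF and missingness filters,
  window grids (0-based half-open, BED export).
- **`supergene.synth`** — a generator of diploid cohorts with a planted
  inversion polymorphism (homogenized background, two haplotype pools at
  per-site frequency difference *d*, modifier loci, additive phenotype,
  latitudinal cline) plus ground truth, and a generator of newick window
  trees with a controlled taxon-topology mix.
- **`supergene.scan`** — windowed nucleotide diversity
  π = n/(n−1)·2p(1−p), between-group d<sub>XY</sub> = p₁(1−p₂)+p₂(1−p₁),
  and Hudson F<sub>ST</sub> = 1 − mean(H<sub>w</sub>)/mean(H<sub>b</sub>)
  (ratio of averages; negative estimates reported, not clipped).
- **`supergene.ld`** — composite genotype r² (squared Pearson correlation
  of dosages) and distance-binned LD-decay curves per region.
- **`supergene.genotyper`** — inversion genotyping by PCA (40% MAF
  cutoff) + deterministic 1-D k-means on PC1, heterozygosity-checked
  AA/AB/BB labels, a per-site trend-test association scan, a Kendall
  tau-b latitude trend with permutation p, and an additivity check of
  phenotype on dosage.
- **`supergene.introgression`** — the ABBA-BABA D statistic from
  population allele frequencies with weighted block-jackknife Z and p,
  and topology weighting: exact or Monte-Carlo subsampling of one tip
  per group against the complete catalog of (2g−5)!! unrooted topologies.
- **`supergene.simulate`** — two from-scratch spatial forward-time models
  of inversion maintenance: 1000 diploids with a 100-kb chromosome and
  50-kb inversion, additive phenotype g/2 matched against a selection
  gradient along y, with assortative mating and local competition
  (model 1) or two demes with migration (model 2); sweeps over selection
  × assortment/migration report stability, genotype ratios against the
  observed 37:7:28, and spatial stratification.

## Worked example

```python
from supergene.genotyper import label_genotypes, latitude_trend
from supergene.io import make_windows
from supergene.scan import scan
from supergene.synth import CohortConfig, generate_cohort

cfg = CohortConfig(seed=0)            # 72 samples, genotype ratio 37:7:28, d = 0.8
gm, meta, truth = generate_cohort(cfg)
calls = label_genotypes(gm, ("chr1", *cfg.inversion_interval), maf_cutoff=0.40)
print(calls.summary())
```

```
Inversion genotype calls
  PC1 variance explained: 0.7678 (orientation kept)
  cluster sizes: AA=37, AB=7, BB=28
  observed heterozygosity: AA=0.171, AB=0.814, BB=0.177
  heterozygosity check (AB > AA and AB > BB): passed
```

PC1 of the inversion region separates the three arrangement genotypes;
the middle cluster's heterozygosity (0.814) is far above the outer
clusters' (≈0.17), which is the hallmark of carrying one copy of each
non-recombining haplotype. Continuing,

```python
groups = {g: [s for s, t in zip(gm.sample_ids, calls.genotype) if t == g]
          for g in ("AA", "BB")}
tab = scan(gm, groups, make_windows({"chr1": cfg.chrom_length}, 25_000))
tau, p = latitude_trend(meta, seed=0)
```

prints (via the comparison shown in `scripts/acceptance.py`):

```
mean Hudson FST(AA,BB): 0.787 inside vs -0.0002 outside the inversion
latitude trend: Kendall tau = 0.63, permutation p = 1.0e-04
```

i.e. the arrangement homozygotes are strongly differentiated only inside
the planted inversion, and B-arrangement dosage increases with latitude.

The same operations are available from the shell:

```bash
supergene generate-cohort --out-dir cohort --seed 0
supergene genotype-inversion --vcf cohort/cohort.vcf \
    --region chr1:400000-600000 --maf 0.40 --out-prefix calls
supergene scan --vcf cohort/cohort.vcf --groups groups.tsv --window-size 25000
supergene simulate --config sim.cfg --out simout
```

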