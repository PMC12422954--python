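# bulbopan

Analysis toolkit for haplotype-resolved genomics of diploid and
autotetraploid plants, built around the computational steps used to
assemble and interpret haplotype-resolved pangenomes of bulbous barley
(*Hordeum bulbosum*) and its crop relative *H. vulgare*:

- **Hi-C haplotype phasing** (`bulbopan.hic`) — assign assembly contigs to
  haplotypes from chromatin-contact signal: border-restricted contact
  matrices, removal of Rabl-configuration positional effects by a linear
  model, chromosome-wise PCA with a PC1 split for diploids, k-means on
  PC1/PC2 with recursive pairwise-PCA refinement for autotetraploids,
  nearest-centre placement of multi-copy (IBD) contigs, and a Hi-C majority
  rule for leftovers.
- **Gamete-based phase validation** (`bulbopan.pollen`) — from single-pollen
  genotype calls: 200-kb binning, adjacent-marker recombination fractions,
  flagging of marker pairs with r > 50% (mis-phasing signatures), majority-
  haplotype support per marker and the genome-wide phasing error rate.
- **Single-copy pangenome** (`bulbopan.pangenome`) — k-mer occurrence
  masking (31-mers once-only for FISH probe design, ploidy-scaled cutoffs
  for the pangenome), greedy 95%-identity clustering, growth curves over
  ordered genome additions, and core/shell/cloud classification including
  haplotype-specific core sequence.
- **Introgression-line analysis** (`bulbopan.introgression`) — normalized
  1-Mb read depth (count / total × 10⁶), donor-segment calling at the
  >200 threshold, donor matching by identity-by-state distance and mosaic
  breakpoint detection.
- **Ancestral haplotype groups and dating** (`bulbopan.ahg`) — pairwise
  variant distances in 5-Mb windows, kernel-density peaks of the distance
  distribution, CNV masking (0.6/1.4 normalized coverage), semi-supervised
  founder-indexed AHG assignment at a distance threshold, IBD block
  detection, and divergence dating via T/g = D/2μ.
- **Local genome-size-change rates** (`bulbopan.sizerates`) — strict joint
  98th/95th percentile filtering of synteny anchors, a robust monotone
  local-linear size map between two genomes, per-1-Mb local rates and the
  partition into locally expanded regions.
- **Synthetic data with known truth** (`bulbopan.simulate`) — generators
  for every input above: multi-haplotype populations with staged
  divergence, contig sets with optional IBD tracts, Rabl-decaying Hi-C
  contact counts, gamete panels with Poisson crossovers and injected phase
  flips, and introgression-line depth tracks.

The real study data (ENA BioProjects PRJEB65276 / PRJEB65918) are not
required: every stage is exercised end-to-end on simulated inputs whose
ground truth is returned alongside the data.

## The model at the core

Two haplotypes that diverged T years ago accumulate pairwise differences at
density D = 2μT/g per site (μ the per-site per-generation mutation rate,
g the generation time in years). Windowed pairwise distances in a
structured population are therefore multimodal: recently coancestral pairs
cluster at a low density, deeply diverged pairs at a high one. With the
rates used throughout (μ = 6.5 × 10⁻⁹, g = 2 yr), the two modes at 9,500
and 14,500 variants per Mb date to ≈1.46 and ≈2.23 Ma, and a threshold
between them (11,000/Mb) partitions haplotypes into ancestral haplotype
groups window by window.

## Worked example

```python
from bulbopan import simulate as sim, hic, ahg

# phase a synthetic diploid assembly from Hi-C links
cs = sim.make_assembly_sim(seed=1, ploidy=2, n_contigs=30,
                           chrom_lengths={"chr1": 100_000_000, "chr2": 100_000_000})
mat = sim.make_hic(cs, intra_boost=5.0, rabl_scale=50e6, mean_links=100.0, seed=2)
norm, diag = hic.rabl_normalize(mat, cs)
asn = hic.rescue_unphased(hic.phase_diploid(norm, cs), mat, cs)
print(f"contigs: {len(cs.df)}  Rabl fit R2: {diag['r2']:.3f}")
print(f"phased: {len(asn.assigned)}  accuracy vs truth: {hic.assignment_accuracy(asn, cs):.3f}")

# recover divergence structure of a 12-haplotype population
split = 14_500 / 1e6 / (2 * sim.DEFAULT_MU) * sim.DEFAULT_GENERATION_TIME
vm, truth = sim.make_population(seed=3, groups={"A": 4, "B": 4, "C": 4},
                                split_times=split, theta_within=9_500 / 1e6,
                                seq_length=100_000_000)
tensor = ahg.window_distances(vm)
peaks = ahg.estimate_peaks(tensor)
print(f"distance peaks (per Mb): {[round(p) for p in peaks.peaks]}")
print(f"suggested threshold: {peaks.threshold:.0f} per Mb")
print(f"high peak dates to {ahg.divergence_time(peaks.peaks[-1], per_mb=True) / 1e6:.2f} Ma")
```

prints

```
contigs: 120  Rabl fit R2: 0.232
phased: 120  accuracy vs truth: 1.000
distance peaks (per Mb): [9502, 14490]
suggested threshold: 11934 per Mb
high peak dates to 2.23 Ma
```

All 120 contigs of the two-chromosome diploid panel are assigned their true
haplotype (accuracy 1.000); the kernel-density estimate of the pooled
window distances recovers the two simulated divergence modes to within a
fraction of a percent, the data-driven threshold falls between them, and
the deeper mode dates to 2.23 Ma under T/g = D/2μ.

A thin CLI mirrors the library (`bulbopan simulate …`, `bulbopan phase`,
`bulbopan pollen`, `bulbopan ils`, `bulbopan ahg`, `bulbopan sizerates`);
all files are plain TSV/BED/VCF/JSON.

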