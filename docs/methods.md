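# Methods

This note documents the models behind each module, the parameters that
matter, the choices made where the design was open, and what the synthetic
data do and do not establish about behaviour on real data.

## Synthetic data (`bulbopan.simulate`)

**Population model.** Haplotypes are simulated under an infinite-sites
model on a two-level star phylogeny: haplotypes within a group coalesce
recently (pairwise per-site divergence `theta_within`), groups split `T`
years ago, giving expected between-group divergence 2μT/g per site.
Mutation counts per branch are Poisson; positions are uniform and globally
unique (collisions are re-drawn, since two hits at one site would cancel).
A per-pair split-time map is fitted to the star by least squares because an
arbitrary symmetric matrix need not be tree-additive; callers get an error
if the requested times imply negative branches. There is no recombination
and no selection: haplotypes are exchangeable within groups, which is the
regime the windowed-distance methods assume.

**Defaults.** μ = 6.5 × 10⁻⁹ per site per generation and g = 2 years are
the rates used for all dating; they make a distance peak of 14,500
variants/Mb correspond to 2.23 Ma and 9,500/Mb to 1.46 Ma.

**Hi-C signal model.** Expected links between same-chromosome contigs i, j
are `mean_links · exp(−|pos_i − pos_j| / rabl_scale)`, multiplied by
`intra_boost` when the contigs share a haplotype (or an IBD copy), then
Poisson-sampled. The exponential decay stands in for the real (unspecified)
contact decay: its role is solely to create the positional confounder the
normalization step must remove. Defaults — `intra_boost` 5, `rabl_scale`
50 Mb, `mean_links` 100 — put the haplotype signal well above Poisson noise
while keeping the positional trend dominant in raw counts (the Rabl fit
explains ~23% of log-count variance on default panels).

**Gametes.** Each gamete is an alternating two-haplotype mosaic with
Poisson(λ) crossovers placed uniformly along the chromosome (λ = 2 by
default; pericentric crossover suppression is not modelled). Assembly
mis-phasing is emulated by label-swapping all gametes inside `flip_blocks`;
per-call error and missingness are independent Bernoulli. Panels default to
96 gametes, matching a typical sorted-pollen sequencing batch.

**IL depth tracks.** Donor-genome windows carry Poisson counts whose
normalized expectation is 1,000 inside injected segments and 10 outside
(cross-mapping background); both are far from the 200 calling threshold, so
detection errors come only from the Poisson tails. Segments are 1-Mb
aligned and non-overlapping by construction.

All coordinates everywhere are 0-based half-open.

## Hi-C phasing (`bulbopan.hic`)

**Border matrix.** Only links with both ends within 2 Mb of a contig end
are counted; contigs shorter than 4 Mb contribute over their full length.
Border restriction reflects that inter-contig proximity signal concentrates
at contig ends.

**Rabl normalization.** `log1p(count)` for same-chromosome contig pairs is
regressed on (a) inter-contig distance and (b) the pair's mean distance to
the chromosome ends, by ordinary least squares; the residual matrix feeds
the clustering. Predictor (b) captures the telomere/centromere polarization
of Rabl-configured nuclei; the log1p transform linearizes the exponential
decay while tolerating zeros. The exact predictors of the published model
are not public; this set removes the distance trend to |r| < 0.05 residual
correlation on decay-only matrices.

**Diploid.** Chromosome-wise PCA of residual link profiles (rows and
features are the single-copy contigs ≥ 1 Mb); the PC1 sign splits the two
haplotypes. Fewer than four eligible contigs is refused as
under-determined. Copy-number-2 contigs in a diploid can only be shared by
both haplotypes and are assigned directly.

**Autotetraploid.** k-means (k = ploidy, 50 restarts, fixed seed) on
PC1/PC2 of the same profiles. Clusters whose cumulative length is nearest
to m ≥ 2 haplotype-equivalents (nearest-integer rule on cluster length ÷
one haplotype's expected share) are re-split by a sub-PCA. Every pair of
clusters must then separate in a pairwise PCA restricted to the pair's own
contigs; "complete separation" is operationalized as silhouette > 0.5 of
the split on PC1. The pairwise stage is run as an unconditional refinement:
each pair is re-split by 2-means on PC1 of its sub-matrix and the re-split
is adopted whenever it increases the pairwise silhouette. This matters in
practice: two haplotypes sharing a long IBD tract can pass a fixed 0.5
cutoff while ~10% of their contigs sit on the wrong side of the global
2-PC k-means boundary, and only the pairwise re-projection separates them.
Refinement iterates to a fixed point (bounded by `max_depth` = 6); pairs
still below the cutoff are reported as inseparable rather than looped on.
Multi-copy contigs are assigned the `copy_number` nearest haplotype centres
in the global PC space. Haplotype labels are arbitrary per chromosome
(ordered by leftmost member position for determinism); accuracies are
therefore computed after optimal (Hungarian) label matching.

**Rescue.** Unphased contigs take the haplotype(s) with the largest summed
raw link count to assigned contigs on their chromosome; ties and zero-link
contigs stay unassigned with explicit flags.

## Gamete validation (`bulbopan.pollen`)

Site calls are aggregated into 200-kb bins by majority (ties and empty
bins are missing). For each adjacent marker pair, r = discordant ÷
informative gametes, using only gametes non-missing at both markers; pairs
with < 5 informative gametes are flagged low-support. Flagged boundaries
(r > 0.5) are paired sequentially into candidate mis-phased intervals — a
flip block produces flagged pairs at both borders — with an unpaired
trailing boundary reported as a point switch. Each gamete's majority
haplotype per chromosome is its modal call (50/50 gametes are excluded);
the phasing error rate is the fraction of markers where fewer than half of
the informative gametes support their majority haplotype, reported with a
Clopper–Pearson 95% CI. With per-call error e, baseline pair discordance is
≈ 2e(1−e) plus true recombination — at the default 1% error and λ = 2
crossovers per chromosome this stays far below the 0.5 switch threshold.
Genetic-map construction itself is out of scope; co-linearity is summarized
instead by the rank correlation between marker order and cumulative map
distance Σ min(r, 0.5).

## Single-copy pangenome (`bulbopan.pangenome`)

k-mers are canonical (strand-collapsed; the strand convention is a
documented choice) and N-containing k-mers always mask. A base is single
copy iff every k-mer covering it occurs no more often than allowed: once
for probe design (k = 31 for diploids, 34 for tetraploids to raise probe
density), or up to ploidy within a genotype's combined haplotypes for the
pangenome — a k-mer seen ≥ 3 times in a diploid (≥ 5 in a tetraploid) has
more copies than haplotypes and disqualifies its region. The occurrence
cutoff is exposed (`max_occurrences`) because the retain/exclude reading of
the rule is ambiguous in prose; the exclusion reading is the default.
Probe candidates are unmasked runs strictly longer than 45 bp.

Clustering is greedy: fragments (≥ 100 bp; shorter ones are dropped to
avoid spurious clusters) sorted by length descending; each joins the first
cluster whose representative matches at ≥ 95% identity, else founds a new
cluster. Identity is computed by semi-global (infix) alignment of the
shorter sequence within the representative on both strands (edlib edit
distance ÷ query length), so the shorter sequence is always fully covered —
this realizes the ≥ 80% coverage floor trivially. Greedy order-dependence
is checked against a brute-force single-linkage oracle at desk scale; at
~2% pairwise divergence the two agree, near the 95% threshold they may not.
Pangenome size after m genomes is the sum of representative (largest-
member) lengths of clusters contributed by the first m genomes; curves are
summarized over 100 random orderings (or exhaustive enumeration on small
panels, where the sampled mean is exact). Core = present in all units,
cloud = exactly one, shell = otherwise, computed at haplotype and genotype
level; a genotype-level core cluster absent from one haploid of a genotype
is flagged haplotype-specific core for that genotype.

## Introgression lines (`bulbopan.introgression`)

Normalized depth = window count ÷ total aligned reads × 10⁶; the input is
a count (the formula's numerator), not an averaged per-base depth. Donor
windows strictly above 200 are introgressed; runs are merged across at most
one sub-threshold interior window (`gap_windows` = 1, a smoothing choice).
Hybrid-reference bookkeeping — a recipient/donor label per window —
replaces actual alignment to a concatenated genome, which is out of scope.
IBS distance to each donor haplotype is the mismatch fraction over
pairwise-complete sites in the segment; the assignment is the argmin, with
ties flagged ambiguous and segments with < 10 informative sites flagged
undetermined. A per-1-Mb argmin series supports mosaic detection:
assignment runs shorter than 3 windows (`persistence`) are treated as noise
and merged into their predecessor; boundaries between surviving runs are
the reported breakpoints.

## AHGs and dating (`bulbopan.ahg`)

Pairwise distances are difference counts over pairwise-complete sites in
5-Mb windows, scaled to per-Mb; windows with < 50 complete sites for a pair
are masked. Peaks of the pooled distribution come from a Gaussian KDE on a
512-point grid; the suggested threshold is the density minimum between the
two largest peaks, and the conventional fixed threshold 11,000/Mb may be
passed instead. Windows with normalized coverage < 0.6 or > 1.4 (strict)
are CNV-masked before assignment. Assignment is founder-indexed and
semi-supervised: haplotypes are processed by priority class then input
order; each joins the nearest existing founder below the threshold or
founds a new AHG, so labels are stable references to founder haplotypes and
reversing the priority renames labels without changing the partition. The
published tool's Bayesian smoothing is replaced by a documented mode filter
over 3 windows (removing single-window flips); its variant-density
parameter (2,500 SNPs/Mb) is accepted for interface compatibility but
unused. Divergence time is T = g·D/(2μ); distances given per Mb are
converted to per site. Two different μ values circulate for this system
(6.5 × 10⁻⁹ and 0.7 × 10⁻⁸); only the former is consistent with dating
14,500/Mb to 2.23 Ma, so it is the default and both are accepted via the
`mu` argument. IBD blocks are maximal window runs below 500/Mb, far under
the within-group mode.

## Size rates (`bulbopan.sizerates`)

Anchors are filtered by strict joint percentiles (quality > P98 AND length
> P95, computed over the whole input; the quality field is configurable
since score-vs-mapQ is not specified upstream). The filter is intentionally
harsh: with independent quality/length ranks it keeps ~0.1% of anchors,
with correlated ranks ~2%. The A→B size map replaces the published GAM
with robust local linear regression: tricube kernel, Tukey-bisquare IRLS
(4 iterations) so anchors displaced by inversions or spurious alignments
are nulled rather than down-weighted, evaluated at 1-Mb grid boundaries,
then projected to a monotone map by isotonic regression; the local rate is
the finite difference across each window, so the summed rate telescopes to
the fitted B-span. The kernel support radius (`bandwidth`) is 2 Mb: the
radius bounds the resolution of the fitted map, and a wider kernel —
including the 5-Mb radius considered first — provably blurs a sharp rate
change over its own width, biasing rates several percent at 2–3 Mb from a
breakpoint regardless of the robust loss (the bias is smooth leverage, not
outlier contamination). Where a 2-Mb window holds too few anchors to pin
the slope (chromosome ends, alignment deserts) the radius widens adaptively
until the kernel's effective sample reaches 40 anchors. Rates below/above
the neutral band [0.95, 1.05] (a reporting convenience) are merged into
A-expanded / B-expanded intervals.

## Problem sizes and what the tests show

Test and acceptance runs use desk-scale conditions chosen to keep every
statistic's sampling error well inside its tolerance: diploid panels of
2 × 100 Mb chromosomes with 30 contigs per haplotype per chromosome over
10 seeds; one tetraploid 100-Mb panel with a 20-Mb IBD tract; 96 gametes ×
2,000 bins; 20 ILs with 5–50 Mb segments against a 4-haplotype, 100-Mb
donor panel; 12 haplotypes × 100 Mb for AHG recovery; 10,000 anchors on a
500-Mb chromosome (one per 50 kb, the order of density a strict percentile
filter leaves from chromosome-scale alignments) with 50-kb positional
noise.

Passing these suites shows the algorithms recover truth under their own
generative assumptions — exchangeable haplotypes without recombination,
exponential contact decay, uniform crossovers, Poisson depth with a clean
recipient/donor split. Real data violate each in ways the generators do
not model: linkage and introgression structure within groups, distance-
dependent contact decay that is not exponential, crossover interference
and pericentric suppression, mappability- and GC-driven depth artefacts,
collapsed repeats mimicking CNV, and reference bias in variant calls.
Genome-scale figures from the original study (total SNP counts, core
fractions, cumulative introgressed length) depend on the real sequencing
data and are deliberately not targets of the synthetic suites.

## Known limitations

- The population simulator has no recombination, so AHG boundaries in
  synthetic data are window-exact; real block mosaics are harder.
- Greedy identity clustering is order-dependent near the identity
  threshold; equivalence to single linkage is only asserted at ~2%
  divergence.
- The tetraploid silhouette cutoff (0.5) and the pairwise-refinement
  adoption rule are heuristics; pathological contact matrices can still
  yield inseparable pairs, which are reported, not resolved.
- `fit_size_map` assumes co-linear chromosomes apart from local
  disturbances; a whole-arm translocation breaks the monotone-map premise
  and will be flattened by the isotonic projection rather than flagged.
- The Rabl model uses two predictors; residual positional structure beyond
  them (e.g. compartment signal) would leak into the clustering.
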