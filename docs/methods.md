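# Methods

This note records the statistical and computational choices in `ecepi`,
the defaults, and the assumptions behind the synthetic-data generator.

## Coordinate conventions and interval algebra

All intervals are 0-based, half-open (`[start, end)`, BED convention) and
strand-free. The algebra is implemented directly on per-chromosome sorted
`int64` arrays rather than through an external interval library, because
the boundary semantics are the contract of the whole pipeline and are
pinned by tests against independent per-base boolean-array oracles:

- `normalize` — sort and union; adjacent intervals (`end == next.start`)
  fuse.
- `merge_within(s, gap)` — transitively fuses intervals whose gap is
  ≤ `gap` bases (so `merge_within(s, 0) == normalize(s)`); equivalent to
  dilation by `gap/2`, union, erosion.
- `intersect_all` — N-way base-level intersection (pointwise AND).
- `subtract` — pointwise AND-NOT.
- `overlaps_by(a, b, k)` — shared bases ≥ k; two intervals that merely
  touch share 0 bases.
- `nearest_distance(site, points)` — 0 if a point lies in `[start, end)`,
  otherwise the distance to the nearer edge base; `None` when the site's
  chromosome carries no points.

## Site classification and reference assembly

Per sample, an **active promoter** is an H3K4me3 peak overlapping H3K27ac
by ≥ 1 bp and keeps the H3K4me3 extent; an **enhancer** is an H3K27ac peak
with no H3K4me3 overlap; H3K4me3-only peaks are dropped as inactive.
Promoter and enhancer base sets are therefore disjoint by construction.

A cell-type reference keeps only the bases present in **every** donor
(`intersect_all`), then fuses fragments within 100 bp — a consensus rule
that trades sensitivity for reproducibility across donors. Sex
chromosomes are excluded to avoid donor-sex artefacts. Cell-type
references are merged (same 100-bp rule) into one catalogue; a cell type
is a member of a merged site if its own reference overlaps it by ≥ 1 bp.
The sharing histogram reports, per class, the fraction of sites present
in exactly *n* of the *T* cell types.

**Specificity filter:** a site is removed whole if it overlaps (≥ 1 bp)
any same-mark peak — promoters against H3K4me3, enhancers against
H3K27ac — from any non-exempted member of an external exclusion panel.
Exemptions exist so that panel members of the same lineage (e.g. an
endothelial line like `E122`) do not erase genuinely lineage-shared
biology. An empty panel is allowed but warned about.

**Distal annotation:** an enhancer site is distal when its edge-based
distance to the nearest TSS is strictly greater than 10 kb; sites on
chromosomes without any TSS get a missing flag rather than a guess.

## Loop annotation

Anchors are labelled against the catalogue with promoter precedence
(an anchor spanning both classes is P). The unordered label pair gives
the category: P–P, E–P, E–E, or *other* (any `none`). E–P loops carry
(a) a distal flag — true if any enhancer-side site is distal; never set
for inter-chromosomal pairs — and (b) target genes: TSSs lying inside the
promoter-side site. Summaries report counts and percentages per category
for all loops and for the FDR < 0.05 stratum, plus distal E–P loops as a
percentage of E–P loops; percentages are reported unrounded and rounded
to one decimal.

## GWAS SNP enrichment

Trait matching is a case-insensitive substring test (defaults: *heart*,
*coronary*, *cardiac*), de-duplicated by (chromosome, position) so a SNP
listed under several traits counts once. Counts use a 100-kb window on
the site midpoint, `[mid − w/2, mid + w/2)`, clipped at chromosome ends;
100 kb is chosen to absorb linkage disequilibrium around the lead SNP.

The null distribution is built **per site**: the site is re-placed
uniformly at random on its own chromosome (width preserved, centromeric
intervals avoided by rejection sampling) `n_perm = 1000` times and the
window count recomputed. Enrichment is the permutation Z-score
`(observed − null mean)/null sd`, called at Z > 5 — deliberately
stringent because the per-site nulls are discrete and heavy-tailed at low
SNP density. A site whose null count never varies has an undefined Z and
is never called.

## Mark-to-expression regression

For gene *g* and mark *m*, the feature is
`x_m = log(1 + peak-covered bases of m in [TSS − 2 kb, TSS + 2 kb))` —
a depth-free quantity computable from peak calls alone (per-base depth
can be supplied instead, in which case depth is summed over peak bases).
The model

    log(TPM + 1) = a + b1·x1(H3K4me3) + b2·x2(H3K27ac) + ε

is fitted by OLS (numpy least squares; three parameters need no heavier
machinery) over protein-coding autosomal genes, pooling all matched
ChIP/RNA samples. A rank-deficient design (collinear or constant
features) is an error, not a silent pseudo-inverse. Model quality and
cell-type specificity are read off the matrix of Pearson correlations
between predictions from each ChIP sample and observations from each RNA
sample: matched pairs should dominate their row/column.

## Differential analysis

Intensity matrices (sites × samples, non-negative) are quantile
normalized: each column's values are replaced by the across-column mean
of sorted values at their rank, ties receiving the mean of the targets
their rank range spans. This assumes most sites behave alike, so
distributional differences between samples are technical.

Rows are tested on log2(x + 1) with a vectorized one-way fixed-effects
ANOVA across cell-type groups, F = [SS_between/(g−1)] / [SS_within/(n−g)];
a normal-theory test on the log scale is a reasonable desk-scale
replacement for count-model (negative-binomial GLM) machinery and keeps
the calibration testable (null p-values are verified uniform). Zero
total variance gives p = 1; perfect separation gives p = 0. P-values are
BH-adjusted (statsmodels) and called at FDR < 10⁻⁵ — stringent because
with 27 samples across 9 groups even modest shifts reach tiny p-values.

Significant rows are summarized as per-group means of logged values,
row-Z-scored (sample sd, ddof = 1; constant rows become zeros and are
flagged), and partitioned with k-means (scikit-learn, Lloyd, k-means++
seeding, 10 restarts, k = 6). Labels are renumbered by descending
cluster size for stable output. Note quantile normalization compresses
shifts confined to few groups (rank targets average shifted and
unshifted columns), so sensitivity at FDR < 10⁻⁵ is deliberately
conservative.

## Synthetic data generator

The generator plants a known architecture and emits every pipeline input:

- **Genome**: 5 autosomes × 10 Mb, a central centromeric interval (4 % of
  the chromosome), site slots every 35 kb outside 105-kb end margins.
  Slots are assigned round-robin **across** chromosomes and alternate
  gene/enhancer use; the alternation guarantees gene/enhancer
  interleaving only for an odd chromosome count (the default, 5).
- **Sites**: shared promoters/enhancers present in all 9 cell types,
  type-specific sites present in exactly one, a proximal-enhancer subset
  placed 2.5 kb from a TSS (inside the 10-kb distal threshold), and a
  panel-ubiquitous subset that the specificity filter must remove.
  Default truth catalogue: 238 sites (58 promoters, 180 enhancers).
- **Peaks**: each member site emits a 1-kb peak per donor with Gaussian
  edge jitter (sd 20 bp, well under the 100-bp merge gap, so recovery is
  exact) and optional Bernoulli dropout. Promoter sites emit both marks;
  enhancer sites H3K27ac only. Panel members peak only at ubiquitous
  sites, except the exempted member, which peaks everywhere.
- **SNPs**: Poisson background (40 SNPs/Mb, ≈ 2000 total) with traits
  drawn from matching and decoy vocabularies; five designated
  lineage-private distal enhancers get 20× local deposits of matching
  SNPs confined to ±10 kb of the site, so neighbouring sites' windows
  stay clean. Hotspot sites are spread at most one per chromosome —
  mirroring the genome-wide dispersion of real trait loci — because the
  within-chromosome permutation null degrades when one chromosome hosts
  several hotspots (shuffles land in other hotspots and inflate the null
  sd). The 5 × 10 Mb genome keeps the 100-kb window ≈ 1 % of a
  chromosome for the same reason.
- **Loops**: 500 anchor pairs drawn to category proportions
  (35/45/10/10 %); both anchors of a loop lie on one chromosome, as
  ChIA-PET ligation products are intra-chromosomal contacts. *Other*
  loops use guaranteed site-free pockets between slots. A configurable
  fraction (30 %) receives FDR < 0.05.
- **Matrices**: log-normal site intensities with planted 4-fold shifts in
  a random subset of groups for 5 % of sites; expression is generated
  **through the package's own feature definition** — TPM =
  exp(a + b1·x1 + b2·x2 + ε) − 1 with (a, b1, b2) = (1.0, 0.8, 0.3) —
  so with ε = 0 the regression recovers the coefficients to machine
  precision.

## Pipeline and provenance

Stages (`simulate → classify → reference → specific → distal → loops /
gwas / regress / diff → cluster`) read and write flat files (BED, BEDPE,
TSV, JSON) in one working directory. Each stage records a provenance
JSON with its parameter echo and MD5 checksums of inputs; a stage is
skipped when parameters, inputs and outputs are all unchanged. All
randomness (generator, permutations, k-means restarts) flows from
explicit integer seeds.

## Limitations

- Peak calls are consumed as given; no read-level processing or peak
  calling is performed.
- The ANOVA-on-logs differential test ignores count overdispersion
  structure that a negative-binomial GLM would model.
- The permutation null preserves site width and chromosome but not local
  covariates (GC, gene density); at desk scale this is the intended
  behaviour of a uniform within-chromosome shuffle.
- The generator emits sharp, rectangular peaks and Gaussian jitter; it
  does not model broad domains, copy-number variation, or mappability.
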