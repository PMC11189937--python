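# Methods

## Problem

Patients with del(5q) myelodysplastic syndrome carry a clonal interstitial
deletion on the long arm of chromosome 5 in a mosaic fraction of their
hematopoietic cells. Linking each single cell's transcriptome to its genotype
requires calling the deletion from scRNA-seq alone, which is hard: UMI counts
are sparse and noisy, and a hemizygous loss changes dosage by only ~2x. The
package genotypes each CD34+ cell with two complementary evidence channels and
accepts a call only when both agree:

* **Expression channel** — genes lose ~50% dosage inside the deleted region,
  visible as a depressed average expression across genomic bins;
* **Allele channel** — heterozygous SNPs inside a hemizygous region lose one
  haplotype, so the B-allele frequency (BAF) collapses toward 0 or 1.

A cell is `del5q` only if both channels call the region deleted, `non_del5q`
only if neither channel sees any alteration, and `ambiguous` otherwise
(channel disagreement, an amplified arm call, or insufficient SNP coverage).
Ambiguous cells stay in the outputs but are excluded from del-vs-non-del
contrasts — the two class definitions (both channels deleted; neither channel
altered) leave disagreeing cells in neither class, and silently forcing them into `non_del5q` would bias every
downstream fraction and contrast.

## Synthetic cohorts

Real cohorts of this design are controlled-access; the bundled simulator
generates cohorts with the statistical structure the genotyper assumes, plus
ground-truth labels, so every claim the tests make is checked against known
truth.

**Counts.** For cell *c*, gene *g*: counts ~ NB(mu, phi) with
`mu = s_c * m_{g,t(c)} * d_{cg}` and `Var = mu + phi*mu^2` (Gamma-Poisson
sampling). Library-size factors `s_c ~ LogNormal(0, 0.35)`; baseline gene
means `Gamma(shape=1, scale=2)` shared across cell types, with each of the
(default 10) hematopoietic progenitor types up-regulating a random 8% of
genes 3-fold; a single dispersion `phi = 0.3` is shared across genes (a
per-gene option exists in the DE study). Dosage `d = 0.5` for target-region
genes in deleted cells, 1 otherwise. The six detectable commonly-deleted-
region markers (CD74, RPS14, BTF3, COX7C, HINT1, RPS23) get a 10x elevated
baseline so they are reliably detected despite sparsity, mirroring the fact
that only a handful of region genes are well detected in real data.

**Genome.** A 40 Mb target region on chr5q (proximal edge 71 Mb) holds 300
genes by default; the remaining 1,700 genes cover chr1, chr5p and the 5q
flanks. 150 het SNPs tile the region; 150 flank SNPs sit on chr5 outside it.
Coordinates are 0-based half-open in memory, 1-based for SNP positions in
files (VCF convention).

**Alleles.** Per (cell, SNP), total reads ~ Poisson(6); diploid SNPs draw
alt ~ Binomial(total, 0.5). In deleted cells at in-region SNPs one haplotype
is retained — drawn once per SNP per *sample*, because the deletion is one
clone per patient — and the lost allele appears per read with probability
`error_rate = 0.02`. The per-SNP coverage mean of 6 is a deliberate plumbing
choice, not an estimate of any particular platform: with ~1 read per SNP,
|BAF − 0.5| is 0.5 for *every* covered SNP, diploid or not, and no per-cell
BAF statistic can discriminate. Multi-read SNP coverage is what makes
per-cell allelic evidence meaningful; cohorts with thinner coverage should
expect most cells to become `uninformative`/`ambiguous` rather than
mis-called.

**Study conditions.** Defaults are the conditions the genotyper is designed
for: four patient samples of 2,000 cells whose clone fractions span the
clinically observed karyotype range (0.35, 0.50, 0.70, 0.90), plus two
healthy reference samples of 1,500 cells. The number of deleted cells per
sample is exactly `round(cells * fraction)`. An optional per-cell-type bias
weight vector concentrates deleted cells in chosen lineages, giving the
lineage-enrichment statistics something real to find.

**What the simulator does not model:** doublets, ambient RNA, batch effects,
subclonal hierarchies, realistic transcriptome-wide mean-variance trends, or
cell-type-specific dosage response. Passing tests therefore demonstrate that
the inference machinery is correct and calibrated under its stated
assumptions — not that it would achieve the same operating point on any real
dataset.

## Expression channel

Normalized expression (`log1p(count / total * 1e4)`) is averaged per cell
into 220 kb genomic bins (genes mapped by start coordinate, half-open tiles),
baselined by subtracting the mean bin profile of the pooled healthy reference
cells, imputed (empty bins copy the nearest gene-bearing bin on the same
chromosome) and smoothed with a centered moving average of half-width 2 bins
(the window shrinks at chromosome ends). The Bayesian segmentation used by
full-scale expression-CNA callers is intentionally replaced by this moving
average — a declared simplification with the same contract (relative dosage
per bin).

Per sample, cells are clustered with k-means (k = 80, 10 restarts, fixed
seed) on the target-region bins, and cluster centroids are split into two
groups by an exact 1-D two-means over their mean region score. The lower
group is called deleted iff its mean is below the cutoff.

**Cutoff calibration.** k-means concentrates the lowest-scoring cells into
clusters even in pure noise, so the lower centroid group of a deletion-free
sample sits around −0.07..−0.15 on the log1p scale at the default depth —
a naive "slightly negative" cutoff would call ~20% of healthy cells deleted.
A true hemizygous (dosage 0.5) cluster sits near −0.40, and dosage 0.6 near
−0.30. The default cutoff −0.25 lies between the two regimes, giving both a
clean negative control (≤1% false deletion calls) and essentially full
sensitivity at hemizygous dosage. Cohorts with much lower depth or very few
region genes widen the noise regime; the cutoff is config-overridable.

## Allele channel

Per covered SNP, deviation `d = |alt/(ref+alt) − 0.5|`. Per cell and arm:

* the arm deviation is the coverage-weighted mean of `d` over covered arm
  SNPs; cells with fewer than `min_snps = 3` covered SNPs are
  `uninformative` — a first-class outcome, because coverage-starved cells
  carry no allelic information and must not silently count as diploid;
* multiscale consistency: the position-ordered deviation sequence is median-
  filtered at four window sizes (1, 3, 5, 7 SNPs); a scale "flags" the arm if
  its mean smoothed deviation exceeds `d_event = 0.2`; the consistency is the
  flagged fraction. An event requires consistency ≥ 0.75: raising the
  threshold demands agreement across more evidence levels before an
  aberration is accepted.
  `d_event = 0.2` sits between the diploid sampling regime (mean deviation
  ~0.16 at Poisson-6 coverage) and the hemizygous regime (~0.5 − error).
* direction: BAF deviation cannot tell loss from gain, so the event sign
  comes from the cell's arm-level expression shift versus the reference
  (negative → deleted, positive → amplified, exact tie → neutral).

## Validation statistics

* **Marker dosage check** (per sample): pseudobulk mean normalized expression
  of the six CDR markers in `del5q` vs `non_del5q` cells; a dosage-consistent
  classification makes all six lower in `del5q` in every sample.
* **Region enrichment**: per-gene two-sided Mann-Whitney rank-sum tests
  between the genotype classes (a vectorized tie- and continuity-corrected
  normal approximation, equality-tested against scipy), then a one-sided
  hypergeometric over-representation of target-region genes in the
  "downregulated" set. The down-set rule defaults to raw p < 0.05 rather
  than BH-adjusted: under label permutation a BH down-set is almost always
  empty, pinning the enrichment p at 1 and making the shuffle control
  uninterpretable, whereas the raw rule keeps the per-perm statistic
  continuous (BH mode remains available for conservative reporting). Such comparisons
  are often labelled "signed-rank" in the field, but the groups here are
  unpaired cells, so the applicable unpaired rank-sum form is used (an exact
  signed-rank mode exists for genuinely paired abundance comparisons).
* **Shuffle (fade-away) control**: genotype labels are permuted uniformly
  among classified cells and the enrichment p recomputed per permutation.
  With true labels the enrichment is extreme; under shuffling it collapses
  (median permuted p ≫ true p). One honest caveat: per-gene tests are
  exactly calibrated under permutation (measured 5.01% of genes at
  p < 0.05), but the per-permutation *enrichment* p is not exactly uniform
  when the data carry a strong real signal — each random relabeling over- or
  under-samples truly deleted cells, leaking a coherent sliver of the dosage
  effect into all region genes at once, so the tail probability
  P(enrichment p < 0.05) inflates to ~0.14 regardless of cohort size (the
  coherent leak scales as z_true/√N × √N). The uniformity claim holds only
  under genuine label exchangeability, and that is how the property test
  checks it (a dosage-1.0 cohort).
* **Concordance**: per-sample |estimated − expected| clone fraction, with
  both denominators reported (all cells, and classified cells only) since a
  karyotype-style percentage can be defined either way.

## Lineage enrichment and abundance

Accumulation of `del5q` cells in a cell type is scored per sample (and
pooled) with the one-sided hypergeometric tail P(X ≥ k), reported raw and as
−log10(p) with a 0.05 significance mask — deliberately unadjusted, matching
the per-patient heatmap convention. Ambiguous cells are excluded from both
numerator and population. Cross-condition cell-type abundance uses the exact
two-sided rank-sum test on per-sample proportions; with 3-vs-4 samples the
smallest attainable two-sided p is 2/35 ≈ 0.057, which is why such
comparisons bottom out near 0.06.

## Differential expression

**Pseudobulk NB GLM.** Raw counts are summed per (sample, cell type, group)
replicate (replicates under 20 cells are dropped); per gene, nested NB GLMs
(log link, log-library-size offset) are compared by LRT against chi-square
df = 1; log2FC is the group coefficient / ln 2. Genes with total count < 10
are reported untested. Significance: BH-adjusted p < 0.05 and |log2FC| > 2.

*Dispersion.* Per-gene dispersions from a handful of replicates are far too
noisy to use directly: plugging them in (even method-of-moments with df
correction, shrunk 60% toward the median) inflates the null type-I rate at
p < 0.05 to 0.08-0.09. The package instead estimates each gene's dispersion
by Cox-Reid adjusted profile likelihood (grid-maximized, vectorized), takes
the *common* dispersion as the pooled-APL maximizer — the median of per-gene
estimates is biased low in this regime — and shrinks per-gene values toward
it with weight df_resid/(df_resid + prior_df), prior_df = 10. With 3-vs-3
replicates this yields measured null type-I rates of 0.056-0.062 at nominal
0.05 and recall ≥ 0.95 for |log2FC| = 3 spikes at the standard filter.

**Hurdle test** (for contrasts without enough replicate structure): per gene,
a detection component (2×2 logistic LRT of expressed/not vs group, closed
form) plus a continuous component (Gaussian LRT on normalized expression
among expressing cells); the statistics add, df = number of estimable
components (detection drops when saturated or empty; continuous drops when a
group never expresses). log2FC = difference of group mean normalized
expressions / ln 2.

**BH adjustment** is the standard step-up procedure (NaNs propagate), applied
within one cell type and contrast.

## Pipeline and reproducibility

`run_all` executes simulate → QC → both channels → consensus → validation →
enrichment → DE, derives every stage seed deterministically from one global
seed (stage-name CRC hashing), and writes a manifest with SHA-256 checksums
of every file in the run directory; two runs with the same config are
byte-identical. Logging goes to stderr only, so the manifest fully covers
the directory. QC defaults (min 200 genes, 500-100,000 UMIs, complexity
log10(genes)/log10(UMIs) ≥ 0.8, mito ≤ 0.2, ribo ≤ 0.6 by gene-name prefix)
are conventional, config-overridable, and not tuned to reproduce any
particular retained-cell count; a cell with ≤1 UMI fails the complexity rule
by definition rather than dividing by zero.

## Problem sizes used by the test suite and acceptance script

The design-scale cohort (4×2,000 patient cells + 2×1,500 reference cells,
2,000 genes) runs every stage in well under a minute each; the DE calibration
uses 2,000 genes at 3-vs-3 replicates; the shuffle control uses 100
permutations; unit tests use a 2×400-cell cohort with k scaled down to keep
≥30 cells per k-means cluster, the regime the posterior clustering is
designed for.

## Known limitations

* The expression channel's fixed cutoff presumes the default depth/region
  size; very shallow cohorts need recalibration (both regimes shift).
* The allele channel needs multi-read SNP coverage (see above); it reports
  `uninformative` rather than guessing.
* The shuffle control's tail probability is conservative-in-spirit but not
  exactly uniform in the presence of strong true signal (see above).
* The hurdle test's continuous component assumes approximate normality of
  log1p expression among expressing cells; it is a screening statistic, not
  an exact test.
* No batch, covariate, or compositional adjustments anywhere — out of scope
  by design.
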