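# Methods

## Model and procedure

`genescout` prioritizes GWAS associations inside pre-specified candidate
genes. The statistical object is simple: restricting attention to a gene
set shrinks the number of independent tests, so the family-wise error rate
α can be divided by the number of independent SNPs in the tested regions
rather than by the genome-wide million.

**Gene store.** refFlat annotation lists one transcript per line in 0-based
half-open coordinates. One span per gene symbol is retained — the longest
transcript, with span ties broken by the lexicographically smallest
transcript id so that rebuilding the store is deterministic. Genes whose
transcripts map to more than one chromosome are excluded as ambiguous and
listed in a report; genes with several same-chromosome placements keep the
longest. Chromosome names are compared with the `chr` prefix stripped.
The store size N_db is the denominator of the enrichment background rate.

**Regions.** Each candidate gene span is extended by `flank_bp`
(default 10,000 bp) on both sides, clipped at zero, covering exons,
introns and proximal regulatory sequence. Overlapping regions are *not*
merged: a SNP in k overlapping regions is counted and reported once per
gene, and independent-SNP sums are taken literally over regions. The
un-deduplicated sum gives a larger M, hence a stricter threshold — the
conservative direction.

**Independent SNPs.** A reference genotype panel (VCF or dosage matrix)
is reduced chromosome-wise: SNPs with minor-allele frequency < 0.01 are
dropped, then a window of 50 SNPs advancing in steps of 5 is scanned and,
within each window, one member of every retained pair with squared dosage
correlation r² > 0.2 is greedily removed — always the lower-MAF member of
the currently worst pair, the position-later one on an MAF tie. Windows
and steps are SNP counts, not base pairs. Missing genotypes enter through
pairwise-complete r² and non-missing-denominator MAF; a constant vector
contributes r² = 0. The retained positions are persisted per
(ancestry, chromosome) table in a single SQLite file. The guarantee used
downstream — no retained pair that ever shared a window exceeds the r²
ceiling — holds by construction and is re-verified in the test suite.
plink's unpublished internal tie-handling may differ; bit-identity with
plink is not claimed, only the same documented greedy rule, fixed
deterministically.

**Thresholds.** Four modes: per-gene Bonferroni α/m_g (default; genes
with m_g = 0 are excluded from scanning with a warning), list-wise
Bonferroni α/M with M = Σ m_g, Benjamini–Hochberg FDR over the
candidate-region SNP p-values at level q, and a fixed user value.
Scanning applies *strict* inequality p < t everywhere. Because BH
declares the boundary p-value itself a discovery, the stored FDR
threshold is `nextafter(p_(k), 1)` — one ulp above the largest passing
p — so that the strict rule yields exactly the BH discovery set; when
nothing passes, the threshold is the smallest positive float, which no
(clamped) p-value can undercut. Coordinates: gene-store spans are 0-based
half-open; a 1-based summary position q lies in region [s, e) iff
s < q ≤ e; independent-SNP counting uses the matching half-open 1-based
interval [s+1, e+1). Summary p-values of exactly 0 are clamped to the
smallest positive float with a warning; unparseable rows are skipped and
counted.

**Enrichment.** At a single fixed threshold t (list-wise, FDR or fixed
mode — per-gene mode is rejected because a binomial model presumes one
threshold), every store gene is flanked and scanned; the background rate
p is the significant fraction. The candidate list's observed count x out
of n is scored by P(X ≥ x) under Binomial(n, p), computed with the
survival function: the literal 1 − CDF subtraction would cancel
catastrophically for the very small tails this statistic produces. When
gonosomal genes are excluded from candidate lists they are excluded from
the background universe too, keeping numerator and denominator
consistent.

Two null distributions validate the binomial shortcut: `resampling_null`
draws random gene lists of the same size uniformly without replacement
from the store (per-draw list-wise threshold recomputation, or a fixed
threshold for calibration studies) and counts significant genes per draw;
`binomial_null_sim` draws Binomial(n, p) directly. `compare_nulls` pairs
the two samples' order statistics (a QQ plot) and reports the Spearman
rank correlation with average ranks for ties; two constant samples give
NaN with a warning rather than a fabricated coefficient.

## Synthetic data: what it emulates and what it does not

The generator produces, from a single seeded configuration, a refFlat
catalog of non-overlapping genes (1–3 transcripts each, the first strictly
longest, so the expected canonical span is known exactly), genotype panels
with block-exchangeable LD, and GWAS summary files that are uniform-p
under the null with optional planted signals. All outputs are pure
functions of the configuration: one seed, byte-identical files.

LD model: each block of `ld_block_size` consecutive SNPs shares a latent
haplotype with frequency drawn from `maf_range`; SNPs flip away from it
with probability (1 − √r)/2, giving block-mate correlation ≈ r
(exact duplicates at r = 1, independent SNPs with their own frequencies at
r = 0). Cross-block correlation is ~0. This exercises MAF filtering and
windowed pruning transparently but does not emulate realistic allele
frequency spectra, recombination gradients, population structure or
imputation noise. Null p-values are i.i.d. uniform, ignoring the
LD-induced p-value correlation of real summary files; the enrichment null
is defined gene-wise, and flanked regions of neighboring genes are kept
disjoint (intergenic gaps exceed twice the flank) so gene-level
significance events are independent under the null. Passing tests
therefore demonstrate the statistical machinery, not robustness to real
LD leakage between adjacent genes.

## Study conditions

Problem sizes were chosen once, as the package's desk-scale study
conditions, and are fixed in `null_study_config` / `planted_study_config`:

- **Null calibration study**: 2,000 genes (2–5 kb) on four 16 Mb
  chromosomes, gaps 21–25 kb, flank 10 kb, 333,000 summary SNPs per
  chromosome (~48 bp mean spacing, ~500 SNPs per flanked region); 500
  null iterations of 300-gene lists at fixed thresholds 10⁻²–10⁻⁵.
  The region SNP content of ~500 is the density at which *every*
  threshold in that 3-decade range stays informative: much sparser and
  the 10⁻⁵ counts collapse toward a constant zero; much denser and the
  10⁻² counts saturate at the list size — either degeneracy voids a rank
  correlation. A matched hypergeometric-versus-binomial simulation showed
  this choice maximizes the worst-case QQ Spearman.
- **Type-I calibration**: same world; 200 random 50-gene lists scored at
  a fixed threshold of 1.4×10⁻³, where the per-gene rate is ~0.5. The
  binomial tail is discrete, so the attained level of "p_enrichment
  < 0.05" sits below 0.05 unless n·p is well away from 0 and n — the
  chosen regime keeps the attained level inside the expected band.
- **Planted-recovery study**: 500 genes on one 16 Mb chromosome;
  reference panel of 40,000 SNPs (~400 bp spacing, ~60 independent SNPs
  per region after pruning); the summary file keeps every fourth panel
  site, emulating an array-based GWAS typed at a subset of the reference
  panel. That 4:1 ratio matters: under a list-wise threshold α/M the
  expected number of *chance* sub-threshold SNPs in the candidate regions
  is α × (scanned SNPs / independent SNPs), so scanning fewer sites than
  the panel keeps exact truth recovery overwhelmingly probable while the
  planted p = 10⁻¹⁵ signals always pass. Each of 100 replicates draws 50
  candidates, plants signals in 5, and must both detect enrichment
  (P < 0.05) and recover exactly the planted genes.

## Numerical choices and degenerate inputs

- Threshold ties: scanning is strictly exclusive (p = t is not a hit).
- Pruning determinism: removal rule fixed as documented; the window
  schedule stops after the first window reaching the end of the
  MAF-surviving SNP list.
- r² of a constant dosage vector is 0 (no information), not NaN.
- `allele_frequency` errors on an all-missing column; whole all-missing
  panel columns are dropped with a warning during pruning.
- Empty regions score min-p = ∞, so they can never be significant.
- Spearman of two constant count vectors is reported as NaN with a
  warning.
- Seeds: every stochastic routine takes an explicit seed and uses an
  isolated `numpy` Generator; nothing draws from global state.

## Limitations

- Exact plink tie-handling is unpublished; retained sets may differ from
  plink's in ties while satisfying the same r² guarantee.
- The FDR universe is the candidate-region SNPs only; other choices of
  universe (e.g. genome-wide) would give different FDR thresholds.
- Overlapping flanked regions double-count independent SNPs in the
  list-wise sum (deliberately conservative).
- Candidate-list construction (ortholog mapping, phenotype ontology
  queries) and genome-build liftover are out of scope: inputs must be
  pre-resolved gene symbols and build-matched summary files.
- The resampling null draws from the full store, including the candidate
  genes themselves; with candidate lists that are a large fraction of the
  store this slightly inflates the null.
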