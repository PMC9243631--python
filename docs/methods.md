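# Methods

## The measurement being modelled

`tribe-edit` implements the analysis side of an RNA-editing proximity assay
(hyperTRIBE) for identifying stress-granule transcripts. An RNA-binding
protein (FMR1) is fused to the hyperactive catalytic domain of ADAR; RNAs
near the fusion acquire A-to-I edits, which sequencing reads as A-to-G
mismatches. Cells are profiled in three conditions — uninduced (no fusion,
endogenous ADAR only), basal medium (Schneider's, fusion expressed, no
stress) and arsenite stress (stress granules form) — in triplicate. A
transcript recruited to stress granules should be edited more under arsenite
than in basal medium; that differential is the pipeline's signal.

The pipeline starts from per-position base counts (a thin SAM pileup builder
is provided for small inputs) and proceeds: expression filter → edit-site
calling → per-gene editing frequencies → empirical-Bayes differential test →
group classification → downstream feature, single-cell and colocalization
statistics.

## Coordinate and orientation conventions

Internal coordinates are 0-based half-open everywhere; GTF, VCF and SAM
conversions happen only at file boundaries. Mismatch classes are reported in
*transcript* orientation: a genomic T>C substitution on a minus-strand gene
is an A>G edit. Base-count tables always carry genome-strand bases; the
complementing happens in classification.

## Edit-site calling

Discovery pools the base counts of all samples (the merged-library view).
Per position, the candidate alternative allele is the highest-count
non-reference base (ties broken A<C<G<T; at most one allele per position).
A site is retained when

- pooled alternative count ≥ `min_alt` (default 3),
- pooled depth ≥ `min_depth` (default 10),
- quality > `qual_min` (default 250), where quality is the phred-scaled
  binomial tail `-10·log10 P[Binom(depth, ε) ≥ alt]` against a fixed
  per-base error rate ε (default 1e-3), capped at 5000,
- pooled allele frequency < `af_max` (default 0.95), which removes
  homozygous genomic variants, and
- the (chrom, pos, alt) triple is not on the known-variant exclusion list.

The binomial-tail quality is a deliberately simple stand-in for a
genotyper's site quality: it asks only "could this many alternative reads
be sequencing error?", which is the part of the evidence the rest of the
pipeline needs. The 250/0.95 defaults mirror the hard cut-offs used in the
original bulk analysis.

## Editing frequencies

Per site, the editing frequency is alt/depth (e.g. 17 G of 53 reads →
0.32). Per gene two summaries exist:

- **Strategy A (default, "average editing frequency")** — unweighted mean
  of per-site frequencies. For sites 17/53 and 23/58: (0.3208 + 0.3966)/2 =
  0.3587.
- **Strategy B ("pooled")** — summed edits over summed depth:
  (17+23)/(53+58) = 0.3604.

They coincide exactly when site depths are equal and diverge for genes with
strongly varying depth (sites {0/1000, 5/10} give 0.005 vs 0.25). Replicates
are either pooled (each replicate's site observation enters the summary;
counts simply add under strategy B) or summarised per replicate and
averaged (`replicate_mode="mean"`). Sites with zero depth in a sample are
omitted from that sample's mean — absence of coverage is not absence of
editing.

## The empirical-Bayes differential test

The test asks, per gene, whether the arsenite editing proportion exceeds the
basal one. Construction:

1. Pool replicate counts within condition at the gene's retained sites,
   giving (k, n) per gene × condition. The default feed is the raw count
   pool (strategy-B view); `site_weighting="equal"` instead maps the
   strategy-A mean frequency onto the pooled depth (k = round(mean_freq·n)),
   which lets the analysis be repeated under the average-frequency view.
2. Fit one shared beta prior Beta(α, β) by maximising the beta-binomial
   marginal likelihood over all (gene × condition) observations
   (Nelder-Mead on log-parameters from a method-of-moments start; degenerate
   all-zero/all-one data fall back to the floored moment estimate, flagged).
   The shared prior borrows strength across genes and shrinks low-coverage
   proportions.
3. Conjugate posteriors per condition: Beta(α + k, β + n − k).
4. One-sided evidence p = 1 − P(θ_ars > θ_basal), with
   P(θ_ars > θ_basal) = ∫ f_ars(x) F_basal(x) dx computed by adaptive
   Gauss-Kronrod quadrature (abs. tolerance 1e-10). The production path
   uses a vectorised 200-node Gauss-Legendre rule over the ars-posterior's
   [1e-13, 1−1e-13] quantile range; it agrees with the adaptive rule to
   well below 1e-8 and with 1e7-draw Monte-Carlo to sampling error.
5. Significance at raw p < 0.01 (the published rule); Benjamini-Hochberg
   FDR is reported alongside as a QC column, never as the decision rule.

Genes lacking coverage in either condition are skipped with a warning.

## Group classification and endogenous flags

Among tested genes: **group 1** = not significant; significant genes are
**group 3** when their pooled basal alternative count is below the same
`min_alt` evidence floor used in site calling, otherwise **group 2**. A
strict variant (`basal_zero_rule="strict"`, exactly zero basal alt reads)
is available but not the default: with ~1,500 pooled basal bases per gene,
sequencing error alone produces ≥1 spurious alternative read a substantial
fraction of the time, so literal zero misclassifies genuinely basal-silent
genes as group 2 while the evidence floor does not. The groups partition
the tested set by construction.

A gene is flagged *endogenously edited* when any retained site has ≥
`min_alt` pooled alternative reads in the uninduced condition — editing
attributable to native ADAR rather than the induced fusion. Flagged genes
are kept in all downstream sets; the flag is informational.

## The synthetic-data generator

The generator is first-class code: it defines the conditions under which
every statistical property of the pipeline is demonstrated.

Per gene: a strand (half minus by default), 150 candidate positions with
uniform random reference bases, of which 5 existing adenosines are the true
edit sites (edited sites are chosen among positions already carrying A so
the overall base composition stays uniform; the sparsity mirrors the
observation that only a handful of adenosines per transcript are edited).
20% of genes are stress-granule genes; a quarter of those ("group 3 truth")
have basal rate exactly 0, the rest draw basal site rates from
Beta(2, 38) (mean 0.05) and all SG genes draw arsenite rates from
Beta(5, 15) (mean 0.25). Non-SG genes either carry no editing (40%) or
share one Beta(2, 38) rate across Schneider's and arsenite — *shared*, so
that a configuration with `frac_sg_genes=0` is an exact null for the
differential test. A 20% subset of basally edited genes is endogenous
(uninduced rate equals the basal rate); all other genes have uninduced
rate 0. 5% of genes are low-expression (depth scaled by 1e-3) to give the
TPM filter something to remove.

Coverage per position and library is NegativeBinomial with mean 100 and
dispersion 5 (variance 100 + 100²/5), the two-parameter minimum for
overdispersed RNA-seq coverage. Reads at a site are generated through a
per-read channel: the true base is the edit with probability θ, then the
base is miscalled uniformly over the three other bases with probability
ε = 1e-3. The observed alt-base rate is therefore θ(1−ε) + (1−θ)ε/3: a
miscalled edited base still reads non-reference (it lands on C or T), and a
site with θ = 0 is statistically indistinguishable from background error —
which keeps the twelve mismatch classes exchangeable in a no-editing
simulation, a property the test suite checks by chi-square. Everything is
generated in transcript orientation and complemented at emission for
minus-strand genes, so plus- and minus-strand runs of the same seed carry
byte-identical transcript-oriented signal.

The single-cell mode splits cells evenly between Schneider's and arsenite,
draws an ADAR fusion count per cell from Poisson(5), and scales each cell's
site rates by min(1, 0.2 · adar_count) — a cell without ADAR shows only
error background. Per-cell coverage is shallow (mean 1–2 reads per
position) and only nonzero-depth rows are emitted, as in real single-cell
tables. Bulk and single-cell simulations of the same config and seed share
gene/site ground truth, which is what makes matched-depth bulk-vs-pseudobulk
comparisons meaningful.

The smFISH mode places RNA spots in unit-square cells containing one square
granule covering a configurable area fraction. The probability that a spot
falls inside the granule is logistic in the gene's true log2 arsenite/basal
fold change (slope 1.5, midpoint 1, i.e. 50% recruitment at 4-fold);
zero-basal genes are capped at 2^6-fold. Uniform-placement and fixed-
probability modes exist for geometric calibration tests.

What the generator does **not** emulate: positional read structure and
alignment artefacts (counts are drawn per position, not per read, except in
the small `simulate_sam` mode), base-quality structure, UMI/barcode
chemistry, isoform structure, batch effects, and any coupling between
expression level and editing. Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to alignment
or library artefacts.

## Downstream statistics

- Feature lengths (transcript/CDS/UTRs, strand-aware) come from merged GTF
  exon models; set comparisons use the two-sided Mann-Whitney U — scipy's
  exact null for tie-free samples with n₁·n₂ ≤ 10⁴, the tie-corrected
  normal approximation otherwise.
- Set overlaps use the exact upper-tail hypergeometric probability.
- Replicate QC reports pairwise-complete Pearson correlations and Euclidean
  distances between per-gene frequency profiles.
- Colocalization counts spots inside any of their cell's granule polygons
  (boundary-inclusive, shapely); the editing-vs-localization relation is an
  OLS of colocalization fraction on fold change, with infinite fold changes
  (zero basal) excluded by default or winsorized to the largest finite
  value behind a flag; a log2-fold option exists.

## Problem sizes used in tests and the acceptance script

Sizes are the package's own choices for its demonstration runs: type-I
error on 10 null simulations of 2,000 genes; recovery, spectra and strategy
concordance on the 1,000-gene default; prior recovery on 500 beta-binomial
genes against a 100×100 grid oracle; bulk-vs-pseudobulk on a 300-gene
panel with 300 cells at cell depth 2 against triplicate bulk at depth 100
(matched 300 reads per position per condition); Monte-Carlo oracles use
10⁷ draws. Strategy concordance in the acceptance script is averaged over
three replicate simulations because a single run's estimate at ~640 tested
genes has a standard error of a few tenths of a percent.

## Numerical choices and degenerate inputs

Quality scores cap at 5000; depth-0 or alt-0 positions score 0. The prior
fit requires ≥10 covered observations, clips parameters to [1e-3, 1e6] and
keeps the moment estimate if the optimizer fails to improve on it.
`prob_greater` requires strictly positive parameters. Fold changes with
zero basal frequency return +inf with a flag rather than raising. Empty
variant sets, empty spectra and header-only count tables round-trip without
error. Tie-breaking in allele selection is deterministic (A<C<G<T) so
repeated runs are reproducible; the simulator's seed fixes every random
draw.

## Known limitations

- The binomial-quality site caller has no genotype-likelihood model;
  systematic errors (strand bias, misalignment hotspots) would pass the
  error-only null it tests against.
- The EB test pools replicates within condition and therefore does not
  separate biological from technical variance; a replicate-aware analysis
  can be emulated with `replicate_mode="mean"` summaries but the default
  decision rule is the pooled one.
- Group 3 membership depends on the `min_alt` floor; at much deeper
  coverage than the defaults the floor should scale with expected error
  reads (n·ε/3).
- The smFISH model ignores optical crowding, segmentation error and
  multi-granule geometry beyond what polygon input expresses.
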