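# Methods

This note records the models, parameter choices and numerical conventions
behind `senoscore`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Synthetic cell population

Cells carry a binary latent senescence state `s_c ~ Bernoulli(f)` with
`f = 0.20` by default. Gene g in cell c has log relative abundance

    log w_gc = η_g + β_g s_c + donor_gc + tech_gc,

with baselines `η_g ~ N(0, 1)`, module loadings `β_g` (maturation 0.9 over
120 genes, interferon-response 0.6 over 60, SASP 0.0 over 40 — the SASP
module is deliberately unresponsive, mirroring its absence in senescent beta
cells), and per-(gene, batch) effects with s.d. 0.15 over 4 donors and 2
technologies. Abundances are multiplied by Gamma(1/φ, φ) noise with φ = 0.4
(typical droplet-data overdispersion, variance μ + φμ²) and counts are drawn
multinomially at a lognormal(8.0, 0.4) library size (~3,000 UMI median), so
column sums equal library sizes exactly and marginals are negative-
binomial-like. The latent state is binary rather than continuous because the
analysis classifies cells into discrete marker-high/neg groups.

The anchor marker (`CDKN2A`) is modelled for *specificity with partial
capture*: a very low baseline (log weight −5, scaled with gene count so its
relative abundance is size-invariant) plus a +6.2 loading in senescent
cells, and zero-inflation that removes all marker counts from a senescent
cell with probability 1 − capture (capture = 0.75). Under the defaults this
yields detection in ~14–15% of cells while ~20% are truly senescent —
the regime in which naive correlation ranking degrades and recovery helps.
Capture is modelled as zero-inflation rather than a lower mean because the
quantity of interest downstream is the *detection rate*.

Ten designated `MT-` genes with elevated baseline provide a realistic
mitochondrial fraction for the QC filters.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects that are confounded with the senescent state, UMI saturation, and
gene–gene correlation beyond the planted modules and batch structure.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under a faithful-but-idealised noise model, not performance on
any particular tissue atlas.

## QC and transforms

Two cell-filter profiles are shipped: `compendium` (1000–9000 detected
genes, UMI ≥ 500, mitochondrial ratio < 0.20, complexity > 0.80) and `tenx`
(≥ 200 genes, UMI ≥ 200, mito < 0.10, complexity > 0.80). Complexity is
read as `log10(n_genes)/log10(n_UMI)`; the alternative reading
`log10(genes/UMI)` is always negative and could never exceed 0.8.
Expression is `Ex = log2((CPM/10)+1)`; genes are kept when `Ex > 3.5`
(strict) in at least 2% of cells (inclusive). Scaling uses the sample
standard deviation (ddof = 1) and clips at ±10, the common single-cell
convention; constant genes scale to zero. "Detected" means raw count ≥ 1.
Pipeline order is QC → Ex → gene filter → recovery, recorded in provenance.

## Expression recovery

Full LASSO-per-gene recovery is replaced by a same-skeleton, desk-scale
variant: the prior mean μ̂ comes from ridge regression (penalty 1e-2, on 20
principal components of the log-normalised matrix, intercept unpenalised,
deterministic full-SVD PCA), floored at 1e-6; the per-gene dispersion φ_g is
fitted by bounded 1-D maximum likelihood on log φ ∈ [−12, 6] and accepted
only if it beats the Poisson limit (otherwise φ_g = 0 and the posterior
equals the prediction). Size factors are `s_c = total_c / median(total)`.
The posterior mean is bounded between observation and prediction entrywise
(a property test), and the per-gene reliability

    w_g = sqrt( Var_c(λ̂_g) / (Var_c(λ̂_g) + mean_c posterior_var_g) )

multiplies into the adjusted correlation `r_adj = r · w_g · w_marker` that
ranks genes against the marker. Correlations are computed on the recovered
values before any scaling (both options exist; this is the default and is
recorded in provenance). Ties in `r_adj` break by gene name. On the default
dropout simulation, the adjusted-correlation estimates have strictly lower
mean absolute error against the planted correlations than raw-count
estimates; the gain comes mostly from the reliability shrinkage of null
genes and the imputation of the zero-inflated marker.

## Signatures, scores, classification

The marker signature is the top-N (default 100) genes by `r_adj`. Controls
are drawn per signature gene from 25 equal-frequency bins of mean `Ex`
(100 controls per gene, sampled without replacement, seeded); when a bin is
smaller than requested the whole bin is used with a warning. The per-cell
score is exactly `SC = mean(Es over G) − mean(Es over C)`. Because `Es`
rows are centred, the across-all-cells mean of any score is identically
zero; null calibration is therefore assessed on random half-samples of
cells. Classification thresholds are linear-interpolation percentiles with
strict inequalities on both sides ("> upper", "< lower"); ties fall into
the middle class. Defaults: 70/30 for transcript-based classes, 80/20 for
staining intensities.

## Hurdle differential expression

Per gene, a logistic model on the detection indicator and a Gaussian model
on `Ex` among detected cells share a design of intercept + class + donor +
technology dummies + centred cellular detection rate (CDR). CDR follows the
common two-part-model convention and is switchable off. The logistic part
carries an L2 penalty of 1e-4 (Newton-IRLS, 60 iterations, step tolerance
1e-8) to tame separation; the likelihood-ratio statistic sums the two
parts' deviance drops for the class term, with degrees of freedom equal to
the number of estimable parts (a gene detected everywhere contributes only
the continuous part; a gene whose detected cells lie in one class
contributes only the detection part). Genes detected in < 3 cells are
skipped. Significance applies both a BH-adjusted p threshold and a
fold-change threshold; presets `scrna` (P_adj < 0.05) and `mrna`
(P_adj < 0.1, FC > 1.5) are provided. `log2FC` is the difference of class
means of `Ex` (already a log2-scale quantity). Confidence intervals are
2.5/97.5 percentiles over 150 cycles of resampling 500 cells per class with
replacement, seeded. Calibration at 2 × 500 cells: type-I error at α = 0.01
within [0.004, 0.02]; planted δ = 1 shifts recovered with ≈95% CI coverage
and empirical FDR ≈ 3% at P_adj < 0.05.

## Enrichment

Preranked GSEA uses the weighted-KS running sum: hit steps `|metric|^p`
(p = 1 default; equal steps if all weights vanish), miss steps uniform, ES
the extremum of larger magnitude with magnitude ties (within 1e-12)
resolving to the positive side. The null permutes gene labels (random sets
of equal size), the natural choice for a preranked input; NES divides ES by
the mean |null ES| of matching sign; nominal p is the same-sign exceedance
fraction; FDR pools sign-normalised null and observed NES in the standard
way. Sets overlapping fewer than 5 ranked genes, or all of them, are
skipped with a reason. ORA is the upper-tail hypergeometric `P(X ≥ k)` with
BH across sets; k = 0 gives p = 1 exactly.

## Chromatin

All coordinates are 0-based half-open; the promoter window is
`[tss − 2000, tss + 2000)`, so a peak starting exactly at `tss + 2000` does
not overlap. A TSS is an active promoter when H3K27ac, ATAC and H3K4me3
peaks each overlap the window; an enhancer is an H3K27ac peak overlapping
H3K4me1 outside every promoter window, reported on the H3K27ac coordinates
(differential activity is quantified on H3K27ac peaks; the intersection is
available by config). Nearest-gene linking measures from the element
midpoint, breaking ties toward the smaller coordinate then the smaller
name, with distances signed by strand.

The differential region test normalises by median-of-ratios size factors
(geometric-mean centred so they multiply to 1), estimates per-region
dispersion by pooled within-condition method-of-moments floored at the
median dispersion across expressed regions — the conservative max-rule that
guards against small-sample underestimation — and tests the condition
coefficient of a per-region NB GLM (log link, size-factor offsets,
vectorised IRLS) with a standard-normal Wald reference. No dispersion-trend
or fold-change shrinkage is applied; thresholds default to P_adj < 0.05 and
|FC| > 1.5. At 3 + 3 replicates, depth 50 and dispersion 0.05 this yields a
null p < 0.05 rate of 0.04–0.06, sensitivity ≈ 0.9 for |log2FC| ≥ 1.585 and
empirical FDR ≤ 0.08.

PWM scanning quantises log-odds (probabilities from counts + 0.5
pseudocount over a uniform background) to a 1e-4 grid and computes the
exact null score distribution by dynamic-programming convolution over
positions; the threshold is the smallest *attainable* score whose
upper-tail probability is ≤ the requested p (1e-4 per window by default),
which matches exhaustive k-mer enumeration by construction. Both strands
are scanned; `N` bases contribute zero log-odds; sites shorter than the
motif fail with a flag; a site-level BH q over best-window p-values is also
reported.

CTCF sites are categorised with precedence promoter → enhancer–promoter
intervening (an enhancer strictly on one side and an active promoter
strictly on the other, both within 200 kb of the site midpoint; linkage to
the nearest opposite-side promoter) → TAD boundary (overlap with a supplied
boundary interval) → other, with the intervening and boundary flags
retained when both hold. Boundary intervals are explicit inputs; deriving
them from published contact maps is upstream of this package. The
boundary-upregulation test is an upper-tail hypergeometric of the overlap
between genes linked to boundary sites with negative binding change and the
upregulated gene set, within the tested universe.

## Toy genome layout

Each planted CTCF site (and each extra promoter/enhancer/TSS) occupies its
own ~400 kb block on a single toy chromosome whose length is derived from
the block count (~90 Mb at defaults). Block isolation guarantees that the
200 kb intervening rule cannot couple neighbouring plantings, which is what
makes planted categories exactly recoverable and lets truth-based recall
and precision equal 1.0 for the deterministic interval rules. Region counts
(2 × 3 replicates, NB dispersion 0.05, mean depth 50, lognormal(0, 0.15)
sample depth factors) carry planted |log2FC| = 2 for changed sites, split
symmetrically between conditions. Boundary sites all carry planted binding
loss; their linked genes are planted upregulated with probability 0.9
(coupling), against a 10% background upregulation rate. A planted
gene-level expression count table allows upregulation to be *recovered* by
the differential test rather than read from truth in the pipeline.

## Intensity tables

Per-cell channel intensities are lognormal with a class shift on the log
scale (p16 shift 1.2, HLA-I shift 0.6, s.d. 0.5) and cytoplasmic-DNA focus
counts are Poisson with rates 0.15 (non-senescent) vs 0.30 (senescent) — a
2× prevalence ratio. Zero shift reduces percentile classification to
chance, which the tests verify.

## Problem sizes and seeds

All randomness flows from explicit seeds (`numpy.random.default_rng`).
Standard experiment sizes used by the test suite and the acceptance script:
2,000 cells × 2,000 genes for signature recovery and recovery utility;
1,000 genes × 2 × 500 cells for hurdle calibration; 200 genes × 2 × 600
cells for bootstrap coverage; 2,000 regions at 3 + 3 replicates for the
differential region test; 100 boundary sites at coupling 0.9 for the
enrichment power check and 200 replicates over a 20,000-gene universe for
its null; 1,000 random interval fixtures for the brute-force oracles;
motif widths ≤ 8 for exhaustive PWM enumeration.

## Known limitations

The recovery predictor is linear in PC space and will under-impute
expression programs orthogonal to the leading components; the hurdle
continuous part assumes Gaussian `Ex` given detection, adequate at these
depths but approximate for very low-expressed genes; the differential
region test has no dispersion-trend shrinkage, so its power profile differs
from shrinkage-based tools at very low counts; GSEA FDR uses the classic
pooled-NES estimate, which is conservative for few sets; the toy genome's
block isolation removes the ambiguous multi-element neighbourhoods found in
real genomes, where the intervening rule's nearest-promoter choice matters
more.
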