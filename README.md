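# senoscore

Marker-anchored senescence signature discovery and regulatory-genomics
classification for pancreatic beta-cell data.

A small fraction of adult human beta cells express the senescence marker
p16 (*CDKN2A*). Characterising them from single-cell transcriptomes is hard
because the p16 transcript is short, lowly expressed and only partially
captured, and because the downstream claims — that p16-high cells carry a
functional-maturation gene program, respond more strongly to interferon,
and reorganise their chromatin — rest on a long chain of computational
steps. `senoscore` implements that chain as a tested, reusable library:

* **QC and transforms** — cell filters (detected genes, UMI, mitochondrial
  ratio, complexity `log10(genes)/log10(UMI)`), expression
  `Ex = log2((CPM/10) + 1)`, gene filtering (`Ex > 3.5` in ≥ 2% of cells),
  and per-gene scaling `Es`.
* **Expression recovery** — a Gamma–Poisson empirical-Bayes scheme: counts
  are `Poisson(s_c · λ)` with a Gamma prior whose mean is predicted from the
  principal components of the log-normalised matrix and whose variance is
  `φ_g · μ̂²` (per-gene ML dispersion). The posterior mean
  `λ̂ = (y + 1/φ_g) / (s_c + 1/(φ_g μ̂))` interpolates between observation
  and prediction, and a per-gene reliability weight `w_g` shrinks
  correlations of noisily recovered genes.
* **Signatures and module scores** — genes ranked by the reliability-adjusted
  correlation `r·w_g·w_marker` to the marker; top-N (100/250/500) signatures;
  per-cell scores `SC = mean(Es over G) − mean(Es over C)` against
  expression-matched control sets; signature–signature Pearson matrices;
  percentile classification of cells (70/30 for transcript levels, 80/20 for
  staining intensities).
* **Hurdle differential expression** — per-gene two-part models (logistic on
  detection, Gaussian on `Ex` given detection) with donor/technology and
  cellular-detection-rate covariates, combined likelihood-ratio tests,
  Benjamini–Hochberg correction, and 95% fold-change CIs from 150 cycles of
  resampling 500 cells per class.
* **Enrichment** — weighted-KS preranked GSEA with a random-gene-set null and
  NES/FDR, plus upper-tail hypergeometric over-representation.
* **Chromatin classification** — active promoters (H3K27ac ∧ ATAC ∧ H3K4me3
  within ±2 kb of a TSS), enhancers (H3K27ac ∩ H3K4me1 outside promoter
  windows), nearest-gene linking, a simplified median-of-ratios + NB-GLM
  differential region test (`P_adj < 0.05`, `|FC| > 1.5`), PWM motif scanning
  with an exact dynamic-programming null, CTCF site categorisation
  (promoter / enhancer–promoter intervening within 200 kb / TAD boundary /
  other) and a hypergeometric test for upregulation of genes linked to
  boundary sites that lose CTCF binding.
* **Synthetic data** — generators that plant all of the above structure
  (latent senescent state, low-capture marker, correlated modules, toy genome
  with promoter/enhancer/CTCF classes, boundary-loss→upregulation coupling,
  intensity tables) with truth tables, so every stage is testable offline.

## Worked example

```python
import numpy as np
from senoscore import syndata, qc, recovery, signature

cfg = syndata.SimConfig(seed=1)          # 2000 cells x 2000 genes, defaults
pop = syndata.generate_cell_population(cfg)
cm = qc.CountMatrix.from_population(pop)

print(f"marker detected in {qc.detected_fraction(cm, 'CDKN2A'):.1%} of cells")

kept = qc.filter_cells(cm, qc.compute_cell_qc(cm), "tenx")
ex = qc.filter_genes(qc.transform_ex(kept))
sub = kept.subset(gene_mask=np.isin(kept.gene_names, ex.gene_names))

rec = recovery.recover_expression(sub)
ranking = recovery.rank_genes_by_marker(rec, "CDKN2A")
sig = signature.build_marker_signature(ranking, N=100)

module = set(pop.gene_meta.index[pop.gene_meta["module"] == "maturation"])
print(f"top-100 signature: {len(set(sig.genes) & module)} of 100 genes "
      f"from the planted maturation module")

labels = signature.classify_cells_by_value(
    rec.to_frame().loc["CDKN2A"], upper_pct=70, lower_pct=30)
sen = pop.cell_truth["senescent"].reindex(labels.labels.index)
print(f"senescent fraction among marker-high cells: "
      f"{sen[labels.labels == 'high'].mean():.1%} "
      f"(vs {sen.mean():.1%} overall)")
```

prints

```
marker detected in 13.8% of cells
top-100 signature: 99 of 100 genes from the planted maturation module
senescent fraction among marker-high cells: 72.3% (vs 21.7% overall)
```

The marker is detected in ~14% of cells even though 22% are senescent —
that is the planted partial capture. Despite it, the recovered-expression
ranking reconstructs the planted marker-correlated module almost perfectly,
and marker-high cells are strongly enriched for the true senescent state.

A full end-to-end run (simulation → QC → recovery → signatures →
classification → DE → enrichment → chromatin) with provenance tracking:

```bash
senoscore run --seed 0 --out pipeline_out
```

Other subcommands (`simulate`, `qc`, `rank`, `classify`, `diffbind`,
`promoters`, `enhancers`) operate on a fixtures directory; see
`senoscore --help`.

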