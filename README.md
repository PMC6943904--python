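# hfomics

Multi-level transcriptomic analysis of human heart-failure (HF)
progression, packaged as a tested, reusable pipeline.  It is aimed at
computational biologists who want to run — or stress-test — the full
analysis chain that links bulk expression profiles of failing left
ventricles to a candidate plasma biomarker:

1. **Preprocessing** — expression filters (mRNAs below 1 FPKM in more
   than 80% of samples removed; lncRNA candidates ≥ 200 nt with ≥ 2
   exons; miRNAs with > 10% missing measurements dropped) and PCA QC.
2. **Differential expression** — per-gene Welch t-test on log2(x+1) with
   Benjamini–Hochberg adjustment; a gene is DE when p_adj < 0.05 and
   |log2FC| > 1, with log2FC = log2((x̄_HF + 1)/(x̄_ctl + 1)).
3. **Regulatory networks** — consensus miRNA targets (≥ 2 prediction
   tools, or experimentally validated) filtered by Spearman correlation
   over HF samples (ρ < 0, p < 0.05 for miRNA→mRNA; p < 0.05 either sign
   for lncRNA–mRNA and miRNA–lncRNA), and enumeration of
   miRNA–lncRNA–mRNA feed-forward loops (FFLs).
4. **Fibrosis gene selection** — an in-repo coordinate-descent lasso,
   min_{β,b0} (1/2n)‖y − b0 − Xβ‖² + λ‖β‖₁, regressing the Masson
   fibrosis percentage on standardised log2 expression of the DE genes,
   with λ chosen by 5-fold cross-validation.
5. **Survival / biomarker evaluation** — Pearson screening of expression
   against time to heart transplantation (HTx), Kaplan–Meier curves with
   the Mantel–Cox log-rank test for median-split groups, univariate Cox
   hazard ratios (Breslow partial likelihood), and ROC analysis of a
   plasma marker with the Youden-optimal cutoff.

Patient-level data of the kind this pipeline targets are not
redistributable, so the package ships a first-class synthetic cohort
generator (`hfomics.simulate`) that emulates the study design — 21 HF vs
9 control discovery samples, fibrosis histology for 18 of 21, a
139-patient plasma cohort split 29 (≤ 1 year to HTx) vs 110 — with
planted DE genes, miRNA repressions, lncRNA co-regulations, FFL triples,
a sparse linear fibrosis model and a survival-driving marker gene, all
recorded in a ground-truth object for recovery testing.

## Worked example

Run the bundled synthetic demo end to end (about 10 s):

```bash
hfomics run-all --seed 42 --outdir demo_out
```

which prints the per-stage manifest:

```
preprocess: {'n_mrna': 500, 'n_lncrna': 120, 'n_mirna': 150}
differential_expression: {'n_de_mrna': 49, 'n_de_lncrna': 12, 'n_de_mirna': 17}
network: {'n_edges_mir_mrna': 10, 'n_edges_lnc_mrna': 46, 'n_edges_co_regulatory': 67, 'n_ffls': 5}
fibrosis: {'lambda': 0.22367271843698333, 'n_selected': 14}
survival: {'n_survival_genes': 2, 'marker': 'GENE0041', 'log_rank_p': 2.2874966058922065e-06,
           'auc': 0.8501567398119122, 'cutoff_ng_ml': 242.7288369080003, ...}
```

Reading the numbers: the cohort was simulated with 50 planted DE mRNAs,
of which 49 are called at the twofold/0.05 thresholds; 10 of the planted
miRNA→mRNA repressions survive the consensus-target and
negative-correlation filters at n = 21 HF samples (power rises to > 95%
at n = 50); 5 FFL triples are enumerated in the co-regulatory network;
the cross-validated lasso keeps 14 of 49 candidate genes for the
fibrosis model; and the marker-gene median split separates survival
(log-rank p ≈ 2.3 × 10⁻⁶), while the plasma marker classifies early
transplantation with AUC 0.85 in this particular cohort draw (designed
long-run AUC 0.789).  Outputs land in `demo_out/`: `de_*.tsv`,
`network_*.tsv`/`.sif`, `ffls.tsv`, `fibrosis_genes.tsv`,
`km_curves.tsv`, `roc_curve.tsv`, `summary.json` and a `manifest.json`
with per-stage counts and output checksums (reruns with the same seed
are byte-identical).

The same stages are available as library calls:

```python
from hfomics import CohortSpec, generate_cohort
from hfomics.de import de_test, de_genes
from hfomics.fibrosis import select_fibrosis_genes

ds = generate_cohort(CohortSpec(seed=42))
degs = de_genes(de_test(ds.mrna))
fit = select_fibrosis_genes(ds.mrna.hf_samples(), ds.fibrosis, degs, seed=0)
print(fit.lam, fit.selected)
```

and individually on fixture directories via the CLI subcommands
`simulate`, `preprocess`, `de`, `network`, `fibrosis`, `survival`,
`validate`.

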