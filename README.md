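# gcresponse

Predicting chemotherapy response in advanced gastric cancer from integrated
tumour profiles: immune signatures, copy-number signatures, targeted-variant
flags and clinical covariates feed a random-forest classifier that is
distilled into a single interpretable decision tree.

The package is aimed at translational cancer genomics groups who have
(or plan to produce) bulk RNA-seq, shallow whole-genome segment calls and
targeted panel sequencing from pre-treatment biopsies, and who want a
reusable, fully tested implementation of the analysis protocol — exercised
end-to-end on a synthetic cohort generator with planted ground truth, so no
controlled-access patient data is needed to develop against or validate.

## What it computes

- **Immune deconvolution** — per-sample leukocyte fractions `f` solve the
  non-negative least-squares problem `min ||y − R f||₂, f ≥ 0` against a
  6-cell-type reference matrix `R` (B, CD4⁺T, CD8⁺T, NK, monocytes,
  neutrophils), renormalised to the simplex. Ward clustering of the
  fractions defines immune subgroups named for their dominant cell type.
- **Copy-number signatures** — segment profiles are encoded into a 24-bin
  context matrix (6 total-CN classes × 4 length classes) and factorised by
  KL-divergence NMF, `C ≈ E S` with spectra `S` on the simplex; extracted
  spectra are assigned to a bundled catalog (CN1-like / CN4-like /
  CN9-like) by cosine similarity, and exposures are compared between
  response groups with the two-sided Mann–Whitney U test.
- **Variant rules** — MSI status from mutated-marker counts over BAT25 /
  MS05 / MS11 (0 → MSS, 1 → MSI-low, ≥2 → MSI-high), pharmacogenomic flags
  over GSTP1 / DPYD / CYP2A6 / UGT1A1, pathogen positivity at ≥10× the
  cohort-median read count, and Fisher exact association tests.
- **Response model** — features are assembled into one table with
  RECIST-style labels (PR/CR → Responder; SD/PD → Non-responder); a
  shadow-feature (Boruta-style) wrapper confirms all-relevant features by a
  Bonferroni-corrected binomial test on importance "hits"; a bagged-tree
  ensemble is trained on the confirmed features, scored by the rank-statistic
  AUC (out-of-bag and held-out), and distilled into a single
  cost-complexity-pruned representative tree selected by fidelity to the
  ensemble's predictions.
- **Gene-set scoring and survival** — weighted Kolmogorov–Smirnov enrichment
  with a gene-permutation null on Welch-t-ranked genes, mean-z signature
  scores, the square-root-of-product neutrophil signature, Kaplan–Meier
  curves and the log-rank test.
- **Neutrophil subcluster analysis** — single-cell QC, log-normalisation,
  tumour-associated-neutrophil (TAN1–4, NETosis) marker scoring, cosine
  annotation of subclusters against reference states, and per-sample
  pro-/anti-tumour role fractions.

## Worked example

```python
import gcresponse as g

cohort = g.simulate_cohort(seed=7)            # 65 samples, planted truth
model = g.ChemoResponseModel.from_cohort(cohort, seed=7, boruta_max_iter=40,
                                         boruta_trees=80, n_estimators=300)
results = model.fit()
print(results.summary())
```

```
Chemotherapy response model
============================================================
samples (train/test):      45/20
features assembled:        42
Confirmed / Tentative / Rejected: 4 / 2 / 36
selection iterations:      40
ensemble trees:            300
AUC (train, out-of-bag):   0.974
AUC (held-out test):       0.912
accuracy (held-out test):  0.850
distilled tree fidelity:   0.900
tree features used:        cn_Sig2_CN9-like, fraction_CD4T, fraction_Neutrophils
------------------------------------------------------------
top features by ensemble importance:
  fraction_Neutrophils                     0.4051
  fraction_CD4T                            0.3566
  cn_Sig2_CN9-like                         0.1303
  subgroup_Neutrophils                     0.1080
```

Reading the output: of 42 assembled features, the selection loop confirmed
4 as relevant; the ensemble separates held-out Responders from
Non-responders with AUC 0.91, and the distilled tree reproduces the
ensemble's held-out predictions 90% of the time using the neutrophil
fraction, the CD4⁺ T-cell fraction and the CN9-like signature exposure —
the planted drivers of response in the synthetic cohort. The model card,
ROC table and tree renderings are exported by `results.save_model_card()`,
`results.plot_roc()`, `results.tree.to_text()` / `to_dot()`.

The same protocol runs from the shell:

```bash
gcresponse simulate --seed 7 --outdir cohort/
gcresponse all --indir cohort/ --seed 7 --outdir run/   # or omit --indir to simulate
```

## Layout

```
src/gcresponse/
  io.py          readers/writers (TSV/SEG/CSV/GMT) + expression transforms
  synthetic.py   cohort and single-cell generators with planted truth
  immune.py      NNLS deconvolution, subgroups, Welch ranking, GSEA, scores
  cnsig.py       CN context encoding, KL-NMF, catalog matching
  variants.py    MSI / PGx / pathogen rules, Fisher association
  response.py    feature assembly, Boruta-style selection, RF + distillation
  neutrophil.py  single-cell QC, marker scoring, cosine annotation, roles
  survival.py    Kaplan–Meier, log-rank, median splits
  cli.py         stage-wise and end-to-end command line
docs/methods.md  model assumptions, parameter choices, limitations
```
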