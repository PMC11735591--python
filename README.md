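# jointica

Joint independent component analysis (joint ICA) for multimodal structural
neuroimaging: fuse grey-matter (GM) feature maps with streamline-weighted
FA white-matter (WM) connectomes into components that span both tissues,
check their stability with ICASSO, attribute them to atlas regions and
connectome edges, and relate their subject loadings to clinical phenotype
and cognition. Built for the study design of multiple-sclerosis covariance
analyses — ~90 subjects in three phenotypes (RRMS/SPMS/PPMS), a 121-region
DKT-style parcellation, 121×121 connectomes — and for anyone asking whether
*joint* GM+WM patterns explain cognitive outcomes better than either tissue
alone.

## The model

With `X` the subjects × features matrix of concatenated, variance-balanced
GM and WM blocks,

    X = A S

where `A` (subjects × C) is a single loading matrix shared by both
modalities and each row of `S` (C × features) is a source map with a GM
part and a WM part. `Aᵀ` tells you *who* expresses a pattern; `S` tells you
*where* it lives. Estimation is FastICA on PCA-whitened data (features as
samples); stability is assessed by rerunning the decomposition from
bootstrap resamples and random initialisations, clustering all estimates by
|correlation|, and summarising each cluster with the quality index
Iq = mean intra-cluster − mean extra-cluster similarity. Component anatomy
comes from |z| > 5 thresholding of GM maps (regions with ≥ 5% suprathreshold
features contribute) and the two-sided 99% normal bound (|z| ≥ 2.576) on WM
edge maps. The statistical battery includes cohort z-scored cognitive
domain scores, Spearman and age/sex-adjusted partial Pearson correlations,
ANCOVA with covariate-adjusted Tukey HSD, AIC-stepwise regressions with
forced covariates, likelihood-ratio model comparisons, and
Benjamini–Hochberg FDR.

No cohort of this kind is openly deposited, so the package includes a
synthetic-cohort generator (`jointica.simulate`) that plants known joint
sources, group structure, and loading-driven cognition — every downstream
stage can be validated against ground truth. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
from jointica import SimConfig, generate_dataset, jointica_fit, match_components

dataset, truth = generate_dataset(SimConfig(k_sources=4, seed=7))
dec = jointica_fit(dataset.gm, dataset.wm, n_components=4, seed=7)
report = match_components(truth, dec)
print(report.to_frame().round(4))
```

prints (from `examples/02_joint_ica_recovery.py`):

```
 true_source  component  loading_abs_corr  gm_source_abs_corr  wm_source_abs_corr
           0          0            0.9998              0.9900              0.9899
           1          1            0.9999              0.9890              0.9896
           2          2            0.9998              0.9875              0.9883
           3          3            0.9998              0.9882              0.9889
```

Each row is one planted source matched (Hungarian assignment) to one
estimated component: at SNR 5 the shared loadings and both modality
patterns are recovered almost exactly. The stability analysis on the same
cohort (`examples/03_icasso_stability.py`) prints

```
SNR  5.0: Iq = [0.901, 0.893, 0.998, 0.998]
SNR  0.2: Iq = [0.161, 0.178, 0.116, 0.118]
```

— compact clusters for every component at realistic noise, collapse when
the signal is buried. The `examples/` directory walks through each
capability: cohort simulation, recovery scoring, stability, attribution
with directionality arrows, and the cognition battery with joint vs
single-tissue model comparison.

A thin CLI covers batch runs:

```bash
jointica simulate --out cohort/ --seed 7
jointica fit --gm cohort/gm_features.csv --wm cohort/wm_features.csv \
             --components 20 --seed 7 --out fit/
jointica run-all --out run/ --seed 7
```

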