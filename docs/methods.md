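# Methods

`jointica` implements a multimodal fusion analysis for structural
neuroimaging of multiple sclerosis cohorts: grey-matter (GM) feature maps
and streamline-weighted fractional-anisotropy (FA) white-matter (WM)
connectomes are decomposed together into joint components with a single
subject-loading matrix, component stability is assessed by repeated-run
clustering, components are attributed to parcellation regions and edges,
and subject loadings are related to clinical phenotype and cognition.
Because cohort MRI data of this kind are not openly deposited, the package
ships a synthetic-cohort generator with planted ground truth; every claim
the test suite and `scripts/acceptance.py` make is measured against that
ground truth.

## The fusion model

Let `X` be the subjects × features matrix formed by concatenating the GM
block (voxel- or ROI-level features) and the WM block (the strict upper
triangle of each subject's R×R combined connectome, R(R−1)/2 edge features;
7260 for R = 121). The model is

    X = A S,    A ∈ R^{n×C},  S ∈ R^{C×F}

with one shared loading matrix `A` across both modalities and source rows
`S` that split into a GM part and a WM part at the recorded concatenation
boundary. Estimation is spatial ICA with features as samples: `Xᵀ` is
PCA-whitened to `C` dimensions and unmixed by the FastICA fixed-point
iteration (logcosh contrast, symmetric decorrelation, tolerance 1e-6, at
most 1000 iterations, random orthonormal initialisation from a seed).
`A @ S` equals the rank-C PCA reconstruction of the preprocessed data to
machine precision regardless of ICA convergence; convergence failures are
flagged on the result rather than raised.

Two conventions make runs reproducible and comparable: each source row is
signed so its largest-magnitude element is positive, and components are
ordered by descending variance explained. Direction labels with anatomical
meaning (the ↑/↓ arrows) are assigned afterwards from correlations with
tissue values, not from the algebraic sign.

### Preprocessing and modality balancing

Each feature is centered across subjects. Each modality block is divided by
the square root of its total feature variance, so both blocks carry unit
total variance into the joint matrix. Without this the 7260-edge WM block
would dominate a 2000-feature GM block by feature count alone. The
balancing scheme is a package design choice (toolboxes that implement this
fusion do not document theirs); the record of centers and scales is stored
and invertible.

### Single-tissue models

`single_tissue_ica` applies the identical centering, scaling and FastICA
path to one modality. It deliberately omits any cross-modality coupling
term in the update rule: it is plain per-modality ICA, used as the
comparison model family, and is labelled as such.

## Connectome features

The WM input per subject is a pair of R×R symmetric, zero-diagonal,
nonnegative matrices: streamline counts and mean tract FA. They are
combined edgewise as `w_ij = fa_ij · sc_ij` (streamline-weighted FA); a
`proportional` switch divides by the subject's total streamline count for
the alternative reading in which weights are FA contributions per unit of
total connectivity. Edges with zero streamlines always get weight zero.
Edge order is the row-major strict upper triangle, 0-based internally;
interchange files label edges by ROI-name pairs to avoid index-base
confusion. Whether streamline counts should be log-transformed before
combination is unknown for the emulated pipeline; no transform is applied.

## ICASSO stability

`run_icasso` refits the decomposition M times (default 20; seeds
`base_seed … base_seed+M−1`), pools all M·C source estimates, computes
pairwise similarity as |Pearson correlation| of source rows, clusters with
average-linkage agglomerative clustering on distance 1 − |corr| cut at C
clusters, and reports per cluster

* the quality index `Iq` = mean intra-cluster similarity (off-diagonal)
  minus mean similarity to estimates outside the cluster, and
* the centrotype, the member with the largest summed intra-cluster
  similarity (ties break to the lowest run index).

`select_centrotypes` assembles the representative decomposition from the C
centrotypes, recomputing loadings by least squares of the preprocessed data
on the centrotype sources and re-applying the sign/order convention.

What varies between runs matters. With random initialisation only, FastICA
converges to the same fixed points from almost any start once
feature-samples are plentiful (~9k here), so `Iq` stays near 1 at any noise
level — the index then measures algorithmic convergence, not statistical
reliability, and is uninformative about component quality. The default is
therefore the canonical ICASSO setting `resampling="both"`: each run refits
on a bootstrap resample of the features with a fresh initialisation, and the
estimated unmixing is re-applied to the full data so estimates stay
comparable. Measured on the default cohort, this separates the regimes
cleanly (all `Iq` ≥ 0.89 at SNR 5; minimum `Iq` ≈ 0.1 at SNR 0.2), while
`resampling="randinit"` remains available for the convergence-only
question.

## Attribution thresholds

* GM: each component's GM source part is z-scored across features (sample
  SD) and thresholded at |z| > 5 (strict, as written). A region contributes
  when ≥ 5% of its features are suprathreshold — boundary inclusive, with
  the region's own feature count as denominator (the alternative,
  component-size denominator, would make overlap depend on how many other
  regions a component touches).
* WM: the z-scored edge vector is thresholded at the two-sided 99% normal
  confidence bound, |z| ≥ Φ⁻¹(0.995) ≈ 2.5758; surviving edges map back to
  unique ROI pairs through the upper-triangle indexing.
* Directionality: Spearman correlation (average ranks for ties) between a
  region's TIV-normalised volume — or an edge's combined weight — across
  subjects and the component's loading column; ↑ for positive, ↓ for
  negative, with the two-sided p.

Note that |z| > 5 on a z-scored map bounds the surviving fraction at
1/25 = 4% of features (Chebyshev), so a source spread over more than ~4% of
features can never have all of its support survive; the generator's default
source sparsity (below) respects this.

## Statistics

* **Cognitive domain scores**: raw test scores are z-scored against the
  cohort (sample SD) and averaged within each domain — information
  processing speed, verbal memory, visual memory, executive function,
  working memory; two tests per domain in the synthetic battery.
* **Spearman associations** of loadings with whole-brain tissue summaries
  (TIV-normalised cortical and deep GM volume, mean FA over connected
  edges, total streamline count).
* **Partial Pearson** of loadings with domain scores: both variables are
  residualised on [1, age, sex] by least squares and the residuals
  correlated; p from t with n − 2 − k df. Sex is coded F=0/M=1; age in
  years, uncentered (affects only intercepts).
* **ANCOVA + Tukey HSD**: group F from the partial sum of squares of the
  phenotype factor in `outcome ~ group + age + sex`; post-hoc contrasts on
  covariate-adjusted means via the studentized-range distribution with the
  model residual df (Tukey–Kramer under unequal group sizes). The nested
  SSR difference is clamped at 0 to absorb catastrophic cancellation when
  the reduced model fits exactly.
* **Stepwise regression**: bidirectional search by AIC from the
  forced-covariate model (age, sex never removed); single best move per
  step, ties to the earlier-indexed candidate; collinear candidates skipped
  with a warning. AIC is the criterion because the emulated analysis
  environment's standard stepwise defaults to it; the criterion is a config
  parameter.
* **Likelihood-ratio comparison**: statistic 2·|llA − llB| with Gaussian
  OLS log-likelihoods (= n·ln(RSS_worse/RSS_better)), df = |Δ params| with
  a floor of 1, p from the chi-square upper tail. Joint vs single-tissue
  models are generally non-nested; the comparison is still reported, with
  `non_nested: true` in the output rather than a silent correction, since
  the chi-square reference is then only an approximation.
* **FDR**: Benjamini–Hochberg step-up. Families are per analysis table —
  per tissue-summary column across components for the Spearman table, per
  cognitive domain across components for the partial-correlation table;
  both family modes are config-exposed because the emulated analysis does
  not state its family structure.

## The synthetic cohort generator

The generator emulates the study design, not MRI physics:

* **Cohort**: 90 subjects split 53:22:14 (largest remainder) across RRMS,
  SPMS, PPMS; ages drawn per group from N(41.9, 10.1²), N(54.0, 7.24²),
  N(50.9, 8.99²) years clipped to [18, 65]; sex Bernoulli at the 29:60
  male:female cohort ratio; TIV ~ N(1450, 120²) ml.
* **Parcellation**: 121 regions, 101 cortical + 20 deep GM; GM features
  assigned to regions in contiguous near-equal blocks.
* **Sources**: each of k sources has a sparse GM pattern (default 2% of
  features, disjoint supports, magnitudes bounded below by 1 with random
  signs, unit norm) and a WM pattern activating the mutual edges of a small
  ROI set (clique size derived from the same sparsity, ≈ 2% of edges) —
  a covarying subnetwork. The 2% default keeps every active feature's |z|
  above the GM threshold of 5 in the noiseless limit (min |z| ≈ 5.6); at 5%
  sparsity even a noiseless constant-magnitude source peaks at
  |z| = 1/√0.05 ≈ 4.5 and planted support would be undetectable by
  construction. Per-source modality confinement (`"gm"`, `"wm"`, `"joint"`)
  lets scenarios plant tissue-specific patterns.
* **Loadings**: standard normal columns, standardized, with phenotype mean
  shifts on the first two sources so group contrasts have signal.
* **Noise and SNR**: `snr` is the ratio of the signal SD measured over the
  features a source actually touches to the additive noise SD. Measuring
  over all features would let the ~98% zero columns dilute the signal SD
  and make a configured SNR of 5 behave like ~20. Default 5 per modality.
* **Connectome factoring**: the combined WM row sits on a fixed positive
  baseline (constant across subjects, removed by centering); per-subject FA
  edge values in (0.05, 0.95) factor each combined weight exactly into
  FA × streamline count, so the feature-builder path reproduces the WM
  matrix bit-for-bit.
* **Cognition**: domain score = β·loadings + age-slope·age + noise, with
  noise variance set so each raw domain score has variance ≈ 1 before
  z-scoring (matching the cohort-z-score convention); default age slope
  −0.015 z/year. Raw test scores are affine transforms of the domain score
  plus test noise, on plausible instrument scales.

What the generator does **not** emulate: registration error, lesions,
partial-volume effects, spatial autocorrelation of noise, non-Gaussian
measurement error, missing data. Passing tests therefore demonstrate that
the algorithms are implemented correctly and behave as theory predicts on
data satisfying the model's assumptions — not that real cohort effect sizes
would be recovered.

## Validation scenarios and problem sizes

The acceptance checks run at the study scale (n = 90, 2000 GM features,
121 ROIs / 7260 edges, k = 4, C = 4) with 10-run ICASSO, 10-seed
attribution sweeps, 25-seed model-comparison sweeps and 500-fit null
calibration — sizes chosen so the whole battery completes in a few minutes
on one CPU while keeping Monte-Carlo error well below the decision margins.

Two model-comparison scenarios probe the qualitative pattern of interest:

* **Mixed-tissue cognition**: a domain driven by one GM-confined plus one
  WM-confined source (β = 0.45 each) at SNR 5. Each single-tissue model can
  express only half the signal, so the joint model's adjusted R² should win
  essentially always (measured 25/25 seeds). With all-joint sources the
  three models recover the same loadings and the comparison is a coin flip
  — that variant is uninformative and not used as a check.
* **WM-confined cognition**: a domain driven only by a WM-confined source
  (β = 0.6) at SNR 0.5. The GM block contributes pure noise to the joint
  estimate of that source, so the WM-only model wins (measured 23/25
  seeds). This dilution advantage exists only when noise matters: at SNR 5
  the joint and WM estimates are both near-perfect and tie. The noisy
  regime is the scientifically relevant one for this scenario — real
  voxel/edge-level effect sizes are weak, which is why tissue-specific
  models can outperform fusion on tissue-specific functions.

## Numerical and degenerate-input choices

* Constant maps, zero-variance modalities, singular designs, out-of-range
  p-values and misaligned subject lists raise validation errors naming the
  problem; non-convergence of a FastICA run is a flag, and in ICASSO such
  runs are excluded from clustering with a warning.
* `fastica_fit` accepts C ≤ min(n, F); the joint and single-tissue entry
  points enforce C ≤ min(n−1, F) because feature centering removes one
  degree of freedom from the subject space.
* All randomness descends from one root seed with fixed stage offsets
  (simulation: root; single ICA fit: root+1000; ICASSO base: root+2000);
  reruns with the same configuration are byte-identical for deterministic
  stages.

## Known limitations

* The joint vs single-tissue likelihood-ratio test is non-nested; p-values
  are approximations and flagged as such.
* Plain per-modality ICA stands in for coupled multimodal variants with an
  explicit inter-modality term in the update rule; the comparison family is
  labelled accordingly.
* Iq from bootstrap ICASSO measures reproducibility under resampling of
  features, which assumes exchangeable features; spatially autocorrelated
  real maps violate this mildly (block bootstrap would be the refinement).
* The generator's disjoint sparse supports make attribution clean by
  design; overlapping real anatomy would lower the Jaccard agreement
  reported by the validation harness.
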