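# Methods

This note documents the models, defaults and numerical choices behind
`varicourse`, and what the synthetic benchmark does and does not establish
about real data.

## Quantification and filtering

Counts are converted to TPM per sample: `rate_g = counts_g/length_g`,
`TPM_g = 10⁶·rate_g/Σ rate`. Counts are accepted as floats so fractional
multi-mapping counts pass through. Four filters precede every variability
statistic, applied per analysed time-point:

1. mean TPM over **all loaded samples** ≥ 5 (computed over whatever samples
   are present, so a partial run is explicit rather than silently different);
2. gene length ≥ 150 bp;
3. strictly fewer than 5 individuals with TPM 0 at the time-point;
4. mean TPM at the time-point ≥ 5.

Mean thresholds are inclusive (`≥ 5`), the zero rule strict (`< 5`). The
"averaged expression" is the arithmetic mean of TPM (not log-TPM); that
interpretation is flagged here rather than buried in code.

## Trend fit

CV² (unbiased sample variance over squared mean, across individuals) is
regressed on 1/μ with a gamma-family GLM, identity link, by IRLS
(statsmodels; convergence `tol = 1e-8`, ≤ 100 iterations, OLS start values).
An exact interpolating fit (zero deviance) is accepted as converged; any
failure falls back to OLS on (CV², 1/μ) with a warning and is recorded in
the fit metadata. The fit subset is genes with mean above `minMeanForFit`,
which defaults to the 40th percentile of means among genes with CV² > 0.05.
The CV² floor is lower than single-cell conventions because
inter-individual CV² is much smaller than inter-cell CV²; both knobs are
exposed (`fit_quantile`, `cv2_floor`, or an explicit `min_mean_for_fit`).
Fits on fewer than 50 genes, or with a single distinct mean, are refused as
unidentifiable. No spike-in-based technical trend is fitted: the trend uses
endogenous filtered genes only.

## Overdispersion test and gene sets

With m individuals and minimum biological CV of 10%
(`minBiolDisp = 0.01`): `cv2th = α₀ + minBiolDisp + α₀·minBiolDisp`,
`denom = (μ·a₁ + μ²·cv2th)/(1 + cv2th/m)`, statistic
`(m−1)·μ²·CV²/denom ~ χ²(m−1)` under the null, upper tail. BH adjustment,
HVG call at `p_adj < 0.10` (strict inequality). Genes failing pre-tests
(zero CV², non-positive denominator from a pathological fit) are excluded
with a warning record, never silently dropped; corrected CV² of a zero CV²
is NaN, never −∞. LVGs are the exact bottom-n (default 1,000) by corrected
CV² with lexicographic gene-ID tie-break; random sets are seeded simple
random samples without replacement, size-matched to the HVG set.

The detector's operating characteristics at the study design (m = 14,
2,000 genes, 10% planted at 4× trend) are measured by the test suite: the
false-discovery proportion against planted truth is far below the nominal
10% (the `minBiolDisp` offset makes the test conservative), while mean
sensitivity is ≈ 0.5 — at 14 individuals a 4-fold CV² excess is simply a
moderate signal for a χ²₁₃ statistic after BH. Both numbers are properties
of the method at this design, not implementation artifacts; the generator's
realized CV² was verified to sit within ~3% of its targets.

## Time-course structures

* **Sharing**: cell (i, j) is 100·|HVG_i ∩ HVG_j|/|HVG_i| (row-conditioned;
  the resulting asymmetric matrix is symmetrised implicitly by averaging
  ordered pairs in the block summaries). Jaccard is available via config.
* **Day/night blocks**: the first half of the time-points is day, the
  second night; the last day time-point (the ZT12 analogue, harvested at
  dusk) behaves like a night point and is excluded from the block averages
  by default where enough time-points remain.
* **Clustering**: hierarchical, distance 1 − Pearson on corrected-CV²
  profiles, complete linkage by default (the default of the R `hclust`
  convention this follows), cut to k = 4. Constant or incomplete profiles
  are unlabelled with a warning. Linkage and k are configurable — see
  limitations below for why Ward is worth considering.
* **Profile coupling**: Spearman (config: Pearson) correlation per gene
  between mean-normalised expression and corrected CV² profiles, split into
  significant-positive / significant-negative / non-significant at p ≤ 0.05.
* **Subsampling saturation**: for subset sizes k < M the full pipeline
  (filter → trend refit → corrected CV²) is rerun per draw and compared to
  the full-M values by Spearman correlation over the jointly retained genes.

## Enrichment stages

Wilcoxon rank-sum (scipy's exact small-sample path) for quantitative
features, with a percentile envelope of random-set medians; one-sided
hypergeometric upper-tail with BH for set overrepresentation (the standard
convention for TF-target and category tests, consistent with the Fisher
test used for families); two-sided Fisher exact per TF family; chi-square
with Yates continuity correction for 2×2 chromatin-mark presence tables
(mirroring R's `chisq.test` default; configurable), with automatic Fisher
fallback when an expected cell is below 1. Tissue specificity is Shannon
entropy in bits of the gene's relative expression across tissues
(`H = −Σ p_t log₂ p_t`, zero tissues contributing 0 in the limit; all-zero
genes filtered to NaN); low H = tissue-restricted. The size-matched control
restricts sets to a 1,100–1,400 bp length window.

The fragmentation control partitions a gene into contiguous fragments with
lengths drawn uniformly in 250–300 bp (the final fragment absorbs a short
remainder, so every fragment is ≥ 250 bp), splits each individual's count
multinomially with probabilities proportional to fragment length (counts
conserved exactly), and re-runs the full TPM → filter → trend → test chain
on the fragmented matrix. Because TPM is length-normalised, a fragment's
expected TPM equals its parent's and the multinomial adds only
O(1/(p·count)) extra CV²; measured fragment–parent HVG concordance on
clearly-called genes exceeds 95%.

## Synthetic data generator

The generator emulates the study design end-to-end: 12 time-points
(ZT2–ZT24) × 14 individuals (168 transcriptomes; 16 individuals supported
for saturation analyses), diurnal mean profiles, NB inter-individual noise
on a CV² = a₁/μ + α₀ trend, planted HVGs in day/night/always clusters, and
planted feature associations. Choices that matter:

* **Noise model**: negative binomial on counts with per-gene size chosen by
  inverting `CV²_target = 1/mean_count + 1/size` at the expected depth
  (Poisson when the target is below the shot-noise floor). TPM
  renormalisation leaves a small approximation error; realized CV² matches
  targets within a few percent.
* **Mean scale**: baseline means are log-uniform over `mean_range`
  (default 2–2000 TPM). Because TPM forces each sample to sum to 10⁶, only
  the log-range *ratio* survives renormalisation in a closed simulated
  transcriptome; three decades keeps both the shot-noise-dominated and the
  α₀-dominated regimes populated and makes the 5-TPM filters bite.
* **Biological heterogeneity**: each gene's dispersion is scattered around
  the trend by a log-normal factor (σ = 0.5 natural-log units, mean 1 so
  binned CV² still matches the trend). Real CV²–mean clouds scatter
  severalfold around their trend; without this, the corrected-CV² ranking
  of null genes is pure noise and subsampling-stability estimates are
  unrealistically pessimistic. Set `biological_cv2_sigma = 0` for the
  exactly on-trend null used in calibration simulations.
* **Diurnal profiles**: 40% flat, 30% day-peaking, 30% night-peaking
  sinusoids, amplitude 0.5 — enough to create day/night expression
  structure without zero-crossing means.
* **Library sizes**: log-normal with 10% CV around 5×10⁶, exercising TPM
  normalisation mildly.
* **Clusters**: planted HVGs are split round-robin over
  day (time-points 1–6) / night (7–12) / always masks; per-cluster CV²
  multipliers are configurable.
* **Features**: the annotation layer (lengths, introns, TF targets, marks,
  tissue profiles) is drawn separately from the count simulator's internal
  length bookkeeping, with multiplicative HVG-vs-null effect folds
  (defaults: length ×0.7, introns ×0.7 on a length-proportional Poisson
  rate, 2× TF-target odds for a quarter of 60 TFs, per-mark prevalence
  folds, Dirichlet tissue restriction). All folds at 1 make planted and
  null genes exchangeable, which the calibration tests verify.

What passing on synthetic data does **not** show: the generator has no
batch structure (the original analyses applied batch correction upstream),
no spike-ins, no read-level effects (mapping, duplicates), no correlated
gene modules beyond the planted clusters, and gene-wise independent noise.
Results on real data additionally depend on those factors.

## Problem sizes

Simulations in the test suite and the acceptance script use 2,000-gene
transcriptomes, 14–16 individuals and 1–12 time-points, with 20–50 seeded
replicates per property — large enough for the Monte-Carlo tolerances
asserted, small enough that the entire suite runs in well under a minute
per heavy test.

## Known limitations

* The exact fit-subset quantile/floor used in the original analyses is not
  recoverable; the defaults here are conventions and remain configurable.
* Complete-linkage clustering on 1 − Pearson cannot recover a *flat*
  variability archetype: Pearson centres profiles, so always-variable genes
  (constant corrected CV² plus noise) form a zero-signal cloud that
  complete linkage scatters into the day/night clusters (measured ARI ≈
  0.55 against planted truth at the default design). Ward linkage on the
  same distance recovers the partition far better (ARI ≈ 0.8) and is
  available via `linkage_method="ward"`; on real data, "always variable"
  genes have temporal structure of their own, which is why the same
  algorithm separates them there.
* At 14 individuals the overdispersion test is conservative and moderately
  powered for 4-fold CV² excess (see above); reported HVG sets should be
  read as high-confidence, not exhaustive.
* The Shannon-entropy stage uses relative expression across tissues; an
  absolute-expression variant would weight tissues differently.
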