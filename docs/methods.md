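# Methods

`cemsnorm` implements a workflow for making capillary-electrophoresis
mass-spectrometry (CE-MS) urine metabolome profiles comparable across runs
and years: it identifies *stable endogenous metabolite features* —
"housekeeping" (m/z, migration-time) features whose peak height barely
varies across healthy and diseased samples — and uses them as internal
standards to align migration times and normalize intensities of any new
sample against a fixed reference dataset. On top of the normalized
profiles it provides the point-mass-at-zero (PMV) quality-control
taxonomy and a Wilcoxon/Benjamini–Hochberg + RBF-SVM biomarker
discovery/validation chain.

## Data model

A *feature* is an (m/z, migration time) pair; its id renders as
`"<mz>/<mt>"` with six / three decimals. Peak height is the abundance
proxy. Zero intensities are missing by definition and stored as NaN
everywhere; a missing value is a PMV. All normalization mathematics runs
on log2 intensities, where multiplicative dilution is an additive
per-sample offset.

## Reference construction

Runs are restricted to the 520–3650 s migration-time window (bounds
inclusive; the excluded regions are salt- and noise-dominated), features
are grouped across runs by single-linkage within |Δm/z| ≤ 0.01 Th and
|ΔMT| ≤ 20 s (the consensus key is the group centroid; within-sample
collisions keep the larger peak), and only features present in ≥50% of
runs are retained. The grouping tolerances are package conventions: the
m/z tolerance mirrors the mass-match tolerance used for new samples, the
MT tolerance the peak-grouping bandwidth of the upstream peak picker,
whose settings are carried as provenance metadata only. Reference
building assumes the input runs were migration-time aligned upstream.

## Stable-feature selection

Two scores rank features by inter-sample stability:

* **Identity hyperline** (default). In the n-dimensional sample space a
  perfectly stable feature lies on the line x₁ = … = xₙ. The score is the
  Euclidean point-to-line distance, computed in closed form as
  d(v) = √Σⱼ (vⱼ − v̄)², which is what minimizing over a dense grid of
  points t·(1,…,1) converges to. The distance is invariant to translation
  along the line, so a uniform (dilution-like) shift does not penalize a
  feature — the reason the score is computed on log2 intensities.
* **Robust linear model residuals.** Each sample's abundances are
  regressed (Huber M-estimation, intercept included) on the per-feature
  median baseline; a feature's score is its largest absolute residual
  over the sample models (`mean` available as a milder aggregate). The
  hyperline route is the default because it needs no baseline
  assumption.

Only features with ≤10% missing across reference runs enter the candidate
pool (a standard must be broadly detectable); remaining gaps are filled
with the feature median before scoring. The first 1000 candidates in
ascending score order (ties broken by feature id) feed a forward
selection: for every prefix size k from 10 upward the whole matrix is
normalized with the prefix as standards and the variability metric

    M = MAD_j( median_i x_ij )

is computed — the unscaled median absolute deviation across samples of
the per-sample median normalized intensity (the consistency constant
would only rescale M without moving its argmin). The smallest k attaining
the minimal M wins; a normalization failure at some k records M = +∞ and
the search continues.

At desk scale the M(k) profile deserves a caveat: with a few hundred
features the metric's noise floor — the sampling error of a median over m
features, roughly σ̄/√m — exceeds the differences in standards' fit
error, so M(k) is nearly flat and the *size* of the selected set is
weakly identified even when the selected set contains essentially all
truly stable features and normalizes well. The package's tests therefore
assert recovery and normalization power, not a particular set size; with
thousands of features (the intended operating point) the minimum is
better determined.

## New-sample processing

1. **Window filter.** New samples use the 840–3000 s window (sodium-salt
   region and late tail excluded).
2. **Mass match.** Each sample feature is assigned to the nearest
   reference m/z within 0.01 Th; equidistant ties resolve to the smaller
   reference m/z. A coarse constant-offset pre-alignment plus a ±60 s MT
   gate (configurable, disable for mass-only matching) prevents
   cross-feature collisions. Unmatched features are excluded from
   downstream analysis but kept for audit.
3. **Migration-time alignment.** The matched internal standards seed a
   1-D k-means (k = number of matched standards, Lloyd updates, an
   emptied cluster keeps its center) over all feature MTs. Each cluster's
   offset is the reference-minus-observed MT of its seed standard; a
   LOESS curve of offset versus observed MT across the standards is
   applied to every feature, and the procedure is iterated (5 iterations
   by default). Because each cluster typically contains exactly one
   standard, a per-cluster curve would be underdetermined; the
   cross-cluster curve is this package's declared interpretation. With
   fewer than two standards a constant-offset fallback is used with a
   warning.
4. **Intensity normalization.** With ≥10 usable standards, a LOESS curve
   is fit through (reference log2 abundance of each standard — its median
   over reference runs — versus its observed log2 abundance); the
   correction c(x) = fitted(x) − x is subtracted in log2 from every
   matched feature at the feature's own reference abundance. Outside the
   standards' abundance range the correction is held constant at the
   boundary value (LOESS extrapolation is ill-defined, and an unclamped
   curve turns the boundary fit error into an unbounded correction).

All LOESS fits use degree-1 local polynomials with span 0.75 and one
robustifying iteration; below four points a plain linear fit replaces the
local regression. The span is a package default — the method the workflow
names does not fix one.

## QC and the PMV taxonomy

Per-feature CV uses the sample (n−1) standard deviation over the mean of
the observed raw intensities. In a two-group matrix each feature is
labelled `no_point_mass` (no missing value in either group), `consonant`
(the group with the strictly higher PMV proportion has the smaller
continuous-part mean) or `dissonant` (higher PMV proportion and higher
mean). Equal nonzero PMV proportions classify consonant: dissonance
requires the higher-PMV group to be established, which a tie cannot do. A
group with no observed values has an undefined continuous mean and is
treated as the smaller one. Consonance is the signature of
detection-limit censoring when missingness tracks abundance — in
particular when sample-level dilution drives both which values are lost
and where the observed means sit; dissonance flags candidate biological
absence. With identically distributed groups and a sharp detection
threshold the two labels are provably equally likely (survivors of both
groups come from the same truncated distribution), so a high consonant
fraction is evidence of abundance-coupled, i.e. technical, missingness
rather than a mathematical necessity.

## Biomarker discovery and validation

Only features detected in ≥75% of the samples of *each* group enter the
statistics. Discovery-cohort missing values are imputed with the
per-feature mean of the observed values in the sample's own group;
validation samples — whose group is unknown — use the per-feature mean
over all discovery samples, computed after discovery imputation so it is
defined for every biomarker. Two-sided Wilcoxon rank-sum tests (exact
when both groups have ≤20 samples and no ties, otherwise the
tie-corrected normal approximation; constant features get p = 1) are
adjusted by Benjamini–Hochberg, with adjusted p < 0.05 significant. The
significant features, standardized by their training mean/sd, train a
C-classification RBF SVM with C = 1 and γ = 0.03125; a decision score
> 0 predicts disease (a score of exactly 0 does not). The model stores
its support vectors, dual coefficients, intercept and preprocessing, so a
serialized model reproduces training scores bit-exactly. Evaluation
reports the confusion counts, sensitivity and specificity in percent
rounded to one decimal, the rank-based (Mann–Whitney) AUC with ties
counted half, and a percentile-bootstrap 95% CI (2000 resamples, seeded).

A caution on cross-validation under the null: leave-one-out accuracy of a
no-signal classifier on a balanced cohort is biased far *below* 50%,
because the held-out sample's class is always the training minority;
chance-level behavior should be checked on a held-out balanced set.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with one seeded generator behind every draw:

* log-normal base abundances, log2 ~ N(18.5, 2.8) (~5 orders of
  magnitude across ±3 sd);
* per-sample dilution, log2 offsets ~ N(0, 0.5), optionally plus a
  coherent disease-group offset (impaired urine concentration);
* 10% stable features at ~5% CV placed on abundance quantiles above the
  censoring zone (a standard that is often undetectable could not serve
  as one), the rest drawing per-feature log2 noise sd from a 0.45–1.2
  continuum — real metabolite CVs form a continuum, and a single shared
  noise level would make the forward-selection objective monotone by
  construction;
* 30 differential features at fold change 2.0 whose noise sd is drawn
  from 0.35–0.7 (CV ≈ 27–60%): a reproducible two-fold marker at cohort
  sizes of 15 vs 34 is, by power arithmetic, a moderate-variance feature;
* per-sample migration-time warps (constant shift, linear drift or a
  smooth low-frequency curve) and ≤0.002 Th m/z jitter;
* technical censoring as a logistic detection-probability curve (width
  1 log2 unit) around the intensity quantile 0.05 — a sharp threshold
  would destroy the abundance signal among surviving values;
* optional biological absence: an affected feature is missing in a random
  ~70% of one group's samples and elevated ~2× in the carriers, the
  bimodal excretion pattern that produces dissonant features.

Default cohort sizes mirror the application study: 15 vs 34 discovery,
7 vs 17 validation. Every missing cell carries exactly one mechanism
label (technical or biological) in the returned truth object, alongside
the planted scale factors, warps, stable/differential flags and recovery
metrics helpers.

What the generator does **not** emulate: raw spectra, isotope envelopes
and adducts, electrophoretic physics, correlated metabolite modules, or
drift in m/z calibration. Passing tests demonstrate that the algorithms
recover the structure they target under the stated statistical model; on
real data, matching and alignment additionally contend with peak-picking
artifacts and annotation ambiguity that are out of scope here.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 120–300 features and
16–73 samples with fixed seeds — sizes chosen so every stage, including
the exhaustive forward-selection sweep, is exercised end to end while the
whole suite stays quick on a laptop. Tolerances: hyperline closed form vs
grid oracle ≤1e-6 relative; BH vs brute force and AUC vs exhaustive pair
enumeration to machine precision; alignment recovery <1 s RMSE on
standards; dilution factors within 5% median; differential recall ≥80%
and held-out AUC ≥0.85 as seed medians. Degenerate inputs fail loudly:
empty MT windows warn, a sample with no mass matches, an all-missing
column, a constant RLM baseline, fewer than 10 usable standards, and
single-class training all raise errors.
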