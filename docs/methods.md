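# Methods

This note documents the statistical procedures `lipomir` implements, the
choices made where the underlying study protocol left details open, what
the synthetic-data generator does and does not emulate, and the numerical
conventions.

## 1. Quantification model

Each qPCR assay is calibrated by a linear standard curve
`Ct = b + m·log10(copies)` fitted by ordinary least squares to a serial
dilution of synthetic template (default 6 points spanning 10^6 → 10^1
copies).  The amplification efficiency is derived from the slope,
`E = 10^(−1/m) − 1`; a perfect-doubling assay has `m = −1/log10 2 ≈
−3.32`, `E = 1`.  Interpolation of a sample Ct on the fitted line already
adjusts for efficiency, so no second-stage correction is applied.
Curves with non-negative fitted slope, or with fewer than two distinct
dilution points, are rejected as unusable assays.

**Replicate handling.**  Technical replicates are averaged in Ct space
before interpolation (Ct noise is approximately additive on the cycle
scale).  A well with at least one detected replicate uses the detected
mean; only an all-non-detect well is a non-detect.  Averaging in copy
space instead would weight replicates multiplicatively and inflate
missingness at the detection margin.

**Spike-in normalization.**  Three spike-in control RNAs of known input
quantity are carried through the same calibration.  The per-sample
normalization factor is the geometric mean over controls of
observed/expected copies — scale-symmetric for log-distributed
quantities — and every copy number in the sample is divided by it.  When
spike-ins carry a planted multiplicative factor and no noise, this removes
the factor exactly (enforced to 1e-9 in the tests).

## 2. Preprocessing

* **Detection filter**: an assay is retained when its detection rate over
  all samples (classes pooled) is ≥ 0.90; the boundary is inclusive
  (exactly 90% is kept), reading "detected in less than 90% … excluded"
  literally.
* **Global mean normalization**: detected copies are log2-transformed and
  each sample is centered on its mean over the *detected* entries of the
  filtered panel.  This makes the matrix invariant to any per-sample
  multiplicative scaling left over after spike-in normalization.
* **Imputation**: per miRNA, mean `m` and sample SD `s` (ddof = 1) are
  computed once over the detected values (single pass — replacements never
  feed back into the statistics, keeping the rule deterministic and
  order-independent).  Missing values and values below `m − 3s` become the
  minimum observed value inside `[m − 3s, m + 3s]`; values above `m + 3s`
  become the maximum inside the window.  A miRNA with no value in its
  window signals corrupt input.  Imputation runs after normalization: the
  rule feeds feature selection, which operates on the analysis (log2,
  centered) scale.

The filter → normalize → impute composition is idempotent on its own
output whenever no *detected* value lies outside its miRNA's 3-SD window
(the property test uses bounded noise for exactly this reason): clipping a
detected outlier shifts the window statistics on re-application, so exact
idempotency cannot hold in general.

* **Exploration**: PCA via SVD of the column-centered matrix (variance
  fractions are eigenvalue shares), and agglomerative clustering of
  samples with correlation distance and average linkage.  Distance and
  linkage are recorded in the output because the choice is conventional,
  not prescribed.

## 3. Panel selection

For a binary contrast with positive class the malignant /
less-differentiated label:

* 100 repeats of stratified 4-fold cross-validation.  Within each
  training fold — and only there — features are standardized and ranked
  by the absolute coefficients of an L2-penalized logistic regression
  (C = 1, lbfgs); ties break lexicographically by miRNA id; zero-variance
  features rank last.  RBF-kernel SVMs (C = 1, gamma = "scale") on the
  top-k features, k = 1…12, are scored on the held-out fold.
* Fold ROCs are **vertically averaged**: the TPR is interpolated on a
  fixed 101-point FPR grid and averaged over the four folds, giving one
  cross-validated ROC per repeat whose trapezoidal area is the repeat
  AUC.  The per-k curve reports the mean and the 2.5/97.5 percentiles
  over the 100 repeat AUCs.  The percentile band is widened to contain
  the mean when the repeat distribution is skewed enough to exclude it
  (e.g. 99 repeats at AUC 1.0 and one below: the mean falls under the
  2.5th percentile).
* **Stopping rule**: the optimal k is the smallest with
  `AUC(k+1) − AUC(k) < 0.01`, falling back to k_max = 12.  (The source
  protocol states 0.01 in its methods and 0.1 in its results narrative;
  the methods value is the default and `delta` is a parameter.)
* The final panel re-runs the ranking once on all samples pooled and
  annotates each marker with the sign of the class-mean difference.

Hyperparameters (C = 1 for both models, default kernel width) are the
conventional defaults; the protocol names only the model families.  The
no-leak property is enforced by a permutation test: with labels freshly
permuted per repeat (`permute_labels=True`), the mean AUC at every k must
stay within [0.44, 0.56].  Note that for a *fixed* random labeling the
dataset-conditional CV AUC fluctuates by ±0.08 or more at n = 60 — only
the permutation-averaged null is tight enough to detect leakage.

## 4. Pathway enrichment

* **Targeting**: the gene universe is the union of all miRNA target sets.
  For each (miRNA, pathway) pair, the overlap of the target set with the
  pathway genes (intersected with the universe) is scored by the
  upper-tail hypergeometric p-value; a miRNA targets a pathway when the
  overlap is ≥ 1, with targeting weight `−log10(p)`.
* **Filters**: pathways targeted by fewer than 10 or more than 200
  miRNAs, or with < 50% of their targeting miRNAs measured, are dropped
  (boundaries inclusive: 10, 200 and exactly half are kept).
* **Running statistic**: miRNAs are ranked by log2 fold change (plain
  class-mean difference on the log2 scale, descending, ties broken by
  id).  Walking the list, a hit increments the running sum by
  `w/Σw` with `w = |log2FC| × targeting weight`, a miss decrements by
  `1/(N − n_hits)`.  ES is the signed running-sum value of maximal
  absolute deviation; when the positive and negative extrema tie exactly,
  the positive one is taken.  All-zero hit weights give ES = 0 by
  convention.  The leading edge comprises hits at or before the extremum
  (strictly after it for negative ES).  The hit-weight product is the
  minimal combination honoring both stated factors (fold change and
  targeting p-value); it is exposed as a pluggable weight input rather
  than hard-coded dogma.
* **Null**: sample labels are permuted (default 5000 rounds), fold
  changes and every pathway's ES recomputed per round.  The two-sided
  permutation p uses add-one smoothing, `p = (1 + #{|ES_null| ≥
  |ES_obs|})/(n_perm + 1)`, so p is never exactly zero.
* **FDR**: `q = [share of pooled null |ES| ≥ |ES_obs|] / [share of
  observed |ES| ≥ |ES_obs|]`, clipped to [0, 1] and monotonized by a
  cumulative minimum from the weakest pathway upward (BH-style), so a
  larger |ES| never carries a larger q.  Pooling the null across pathways
  trades per-pathway exactness for stability at small permutation counts.
* **Significance**: strict `p < 0.01` and `q < 0.05`.

## 5. The synthetic-study generator

`simulate_dataset` draws, per sample s and assay a, true log2 copies from
`N(mu_class(s),a, biological_sd)` (lognormal copies — the standard
expression-simulation choice and the scale the analysis operates on),
multiplies by the sample's technical factor `2^t_s` with
`t_s ~ N(0, technical_factor_sd)`, maps copies to Ct through the assay's
standard curve (slope uniform in (−3.6, −3.2), intercept in (36, 40)),
adds `N(0, replicate_sd)` per technical replicate, and censors wells with
Ct above `lod_ct` as non-detects — a hard-threshold LOD being the minimal
mechanism that produces the missingness the filter and imputation rules
need.  Spike-in wells carry the technical factor but no biological
variation, matching their role of measuring isolation efficiency.

Defaults state the emulated world: class sizes 34/24/20/16/18
(lipoma/WDLPS/DDLPS/MFS/UPS), 350 assays, 2 replicates, 3 spike-ins at
10^3–10^5 copies, LOD Ct 35, six planted markers at |log2FC| = 2 split
evenly between up- and down-regulation and applied to every non-baseline
class.  The assay platform publishes no noise magnitudes, so the noise
defaults are plausible for FFPE qPCR rather than claims about the
instrument: replicate SD 0.25 Ct, biological SD 1.0 log2 units, technical
factor SD 0.5 log2 units.  Assay base abundances are uniform on
(6, 15) log2 copies by default (fully detectable); the analysis scripts
lower the floor to 4 so that a realistic fraction of assays (~5%) fails
the 90% detection filter, emulating a panel where some targets sit near
the LOD in FFPE material.

`simulate_pathway_resources` draws random target sets (20–50 genes from a
4000-gene universe) and pathway gene sets (30–100 genes).  Each planted
pathway is built from the planted markers of a *single* regulation
direction (alternating across planted pathways), every such marker
contributing 10 of its target genes: a regulated pathway concentrates its
strong targeting miRNAs at one extreme of the fold-change ranking.  A
pathway planted with both directions at once would have its positive and
negative running-sum excursions cancel and is not what "up-regulated
pathway" means.  Non-planted pathways are uniform random gene sets,
enriched for planted markers only by chance.

**What a green test does not establish.**  The generator's miRNAs are
independent given class; real miRNA panels are strongly co-expressed, so
principal components in synthetic data capture far less variance than the
~20/15/13% reported for real profiles, and marker panels face no
correlated confounders.  There is no FFPE degradation gradient, no batch
structure beyond the scalar per-sample factor, no pre-amplification
chemistry, and no sequence-level realism.  Recovery results therefore
validate the *statistical machinery*, not clinical performance; the
study's real-data AUCs are not reproducible from synthetic data and are
not claimed.

## 6. Numerical conventions and degenerate inputs

* All randomness flows from integer seeds through numpy `SeedSequence`
  streams; identical config + seed reproduces byte-identical outputs.
* Standardization uses population SD (ddof = 0) to match scikit-learn's
  scaler; the imputation SD uses ddof = 1 to match the convention of
  analysis software for outlier windows.
* Detection-filter, pathway-size and measured-fraction boundaries are all
  inclusive per the literal protocol wording.
* Zero-variance features are dropped from ranking with a warning;
  single-class inputs, empty hit sets, non-positive copies and
  sub-2-point dilution series raise `ValueError` naming the offender.
* The permutation p-value's add-one smoothing means the smallest
  attainable p at 5000 permutations is ~2.0 × 10⁻⁴; reported values below
  that are not representable under any standard convention and are not
  emulated.

## 7. Known limitations

* The exact weight formula of the published miRNA-set enrichment tool the
  protocol cites is not public; the `|log2FC| × −log10(p)` hit weight is
  this package's documented choice, and sidedness is fixed to two-sided
  on |ES|.
* The pooled-null FDR is conservative when pathway sizes (and hence null
  ES scales) differ widely; a per-pathway normalized ES would be the next
  refinement.
* The CV confidence band is a percentile interval over repeat AUCs, which
  understates uncertainty from the single finite sample (repeats share
  the data); it matches the protocol's construction, not a bootstrap over
  samples.
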