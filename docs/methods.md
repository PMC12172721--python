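# Methods

## The analysis in brief

The package studies how well sex can be classified from spatially
normalized, Jacobian-modulated gray-matter volume (GMV) images once total
intracranial volume (TIV) — a strongly sex-associated nuisance variable —
has been removed by matching. The pipeline is: generate (or load) a cohort
of images with demographic metadata, z-score-normalize each image inside a
gray-matter mask, optionally TIV-match the cohort, train voxelwise logistic
regression and/or a small 3D CNN under nested 5×5 cross-validation, and
evaluate accuracy, AUC, region importance and confound-leakage diagnostics.

## The synthetic-data generator

Real study data of this kind is access-restricted, so the generator produces
cohorts with the statistical structure the analysis assumes, at a
configurable grid size.

**Demographics.** Two profiles emulate the published cohort summaries: a
large adult cohort (n = 3298, ages 21–90, male/female mean TIV 1609/1406 ml,
range 946–2209 ml, GMV/TIV ≈ 0.416, 48.7% male) and a young-adult cohort
(n = 399, ages 22–36, mean TIV 1584/1367 ml, range 1028–1880 ml, GMV/TIV ≈
0.490, 46.4% male). Age and per-sex TIV follow truncated normals; the
spreads (TIV sd 115–130 ml, age sd 16 y and 3.5 y) are free parameters
chosen to hit the stated ranges with realistic male/female overlap. Sex
counts are exact (`round(n·male_fraction)`) rather than binomial so that
matching behaves stably at small n.

**Atlas.** An ellipsoidal brain mask (axes at 90% of the grid half-extents)
is partitioned into `n_regions` (default 17) contiguous regions by
nearest-seed (Voronoi) growth from uniformly drawn seed voxels. The default
grid is 32×38×32 — the same aspect ratio as the full 113×137×113 reference
grid — with full-resolution generation supported but not the test default.

**Images.** Region *i* of a subject receives expected volume

    V_i = a_i · (TIV/TIV_ref)^{β_i} · (1 + s_i·1[female]) · g · r_i

spread uniformly over its voxels, plus i.i.d. voxel noise truncated at zero.
Here `a_i` are base volumes at the reference TIV (scaled so their sum equals
the profile's GMV fraction times the reference TIV), `β_i` region-specific
power-law exponents, and `s_i` multiplicative sex effects. Defaults: per-
region densities U(0.6, 1.4) (so the normalized image is non-degenerate even
without noise), `β_i ~ U(0.7, 1.2)` (heterogeneous, the leakage mechanism),
`s_i ~ N(0, 0.04)` (broad, modest regional sex differences), voxel noise sd
= 0.2 × the mean voxel value.

Two multiplicative lognormal noise terms model individual variability that
the region-law alone misses: a **global subject scale** `g` (sd 0.1,
individual variation of the GMV/TIV ratio) and **per-region variation**
`r_i` (sd 0.05, anatomical variability of regional volumes beyond the TIV
law). Without them every image is a deterministic function of (TIV, sex) and
all classifiers saturate at AUC 1.0. With them the generator reproduces the
qualitative regime of real cohorts: raw voxel-sum/TIV correlation ≈ 0.7,
unmatched cross-validated accuracy in the mid-90s, matched accuracy a few
points lower, and within-sex femaleness–TIV correlations ≈ −0.3 after
unmatched training that attenuate under matching. The global scale is
removed exactly by per-image z-score normalization, so it affects only
raw-image diagnostics.

**What the generator does not model** — and hence what passing tests cannot
show about real data: spatial anatomy (regions are Voronoi cells, not
structures), within-region texture, registration error, scanner effects,
age-dependent atrophy, or any coupling between age and regional volumes.
Conclusions supported by the synthetic suites are about the *pipeline*
(identities, protocol correctness, recovery of planted effects, the leakage
mechanism), not about brains.

## Preprocessing

The mask is a probability grid thresholded inclusively at 0.5. Each image is
standardized inside the mask, `x̃_j = (x_j − μ)/σ`, with out-of-mask voxels
set to zero. σ uses the population (divide-by-N) convention; the choice is
immaterial to the identities (zero mean, unit sd, zero sum, idempotence) but
one convention must be fixed for bit-reproducibility. Near-constant in-mask
images (σ ≤ 1e−12·max(1, |μ|)) are rejected as degenerate rather than
amplified into noise.

Centering forces every normalized image's voxel sum to zero, which removes
the voxel-sum/TIV channel; heterogeneous `β_i` nonetheless leave decodable
TIV information (a ridge regression on normalized desk-scale images recovers
TIV with R² ≈ 0.6 at n = 600), which is exactly the leakage the matched
analysis guards against.

## Matching

Bins are half-open `[10k, 10(k+1))` ml anchored at 0 (the bin anchor is a
convention; only the width is substantive). Within each bin the smaller sex
subgroup is kept whole and the larger one subsampled uniformly without
replacement from a single seeded generator, bins processed in ascending
order. Bins with one sex absent contribute nothing. Diagnostics report the
best single-TIV-threshold accuracy on the matched subset (near chance by
construction) and the two-sample KS test between the matched sexes' TIV.

## Classifiers

**Voxelwise logistic regression** scores `z = w₀ + Σ_j w_j x̃_j` over the
whole input cuboid (m + 1 parameters; 1,749,354 at full resolution). The
training objective is mean cross-entropy plus `λ·‖w‖²` with λ = 0.1, the
penalty un-normalized by batch size and excluding the bias; the convention
is pinned by a test against an independent penalized-likelihood solver
(`C = 1/(2nλ)` in the scikit-learn parametrization).

**The 3D CNN** follows the fixed architecture: 6³ max-pool (stride 6, floor
division, no padding) → valid 7³ convolution with 32 filters → per-element
PReLU → 2³ max-pool → flatten → dense 128 → per-element PReLU → dropout 0.5
→ dense 1. Pooling uses floor division because the printed full-resolution
shape trace (113×137×113 → 18×22×18 → 32×12×16×12 → 32×6×8×6 → 9216 → 128 →
1) requires it, and PReLU slopes are per-element because that is the only
convention reproducing the published total of 1,264,769 trainable
parameters. The final layer is exactly a logistic regression on the 128
penultimate features (asserted by feature extraction). A desk-scale variant
(2³ pool, 3³ conv, 8 filters, dense 32) shrinks the receptive sizes with the
grid; the full-size spec is retained for the parameter arithmetic. The
implementation is a small numpy layer stack with explicit backpropagation;
dropout is inverted (active only in training), so fitted models are
deterministic at evaluation.

Both models train with Adam (lr 10⁻⁴ default), mini-batch size 16 (a config
default; scores are averaged over the batch), weights initialized He/Glorot
from the run's seeded generator (logistic regression starts at zero).
Scores at exactly z = 0 classify as male (strict p > 0.5 rule).

## Cross-validation protocol

`k×ℓ = 5×5`: the cohort is shuffled and split into 5 near-equal outer folds
(remainders spread one-per-fold, since exact equality is impossible when
5 ∤ n); each outer round holds one fold back for testing and splits the rest
into 5 inner folds, one serving as validation set — 25 runs, training on 64%
of the data at n divisible by 25. During training the validation loss is
evaluated once per epoch on the full validation set; if it fails to improve
by more than 10⁻⁴ for more than 4 consecutive epochs the learning rate is
multiplied by 0.75 and the counter resets (reset-after-reduction is a
choice; the alternative keeps accumulating). Weights are checkpointed at
every new validation-loss minimum and the checkpoint — never the final state
— is evaluated on the test fold. Per-run RNG derives from
(seed, outer, inner), so any single run is independently reproducible. A
bookkeeping audit asserts per run that test ids are disjoint from all ids
that influenced parameter updates or schedule decisions.

Scenario epoch counts: logistic regression 30 epochs (60 in ROI
experiments); the CNN 100 on complete/reduced cohorts, 200 on matched data
and in ROI experiments.

## Region importance

Occlusion is applied **after** z-score normalization (zeroing normalized
voxels), for both training and prediction; re-normalizing after occlusion
would change the whole-brain statistics and break the identical-pipeline
framing. 'only ROI' keeps one region, 'masked ROI' removes it; the two
reconstruct the input exactly. All regions reuse one fold plan so rows are
comparable; the result table is sorted by descending AUC of the first model,
ties broken by voxel count descending.

Weight maps scale each voxel weight by the per-voxel sd of the normalized
values over the training sample, `w′_j = σ_j w_j`, preserving the score
identity `z = w₀ + Σ w′_j x̃_j/σ_j` over σ_j > 0 voxels (zero-σ voxels are
constant across the sample and flagged). Maps from the 25 CV repetitions are
split by sign, summed voxelwise, smoothed (Gaussian, 1 mm FWHM, kernel
truncated at 4 sd, applied before upsampling), interpolated into 0.5 mm
space (trilinear), scaled to max 1 and multiplied by the number of maps; the
display threshold (7) is a rendering parameter only.

## Evaluation choices

- ROC by threshold sweep (ties as simultaneous steps), AUC by trapezoid;
  curve averaging is vertical interpolation of TPR on a 101-point FPR grid,
  and the reported mean AUC is the arithmetic mean of per-run AUCs.
- The Wald test for femaleness–covariate correlations is the two-sided
  t-test on the simple-regression slope (asymptotically equivalent).
- The TIV-threshold baseline scans all midpoints of adjacent sorted TIVs
  plus the extremes, classifying female iff TIV < threshold; ties go to the
  smaller threshold.
- The paired sign test is exact binomial on the discordant pairs, two-sided
  by doubling the smaller tail and capping at 1 (no mid-p).
- Cross-cohort evaluation scores the full other cohort with each of the 25
  CV models without retraining.

## Problem sizes and reproducibility

The default study scale for the synthetic suites is the 32×38×32 grid with
n = 600 subjects (matched subsets ≈ 240); chance-level (null) checks average
the cross-validated AUC over three generated cohorts because a single small
matched cohort estimates a null AUC with sd ≈ 0.04. Every random draw —
demographics, atlas, effects, image noise, splits, batching, initialization,
dropout — derives from explicit integer seeds through spawned generator
streams; identical inputs reproduce identical cohorts and identical results.

## Known limitations

- Cross-validated null AUC on small matched cohorts scatters around chance
  (sd ≈ 0.04 at ~240 subjects); single-cohort values of 0.41–0.54 are
  expected noise, not signal.
- The numpy CNN is for study-scale grids; full-resolution training is
  supported in principle but slow, and the package's quantitative CNN claims
  are architecture arithmetic, not full-scale benchmarks.
- The generator's region-level laws cannot validate spatial interpretation
  (weight-map anatomy); only the algebraic identities and repeatability
  mechanics of the weight-map pipeline are testable here.
- With a single strongly planted region, 'masked ROI' removes the signal
  entirely — unlike distributed effects, where masking any one region is
  compensated; both regimes are exercised in the tests.
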