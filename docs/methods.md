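# Methods

## Pipeline overview

`painconn` implements a single-trial connectivity–behaviour analysis as
five composable stages:

1. **Region course extraction.** Each region's voxel × time matrix is
   reduced to the first principal component of the time-indexed voxel data
   (voxels demeaned over time, no variance normalization — PCA on raw
   courses). The PC sign is anchored so the score series correlates
   nonnegatively with the across-voxel mean course; this removes the
   arbitrary sign of the eigendecomposition. A consequence of any
   data-driven anchor is odd symmetry: reflecting the data reflects the
   course. The score series is scaled to unit sample variance.
2. **Design regression.** A stimulation boxcar (one block per trial,
   ending with the plateau), its first temporal difference, and an
   intercept are regressed out of each whole-session course by least
   squares. The boxcar is not HRF-convolved: within the analysis window it
   is constant, so the regression shifts plateau samples by a constant and
   leaves within-window correlations untouched, while still removing
   stimulation-locked steps from the rest of the session. Residualization
   is session-wise, before window extraction.
3. **Plateau windows and edge statistics.** The final
   `floor(30 / 1.96) = 15` volumes of each 40 s stimulation period form
   the trial's window. Per region and window, an iterative two-sided
   Grubbs test (alpha 0.05) drops the most extreme sample while
   `G = max|x − mean| / sd` exceeds
   `G_crit(N) = ((N−1)/√N) · sqrt(t² / (N−2+t²))`, `t` the upper
   `alpha/(2N)` Student-t quantile on `N−2` df, never dropping below three
   retained samples. Each unordered region pair is Pearson-correlated over
   the intersection of both regions' retained samples (pairwise-complete,
   preserving time alignment); pairs with fewer than 10 common samples are
   marked missing; `|r|` is clamped at `1 − 1e−7` before `z = atanh(r)`.
   A config switch (`filter_mode="coefficients"`) instead screens each
   edge's trial-wise z values within subject, for comparison.
4. **Mixed models.** See below.
5. **Permutation correction and reporting.** See below.

## Random-intercept REML by 1-D profiling

All three models are Gaussian random-intercept LMEs, so the marginal
covariance is `sigma² (I + lambda Z Z')` with a single free ratio
`lambda = sigma²_group / sigma²_resid`. Profiling fixed effects and
`sigma²` leaves

    crit(lambda) = (n − p) log RSS(lambda) + log|M| + log|X' M⁻¹ X|,
    M = I + lambda Z Z',

whose every ingredient reduces to per-group sums because
`M⁻¹ = I − diag_g(c_g J)` with `c_g = lambda / (1 + lambda n_g)`. The
criterion is evaluated on `{0} ∪ logspace(−6, 4, 41)` and the bracket
around the grid minimum is refined by 40 golden-section iterations in
log-space; the zero-variance boundary is always compared and, when chosen,
the fit is exact OLS. Standard errors are GLS at the REML optimum;
t = beta/se. Because downstream inference is permutation-based, no
reference distribution for t is assumed (nominal residual df are reported
for information; single-fit convenience p-values use the normal
reference).

The mass fitter vectorizes this over edges and outcome columns
simultaneously: predictor-side group sums are precomputed once, and each
criterion evaluation is a handful of elementwise operations on
(edges × outcomes) arrays. Balanced groupings (equal trials per subject,
the design here) make the shrinkage weight a scalar per cell, which is the
fast path; unbalanced groupings fall back to explicit per-group
reductions. A 200-replicate permutation null over 66 edges refits
~13 000 models in well under a second on one core. Cross-checks: the
batched path agrees with the scalar path to ~1e−6 in t, and the scalar
path agrees with lme4's REML t-values to ~1e−5 on random datasets (the
packaged tests verify 1e−4; statsmodels' MixedLM agrees at its own
optimizer precision, ~1e−2).

Model-specific choices: the predictor z is standardized within each edge
dataset before fitting, so slopes are in rating units per SD of Fisher-Z
and comparable across edges (raw-scale slopes are also reported). Each
condition's dataset is that condition's trials plus the unmodulated
trials. M2 is fitted as a binary target-versus-rest condition contrast
with random intercepts on the original subject:condition cells; the
general multi-level interaction model (reference = first condition) is
available as `fit_condition_interaction`. M3 maps streamline counts
through `log(1 + count)` and standardizes across subjects before the
product; edges are prefiltered at M1 `|t| > 2`. Edges missing in more than
20% of rows are skipped (config-exposed); less-missing edges are fitted on
their complete rows.

## Permutation inference

Ratings are permuted within subject (all conditions pooled), preserving
each subject's rating level — the exchangeability unit consistent with the
random-intercept structure; a global-shuffle mode exists for comparison.
Per repetition the entire edge set is refitted and the maximum |t| over
fitted edges recorded, identically in observed and null passes (skipped
edges excluded from both). Corrected p-values use add-one smoothing,
`p = (1 + #{max ≥ |t|}) / (n_perms + 1)`, never exactly zero; the
significance threshold is the matching upper quantile of the null maxima,
and `p ≤ alpha ⟺ |t| > threshold` holds by construction with ties
resolved conservatively. Repetition seeds are spawned per repetition from
the master seed, so results are independent of worker count and chunking.
Null maxima are extreme-value-like and right-skewed; the calibration tests
assert positive sample skewness.

## The synthetic generator

The generator emulates the study design the analysis assumes: 20 subjects;
four conditions (first unmodulated) of 12 trials; each trial 10 s rest
(5 volumes) + 40 s stimulation (20 volumes) at TR 1.96 s, plateau = last
15 volumes; ratings on a 0–100 scale in steps of 5 (clipped after noise).
Defaults: subject-intercept SD 10 and rating-noise SD 10 rating units;
condition means 60 (unmodulated) and 40 (interventions), matching an
attenuation of about 20 points; baseline inter-regional correlation 0.1
(compound-symmetric, positive definite by construction); AR(1) noise with
coefficient 0.3 for BOLD-like smoothness without HRF modelling; a
stimulation-locked activation step per region (removed by the design
regression). The default region count for desk-scale runs is 12; the
371-region layout is available via `ParcelAtlas.template()`.

Each trial carries a latent attenuation performance `u ~ N(0,1)` — in all
conditions, so unmodulated trials fluctuate naturally. For a planted edge
the within-plateau correlation is steered to `r = tanh(z0 + gain·u)`
(`z0 = atanh(0.3)`, gain 0.35: trial correlations span roughly 0–0.75 over
±2 SD of `u`) by building both regions' plateau samples from fresh
innovations plus a shared component of weight `|r|`. Using fresh
innovations means planted trial-varying coupling does not leak into edges
adjacent to the planted regions, which keeps every non-planted edge
exactly null — at the cost that a planted region's plateau loses its
AR(1)/baseline continuity, a feature no stage of the pipeline depends on.

Ratings are `condition mean + subject intercept + Σ beta·z_std +
Σ gamma·w_subj·z_std + noise`, where `z_std` is the *realized* plateau
Fisher-Z of the edge standardized over the dataset — so planted slopes are
on exactly the scale the mass fit estimates — and `w_subj` is the
subject's standardized log(1 + streamline count). Streamline matrices are
symmetric, zero-diagonal negative-binomial draws (mean 300, dispersion 2),
overdispersed like tractography output. Default effect sizes: −8 rating
units per SD Fisher-Z for a coupled edge (a strong single-edge effect on a
0–100 scale), 3.5 per SD of structural weight for mediation — a moderate
interindividual modulation, about half the group-level effect, large
enough for reliable detection at 20 subjects yet small enough that
subject-permuted streamline counts leave no detectable effect (with G
subjects a permutation retains sample correlation ~1/√G with the true
weights, so the permuted statistic scales as |t_true|/√(G−1)).

What the generator does **not** emulate: HRF dynamics, head motion,
physiological noise, spatial structure within regions beyond
positive-loading voxels, and real parcellation geometry. Passing tests
therefore demonstrate the statistical machinery — estimation, calibration,
error control — under the assumed generative structure, not robustness to
fMRI artefacts.

## Calibration study sizes

The packaged tests and `scripts/acceptance.py` run, per replicate, the
full pipeline at 20 subjects × 12 regions × (12 intervention + 12
unmodulated) trials, i.e. 480 observations per fit over 66 edges, with
200-permutation nulls. Test-suite calibrations use 500 global-null
replicates (family-wise false-positive rate asserted within [0.03, 0.07]
at alpha 0.05), 40 planted-slope replicates, and 100 mediation replicates;
the acceptance script reports 150/20/40 replicates for the same
quantities. Mediation power runs use 6 regions, since only the planted
edge's column enters the M3 fit.

## Numerical choices and degenerate inputs

* `|r|` clamped at `1 − 1e−7` keeps Fisher Z finite for degenerate
  (identical or perfectly correlated) windows.
* Constant windows: the scalar Grubbs filter raises on zero-variance
  input; in the vectorized tensor path a zero-variance region yields
  missing (NaN) edges rather than an abort.
* Rank-deficient fixed-effect designs (constant predictor, constant
  structural weights, degenerate product terms) raise with a message
  naming the cause.
* The REML grid spans lambda ∈ [1e−6, 1e4]; an optimum at the upper edge
  flags `converged=False`.
* Golden-section refinement (40 iterations over a ~0.5-decade bracket)
  fixes lambda to ~1e−9 relative, tight enough that t matches an
  independently converged implementation to better than 1e−4.

## Known limitations

* Random intercepts only — no random slopes, crossed effects, or
  non-Gaussian outcomes; directionality is out of scope.
* The max-statistic correction controls FWER only; no FDR or cluster
  variants, and no generalized-Pareto tail smoothing of permutation
  p-values.
* M2 permutation nulls refit edge by edge (no batched path) and are meant
  for moderate edge counts.
* Whether the original outlier screening applied to time points or to
  trial-wise coefficients is ambiguous; time-point screening is the
  default, with the alternative behind a config switch.
* The NPS (pain-signature) region subset is data: an atlas flag column,
  not a hard-coded list; its internal-edge average is tested uncorrected
  by design.
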