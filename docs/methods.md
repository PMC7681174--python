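# Methods notes

## Model and procedure

The pipeline relates two subject × subject dissimilarity structures. On
the behavioral side, a trait score per subject (here a two-informant
callous-unemotional questionnaire total or subscale) is normalized by the
in-sample maximum, *s*ᵢ ∈ (0, 1], and expanded into pairwise
dissimilarity models: the two Anna Karenina models (max(*s*ᵢ, *s*ⱼ) and
1 − min(*s*ᵢ, *s*ⱼ)), which encode the hypothesis that subjects at one
end of the scale respond alike while the rest are idiosyncratic, and the
nearest-neighbor models (|*s*ᵢ − *s*ⱼ|, or item-wise Euclidean distance),
which encode relative similarity. On the neural side, each searchlight
yields an RDM of 1 − Spearman ρ between subjects' multivoxel beta
patterns. Correspondence is the Spearman correlation of the two strictly
lower triangles, tested with a Mantel permutation test (joint row/column
shuffles of the model matrix) and mapped back to searchlight centers, then
thresholded by cluster-forming p, cluster extent, and BH-FDR.

Assumptions worth making explicit: one beta map per subject × condition
on a single shared grid (no resampling is performed — grid mismatch is an
error, because resampling would silently change searchlight membership);
exchangeability of subject labels under the null; and rank-scale
relationships throughout (all correlations are Spearman, so monotone
transforms of patterns or scores are irrelevant).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| V | 100 voxels | searchlight size: V nearest in-mask voxels by mm distance |
| B | 1000 | Mantel permutations per test |
| p_cluster_forming | .005 | per-center threshold before clustering |
| k_min | 10 voxels | minimum cluster extent |
| q | .05 | BH-FDR level over all defined centers |
| connectivity | 18 | cluster neighborhood (6 faces / 18 +edges / 26 +corners) |
| voxel size | 3 mm isotropic | grid spacing used for searchlight distances |
| items, levels | 24, 0–3 | questionnaire layout; subscale map configurable |

The searchlight is V-nearest-neighbors rather than a fixed radius, so the
pattern dimensionality is constant everywhere, including near mask edges
where an implicit sphere would truncate; a `radius_cap_mm` option skips
centers whose enclosing radius grows past a cap, for users who prefer
dropping edge centers to letting neighborhoods stretch.

## Permutation p-values and signs

p is the fraction of permuted statistics *strictly* exceeding the
observed one, with denominator B, so p = 0 is attainable — the unsmoothed
estimator matching reporting conventions like "p < .0001" at B = 1000.
An add-one smoothed option ((r+1)/(B+1)) exists and is off by default.
The test is one-sided; in searchlight maps the tested direction follows
the sign of the observed ρ (`alternative="auto"`), so that negative
"anticorrespondence" clusters carry an interpretable p instead of p ≈ 1,
and the cluster table separates the two signs. One permutation schedule,
derived from the seed, is shared by all searchlights of a map so that
centers are compared against the same null draws; independent schedules
per center are available by flag. Because a joint row/column shuffle only
permutes which pair each lower-triangle cell refers to, ranks permute
with the pairs, and the whole permutation loop reduces to index gathers
plus a matrix–vector product on standardized rank vectors — this is what
makes a 2,000-center map at B = 1000 run in seconds, with no change in
the statistic computed.

## Synthetic data: what it emulates, and what it does not

The generator emulates the target study design's bookkeeping and statistical
structure: 37 recruited → 4 motion-excluded → 3 attention-excluded → 30
analyzed subjects; 24 ordinal items × 2 correlated informants with
injectable missing and double-marked cells; covariates age ∈ [10, 17],
binary gender, IQ ~ N(100, 15); a blocked task manifest (two 3-min
baseline runs of 72 volumes at TR 2.5 s; four 4-min-13-s context runs of
102 volumes, 3 contexts × 2 presentations = 6 contextualized blocks per
run); and per-condition beta volumes on a 3 mm grid.

Planted intersubject structure: within a planted region, subject i's
pattern is wᵢ·G + noise where G is a shared unit-variance spatial pattern
and the loading is (1 − *s*ᵢ) for low-alike, *s*ᵢ for high-alike, and
(cos(π*s*ᵢ/2), sin(π*s*ᵢ/2)) on two orthogonal patterns for the
nearest-neighbor kind, so pattern similarity decays smoothly with
|*s*ᵢ − *s*ⱼ|. Voxel noise is independent (Gaussian, SD 1.0 in units of
the planted pattern; see below) with no spatial autocorrelation by
default — a smoothed-noise option exists to stress cluster inference.
Covariates are independent of the latent trait unless a confounded mode
is requested, keeping partial-correlation recovery tests clean.

What passing tests therefore do **not** show about real data: no
hemodynamics or first-level GLM structure, no spatially autocorrelated
noise (cluster extents on real maps are broader), no informant response
styles beyond a shared latent trait, and no trait–covariate confounding
unless enabled.

### Noise default and the limits of model discrimination

The noise SD default of 1.0 was fixed by a design-stage power analysis of
the generator's recovery behavior: at effect weight w = 0.8 it yields
planted-region pattern correlations of roughly 0.1–0.4 between
high-loading subject pairs, in the range of realistic intersubject
pattern correlations, and gives the searchlight pipeline reliable power —
each planted region is recovered (≥ 50% voxel coverage by positive
surviving clusters) by its own model across seeds.

A stronger property — that each model recovers *only* its own region —
does not hold reliably at any noise level, and users should not expect it
of real data either. The three models built from one score sample are
mutually rank-correlated: over pairs, |*s*ᵢ − *s*ⱼ| correlates ≈ 0.3–0.7
with whichever Anna Karenina model the sample's score distribution favors
(their sum is roughly constant ≈ 0.9), and max vs. 1 − min correlate
≈ −0.47. A region carrying one model's structure is therefore genuinely,
not spuriously, correlated with at least one other model whenever it is
detectable at all: the cross-model effect is ~0.5–0.7× the own-model
effect at every signal-to-noise ratio, while the p < .005 Mantel cutoff
sits at ρ ≈ 0.13 (null SD ≈ 0.049 at n = 30). The window in which the own
effect is detectable but 0.6× it is not is narrower than this
inter-model correlation allows. This mirrors the empirical observation
that the two nearest-neighbor variants produce map-level ρ ≈ 0.7
similarity: the models are overlapping hypotheses, and overlapping
clusters across models are expected behavior, best adjudicated by effect
sizes rather than exclusive significance.

## Numerical choices

- Spearman everywhere uses average ranks for ties; equal rank vectors
  short-circuit to ρ = 1 exactly, so map self-comparison is exactly 1.
- Searchlight membership ties at the cutoff distance are broken by
  ascending (x, y, z) voxel index; squared mm distances are rounded at
  1e-6 before comparison so algebraically equal distances compare equal.
- Anna Karenina model diagonals follow the defining formula but never
  enter any statistic (all statistics use the strictly-lower triangle);
  nearest-neighbor diagonals are exactly 0.
- Degenerate searchlights (constant pattern for some subject, zero rank
  variance) are recorded as undefined centers with a reason, never fatal;
  degenerate whole-matrix inputs raise a dedicated error (CLI exit 3).
- Partial Spearman: ranks are residualized on ranked covariates plus
  intercept by least squares; p uses the t approximation with
  n − 2 − #covariates degrees of freedom.
- BH-FDR is applied per map (per condition × model), voxel-level, and a
  cluster is flagged as FDR-surviving if any member center passes.
- Problem sizes in tests and the acceptance script: a ~2,240-voxel box
  mask (20 × 14 × 8 at 3 mm) with three 125-voxel planted regions, B =
  1000 for maps, B = 200 for the 500-replicate null calibration, 20 seeds
  for recovery — sizes chosen to exercise the full pipeline at desk scale.

## Known limitations

- No spatial normalization, smoothing, alignment or hyperalignment; the
  pipeline begins at beta maps on a shared grid.
- No parametric Mantel approximation and no FWE/random-field or
  threshold-free cluster correction; inference is permutation + BH-FDR.
- Whether FDR should pool across condition × model maps is a reporting
  choice; the default (per map) is the more liberal per-map convention.
- The one-sided-by-sign permutation p is a pragmatic convention for
  reporting anticorrespondence clusters; a strictly positive-direction
  test is available via `alternative="greater"`.
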