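# isrsa

Searchlight **intersubject representational similarity analysis (IS-RSA)**
for task fMRI, linking individual differences in a behavioral trait to
intersubject similarity of multivoxel neural response patterns.

## The problem and who this is for

Conventional univariate analyses ask where mean activation scales with a
trait. IS-RSA asks a different question: do people who occupy similar
positions on a trait scale show similar *patterns* of neural response?
The package targets studies of the kind where ~30 participants each
contribute one beta map per task condition (here, viewing fearful faces
under different interpretive contexts) plus a two-informant trait
questionnaire (callous-unemotional traits scored from child and parent
reports). It is aimed at researchers who have first-level beta maps and a
subject table and want a tested, scriptable IS-RSA pipeline.

## The method

1. **Trait scoring.** For each of K ordinal items (default 24 items,
   responses 0–3), the combined response is the maximum over both
   informants' marks; an item only one informant answered uses that
   answer; an item neither answered is imputed as the mean of the
   subject's remaining items. Totals and subscale sums follow, and scores
   are normalized by the in-sample maximum: *s*ᵢ = scoreᵢ / max(score).

2. **Intersubject dissimilarity models.** For each subject pair (i, j):
   - low-alike (Anna Karenina): *d*ᵢⱼ = max(*s*ᵢ, *s*ⱼ) — low scorers alike;
   - high-alike: *d*ᵢⱼ = 1 − min(*s*ᵢ, *s*ⱼ) — high scorers alike;
   - nearest neighbors: *d*ᵢⱼ = |*s*ᵢ − *s*ⱼ|;
   - item-wise nearest neighbors: Euclidean distance between raw item
     vectors.

3. **Neural RDMs.** For every in-mask voxel, a searchlight of its V = 100
   nearest in-mask voxels (millimeter distance, deterministic tie-break)
   defines a pattern per subject; the neural RDM entry is 1 − Spearman ρ
   between two subjects' patterns (n(n−1)/2 = 435 pairs at n = 30).

4. **Inference.** The IS-RSA statistic is the Spearman ρ between the
   lower triangles of model and neural RDMs. A Mantel permutation test
   shuffles subject labels (rows and columns jointly) B = 1000 times;
   p = #{ρ_perm > ρ_obs}/B. ρ and p are assigned to the searchlight center.

5. **Thresholding.** Maps are binarized at p < .005, split by the sign of
   ρ, labeled into connected clusters (default 18-connectivity), kept at
   extent k ≥ 10, and flagged by Benjamini–Hochberg FDR at q = .05 over
   all defined centers. Cluster tables report peak mm coordinates, extent
   and peak ρ per sign.

A synthetic-data module generates the whole study — cohort with
two-informant responses, covariates (age, gender, IQ), exclusion flags,
and beta volumes with *planted* intersubject structure per model — so the
entire pipeline is testable without any scanner data.

## Worked example

```bash
isrsa simulate --out run/ --seed 5 --conditions afraid_for_you
isrsa score run/subjects.tsv --out run/scored.tsv
# -> "scored 30 of 37 recruited subjects"
isrsa build-models run/scored.tsv --out run/models
isrsa searchlight --betas run/betas_afraid_for_you.nii.gz \
    --manifest run/betas_afraid_for_you.json --mask run/mask.nii.gz \
    --model run/models/model_high_alike.tsv --out run/map_high -B 1000
# -> "wrote run/map_high_rho.nii.gz and run/map_high_p.nii.gz
#     (2240 searchlights, 0 undefined)"
isrsa threshold run/map_high --out run/clusters_high.tsv
# -> "8 clusters (3 pass extent, 8 pass FDR)"
```

The simulated study plants three regions (one per model kind) at effect
weight 0.8. The cluster table for the high-alike model shows a 394-voxel
positive cluster peaking at (48, 9, 9) mm with ρ = .68 — the high-alike
planted region — and a 250-voxel *negative* (anticorrespondence) cluster
at (9, 9, 9) mm with ρ = −.44 over the low-alike region, whose structure
is rank-anticorrelated with the high-alike model; the remaining small
clusters fail the k ≥ 10 extent threshold. The same steps with
`model_low_alike.tsv` or `model_nn_abs.tsv` recover the other regions.

The library mirrors the CLI: `score_cohort`, `build_model`,
`build_searchlights`, `pattern_rdm`, `mantel_test`, `searchlight_isrsa`,
`threshold_map`, `compare_maps`, `partial_spearman` (the last for ROI
analyses such as mean amygdala activation vs. trait controlling for age,
gender and IQ).

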