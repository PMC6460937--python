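# netmosaic

Multilevel mapping of sex-related effects in intrinsic functional brain
networks: group spatial ICA with stability clustering and guided
back-reconstruction, spectral component sorting, voxelwise MANCOVA-based
detection of directional effects with FDR control, and the mapping of
dimorphic brain locations onto meta-analytic neurocognitive association
maps ("footprint" statistics). A fully ground-truthed synthetic-cohort
generator replaces restricted-access study data, so every stage can be
exercised and validated at desk scale.

## The scientific problem

Resting-state fMRI reveals spatially organized intrinsic networks (INs) —
default mode, fronto-parietal, sensorimotor, visual, and so on. Whether
and where these networks differ between males and females is contested.
The analysis implemented here asks, for whole-brain models of increasing
resolution: at which voxels does a network's spatial map differ by sex,
in which direction (F > M or M > F), how large are those effects, what
fraction of each network do they occupy — and how do the affected brain
locations coincide with meta-analytic maps of neurocognitive functions
(reading, mental rotation, working memory, ...)?

The workflow, per model order:

1. **Preprocess/QC** — drop equilibration volumes (124 → 120 at TR = 3 s),
   compute DVARS (RMS of the volume-to-volume signal difference over the
   brain mask) and mask correspondence; optionally build a motion-matched
   subsample in which DVARS no longer differs by sex.
2. **Group spatial ICA** — per-subject PCA reduction (k = 20/50/110),
   temporal concatenation, second PCA to the model order C (15/40/100),
   Infomax ICA run R = 10 times from random initializations, agglomerative
   clustering of the pooled components on 1 − |r| with centrotype
   aggregation (stability analysis), then subject-specific maps and
   timecourses by group-information-guided back-reconstruction
   (negentropy + λ·correlation-with-reference under a unit-norm
   constraint), everything z-scored.
3. **Sorting** — per component: fALFF-like ratio
   ∫₀^0.10 P(f) df / ∫₀.₁₅^0.25 P(f) df, dynamic range
   P(f_peak) − min_{f>f_peak} P(f), and gray-matter overlap of the
   supra-threshold map; a component is a network only if all three pass.
4. **Network maps** — voxelwise one-sample t over subject maps,
   thresholded at mean + 4σ.
5. **Dimorphism statistics** — design matrix with sex (F = 1, M = 0), age
   bin, estimated IQ, scanner and DVARS; backward MANCOVA reduction
   (Lawley–Hotelling trace on a PCA-reduced response); voxelwise OLS for
   the sex coefficient with nuisance partialled out; Benjamini–Hochberg
   FDR at q ≤ 0.01 pooled across all networks of a model; directional
   split by the sign of β_sex; connected-cluster average betas
   (6/18/26-connectivity); per-network significant-voxel fractions.
6. **Footprint** — intersect each direction's unique dimorphic voxels
   (pooled across networks) with each association map's active set;
   per term report F > M and M > F counts and the male-excess percentage
   (M − F)/F × 100.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the synthetic
benchmark cohort (40 subjects, 6 planted network + 3 artefact sources,
20×20×12 grid, 120 timepoints after trimming):

```bash
python analysis/01_simulate_cohort.py --seed 1 --outdir results/cohort
python analysis/02_qc_motion_match.py --seed 1 --outdir results/qc
python analysis/03_group_ica_recovery.py --seed 1 --outdir results/ica
python analysis/05_sex_effect_stats.py --seed 1 --outdir results/stats
```

The QC step prints the planted male motion excess and its removal:

```
DVARS by sex before matching: t = 3.60, p = 0.000906
removed 7 subjects; after matching: t = 1.89, p = 0.0689
```

The decomposition step matches every planted source
(`sources recovered at |r| >= 0.9: 9 of 9`), and the statistics step
recovers the planted ±1.0 effects with cluster-average betas within a few
percent (`F>M ... mean_beta 0.994`, `M>F ... mean_beta -0.992`) at
q ≤ 0.01. `analysis/06_footprint.py` reproduces the constructed
asymmetry: with many small M > F plants and few large F > M plants the
male footprint exceeds the female one for all 16 terms.

There is also a CLI over the same library (`netmosaic run-all --config
config.yaml --out outdir`, with `simulate`, `qc`, `match`, `ica`, `sort`,
`maps`, `stats`, `footprint`, `report` subcommands).

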