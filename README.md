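# swaylearn

Classification of diagnostic group (autism spectrum disorder vs typical
development) from whole-body movement recorded during static balance tasks:
markerless skeleton kinematics (20 joints × x,y,z) plus balance-board
centre-of-pressure coordinates (x,y), 62 channels per frame. The package is
aimed at movement scientists and digital-phenotyping researchers who want a
tested, reproducible implementation of this analysis — and, because the
original participant recordings are not public, it ships a synthetic-cohort
simulator that carries the statistical structure the analysis assumes, so
every stage can be exercised and calibrated end to end.

## The method

For each recording (one participant holding one of 10 balance poses in one
session):

1. **Cleaning** — missing samples are forward-filled; each channel is
   denoised by a level-5 Haar discrete wavelet transform, keeping the
   (decimated) approximation coefficients rescaled to dyadic block means;
   the series is trimmed to a centred window of at most 10,000 samples; and
   whole files with extreme variance are discarded by fitting an exponential
   distribution to each channel's variances across a pose's files and
   cutting at the 10⁻⁷ upper tail, x\*₍d₎ = mean₍d₎ · ln 10⁷.
2. **Features** — a sliding window (size W = 20, shift S = 10) over the
   cleaned series; per window and channel, the Shannon entropy H of the
   10-bin value histogram and the population variance σ², giving vectors of
   length 124 = 2 × 62.
3. **Classifier** — one random forest of 10 CART trees per pose, trained on
   that pose's window vectors. Hierarchical majority voting: each vector
   votes ASD iff its mean tree score ≥ 0.5; each pose's partial decision is
   the vector-vote majority; the participant's label is the majority of pose
   decisions (ties → ASD). A continuous output is also produced: the ASD
   probability p (mean vector score averaged over poses) rescaled to the
   boundary distance 2p − 1 ∈ [−1, +1].
4. **Evaluation** — stratified 5-fold cross-validation at the participant
   level with precision, recall, specificity, MCC and F1 (ASD = positive
   class); differential experiments drop the joint z-channels (84 features)
   or balance the group sizes by subsampling.
5. **Interpretation** — features ranked by total mean decrease in impurity
   (per-forest normalized MDI summed over the 10 forests, so totals lie in
   [0, 10]); fold-to-fold top-20 overlap; Cohen's d group effect sizes on
   per-participant feature means; Pearson/Spearman correlation of boundary
   distance with age and clinical covariates.

## Worked example

```python
from swaylearn import SimulationConfig, run_study

config = SimulationConfig(n_asd=10, n_td=10, n_poses=4, rng_seed=7)
result = run_study(config, k=5, cv_seed=7)
```

With this seed the run prints (see `swaylearn.pipeline.StudyResult` for the
fields):

```text
5-fold CV (out of fold): precision=0.93 recall=0.80 specificity=0.90 MCC=0.75 F1=0.83
QC discarded 5.0% of files (recall vs ground truth: 1.00)
fold top-20 overlap with full model: 0.80
top 5 features by total MDI:
  variance:board:y         0.299
  variance:foot_R:y        0.251
  variance:head:x          0.247
  variance:foot_R:x        0.246
  variance:shoulder_R:z    0.214
boundary distance vs latent severity: r=+0.76 (p=1.0e-04, n=20)
boundary distance vs age:             r=-0.52 (p=0.02, n=20)
```

Reading this: the ensemble separates the two synthetic groups well above
chance (MCC 0.75); the variance-QC stage removed exactly the files the
simulator corrupted; the top-ranked features sit on the channels into which
the simulator injected the group effect (postural sway, feet, head,
shoulders); and the continuous boundary distance tracks the latent motor
severity positively and age negatively — younger, more affected
participants land deeper on the ASD side of the boundary.

The same pipeline is available stage by stage from the shell:

```sh
swaylearn simulate --out raw --seed 7
swaylearn clean --manifest raw/manifest.tsv --out cleaned --sessions 2,3,4
swaylearn cv --manifest cleaned/manifest.tsv --out cv_results --k 5 --seed 7
swaylearn cv --manifest cleaned/manifest.tsv --out cv_xy --xy-only   # 84 features
swaylearn interpret --manifest cleaned/manifest.tsv --out interp \
    --distances cv_results/distances.tsv
```

Real data in the same tab-delimited 62-column format (one file per
participant/session/pose plus a manifest) flow through the identical
`clean`/`cv`/`interpret` stages.

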