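# lumbarqmri

Multiparametric MRI quantification of the posterior lumbar muscles — the
multifidus and the erector spinae — with a digital phantom that makes every
stage of the pipeline testable against known ground truth.

MRI can measure three complementary aspects of paraspinal muscle health
without a biopsy: **size** (segmented muscle volume on a high-resolution
anatomical scan), **quality** (fat signal fraction from two-point Dixon
fat–water imaging, since fatty infiltration displaces contractile tissue),
and **microstructure** (restricted water diffusion from diffusion tensor
imaging, sensitive to fiber size, plus streamline tractography for fiber
architecture).  In healthy, active adults these quantities vary strongly and
systematically with vertebral level: the erector spinae dominates above L5
and withers below the iliac crest, the multifidus dominates at L5/S1, and
fat fraction rises monotonically from L1 to S1, with most fat sitting in an
epimuscular shell rather than infiltrating the muscle.  `lumbarqmri`
implements the full quantification chain and a phantom generator whose
ground truth encodes exactly that level-dependent structure, so the
population aggregates become parameter-recovery targets.

## The measurements

**Dixon fat–water separation.** With in-phase (IP = W + F) and out-of-phase
(OP = W − F) images,

    S_w = (IP + OP) / 2,   S_f = IP − S_w,   fat signal fraction = S_f / (S_f + S_w)

computed voxelwise, clamped to keep the fraction in [0, 1]; voxels with no
usable signal are flagged and excluded from ROI means.

**Diffusion tensor fit.** Single-shell signals follow
S_i = S0 · exp(−b gᵢᵀ D gᵢ); the six unique elements of D are estimated per
voxel by log-linear least squares over 45 directions at b = 400 s/mm².
From the sorted eigenvalues λ1 ≥ λ2 ≥ λ3 (mm²/s):

    MD = (λ1 + λ2 + λ3) / 3
    RD = (λ2 + λ3) / 2
    FA = √(3/2) · √Σ(λi − MD)² / √Σλi²   ∈ [0, 1]

**Level ROIs.** Muscle masks drawn on the anatomical grid are cut into six
axial slabs (L1–S1) bounded halfway between the endplates of adjacent
vertebrae, then carried to the Dixon and DWI grids by nearest-neighbour
resampling.  Volume = voxel count × voxel volume on the anatomical grid;
every other metric is the mean over masked voxels on its native grid.

**Tractography.** Deterministic interpolated-streamline integration along
the principal eigenvector (fixed 0.75 mm step, bidirectional from each
seed), terminating on mask exit, on a turn sharper than 15° between
successive steps, or when FA drops below 0.1.  Per-track length, mean
direction, and pennation angle relative to the superior–inferior axis are
reported, and tracks export to TrackVis `.trk`.

**Statistics.** Two-way repeated-measures ANOVA (within-subject factors
muscle and level; each effect tested against its subject×factor interaction
mean square), Sidak-adjusted paired post hocs per level
(p_adj = 1 − (1 − p)⁶), and a fat-fraction-covariate sensitivity re-analysis.

## Worked example

A reduced-scale run (20% muscle volumes, 5 subjects — a few seconds):

```python
from lumbarqmri import pipeline

cfg = pipeline.RunConfig(mode="full", output_dir="demo", seed=0,
                         n_subjects=5, between_subject_cv=0.08, snr=40.0,
                         volume_scale=0.2, write_maps=False, max_seeds=200)
pipeline.run(cfg)
print(open("demo/summary.txt").read())
```

prints (abridged):

```
multifidus: mean volume 10.6 mL, mean fat fraction 0.202
erector_spinae: mean volume 24.0 mL, mean fat fraction 0.221
pooled fat fraction by level: L1 0.184, L2 0.189, L3 0.182, L4 0.183, L5 0.196, S1 0.335
fraction of muscle voxels with fat fraction > 0.45: 0.133

Repeated-measures ANOVA — metric: volume_ml
effect                   F  df1  df2           p
muscle           3358.8077    1    4   5.308e-07
level             277.4887    5   20    9.34e-18
muscle * level    542.6699    5   20   1.235e-20

post hoc (multifidus − erector spinae), Sidak-adjusted:
L1           -27.802   2.555e-06   1.533e-05  *
...
L5            8.7064   1.051e-05   6.303e-05  *
S1            9.2053   4.645e-05   0.0002787  *
```

Reading it: at 20% scale the erector spinae averages 24.0 mL vs 10.6 mL for
the multifidus (the 125.8 vs 54.0 mL of a full-scale phantom, scaled); the
fat fraction climbs toward S1 and ~13% of muscle voxels exceed 0.45; all
three omnibus effects on volume are significant, and the post hocs flag the
multifidus as smaller at L1–L4 (negative differences) but larger at L5/S1 —
the level crossover the phantom's ground truth encodes.

The same pipeline is available from the shell:

```sh
lumbarqmri --mode full --n-subjects 10 --seed 0 --out results/
```

which writes per-subject fat-fraction and diffusion maps (NIfTI), `.trk`
tract files, `level_table.csv` (one row per subject×muscle×level),
`anova.csv`, and `summary.txt`.

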