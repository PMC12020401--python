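# cranioshape

Objective assessment of craniofacial surgical outcomes from 3D head shape.

Syndromic craniosynostosis (Apert, Crouzon and related syndromes) deforms the
midface; osteotomy procedures such as monobloc advancement, facial
bipartition or Le Fort III aim to move it back toward a typical shape.
Judging how well a procedure succeeded is traditionally subjective.  This
package implements a quantitative alternative for researchers in craniofacial
morphometrics: head surfaces in dense point correspondence with a shared
template are encoded by a region-disentangled variational autoencoder into a
latent vector `z ∈ R^75`, partitioned into fifteen 5-dimensional subsets
`z_r`, one per anatomic subunit (orbits, nose, upper lip, frontal region,
...).  Within that latent space:

- each diagnostic class (healthy, syndrome A, syndrome B) is modelled as a
  Gaussian with its own covariance; diagnosis is quadratic discriminant
  analysis (QDA), and a 2D linear discriminant (LDA) projection visualizes
  the class manifold;
- distances are measured with the Mahalanobis distance under the healthy
  covariance, `d_M(z1, z2) = sqrt((z1−z2)ᵀ Σ_H⁻¹ (z1−z2))`, which is
  calibrated in standard deviations of the healthy population (`d_M = 1`
  means one SD apart);
- each surgical intervention, given pre- and postoperative meshes, receives
  a regional outcome score per anatomic subunit

      m_r = [ d_M(z_pre^r, z_post^r) / d_M(z_post^r, μ_H^r) ] · ⟨ŝ_r, v̂_H^r⟩

  where `μ_H^r, Σ_H^r` are the healthy mean and covariance in region `r`,
  `ŝ_r` is the unit direction of the surgical movement and `v̂_H^r` the unit
  direction from the preoperative point toward the healthy mean (both in the
  whitened regional space).  Large positive `m_r`: a substantial movement,
  aligned with the ideal trajectory, ending close to the healthy centre.
  Negative `m_r`: movement in the adverse direction.

Because real craniofacial cohorts are small and private, the package ships a
first-class synthetic-data module: a head-like template partitioned into 15
contiguous regions, populations whose class identity is a region-localized
smooth shape offset with known ground truth, spectral-interpolation
augmentation, and simulated surgery with a known completeness `α` (0 = no
change, 1 = deviation fully removed, >1 = overcorrection).  Every claim the
package makes is tested against that ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study; each regenerates
its inputs deterministically from `--seed` (default 7) and caches the trained
model, so they can be run individually or in order:

```
python analysis/01_simulate_cohort.py    --out results/analysis
python analysis/02_augment_population.py --out results/analysis
python analysis/03_train_autoencoder.py  --out results/analysis
python analysis/04_classify_and_project.py --out results/analysis
python analysis/05_assess_outcomes.py    --out results/analysis
```

Output of a full run (seed 7):

```
template: 642 vertices, 1280 faces, 15 regions
mean within-class vertex RMS distance: 1.25 mm
mean between-class vertex RMS distance: 4.70 mm (3.8x the within-class scatter)

augmented cohort: 300 subjects (target 100/class, basis k=128)
endpoint identity residuals: lambda=0 -> 6.9e-18 mm, lambda=1 -> 1.4e-17 mm

training: 300 epochs, total loss 0.9240 -> 0.0250
mean per-vertex reconstruction error: 0.104 mm (5.8% of the population's
  mean deviation from the template, 1.789 mm)
latent perturbation of region 6 (central_midface): in-region mean movement
  2.762 mm, off-region 0.023 mm (0.8%)

confusion matrix (rows true, columns predicted):
         healthy  synA  synB
healthy       30     0     0
synA           0    30     0
synB           0     0    30
per-class precision: {'healthy': 1.0, 'synA': 1.0, 'synB': 1.0}

assessed 15 surgical pairs across 3 procedures
  monobloc     targeted regions median m_r +2.07; untouched median |m_r| 0.05
  lefort3      targeted regions median m_r +2.45; untouched median |m_r| 0.11
  bipartition  targeted regions median m_r +1.02; untouched median |m_r| 0.01
global latent distance to the healthy mean decreased for 15/15 patients
```

Reading the numbers: the three classes are cleanly separable in shape space
(4.7 mm between classes vs 1.25 mm within), the autoencoder reconstructs to
about 6% of the shape signal, and perturbing one region's latent subset moves
essentially only that region's surface — the disentanglement the regional
metric relies on.  Held-out diagnosis is perfect at these effect sizes.  The
outcome metric scores the regions each simulated procedure actually targeted
(completeness 0.5–0.8 gives `m_r` of roughly `α/(1−α)` when the movement is
straight toward the healthy mean) while untouched regions stay near zero —
including the frontal/supraorbital regions under the subcranial "lefort3"
analogue.  The scripts also write the manifold arrow plot (pre → post per
patient over the class contours), the per-region `m_r` boxplot table, and a
per-vertex displacement heatmap whose colour scale saturates at 10 mm.

The same pipeline is available as a single call
(`cranioshape.pipeline.run_pipeline`) driven by a `PipelineConfig` or a TOML
file; rerunning with the same seed reproduces every CSV byte for byte.

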