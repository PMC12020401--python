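# Methods

## Setting and assumptions

All analysis happens downstream of dense point correspondence: every mesh has
the template's vertex count and triangulation, so vertex `i` is the same
anatomical point on every head.  Correspondence is treated as external
preprocessing — the package validates the topological contract (vertex count,
identical face list, finite coordinates, single connected 2-manifold) and
refuses meshes that break it, but never registers surfaces itself.  Anatomic
subunits are a per-vertex partition (every vertex in exactly one of `R`
non-empty regions) stored as a sidecar CSV, keeping the mesh files dialect
portable.  Vertex indices are 0-based internally; region ids are 1-based.

## Synthetic study conditions

The generator emulates the structure of a craniofacial cohort while staying
fully controlled:

- **Template** — an icosphere subdivided `n` times (642 vertices at the
  study scale `n = 3`; `n = 4`, 2562 vertices, is the default for the
  template constructor) anisotropically scaled to head proportions
  (semi-axes 75 × 95 × 110 mm) with a nose-like radial protrusion on the
  facial side.  The 15-region partition grows geodesic cells from fixed,
  roughly equally spaced anchor directions with seeded edge-length jitter;
  label propagation along shortest paths guarantees contiguous cells.  The
  region names are nominal labels, not registered anatomy.
- **Shape variation** — all displacement fields are spanned by nine
  low-order polynomial harmonics of the radial direction (constant, linear,
  quadratic), so variation is spatially smooth, as biological and surgical
  shape change is.  A class signature is such a field confined to designated
  regions (squared one-ring falloff keeps ≥ 90% of its energy inside them),
  scaled to a per-region RMS effect size.  Defaults: syndrome A loads 10 mm
  on the central midface and 8 mm on nose and upper lip; syndrome B loads
  10 mm on the frontal region and 8 mm on the supraorbital region and
  central midface; the healthy class has no offset.  Within-class individual
  variation is a Gaussian combination of 3 shared smooth modes scaled to a
  1 mm per-vertex RMS — a deliberately low-rank statistical-shape-model
  assumption that keeps each region's variation representable in a
  5-dimensional latent subset.  Effect sizes are therefore 8–10× the
  individual scale; 30 subjects per class train, 30 per class are held out.
  The population *structure* (offset fields, modes) is a function of the
  spec seed alone; a separate draw seed resamples individuals from the same
  distribution, which is how held-out cohorts are made.
- **Surgery** — on a target region set, vertices move by `α` times the
  difference to the healthy mean mesh (toward, away, or along a random
  smooth field of matched norm), with a one-ring blend outside the target
  set and optional smooth residual noise.  Ground truth (`α`, targets, mode)
  is recorded per subject.  `α > 1` is allowed: it models deliberate
  overcorrection past the healthy mean.
- **What the generator does not model** — age structure and growth (the
  cohorts the method is aimed at span infancy to adulthood), sex covariates,
  realistic facial geometry, acquisition artifacts, and registration error.
  Passing tests therefore demonstrate the *methodology* (geometry, metric,
  disentanglement, recovery under known ground truth), not clinical
  performance on real heads.

## Spectral augmentation

Populations are enlarged by blending same-class mesh pairs in the eigenbasis
of the template's uniform symmetric-normalized graph Laplacian (topology
only; robust on synthetic meshes).  Coordinates are projected onto the first
`k = 128` eigenvectors, parent coefficients mixed linearly with
`λ ~ Uniform(0.2, 0.8)`, and the out-of-basis residual mixed with the same
`λ` — so `λ ∈ {0, 1}` reproduces the parents exactly at any `k`, and the
interpolate's high-band energy never exceeds the λ-blend of its parents'.
Pairing is strictly within class so label inheritance is unambiguous.
Mid-range λ avoids near-duplicates.  Augmentation of the healthy class is
supported and used in the end-to-end study (all classes to 100), though the
augmentation helper skips the healthy class by default; healthy-class
Gaussians in the pipeline are fitted on original subjects only by default,
since augmented counts reflect policy, not prevalence (both are config
switches).

## The region-disentangled autoencoder

Each region has its own encoder (a linear map, optionally an MLP, from the
region's centered vertex block to a 5-dimensional diagonal-Gaussian
posterior) and its own decoder (latent subset back to the block); the
concatenation gives the 75-dimensional latent.  Disentanglement is thus
architectural; a boundary smoother (0.5 self + 0.5 one-ring mean on
region-boundary vertices) joins the decoded blocks, and it is applied inside
the training loss so the decoders learn to compensate its bias.  The loss is

    recon MSE + β · KL(posterior ‖ N(0, I)) + anchor · ½‖μ‖²/D + γ · swap,

with the KL averaged per latent dimension.  The `mean_anchor` term (0.1)
adds weight on the posterior-mean part of the divergence: it pins the latent
scale near the prior's, which matters because the swap-consistency penalty
is an absolute latent-space mismatch and would otherwise be diluted by
inflating latents (observed as a slow scale drift along the
encoder-scale/decoder-scale degeneracy).  β = 0.01 sets the posterior noise
floor well below the reconstruction target.  The swap penalty (γ = 1, 16
hybrids per batch) encodes mesh-space hybrids built by `region_swap`
(region `r` of one subject blended into another over a two-ring falloff) and
penalizes any deviation of the hybrid's latent from the swapped subset of
one parent and the remaining subsets of the other — this is what teaches
encoders to ignore the boundary contamination that blending necessarily
introduces into neighbouring blocks.  Training is full NumPy with manual
backprop and Adam (lr 0.01, cosine-decayed to bound optimizer drift), 300
epochs, batch 64, deterministic given the seed; inference uses the posterior
mean, so encoding is deterministic too.  Divergent (non-finite) training
raises with the epoch index.

Locality thresholds used in tests (off-region response < 20% of in-region)
are test parameters characterizing this toy model, not claims about any
larger architecture.

## Latent statistics

Per-class Gaussians are fitted with Ledoit–Wolf shrinkage by default (a
scalar shrinkage toward the scaled identity is available), plus a ridge
`ε · trace(Σ)/dim · I` with `ε = 1e-6`, escalated tenfold until the matrix
is positive definite — small per-region sample sizes make singular fits
likely otherwise.  Per-region distributions are the d×d diagonal blocks.
The Mahalanobis distance uses the standard form (inverse covariance, square
root); the literal quadratic form with the covariance and no root is exposed
for comparison but has no SD calibration — only the standard form satisfies
"distance 1 ⇔ one SD apart", which is the calibration the package tests.
QDA classifies by Gaussian log-density plus log prior (uniform priors by
default; argmax ties broken by class-name order for determinism).  LDA is
used only to draw the 2D manifold; with three classes the discriminant space
is exactly 2D, with two classes the single axis is padded with a declared
zero second axis.  The 2D projection is frozen after fitting — pre/post
surgical points are projected, never refitted — and it never enters the
outcome metric.

## The regional outcome metric

`m_r = [d_M(z_pre^r, z_post^r) / max(d_M(z_post^r, μ_H^r), ε)] · ⟨ŝ_r, v̂_H^r⟩`
with `ε = 1e-6` (in SD units).  Versors and the inner product are computed
in the whitened regional space (`Σ_H^r`^{-1/2}-scaled coordinates) so that
directions and distances share one geometry; this also makes every component
of `m_r` invariant under any common invertible linear reparametrization of
latents and covariance.  The ratio form is the primary reading — it rewards
procedures that end close to the healthy centre; the product form (movement
times residual distance) is available behind a switch for comparison.
Degeneracies are flagged, not raised: zero surgical movement yields
`m_r = 0` with a `no_movement` flag; a postoperative point at the healthy
mean floors the denominator at `ε` and sets `denominator_floored`.  On an
ideal noise-free trajectory with completeness `α`, `m_r = α/(1−α)` — strictly
increasing in `α`, with the floored cap at `α = 1`.

Cohort summaries group purely by procedure label (median, quartiles, n, flag
counts per region × procedure); patient history is not modelled.

## Numerical and reporting choices

- Mesh files: ASCII PLY (`property double`) and OBJ written at full
  precision, so write/read round trips are exact to well below 1e-6 mm.
- Laplacian eigenpairs: dense `eigh` up to 2000 vertices, shift-invert
  Lanczos beyond; eigenvector signs fixed (largest-magnitude entry
  positive) for determinism.
- Displacement heatmaps clip the colour field at 10 mm by default (raw
  values are always retained in exports).
- One global seed drives every stochastic stage of the pipeline; stage
  outputs are cached (the trained model as a checkpoint archive) and CSV
  outputs are byte-stable across reruns.
- Problem sizes in the shipped study: 642-vertex template, 30 + 30 subjects
  per class, augmentation to 100 per class, 300 training epochs — sizes at
  which the full analysis runs in well under a minute on one CPU while every
  contract (reconstruction < 10% of shape signal, locality < 20%, held-out
  precision) is comfortably met.

## Known limitations

The toy autoencoder is linear per region by default: it is sufficient for
the low-rank synthetic variation model and keeps training convex-like and
fast, but it is not a statement about what real craniofacial variation
requires.  The anatomical region names are nominal.  The metric inherits the
known caveat of aiming at the *mean* healthy shape: a straight whitened-space
trajectory is the declared ideal; curved (geodesic) latent trajectories are
out of scope.  Correlation with patient-reported outcomes is likewise out of
scope.
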