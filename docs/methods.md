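# Methods

## Problem

Task-based fMRI contrast maps (e.g. working-memory 2-back vs 0-back) are
expensive to acquire and noisy at the individual level, while resting-state
fMRI is cheap and carries a stable individual "fingerprint".  This package
implements a surface-based predictive model that maps a subject's
resting-state functional connectome, expressed vertex-wise on a spherical
cortical mesh, to that subject's multi-contrast task activation maps, along
with the reference predictors and the evaluation framework needed to decide
whether such a model captures *individual* structure rather than merely the
group mean.

## Data representation

All fields live on icospheres: recursively subdivided icosahedra with
`V = 10·4^L + 2` vertices at level `L`.  Vertex ordering is canonical — the
12 base vertices first, then the midpoints added by each subdivision in
sorted parent-edge order — so a coarse mesh is always an index prefix of the
next finer mesh and pooling between levels is an index restriction.  Real
cortical surfaces (e.g. fs_LR 32k, which is not a true icosphere) are
brought onto this hierarchy by nearest-neighbour resampling on the unit
sphere (`surface_io.resample_nearest`); GIFTI and CIFTI-2 adapters handle
the standard file formats, expanding CIFTI brain-model indexing to
full-surface arrays with an explicit cortex mask.

The model input is the vertex-to-ROI functional connectome: entry (i, j) is
the Pearson correlation between vertex i's rest timeseries and the mean
timeseries of ROI j, where ROIs are defined by winner-take-all assignment of
vertices to parcellation component z-maps (ties to the lowest component
index; degenerate constant series produce r = 0 rather than NaN).  Left and
right hemisphere connectomes can be concatenated channel-wise (2M channels)
under the fs_LR convention that equal vertex indices are contralateral
homologs.  Channels are z-scored with statistics estimated on the training
subjects only and stored with the model.

## Network

Convolution on the mesh uses parameterized differential operators.  For each
mesh level we assemble sparse matrices for the east–west derivative `D_ew`
(azimuthal direction), the north–south derivative `D_ns` (direction of
increasing polar angle) and a uniform graph Laplacian, each supported on the
one-ring.  The derivative rows come from a per-vertex least-squares fit of a
linear function over the ring in the tangent plane; at the (up to two) polar
vertices, where the azimuthal frame degenerates, the frame of the
lowest-index non-degenerate neighbour is projected onto the tangent plane.
All operators annihilate constants by construction.  A convolution layer
computes a learned per-channel-pair mixture of `[f, D_ew f, D_ns f, Lap f]`
plus a channel bias — 4 parameters per input/output channel pair, regardless
of resolution.

The model is a U-Net over consecutive icosphere levels: encoder blocks
(convolution → instance normalization → leaky ReLU; one convolution per
block by default — at small step budgets the shallower block converges
substantially faster at matched epochs, and `convs_per_block` is
configurable) with index-prefix restriction between stages,
a mirrored decoder with midpoint-averaging upsampling, optional skip
concatenation of encoder features, and a final linear convolution (the
"head") onto the output contrast channels at the input level.  The
head/backbone split is the unit of transfer learning.  All forward and
backward passes are explicit numpy/scipy computations; analytic gradients
are verified against numerical differentiation to 1e-4 relative in the test
suite.  The Laplacian is the uniform graph version by default: on the
near-regular icosphere the difference from the cotangent weights is small
and the uniform operator is exactly reproducible.

## Losses and training

Phase 1 minimizes the reconstructive loss `L_R`, the mean squared difference
between prediction and target over unmasked vertices × channels (mean, not
sum, so margins are resolution-independent).  Phase 2 minimizes

    L_RC = [L_R − α]+ + [L_R − L_C + γ]+

where `L_C` averages the prediction-to-*other*-subject divergence over the
(N²−N)/2 unordered pairs of the minibatch (with the standard batch size of
2, exactly one pair).  Margins are initialized from the converged phase-1
model: `α₀` is the average training reconstructive loss; for `γ₀` two rules
are implemented, because the source description is ambiguous: `γ₀ = L̄_C`
("absolute") or `γ₀ = max(L̄_C − L̄_R, 0)` ("gap", default).  We measured
both on synthetic cohorts: under the absolute rule the contrastive hinge
never disengages, so training settles at a stochastic equilibrium with
`L_R` strictly above α (the restoring force requires the first hinge to be
active); the gap rule lets contrastive pressure disengage once the gap is
met and keeps `L_R` at the margin, which matches the intended behaviour of
staying within the phase-1 reconstruction error.  During phase 2, α is
halved and γ doubled every 20 epochs.

Optimization is Adam (default lr 1e-3; the scaled benchmark uses 2e-2 for
the MSE phase and lr/8 for the R-C refinement phase — chosen for convergence
speed at small step counts, with the smaller refinement step keeping the
stochastic excess of `L_R` over α small).  One connectome is sampled per
subject per epoch from the run-segment pool (contiguous halves by default);
at test time predictions from all segments are averaged.  Training is
deterministic given the seed (single-threaded); the best state by validation
loss (training loss when no validation set is given) is restored at the end.

Finetuning on small cohorts uses MSE only, in three modes: `denovo` (fresh
seed, the control arm), `full_with_new_head` (fresh head for a new contrast
set, all parameters trained), and `backbone_only` (head frozen, loss
restricted to a channel mask; held-out channels receive exactly zero
gradient and improve only through the shared backbone).

## Baselines

The group average is the vertex-wise mean of the training subjects' maps.
The linear baseline fits, per training subject and per parcel, a
least-squares map (minimum-norm pseudoinverse, relative cutoff 1e-10, no
intercept) from the parcel's vertex-to-ROI features to its activation
values, then averages coefficients over subjects; by linearity this equals
ensembling the per-subject models.  Each contrast is solved separately
against the same feature matrix.

## Evaluation

Dice at threshold fraction x compares the top-x most activated vertex sets
(k = max(1, round(x·V_masked)), banker's rounding, ties to the lower vertex
index; signed values by default, with absolute/deactivated modes available).
Integrating Dice over x ∈ {0.05, …, 0.50} by the composite trapezoidal rule
gives the Dice AUC; the integration axis is the threshold *fraction*, so
perfect agreement scores 0.45.  Whole-brain R² is per contrast, with the
mean over contrasts as summary.  Subject identification builds the N×N
matrix of Dice AUCs between subject j's prediction and subject i's target;
a subject is identified when its column's strict maximum lies on the
diagonal (ties count as failures).  A contrast is individual-level reliable
when the mean target-vs-repeat Dice AUC exceeds the mean
target-vs-group-average Dice AUC.

## Synthetic cohorts

The generator emulates the structure of a multi-session surface fMRI study:
several rest runs and two task visits per subject, with a low-dimensional
latent fingerprint z_i coupling the two modalities.

* Parcellation: M seed vertices by farthest-point sampling; labels by
  nearest seed; synthetic component z-maps are distance-decay bumps, so
  winner-take-all recovers the generating labels.
* Rest: latent ROI signals are unit-variance AR(1) series (φ = 0.5), mixed
  into vertex space through loadings `W_i = base + Σ_k z_ik B_k`, where
  `base` is a smooth own-ROI profile shared by all subjects and `B_k` are
  fixed smooth basis fields; white sensor noise σ_ts is added per timepoint.
  The vertex-to-ROI correlation structure therefore carries z_i.
* Task: `Y_i = T_c + (ρ/√F) Σ_f φ_f(z_i) D_f + ε_visit`, with smooth group
  templates T_c, smooth coupling fields D_f, and visit-independent scan
  noise σ_scan; the map is smoothed by s iterations of one-ring averaging.
  In linear mode the latent features φ are the standardized latents; the
  nonlinear mode adds centered squares and pairwise products, producing a
  rest→task link that a parcel-wise linear readout cannot fully capture.
  The 1/√F normalization makes ρ (`deviation_scale`) the deviation-to-
  template amplitude ratio independent of the feature count.

Domain shift is modelled by splitting the generator's randomness: the
structural fields (parcellation, templates, coupling, loading basis) are
drawn from a `structure_seed`, subjects and noise from `seed`.  A transfer
cohort keeps the pretraining cohort's structure_seed — same "population" and
task set — draws new subjects, and perturbs the templates with a smooth
acquisition-shift field *shared across contrasts* (scanner and
preprocessing effects hit every contrast alike); the shared shift is what
makes leave-one-contrast-out backbone finetuning meaningful, since
adaptation learned on other contrasts transfers to the held-out one.

Contrast maps are not independent across channels: a fraction
(`contrast_share`, default 0.7) of each template and coupling field's
variance is carried by a small set of shared smooth spatial systems
(`n_systems`, default 3), emulating the strong inter-contrast correlation of
real task batteries that probe overlapping networks.  This shared structure
is also what makes leave-one-contrast-out transfer meaningful: corrections
learned on some contrasts constrain the others.

Default study conditions (CohortConfig): icosphere level 3 (642 vertices),
M = 10 ROIs, C = 6 contrasts, K = 3 latents, 2 runs × 400 timepoints,
2 visits, β = 1, σ_ts = 0.4, σ_scan = 0.35, s = 2, ρ = 1.2,
contrast_share = 0.7.  These choices
emulate, at desk scale, a regime in which (i) connectomes are stable
estimates (long runs relative to noise — the premise that rest data suffices
to fingerprint individuals), and (ii) the contrasts are individual-level
reliable with substantial inter-subject variability: the repeat visit beats
the group average clearly, as in the reliable-contrast subset that the
evaluation framework is designed around.  What the generator does *not*
emulate: hemodynamics, spatial autocorrelation of sensor noise, motion or
physiological artifacts, inter-subject misregistration, and a medial wall
(masks default to all-true; all metrics and losses accept masks).  Passing
tests on these cohorts therefore demonstrates the correctness and the
qualitative behaviour of the method — individual-specific prediction beyond
the group mean, the benefit of the contrastive phase for identifiability,
the transfer-learning orderings — not performance on real fMRI.

## Scaled experiment sizes

The end-to-end benchmark trains a depth-2 U-Net (widths 32/64/96, instance
norm, leaky ReLU) on 40 training subjects for 30 MSE epochs + 20 R-C epochs
at batch size 2, and evaluates on 10 held-out subjects; the transfer
experiment moves the pretrained model to a 12-subject cohort from the same
population with a shared acquisition shift (15 finetuning epochs at lr
5e-3, 10 backbone-only epochs, one contrast held out).  These sizes run in
a few minutes on one CPU.  They are two orders of
magnitude below a real cohort; the expected behaviour at this scale is the
*orderings* (model above group-average and linear baselines, finetuning
above de-novo training, identification improving with the contrastive
phase), not any published effect size.

## Numerical choices

* Correlations are clipped to [−1, 1]; degenerate series give r = 0 with a
  warning, keeping tensors finite.
* Pseudoinverse cutoff 1e-10 (relative) in the linear baseline; parcels can
  be under-determined.
* Winner-take-all assigns even when all z-scores are negative (an optional
  z-floor exists, off by default).
* Top-k ties resolve to the lower vertex index; identification ties count
  against the model.
* Instance normalization uses ε = 1e-5; biases feeding a normalization layer
  are retained for simplicity even though they are absorbed by it.
* Checkpoints are single .npz archives holding parameters, the architecture
  spec, normalization statistics and a provenance block.

## Known limitations

* Pure-numpy training is two to three orders of magnitude slower than a GPU
  framework; the package is meant for method study at reduced scale, not
  full-cohort training.
* The spherical convolution is not rotation-equivariant (the operator frame
  is anchored to the poles), matching the cited construction rather than
  spectral spherical CNNs.
* `fixed`-length segmentation drops the trailing remainder of a run.
* The linear baseline inherits the parcellation; badly under-sampled parcels
  rely on the pseudoinverse cutoff.
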