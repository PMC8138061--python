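# Methods

`msdiffusion` implements a complete single-shell diffusion-MRI lesion
analysis — voxelwise model fitting, 3D region-of-interest (ROI)
construction, and SVM-based feature evaluation — and pairs it with a
synthetic phantom generator so that every stage is testable without
patient data.  This note documents the models, the defaults and why they
were chosen, what the phantom does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Acquisition model

The reference acquisition is a clinical single-shell protocol:
b = 1000 s/mm², 3 b0 volumes, 45 diffusion directions, 2 mm isotropic
voxels.  Direction sets are generated by electrostatic repulsion with
antipodal symmetry (seeded L-BFGS minimization of the Coulomb energy); the
45-direction layout has a minimum pairwise angle above 20°.  Gradient
tables are read and written in the FSL bval/bvec dialect; volumes in
NIfTI-1.

## Phantom

The phantom is a mirrored-hemisphere slab: two x-oriented white-matter
bundles placed symmetrically about the mid-sagittal plane, an isotropic
background (ADC 0.8 × 10⁻³ mm²/s), and spherical lesions embedded in the
left-hemisphere bundle.  The noiseless signal is the multi-tensor closed
form S = S0 · Σ f_k exp(−b gᵀD_k g); noise is Rician with channel
σ = S0/SNR (SNR = ∞ gives the exact noiseless signal, which the fitting
round-trip tests rely on).  The left–right flip axis is the grid x axis;
under mirroring, the x component of a gradient direction changes sign,
which leaves the x-aligned bundle signal invariant — the convention every
contralateral-NAWM operation in the package assumes.

Two lesion contrast mechanisms are provided, reflecting the two axes of
lesion pathology probed downstream:

* **Diffusivity contrast** — the lesion (and optionally its erosion-defined
  core) carries its own tensor eigenvalues; the default core/shell pairing
  emulates a hypocellular lesion center (core λ = (2.1, 0.8, 0.8) × 10⁻³
  vs. shell (1.6, 0.45, 0.45) × 10⁻³ mm²/s): mean diffusivity rises
  strongly, radial diffusivity more than axial.
* **Orientation contrast** — the lesion signal is a mixture of tensor
  copies on a cone about the bundle axis (half-angle `dispersion_deg`,
  6 fan components + 1 axial) plus optionally a second crossing population.
  The mixture preserves the trace, so the contrast is carried by
  orientation structure, not total diffusivity.

Regional biological variability is drawn once per lesion region and,
independently, once per mirrored contralateral region: a multiplicative
eigenvalue jitter (`regional_scale_sd`), a dispersion half-angle
(`dispersion_sd` around the region's mean), and a crossing fraction
(`crossing_sd`, lesions only).  This is what makes ROI-level feature
distributions overlap between classes the way heterogeneous tissue does;
without it every classification task on the phantom is perfectly separable
and feature rankings degenerate.

Two named cohort conditions freeze the study settings used by the
acceptance checks:

* `orientation_contrast_cohort` — NAWM baseline dispersion 26° ± 8°,
  lesion dispersion 40°, crossing fraction 0.22 ± 0.12 at 50°, lesion
  fiber components (1.5, 0.4, 0.4) × 10⁻³ (modest anisotropy reduction),
  diffusivity jitter 15 %, SNR 40, 8 subjects with 3–6 lesions each.  The
  three lesion abnormalities (dispersion, crossing, component shape) are
  deliberately *distinct* latents: a single orientational latent makes all
  orientation features redundant copies of one another and recursive
  feature elimination then keeps only the best-measured one.
* `diffusivity_contrast_cohort` — large lesions (radius 3–3.8 voxels, so
  cores exist), the core/shell eigenvalue gradient above, common baseline
  dispersion 18° ± 8° for core and shell, jitter 8 %, SNR 40, 6 subjects.

The SNR and the direction scheme of the emulated protocol are not fixed by
the protocol description itself; SNR 40 on the b0 (typical for clinical
2 mm DWI at 3 T) and the repulsion layout are package choices.  What the
phantom does **not** emulate: EPI/eddy distortions, motion, partial-volume
averaging at lesion boundaries (masks are binary), anatomical T1/T2
contrast, registration error (the mirror transform is exact), and
pathology beyond the two contrast mechanisms.  Passing tests therefore
demonstrate internal consistency of the pipeline and the *direction* of
feature sensitivities, not clinical performance.

## ROI construction

Lesion components are labeled under 26-connectivity (faces + edges +
corners, the convention used for 3D lesion clustering) and numbered by
descending voxel count, ties broken by the component's minimal (z, y, x)
voxel.  Contralateral NAWM ROIs are the lesion masks mapped through a grid
involution — by default the exact left–right flip; any involutive
transform can be supplied so a registration-derived map can be plugged
in — intersected with white matter and cleaned of every lesion voxel.  A
pair is dropped when fewer than 50 % of the mirrored voxels survive the
exclusion (`min_retention`, configurable); pairing pipelines on real
cohorts discard an appreciable fraction of lesions at this step without a
standard published cutoff, so the threshold here is a package choice.

The lesion core is the binary erosion with the full 3 × 3 × 3 structuring
element: exactly the voxels whose 26 neighbors all lie inside the lesion.
This is the only structuring element that makes the shell (lesion minus
core) single-voxel-thick in the same 26-adjacency sense the labeling uses.
Out-of-grid voxels count as background, so a lesion touching the volume
edge loses its border layer to the shell.  Lesions whose erosion is empty
(thinner than 3 voxels in any direction) are ineligible — a normal
outcome, not an error.  Reference values: a 3³ cube splits 1 / 26, a 5³
cube 27 / 98, a 2-voxel-thick slab is ineligible.

## DTI

Per voxel, ln S = ln S0 − b gᵀD g is solved by ordinary least squares over
the six tensor elements plus ln S0 (plain OLS, no weighting or outlier
rejection — the classical default of the era this pipeline reproduces).
Non-positive signals are clamped to 10⁻¹⁰ before the log and flagged;
negative eigenvalues are clamped to zero (not reflected) and flagged.
Scalars: MD = tr(D)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
FA = √(3/2)·‖λ − MD‖/‖λ‖, with FA ≡ 0 for an all-zero tensor.  Noiseless
round trips recover eigenvalues to 10⁻⁹ mm²/s and agree with an
independent nonlinear least-squares fit to 10⁻⁶ relative.

## Single-shell HARDI

**ODF.**  Analytic Q-ball: the b0-normalized signal is projected on a
real, even-order, antipodally symmetric spherical-harmonic basis (order 6
for 45 directions → 28 coefficients) with Laplace–Beltrami regularization
(λ = 0.006, the standard value for this reconstruction), then the
Funk–Radon transform is applied as the diagonal operator 2π P_ℓ(0).
Amplitudes are evaluated on the acquisition's own 45 directions and
min–max normalized to [0, 1] per voxel before downstream use.

**ODF energy.**  The voxel's N amplitudes are treated as a sample, fitted
with a normal distribution by maximum likelihood (mean and population
standard deviation, floored at 10⁻⁶ in normalized units), and each
amplitude is converted to its fitted density p_i.  The energy is
Σ_i log(p_i²) = 2 Σ_i log p_i — twice the log-likelihood of the amplitude
sample under its own normal fit.  A orientationally simple voxel has a
tight, near-normal amplitude distribution and high energy; crossing or
dispersed structure spreads the distribution and lowers it.  Densities are
not probabilities, so the sign of the energy is unconstrained, and
rescaling all amplitudes by c shifts it by exactly −2N log c — the reason
the per-voxel min–max normalization matters.  Two aggregation readings are
possible ("log of the squared probabilities of all directions"); the sum
Σ log p_i² is the default because it treats the direction collection
symmetrically and is a log-likelihood, while log Σ p_i² is available as
`mode="log_of_sum"`.  The normal fit is per voxel; a region-level fit is
the other conceivable reading and is not implemented.

**Compartment maps.**  A linearized dictionary formulation: axially
symmetric response atoms are tabulated as functions of |cos θ| between
gradient and symmetry axis, aligned per voxel to the principal DTI
eigenvector, and fitted by non-negative least squares with Tikhonov
damping on unit-normalized columns (damping 10⁻⁴; normalization keeps the
penalty from favoring weak-signal atoms).  Two sub-models are fitted
independently, as their reference implementations do:

* sticks dispersed by a Watson distribution over
  κ ∈ {0.25, 0.5, 1, 2, 4, 8, 16, 32, 64} plus an isotropic ball →
  ODI = (2/π) arctan(1/κ̄) with κ̄ the stick-weight-averaged κ, and
  ICVF = stick weight / (stick + ball weight);
* Gaussian-phase-approximation (van Gelderen) cylinders over 12 radii
  0.5–10 µm plus a ball, under nominal pulse timings δ = 30 ms,
  Δ = 40 ms → diameter = 2 × weight-averaged radius, and axon density =
  cylinder weight fraction / (π r̄²) in µm⁻².

Intrinsic diffusivities are fixed (d∥ = 1.7 × 10⁻³, d_iso = 3.0 × 10⁻³
mm²/s) — on a single shell they are not identifiable jointly with the
volume fractions.  Watson integrals use a deterministic polar × azimuth
product quadrature (400 × 64) with polar nodes clustered toward the mean
axis, accurate through the near-coherent regime (κ = 10⁶ matches the pure
stick to 10⁻⁶).  Cylinder radii below ≈ 3 µm are indistinguishable from
sticks at b = 1000 (atom signal distance ~10⁻³), so the diameter map is
reported but treated as weakly identified everywhere.

## Tractography

Deterministic FACT: one seed per seed-mask voxel center, bidirectional
propagation along the voxelwise principal eigenvector with nearest-voxel
lookup, step sign chosen to stay within 90° of the previous step, and
termination on leaving the mask, FA < 0.15, or a turning angle above 35°
(the recommended threshold for this algorithm; FA threshold and 1 mm step
are package defaults, configurable).  FDi counts *distinct* streamlines
per voxel (set semantics — a loop counts once); FTi counts endpoints, two
per streamline.  Both maps are invariant under streamline reversal.

## Feature tables and classification

Each ROI sample is the mean of each map over the ROI's voxels: 11 features
(AD, RD, MD, FA, ODI, density, diameter, ICVF, ODF_energy, FDi, FTi) for
the lesion-vs-NAWM and between-subject tasks, 9 for core-vs-shell (FDi and
FTi are excluded — streamline counts are too sparsely represented in
single-voxel-scale sub-ROIs).  Features are min–max normalized to [0, 1]
over the whole table before cross-validation, reproducing the protocol
this pipeline emulates; that normalization leaks the test range into
training, so a strict per-fold variant (`minmax_normalize_fold`) is
provided for sensitivity analyses.

**SVM-RFE.**  Ten random 10-fold partitions; each leave-one-fold-out
subset (90 % of rows) trains one recursive-feature-elimination run with a
linear SVM, C = 1, eliminating exactly one feature per step by smallest
squared weight (ties: lowest column index).  The last survivor holds rank
1; 10 × 10 = 100 constructions give each feature a mean and sd of rank.

**SVM-IC.**  Features enter one at a time in mean-rank order.  Each top-k
model is evaluated by stratified 10-fold cross-validation (one partition
reused across k, so successive models are paired sample-by-sample);
test-fold decision values are pooled into one rank-aggregated ROC per k.
Reported per k: pooled accuracy (fold-mean also emitted), AUROC, McNemar
tests against a seeded Bernoulli(½) guesser and against the previous
model, an exact binomial test of accuracy vs 0.5, and DeLong tests of the
AUROC against 0.5 and against the previous model.  Pooled (rather than
vertically averaged) ROCs are the default reading of "rank aggregated";
the fold-mean accuracy is also reported since either convention is
defensible.

## Statistics

McNemar: continuity-corrected χ² (|b−c|−1)²/(b+c) on 1 df, and the exact
two-sided binomial p = min(1, 2 min(P(X≤b), P(X≥b))) with
X ~ Bin(b+c, ½); the exact variant returns p = 1 with a flag when there
are no discordant pairs.  DeLong: Mann–Whitney AUC with half-credit ties;
variances and covariances from the placement-value structural components;
two-sided normal p; the single-model variant tests AUC = 0.5.  Cohort
stratification: subjects with lesion counts strictly above the 75th /
below the 25th percentile (linear-interpolation quantiles) form the high /
low groups; boundary subjects are excluded, and a degenerate distribution
(both groups empty) is an error.

## Numerical and design notes

* Eigendecompositions use symmetric solvers; eigenvalues are reported in
  descending order with orthonormal eigenvectors.
* All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical phantoms, rankings, and curves.
* The flip transform is validated as an involution before use; non-grid
  transforms must be supplied by the caller as mask→mask callables.
* Empty masks: labeling an empty lesion mask yields zero ROIs;
  empty ROI rows are skipped with a warning; an all-zero voxel gets zero
  compartment maps with a flag rather than an error.
* Constant feature columns normalize to 0 with a warning (FTi is constant
  on fully coherent phantoms, for instance).
* Problem sizes in the test suite and acceptance script — 40 × 40 × 20
  grids, 6–8 subjects per cohort, 40–72 ROI rows per task — are the
  package's reference configuration for desk-scale reproduction; the
  modules themselves are size-agnostic.

## Known limitations

* Diameter/density at b = 1000 s/mm² are weakly identified; they are
  computed and reported but no quantitative claim should rest on them.
* ODI from the dictionary fit is biased upward in coherent tissue at
  moderate SNR (noise reads as dispersion); comparisons should be within
  one protocol and SNR level.
* The phantom's lesion masks are geometric spheres without partial-volume
  boundaries, so ROI means are cleaner than in real data; classification
  accuracies on the phantom are not calibrated to clinical values.
* Whole-dataset min–max normalization before cross-validation reproduces
  the emulated protocol but is a known leakage risk; use the per-fold
  variant when measuring generalization.
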