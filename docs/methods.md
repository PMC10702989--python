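# Methods

This note documents the models and procedures implemented in `fsnmm`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The framework studies single-SNP imaging-genetics association in a
cohort with ordered diagnosis classes (healthy controls, moderate
depression, severe depression). Each subject carries two phenotype
modalities indexed by the same brain parcellation (by default the 116
AAL regions):

* **node features** — mean gray-matter volume per ROI, from sMRI;
* **edge features** — one weighted clustering coefficient per ROI,
  computed from the subject's ROI×ROI Pearson functional-connectivity
  (FC) matrix of resting-state BOLD series.

The response is one SNP's additive genotype code y ∈ {0,1,2}^N (minor
allele dosage). The pipeline starts from ROI-level tables; voxel-level
preprocessing, registration and genotype QC are upstream and out of
scope.

## Feature construction

FC is the Pearson correlation of per-ROI series standardized to zero
mean and unit variance. The per-ROI clustering coefficient uses the
Onnela geometric-mean-of-triangles statistic on the fully weighted
graph,

c_i = (1 / k_i(k_i−1)) Σ_{j≠h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3},

with ŵ = |w| / max|w| over off-diagonal weights and k_i the count of
nonzero incident weights. This statistic is threshold-free (no
binarization of the FC matrix), bounded in [0,1], invariant to global
positive rescaling, and — with the absolute-value convention — to the
sign of any entry. Negative correlations may alternatively be zeroed
(`negative_weights="zero"`); absolute values are the default because
they keep every ROI's full connectivity profile in play. Feature
columns are z-scored; inside cross-validation the scaling is always fit
on training subjects only and applied to held-out subjects.

## Diagnosis-restricted self-expressive networks

Each subject's feature vector is reconstructed as a sparse nonnegative
combination of the *other subjects with the same diagnosis*:

min_{w≥0} ½‖x_i − D w‖² + λ‖w‖₁,

where D stacks the same-class donors. Nonnegativity is a constraint of
the optimization (the feasible set), not a post-hoc truncation of a
signed solution; the two differ in general. The solver is cyclic
coordinate descent on the donor Gram matrix with nonnegative
soft-thresholding, coordinates visited in subject order (deterministic
under duplicated donors), stopping when the largest coordinate update
falls below 1e-8 or after 10,000 sweeps. The per-subject codes are
stacked and symmetrized, W = W̃ + W̃ᵀ, diagonal forced to zero, giving a
symmetric nonnegative class-blocked subject network per modality.

The sparsity level λ is not dimensionless, so the default is expressed
relative to the data: λ = 0.1·λ_max, where λ_max (from the KKT
conditions) is the smallest penalty that zeroes every subject's code.
This keeps the network density comparable across datasets and
modalities; the fraction and the absolute value are both overridable.

## Fusion by class-guided diffusion

For each modality the network is row-normalized within each subject's
class (the *local affinity* A, the diffusion kernel; rows with no
within-class weight stay zero). The kernels are computed once and held
fixed. Each iteration replaces modality m's network by the
kernel-diffused average of the other modalities:

W^m ← A^m [ Σ_{q≠m} W^q / (M−1) ] (A^m)ᵀ,

restricted to within-class entries. The fused network W^f is the
off-diagonal modality average with zero diagonal. Convergence is
monitored by the relative Frobenius change of W^f between iterations;
iteration stops below 1e-6 or at the cap (default 10 iterations, hard
cap 25; the cap exists because the tuning regime of the method used up
to 25). If ‖W^f‖ = 0 the change is defined as 0 and iteration stops.

**Scale renormalization.** The fixed-kernel update is a linear map
whose spectral radius on the relevant subspace is slightly below one,
so the bare iteration shrinks the networks' overall scale geometrically
— the relative-change monitor then measures that scale decay and
plateaus around 10⁻² instead of converging. Each modality iterate is
therefore renormalized by its symmetric degree scaling
W ← D^{−1/2} W D^{−1/2} (D = row sums), standard practice in
similarity-network-fusion implementations. This pins the scale while
preserving symmetry, nonnegativity and the class-block support; with it
the monitor reaches 1e-6 within roughly 11–15 iterations on the default
synthetic data. `fuse(normalize="none")` runs the bare update, which is
what the loop-transcription equivalence tests check.

Two index conventions exist for the diffusion's column sum
(`cross_class="zero"` restricts both indices to the row subject's
class, forcing cross-class entries to zero; `"snf"` uses the column
subject's class, the classic similarity-network-fusion form). For
class-blocked inputs — which diagnosis-restricted networks are by
construction — the two coincide exactly; the zeroing form is the
default.

**What the converged fusion is.** A converged class-restricted linear
diffusion sits at the dominant-eigenvector limit of its kernels: each
class block is numerically rank one, so the fused reconstruction
W^f X^m is essentially a per-class mean profile. This is what makes
the representation strongly diagnosis-discriminative, and it is also a
real limitation: individual within-class variation does not survive a
converged fusion, so per-ROI weight maps computed on fusion-
reconstructed features identify only the few directions that separate
class means (see *Known limitations*).

## Multi-modality association with joint feature selection

The association model regresses the genotype code on all modalities
simultaneously with a row-group penalty:

min_W ½ Σ_m ‖y − X^m w^m‖² + λ‖W‖_{2,1},  ‖W‖_{2,1} = Σ_j ‖W_{j·}‖₂,

with X^m either the raw or the network-reconstructed features. The
L2,1 norm couples each ROI's coefficients across modalities, so a ROI
is selected in all modalities or none ("consistent ROIs"). y is
centered before fitting; the intercept is implicit, which is harmless
because the evaluation metric (Pearson correlation) is shift-invariant.
No sign constraint is placed on W.

Solver: FISTA (accelerated proximal gradient) with the exact Lipschitz
step 1/L (L = max over modalities of the top Gram eigenvalue), row-wise
group soft-thresholding as the proximal map, deterministic start at
W = 0 (or a warm start), and a monotone restart — if a momentum step
raises the objective, the step is replaced by a plain proximal step
from the last accepted point, which cannot increase the objective at
step 1/L. Stopping: relative objective change below 1e-10 or 5,000
iterations. The single-matrix lasso used by the SM/CM baselines is the
exact M = 1 special case of the same objective and solver.

## Evaluation protocol

Repeated, nested, class-stratified cross-validation. Defaults: 5 outer
folds, 5 inner folds, 5 repeats whose fold partitions are re-drawn with
seeds `seed + repeat`. λ is tuned on the grid
{1e-5, 3e-5, 1e-4, …, 1, 3} by maximizing the mean inner-fold held-out
correlation summed over modalities; ties take the smaller λ. The score
is the Pearson correlation (CC) between predicted and actual genotype
codes, defined as 0 for zero-variance predictions so degenerate
all-zero fits are penalized rather than dropped. Reported values are
mean ± SD across repeats of fold-averaged CC.

The comparison ladder crosses model kinds {SM, CM, MM} with
representations {raw, SN, FSN}. Networks (self-expressive and fused)
are always estimated from the outer-training fold only; the inner CV
tunes λ on the reconstructed training features. Inner-CV fits run at a
reduced iteration cap (1,000) since they only steer the λ choice; the
final refit on the full training fold runs at full precision.

**Held-out subjects under SN/FSN.** How new subjects enter a
reconstruction defined over the training cohort is genuinely open.
Default (`sparse_code_on_train`): a test subject is nonnegatively
sparse-coded against all training subjects *without label restriction*
(its diagnosis is unknown at prediction time), and the code is applied
to the reconstructed training rows, expressing the subject in the same
representation the model was fit in. Applying the code to raw training
rows instead creates a train/test representation mismatch that is
severe precisely when the reconstruction is far from the identity.
`raw` skips test reconstruction; `transductive` builds networks over
all subjects with all labels before splitting — it leaks test labels
and exists only to reproduce a literal all-subjects reading of the
fused model; it must not be used for honest evaluation.

SNP screening runs the configured variant on every polymorphic column
of a genotype table (monomorphic SNPs are skipped and logged) and sorts
by mean held-out CC. ROI ranking averages absolute row-group norms over
repeats × folds, max-normalizes, and reports per-modality and joint
top-k plus their intersection ("consistent ROIs"). Group-level edge
reporting averages FC matrices per diagnosis group and returns the k
strongest mean edges at a chosen ROI.

## Synthetic data

The cohort data behind the method are private clinical recordings, so
the generator emulates their structure for testing:

* c diagnosis classes (default 3 × 50 subjects); per class and modality
  an orthonormal basis of a low-dimensional subspace (default 4 of 60
  dimensions) and subjects as random subspace points — the regime in
  which within-class self-expression reconstructs subjects well;
* a planted support of k ROIs (default 6) shared across modalities with
  coefficients of magnitude `effect_size`;
* class-mean offsets on the support ROIs (`class_sep`): diagnosis
  groups differ in mean phenotype exactly where the genotype signal
  lives, reflecting the premise that a risk SNP associates with the
  disease-relevant regions. Off-support features carry no class-mean
  differences — an idealization; in real cohorts disease effects are
  not perfectly localized;
* the latent response is built from the *noise-free* features
  (signal lives in the class/subspace structure; measurement noise is
  added afterwards to the observed features — an errors-in-variables
  setup, which is the regime in which self-expressive denoising can
  help at all);
* `additive_012` mode thresholds the latent response at its empirical
  tertiles onto {0,1,2}. This yields balanced genotype codes with a
  monotone link to the linear signal; it is a simplification, not an
  allele-frequency model (no Hardy-Weinberg structure, no LD, no
  population stratification);
* noise defaults (feature and response SD 1.0 against unit-scale clean
  variance) put held-out CC for the full method near 0.5 — the
  weak-signal regime this class of method targets, rather than a
  saturated one where reconstruction has nothing to add.

All randomness flows from one seeded generator; every dataset records
its configuration. `permute_response` produces matched null datasets.

Because the generator realizes the method's own premises (exact
low-dimensional class subspaces, genotype signal localized on
class-separating ROIs), passing tests demonstrate internal consistency
of the implementation and the qualitative behavior of the method under
those premises — not performance on real imaging cohorts, where the
premises hold at best approximately.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations to keep
a complete run cheap on a single core while preserving the regimes of
interest: ladder/ordering comparisons use N = 45 (3 × 15) subjects with
d = 60 features over 20 generated datasets; null calibration uses
N = 45, d = 20 over 20 datasets; support recovery uses N = 150, d = 60
(its stated conditions); fusion convergence uses N = 60, d = 60. The
evaluation protocol in these checks runs one repeat of 5-fold nested
CV per dataset, with the across-dataset average taking the role of the
across-repeat average.

## Numerical choices

* Coordinate descent tolerance 1e-8 on the max coordinate update,
  10,000-sweep cap; the kernel is JIT-compiled when numba is present
  (pure-Python fallback otherwise, identical arithmetic).
* FISTA: exact Lipschitz constant from Gram spectra; relative objective
  tolerance 1e-10, 5,000-iteration cap; momentum restart on objective
  increase guarantees monotonicity.
* λ grids are shared across modalities because features are z-scored.
* Degenerate inputs: a subject alone in its class yields an all-zero
  code (warning); zero-sum affinity rows stay zero; a zero fused
  network terminates fusion; zero-variance predictions score CC 0;
  constant feature columns raise an error naming the feature.
* Ties: grid-search ties take the smaller λ; coordinate order fixes
  ties among duplicated donors; stable sorts fix ranking ties.

## Known limitations

* A converged class-guided diffusion collapses class blocks to rank
  one. Consequently ROI-level support recovery from fusion-
  reconstructed features is limited to roughly one direction per class:
  the shipped recovery experiment at N = 150 with a 6-ROI planted
  support recovers at most ~4 support ROIs regardless of λ, and the
  corresponding acceptance check fails by design of the method, not by
  solver error. Weight maps from the raw or SN representations do not
  have this limitation.
* The CC metric is computed per modality; no significance testing of
  CC differences between variants and no multiple-testing correction
  across screened SNPs are performed.
* The lasso/L2,1 losses are squared-error on the 0/1/2 codes; ordinal
  or logistic losses are out of scope.
* Affine or kernelized self-expression (Σw = 1 variants) is not
  implemented.
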