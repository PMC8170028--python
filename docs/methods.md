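# Methods

## Model and procedure

flexitomo treats heterogeneity analysis of cryo-ET subtomograms as a
per-particle inverse problem. A flexible reference is parametrized by
normal-mode amplitudes; for each subtomogram the method estimates jointly
the amplitudes (elastic parameters) and the rigid-body pose (three ZYZ
intrinsic Euler angles and three voxel shifts) that maximize the
wedge-constrained cross-correlation between the rendered reference and the
data. The amplitude vectors of all subtomograms are then analyzed in a
low-dimensional PCA space.

### Reference structures

An atomic model is used directly (chain filtering supported). A density map
is first converted into pseudoatoms: isotropic 3-D Gaussians of a common
standard deviation (default 1 voxel), placed by greedy residual-peak search
with parabolic sub-voxel localization and periodically re-fit by sparse
linear least squares on the amplitudes, until the relative L2 approximation
error drops below a target (default 5%). The interior placement/refinement
schedule is this package's own; only the (sigma, target error) contract and
the stopping rule are externally defined, so pseudoatom *counts* are
implementation-sensitive. Atom weights default to 1: neither the elastic
network nor the rendering is mass-weighted.

### Normal mode analysis

The elastic network is a Tirion model: every pair of nodes closer than a
cutoff (default 8 Å for atomic models; for pseudoatomic models a quantile of
the pairwise-distance distribution, default the 1st percentile) is joined by
a spring of identical stiffness k = 1. The eigenvalue scale is arbitrary —
the pipeline consumes only mode shapes and amplitudes. Two diagonalization
routes:

* **Cartesian** — direct diagonalization of the 3N×3N Hessian (dense up to
  3N = 3000, shift-invert Lanczos above). Used for pseudoatomic models.
* **RTB** — one or more consecutive residues form rigid blocks; the Hessian
  is projected on the per-block rigid-body subspace (≤ 6 DOF per block,
  orthonormalized about the block centroid, degenerate DOFs dropped), the
  reduced matrix diagonalized and eigenvectors back-projected to 3N and
  renormalized to unit norm. Used for atomic models.

Modes are numbered globally from 1; the first six are the zero-frequency
rigid-body motions and are never selectable for elastic alignment. Each
mode carries a collectivity κ ∈ [1/N, 1] (exponential of the entropy of
normalized squared per-atom displacements). Default selection: the lowest
frequency modes above a collectivity threshold, with manual extra indices
for expert choices. Mode signs are fixed (largest-magnitude component
positive) for reproducibility.

Because selected modes are unit-norm and orthonormal, displacement by
amplitudes a gives RMSD = ‖a‖/√N exactly; amplitude 200 on each of two
modes of a 1656-atom structure gives √(2·200²/1656) = 6.95 Å. All
amplitude-error-to-Å conversions use this identity.

### Rendering and simulation

Structures are rendered as sums of unit-mass isotropic Gaussians (default
sigma = 1 voxel), truncated at 4σ (mass loss < 10⁻³). Volumes are cubic,
indexed [z, y, x], geometric center at voxel n/2; MRC2014 mode-2 I/O.

The synthetic-data generator reproduces the validation study's conditions
and is first-class, tested code:

* **"Discrete"**: amplitude pairs on the two generator modes drawn from
  {(−150, 0), (+150, 0), (0, +150)}, classes as equal as n allows.
* **"Continuous"**: equal amplitudes on both modes, uniform in [−200, 200].
* Poses: Euler angles uniform in [0, 360)³; shifts uniform in ±5 voxels.
* Forward model per subtomogram: deform → render (64³, 2.2 Å/voxel) →
  rotate/shift → project tilt series (−60°…+60°, 1° steps; parallel beam
  along z, tilt about y) → CTF (defocus −1 µm, 300 kV, Cs 2 mm, amplitude
  contrast 0.1) with Gaussian white noise at SNR 0.01 split half before and
  half after the CTF (the pre-CTF part variance-compensated so the split is
  exact after filtering; noise normalized per image) → direct Fourier
  reconstruction.
* Reconstruction inserts each image's 2-D DFT as a central slice with
  trilinear gridding and hit-count weighting on a 2× oversampled Fourier
  grid (zero-padded images), crops back to the acquisition box and
  restricts the Fourier support to the trusted region. Without
  oversampling, trilinear smearing at the spectrum's correlation length
  (≈ 1.5 voxels for a box-filling particle) caps the fidelity of all
  reconstructions near FSC ≈ 0.9; with it the noise-free identity pipeline
  correlates > 0.99 with the wedge-filtered rendering.

The wedge geometry: a sample (kx, ky, kz) is trusted iff
atan2(|kz|, |kx|) ≤ tilt_max. Counted inside the in-plane Nyquist disk
(where angles are uniformly distributed) a ±60° range excludes 1/3 of the
samples; the corners of the Fourier cube beyond that disk are never sampled
by any tilt and are not part of the angular-mask accounting.

What the generator does **not** emulate: crowded cellular backgrounds, dose
accumulation over tilts, per-tilt defocus gradients, and per-tilt alignment
errors. Passing tests therefore demonstrate correctness of the estimator
under the stated forward model, not robustness to those real-data effects.

### Combined elastic and rigid-body alignment

The wedge-constrained CC is a Pearson correlation over trusted Fourier
coefficients (DC excluded, which subtracts the means), equal to the plain
correlation of the two wedge-filtered volumes. The matching CC is
band-limited (default 0.25 cycles/voxel): the data carry no usable signal
near Nyquist at the simulated SNR, and the fast rotational matching this
step follows is band-limited by construction.

When the data's CTF is known, the rendered reference is modulated by the
radial CTF profile before matching (`AlignmentOptions.ctf`, off by
default). A coefficient at radius |k| in a tilt-series reconstruction
carries the factor CTF(|k|); without this modulation the correlation
contributions beyond the first CTF zero (0.157 cycles/voxel at −1 µm,
300 kV, 2.2 Å voxels) have inverted sign and bias the pose optimum by
5–10°, an order of magnitude above the method's intrinsic accuracy.

Pose search ("fast rotational matching", hierarchical):

1. one global scan of a near-uniform SO(3) grid (default 20° steps, tilt
   rings weighted by sin θ) scored at a Fourier-cropped 32³ copy of the
   subtomogram, translations from the FFT correlation peak with parabolic
   sub-voxel interpolation (the correlation value is corrected by the
   separable parabolic peak gain — scoring at integer shifts only biases
   the rotation search by several degrees);
2. the best candidates (default 5, deduplicated at 3°) are refined by a
   greedy pattern search over small rotations about the three axes
   (avoiding Euler gimbal issues) and kept as parallel "tracks";
3. at every objective evaluation of the amplitude search each track is
   locally re-refined for the current deformation and the best is re-scored
   at full resolution — so the rigid parameters are re-estimated every
   evaluation while staying robust to basin swaps;
4. a final full-resolution polish (down to 1°) and an exact CCC evaluation
   at the sub-voxel pose produce the reported result.

Amplitude search: a derivative-free quadratic-model trust-region minimizer
(full quadratic interpolation on (n+1)(n+2)/2 points, exact More–Sorensen
trust-region steps, ridge-stabilized least-squares model fits). Amplitudes
start at zero; initial radius = 100 × `trust_region_scale` (scale 1 covers
the ±200 amplitude range of the study after at most one expansion; 1–2 for
larger motions, 0.5–0.9 for smaller), final radius 1 amplitude unit,
default budget 60 evaluations. Ties in CCC prefer the smaller deformation,
then the smaller rotation. The optimizer never raises for valid inputs;
failures return the best-so-far result flagged as non-converged.

`align_dataset` processes subtomograms independently (optional process
pool; results identical for any worker count) and can checkpoint/resume
from a partial TSV.

### Conformational space

PCA of the n×M amplitude table (centered, components by descending
variance, deterministic sign convention). Outliers are flagged by squared
Mahalanobis distance to the sample mean/covariance **in the full
M-dimensional amplitude space** (not post-PCA; the exclusion guards the
amplitudes themselves and is independent of the chosen embedding
dimension), with p-values from the chi-square law with M degrees of
freedom; defaults p > 0.01 (discrete-type data) or p > 0.001
(continuous-type). Groups are axis-aligned ellipses in projected
coordinates, optionally sub-filtered by CCC. Group averaging applies the
inverse rigid pose per item (one trilinear resampling); with wedge filling,
each item's untrusted coefficients (its wedge mask rotated along with it)
are replaced by the global average's before summation, giving the average
full Fourier support. Trajectories are piecewise-linear paths sampled
uniformly by arc length (default 10 frames), inverse-mapped to amplitudes
and applied to the reference; frames export as multi-model PDB.

FSC uses 1-voxel shells with linear interpolation at the threshold (default
0.143); no crossing reports Nyquist with a flag. An optional soft spherical
mask (Gaussian-smoothed edge) matches common masking practice. For
comparisons against unmodulated references, `phase_flip_radial` applies the
minimal CTF correction (sign flipping) — without it the FSC of any
CTF-affected reconstruction collapses at the first CTF zero regardless of
noise level.

## Validation design and problem sizes

The test suite validates against a fully synthetic reference: a
deterministic multi-lobe globule of 1656 atoms (seven overlapping lobes of
unequal size along a seeded random walk, four jittered atoms per residue).
A quasi-uniform ball is useless here — its smoothed density is nearly
spherically symmetric and cannot be oriented; the lumpy globule's rotational
self-correlation stays below 0.87 over test rotations while remaining
connected at the 8 Å cutoff with collective low modes. It matches the scale
of the small enzyme used in the original validation (1656 atoms), so box
size (64³), voxel size (2.2 Å), amplitude ranges and the amplitude→Å
conversion carry over unchanged.

Problem sizes in the acceptance tests, chosen to keep the default `pytest`
run around 15 minutes on one core: 12 "Discrete" + 12 "Continuous"
subtomograms at the full imaging conditions (SNR 0.01, −1 µm, ±60°) for the
error tables and class separation, and 30 single-conformation subtomograms
for the averaging/FSC property. At n = 12 the sample means carry sampling
error, so the error-table checks are magnitude bounds (about twice the
published means) rather than two-sided comparisons; the measured means are
typically *below* the published ones (amplitudes ≈ 6/6/10 vs 16.5/10.9/10.7;
angular ≈ 1.6° vs 1.33°; shift ≈ 0.13 vs 0.19 voxels), consistent with the
CTF-modulated matching reference.

## Numerical choices

* Gaussian kernel truncation 4σ; rendering via a compiled scatter kernel.
* Rotations: trilinear interpolation (compiled kernel in the alignment hot
  path, scipy elsewhere), zero outside the box; all rotations about the
  center voxel n/2; shifts applied after rotation.
* Single-precision real FFTs in the alignment inner loop (half-spectrum
  with per-plane doubling weights — exact for Hermitian-symmetric masks);
  double precision for user-facing CCC/FSC values.
* Eigen-solvers: LAPACK `eigh` with index subsets (dense), ARPACK
  shift-invert above 3000 DOF; degenerate RTB block DOFs dropped at
  1e-10 relative tolerance.
* Determinism: every stochastic step takes an explicit seed; the optimizer,
  pseudoatomizer and searches are deterministic; dataset generation spawns
  per-item seeds below 2³¹ from the master seed.

## Known limitations

* The forward model omits crowded backgrounds, dose and defocus gradients
  (see above); accuracy numbers on real tomograms will be worse.
* The global orientation scan at 20° with 5 refined candidates can in
  principle miss the true basin for highly symmetric particles; symmetric
  complexes also break the uniqueness of the pose estimate itself.
* CTF handling is a single radial profile (no per-tilt defocus, no
  astigmatism) and amplitude modulation is left uncorrected (phase flipping
  only).
* The trust-region model assumes the CCC is locally smooth in the
  amplitudes; for very low SNR combined with many modes (> ~6) the search
  budget may need raising.
* Pseudoatom counts are not comparable across implementations (see
  Reference structures); only the approximation-error contract is.
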