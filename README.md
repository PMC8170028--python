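# flexitomo

Continuous conformational variability analysis of cryo-electron tomography
subtomograms by combined elastic (normal-mode) and rigid-body 3D-to-3D
alignment of a flexible reference, with missing-wedge compensation.

## The problem

Macromolecular complexes imaged *in situ* by cryo-ET are flexible: each
extracted subtomogram holds the complex in a different conformation,
orientation and position, buried in heavy noise and distorted by the missing
wedge (the unsampled double-wedge of Fourier space left by the limited tilt
range, typically ±60°). Classification-based heterogeneity analysis assumes
a few discrete states; for gradual (continuous) conformational changes that
assumption breaks down.

flexitomo instead describes each subtomogram by a small set of continuous
parameters. A reference structure — an atomic model, or a density map
converted into Gaussian pseudoatoms — is made flexible through normal mode
analysis of its elastic network (Tirion model: identical springs between all
(pseudo)atom pairs closer than a cutoff). For each subtomogram it seeks
normal-mode amplitudes $a_m$, Euler angles and shifts maximizing the
**wedge-constrained cross-correlation** (CCC): the Pearson correlation of
the subtomogram with the deformed, rotated and shifted reference rendering,
evaluated only over trusted Fourier coefficients:

$$
\hat a = \arg\max_{a}\;\max_{R,\,t}\;
\mathrm{CCC}\!\left(\,T_{R,t}\,\rho\!\Big(\mathbf r + \sum_m a_m\,\mathbf u_m\Big),\;V\right)
$$

where $\mathbf u_m$ are unit-norm low-frequency, high-collectivity modes,
$\rho(\cdot)$ renders coordinates as a density volume and $T_{R,t}$ applies
the pose. The amplitude search is a derivative-free quadratic-model
trust-region optimization started at $a=0$; the inner pose search is a fast
hierarchical rotational matching with FFT-based translation scoring. The
per-subtomogram amplitude vectors are then projected by PCA into a 2-D/3-D
*space of conformations*, outliers are removed by a chi-square test on
Mahalanobis distances, and dense regions are exploited by subtomogram
averaging (with optional missing-wedge filling from the global average) and
by animating trajectories mapped back to amplitudes by inverse PCA.

Because amplitudes act along unit-norm orthonormal modes, they convert
exactly to physical displacement: $\mathrm{RMSD} = \lVert a\rVert/\sqrt N$ Å
for an $N$-atom structure.

The package includes the full synthetic data generator used for validation:
elastic deformation → Gaussian rendering → random pose → ±60° tilt-series
projection → CTF with split noise at a target SNR → direct Fourier
reconstruction with the missing wedge.

## Worked example

Generate a small "Discrete" dataset (three conformations of a synthetic
1656-atom enzyme-sized structure at SNR 0.01, defocus −1 µm, ±60° wedge)
and recover the conformational and pose parameters:

```python
from flexitomo import (
    AlignmentOptions, CTFParams, align_dataset, alignment_errors,
    compute_modes_rtb, generate_dataset, select_modes,
)
from flexitomo.phantoms import make_globular_structure

ref = make_globular_structure(n_atoms=1656, seed=0)
modes = compute_modes_rtb(ref, residues_per_block=2, cutoff=8.0, n_modes=12)
selection = select_modes(modes, 3)
print("selected modes:", selection.indices)

subs, truth = generate_dataset(
    ref, modes, "Discrete", 6, box=64, voxel_size=2.2,
    snr=0.01, ctf=CTFParams(defocus_um=-1.0),
    tilt_range=(-60, 60), seed=42,
)
table = align_dataset(ref, modes, selection, subs,
                      AlignmentOptions(ctf=CTFParams(defocus_um=-1.0)))
errors = alignment_errors(table, truth, (7, 8, 9))
print(errors[["err_a7", "err_a8", "err_a9", "angular", "shift"]]
      .mean().round(2))
```

Output (a few minutes on one core):

```
selected modes: [7, 8, 9]
err_a7      6.26
err_a8      5.86
err_a9     10.25
angular     1.61
shift       0.13
dtype: float64
```

The mean absolute amplitude errors (~6–10 amplitude units ≈ 0.2–0.3 Å of
displacement for this 1656-atom structure), the mean angular error (1.6°)
and the mean shift error (0.13 voxels) show that conformation and pose are
recovered well below the scale of the simulated motion (amplitudes ±150,
i.e. several Å) despite SNR 0.01 and the missing wedge. Mode 9 was not used
by the generator, so its error measures pure noise leakage.

A command-line interface mirrors the library:

```bash
flexitomo simulate --spec discrete --n 100 --snr 0.01 --seed 1 --out data/
flexitomo align --ref data/reference.pdb --modes data/modes --select 7,8,9 \
                --subtomos data/ --defocus -1.0 --out alignment.tsv
flexitomo space --alignment alignment.tsv --dims 2 --pmin 0.01
flexitomo run --config pipeline.yaml        # full resumable pipeline
```

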