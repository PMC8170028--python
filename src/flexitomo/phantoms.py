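"""Synthetic reference structures and test phantoms.

These stand-ins are fully synthetic: deterministic, protein-like in size and
density, but not derived from any deposited structure.  The default globule
matches the scale of a small enzyme (1656 heavy atoms in ~45 A), so normal
mode amplitudes, box sizes and voxel sizes carry over unchanged.
"""

from __future__ import annotations

import numpy as np

from .structures import AtomicStructure, DensityVolume

__all__ = ["make_globular_structure", "make_asymmetric_volume"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _ball_fill(n_points: int, radius: float) -> np.ndarray:
    """Quasi-uniform deterministic fill of a ball (golden-angle spiral)."""
    i = np.arange(n_points)
    r = radius * ((i + 0.5) / n_points) ** (1.0 / 3.0)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    rho = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE
    return np.stack([r * rho * np.cos(phi), r * rho * np.sin(phi), r * z], axis=1)


def make_globular_structure(
    n_atoms: int = 1656,
    atoms_per_residue: int = 4,
    n_lobes: int = 7,
    jitter: float = 1.2,
    seed: int = 0,
) -> AtomicStructure:
    """Deterministic lumpy multi-lobe synthetic structure.

    A chain of overlapping lobes of unequal sizes laid out along a seeded
    random walk: lumpy and rotationally asymmetric at low resolution (like a
    real multi-domain protein), unlike a uniform ball whose smoothed density
    is nearly spherically symmetric and hence impossible to orient.  Each
    residue carries ``atoms_per_residue`` atoms jittered around its center;
    adjacent lobes overlap, so the elastic network stays connected at the
    default 8 A cutoff.  Centered at the origin; unit weights; consecutive
    residue numbering for RTB blocks.
    """
    rng = np.random.default_rng(seed)
    n_res = int(np.ceil(n_atoms / atoms_per_residue))
    lobe_radius = rng.uniform(6.5, 11.0, n_lobes)
    lobe_centers = np.zeros((n_lobes, 3))
    for k in range(1, n_lobes):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        lobe_centers[k] = lobe_centers[k - 1] + d * 0.75 * (
            lobe_radius[k - 1] + lobe_radius[k]
        )
    vol = lobe_radius**3
    n_per = np.maximum(1, np.round(n_res * vol / vol.sum()).astype(int))
    while n_per.sum() != n_res:  # fix rounding drift
        n_per[int(np.argmax(n_per))] += int(np.sign(n_res - n_per.sum()))

    centers = np.concatenate([
        c + _ball_fill(m, r)
        for c, r, m in zip(lobe_centers, lobe_radius, n_per)
    ])
    coords = np.empty((n_atoms, 3))
    residue_index = np.empty(n_atoms, dtype=int)
    k = 0
    for res in range(n_res):
        for _ in range(min(atoms_per_residue, n_atoms - k)):
            coords[k] = centers[res] + rng.normal(0.0, jitter, 3)
            residue_index[k] = res
            k += 1
        if k >= n_atoms:
            break
    coords -= coords.mean(axis=0)
    return AtomicStructure(coords=coords, residue_index=residue_index)


def make_asymmetric_volume(n: int = 32, voxel_size: float = 2.0,
                           seed: int = 0, spread: float = 0.29,
                           width_range: tuple[float, float] = (1.2, 2.6),
                           n_blobs: int = 9) -> DensityVolume:
    """Asymmetric Gaussian-blob phantom for rigid-alignment tests.

    ``spread`` is the blob-center range as a fraction of the box size; keep
    it small (and widths large) for band-limited phantoms whose projections
    conserve mass to interpolation accuracy.
    """
    rng = np.random.default_rng(seed)
    ax = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    data = np.zeros((n, n, n))
    # well-spread blobs of distinct sizes -> no rotational pseudo-symmetry
    nb = n_blobs
    centers = rng.uniform(-n * spread, n * spread, size=(nb, 3))
    widths = rng.uniform(*width_range, size=nb)
    heights = rng.uniform(0.5, 2.0, size=nb)
    for c, w, h in zip(centers, widths, heights):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        data += h * np.exp(-d2 / (2 * w**2))
    return DensityVolume(data.astype(np.float32), voxel_size)
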