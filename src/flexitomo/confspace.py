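"""Conformational-space construction and exploitation.

The per-subtomogram normal-mode amplitude vectors are projected onto a 2-D
or 3-D space by linear PCA; isolated points are excluded by a chi-square
test on the squared Mahalanobis distance (computed in the full amplitude
space); dense regions are grouped and their subtomograms averaged (with
optional missing-wedge filling from a global average); trajectories through
the space are inverse-mapped to amplitudes and animated by deforming the
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structures import DensityVolume, structure_to_volume
from .nma import NormalModeSet, ModeSelection, deform
from .tomosim import RigidParams, Subtomogram, wedge_mask
from .align import _fourier_crop  # noqa: F401  (re-exported convenience)

__all__ = [
    "ConformationalSpace",
    "Trajectory",
    "EllipseRegion",
    "pca_fit_project",
    "inverse_map",
    "mahalanobis_filter",
    "select_group",
    "average_group",
    "fit_trajectory",
    "animate_trajectory",
    "FSCCurve",
    "fsc",
    "resolution_at",
    "soft_spherical_mask",
    "plot_space",
    "save_space",
    "load_space",
]


@dataclass
class ConformationalSpace:
    """Low-dimensional embedding of per-subtomogram amplitude vectors."""

    mean: np.ndarray  # (M,)
    basis: np.ndarray  # (M, d), orthonormal columns
    points: np.ndarray  # (n, d) projected coordinates
    explained_variance: np.ndarray  # (d,)
    ccc: np.ndarray | None = None  # per-point correlation, for 1-CCC coloring
    inlier: np.ndarray | None = None
    p_values: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.basis.shape[1]


@dataclass
class Trajectory:
    """Piecewise-linear path through the conformational space."""

    control_points: np.ndarray  # (k, d), k >= 2
    n_frames: int = 10

    def __post_init__(self):
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if len(self.control_points) < 2:
            raise ValueError("a trajectory needs at least 2 control points")

    def sample(self, n_frames: int | None = None) -> np.ndarray:
        """Points sampled uniformly by arc length along the segments."""
        n_frames = n_frames or self.n_frames
        if n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        cp = self.control_points
        seg = np.linalg.norm(np.diff(cp, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        if total == 0:
            return np.repeat(cp[:1], n_frames, axis=0)
        targets = np.linspace(0.0, total, n_frames)
        out = np.empty((n_frames, cp.shape[1]))
        for i, s in enumerate(targets):
            j = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
            f = (s - cum[j]) / seg[j] if seg[j] > 0 else 0.0
            out[i] = cp[j] + f * (cp[j + 1] - cp[j])
        return out


@dataclass
class EllipseRegion:
    """Axis-aligned ellipse (2-D) / ellipsoid (3-D) in projected coordinates."""

    center: tuple
    radii: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if np.any(r <= 0):
            raise ValueError("radii must be positive")
        return np.sum(((points - c) / r) ** 2, axis=1) <= 1.0


def pca_fit_project(amplitudes: np.ndarray, d: int = 2,
                    ccc: np.ndarray | None = None) -> ConformationalSpace:
    """Centered linear PCA of an n x M amplitude table.

    Components are ordered by descending variance with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """
    from sklearn.decomposition import PCA

    X = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    n, M = X.shape
    if not n > d or d < 1:
        raise ValueError("need n > d >= 1")
    d = min(d, M)
    pca = PCA(n_components=d, svd_solver="full")
    proj = pca.fit_transform(X)
    basis = pca.components_.T.copy()  # (M, d)
    for j in range(d):
        i = int(np.argmax(np.abs(basis[:, j])))
        if basis[i, j] < 0:
            basis[:, j] *= -1
            proj[:, j] *= -1
    return ConformationalSpace(
        mean=pca.mean_, basis=basis, points=proj,
        explained_variance=pca.explained_variance_,
        ccc=None if ccc is None else np.asarray(ccc, dtype=float),
    )


def inverse_map(space: ConformationalSpace, points: np.ndarray) -> np.ndarray:
    """Map projected coordinates back to M-dimensional amplitude vectors."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return space.mean + pts @ space.basis.T


def mahalanobis_filter(amplitudes: np.ndarray, p_threshold: float = 0.01):
    """Chi-square outlier test on squared Mahalanobis distances.

    Distances are computed to the sample mean/covariance of the full
    M-dimensional amplitude table; p-values come from the chi-square law
    with M degrees of freedom.  Points with ``p <= p_threshold`` are flagged
    as outliers.  Returns ``(inlier_flags, p_values)``.
    """
    X = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    n, M = X.shape
    if n <= M:
        raise ValueError("need more points than dimensions")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; using pseudo-inverse", stacklevel=2)
        cinv = np.linalg.pinv(cov)
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, cinv, diff)
    p = stats.chi2.sf(d2, df=M)
    return p > p_threshold, p


def select_group(space: ConformationalSpace, region: EllipseRegion,
                 min_ccc: float | None = None) -> np.ndarray:
    """Indices of inlier points inside a region (optionally CCC-filtered)."""
    inside = region.contains(space.points)
    if space.inlier is not None:
        inside &= space.inlier
    if min_ccc is not None:
        if space.ccc is None:
            raise ValueError("space carries no CCC values")
        inside &= space.ccc >= min_ccc
    return np.nonzero(inside)[0]


def _aligned_volume(sub: Subtomogram, rigid: RigidParams) -> np.ndarray:
    """Undo a subtomogram's rigid pose: rotate(shift(sub, -t), R^-1)."""
    from scipy.ndimage import affine_transform
    from .tomosim import _index_affine

    R = rigid.matrix()
    n = sub.n
    # aligned(x) = sub(R x + t) about the center
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    M = perm @ R @ perm
    c = np.full(3, n // 2, dtype=float)
    t = perm @ np.asarray(rigid.shift, dtype=float)
    offset = c + t - M @ c
    return affine_transform(np.asarray(sub.volume.data, dtype=np.float64), M,
                            offset=offset, order=1, prefilter=False)


def _rotated_mask(sub: Subtomogram, rigid: RigidParams) -> np.ndarray:
    """Trusted-region mask of an aligned subtomogram (wedge rotated with it)."""
    from scipy.ndimage import affine_transform

    n = sub.n
    m = wedge_mask(n, sub.wedge, shifted=True).astype(np.float64)
    R = rigid.matrix()
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    M = perm @ R @ perm
    c = np.full(3, n // 2, dtype=float)
    offset = c - M @ c
    rot = affine_transform(m, M, offset=offset, order=1, prefilter=False, cval=0.0)
    return np.fft.ifftshift(rot >= 0.5)


def average_group(
    subtomograms: list[Subtomogram],
    rigids: list[RigidParams],
    indices=None,
    wedge_fill: bool = False,
    global_average: DensityVolume | None = None,
) -> DensityVolume:
    """Average subtomograms after undoing their rigid poses.

    With ``wedge_fill`` the Fourier coefficients each item is missing (its
    wedge, rotated along with the item) are replaced by those of the global
    average before summation, so the group average has full Fourier support.
    """
    if indices is None:
        indices = range(len(subtomograms))
    indices = list(indices)
    if not indices:
        raise ValueError("empty group")
    if wedge_fill and global_average is None:
        raise ValueError("wedge_fill requires a global average")
    n = subtomograms[indices[0]].n
    voxel = subtomograms[indices[0]].volume.voxel_size
    acc = np.zeros((n, n, n))
    Fg = np.fft.fftn(np.asarray(global_average.data, dtype=np.float64)) \
        if wedge_fill else None
    for i in indices:
        vol = _aligned_volume(subtomograms[i], rigids[i])
        if wedge_fill:
            mask = _rotated_mask(subtomograms[i], rigids[i])
            F = np.fft.fftn(vol)
            F = np.where(mask, F, Fg)
            vol = np.fft.ifftn(F).real
        acc += vol
    return DensityVolume((acc / len(indices)).astype(np.float32), voxel)


def fit_trajectory(points, n_frames: int = 10) -> Trajectory:
    """Piecewise-linear trajectory through ordered control points."""
    return Trajectory(np.asarray(points, dtype=float), n_frames=n_frames)


def animate_trajectory(
    traj: Trajectory,
    space: ConformationalSpace,
    ref,
    ms: NormalModeSet,
    selection: ModeSelection,
    n_frames: int | None = None,
):
    """Deformed reference structures along a trajectory.

    Each frame point is inverse-mapped to an amplitude vector and the
    reference is displaced accordingly; returns the list of structures.
    """
    amps = inverse_map(space, traj.sample(n_frames))
    return [deform(ref, ms, selection, a) for a in amps]


def export_animation_pdb(structures, path) -> None:
    """Write animation frames as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from .structures import PseudoatomModel

    n = structures[0].n_atoms
    stack = struc.AtomArrayStack(len(structures), n)
    stack.coord = np.stack([np.asarray(s.coords, dtype=np.float32) for s in structures])
    stack.atom_name = np.full(n, "CA")
    stack.res_name = np.full(n, "ALA")
    stack.chain_id = np.full(n, "A")
    stack.res_id = np.arange(1, n + 1)
    stack.element = np.full(n, "C")
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

@dataclass
class FSCCurve:
    frequency: np.ndarray  # 1/A, shell centers
    values: np.ndarray
    voxel_size: float


def fsc(v1: DensityVolume, v2: DensityVolume) -> FSCCurve:
    """Fourier shell correlation between two volumes (shell width 1 voxel)."""
    if v1.data.shape != v2.data.shape:
        raise ValueError("volumes must share a grid")
    if v1.voxel_size != v2.voxel_size:
        raise ValueError("volumes must share a voxel size")
    n = v1.n
    F1 = np.fft.fftn(np.asarray(v1.data, dtype=np.float64))
    F2 = np.fft.fftn(np.asarray(v2.data, dtype=np.float64))
    k = np.fft.fftfreq(n) * n
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    shells = np.clip(np.round(r).astype(int), 0, n // 2)
    nshell = n // 2 + 1
    num = np.zeros(nshell, dtype=complex)
    d1 = np.zeros(nshell)
    d2 = np.zeros(nshell)
    np.add.at(num, shells.ravel(), (F1 * np.conj(F2)).ravel())
    np.add.at(d1, shells.ravel(), (np.abs(F1) ** 2).ravel())
    np.add.at(d2, shells.ravel(), (np.abs(F2) ** 2).ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.real(num) / np.sqrt(d1 * d2)
    vals = np.nan_to_num(vals, nan=0.0)
    freq = np.arange(nshell) / (n * v1.voxel_size)
    return FSCCurve(freq, vals, v1.voxel_size)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Resolution (A) at the first crossing below the threshold.

    Linear interpolation between shells; if the curve never drops below the
    threshold, the Nyquist resolution is returned with ``crossed = False``.
    """
    vals = curve.values
    freq = curve.frequency
    for i in range(1, len(vals)):
        if vals[i] < threshold <= vals[i - 1]:
            f = freq[i - 1] + (threshold - vals[i - 1]) * (
                (freq[i] - freq[i - 1]) / (vals[i] - vals[i - 1])
            )
            return float(1.0 / f), True
    nyquist = 1.0 / (2.0 * curve.voxel_size)
    return float(1.0 / nyquist), False


def soft_spherical_mask(n: int, radius: float, soft_sigma: float = 5.0) -> np.ndarray:
    """Spherical binary mask with Gaussian-smoothed edges (voxel units)."""
    from scipy.ndimage import gaussian_filter

    ax = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    hard = (np.sqrt(xx**2 + yy**2 + zz**2) <= radius).astype(float)
    return gaussian_filter(hard, soft_sigma) if soft_sigma > 0 else hard


# ---------------------------------------------------------------------------
# Persistence & plotting
# ---------------------------------------------------------------------------

def save_space(space: ConformationalSpace, path) -> None:
    """Write projected points as TSV plus a ``.json`` sidecar (mean, basis)."""
    import json
    import pandas as pd
    from pathlib import Path

    cols = {"index": np.arange(len(space.points))}
    for j in range(space.d):
        cols[f"pc{j + 1}"] = space.points[:, j]
    if space.p_values is not None:
        cols["p_value"] = space.p_values
    if space.inlier is not None:
        cols["inlier"] = space.inlier.astype(int)
    if space.ccc is not None:
        cols["ccc"] = space.ccc
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "mean": space.mean.tolist(),
        "basis": space.basis.tolist(),
        "explained_variance": space.explained_variance.tolist(),
    }))


def load_space(path) -> ConformationalSpace:
    import json
    import pandas as pd
    from pathlib import Path

    table = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    pcs = [c for c in table.columns if c.startswith("pc")]
    return ConformationalSpace(
        mean=np.asarray(meta["mean"], dtype=float),
        basis=np.asarray(meta["basis"], dtype=float),
        points=table[pcs].to_numpy(dtype=float),
        explained_variance=np.asarray(meta["explained_variance"], dtype=float),
        ccc=table["ccc"].to_numpy() if "ccc" in table else None,
        inlier=table["inlier"].to_numpy(dtype=bool) if "inlier" in table else None,
        p_values=table["p_value"].to_numpy() if "p_value" in table else None,
    )


def plot_space(space: ConformationalSpace, path, title: str = "Conformational space"):
    """Scatter plot of the first two PCs colored by 1 - CCC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    color = 1.0 - space.ccc if space.ccc is not None else None
    sc = ax.scatter(space.points[:, 0], space.points[:, 1], c=color,
                    s=12, cmap="viridis")
    if color is not None:
        fig.colorbar(sc, ax=ax, label="1 - CCC")
    if space.inlier is not None and not space.inlier.all():
        out = ~space.inlier
        ax.scatter(space.points[out, 0], space.points[out, 1], marker="x",
                   c="red", s=20, label="outlier")
        ax.legend()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
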