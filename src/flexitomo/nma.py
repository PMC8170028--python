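"""Elastic-network normal mode analysis.

The network is a Tirion model: every pair of (pseudo)atoms closer than a
cutoff distance is connected by an identical harmonic spring, giving the
Hessian the familiar block structure

    H_ij = -k (d d^T) / |d|^2   (i != j, |d| <= cutoff, d = r_i - r_j)
    H_ii = -sum_{j != i} H_ij

No mass weighting is applied: the pipeline only consumes mode *shapes* and
amplitudes, for which the eigenvalue scale (spring constant) is irrelevant.
Modes are numbered globally starting at 1; for a connected network modes 1-6
are the zero-frequency rigid-body motions and are excluded from elastic
alignment.

Two diagonalization routes are provided: the Cartesian method (direct
diagonalization of the 3N x 3N Hessian, used for pseudoatomic models) and the
rotation-translation-block (RTB) method (per-block rigid degrees of freedom,
used for atomic models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .structures import AtomicStructure, PseudoatomModel

__all__ = [
    "ElasticNetwork",
    "NormalModeSet",
    "ModeSelection",
    "build_hessian",
    "compute_modes_cartesian",
    "compute_modes_rtb",
    "collectivity",
    "select_modes",
    "deform",
    "rmsd",
    "pseudoatom_cutoff",
    "save_modes",
    "load_modes",
]

#: dense diagonalization is used up to this many Cartesian degrees of freedom
DENSE_LIMIT = 3000


@dataclass
class ElasticNetwork:
    """Tirion elastic network: coordinates, cutoff (A) and spring constant."""

    coords: np.ndarray
    cutoff: float = 8.0
    spring_constant: float = 1.0

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def pairs(self) -> np.ndarray:
        """(n_pairs, 2) index pairs within the cutoff."""
        tree = cKDTree(self.coords)
        return np.array(sorted(tree.query_pairs(self.cutoff)), dtype=int).reshape(-1, 2)


@dataclass
class NormalModeSet:
    """Normal modes as unit-norm columns of a 3N x M matrix.

    ``mode_numbering`` is the 1-based global index of each column (column m
    of a full spectrum has number m+1); eigenvalues are ascending.
    """

    modes: np.ndarray  # (3N, M)
    eigenvalues: np.ndarray  # (M,)
    collectivities: np.ndarray  # (M,)
    mode_numbering: np.ndarray  # (M,) 1-based

    def __post_init__(self):
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.collectivities = np.asarray(self.collectivities, dtype=float)
        self.mode_numbering = np.asarray(self.mode_numbering, dtype=int)

    @property
    def n_atoms(self) -> int:
        return self.modes.shape[0] // 3

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def column(self, mode_number: int) -> np.ndarray:
        """Mode by its 1-based global number, as a (3N,) vector."""
        pos = np.nonzero(self.mode_numbering == mode_number)[0]
        if not pos.size:
            raise KeyError(f"mode {mode_number} not in set")
        return self.modes[:, pos[0]]


@dataclass
class ModeSelection:
    """Global mode numbers chosen for elastic alignment (never 1-6)."""

    indices: list[int]
    criteria: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(i <= 6 for i in self.indices):
            raise ValueError("modes 1-6 are rigid-body modes and cannot be selected")

    def __len__(self) -> int:
        return len(self.indices)

    def matrix(self, ms: NormalModeSet) -> np.ndarray:
        """(3N, len(self)) matrix of the selected mode columns."""
        return np.stack([ms.column(i) for i in self.indices], axis=1)


def _as_network(obj, cutoff=8.0) -> ElasticNetwork:
    if isinstance(obj, ElasticNetwork):
        return obj
    return ElasticNetwork(np.asarray(obj.coords if hasattr(obj, "coords") else obj), cutoff)


def build_hessian(net: ElasticNetwork) -> sp.csr_matrix:
    """Assemble the 3N x 3N Tirion Hessian (sparse CSR)."""
    coords = net.coords
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two atoms")
    pairs = net.pairs()
    k = net.spring_constant
    rows, cols, vals = [], [], []
    for i, j in pairs:
        d = coords[i] - coords[j]
        d2 = d @ d
        if d2 == 0:
            continue
        block = k * np.outer(d, d) / d2
        for a in range(3):
            for b in range(3):
                v = block[a, b]
                rows += [3 * i + a, 3 * j + a, 3 * i + a, 3 * j + a]
                cols += [3 * j + b, 3 * i + b, 3 * i + b, 3 * j + b]
                vals += [-v, -v, v, v]
    H = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    return H


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def _finish_modeset(modes, eigenvalues) -> NormalModeSet:
    order = np.argsort(eigenvalues)
    eigenvalues = np.clip(eigenvalues[order], 0, None)
    modes = modes[:, order]
    modes = modes / np.linalg.norm(modes, axis=0)
    modes = _fix_signs(modes)
    coll = np.array([collectivity(modes[:, m]) for m in range(modes.shape[1])])
    return NormalModeSet(
        modes=modes,
        eigenvalues=eigenvalues,
        collectivities=coll,
        mode_numbering=np.arange(1, modes.shape[1] + 1),
    )


def compute_modes_cartesian(net: ElasticNetwork | AtomicStructure | PseudoatomModel,
                            n_modes: int, cutoff: float = 8.0) -> NormalModeSet:
    """Lowest-frequency normal modes by direct Hessian diagonalization.

    Dense up to ``DENSE_LIMIT`` degrees of freedom, shift-invert Lanczos
    above.  Columns are orthonormal; for a connected network the first six
    eigenvalues are numerically zero.
    """
    net = _as_network(net, cutoff)
    H = build_hessian(net)
    dof = H.shape[0]
    if n_modes > dof:
        raise ValueError("n_modes exceeds 3N")
    if dof <= DENSE_LIMIT:
        w, v = scipy.linalg.eigh(H.toarray(), subset_by_index=[0, n_modes - 1])
    else:
        w, v = sp.linalg.eigsh(H, k=n_modes, sigma=-1e-6, which="LM")
    return _finish_modeset(v, w)


def _block_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal rigid-body basis (translations + rotations) of one block.

    Returns (3*nb, <=6); degenerate rotational DOFs (single atoms, collinear
    blocks) are dropped.
    """
    nb = len(coords)
    c = coords - coords.mean(axis=0)
    cols = []
    for a in range(3):
        t = np.zeros((nb, 3))
        t[:, a] = 1.0
        cols.append(t.ravel())
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        rot = np.cross(np.broadcast_to(axis, (nb, 3)), c)
        cols.append(rot.ravel())
    B = np.stack(cols, axis=1)
    # orthonormalize, dropping null directions
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def compute_modes_rtb(
    s: AtomicStructure,
    residues_per_block: int = 1,
    cutoff: float = 8.0,
    n_modes: int = 20,
) -> NormalModeSet:
    """Normal modes by the rotation-translation-block (RTB) reduction.

    Consecutive residues are grouped into rigid blocks; the Hessian is
    projected onto the per-block rigid-body subspace (at most 6 DOF per
    block, about the block centroid), the reduced matrix is diagonalized, and
    eigenvectors are back-projected to 3N and renormalized to unit norm.
    """
    if residues_per_block < 1:
        raise ValueError("residues_per_block must be >= 1")
    res = np.asarray(s.residue_index)
    block_id = np.unique(res, return_inverse=True)[1] // residues_per_block
    coords = np.asarray(s.coords, dtype=float)
    n = len(coords)
    net = ElasticNetwork(coords, cutoff)
    H = build_hessian(net)

    blocks = [np.nonzero(block_id == b)[0] for b in np.unique(block_id)]
    cols = []
    rows = []
    data = []
    col0 = 0
    for atoms in blocks:
        basis = _block_basis(coords[atoms])
        dof_rows = np.stack([3 * atoms + a for a in range(3)], axis=1).ravel()
        for j in range(basis.shape[1]):
            rows.append(dof_rows)
            cols.append(np.full(dof_rows.size, col0 + j))
            data.append(basis[:, j])
        col0 += basis.shape[1]
    P = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, col0),
    ).tocsr()

    reduced = (P.T @ (H @ P.toarray()))
    reduced = np.asarray(reduced)
    reduced = 0.5 * (reduced + reduced.T)
    n_modes = min(n_modes, reduced.shape[0])
    w, v = scipy.linalg.eigh(reduced, subset_by_index=[0, n_modes - 1])
    modes = P @ v
    return _finish_modeset(modes, w)


def collectivity(mode: np.ndarray, n_atoms: int | None = None) -> float:
    """Entropy-based degree of collectivity of a mode, in [1/N, 1].

    ``kappa = exp(-sum p_i log p_i) / N`` with ``p_i`` the normalized squared
    per-atom displacement.  1 means all atoms move equally; 1/N means a
    single atom moves.
    """
    u = np.asarray(mode, dtype=float).reshape(-1, 3)
    if n_atoms is None:
        n_atoms = len(u)
    p = (u**2).sum(axis=1)
    total = p.sum()
    if total == 0:
        raise ValueError("zero mode vector")
    p = p / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float(np.exp(entropy) / n_atoms)


def select_modes(
    ms: NormalModeSet,
    n_lowest: int,
    min_collectivity: float = 0.0,
    extra: tuple[int, ...] = (),
) -> ModeSelection:
    """Pick low-frequency, high-collectivity modes for elastic alignment.

    Returns the ``n_lowest`` lowest-eigenvalue modes (global numbers > 6)
    whose collectivity is at least ``min_collectivity``; expert choices can
    be appended via ``extra`` (global mode numbers).  If fewer modes qualify
    than requested, a warning is issued and the shorter list returned.
    """
    candidates = [
        (num, lam, kappa)
        for num, lam, kappa in zip(ms.mode_numbering, ms.eigenvalues, ms.collectivities)
        if num > 6 and kappa >= min_collectivity
    ]
    chosen = [int(num) for num, _, _ in
              sorted(candidates, key=lambda t: t[1])[:n_lowest]]
    if len(chosen) < n_lowest:
        warnings.warn(
            f"only {len(chosen)} modes with collectivity >= {min_collectivity}; "
            f"requested {n_lowest}", stacklevel=2,
        )
    for e in extra:
        if e not in chosen:
            chosen.append(int(e))
    return ModeSelection(
        indices=chosen,
        criteria={"n_lowest": n_lowest, "min_collectivity": min_collectivity,
                  "extra": tuple(extra)},
    )


def deform(s, ms: NormalModeSet, sel: ModeSelection, amplitudes):
    """Displace a structure along selected modes: r'_i = r_i + sum_m a_m u_m,i."""
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if len(amplitudes) != len(sel):
        raise ValueError(
            f"{len(amplitudes)} amplitudes for {len(sel)} selected modes"
        )
    U = sel.matrix(ms)  # (3N, M)
    disp = (U @ amplitudes).reshape(-1, 3)
    return s.with_coords(np.asarray(s.coords, dtype=float) + disp)


def rmsd(s1, s2) -> float:
    """Root-mean-square deviation (A) without superposition."""
    a = np.asarray(s1.coords if hasattr(s1, "coords") else s1, dtype=float)
    b = np.asarray(s2.coords if hasattr(s2, "coords") else s2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"size mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pseudoatom_cutoff(coords: np.ndarray, percentile: float = 0.01) -> float:
    """Interaction cutoff from the pairwise-distance distribution.

    Returns the distance below which the given fraction of all pairwise
    distances lies (default: 1% — configurable, as appropriate for
    pseudoatomic models whose spacing depends on the map).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) < 2:
        raise ValueError("need at least two points")
    d = pdist(coords)
    if d.max() == 0:
        raise ValueError("all coordinates coincide")
    return float(np.quantile(d, percentile))


# ---------------------------------------------------------------------------
# Persistence: one plain-text matrix file per mode + a TSV metadata table
# ---------------------------------------------------------------------------

def save_modes(ms: NormalModeSet, directory) -> None:
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in range(ms.n_modes):
        np.savetxt(
            directory / f"mode_{ms.mode_numbering[m]:04d}.txt",
            ms.modes[:, m].reshape(-1, 3), fmt="%.10e",
        )
    pd.DataFrame({
        "mode": ms.mode_numbering,
        "eigenvalue": ms.eigenvalues,
        "collectivity": ms.collectivities,
    }).to_csv(directory / "modes.tsv", sep="\t", index=False)


def load_modes(directory) -> NormalModeSet:
    import pandas as pd

    directory = Path(directory)
    meta = pd.read_csv(directory / "modes.tsv", sep="\t")
    cols = []
    for num in meta["mode"]:
        cols.append(np.loadtxt(directory / f"mode_{int(num):04d}.txt").ravel())
    return NormalModeSet(
        modes=np.stack(cols, axis=1),
        eigenvalues=meta["eigenvalue"].to_numpy(),
        collectivities=meta["collectivity"].to_numpy(),
        mode_numbering=meta["mode"].to_numpy(),
    )
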