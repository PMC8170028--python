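"""Combined elastic (normal-mode) and rigid-body 3D-to-3D alignment.

For each subtomogram the method searches normal-mode amplitudes ``a`` and a
rigid-body pose maximizing the wedge-constrained cross-correlation (CCC)
between the subtomogram and the rendered, deformed, posed reference:

    a* = argmax_a  max_{R, t}  CCC( shift_t(rot_R(render(deform(ref, a)))), sub )

The CCC is a Pearson correlation evaluated only over the trusted Fourier
region (outside the missing wedge).  The outer amplitude search starts at
``a = 0`` and uses a derivative-free quadratic-model trust-region optimizer
whose radius shrinks iteratively; the inner rigid-body search is a fast
hierarchical rotational matching: a global orientation grid scored at a
Fourier-cropped resolution with the translation obtained from the
correlation peak (sub-voxel by parabolic interpolation), then local
rotational refinement re-scored at full resolution.  After the first
(global) evaluation the rigid pose is re-estimated at every objective
evaluation by warm-started local refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .structures import DensityVolume, structure_to_volume
from .nma import NormalModeSet, ModeSelection, deform
from .optimize import minimize_trust_region
from .tomosim import (
    RigidParams, Subtomogram, WedgeDescriptor, wedge_mask, _index_affine,
    rotate_shift_volume,
)

__all__ = [
    "AlignmentOptions",
    "AlignmentResult",
    "constrained_cc",
    "rigid_align",
    "elastic_rigid_align",
    "align_dataset",
    "results_to_table",
]


@dataclass
class AlignmentOptions:
    """Knobs of the combined alignment.

    ``trust_region_scale`` controls the normal-mode amplitude search range
    (initial trust radius = 100 x scale, final radius 1): increase towards 2
    for larger motions, decrease towards 0.5 for smaller ones.
    """

    trust_region_scale: float = 1.0
    max_iterations: int = 60  # objective-evaluation budget of the amplitude search
    final_radius: float = 1.0
    coarse_step: float = 20.0  # deg, global orientation grid
    fine_step: float = 1.0  # deg, finest local rotational refinement
    max_shift: float = 8.0  # voxels, translation search bound
    coarse_size: int = 32  # Fourier-crop size for the global/inner search
    top_candidates: int = 5  # grid candidates kept for local refinement
    max_frequency: float = 0.25  # cycles/voxel, band limit of the matching CC
    render_sigma: float | None = None  # A; None -> one voxel
    #: optional CTF model of the data; when set, the rendered reference is
    #: modulated by the radial CTF profile before matching (a coefficient at
    #: radius |k| in a tilt-series reconstruction carries the factor CTF(|k|),
    #: so this makes the reference spectrally consistent with the data)
    ctf: "CTFParams | None" = None

    def __post_init__(self):
        if self.trust_region_scale <= 0:
            raise ValueError("trust_region_scale must be positive")


@dataclass
class AlignmentResult:
    amplitudes: np.ndarray
    rigid: RigidParams
    ccc: float
    iterations: int
    converged: bool
    error: str | None = None


# ---------------------------------------------------------------------------
# Wedge-constrained correlation machinery
# ---------------------------------------------------------------------------

class _MaskedTarget:
    """Precomputed FFT, wedge mask and norm of one subtomogram at one size.

    Internally uses single-precision real FFTs (half-spectrum); Hermitian
    symmetry of the wedge mask makes the masked inner products exact with
    per-plane doubling weights.
    """

    def __init__(self, data: np.ndarray, wedge: WedgeDescriptor,
                 max_frequency: float | None = None):
        import scipy.fft

        n = data.shape[0]
        self.n = n
        mask = wedge_mask(n, wedge)
        mask[0, 0, 0] = False  # exclude DC == subtract means
        if max_frequency is not None and max_frequency < 0.5:
            k = np.fft.fftfreq(n)
            kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
            mask &= kx**2 + ky**2 + kz**2 <= max_frequency**2
        self.mask = mask[:, :, : n // 2 + 1]
        # doubling weights for the redundant half-spectrum (kx not in {0, n/2})
        w = np.full(n // 2 + 1, 2.0, dtype=np.float32)
        w[0] = 1.0
        w[-1] = 1.0
        self.weights = np.where(self.mask, w[None, None, :], 0.0).astype(np.float32)
        F = scipy.fft.rfftn(np.asarray(data, dtype=np.float32))
        self.F_masked = np.where(self.mask, F, 0.0)
        self.norm = float(np.sqrt(np.sum(self.weights * np.abs(self.F_masked) ** 2)))
        self._fft = scipy.fft

    def correlate(self, ref_data: np.ndarray, max_shift: float):
        """Best shift and CC of ``shift_t(ref)`` against the target.

        Returns (cc, shift_xyz, cc_at_zero_shift).
        """
        F = self._fft.rfftn(np.asarray(ref_data, dtype=np.float32))
        F = np.where(self.mask, F, 0.0)
        ref_norm = float(np.sqrt(np.sum(self.weights * np.abs(F) ** 2)))
        if ref_norm == 0 or self.norm == 0:
            raise ValueError("zero variance inside the trusted Fourier region")
        n = self.n
        corr = self._fft.irfftn(self.F_masked * np.conj(F), s=(n, n, n))
        ms = int(min(max_shift, n // 2 - 1))
        # allowed (wrapped) shifts: each axis in [-ms, ms]
        idx = np.r_[0:ms + 1, n - ms:n] if ms > 0 else np.r_[0:1]
        sub = corr[np.ix_(idx, idx, idx)]
        best = np.unravel_index(int(np.argmax(sub)), sub.shape)
        t_idx = [int(idx[b]) for b in best]  # (tz, ty, tx)

        def wrap(i):
            return i - n if i > n // 2 else i

        # parabolic sub-voxel refinement per axis; the correlation value is
        # corrected by the separable parabolic peak gain, otherwise sub-voxel
        # residual shifts bias the rotation search
        shift = []
        f1 = float(corr[tuple(t_idx)])
        peak = f1
        for ax, ti in enumerate(t_idx):
            sl = [t_idx[0], t_idx[1], t_idx[2]]
            sl[ax] = (ti - 1) % n
            f0 = corr[tuple(sl)]
            sl[ax] = (ti + 1) % n
            f2 = corr[tuple(sl)]
            b = 0.5 * (f2 - f0)
            a = 0.5 * (f0 + f2 - 2 * f1)
            delta = float(np.clip(-b / (2 * a), -0.5, 0.5)) if a < 0 else 0.0
            shift.append(wrap(ti) + delta)
            peak += max(0.0, b * delta + a * delta**2)
        cc = peak * self.n**3 / (ref_norm * self.norm)
        shift_xyz = (shift[2], shift[1], shift[0])
        cc0 = float(corr[0, 0, 0]) * self.n**3 / (ref_norm * self.norm)
        return cc, shift_xyz, cc0


def constrained_cc(a: DensityVolume | np.ndarray, b: Subtomogram) -> float:
    """Pearson correlation over the trusted (non-wedge) Fourier region.

    Equivalent to the real-space Pearson correlation of the two
    wedge-filtered volumes; with a +/-90 deg wedge it reduces to the plain
    Pearson correlation.
    """
    data = a.data if isinstance(a, DensityVolume) else np.asarray(a)
    if data.shape != b.volume.data.shape:
        raise ValueError("volumes must share a grid")
    n = data.shape[0]
    mask = wedge_mask(n, b.wedge)
    mask[0, 0, 0] = False  # exclude DC == subtract means
    Fa = np.where(mask, np.fft.fftn(np.asarray(data, dtype=np.float64)), 0.0)
    Fb = np.where(mask, np.fft.fftn(np.asarray(b.volume.data, dtype=np.float64)), 0.0)
    na = np.sqrt(np.sum(np.abs(Fa) ** 2))
    nb = np.sqrt(np.sum(np.abs(Fb) ** 2))
    if na == 0 or nb == 0:
        raise ValueError("zero variance inside the trusted Fourier region")
    return float(np.sum((Fb * np.conj(Fa)).real) / (na * nb))


def _fourier_crop(data: np.ndarray, m: int) -> np.ndarray:
    """Downsample a cubic volume to m^3 by cropping its centered spectrum."""
    n = data.shape[0]
    if m >= n:
        return np.asarray(data, dtype=np.float64)
    F = np.fft.fftshift(np.fft.fftn(np.asarray(data, dtype=np.float64)))
    lo = n // 2 - m // 2
    Fc = F[lo:lo + m, lo:lo + m, lo:lo + m]
    out = np.fft.ifftn(np.fft.ifftshift(Fc)).real
    return out * (m**3 / n**3)


def _rotate(data: np.ndarray, R: np.ndarray) -> np.ndarray:
    from ._kernels import rotate_trilinear

    M, off = _index_affine(R, data.shape[0])
    src = np.ascontiguousarray(data, dtype=np.float32)
    out = np.empty_like(src)
    rotate_trilinear(src, np.ascontiguousarray(M), np.ascontiguousarray(off), out)
    return out


def _global_orientations(step: float) -> list[np.ndarray]:
    """Near-uniform SO(3) grid: tilt rings weighted by sin(tilt)."""
    Rs = []
    tilts = np.arange(0.0, 180.0 + 0.5 * step, step)
    for tilt in tilts:
        n_rot = max(1, int(round(360.0 * np.sin(np.radians(tilt)) / step)))
        for rot in np.arange(n_rot) * (360.0 / n_rot):
            for psi in np.arange(0.0, 360.0, step):
                Rs.append(Rotation.from_euler(
                    "ZYZ", [rot, tilt, psi], degrees=True).as_matrix())
    return Rs


def _neighbor_rotations(R: np.ndarray, step_deg: float) -> list[np.ndarray]:
    """Premultiplied small rotations about x, y, z (avoids Euler gimbal)."""
    out = []
    for ax in range(3):
        for s in (+1.0, -1.0):
            v = np.zeros(3)
            v[ax] = np.radians(s * step_deg)
            out.append(Rotation.from_rotvec(v).as_matrix() @ R)
    return out


def _local_refine(ref_data, target: _MaskedTarget, R, step, min_step, max_shift):
    """Greedy pattern search over rotations; returns (cc, R, shift)."""
    cc, shift, _ = target.correlate(_rotate(ref_data, R), max_shift)
    while step >= min_step:
        improved = False
        for Rn in _neighbor_rotations(R, step):
            ccn, shiftn, _ = target.correlate(_rotate(ref_data, Rn), max_shift)
            if ccn > cc:
                cc, R, shift = ccn, Rn, shiftn
                improved = True
        if not improved:
            step /= 2.0
    return cc, R, shift


class _RigidMatcher:
    """Hierarchical rigid search against one subtomogram.

    Scores a global orientation grid at a Fourier-cropped size, refines the
    best candidates locally, and polishes at full resolution.  Subsequent
    calls with ``warm_start`` only refine locally around the previous pose.
    """

    def __init__(self, sub: Subtomogram, opts: AlignmentOptions):
        self.opts = opts
        n = sub.n
        self.n = n
        self.full = _MaskedTarget(sub.volume.data, sub.wedge, opts.max_frequency)
        m = min(opts.coarse_size, n)
        self.m = m
        self.scale = n / m
        # band limit in cycles/voxel scales with the crop factor
        self.coarse = (
            self.full if m == n
            else _MaskedTarget(_fourier_crop(sub.volume.data, m), sub.wedge,
                               min(0.5, opts.max_frequency * self.scale))
        )

    def _coarse_of(self, ref_data):
        return ref_data if self.m == self.n else _fourier_crop(ref_data, self.m)

    def global_candidates(self, ref_data) -> list[np.ndarray]:
        """Scan the global orientation grid; locally refined top candidates.

        The returned rotations seed the per-evaluation "tracks": plausible
        pose basins that are each re-refined as the deformation changes, so
        the rigid re-estimation stays robust to basin swaps even though it
        is local after this one global scan.
        """
        opts = self.opts
        small = self._coarse_of(ref_data)
        max_shift_c = opts.max_shift / self.scale
        scored = []
        for R in _global_orientations(opts.coarse_step):
            cc, shift, _ = self.coarse.correlate(_rotate(small, R), max_shift_c)
            scored.append((cc, R))
        scored.sort(key=lambda t: -t[0])
        tracks = []
        for cc0, R in scored[: opts.top_candidates]:
            cc, Rr, _ = _local_refine(
                small, self.coarse, R, opts.coarse_step / 2, 2.0, max_shift_c,
            )
            tracks.append((cc, Rr))
        tracks.sort(key=lambda t: -t[0])
        return self._dedupe([R for _, R in tracks])

    @staticmethod
    def _dedupe(rotations, min_angle=3.0):
        kept: list[np.ndarray] = []
        for R in rotations:
            dup = False
            for K in kept:
                cos = np.clip((np.trace(R @ K.T) - 1.0) / 2.0, -1.0, 1.0)
                if np.degrees(np.arccos(cos)) < min_angle:
                    dup = True
                    break
            if not dup:
                kept.append(R)
        return kept

    def refine_tracks(self, ref_data, tracks, step=4.0):
        """Refine every candidate pose; return the best at full resolution.

        Returns ``(cc, R, shift, new_tracks)``.
        """
        small = self._coarse_of(ref_data)
        max_shift_c = self.opts.max_shift / self.scale
        new_tracks = []
        best = (-np.inf, None)
        for R in tracks:
            cc, Rr, _ = _local_refine(small, self.coarse, R, step, 1.0, max_shift_c)
            new_tracks.append(Rr)
            if cc > best[0]:
                best = (cc, Rr)
        R = best[1]
        cc, shift, _ = self.full.correlate(_rotate(ref_data, R), self.opts.max_shift)
        return cc, R, shift, self._dedupe(new_tracks)

    def global_search(self, ref_data):
        tracks = self.global_candidates(ref_data)
        best = (-np.inf, None, None)
        for R in tracks:
            cc, Rr, shift = self.polish(ref_data, R)
            if cc > best[0]:
                best = (cc, Rr, shift)
        return best

    def polish(self, ref_data, R):
        """Full-resolution pattern refinement down to the finest step."""
        cc, R, shift = _local_refine(
            ref_data, self.full, R, 2.0, self.opts.fine_step, self.opts.max_shift
        )
        return cc, R, shift


def rigid_align(ref: DensityVolume, sub: Subtomogram,
                opts: AlignmentOptions | None = None) -> tuple[RigidParams, float]:
    """Rigid-body alignment of a reference volume to a subtomogram.

    Returns the pose maximizing the wedge-constrained CC, such that
    ``shift(rotate(ref))`` matches the subtomogram.
    """
    opts = opts or AlignmentOptions()
    data = np.asarray(ref.data, dtype=np.float64)
    if float(np.var(data)) == 0:
        raise ValueError("flat reference volume")
    if opts.ctf is not None:
        data = _apply_radial_ctf(data, opts.ctf, ref.voxel_size)
    matcher = _RigidMatcher(sub, opts)
    cc, R, shift = matcher.global_search(data)
    rigid = RigidParams.from_matrix(R, shift)
    # exact CCC at the final (sub-voxel) pose; the search value is an estimate
    cc = constrained_cc(
        rotate_shift_volume(DensityVolume(data, ref.voxel_size), rigid), sub)
    return rigid, float(cc)


def elastic_rigid_align(
    ref,
    ms: NormalModeSet,
    selection: ModeSelection,
    sub: Subtomogram,
    opts: AlignmentOptions | None = None,
) -> AlignmentResult:
    """Joint normal-mode amplitude and rigid-body pose estimation.

    The amplitudes start at zero (undeformed reference); each objective
    evaluation renders the deformed reference on the subtomogram grid and
    re-estimates the rigid pose (globally on the first evaluation, by
    warm-started local refinement afterwards), returning the negative CCC to
    the trust-region optimizer.  Ties in CCC prefer the smaller deformation.
    Never raises for valid inputs: optimizer failure yields a non-converged
    best-so-far result.
    """
    opts = opts or AlignmentOptions()
    n = sub.n
    voxel = sub.volume.voxel_size
    if len(selection) == 0:
        rigid, cc = rigid_align(
            DensityVolume(_render(ref, None, None, None, n, voxel, opts), voxel),
            sub, opts)
        return AlignmentResult(np.zeros(0), rigid, cc, 1, True)

    matcher = _RigidMatcher(sub, opts)
    state = {"tracks": None, "best": None}  # best: (cc, a, R, shift)

    def objective(a):
        data = _render(ref, ms, selection, a, n, voxel, opts)
        if state["tracks"] is None:
            state["tracks"] = matcher.global_candidates(data)
        cc, R, shift, state["tracks"] = matcher.refine_tracks(data, state["tracks"])
        b = state["best"]
        if b is None or cc > b[0] + 1e-12 or (
            abs(cc - b[0]) <= 1e-12 and np.linalg.norm(a) < np.linalg.norm(b[1])
        ):
            state["best"] = (cc, np.asarray(a, dtype=float).copy(), R, shift)
        return -cc

    err = None
    converged = False
    n_evals = 0
    try:
        res = minimize_trust_region(
            objective,
            np.zeros(len(selection)),
            initial_radius=100.0 * opts.trust_region_scale,
            final_radius=opts.final_radius,
            max_evaluations=opts.max_iterations,
            tie_break=lambda a: float(np.linalg.norm(a)),
        )
        converged = res.converged
        n_evals = res.n_evaluations
    except Exception as exc:  # noqa: BLE001 — contract: best-so-far, no raise
        err = f"{type(exc).__name__}: {exc}"
        warnings.warn(f"amplitude optimization aborted: {err}", stacklevel=2)
    if state["best"] is None:
        return AlignmentResult(np.zeros(len(selection)), RigidParams(),
                               np.nan, n_evals, False, error=err or "no evaluation")
    cc, a, R, shift = state["best"]
    # final full-resolution rigid polish at the best amplitudes
    data = _render(ref, ms, selection, a, n, voxel, opts)
    cc2, R2, shift2 = matcher.polish(data, R)
    if cc2 >= cc:
        cc, R, shift = cc2, R2, shift2
    rigid = RigidParams.from_matrix(R, shift)
    # exact CCC at the final (sub-voxel) pose; the search value is an estimate
    ccc = constrained_cc(rotate_shift_volume(DensityVolume(data, voxel), rigid), sub)
    return AlignmentResult(
        amplitudes=a, rigid=rigid,
        ccc=float(ccc), iterations=n_evals, converged=converged, error=err,
    )


_ctf_profile_cache: dict = {}


def _apply_radial_ctf(data: np.ndarray, ctf, voxel: float) -> np.ndarray:
    key = (data.shape[0], voxel, ctf.defocus_um, ctf.voltage_kv, ctf.cs_mm,
           ctf.amplitude_contrast)
    h = _ctf_profile_cache.get(key)
    if h is None:
        from .tomosim import ctf_function

        n = data.shape[0]
        k = np.fft.fftfreq(n, d=voxel)
        kz, ky, kx = np.meshgrid(k, k, k[: n // 2 + 1], indexing="ij")
        h = ctf_function(ctf, np.sqrt(kx**2 + ky**2 + kz**2)).astype(np.float32)
        if len(_ctf_profile_cache) > 8:
            _ctf_profile_cache.clear()
        _ctf_profile_cache[key] = h
    import scipy.fft

    n = data.shape[0]
    return scipy.fft.irfftn(
        scipy.fft.rfftn(np.asarray(data, dtype=np.float32)) * h, s=(n, n, n)
    )


def _render(ref, ms, selection, amplitudes, n, voxel, opts: AlignmentOptions):
    if amplitudes is None or ms is None:
        s = ref
    else:
        s = deform(ref, ms, selection, amplitudes)
    data = structure_to_volume(s, n, voxel, sigma=opts.render_sigma).data
    if opts.ctf is not None:
        data = _apply_radial_ctf(data, opts.ctf, voxel)
    return data


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------

def _align_one(args):
    i, ref, ms, selection, sub, opts = args
    try:
        return i, elastic_rigid_align(ref, ms, selection, sub, opts)
    except Exception as exc:  # noqa: BLE001 — per-item failures are recorded
        return i, AlignmentResult(
            np.full(len(selection), np.nan), RigidParams(), np.nan, 0, False,
            error=f"{type(exc).__name__}: {exc}",
        )


def align_dataset(
    ref,
    ms: NormalModeSet,
    selection: ModeSelection,
    subtomograms: list[Subtomogram],
    opts: AlignmentOptions | None = None,
    workers: int = 1,
    checkpoint=None,
):
    """Align every subtomogram independently; returns a pandas DataFrame.

    Order-preserving and independent of ``workers``.  If ``checkpoint`` is a
    TSV path, finished rows are appended as they complete and already-present
    indices are not recomputed on a re-run.
    """
    import pandas as pd
    from pathlib import Path

    if not subtomograms:
        raise ValueError("empty dataset")
    opts = opts or AlignmentOptions()
    done: dict[int, dict] = {}
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        if checkpoint.exists():
            prev = pd.read_csv(checkpoint, sep="\t")
            done = {int(r["index"]): dict(r) for _, r in prev.iterrows()}

    todo = [i for i in range(len(subtomograms)) if i not in done]
    tasks = [(i, ref, ms, selection, subtomograms[i], opts) for i in todo]
    rows = dict(done)

    def record(i, result):
        row = {"index": i}
        for num, a in zip(selection.indices, np.atleast_1d(result.amplitudes)):
            row[f"a{num}"] = float(a)
        rot, tilt, psi = result.rigid.euler
        x, y, z = result.rigid.shift
        row.update(rot=rot, tilt=tilt, psi=psi, x=x, y=y, z=z,
                   ccc=result.ccc, iterations=result.iterations,
                   converged=result.converged,
                   error="" if result.error is None else result.error)
        rows[i] = row
        if checkpoint is not None:
            pd.DataFrame([rows[j] for j in sorted(rows)]).to_csv(
                checkpoint, sep="\t", index=False)

    if workers <= 1 or len(tasks) <= 1:
        for t in tasks:
            i, result = _align_one(t)
            record(i, result)
    else:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=workers) as ex:
            for i, result in ex.map(_align_one, tasks):
                record(i, result)

    return pd.DataFrame([rows[i] for i in sorted(rows)]).reset_index(drop=True)


def results_to_table(results: list[AlignmentResult], selection: ModeSelection):
    """AlignmentResult list -> DataFrame (same columns as align_dataset)."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        row = {"index": i}
        for num, a in zip(selection.indices, np.atleast_1d(r.amplitudes)):
            row[f"a{num}"] = float(a)
        row.update(rot=r.rigid.euler[0], tilt=r.rigid.euler[1], psi=r.rigid.euler[2],
                   x=r.rigid.shift[0], y=r.rigid.shift[1], z=r.rigid.shift[2],
                   ccc=r.ccc, iterations=r.iterations, converged=r.converged)
        rows.append(row)
    return pd.DataFrame(rows)
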