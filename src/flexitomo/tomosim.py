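"""Synthetic cryo-ET subtomogram generation.

Emulates the single-axis tilt acquisition geometry: a molecule is elastically
deformed, rendered, rigid-body transformed, projected into a tilt series
(beam along z, tilt about y), modulated by a CTF with noise split before and
after the CTF, and reconstructed by direct Fourier inversion — which leaves
the characteristic missing wedge in the subtomogram's Fourier transform.

Rotation convention: intrinsic ZYZ Euler angles (rot, tilt, psi), right
handed, about the volume center; shifts are applied after rotation, in
voxels.  Volumes are numpy arrays indexed [z, y, x].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .structures import AtomicStructure, DensityVolume, PseudoatomModel, structure_to_volume
from .nma import NormalModeSet, ModeSelection, deform

__all__ = [
    "RigidParams",
    "CTFParams",
    "TiltSeries",
    "WedgeDescriptor",
    "Subtomogram",
    "GroundTruthRecord",
    "rotate_shift_volume",
    "project_tilt_series",
    "ctf_function",
    "apply_ctf",
    "add_noise_split",
    "reconstruct_fourier",
    "phase_flip_radial",
    "wedge_mask",
    "simulate_subtomogram",
    "draw_ground_truth",
    "generate_dataset",
    "records_to_table",
]


def _matrix_to_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles of a rotation matrix (gimbal-lock warning silenced:
    at tilt 0/180 the rot/psi split is arbitrary and psi = 0 is fine)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


@dataclass
class RigidParams:
    """Rigid-body pose: ZYZ intrinsic Euler angles (deg) and voxel shifts."""

    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rot, tilt, psi
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # x, y, z voxels

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return Rotation.from_euler("ZYZ", self.euler, degrees=True).as_matrix()

    @classmethod
    def from_matrix(cls, R: np.ndarray, shift=(0.0, 0.0, 0.0)) -> "RigidParams":
        rot, tilt, psi = _matrix_to_zyz(R)
        return cls((rot % 360.0, tilt, psi % 360.0), tuple(shift)).canonical()

    def canonical(self) -> "RigidParams":
        """Equivalent parameters with rot, psi in [0, 360) and tilt in [0, 180]."""
        rot, tilt, psi = _matrix_to_zyz(self.matrix())
        if tilt < 0:  # as_euler returns tilt in [0, 180] for ZYZ already
            rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
        return replace(self, euler=(rot % 360.0, tilt, psi % 360.0))


@dataclass
class CTFParams:
    """Microscope contrast transfer function parameters.

    ``defocus_um`` follows the convention where -1 um denotes underfocus.
    """

    defocus_um: float = -1.0
    voltage_kv: float = 300.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.1

    def __post_init__(self):
        if self.voltage_kv <= 0:
            raise ValueError("voltage must be positive")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage_kv * 1e3
        return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


@dataclass
class TiltSeries:
    images: np.ndarray  # (T, n, n), image pixels indexed [y, x]
    angles: np.ndarray  # (T,) tilt degrees, strictly increasing
    ctf: CTFParams | None = None
    pixel_size: float = 1.0

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != len(self.images):
            raise ValueError("one angle per image required")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("tilt angles must be strictly increasing")


@dataclass
class WedgeDescriptor:
    """Single-axis tilt range, e.g. (-60, +60) degrees."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0

    def __post_init__(self):
        if self.tilt_min >= self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")


@dataclass
class Subtomogram:
    volume: DensityVolume
    wedge: WedgeDescriptor

    @property
    def n(self) -> int:
        return self.volume.n


@dataclass
class GroundTruthRecord:
    """Generator draw for one subtomogram."""

    amplitudes: np.ndarray  # per generator mode
    mode_numbers: tuple[int, ...]
    rigid: RigidParams
    label: str  # "Continuous" or Discrete class id ("class0"...)


def _index_affine(R_xyz: np.ndarray, n: int, shift_xyz=None) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset for scipy.affine_transform on [z, y, x]-indexed arrays.

    Produces the volume rotated by ``R`` about the box center and then
    shifted by ``shift`` voxels: out(x) = in(R^-1 (x - c - t) + c).
    """
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx <-> xyz
    Rinv_idx = perm @ R_xyz.T @ perm
    c = np.full(3, n // 2, dtype=float)
    t = np.zeros(3) if shift_xyz is None else (perm @ np.asarray(shift_xyz, dtype=float))
    # out(i) = in(Rinv_idx @ (i - c - t) + c)
    offset = c - Rinv_idx @ (c + t)
    return Rinv_idx, offset


def rotate_shift_volume(v: np.ndarray | DensityVolume, rigid: RigidParams,
                        order: int = 1) -> np.ndarray | DensityVolume:
    """Apply a rigid-body transform (rotate about center, then shift)."""
    data = v.data if isinstance(v, DensityVolume) else np.asarray(v)
    M, off = _index_affine(rigid.matrix(), data.shape[0], rigid.shift)
    out = affine_transform(data, M, offset=off, order=order, prefilter=False)
    if isinstance(v, DensityVolume):
        return DensityVolume(out, v.voxel_size)
    return out


def project_tilt_series(
    v: DensityVolume,
    angles,
    rigid: RigidParams | None = None,
    ctf: CTFParams | None = None,
) -> TiltSeries:
    """Parallel-beam projection of a volume over a set of tilt angles.

    For tilt angle theta the volume is rotated by ``R_y(theta)`` about its
    center and summed along the beam (z) axis.  An optional rigid pose is
    composed into the same interpolation step, so ``project_tilt_series(v,
    angles, rigid)`` equals projecting ``rotate_shift_volume(v, rigid)`` up
    to one interpolation.
    """
    data = np.asarray(v.data, dtype=float)
    n = data.shape[0]
    images = np.empty((len(angles), n, n))
    R0 = np.eye(3) if rigid is None else rigid.matrix()
    t0 = np.zeros(3) if rigid is None else np.asarray(rigid.shift, dtype=float)
    for i, theta in enumerate(angles):
        Ry = Rotation.from_euler("y", theta, degrees=True).as_matrix()
        # total transform: first the particle pose, then the stage tilt
        R = Ry @ R0
        t = Ry @ t0
        M, off = _index_affine(R, n, t)
        rotated = affine_transform(data, M, offset=off, order=1, prefilter=False)
        images[i] = rotated.sum(axis=0)
    return TiltSeries(images, np.asarray(angles, dtype=float), ctf=ctf,
                      pixel_size=v.voxel_size)


def ctf_function(ctf: CTFParams, freq: np.ndarray) -> np.ndarray:
    """CTF(f) = -sqrt(1 - A^2) sin(chi) - A cos(chi) with
    chi = pi * lambda * dz * f^2 - (pi/2) * Cs * lambda^3 * f^4.

    ``freq`` is spatial frequency in 1/Angstrom.
    """
    lam = ctf.wavelength
    dz = ctf.defocus_um * 1e4  # um -> A
    cs = ctf.cs_mm * 1e7  # mm -> A
    a = ctf.amplitude_contrast
    chi = np.pi * lam * dz * freq**2 - 0.5 * np.pi * cs * lam**3 * freq**4
    return -np.sqrt(max(0.0, 1.0 - a**2)) * np.sin(chi) - a * np.cos(chi)


def apply_ctf(img: np.ndarray, ctf: CTFParams, pixel_size: float) -> np.ndarray:
    """Modulate an image by the CTF (multiplication in Fourier space)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    n = img.shape[0]
    fy = np.fft.fftfreq(n, d=pixel_size)[:, None]
    fx = np.fft.rfftfreq(n, d=pixel_size)[None, :]
    h = ctf_function(ctf, np.sqrt(fx**2 + fy**2))
    return np.fft.irfft2(np.fft.rfft2(img) * h, s=img.shape)


def phase_flip_radial(v: DensityVolume, ctf: CTFParams) -> DensityVolume:
    """Minimal CTF correction of a reconstructed volume: sign flipping.

    A tilt-series reconstruction from CTF-modulated images carries the
    radial factor ``CTF(|k|)`` on its Fourier coefficients; multiplying by
    ``sign(CTF)`` restores the correct sign everywhere (leaving the
    amplitude modulation in place), so the volume can be compared against
    unmodulated references, e.g. in FSC computations.
    """
    n = v.n
    k = np.fft.fftfreq(n, d=v.voxel_size)
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    h = ctf_function(ctf, np.sqrt(kx**2 + ky**2 + kz**2))
    s = np.where(h < 0, -1.0, 1.0)
    data = np.fft.ifftn(np.fft.fftn(v.data.astype(float)) * s).real
    return DensityVolume(data.astype(np.float32), v.voxel_size)


def _mean_ctf_power(ctf: CTFParams, n: int, pixel_size: float) -> float:
    fy = np.fft.fftfreq(n, d=pixel_size)[:, None]
    fx = np.fft.fftfreq(n, d=pixel_size)[None, :]
    h = ctf_function(ctf, np.sqrt(fx**2 + fy**2))
    return float(np.mean(h**2))


def add_noise_split(ts: TiltSeries, snr: float, split: float = 0.5,
                    seed: int | None = None) -> TiltSeries:
    """Apply the CTF and add Gaussian white noise at a target SNR.

    The total noise variance per image is ``var(ctf(img)) / snr``; a fraction
    ``split`` of it is injected *before* the CTF (and therefore becomes
    CTF-modulated, with its variance pre-compensated so the post-CTF
    contribution is exactly the requested fraction) and the remainder is
    added after.  If the series carries no CTF, plain additive noise with
    variance ``var(img) / snr`` is used.  Deterministic per seed; noise is
    normalized per image.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not 0 <= split <= 1:
        raise ValueError("split must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.empty_like(ts.images)
    ctf = ts.ctf
    power = _mean_ctf_power(ctf, ts.images.shape[1], ts.pixel_size) if ctf else 1.0
    for i, img in enumerate(ts.images):
        signal = apply_ctf(img, ctf, ts.pixel_size) if ctf else img
        var_sig = float(np.var(signal))
        if var_sig == 0:
            raise ValueError(f"zero-variance tilt image {i}")
        var_noise = var_sig / snr
        if ctf:
            pre = rng.normal(0.0, np.sqrt(split * var_noise / power), img.shape)
            post = rng.normal(0.0, np.sqrt((1 - split) * var_noise), img.shape)
            out[i] = apply_ctf(img + pre, ctf, ts.pixel_size) + post
        else:
            out[i] = img + rng.normal(0.0, np.sqrt(var_noise), img.shape)
    return TiltSeries(out, ts.angles, ctf=ctf, pixel_size=ts.pixel_size)


def wedge_mask(n: int, wd: WedgeDescriptor, shifted: bool = False) -> np.ndarray:
    """Boolean mask of the trusted (sampled) Fourier region.

    A frequency sample ``(kx, ky, kz)`` is trusted iff a tilt angle in the
    acquisition range sampled its central plane; for a single-axis tilt
    about y with the beam along z this is ``atan2(|kz|, |kx|) <= tilt_max``
    for a symmetric range.  Returned in the unshifted ``np.fft.fftn`` layout
    (DC at index 0) unless ``shifted``.
    """
    k = np.fft.fftfreq(n) * n
    kz = k[:, None, None]
    kx = k[None, None, :]
    alpha = np.degrees(np.arctan2(-kz, kx))  # plane angle, in (-180, 180]
    alpha = (alpha + 90.0) % 180.0 - 90.0  # fold k -> -k symmetry into (-90, 90]
    lo = max(wd.tilt_min, -90.0)
    hi = min(wd.tilt_max, 90.0)
    inside = (alpha >= lo) & (alpha <= hi)
    # the tilt axis (kx = kz = 0) is sampled by every image
    inside = inside | ((kz == 0) & (kx == 0))
    mask = np.broadcast_to(inside, (n, n, n)).copy()
    if shifted:
        mask = np.fft.fftshift(mask)
    return mask


def reconstruct_fourier(ts: TiltSeries, wedge: WedgeDescriptor | None = None,
                        oversample: int = 2) -> Subtomogram:
    """Direct Fourier inversion of a tilt series into a subtomogram.

    Each image's 2-D DFT is inserted as a central slice of the 3-D DFT
    (slice normal = beam direction at that tilt) with trilinear gridding and
    per-voxel hit-count weighting; unsampled coefficients stay zero, which
    produces the missing wedge.  The gridding runs on an ``oversample``-times
    finer Fourier grid (images are zero-padded accordingly) to keep the
    trilinear smearing well below the spectrum's correlation length; the
    result is cropped back to the acquisition box and its Fourier support
    restricted to the trusted (non-wedge) region.
    """
    from ._kernels import insert_slices

    if len(ts.images) < 1:
        raise ValueError("need at least one tilt image")
    n = ts.images.shape[1]
    o = max(1, int(oversample))
    m = o * n
    pad = (m - n) // 2
    padded = np.pad(ts.images, ((0, 0), (pad, m - n - pad), (pad, m - n - pad)))
    # centered 2-D DFTs (object centered at m/2 -> treat that voxel as origin)
    slices = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(padded, axes=(1, 2)), axes=(1, 2)),
        axes=(1, 2),
    )
    T = len(ts.angles)
    ex = np.empty((T, 3))
    ey = np.empty((T, 3))
    for t, theta in enumerate(ts.angles):
        Rinv = Rotation.from_euler("y", -theta, degrees=True).as_matrix()
        ex[t] = Rinv @ np.array([1.0, 0.0, 0.0])
        ey[t] = Rinv @ np.array([0.0, 1.0, 0.0])
    facc = np.zeros((m, m, m), dtype=np.complex128)
    wacc = np.zeros((m, m, m), dtype=np.float64)
    insert_slices(facc, wacc, np.ascontiguousarray(slices), ex, ey)
    hit = wacc > 1e-12
    facc[hit] /= wacc[hit]
    facc[~hit] = 0.0
    big = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(facc))).real
    c = m // 2
    vol = np.ascontiguousarray(big[c - n // 2:c + (n + 1) // 2,
                                   c - n // 2:c + (n + 1) // 2,
                                   c - n // 2:c + (n + 1) // 2])
    if wedge is None:
        wedge = WedgeDescriptor(float(ts.angles.min()), float(ts.angles.max()))
    if o > 1:
        # cropping leaks a sinc tail into the wedge; re-zero the untrusted region
        vol = np.fft.ifftn(np.fft.fftn(vol) * wedge_mask(n, wedge)).real
    return Subtomogram(DensityVolume(vol.astype(np.float32), ts.pixel_size), wedge)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

#: amplitude triples of the three discrete classes on (mode 7, mode 8)
DISCRETE_CLASSES = ((-150.0, 0.0), (150.0, 0.0), (0.0, 150.0))
CONTINUOUS_RANGE = (-200.0, 200.0)


def draw_ground_truth(
    kind: str,
    n_subtomograms: int,
    mode_numbers: tuple[int, ...] = (7, 8),
    shift_range: float = 5.0,
    seed: int | None = None,
) -> list[GroundTruthRecord]:
    """Draw per-subtomogram conformational and rigid ground truth.

    "Discrete": classes split as evenly as possible across the three
    amplitude pairs (-150, 0), (+150, 0), (0, +150) on the two generator
    modes.  "Continuous": equal amplitudes on both modes, uniform in
    [-200, 200].  Euler angles uniform in [0, 360) each; shifts uniform in
    [-shift_range, +shift_range] voxels per axis.
    """
    if kind not in ("Discrete", "Continuous"):
        raise ValueError("kind must be 'Discrete' or 'Continuous'")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subtomograms):
        if kind == "Discrete":
            cls = i % len(DISCRETE_CLASSES)
            amps = np.array(DISCRETE_CLASSES[cls])
            label = f"class{cls}"
        else:
            a = rng.uniform(*CONTINUOUS_RANGE)
            amps = np.array([a, a])
            label = "Continuous"
        euler = tuple(rng.uniform(0.0, 360.0, 3))
        shift = tuple(rng.uniform(-shift_range, shift_range, 3))
        records.append(GroundTruthRecord(
            amplitudes=amps, mode_numbers=tuple(mode_numbers),
            rigid=RigidParams(euler, shift), label=label,
        ))
    return records


def simulate_subtomogram(
    ref,
    ms: NormalModeSet,
    record: GroundTruthRecord,
    box: int = 64,
    voxel_size: float = 2.2,
    sigma: float | None = None,
    snr: float = 0.01,
    ctf: CTFParams | None = None,
    tilt_range: tuple[float, float] = (-60.0, 60.0),
    tilt_step: float = 1.0,
    noise_split: float = 0.5,
    seed: int | None = None,
) -> Subtomogram:
    """Run the full forward model for one ground-truth draw."""
    sel = ModeSelection(indices=list(record.mode_numbers))
    deformed = deform(ref, ms, sel, record.amplitudes)
    vol = structure_to_volume(deformed, box, voxel_size, sigma=sigma)
    angles = np.arange(tilt_range[0], tilt_range[1] + 0.5 * tilt_step, tilt_step)
    ts = project_tilt_series(vol, angles, rigid=record.rigid, ctf=ctf)
    if snr is not None and np.isfinite(snr):
        ts = add_noise_split(ts, snr=snr, split=noise_split, seed=seed)
    elif ctf is not None:
        ts = TiltSeries(
            np.stack([apply_ctf(im, ctf, ts.pixel_size) for im in ts.images]),
            ts.angles, ctf=ctf, pixel_size=ts.pixel_size,
        )
    return reconstruct_fourier(ts, WedgeDescriptor(*tilt_range))


def generate_dataset(
    ref,
    ms: NormalModeSet,
    kind: str,
    n_subtomograms: int,
    box: int = 64,
    voxel_size: float = 2.2,
    snr: float = 0.01,
    ctf: CTFParams | None = None,
    tilt_range: tuple[float, float] = (-60.0, 60.0),
    tilt_step: float = 1.0,
    mode_numbers: tuple[int, ...] = (7, 8),
    shift_range: float = 5.0,
    sigma: float | None = None,
    noise_split: float = 0.5,
    seed: int = 0,
) -> tuple[list[Subtomogram], list[GroundTruthRecord]]:
    """Generate a "Discrete" or "Continuous" synthetic dataset.

    Defaults follow the validation conditions: 64^3 boxes at 2.2 A/voxel,
    SNR 0.01 with the noise split around a -1 um defocus CTF, tilts -60..+60
    deg in 1 deg steps, shifts in [-5, +5] voxels.  Fully reproducible per
    seed.
    """
    if ctf is None:
        ctf = CTFParams()
    records = draw_ground_truth(kind, n_subtomograms, mode_numbers,
                                shift_range, seed=seed)
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x51CE])
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in
                   ss.spawn(n_subtomograms)]
    subtomograms = []
    for rec, s in zip(records, child_seeds):
        subtomograms.append(simulate_subtomogram(
            ref, ms, rec, box=box, voxel_size=voxel_size, sigma=sigma,
            snr=snr, ctf=ctf, tilt_range=tilt_range, tilt_step=tilt_step,
            noise_split=noise_split, seed=s,
        ))
    return subtomograms, records


def records_to_table(records: list[GroundTruthRecord]):
    """Ground-truth records as a pandas DataFrame (one row per subtomogram)."""
    import pandas as pd

    rows = []
    for i, r in enumerate(records):
        row = {"index": i, "label": r.label}
        for num, a in zip(r.mode_numbers, r.amplitudes):
            row[f"a{num}"] = a
        row.update(rot=r.rigid.euler[0], tilt=r.rigid.euler[1], psi=r.rigid.euler[2],
                   x=r.rigid.shift[0], y=r.rigid.shift[1], z=r.rigid.shift[2])
        rows.append(row)
    return pd.DataFrame(rows)
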