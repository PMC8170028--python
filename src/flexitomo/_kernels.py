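"""Numba kernels for the two scatter-heavy inner loops.

Both kernels are compiled with ``cache=True`` so repeated processes (workers,
test runs) reuse the on-disk compilation.
"""

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def render_gaussians(out, coords_zyx, weights, sigma, cutoff_sigmas):
    """Splat unit-mass isotropic Gaussians onto a cubic grid.

    Parameters
    ----------
    out : (n, n, n) float64 array, modified in place.
    coords_zyx : (P, 3) voxel positions in array index order (z, y, x).
    sigma : kernel standard deviation in voxels.
    """
    n = out.shape[0]
    r_cut = int(np.ceil(cutoff_sigmas * sigma))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    for p in range(coords_zyx.shape[0]):
        cz, cy, cx = coords_zyx[p, 0], coords_zyx[p, 1], coords_zyx[p, 2]
        w = weights[p] * norm
        z0 = max(int(cz) - r_cut, 0)
        z1 = min(int(cz) + r_cut + 1, n)
        y0 = max(int(cy) - r_cut, 0)
        y1 = min(int(cy) + r_cut + 1, n)
        x0 = max(int(cx) - r_cut, 0)
        x1 = min(int(cx) + r_cut + 1, n)
        for z in range(z0, z1):
            dz2 = (z - cz) ** 2
            for y in range(y0, y1):
                dzy2 = dz2 + (y - cy) ** 2
                for x in range(x0, x1):
                    d2 = dzy2 + (x - cx) ** 2
                    out[z, y, x] += w * np.exp(-d2 * inv2s2)


@numba.njit(cache=True)
def insert_slices(facc, wacc, slices, ex, ey):
    """Gridding of 2-D Fourier slices into a 3-D Fourier accumulator.

    ``facc``/``wacc`` are centered-layout accumulators of shape (n, n, n)
    indexed ``[kz + n/2, ky + n/2, kx + n/2]``.  Slice pixel ``(iv, iu)``
    holds the Fourier value at ``k = u * ex[t] + v * ey[t]`` with
    ``u = iu - n/2``, ``v = iv - n/2``; ``ex``/``ey`` are (T, 3) slice basis
    vectors in (x, y, z) components.  Trilinear scatter with weight
    accumulation.
    """
    T, n, _ = slices.shape
    h = n // 2
    for t in range(T):
        exx, exy, exz = ex[t, 0], ex[t, 1], ex[t, 2]
        eyx, eyy, eyz = ey[t, 0], ey[t, 1], ey[t, 2]
        for iv in range(n):
            v = iv - h
            for iu in range(n):
                u = iu - h
                val = slices[t, iv, iu]
                kx = u * exx + v * eyx + h
                ky = u * exy + v * eyy + h
                kz = u * exz + v * eyz + h
                x0 = int(np.floor(kx))
                y0 = int(np.floor(ky))
                z0 = int(np.floor(kz))
                fx = kx - x0
                fy = ky - y0
                fz = kz - z0
                for dz in range(2):
                    z = z0 + dz
                    if z < 0 or z >= n:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        y = y0 + dy
                        if y < 0 or y >= n:
                            continue
                        wzy = wz * (fy if dy == 1 else 1.0 - fy)
                        for dx in range(2):
                            x = x0 + dx
                            if x < 0 or x >= n:
                                continue
                            w = wzy * (fx if dx == 1 else 1.0 - fx)
                            if w > 0.0:
                                facc[z, y, x] += w * val
                                wacc[z, y, x] += w


@numba.njit(cache=True, fastmath=True)
def rotate_trilinear(src, M, offset, out):
    """out(i) = src(M @ i + offset), trilinear, zero outside (index space)."""
    n = src.shape[0]
    for z in range(n):
        for y in range(n):
            for x in range(n):
                iz = M[0, 0] * z + M[0, 1] * y + M[0, 2] * x + offset[0]
                iy = M[1, 0] * z + M[1, 1] * y + M[1, 2] * x + offset[1]
                ix = M[2, 0] * z + M[2, 1] * y + M[2, 2] * x + offset[2]
                if (iz < 0.0 or iz > n - 1.0 or iy < 0.0 or iy > n - 1.0
                        or ix < 0.0 or ix > n - 1.0):
                    out[z, y, x] = 0.0
                    continue
                z0 = int(np.floor(iz))
                y0 = int(np.floor(iy))
                x0 = int(np.floor(ix))
                fz = iz - z0
                fy = iy - y0
                fx = ix - x0
                acc = 0.0
                for dz in range(2):
                    zz = z0 + dz
                    if zz < 0 or zz >= n:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        yy = y0 + dy
                        if yy < 0 or yy >= n:
                            continue
                        wy = wz * (fy if dy == 1 else 1.0 - fy)
                        for dx in range(2):
                            xx = x0 + dx
                            if xx < 0 or xx >= n:
                                continue
                            acc += wy * (fx if dx == 1 else 1.0 - fx) * src[zz, yy, xx]
                out[z, y, x] = acc
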