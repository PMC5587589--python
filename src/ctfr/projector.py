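"""Matched fan-beam projector pair (forward ``G`` and adjoint ``Gᵀ``).

Siddon-style exact intersection-length ray tracing: each sinogram entry
is the sum of pixel values along one ray weighted by the ray–pixel
intersection lengths in mm.  The back projector scatters with the *same*
weights, so the pair is a true matrix transpose — required for the exact
line-search step size and verified by the adjoint identity in the tests.

One ray is traced per detector bin by default; ``supersample > 1``
averages that many sub-rays per bin and exists for discretization
oracles, not for routine reconstruction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import AttenuationImage, ImageGrid, ScanGeometry, Sinogram

__all__ = ["forward_project", "back_project"]

_EPS = 1e-12


@njit(cache=True, fastmath=False)
def _trace(sx, sy, dx, dy, t_max, xmin, ymin, ymax, pixel, n_rows, n_cols,
           idx_buf, len_buf):
    """Siddon walk of one ray; fills pixel indices / lengths, returns count.

    The ray is ``(sx, sy) + t * (dx, dy)`` with ``(dx, dy)`` a unit
    vector, so segment lengths are in mm.
    """
    xmax = xmin + n_cols * pixel

    # slab clipping against the grid bounding box
    t_lo = 0.0
    t_hi = t_max
    if abs(dx) > _EPS:
        tx1 = (xmin - sx) / dx
        tx2 = (xmax - sx) / dx
        if tx1 > tx2:
            tx1, tx2 = tx2, tx1
        if tx1 > t_lo:
            t_lo = tx1
        if tx2 < t_hi:
            t_hi = tx2
    elif sx <= xmin or sx >= xmax:
        return 0
    if abs(dy) > _EPS:
        ty1 = (ymin - sy) / dy
        ty2 = (ymax - sy) / dy
        if ty1 > ty2:
            ty1, ty2 = ty2, ty1
        if ty1 > t_lo:
            t_lo = ty1
        if ty2 < t_hi:
            t_hi = ty2
    elif sy <= ymin or sy >= ymax:
        return 0
    if t_hi <= t_lo + _EPS:
        return 0

    # next plane-crossing parameters after t_lo
    if abs(dx) > _EPS:
        fx = (sx + t_lo * dx - xmin) / pixel
        cell = np.floor(fx)
        if dx > 0.0:
            tx = t_lo + ((cell + 1.0) * pixel + xmin - (sx + t_lo * dx)) / dx
        else:
            tx = t_lo + (cell * pixel + xmin - (sx + t_lo * dx)) / dx
        dtx = pixel / abs(dx)
    else:
        tx = 1e300
        dtx = 0.0
    if abs(dy) > _EPS:
        fy = (sy + t_lo * dy - ymin) / pixel
        cell = np.floor(fy)
        if dy > 0.0:
            ty = t_lo + ((cell + 1.0) * pixel + ymin - (sy + t_lo * dy)) / dy
        else:
            ty = t_lo + (cell * pixel + ymin - (sy + t_lo * dy)) / dy
        dty = pixel / abs(dy)
    else:
        ty = 1e300
        dty = 0.0

    count = 0
    t = t_lo
    while True:
        tn = tx if tx < ty else ty
        at_end = False
        if tn >= t_hi:
            tn = t_hi
            at_end = True
        seg = tn - t
        if seg > _EPS:
            tm = 0.5 * (t + tn)
            ix = int((sx + tm * dx - xmin) / pixel)
            iy = int((ymax - (sy + tm * dy)) / pixel)
            if 0 <= ix < n_cols and 0 <= iy < n_rows:
                idx_buf[count] = iy * n_cols + ix
                len_buf[count] = seg
                count += 1
        if at_end:
            break
        if tx <= tn:
            tx += dtx
        if ty <= tn:
            ty += dty
        t = tn
    return count


@njit(cache=True)
def _project_all(img_flat, cos_b, sin_b, gammas, sub_weight, n_sub,
                 r_source, t_max, xmin, ymin, ymax, pixel, n_rows, n_cols,
                 sino, forward):
    """Run every ray.  ``forward=True`` gathers into ``sino``; otherwise
    scatters ``sino`` values into ``img_flat`` (adjoint)."""
    n_views = cos_b.shape[0]
    n_rays = gammas.shape[0]          # n_bins * n_sub
    buf_len = n_rows + n_cols + 4
    idx_buf = np.empty(buf_len, dtype=np.int64)
    len_buf = np.empty(buf_len, dtype=np.float64)
    for v in range(n_views):
        cb = cos_b[v]
        sb = sin_b[v]
        sx = r_source * cb
        sy = r_source * sb
        for r in range(n_rays):
            g = gammas[r]
            cg = np.cos(g)
            sg = np.sin(g)
            # central ray direction (-cb, -sb) rotated CCW by gamma
            dx = -cb * cg + sb * sg
            dy = -cb * sg - sb * cg
            count = _trace(sx, sy, dx, dy, t_max, xmin, ymin, ymax, pixel,
                           n_rows, n_cols, idx_buf, len_buf)
            b = r // n_sub
            if forward:
                acc = 0.0
                for k in range(count):
                    acc += len_buf[k] * img_flat[idx_buf[k]]
                sino[v, b] += acc * sub_weight
            else:
                val = sino[v, b] * sub_weight
                for k in range(count):
                    img_flat[idx_buf[k]] += len_buf[k] * val


def _ray_table(geometry: ScanGeometry, supersample: int):
    """Per-view source angles and the flattened sub-ray fan angles."""
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    beta = np.deg2rad(geometry.view_angles)
    gamma = geometry.bin_fan_angles
    if supersample == 1:
        gammas = gamma
    else:
        if geometry.detector_shape == "curved-equiangular":
            dg = geometry.fan_angle / geometry.n_bins
            offs = (np.arange(supersample) - (supersample - 1) / 2.0) \
                / supersample * dg
            gammas = (gamma[:, None] + offs[None, :]).ravel()
        else:
            du = geometry.detector_extent / geometry.n_bins
            centers = (np.arange(geometry.n_bins)
                       - (geometry.n_bins - 1) / 2.0) * du
            offs = (np.arange(supersample) - (supersample - 1) / 2.0) \
                / supersample * du
            u = (centers[:, None] + offs[None, :]).ravel()
            gammas = np.arctan(u / geometry.source_to_detector)
    return np.cos(beta), np.sin(beta), np.ascontiguousarray(gammas)


def _check_fov(grid: ImageGrid, geometry: ScanGeometry) -> None:
    half = max(grid.width, grid.height) / 2.0
    if half > geometry.fov_radius * (1.0 + 1e-9):
        raise ValueError(
            f"grid half-extent {half:.4g} mm exceeds the fan field-of-view "
            f"radius {geometry.fov_radius:.4g} mm"
        )
    half_diag = float(np.hypot(grid.width, grid.height)) / 2.0
    if geometry.source_to_center <= half_diag:
        raise ValueError("X-ray source lies inside the image grid")


def forward_project(image: AttenuationImage, geometry: ScanGeometry,
                    supersample: int = 1) -> Sinogram:
    """Line integrals of ``image`` along every (view, bin) ray, in mm·μ."""
    grid = image.grid
    _check_fov(grid, geometry)
    cos_b, sin_b, gammas = _ray_table(geometry, supersample)
    sino = np.zeros((geometry.n_views, geometry.n_bins))
    img_flat = np.ascontiguousarray(image.values.ravel())
    _project_all(img_flat, cos_b, sin_b, gammas, 1.0 / supersample,
                 supersample, geometry.source_to_center,
                 geometry.source_to_detector,
                 -grid.width / 2.0, -grid.height / 2.0, grid.height / 2.0,
                 grid.pixel_size, grid.n_rows, grid.n_cols, sino, True)
    return Sinogram(geometry=geometry, values=sino)


def back_project(sino: Sinogram, geometry: ScanGeometry, grid: ImageGrid,
                 supersample: int = 1) -> AttenuationImage:
    """Exact transpose of :func:`forward_project` applied to ``sino``."""
    if sino.geometry != geometry:
        raise ValueError("sinogram geometry does not match the given geometry")
    _check_fov(grid, geometry)
    cos_b, sin_b, gammas = _ray_table(geometry, supersample)
    img_flat = np.zeros(grid.n_rows * grid.n_cols)
    _project_all(img_flat, cos_b, sin_b, gammas, 1.0 / supersample,
                 supersample, geometry.source_to_center,
                 geometry.source_to_detector,
                 -grid.width / 2.0, -grid.height / 2.0, grid.height / 2.0,
                 grid.pixel_size, grid.n_rows, grid.n_cols,
                 np.ascontiguousarray(sino.values), False)
    return AttenuationImage(grid=grid,
                            values=img_flat.reshape(grid.shape))
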