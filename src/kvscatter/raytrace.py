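"""Siddon-style exact ray traversal of a 2-D voxel grid.

The tracer returns, for a world-space segment, the voxels crossed and the
exact intersection length in each — the common kernel behind the forward
projector and the ART system matrix, which must agree for reconstruction
round trips to be meaningful.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def trace_ray(p0, p1, origin, voxel_size, shape):
    """Trace the segment p0 -> p1 (world mm, (y, x)) through a grid.

    Returns ``(rows, cols, lengths_mm)`` — voxel indices and the exact
    chord length of the segment inside each voxel. Voxels are visited in
    order along the ray; lengths sum to the in-grid portion of the segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    seg_len = float(np.hypot(*d))
    if seg_len < _EPS:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))

    tmin, tmax = 0.0, 1.0
    for ax in (0, 1):
        lo = origin[ax]
        hi = origin[ax] + shape[ax] * voxel_size[ax]
        if abs(d[ax]) > _EPS:
            a0 = (lo - p0[ax]) / d[ax]
            a1 = (hi - p0[ax]) / d[ax]
            tmin = max(tmin, min(a0, a1))
            tmax = min(tmax, max(a0, a1))
        elif not (lo <= p0[ax] <= hi):
            return (np.empty(0, int), np.empty(0, int), np.empty(0))
    if tmax - tmin < _EPS:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))

    crossings = [np.array([tmin, tmax])]
    for ax in (0, 1):
        if abs(d[ax]) > _EPS:
            planes = origin[ax] + np.arange(shape[ax] + 1) * voxel_size[ax]
            a = (planes - p0[ax]) / d[ax]
            crossings.append(a[(a > tmin) & (a < tmax)])
    alphas = np.unique(np.concatenate(crossings))
    lengths = np.diff(alphas) * seg_len
    mids = (alphas[:-1] + alphas[1:]) / 2.0
    rows = np.floor((p0[0] + mids * d[0] - origin[0]) / voxel_size[0]).astype(int)
    cols = np.floor((p0[1] + mids * d[1] - origin[1]) / voxel_size[1]).astype(int)
    keep = (
        (lengths > _EPS)
        & (rows >= 0) & (rows < shape[0])
        & (cols >= 0) & (cols < shape[1])
    )
    return rows[keep], cols[keep], lengths[keep]


def material_path_lengths(phantom, p0, p1) -> np.ndarray:
    """Per-material path length (mm) of the segment through a phantom."""
    rows, cols, lengths = trace_ray(p0, p1, phantom.origin, phantom.voxel_size,
                                    phantom.shape)
    out = np.zeros(len(phantom.materials))
    if rows.size:
        np.add.at(out, phantom.label_grid[rows, cols], lengths)
    return out


def ray_row(p0, p1, origin, voxel_size, shape):
    """Flat voxel indices + lengths (mm): one row of a tomographic system."""
    rows, cols, lengths = trace_ray(p0, p1, origin, voxel_size, shape)
    return rows * shape[1] + cols, lengths
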