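"""Geodesic distance transforms from interaction seeds.

The geodesic distance from a seed set S to a voxel x is the shortest-path
cost over the voxel adjacency graph (6- or 26-connectivity) with edge weight

    w(a, b) = sqrt( ||a - b||^2_spacing  +  lambda^2 * (I(a) - I(b))^2 )

i.e. the spatial step length in mm combined with the intensity jump, weighted
by ``lambda_intensity``. lambda = 0 gives the pure spatial chamfer metric;
large lambda makes crossing an intensity step arbitrarily expensive, so the
distance respects image boundaries.

Two computations are provided:

* :func:`geodesic_transform` — Toivanen-style raster-scan sweeps (default 8,
  i.e. four forward/backward passes), compiled with numba; fast and an upper
  bound of the true metric;
* :func:`geodesic_transform_exact` — exact multi-source Dijkstra over the
  same graph (scipy.sparse.csgraph), used as the oracle in tests.

:func:`encode_interactions` turns an interaction set into the two geodesic
network input channels (foreground / background), normalized to [0, 1]. An
empty click set yields a constant fill map equal to the documented
upper-bound constant F = P + lambda * R (P = Manhattan grid diameter in mm,
R = intensity range), which normalizes to 1.0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .formats_io import InteractionSet, PhaseVolume

__all__ = [
    "GeodesicMap",
    "geodesic_transform",
    "geodesic_transform_exact",
    "encode_interactions",
    "fill_constant",
]

DEFAULT_SWEEPS = 8


@dataclass
class GeodesicMap:
    """Non-negative distance grid; zero exactly at the seed voxels."""

    values: np.ndarray
    lambda_intensity: float
    seed_count: int


def _offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        offs = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    elif connectivity == 26:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        raise ValueError("connectivity must be 6 or 26")
    return np.array(offs, dtype=np.int64)


def _backward_half(offs: np.ndarray) -> np.ndarray:
    """Offsets that precede a voxel in raster (z, y, x ascending) order."""
    keep = []
    for dz, dy, dx in offs:
        if dz < 0 or (dz == 0 and dy < 0) or (dz == 0 and dy == 0 and dx < 0):
            keep.append((dz, dy, dx))
    return np.array(keep, dtype=np.int64)


@njit(cache=True)
def _sweep(dist, intensity, offs, step_mm, lam, reverse):  # pragma: no cover - numba
    nz, ny, nx = dist.shape
    n_off = offs.shape[0]
    zs = range(nz - 1, -1, -1) if reverse else range(nz)
    for z in zs:
        ys = range(ny - 1, -1, -1) if reverse else range(ny)
        for y in ys:
            xs = range(nx - 1, -1, -1) if reverse else range(nx)
            for x in xs:
                best = dist[z, y, x]
                ival = intensity[z, y, x]
                for k in range(n_off):
                    zz = z + offs[k, 0]
                    yy = y + offs[k, 1]
                    xx = x + offs[k, 2]
                    if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                        continue
                    di = ival - intensity[zz, yy, xx]
                    w = np.sqrt(step_mm[k] ** 2 + (lam * di) ** 2)
                    cand = dist[zz, yy, xx] + w
                    if cand < best:
                        best = cand
                dist[z, y, x] = best


def _as_array_and_spacing(volume) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(volume, PhaseVolume):
        return np.asarray(volume.voxels, dtype=np.float64), volume.spacing
    raise TypeError("volume must be a PhaseVolume")


def _seed_array(seeds: Iterable[Sequence[int]], shape) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(list(seeds), dtype=np.int64))
    if arr.size == 0:
        raise ValueError("seed set is empty (use encode_interactions for the empty case)")
    if arr.shape[1] != 3:
        raise ValueError("seeds must be (z, y, x) triples")
    if np.any(arr < 0) or np.any(arr >= np.array(shape)):
        raise ValueError("seed outside grid bounds")
    return arr


def geodesic_transform(
    volume: PhaseVolume,
    seeds: Iterable[Sequence[int]],
    lambda_intensity: float = 1.0,
    connectivity: int = 26,
    n_sweeps: int = DEFAULT_SWEEPS,
) -> GeodesicMap:
    """Raster-scan geodesic distance map from ``seeds`` over ``volume``.

    ``n_sweeps`` alternating forward/backward sweeps (default 4) relax the
    distance grid; the result upper-bounds the exact metric and converges to
    it as sweeps increase.
    """
    if lambda_intensity < 0:
        raise ValueError("lambda_intensity must be >= 0")
    intensity, spacing = _as_array_and_spacing(volume)
    seed_arr = _seed_array(seeds, intensity.shape)

    offs = _offsets(connectivity)
    bwd = _backward_half(offs)
    fwd = -bwd
    sp = np.asarray(spacing, dtype=np.float64)
    step_bwd = np.sqrt(((bwd * sp) ** 2).sum(axis=1))
    step_fwd = np.sqrt(((fwd * sp) ** 2).sum(axis=1))

    dist = np.full(intensity.shape, np.inf, dtype=np.float64)
    dist[tuple(seed_arr.T)] = 0.0
    for i in range(n_sweeps):
        if i % 2 == 0:
            _sweep(dist, intensity, bwd, step_bwd, float(lambda_intensity), False)
        else:
            _sweep(dist, intensity, fwd, step_fwd, float(lambda_intensity), True)
    return GeodesicMap(
        values=dist, lambda_intensity=float(lambda_intensity), seed_count=len(seed_arr)
    )


def geodesic_transform_exact(
    volume: PhaseVolume,
    seeds: Iterable[Sequence[int]],
    lambda_intensity: float = 1.0,
    connectivity: int = 26,
) -> GeodesicMap:
    """Exact multi-source Dijkstra over the same voxel graph (test oracle)."""
    if lambda_intensity < 0:
        raise ValueError("lambda_intensity must be >= 0")
    intensity, spacing = _as_array_and_spacing(volume)
    shape = intensity.shape
    seed_arr = _seed_array(seeds, shape)
    n = intensity.size
    flat = intensity.ravel()
    idx = np.arange(n).reshape(shape)
    sp = np.asarray(spacing, dtype=np.float64)

    rows, cols, weights = [], [], []
    for off in _backward_half(_offsets(connectivity)):
        src = idx[
            max(off[0], 0) : shape[0] + min(off[0], 0),
            max(off[1], 0) : shape[1] + min(off[1], 0),
            max(off[2], 0) : shape[2] + min(off[2], 0),
        ].ravel()
        dst = idx[
            max(-off[0], 0) : shape[0] + min(-off[0], 0),
            max(-off[1], 0) : shape[1] + min(-off[1], 0),
            max(-off[2], 0) : shape[2] + min(-off[2], 0),
        ].ravel()
        step = np.sqrt(((off * sp) ** 2).sum())
        w = np.sqrt(step**2 + (lambda_intensity * (flat[src] - flat[dst])) ** 2)
        rows.append(src)
        cols.append(dst)
        weights.append(w)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    seed_idx = np.ravel_multi_index(tuple(seed_arr.T), shape)
    dist = _csgraph_dijkstra(
        graph, directed=False, indices=seed_idx, min_only=True
    )
    return GeodesicMap(
        values=dist.reshape(shape),
        lambda_intensity=float(lambda_intensity),
        seed_count=len(seed_arr),
    )


def fill_constant(shape, spacing, lambda_intensity: float, intensity_range: float) -> float:
    """No-seed fill and normalization scale: F = P + lambda * R.

    P is the Manhattan grid diameter in mm (sum over axes of extent), R the
    intensity range of the (normalized) volume. Distances are divided by F
    and clipped to [0, 1]; an empty seed set maps to the constant 1.0.
    """
    p = float(sum((n - 1) * s for n, s in zip(shape, spacing)))
    return p + float(lambda_intensity) * float(intensity_range)


def encode_interactions(
    volume: PhaseVolume,
    iset: InteractionSet,
    lambda_intensity: float = 1.0,
    hu_window: tuple[float, float] = (-100.0, 300.0),
    connectivity: int = 26,
    n_sweeps: int = DEFAULT_SWEEPS,
) -> tuple[GeodesicMap, GeodesicMap]:
    """Foreground/background geodesic input channels, normalized to [0, 1].

    The volume is clip-rescaled to [0, 1] over ``hu_window`` first (the same
    normalization the segmentation networks use), so the default
    ``lambda_intensity = 1`` weights a full-window intensity jump like a
    ~1 mm spatial step. Each empty click side yields the constant fill map.
    """
    iset.check_bounds(volume.shape)
    lo, hi = hu_window
    norm = np.clip((np.asarray(volume.voxels, np.float64) - lo) / (hi - lo), 0.0, 1.0)
    nvol = PhaseVolume(norm, volume.spacing, phase=volume.phase, study_id=volume.study_id)
    fill = fill_constant(volume.shape, volume.spacing, lambda_intensity, 1.0)

    def one_side(points):
        if len(points) == 0:
            return GeodesicMap(
                values=np.ones(volume.shape, dtype=np.float64),
                lambda_intensity=float(lambda_intensity),
                seed_count=0,
            )
        gmap = geodesic_transform(
            nvol, points, lambda_intensity, connectivity, n_sweeps
        )
        gmap.values = np.clip(gmap.values / fill, 0.0, 1.0)
        return gmap

    return one_side(iset.positive), one_side(iset.negative)
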