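"""Sac separation and velocity-reduction metrics.

The study endpoint is the aneurysmal mean velocity reduction

    AMVR = (STAV_pre − STAV_FD) / STAV_pre

where STAV is the space-and-time-averaged velocity magnitude inside the
aneurysm sac, separated from the parent lumen by the ostium (neck) plane.
Parametric geometries carry their analytic neck plane; for voxelized
geometries without one, a minimal-cross-section fallback locates the neck
from the lumen's distance transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import SurfaceGeometry, VoxelGrid, sac_mask

__all__ = ["SacRegion", "AmvrResult", "detect_ostium_plane", "stav", "amvr"]


class NeckDetectionError(RuntimeError):
    pass


@dataclass
class SacRegion:
    """Ostium plane (normal pointing into the sac) and the sac voxel mask."""

    plane_point: np.ndarray  # mm
    plane_normal: np.ndarray  # unit, parent → sac
    mask: np.ndarray  # boolean over grid voxels

    def save_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "plane_point_mm": list(map(float, self.plane_point)),
                    "plane_normal": list(map(float, self.plane_normal)),
                    "sac_voxels": int(self.mask.sum()),
                },
                fh,
                indent=1,
            )


@dataclass
class AmvrResult:
    stav_pre: float  # m/s
    stav_fd: float  # m/s

    @property
    def amvr(self) -> float:
        return amvr(self.stav_pre, self.stav_fd)


def detect_ostium_plane(g: SurfaceGeometry, grid: VoxelGrid) -> SacRegion:
    """Locate the ostium plane and build the sac mask.

    Parametric sidewall geometries return their stored analytic neck plane.
    Otherwise the neck is found automatically: the sac centre is the
    deepest point of the lumen's Euclidean distance transform away from the
    parent axis, and the plane (normal to the axis→sac-centre direction) is
    slid to the minimal fluid cross-section between parent wall and sac.
    """
    plane = g.metadata.get("ostium_plane") if g.metadata else None
    if plane is not None:
        point = np.asarray(plane["point"], float)
        normal = np.asarray(plane["normal"], float)
        normal = normal / np.linalg.norm(normal)
        mask = _connected_sac(grid, point, normal)
        return SacRegion(point, normal, mask)
    return _fallback_neck(g, grid)


def _connected_sac(grid: VoxelGrid, point, normal) -> np.ndarray:
    mask = sac_mask(grid, point, normal)
    if not mask.any():
        raise NeckDetectionError("no voxels on the sac side of the ostium plane")
    comp, _ = ndimage.label(mask)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    return comp == keep


def _fallback_neck(g: SurfaceGeometry, grid: VoxelGrid) -> SacRegion:
    h = grid.h
    fluid = grid.labels > 0
    pts = grid.voxel_centers(fluid)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    axis = vt[0]

    edt = ndimage.distance_transform_edt(fluid, sampling=h)
    sac_c_idx = np.unravel_index(np.argmax(edt), edt.shape)
    sac_center = grid.origin + (np.asarray(sac_c_idx) + 0.5) * h
    sac_radius = float(edt.max())

    # parent lumen radius: clearance along the axis away from the bulge
    t = (pts - centroid) @ axis
    probes = []
    for ti in np.linspace(np.quantile(t, 0.02), np.quantile(t, 0.98), 25):
        p = centroid + ti * axis
        if np.linalg.norm(p - sac_center) < 1.5 * sac_radius:
            continue
        idx = np.clip(((p - grid.origin) / h - 0.5).astype(int), 0,
                      np.asarray(grid.shape) - 1)
        probes.append(edt[idx[0], idx[1], idx[2]])
    if not probes:
        raise NeckDetectionError("cannot probe the parent lumen radius")
    parent_radius = float(np.median(probes))

    offset = sac_center - (centroid + ((sac_center - centroid) @ axis) * axis)
    dist_off = np.linalg.norm(offset)
    if sac_radius < 1.25 * parent_radius or dist_off < 0.5 * parent_radius:
        raise NeckDetectionError(
            "no sac detectable: lumen shows no bulge off the parent vessel"
        )
    normal = offset / dist_off

    # slide the candidate plane from the parent wall toward the sac centre
    # and keep the minimal fluid cross-section near the sac
    foot = sac_center - dist_off * normal  # on the parent axis
    s_vals = (pts - foot) @ normal
    lateral = pts - foot - np.outer(s_vals, normal)
    near = np.linalg.norm(lateral, axis=1) < sac_radius + 2 * h
    best = None
    for s in np.arange(0.6 * parent_radius, dist_off, h / 2.0):
        sel = near & (np.abs(s_vals - s) < h / 2.0)
        area = sel.sum()
        if area == 0:
            continue
        if best is None or area < best[1]:
            best = (s, area)
    if best is None:
        raise NeckDetectionError("no cross-section found between parent and sac")
    point = foot + best[0] * normal
    mask = _connected_sac(grid, point, normal)
    return SacRegion(point, normal, mask)


def stav(flow, sac: SacRegion) -> float:
    """Space-and-time-averaged velocity magnitude in the sac (m/s).

    Averages |u| over all sac voxels and all exported instants (the
    export-instant ordering is immaterial to the mean).
    """
    if not sac.mask.any():
        raise ValueError("empty sac mask")
    if flow.n_instants < 1:
        raise ValueError("flow field has no exported instants")
    return flow.mean_speed(sac.mask)


def amvr(stav_pre: float, stav_fd: float) -> float:
    """Aneurysmal mean velocity reduction (dimensionless fraction ≤ 1)."""
    if stav_pre <= 0:
        raise ValueError("pretreatment STAV must be positive")
    value = (stav_pre - stav_fd) / stav_pre
    if value < 0:
        warnings.warn("treated STAV exceeds pretreatment STAV (negative AMVR)",
                      stacklevel=2)
    return value
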