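"""Parametric aneurysm geometries and voxelization.

Idealized sidewall geometries (spherical sac on a straight or gently curved
parent tube) stand in for patient anatomies: the downstream workflow only
needs a sac, a neck and a parent vessel with labeled openings. Parametric
shapes carry an analytic description (primitive list + ostium plane) in
``metadata`` so that voxelization and neck separation are exact; imported
watertight STL surfaces go through a generic ray-parity voxelizer.

Units are millimetres throughout this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import vtkio

__all__ = [
    "Opening",
    "SurfaceGeometry",
    "VoxelGrid",
    "make_sidewall_aneurysm",
    "extend_openings",
    "voxelize",
    "SOLID",
    "FLUID",
    "INLET",
    "OUTLET0",
]

# voxel labels; outlets are OUTLET0, OUTLET0 + 1, ...
SOLID = 0
FLUID = 1
INLET = 2
OUTLET0 = 3


class GeometryError(ValueError):
    pass


@dataclass
class Opening:
    """A capped vessel opening: planar cap with outward normal."""

    label: str  # "inlet" or "outlet_<i>"
    centroid: np.ndarray  # point on the cap plane (mm)
    normal: np.ndarray  # unit outward normal
    diameter: float  # mm

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if self.diameter <= 0:
            raise GeometryError("opening diameter must be positive")


@dataclass
class SurfaceGeometry:
    """Triangulated vessel (+ optional sac) surface with labeled openings.

    ``metadata`` may hold ``primitives`` (analytic solid description),
    ``ostium_plane`` (``{"point", "normal"}``, normal pointing from the
    parent lumen into the sac) and the generating parameters.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    openings: list
    metadata: dict = field(default_factory=dict)

    @property
    def is_parametric(self) -> bool:
        return "primitives" in self.metadata

    def opening(self, label: str) -> Opening:
        for o in self.openings:
            if o.label == label:
                return o
        raise KeyError(label)

    @property
    def inlet(self) -> Opening:
        return self.opening("inlet")

    @property
    def outlets(self) -> list:
        return [o for o in self.openings if o.label.startswith("outlet")]

    # ---------------------------------------------------------------- I/O
    def save(self, stl_path: str) -> None:
        """Write STL plus a ``<path>.openings.json`` sidecar with cap labels."""
        import trimesh

        mesh = trimesh.Trimesh(self.vertices, self.triangles, process=False)
        mesh.export(stl_path)
        side = {
            "openings": [
                {
                    "label": o.label,
                    "centroid": o.centroid.tolist(),
                    "normal": o.normal.tolist(),
                    "diameter": o.diameter,
                }
                for o in self.openings
            ],
            "metadata": _jsonable(self.metadata),
        }
        with open(str(stl_path) + ".openings.json", "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def load(cls, stl_path: str) -> "SurfaceGeometry":
        import trimesh

        mesh = trimesh.load(stl_path, force="mesh")
        try:
            with open(str(stl_path) + ".openings.json") as fh:
                side = json.load(fh)
        except FileNotFoundError:
            raise GeometryError(
                f"missing opening sidecar {stl_path}.openings.json; openings must be labeled"
            )
        openings = [
            Opening(o["label"], np.array(o["centroid"]), np.array(o["normal"]), o["diameter"])
            for o in side["openings"]
        ]
        md = side.get("metadata", {})
        for key in ("ostium_plane",):
            if key in md:
                md[key] = {k: np.asarray(v, float) for k, v in md[key].items()}
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), openings, md)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ------------------------------------------------------------------ solids


def _inside_primitive(prim: dict, pts: np.ndarray) -> np.ndarray:
    """Vectorized point-in-solid test for one analytic primitive."""
    kind = prim["type"]
    if kind == "cylinder":
        p0 = np.asarray(prim["p0"], float)
        p1 = np.asarray(prim["p1"], float)
        axis = p1 - p0
        length = np.linalg.norm(axis)
        axis = axis / length
        rel = pts - p0
        t = rel @ axis
        rad2 = np.einsum("ij,ij->i", rel, rel) - t * t
        return (t >= 0) & (t <= length) & (rad2 <= prim["radius"] ** 2)
    if kind == "sphere":
        c = np.asarray(prim["center"], float)
        rel = pts - c
        return np.einsum("ij,ij->i", rel, rel) <= prim["radius"] ** 2
    if kind == "arc_tube":
        # torus segment in the x-y plane around `center`
        c = np.asarray(prim["center"], float)
        rel = pts - c
        rho = np.hypot(rel[:, 0], rel[:, 1])
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        a0, a1 = prim["ang0"], prim["ang1"]
        # normalize angle into [a0, a0 + span)
        span = a1 - a0
        ang = np.mod(ang - a0, 2 * np.pi)
        dist2 = (rho - prim["bend_radius"]) ** 2 + rel[:, 2] ** 2
        return (ang <= span) & (dist2 <= prim["radius"] ** 2)
    raise GeometryError(f"unknown primitive type {kind!r}")


def _inside_union(primitives, pts: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(pts), dtype=bool)
    for prim in primitives:
        mask |= _inside_primitive(prim, pts)
    return mask


# ------------------------------------------------------------- mesh pieces


def _tube_mesh(path_pts: np.ndarray, radius: float, n_circ: int = 32):
    """Triangulated open tube along a polyline, with flat cap fans at both ends."""
    path_pts = np.asarray(path_pts, float)
    # orthonormal frames transported along the path
    tangents = np.gradient(path_pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    verts = []
    u = np.cross(tangents[0], ref)
    u /= np.linalg.norm(u)
    for p, t in zip(path_pts, tangents):
        u = u - (u @ t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ang = 2 * np.pi * np.arange(n_circ) / n_circ
        ring = p + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
        verts.append(ring)
    verts = np.concatenate(verts)
    faces = []
    n_ring = len(path_pts)
    for i in range(n_ring - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    # cap fans
    verts = np.vstack([verts, path_pts[0], path_pts[-1]])
    c0 = len(verts) - 2
    c1 = len(verts) - 1
    for j in range(n_circ):
        faces.append([c0, (j + 1) % n_circ, j])
        base = (n_ring - 1) * n_circ
        faces.append([c1, base + j, base + (j + 1) % n_circ])
    return verts, np.asarray(faces, dtype=np.int64)


def _icosphere(center, radius, subdivisions=3):
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return m.vertices + np.asarray(center, float), np.asarray(m.faces)


def _merge_meshes(parts):
    verts = []
    faces = []
    off = 0
    for v, f in parts:
        verts.append(v)
        faces.append(np.asarray(f) + off)
        off += len(v)
    return np.concatenate(verts), np.concatenate(faces)


# --------------------------------------------------------------- builders


def make_sidewall_aneurysm(
    parent_diameter: float,
    sac_diameter: float,
    neck_diameter: float,
    parent_length: float,
    bend_radius: float | None = None,
) -> SurfaceGeometry:
    """Build a sidewall aneurysm: spherical sac on a (possibly curved) tube.

    The sac is a sphere attached over a circular neck on top of the parent
    tube; the neck plane (the analytic ostium plane, tangent to the parent
    lumen, normal pointing into the sac) is stored in ``metadata``. With
    ``sac_diameter == neck_diameter == 0`` a plain straight tube is produced
    (useful for Poiseuille validation).

    Parameters are in mm. Raises :class:`GeometryError` for non-positive
    dimensions or ``neck_diameter > sac_diameter``.
    """
    if parent_diameter <= 0 or parent_length <= 0:
        raise GeometryError("parent diameter and length must be positive")
    has_sac = not (sac_diameter == 0 and neck_diameter == 0)
    if has_sac:
        if sac_diameter <= 0 or neck_diameter <= 0:
            raise GeometryError("sac and neck diameters must be positive (or both zero)")
        if neck_diameter > sac_diameter:
            raise GeometryError("neck diameter cannot exceed sac diameter")
    if bend_radius is not None and bend_radius <= parent_diameter:
        raise GeometryError("bend radius must exceed the parent diameter")

    rp = parent_diameter / 2.0
    L = parent_length
    prims = []
    parts = []

    if bend_radius is None:
        p0 = np.array([0.0, 0.0, 0.0])
        p1 = np.array([L, 0.0, 0.0])
        prims.append({"type": "cylinder", "p0": p0, "p1": p1, "radius": rp})
        n_axial = max(2, int(L / rp) + 1)
        path = np.linspace(p0, p1, n_axial)
        parts.append(_tube_mesh(path, rp))
        inlet = Opening("inlet", p0, [-1.0, 0.0, 0.0], parent_diameter)
        outlet = Opening("outlet_0", p1, [1.0, 0.0, 0.0], parent_diameter)
        mid = np.array([L / 2.0, 0.0, 0.0])
        sac_up = np.array([0.0, 0.0, 1.0])
    else:
        R = bend_radius
        span = L / R
        center = np.array([0.0, R, 0.0])
        prims.append(
            {
                "type": "arc_tube",
                "center": center,
                "bend_radius": R,
                "radius": rp,
                "ang0": -np.pi / 2.0,
                "ang1": -np.pi / 2.0 + span,
            }
        )
        angs = -np.pi / 2.0 + span * np.linspace(0, 1, max(8, int(L / rp) + 1))
        path = center + R * np.stack(
            [np.cos(angs), np.sin(angs), np.zeros_like(angs)], axis=1
        )
        parts.append(_tube_mesh(path, rp))
        a_in, a_out = angs[0], angs[-1]
        inlet = Opening(
            "inlet", center + R * np.array([np.cos(a_in), np.sin(a_in), 0.0]),
            [np.sin(a_in), -np.cos(a_in), 0.0], parent_diameter,
        )
        outlet = Opening(
            "outlet_0", center + R * np.array([np.cos(a_out), np.sin(a_out), 0.0]),
            [-np.sin(a_out), np.cos(a_out), 0.0], parent_diameter,
        )
        a_mid = -np.pi / 2.0 + span / 2.0
        mid = center + R * np.array([np.cos(a_mid), np.sin(a_mid), 0.0])
        sac_up = np.array([0.0, 0.0, 1.0])  # out of the bend plane

    metadata = {
        "parameters": {
            "parent_diameter": parent_diameter,
            "sac_diameter": sac_diameter,
            "neck_diameter": neck_diameter,
            "parent_length": parent_length,
            "bend_radius": bend_radius,
        },
        "parent_radius": rp,
        "parent_axis_point": mid,
        "parent_axis_dir": (outlet.centroid - inlet.centroid)
        / np.linalg.norm(outlet.centroid - inlet.centroid),
    }

    if has_sac:
        Rs = sac_diameter / 2.0
        rn = neck_diameter / 2.0
        # sphere center sits so the sphere cuts the tangent neck plane in a
        # circle of the requested neck diameter
        stand = np.sqrt(max(Rs * Rs - rn * rn, 0.0))
        neck_pt = mid + rp * sac_up
        center_s = neck_pt + stand * sac_up
        prims.append({"type": "sphere", "center": center_s, "radius": Rs})
        parts.append(_icosphere(center_s, Rs))
        metadata["ostium_plane"] = {"point": neck_pt, "normal": sac_up.copy()}
        metadata["sac_center"] = center_s
        metadata["sac_radius"] = Rs

    metadata["primitives"] = prims
    verts, faces = _merge_meshes(parts)
    return SurfaceGeometry(verts, faces, [inlet, outlet], metadata)


def extend_openings(g: SurfaceGeometry, n_diameters: float = 5) -> SurfaceGeometry:
    """Extrude every labeled opening outward by ``n_diameters`` local diameters.

    Inlet/outlet labels (and cap normals) are preserved; cap centroids move to
    the new end planes. Parametric geometries extend their analytic primitive
    list; imported meshes are extended by cap-face surgery.
    """
    if n_diameters < 0:
        raise GeometryError("n_diameters must be non-negative")
    if not g.openings:
        raise GeometryError("geometry has no labeled openings")
    if n_diameters == 0:
        return g

    new_openings = []
    if g.is_parametric:
        prims = list(g.metadata["primitives"])
        parts = [(g.vertices.copy(), g.triangles.copy())]
        for o in g.openings:
            ext = n_diameters * o.diameter
            p0 = o.centroid
            p1 = o.centroid + ext * o.normal
            prims.append({"type": "cylinder", "p0": p0, "p1": p1, "radius": o.diameter / 2.0})
            path = np.linspace(p0, p1, max(2, int(ext / o.diameter * 4)))
            parts.append(_tube_mesh(path, o.diameter / 2.0))
            new_openings.append(replace(o, centroid=p1))
        md = dict(g.metadata)
        md["primitives"] = prims
        md["extended_by"] = n_diameters
        verts, faces = _merge_meshes(parts)
        return SurfaceGeometry(verts, faces, new_openings, md)

    # mesh surgery for imported surfaces
    verts = [g.vertices.copy()]
    faces = np.asarray(g.triangles).copy()
    keep = np.ones(len(faces), dtype=bool)
    extra_faces = []
    n_verts = len(g.vertices)
    for o in g.openings:
        ext = n_diameters * o.diameter
        tri_pts = g.vertices[faces]
        cent = tri_pts.mean(axis=1)
        d = np.abs((cent - o.centroid) @ o.normal)
        e1 = tri_pts[:, 1] - tri_pts[:, 0]
        e2 = tri_pts[:, 2] - tri_pts[:, 0]
        fn = np.cross(e1, e2)
        fn /= np.maximum(np.linalg.norm(fn, axis=1), 1e-30)[:, None]
        cap = (d < 1e-6 * max(1.0, o.diameter) + 1e-9) | (
            (d < 0.05 * o.diameter) & (np.abs(fn @ o.normal) > 0.999)
        )
        if not cap.any():
            raise GeometryError(f"no cap faces found for opening {o.label}")
        rim = _boundary_loop(faces[~cap & keep] if False else faces, cap)
        keep &= ~cap
        rim_pts = g.vertices[rim]
        new_rim = rim_pts + ext * o.normal
        base = n_verts
        verts.append(new_rim)
        n_verts += len(new_rim)
        m = len(rim)
        for j in range(m):
            a, b = rim[j], rim[(j + 1) % m]
            c, dd = base + j, base + (j + 1) % m
            extra_faces.append([a, b, dd])
            extra_faces.append([a, dd, c])
        centroid_new = o.centroid + ext * o.normal
        verts.append(centroid_new[None, :])
        ci = n_verts
        n_verts += 1
        for j in range(m):
            extra_faces.append([ci, base + (j + 1) % m, base + j])
        new_openings.append(replace(o, centroid=centroid_new))
    all_faces = np.vstack([faces[keep]] + [np.asarray(extra_faces, dtype=np.int64)])
    md = dict(g.metadata)
    md["extended_by"] = n_diameters
    return SurfaceGeometry(np.concatenate(verts), all_faces, new_openings, md)


def _boundary_loop(faces, cap_mask):
    """Ordered vertex loop around the hole left by removing cap faces."""
    from collections import defaultdict

    edge_count = defaultdict(int)
    cap_edges = set()
    for f, is_cap in zip(faces, cap_mask):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] += 1
            if is_cap:
                cap_edges.add(key)
    # hole boundary: edges shared between one cap face and one kept face
    boundary = [e for e in cap_edges if edge_count[e] == 2]
    kept_edges = set()
    for f, is_cap in zip(faces, cap_mask):
        if is_cap:
            continue
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            kept_edges.add((min(a, b), max(a, b)))
    boundary = [e for e in boundary if e in kept_edges]
    adj = defaultdict(list)
    for a, b in boundary:
        adj[a].append(b)
        adj[b].append(a)
    start = boundary[0][0]
    loop = [start]
    prev = None
    cur = start
    while True:
        nxts = [v for v in adj[cur] if v != prev]
        if not nxts:
            break
        prev, cur = cur, nxts[0]
        if cur == start:
            break
        loop.append(cur)
    return np.asarray(loop, dtype=np.int64)


# -------------------------------------------------------------- voxel grid


@dataclass
class VoxelGrid:
    """Isotropic voxel labeling of the lumen.

    ``labels[ix, iy, iz]``: 0 solid, 1 fluid, 2 inlet cap, 3+i outlet caps.
    Voxel *centers* are at ``origin + (index + 0.5) * h``; indices are
    0-based half-open boxes. Cap voxels carry the boundary label, not fluid.
    """

    h: float  # mm
    origin: np.ndarray  # mm
    labels: np.ndarray  # int8 [nx, ny, nz]
    openings: list  # Opening objects, order: inlet first, then outlets

    @property
    def shape(self):
        return self.labels.shape

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.h

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def active_mask(self) -> np.ndarray:
        return self.labels > 0

    def fluid_volume(self) -> float:
        """Fluid volume in mm^3 (cap layers included)."""
        return float(np.count_nonzero(self.labels > 0)) * self.h**3

    def save_vtk(self, path: str) -> None:
        vtkio.write_structured_points(
            path, self.labels.astype(np.int32), self.h, self.origin, name="label"
        )


def voxelize(g: SurfaceGeometry, h: float) -> VoxelGrid:
    """Voxelize a closed surface at isotropic spacing ``h`` (mm).

    Parametric geometries are labeled from their analytic solid description;
    imported meshes must be watertight and are classified by ray parity.
    The fluid region is restricted to the 6-connected component containing
    the inlet; an opening left disconnected (too coarse an ``h``) is an error.
    """
    if h <= 0:
        raise GeometryError("voxel spacing h must be positive")
    lo = g.vertices.min(axis=0) - 1.5 * h
    hi = g.vertices.max(axis=0) + 1.5 * h
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    origin = lo

    if g.is_parametric:
        inside = np.zeros(tuple(shape), dtype=bool)
        xs = origin[0] + (np.arange(shape[0]) + 0.5) * h
        ys = origin[1] + (np.arange(shape[1]) + 0.5) * h
        zs = origin[2] + (np.arange(shape[2]) + 0.5) * h
        Y, Z = np.meshgrid(ys, zs, indexing="ij")
        plane = np.stack([np.zeros_like(Y), Y, Z], axis=-1).reshape(-1, 3)
        for ix, x in enumerate(xs):
            plane[:, 0] = x
            inside[ix] = _inside_union(g.metadata["primitives"], plane).reshape(
                shape[1], shape[2]
            )
    else:
        inside = _voxelize_mesh(g, h, origin, shape)

    labels = np.where(inside, FLUID, SOLID).astype(np.int8)

    if not g.openings:
        # closed solid with no vessel openings (e.g. validation spheres):
        # keep the largest connected component, nothing to cap
        comp, n_comp = ndimage.label(labels > 0)
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n_comp + 1))
            labels[comp != (1 + int(np.argmax(sizes)))] = SOLID
        return VoxelGrid(h=h, origin=origin, labels=labels, openings=[])

    # label cap layers (one voxel thick, measured along the outward normal)
    openings = sorted(g.openings, key=lambda o: (o.label != "inlet", o.label))
    if openings[0].label != "inlet":
        raise GeometryError("geometry must have an inlet opening")
    idx = np.argwhere(inside)
    centers = origin + (idx + 0.5) * h
    for k, o in enumerate(openings):
        s = (centers - o.centroid) @ o.normal
        # outermost populated single voxel layer (robust to grids whose
        # voxel centers align exactly with the cap plane)
        band = s > -1.5 * h
        if not band.any():
            raise GeometryError(f"opening {o.label} produced no cap voxels at h={h}")
        cap = s > s[band].max() - 0.5 * h
        if not cap.any():
            raise GeometryError(f"opening {o.label} produced no cap voxels at h={h}")
        lab = INLET if o.label == "inlet" else OUTLET0 + k - 1
        sel = idx[cap]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = lab

    # connectivity: keep the component containing the inlet
    comp, n_comp = ndimage.label(labels > 0)
    inlet_comps = np.unique(comp[labels == INLET])
    inlet_comps = inlet_comps[inlet_comps > 0]
    if len(inlet_comps) == 0:
        raise GeometryError("no inlet voxels after labeling")
    main = inlet_comps[0]
    for k, o in enumerate(openings):
        lab = INLET if o.label == "inlet" else OUTLET0 + k - 1
        cc = np.unique(comp[labels == lab])
        cc = cc[cc > 0]
        if main not in cc:
            raise GeometryError(
                f"opening {o.label} is not connected to the inlet at h={h} "
                f"(resolution too coarse or geometry split into {n_comp} parts)"
            )
    labels[comp != main] = SOLID
    return VoxelGrid(h=h, origin=origin, labels=labels, openings=openings)


def _voxelize_mesh(g: SurfaceGeometry, h, origin, shape):
    """Ray-parity inside test for watertight meshes, one +x ray per (y, z) row."""
    import trimesh

    mesh = trimesh.Trimesh(g.vertices, g.triangles, process=False)
    if not mesh.is_watertight:
        raise GeometryError("imported surface is not watertight; cannot voxelize")
    ny, nz = int(shape[1]), int(shape[2])
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    xs = origin[0] + (np.arange(int(shape[0])) + 0.5) * h
    # tiny deterministic shift keeps rays off triangle edges/vertices
    eps = 1.2345e-7 * h
    tri = g.vertices[np.asarray(g.triangles)]
    hits = [[] for _ in range(ny * nz)]
    for A, B, C in tri:
        y0 = min(A[1], B[1], C[1]) - eps
        y1 = max(A[1], B[1], C[1]) + eps
        z0 = min(A[2], B[2], C[2]) - eps
        z1 = max(A[2], B[2], C[2]) + eps
        j0, j1 = np.searchsorted(ys + eps, [y0, y1])
        k0, k1 = np.searchsorted(zs + eps, [z0, z1])
        if j0 == j1 or k0 == k1:
            continue
        Yg, Zg = np.meshgrid(ys[j0:j1] + eps, zs[k0:k1] + eps, indexing="ij")
        # 2D barycentric in the y-z plane
        d = (B[1] - A[1]) * (C[2] - A[2]) - (C[1] - A[1]) * (B[2] - A[2])
        if abs(d) < 1e-14:
            continue  # triangle parallel to the ray
        wa = ((B[1] - Yg) * (C[2] - Zg) - (C[1] - Yg) * (B[2] - Zg)) / d
        wb = ((C[1] - Yg) * (A[2] - Zg) - (A[1] - Yg) * (C[2] - Zg)) / d
        wc = 1.0 - wa - wb
        m = (wa >= 0) & (wb >= 0) & (wc >= 0)
        if not m.any():
            continue
        xhit = wa * A[0] + wb * B[0] + wc * C[0]
        for jj, kk in zip(*np.nonzero(m)):
            hits[(j0 + jj) * nz + (k0 + kk)].append(xhit[jj, kk])
    inside = np.zeros(tuple(shape), dtype=bool)
    for ri, hx in enumerate(hits):
        if not hx:
            continue
        hx = np.sort(np.asarray(hx))
        hx = hx[np.concatenate([[True], np.diff(hx) > 1e-9])]
        iy, iz = divmod(ri, nz)
        for a, b in zip(hx[0::2], hx[1::2]):
            inside[(xs > a) & (xs < b), iy, iz] = True
    return inside


def sac_mask(grid: VoxelGrid, plane_point, plane_normal) -> np.ndarray:
    """Boolean mask of active voxels on the sac side of an ostium plane."""
    active = grid.labels > 0
    idx = np.argwhere(active)
    centers = grid.origin + (idx + 0.5) * grid.h
    side = (centers - np.asarray(plane_point, float)) @ np.asarray(plane_normal, float) > 0
    mask = np.zeros(grid.shape, dtype=bool)
    sel = idx[side]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask
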