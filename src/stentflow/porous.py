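"""Homogeneous porous-layer representation of a deployed flow diverter.

A braided flow diverter is far below clinically attainable imaging and
meshing resolution (30 µm wires), so its effect on the flow is represented
as a thin homogeneous porous layer whose pressure drop follows the
Darcy-Forchheimer law

    Δp = l_c · v + q_c · v²

with a linear coefficient ``l_c`` [kg/m²s] and a quadratic coefficient
``q_c`` [kg/m³] obtained from bench pressure-drop measurements of deployed
devices. Inside a volumetric solver the areal law becomes a body-force
density ``f = −(l_c/t) u − (q_c/t) |u| u`` over a layer of thickness ``t``,
so that integrating the force across the layer recovers Δp.

The packaged ``hr_scenarios.csv`` fixture holds the sixteen measured
deployment scenarios (two devices × nominal/oversized, repeated insertions)
driving the study module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HRScenario",
    "load_hr_scenarios",
    "pressure_drop",
    "fit_hr_coefficients",
    "PorousLayerField",
    "map_stent_to_porous_voxels",
    "porous_slab_field",
]


@dataclass(frozen=True)
class HRScenario:
    """One measured deployment: device identity and its resistance pair."""

    scenario_id: int
    device: str  # "PED" | "P64"
    wire_count: int  # 48 | 64
    deployment: str  # "nominal" | "oversized"
    l_c: float  # kg/(m^2 s)
    q_c: float  # kg/m^3

    def __post_init__(self):
        if self.l_c < 0 or self.q_c < 0:
            raise ValueError("resistance coefficients must be non-negative")
        if self.deployment not in ("nominal", "oversized"):
            raise ValueError(f"unknown deployment {self.deployment!r}")


def load_hr_scenarios(path=None) -> pd.DataFrame:
    """Load the hydrodynamic-resistance scenario table.

    Defaults to the packaged fixture of the 16 measured deployment
    scenarios; a CSV with the same columns can be supplied instead.
    """
    if path is None:
        src = resources.files("stentflow.data").joinpath("hr_scenarios.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"scenario_id", "device", "wire_count", "deployment", "l_c", "q_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scenario table missing columns {sorted(missing)}")
    if df["scenario_id"].duplicated().any():
        raise ValueError("duplicate scenario ids")
    # validate every row through the dataclass invariants
    for row in df.itertuples(index=False):
        HRScenario(row.scenario_id, row.device, row.wire_count, row.deployment,
                   row.l_c, row.q_c)
    return df


def pressure_drop(l_c: float, q_c: float, v: float):
    """Darcy-Forchheimer pressure drop Δp = l_c v + q_c v² [Pa], v in m/s ≥ 0."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("superficial velocity must be non-negative")
    out = l_c * v + q_c * v * v
    return float(out) if out.ndim == 0 else out


def fit_hr_coefficients(samples) -> tuple:
    """Least-squares (l_c, q_c) from (v [m/s], Δp [Pa]) samples.

    Fits Δp = l_c v + q_c v² with no intercept. Coefficients are clipped at
    zero (with a warning) since negative resistance is unphysical.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (v, dp) samples")
    v, dp = arr[:, 0], arr[:, 1]
    if len(np.unique(v)) < 2 or np.all(v <= 0):
        raise ValueError("samples must span distinct positive velocities")
    A = np.stack([v, v * v], axis=1)
    coef, *_ = np.linalg.lstsq(A, dp, rcond=None)
    l_c, q_c = coef
    if l_c < 0 or q_c < 0:
        warnings.warn("negative fitted resistance clipped to 0", stacklevel=2)
        # refit the remaining coefficient with the other pinned at zero
        if l_c < 0 and q_c < 0:
            return 0.0, 0.0
        if l_c < 0:
            q_c = max(0.0, float(np.dot(dp, v * v) / np.dot(v * v, v * v)))
            return 0.0, q_c
        l_c = max(0.0, float(np.dot(dp, v) / np.dot(v, v)))
        return l_c, 0.0
    return float(l_c), float(q_c)


@dataclass
class PorousLayerField:
    """Porous voxel set with volumetric Darcy-Forchheimer coefficients.

    Per voxel, ``alpha = l_c · k`` [kg/(m³ s)] and ``beta = q_c · k``
    [kg/m⁴] enter the momentum equation as ``f = −alpha·u − beta·|u|·u``,
    where ``k`` [1/m] is a thin-layer kernel whose line integral across the
    layer is 1 — so integrating the force across the layer recovers the
    areal law Δp = l_c v + q_c v² regardless of the crossing direction.
    For a flat uniform slab ``k = 1/t_layer`` in every voxel; rasterized
    curved stent surfaces use a smooth (triangular) distance kernel, which
    avoids staircase artifacts in the local layer resistance.
    """

    voxels: np.ndarray  # (N, 3) int indices into the grid
    t_layer: float  # nominal layer (half-)thickness, mm
    l_c: float
    q_c: float
    kernel: np.ndarray = None  # (N,) 1/m; default uniform 1/t_layer

    def __post_init__(self):
        if self.kernel is None:
            self.kernel = np.full(len(self.voxels), 1.0 / (self.t_layer * 1e-3))

    @property
    def alphas(self) -> np.ndarray:
        return self.l_c * self.kernel

    @property
    def betas(self) -> np.ndarray:
        return self.q_c * self.kernel

    def with_coefficients(self, l_c: float, q_c: float) -> "PorousLayerField":
        """Same voxel set and kernel, different measured resistance pair."""
        return replace(self, l_c=l_c, q_c=q_c)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if len(self.voxels):
            m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return m


def map_stent_to_porous_voxels(stent, grid, t_layer: float,
                               l_c: float = 0.0, q_c: float = 0.0) -> PorousLayerField:
    """Rasterize a deployed stent surface into a diffuse porous voxel layer.

    Wire polylines are sampled at sub-voxel spacing; every fluid voxel
    within ``t_layer`` (mm) of the surface receives a triangular distance
    kernel weight ``k(d) = (1 − |d|/t) / t`` whose line integral across the
    layer is 1, so the areal resistance law is recovered independently of
    how the curved surface cuts the voxel grid. Deterministic: equal
    inputs give identical voxel sets and weights.
    """
    if t_layer <= 0:
        raise ValueError("t_layer must be positive")
    from scipy.spatial import cKDTree

    pts = stent.sample_surface_points(0.3 * grid.h)
    shape = np.asarray(grid.shape)
    ok = np.all((pts >= grid.origin) & (pts < grid.origin + shape * grid.h), axis=1)
    if not ok.any():
        raise ValueError("stent surface lies entirely outside the fluid region")
    tree = cKDTree(pts)
    fluid_idx = np.argwhere(grid.labels == 1)  # strictly fluid, not caps
    centers = grid.origin + (fluid_idx + 0.5) * grid.h
    # cheap prefilter: voxels inside the stent bounding box grown by t_layer
    lo = pts.min(axis=0) - t_layer - grid.h
    hi = pts.max(axis=0) + t_layer + grid.h
    near = np.all((centers >= lo) & (centers <= hi), axis=1)
    d = np.full(len(fluid_idx), np.inf)
    d[near] = tree.query(centers[near], workers=-1)[0]
    sel = d < t_layer
    if not sel.any():
        raise ValueError("stent surface lies entirely outside the fluid region")
    t_m = t_layer * 1e-3
    kernel = (1.0 - d[sel] / t_layer) / t_m
    return PorousLayerField(voxels=fluid_idx[sel], t_layer=t_layer,
                            l_c=l_c, q_c=q_c, kernel=kernel)


def porous_slab_field(grid, axis: int, position_mm: float, thickness_mm: float,
                      l_c: float, q_c: float) -> PorousLayerField:
    """Axis-aligned porous plug: all fluid voxels in a slab across the duct.

    Validation helper for the volumetric-conversion oracle (a channel fully
    blocked by a plug must reproduce the areal Darcy-Forchheimer law).
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    fluid = np.argwhere(grid.labels == 1)
    coord = grid.origin[axis] + (fluid[:, axis] + 0.5) * grid.h
    sel = (coord >= position_mm) & (coord < position_mm + thickness_mm)
    vox = fluid[sel]
    n_layers = max(1, int(round(thickness_mm / grid.h)))
    return PorousLayerField(voxels=vox, t_layer=n_layers * grid.h, l_c=l_c, q_c=q_c)
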