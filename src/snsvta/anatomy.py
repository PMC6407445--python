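"""Synthetic pelvic anatomy and contour-stack lofting.

The pipeline was designed around a segmentation product that cannot be
redistributed: a labelled voxel volume of the pelvic region (fat
background, sacrum with foramina, rectum) built from ~30 sagittal slices
of 3.9 mm thickness and 1.15 mm in-plane resolution.  This module
produces a parametric stand-in with the same ingredients:

* :func:`contours_to_volume` turns a stack of hand-drawn-style planar
  contours into a voxel solid by linear blending of per-slice signed
  distance fields (a reproducible analogue of a CAD "loft").
* :func:`make_synthetic_pelvis` builds the labelled volume directly from
  geometric primitives: a bone slab pierced by four foramen channels and
  a colon tube, embedded in fat.
* :func:`make_homogeneous` builds the matching single-tissue control.

Volumes carry a per-label conductivity table (S/m) used by the field
solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath
from scipy.ndimage import distance_transform_edt

from .labels import BONE, COLON, DEFAULT_CONDUCTIVITY, FAT

__all__ = [
    "GridSpec",
    "ContourStack",
    "TissueModel",
    "PelvisParams",
    "contours_to_volume",
    "make_synthetic_pelvis",
    "make_homogeneous",
    "save_tissue",
    "load_tissue",
    "save_contour_stack",
    "load_contour_stack",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid; voxel centre (i,j,k) sits at origin + (idx + 1/2) * voxel."""

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    shape: tuple[int, int, int]

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class ContourStack:
    """Closed planar polygons drawn on parallel slices.

    ``polygons[i]`` is the list of closed polygons ((n,2) arrays, mm, first
    vertex repeated last) on slice ``i``; slice ``i`` is centred at
    ``first_slice_position + i * slice_thickness`` along ``slice_axis``.
    """

    polygons: list[list[np.ndarray]]
    slice_thickness: float
    pixel_size: tuple[float, float]
    slice_axis: int = 2
    first_slice_position: float = 0.0

    def __post_init__(self):
        if len(self.polygons) == 0 or all(len(p) == 0 for p in self.polygons):
            raise ValueError("contour stack has no non-empty slice")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        for i, polys in enumerate(self.polygons):
            for j, poly in enumerate(polys):
                poly = np.asarray(poly, dtype=float)
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 4:
                    raise ValueError(f"slice {i} polygon {j}: need >=3 vertices, closed")
                if not np.allclose(poly[0], poly[-1]):
                    raise ValueError(f"slice {i} polygon {j} is not closed (first != last vertex)")
                if _self_intersects(poly):
                    raise ValueError(f"slice {i} polygon {j} is self-intersecting")
                self.polygons[i][j] = poly

    @property
    def slice_positions(self) -> np.ndarray:
        return self.first_slice_position + np.arange(len(self.polygons)) * self.slice_thickness


def _self_intersects(poly: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        return False
    return not Polygon(poly[:-1]).is_valid


@dataclass
class TissueModel:
    """Labelled voxel volume with per-label conductivity (S/m)."""

    label_grid: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    conductivity_table: dict[int, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label_grid must be 3-D")
        present = set(np.unique(self.label_grid).tolist())
        missing = present - set(self.conductivity_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from conductivity_table")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.origin), tuple(self.voxel_size), self.label_grid.shape)

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.label_grid.shape, self.voxel_size))

    def copy(self) -> "TissueModel":
        return TissueModel(
            self.label_grid.copy(),
            tuple(self.voxel_size),
            tuple(self.origin),
            dict(self.conductivity_table),
            dict(self.meta),
        )

    def sigma_grid(self) -> np.ndarray:
        """Per-voxel conductivity array (S/m); hardware labels map to 0."""
        sigma = np.zeros(self.label_grid.shape, dtype=np.float64)
        for label, s in self.conductivity_table.items():
            if s > 0:
                sigma[self.label_grid == label] = s
        return sigma


# ---------------------------------------------------------------------------
# contour lofting
# ---------------------------------------------------------------------------

def _slice_sdf(polys: list[np.ndarray], xs: np.ndarray, ys: np.ndarray,
               sampling: tuple[float, float]) -> np.ndarray:
    """Signed distance (negative inside) of the union of polygons on a 2-D grid."""
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = np.zeros(len(pts), dtype=bool)
    for poly in polys:
        inside |= MplPath(poly).contains_points(pts)
    inside = inside.reshape(xx.shape)
    if not inside.any():
        # empty slice: large positive distance everywhere
        return np.full(xx.shape, 1e6)
    if inside.all():
        return np.full(xx.shape, -1e6)
    d_in = distance_transform_edt(inside, sampling=sampling)
    d_out = distance_transform_edt(~inside, sampling=sampling)
    return d_out - d_in


def contours_to_volume(stack: ContourStack, grid: GridSpec) -> np.ndarray:
    """Loft a stack of planar contours into a binary voxel mask.

    Between slice centres the cross-section is obtained by linear
    interpolation of the per-slice signed distance fields; the solid
    extends half a slice thickness beyond the first and last slice, so a
    constant cross-section over ``n`` slices has thickness
    ``n * slice_thickness``.
    """
    ax = stack.slice_axis
    in_plane = [a for a in range(3) if a != ax]
    xs = grid.centers(in_plane[0])
    ys = grid.centers(in_plane[1])
    sampling = (grid.voxel_size[in_plane[0]], grid.voxel_size[in_plane[1]])

    sdfs = np.stack([_slice_sdf(p, xs, ys, sampling) for p in stack.polygons])
    zpos = stack.slice_positions
    zq = grid.centers(ax)

    mask2 = np.zeros((len(zq),) + sdfs.shape[1:], dtype=bool)
    half = stack.slice_thickness / 2.0
    lo, hi = zpos[0] - half, zpos[-1] + half
    for i, z in enumerate(zq):
        if z < lo or z > hi:
            continue
        if z <= zpos[0]:
            sdf = sdfs[0]
        elif z >= zpos[-1]:
            sdf = sdfs[-1]
        else:
            j = int(np.searchsorted(zpos, z) - 1)
            f = (z - zpos[j]) / (zpos[j + 1] - zpos[j])
            sdf = (1.0 - f) * sdfs[j] + f * sdfs[j + 1]
        mask2[i] = sdf < 0

    # move slice axis into place: mask2 is (z, p0, p1) with p0,p1 the in-plane axes
    order = np.argsort([ax, in_plane[0], in_plane[1]])
    return np.transpose(mask2, order)


# ---------------------------------------------------------------------------
# parametric pelvis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PelvisParams:
    """Geometry of the synthetic pelvic volume (all lengths in mm).

    Defaults echo the imaging product the model stands in for: an overall
    extent of roughly 150 x 150 x 120 mm at 1.15 mm isotropic voxels, a
    sacral slab whose thickness equals seven 3.9 mm slices, four foramen
    channels and a rectal tube.
    """

    extent_mm: tuple[float, float, float] = (150.0, 150.0, 120.0)
    voxel_mm: float = 1.15
    slab_x_mm: tuple[float, float] = (55.0, 82.3)      # 27.3 = 7 slices x 3.9 mm
    slab_y_mm: tuple[float, float] = (30.0, 120.0)
    slab_z_mm: tuple[float, float] = (25.0, 105.0)
    foramen_diameter_mm: float = 8.0
    foramen_z_mm: tuple[float, ...] = (85.0, 70.0, 55.0, 40.0)
    foramen_y_mm: float = 72.0
    position_jitter_mm: float = 1.0
    rectum_center_xy_mm: tuple[float, float] = (30.0, 75.0)
    rectum_radius_mm: float = 12.0
    rectum_wiggle_mm: float = 3.0


def _grid_for(extent, voxel) -> GridSpec:
    shape = tuple(int(round(e / voxel)) for e in extent)
    return GridSpec((0.0, 0.0, 0.0), (voxel, voxel, voxel), shape)


def make_synthetic_pelvis(params: PelvisParams | None = None, seed: int = 0) -> TissueModel:
    """Labelled fat/bone/colon volume with foramen channels; deterministic in seed.

    The seed perturbs the foramen centres and the rectal tube path by up
    to ``position_jitter_mm`` / ``rectum_wiggle_mm``, standing in for
    inter-subject variability.  Channel interiors revert to fat
    conductivity.  Foramen centres end up in ``meta['foramen_centers_mm']``
    so that a lead can be threaded through one of them.
    """
    p = params or PelvisParams()
    slab_w = min(p.slab_y_mm[1] - p.slab_y_mm[0], p.slab_z_mm[1] - p.slab_z_mm[0])
    if p.foramen_diameter_mm >= slab_w:
        raise ValueError(
            f"foramen diameter {p.foramen_diameter_mm} mm does not fit the "
            f"bone slab cross-section ({slab_w} mm)")
    rng = np.random.default_rng(seed)
    grid = _grid_for(p.extent_mm, p.voxel_mm)
    labels = np.full(grid.shape, FAT, dtype=np.int16)

    xc = grid.centers(0)[:, None, None]
    yc = grid.centers(1)[None, :, None]
    zc = grid.centers(2)[None, None, :]

    slab = ((xc >= p.slab_x_mm[0]) & (xc <= p.slab_x_mm[1])
            & (yc >= p.slab_y_mm[0]) & (yc <= p.slab_y_mm[1])
            & (zc >= p.slab_z_mm[0]) & (zc <= p.slab_z_mm[1]))
    labels[slab] = BONE

    jit = p.position_jitter_mm
    centers = []
    r_f = p.foramen_diameter_mm / 2.0
    for z0 in p.foramen_z_mm:
        y0 = p.foramen_y_mm + rng.uniform(-jit, jit)
        z1 = z0 + rng.uniform(-jit, jit)
        centers.append((float(y0), float(z1)))
        channel = slab & ((yc - y0) ** 2 + (zc - z1) ** 2 <= r_f ** 2)
        labels[channel] = FAT

    # rectal tube running along z, wiggling in the x-y plane
    phase = rng.uniform(0.0, 2.0 * np.pi)
    w = p.rectum_wiggle_mm
    zz = grid.centers(2)
    x_path = p.rectum_center_xy_mm[0] + w * np.sin(2 * np.pi * zz / p.extent_mm[2] + phase)
    y_path = p.rectum_center_xy_mm[1] + w * np.cos(2 * np.pi * zz / p.extent_mm[2] + phase)
    tube = ((xc - x_path[None, None, :]) ** 2
            + (yc - y_path[None, None, :]) ** 2) <= p.rectum_radius_mm ** 2
    labels[tube] = COLON

    meta = {
        "kind": "synthetic_pelvis",
        "seed": int(seed),
        "params": dataclasses.asdict(p),
        "foramen_centers_mm": centers,
    }
    return TissueModel(labels, (p.voxel_mm,) * 3, (0.0, 0.0, 0.0),
                       dict(DEFAULT_CONDUCTIVITY), meta)


def make_homogeneous(params: PelvisParams | None = None) -> TissueModel:
    """Single-tissue control volume: fat conductivity everywhere, same extent."""
    p = params or PelvisParams()
    grid = _grid_for(p.extent_mm, p.voxel_mm)
    labels = np.full(grid.shape, FAT, dtype=np.int16)
    meta = {"kind": "homogeneous", "params": dataclasses.asdict(p)}
    return TissueModel(labels, (p.voxel_mm,) * 3, (0.0, 0.0, 0.0),
                       {FAT: DEFAULT_CONDUCTIVITY[FAT]}, meta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_tissue(model: TissueModel, path: str | Path) -> None:
    """Write the label volume as NIfTI plus a YAML sidecar (conductivities, meta)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(model.voxel_size) + [1.0])
    affine[:3, 3] = np.asarray(model.origin) + 0.5 * np.asarray(model.voxel_size)
    nib.save(nib.Nifti1Image(model.label_grid.astype(np.int16), affine), str(path))
    sidecar = {
        "conductivity_s_per_m": {int(k): float(v) for k, v in model.conductivity_table.items()},
        "meta": _plainify(model.meta),
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def load_tissue(path: str | Path) -> TissueModel:
    import nibabel as nib

    img = nib.load(str(path))
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in (img.affine[:3, 3] - 0.5 * np.asarray(voxel)))
    sidecar = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    table = {int(k): float(v) for k, v in sidecar["conductivity_s_per_m"].items()}
    return TissueModel(np.asanyarray(img.dataobj).astype(np.int16), voxel, origin,
                       table, sidecar.get("meta", {}))


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_contour_stack(stack: ContourStack, path: str | Path) -> None:
    rows = []
    for i, polys in enumerate(stack.polygons):
        for j, poly in enumerate(polys):
            for x, y in poly:
                rows.append((i, j, x, y))
    pd.DataFrame(rows, columns=["slice_index", "polygon_id", "x", "y"]).to_csv(path, index=False)


def load_contour_stack(path: str | Path, slice_thickness: float,
                       pixel_size: tuple[float, float], **kw) -> ContourStack:
    df = pd.read_csv(path)
    n = int(df["slice_index"].max()) + 1
    polygons: list[list[np.ndarray]] = [[] for _ in range(n)]
    for (i, _j), g in df.groupby(["slice_index", "polygon_id"], sort=True):
        polygons[int(i)].append(g[["x", "y"]].to_numpy(float))
    return ContourStack(polygons, slice_thickness, pixel_size, **kw)
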