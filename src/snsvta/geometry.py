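"""Implanted hardware: quadripolar leads, pulse-generator cuboid, rasterisation.

Two commercial quadripolar leads are modelled (contact 0 is nearest the
tip):

* model 3093 — 1.27 mm diameter; contact lengths 3.0, 10.2, 3.0, 3.0 mm,
  1.5 mm inter-contact gaps;
* model 3889 — 1.27 mm diameter; four 3.0 mm contacts, 3.0 mm gaps.

The implanted pulse generator (IPG) is a 55 x 60 x 10 mm cuboid that
serves as the monopolar return.  Rasterisation labels voxels by a
voxel-centre-inside test: shaft voxels become insulator, contact bands
get per-contact labels, IPG voxels the IPG label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import TissueModel
from .labels import CONTACT0, INSULATOR, IPG

__all__ = [
    "ElectrodeSpec", "IpgSpec", "Placement",
    "make_electrode", "contact_extents", "rasterize_hardware",
    "ELECTRODE_MODELS", "DEFAULT_TIP_OFFSET_MM",
]

#: per-model (contact lengths mm, inter-contact gap mm)
ELECTRODE_MODELS: dict[int, tuple[list[float], float]] = {
    3093: ([3.0, 10.2, 3.0, 3.0], 1.5),
    3889: ([3.0, 3.0, 3.0, 3.0], 3.0),
}

#: distance from lead tip to the start of contact 0 (not published; configurable)
DEFAULT_TIP_OFFSET_MM = 1.5

LEAD_DIAMETER_MM = 1.27


@dataclass(frozen=True)
class ElectrodeSpec:
    """Quadripolar lead; contact offsets are measured from the start of contact 0."""

    model_id: int
    diameter: float
    contacts: tuple[tuple[float, float], ...]   # (offset, length) mm, tip-most first
    shaft_length: float

    def __post_init__(self):
        if len(self.contacts) != 4:
            raise ValueError("electrode must have exactly 4 contacts")
        prev_end = -1e-12
        for off, length in self.contacts:
            if off < prev_end - 1e-12:
                raise ValueError("contacts must be ordered and non-overlapping")
            prev_end = off + length
        if self.diameter <= 0 or self.shaft_length <= 0:
            raise ValueError("diameter and shaft_length must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class IpgSpec:
    """Implanted pulse generator modelled as an axis-aligned cuboid."""

    center: tuple[float, float, float]
    dimensions: tuple[float, float, float] = (55.0, 60.0, 10.0)

    def __post_init__(self):
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("IPG dimensions must be positive")


@dataclass(frozen=True)
class Placement:
    """Lead pose: tip position plus the unit vector from tip towards the proximal end."""

    tip_position: tuple[float, float, float]
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        a = np.asarray(self.axis_direction, float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector (|a| = 1 within 1e-9)")

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.axis_direction, float)

    @property
    def tip(self) -> np.ndarray:
        return np.asarray(self.tip_position, float)


def make_electrode(model_id: int, shaft_length: float = 28.0) -> ElectrodeSpec:
    """Build the spec for one of the supported lead models."""
    if model_id not in ELECTRODE_MODELS:
        valid = ", ".join(str(m) for m in sorted(ELECTRODE_MODELS))
        raise ValueError(f"unknown electrode model {model_id!r}; valid models: {valid}")
    lengths, gap = ELECTRODE_MODELS[model_id]
    contacts = []
    off = 0.0
    for L in lengths:
        contacts.append((off, L))
        off += L + gap
    return ElectrodeSpec(model_id, LEAD_DIAMETER_MM, tuple(contacts), shaft_length)


def contact_extents(spec: ElectrodeSpec, tip_offset: float = DEFAULT_TIP_OFFSET_MM
                    ) -> list[tuple[float, float]]:
    """(start, end) of each contact band, in mm along the axis from the tip."""
    if tip_offset < 0:
        raise ValueError("tip_offset must be >= 0")
    return [(tip_offset + off, tip_offset + off + L) for off, L in spec.contacts]


def _transverse_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (lateral, superior) frame for a lead axis."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(ref, axis)
    v /= np.linalg.norm(v)
    w = np.cross(axis, v)
    return v, w


def rasterize_hardware(tissue: TissueModel, electrode: ElectrodeSpec,
                       placement: Placement, ipg: IpgSpec | None = None,
                       tip_offset: float = DEFAULT_TIP_OFFSET_MM) -> TissueModel:
    """Label electrode shaft, contact bands and IPG voxels into a copy of ``tissue``.

    Voxel membership is decided by the voxel-centre-inside test (no
    partial-volume weighting), so band edges are correct to one voxel.
    """
    grid = tissue.grid
    ext = tissue.extent
    tip, axis = placement.tip, placement.axis

    ends = np.array([tip, tip + axis * electrode.shaft_length])
    r = electrode.radius
    for p in ends:
        if np.any(p - r < np.asarray(tissue.origin)) or \
           np.any(p + r > np.asarray(tissue.origin) + np.asarray(ext)):
            raise ValueError(f"electrode extends outside the tissue volume at {tuple(p)}")
    if ipg is not None:
        c = np.asarray(ipg.center, float)
        h = 0.5 * np.asarray(ipg.dimensions, float)
        if np.any(c - h < np.asarray(tissue.origin)) or \
           np.any(c + h > np.asarray(tissue.origin) + np.asarray(ext)):
            raise ValueError("IPG extends outside the tissue volume")

    out = tissue.copy()
    labels = out.label_grid

    # electrode: work on a bounding sub-box for speed
    lo = np.minimum(ends[0], ends[1]) - (r + 1.0)
    hi = np.maximum(ends[0], ends[1]) + (r + 1.0)
    sl, coords = _subbox(grid, lo, hi)
    pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)   # (..., 3)
    rel = pts - tip
    t_ax = rel @ axis
    rad2 = np.sum(rel * rel, axis=-1) - t_ax ** 2
    # a voxel belongs to the shaft if its centre is inside the cylinder, or if
    # the axis line passes through the voxel cube (the lead is thinner than a
    # voxel at coarse grids and must never rasterise to nothing)
    tv = rel - t_ax[..., None] * axis
    h = np.asarray(tissue.voxel_size, float)
    core = np.all(np.abs(tv) <= h / 2.0 + 1e-12, axis=-1)
    in_axial = (t_ax >= 0) & (t_ax <= electrode.shaft_length)
    in_shaft = in_axial & ((rad2 <= r ** 2 + 1e-12) | core)
    sub = labels[sl]
    sub[in_shaft] = INSULATOR
    for k, (a, b) in enumerate(contact_extents(electrode, tip_offset)):
        band = in_shaft & (t_ax >= a) & (t_ax < b)
        sub[band] = CONTACT0 + k
    labels[sl] = sub

    if ipg is not None:
        c = np.asarray(ipg.center, float)
        h = 0.5 * np.asarray(ipg.dimensions, float)
        sl, coords = _subbox(grid, c - h - 1.0, c + h + 1.0)
        pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
        inside = np.all((pts >= c - h) & (pts <= c + h), axis=-1)
        sub = labels[sl]
        sub[inside] = IPG
        labels[sl] = sub

    for lab in (INSULATOR, IPG, CONTACT0, CONTACT0 + 1, CONTACT0 + 2, CONTACT0 + 3):
        out.conductivity_table.setdefault(lab, 0.0)
    out.meta = dict(out.meta)
    out.meta["hardware"] = {
        "electrode_model": electrode.model_id,
        "tip_position_mm": [float(v) for v in tip],
        "axis_direction": [float(v) for v in axis],
        "tip_offset_mm": float(tip_offset),
        "ipg_center_mm": None if ipg is None else [float(v) for v in ipg.center],
    }
    return out


def _subbox(grid, lo, hi):
    sl = []
    coords = []
    for ax in range(3):
        c = grid.centers(ax)
        i0 = int(np.searchsorted(c, lo[ax]))
        i1 = int(np.searchsorted(c, hi[ax]))
        i0 = max(i0 - 1, 0)
        i1 = min(i1 + 1, grid.shape[ax])
        sl.append(slice(i0, i1))
        coords.append(c[i0:i1])
    return tuple(sl), coords
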