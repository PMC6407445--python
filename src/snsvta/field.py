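"""Quasi-static volume-conductor solver on the voxel grid.

The stimulation-induced potential obeys the Laplace problem
``div(sigma grad V) = 0`` with the tissue conductivities tabulated at the
stimulation frequency (purely resistive model).  Discretisation is a
7-point finite-volume stencil on the regular voxel grid with
harmonic-mean face conductances, which preserves the discrete maximum
principle.  Boundary conditions follow the constant-voltage convention:

* cathode contact voxels: Dirichlet at ``-amplitude`` volts;
* anode voxels (IPG in monopolar mode, a second contact in bipolar
  mode): Dirichlet at 0 V;
* electrode shaft, inactive contacts, inactive IPG and the outer
  boundary of the volume: zero-flux (insulating), implemented as zero
  face conductance.

The linear system is solved by diagonally preconditioned conjugate
gradients from a zero initial guess, so repeated solves are bit
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .anatomy import TissueModel
from .labels import IPG, contact_label

__all__ = [
    "Waveform", "StimConfig", "PotentialField",
    "solve_potential", "sample_potential", "isopotential_volume",
    "trace_field_lines", "activating_function",
    "field_to_vtk", "field_to_nifti",
]

#: conductivity assigned to driven (Dirichlet) metal voxels, S/m
METAL_SIGMA = 1.0


@dataclass(frozen=True)
class Waveform:
    """Monophasic square pulse train of the stimulator."""

    frequency_hz: float = 14.0
    pulse_width_ms: float = 0.21
    duration_ms: float = 1000.0
    shape: str = "monophasic_square"

    def __post_init__(self):
        if self.frequency_hz <= 0 or self.pulse_width_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("waveform timing values must be positive")
        if self.pulse_width_ms >= 1000.0 / self.frequency_hz:
            raise ValueError("pulse width must be shorter than the pulse period")
        if self.shape != "monophasic_square":
            raise ValueError(f"unsupported waveform shape {self.shape!r}")


@dataclass(frozen=True)
class StimConfig:
    """Contact assignment and drive for one stimulation setting.

    ``amplitude`` is in volts; the cathode is driven to ``-amplitude``
    with the anode as 0 V reference.  Monopolar mode returns through the
    IPG; bipolar mode through a second lead contact.
    """

    mode: str                         # 'monopolar' | 'bipolar'
    cathode_contact: int
    anode: int | str = "ipg"          # contact index, or 'ipg'
    amplitude: float = 1.0
    waveform: Waveform = dc_field(default_factory=Waveform)

    def __post_init__(self):
        if self.mode not in ("monopolar", "bipolar"):
            raise ValueError(f"mode must be 'monopolar' or 'bipolar', got {self.mode!r}")
        contact_label(self.cathode_contact)
        if self.mode == "monopolar":
            if self.anode != "ipg":
                raise ValueError("monopolar stimulation must return through the IPG")
        else:
            if not isinstance(self.anode, int):
                raise ValueError("bipolar stimulation needs a contact index as anode")
            contact_label(self.anode)
            if self.anode == self.cathode_contact:
                raise ValueError("bipolar anode must differ from the cathode")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def label(self) -> str:
        an = "ipg" if self.anode == "ipg" else f"c{self.anode}"
        return f"{self.mode}_c{self.cathode_contact}_{an}"


@dataclass
class PotentialField:
    """Solved scalar potential (volts) on the voxel grid at the configured drive."""

    values: np.ndarray
    valid_mask: np.ndarray            # True where the PDE was solved or Dirichlet
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    amplitude: float
    solver_info: dict = dc_field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


class SolverError(RuntimeError):
    pass


def _dirichlet_masks(tissue: TissueModel, stim: StimConfig):
    lg = tissue.label_grid
    cath = lg == contact_label(stim.cathode_contact)
    if stim.mode == "monopolar":
        an = lg == IPG
        what = "IPG"
    else:
        an = lg == contact_label(stim.anode)
        what = f"contact {stim.anode}"
    if not cath.any():
        raise SolverError(f"cathode contact {stim.cathode_contact} not present in the volume "
                          "(rasterise the hardware first)")
    if not an.any():
        raise SolverError(f"no anode in domain: {what} not present in the volume")
    return cath, an


def solve_potential(tissue: TissueModel, stim: StimConfig, tol: float = 1e-8,
                    maxiter: int = 50_000) -> PotentialField:
    """Solve the quasi-static potential for one contact configuration."""
    cath, an = _dirichlet_masks(tissue, stim)
    sigma = tissue.sigma_grid()
    sigma[cath | an] = METAL_SIGMA           # driven metal; links reduce to ~2*sigma_tissue
    dirich = cath | an
    vdir = np.zeros(sigma.shape)
    vdir[cath] = -stim.amplitude

    unknown = (sigma > 0) & ~dirich
    n = int(unknown.sum())
    if n == 0:
        raise SolverError("singular system: no free voxels to solve for")

    idx = np.full(sigma.shape, -1, dtype=np.int64)
    idx[unknown] = np.arange(n)

    h = np.asarray(tissue.voxel_size, float)
    vol = np.prod(h)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows, cols, vals = [], [], []

    for ax in range(3):
        slo = [slice(None)] * 3
        shi = [slice(None)] * 3
        slo[ax] = slice(None, -1)
        shi[ax] = slice(1, None)
        slo, shi = tuple(slo), tuple(shi)
        s1, s2 = sigma[slo], sigma[shi]
        both = (s1 > 0) & (s2 > 0)
        g = np.zeros(s1.shape)
        g[both] = (2.0 * s1[both] * s2[both] / (s1[both] + s2[both])) * (vol / h[ax] ** 2)

        i1, i2 = idx[slo], idx[shi]
        d1, d2 = dirich[slo], dirich[shi]

        uu = both & (i1 >= 0) & (i2 >= 0)
        a, b, w = i1[uu], i2[uu], g[uu]
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-w, -w])
        np.add.at(diag, a, w)
        np.add.at(diag, b, w)

        ud = both & (i1 >= 0) & d2
        np.add.at(diag, i1[ud], g[ud])
        np.add.at(rhs, i1[ud], g[ud] * vdir[shi][ud])
        du = both & d1 & (i2 >= 0)
        np.add.at(diag, i2[du], g[du])
        np.add.at(rhs, i2[du], g[du] * vdir[slo][du])

    if not np.any(diag > 0):
        raise SolverError("singular system: no Dirichlet voxel is coupled to the tissue")
    # voxels with zero diagonal are enclosed by insulation; pin them to 0 V
    isolated = diag == 0
    diag[isolated] = 1.0

    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    dinv = 1.0 / A.diagonal()
    M = LinearOperator((n, n), matvec=lambda x: dinv * x)
    iters = [0]

    def _cb(_xk):
        iters[0] += 1

    x, info = cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=_cb)
    if info != 0:
        raise SolverError(f"conjugate gradient failed to converge (info={info})")
    resid = float(np.linalg.norm(A @ x - rhs))
    rhs_norm = float(np.linalg.norm(rhs))

    slack = 1e-6 * max(stim.amplitude, 1.0)
    if x.min() < -stim.amplitude - slack or x.max() > slack:
        raise SolverError("discrete maximum principle violated: potential outside "
                          f"[{-stim.amplitude}, 0] (min {x.min():.3e}, max {x.max():.3e})")

    V = np.zeros(sigma.shape)
    V[unknown] = x
    V[dirich] = vdir[dirich]
    valid = unknown | dirich
    V = _fill_invalid(V, valid)

    return PotentialField(
        V, valid, tuple(tissue.voxel_size), tuple(tissue.origin), stim.amplitude,
        solver_info={"iterations": iters[0], "residual": resid, "rhs_norm": rhs_norm,
                     "rel_residual": resid / rhs_norm if rhs_norm else 0.0,
                     "n_unknowns": n, "stim": stim.label},
    )


def _fill_invalid(V: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill non-solved (hardware) voxels with neighbour averages.

    Values inside hardware are physically meaningless; filling them keeps
    trilinear interpolation well behaved for sample points adjacent to
    the lead surface.
    """
    V = V.copy()
    filled = valid.copy()
    while not filled.all():
        num = np.zeros(V.shape)
        den = np.zeros(V.shape)
        for ax in range(3):
            for d in (-1, 1):
                src_val = np.roll(np.where(filled, V, 0.0), d, axis=ax)
                src_ok = np.roll(filled, d, axis=ax)
                # roll wraps around; zero out the wrapped plane
                edge = [slice(None)] * 3
                edge[ax] = 0 if d == 1 else -1
                src_ok = src_ok.copy()
                src_ok[tuple(edge)] = False
                num += np.where(src_ok, src_val, 0.0)
                den += src_ok
        grow = ~filled & (den > 0)
        if not grow.any():
            break
        V[grow] = num[grow] / den[grow]
        filled |= grow
    return V


# ---------------------------------------------------------------------------
# field utilities
# ---------------------------------------------------------------------------

def _fractional_index(field: PotentialField, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    f = (pts - np.asarray(field.origin)) / np.asarray(field.voxel_size) - 0.5
    shape = np.asarray(field.values.shape)
    bad = np.any((f < 0) | (f > shape - 1), axis=1)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"point {i} at {tuple(pts[i])} is outside the field grid")
    return f


def sample_potential(field: PotentialField, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the potential (volts) at mm-coordinates."""
    f = _fractional_index(field, points)
    return map_coordinates(field.values, f.T, order=1, mode="nearest")


def isopotential_volume(field: PotentialField, level: float) -> float:
    """Volume (mm^3) of tissue at or below ``level`` volts (cathodic convention)."""
    if level > 0:
        raise ValueError("isopotential level must be <= 0 for cathodic stimulation")
    return float(np.count_nonzero((field.values <= level) & field.valid_mask)
                 * field.voxel_volume)


def trace_field_lines(field: PotentialField, seeds: np.ndarray,
                      step_mm: float | None = None, max_length_mm: float = 400.0
                      ) -> list[np.ndarray]:
    """Streamlines from cathode seeds towards the anode (direction of +grad V).

    Fixed-step integration; a line terminates when it leaves the grid,
    reaches a zero-gradient voxel, or exceeds ``max_length_mm``.
    """
    h = np.asarray(field.voxel_size)
    if step_mm is None:
        step_mm = 0.5 * float(h.min())
    grads = np.gradient(field.values, *field.voxel_size)

    def grad_at(p):
        f = _fractional_index(field, p[None, :])
        return np.array([map_coordinates(g, f.T, order=1, mode="nearest")[0] for g in grads])

    lines = []
    for seed in np.atleast_2d(np.asarray(seeds, float)):
        pts = [seed.copy()]
        p = seed.copy()
        travelled = 0.0
        while travelled < max_length_mm:
            try:
                g = grad_at(p)
            except ValueError:
                break
            norm = np.linalg.norm(g)
            if norm < 1e-12:
                break
            p = p + step_mm * g / norm
            lo = np.asarray(field.origin) + 0.5 * h
            hi = np.asarray(field.origin) + (np.asarray(field.values.shape) - 0.5) * h
            if np.any(p < lo) or np.any(p > hi):
                break
            pts.append(p.copy())
            travelled += step_mm
        lines.append(np.array(pts))
    return lines


def activating_function(field: PotentialField, axon_path: np.ndarray,
                        spacing_mm: float | None = None) -> np.ndarray:
    """Second spatial difference of the extracellular potential along a fibre.

    ``delta2 V[i] = V[i-1] - 2 V[i] + V[i+1]`` (volts) for the interior
    sample points; positive values predict membrane depolarisation.
    """
    pts = np.asarray(axon_path, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("activating function needs at least 3 sample points")
    v = sample_potential(field, pts)
    return v[:-2] - 2.0 * v[1:-1] + v[2:]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def field_to_nifti(field: PotentialField, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(field.voxel_size) + [1.0])
    affine[:3, 3] = np.asarray(field.origin) + 0.5 * np.asarray(field.voxel_size)
    nib.save(nib.Nifti1Image(field.values.astype(np.float32), affine), str(path))


def field_to_vtk(field: PotentialField, path: str | Path) -> None:
    """Write the potential as a legacy ASCII VTK structured-points dataset."""
    v = field.values
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stimulation potential (V)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {v.shape[0]} {v.shape[1]} {v.shape[2]}\n")
        ori = np.asarray(field.origin) + 0.5 * np.asarray(field.voxel_size)
        fh.write(f"ORIGIN {ori[0]} {ori[1]} {ori[2]}\n")
        fh.write(f"SPACING {field.voxel_size[0]} {field.voxel_size[1]} {field.voxel_size[2]}\n")
        fh.write(f"POINT_DATA {v.size}\n")
        fh.write("SCALARS potential float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, v.ravel(order="F")[:, None], fmt="%.6e")
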