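"""Electric and weighting potentials on the detector grid.

The electric potential obeys Gauss's law with the space charge taken as
negligible, so both the electric potential phi and the weighting potential
phi_k of the Shockley--Ramo theorem reduce to Laplace problems that differ
only in their boundary values.  Three alternatives are provided for the
electric potential (A1 uniform field, A2 Laplace solution with
zero-normal-gradient gaps, A3 a convex combination of the two) and two for
the weighting potential (B1 zero-normal-gradient gaps, B2 Dirichlet gap
values from an inverse-distance-weighted transition whose steepness and
zero-crossing position are tunable).

Discretisation is a seven-point finite-difference Laplacian on the node
lattice; homogeneous Neumann faces are realised with mirror ghost nodes.
Systems are solved with a loose GMRES iteration, with a direct sparse
factorisation used below 40k unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Grid3D, CrystalSpec, LABEL_ANODE, LABEL_CATHODE

__all__ = ["ScalarField", "FieldConfig", "SolverError",
           "solve_electric_potential", "solve_weighting_potential",
           "gradient"]

#: Relative residual for the iterative linear solver.
SOLVER_RTOL = 1e-8
#: Below this many unknowns a direct sparse factorisation is used instead.
DIRECT_SOLVE_LIMIT = 40_000


class SolverError(RuntimeError):
    """Linear solve failed; carries the relative residual reached."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class ScalarField:
    """Scalar nodal values on a grid (volts for phi, dimensionless for
    phi_k and the CIE)."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match the grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass(frozen=True)
class FieldConfig:
    """Boundary-condition alternatives for the potential solves.

    ``a3_weight`` is used only by A3 (weight of the uniform-field solution);
    ``b2_power`` and ``b2_scale`` only by B2 (inverse-distance steepness and
    fractional gap position where the weighting potential reaches zero).
    """

    electric_alternative: str = "A1"   # {A1, A2, A3}
    a3_weight: float = 0.5
    weighting_alternative: str = "B1"  # {B1, B2}
    b2_power: float = 2.0
    b2_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.electric_alternative not in ("A1", "A2", "A3"):
            raise ValueError("electric_alternative must be A1, A2 or A3")
        if self.weighting_alternative not in ("B1", "B2"):
            raise ValueError("weighting_alternative must be B1 or B2")
        if not 0.0 <= self.a3_weight <= 1.0:
            raise ValueError("a3_weight must be in [0, 1]")
        if self.b2_power <= 0:
            raise ValueError("b2_power must be > 0")
        if not 0.0 < self.b2_scale <= 1.0:
            raise ValueError("b2_scale must be in (0, 1]")


def _laplace_matrix(grid: Grid3D, dirichlet: np.ndarray) -> sp.csr_matrix:
    """Seven-point Laplacian with mirror-Neumann faces.

    Every node on a box face that is not Dirichlet gets a mirrored ghost
    neighbour, which realises a homogeneous Neumann condition there (this
    covers the inter-anode gaps, the lateral outer boundary and the cut
    faces of a symmetry-reduced grid).  Dirichlet rows are identity.
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    steps = (grid.step, grid.step, grid.step_z)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    free = ~dirichlet.ravel()
    for axis in range(3):
        size = grid.shape[axis]
        if size < 2:
            continue
        h2 = steps[axis] ** 2
        for side in (+1, -1):
            nb = np.roll(idx, -side, axis=axis)
            # On the face where the neighbour is missing, mirror to the
            # opposite neighbour.
            face = [slice(None)] * 3
            face[axis] = -1 if side == +1 else 0
            opp = np.roll(idx, side, axis=axis)
            nb = nb.copy()
            nb[tuple(face)] = opp[tuple(face)]
            r = idx.ravel()[free]
            c = nb.ravel()[free]
            rows.append(r)
            cols.append(c)
            vals.append(np.full(r.size, 1.0 / h2))
            diag[r] -= 1.0 / h2

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    one = np.ones(n)
    vals.append(np.where(free, diag[np.arange(n)], one))
    # Dirichlet rows: identity (diag contribution already zero there).
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return A


def solve_linear(A: sp.csr_matrix, b: np.ndarray,
                 rtol: float = SOLVER_RTOL) -> np.ndarray:
    """Solve A x = b; direct below DIRECT_SOLVE_LIMIT unknowns, loose GMRES
    (lgmres with an incomplete-LU preconditioner) above."""
    n = b.size
    if n <= DIRECT_SOLVE_LIMIT:
        x = spla.spsolve(A.tocsc(), b)
    else:
        ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=15)
        M = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.lgmres(A, b, M=M, rtol=rtol, atol=0.0, maxiter=2000)
        if info != 0:
            res = float(np.linalg.norm(A @ x - b) /
                        max(np.linalg.norm(b), 1e-300))
            raise SolverError(f"lgmres did not converge (info={info})", res)
    bnorm = np.linalg.norm(b)
    res = float(np.linalg.norm(A @ x - b) / max(bnorm, 1e-300))
    if not np.all(np.isfinite(x)) or res > 1e-6:
        raise SolverError("linear solve failed", res)
    return x


def _solve_laplace(grid: Grid3D, dirichlet: np.ndarray,
                   values: np.ndarray) -> np.ndarray:
    A = _laplace_matrix(grid, dirichlet)
    b = np.where(dirichlet.ravel(), values.ravel(), 0.0)
    x = solve_linear(A, b).reshape(grid.shape)
    x[dirichlet] = values[dirichlet]  # exact electrode values
    return x


def solve_electric_potential(grid: Grid3D, crystal: CrystalSpec,
                             cfg: FieldConfig) -> ScalarField:
    """Electric potential phi on the grid.

    The cathode (z = 0) is held at ``-bias_voltage`` and the anode pads at
    0 V, so the field drives electrons toward the anode plane.  A1 is the
    uniform-field (linear-in-depth) solution, A2 the Laplace solution with
    zero-normal-gradient inter-anode gaps and lateral faces, A3 the convex
    combination ``a3_weight * A1 + (1 - a3_weight) * A2``.
    """
    zz = grid.z[np.newaxis, np.newaxis, :]
    L = grid.thickness
    phi_a1 = np.broadcast_to(
        -crystal.bias_voltage * (1.0 - zz / L), grid.shape).copy()
    if cfg.electric_alternative == "A1":
        return ScalarField(grid, phi_a1)

    lab = grid.labels
    dirichlet = (lab == LABEL_CATHODE) | (lab == LABEL_ANODE)
    vals = np.zeros(grid.shape)
    vals[lab == LABEL_CATHODE] = -crystal.bias_voltage
    phi_a2 = _solve_laplace(grid, dirichlet, vals)
    if cfg.electric_alternative == "A2":
        return ScalarField(grid, phi_a2)
    w = cfg.a3_weight
    return ScalarField(grid, w * phi_a1 + (1.0 - w) * phi_a2)


def _pad_rect_distance(px: np.ndarray, py: np.ndarray,
                       centre: np.ndarray, half_pad: float) -> np.ndarray:
    dx = np.maximum(np.abs(px - centre[0]) - half_pad, 0.0)
    dy = np.maximum(np.abs(py - centre[1]) - half_pad, 0.0)
    return np.hypot(dx, dy)


def _b2_gap_values(grid: Grid3D, anode_k: int, pad_size: float,
                   power: float, scale: float) -> np.ndarray:
    """Dirichlet weighting-potential values on anode-plane gap nodes.

    Inverse-distance transition between the selected pad's edge (value 1)
    and the nearest other pad edge (value 0):
    ``v = (1-u)^p / (u^p + (1-u)^p)`` with ``u = t / scale`` (clamped),
    where ``t`` is the fractional position along the gap measured from the
    selected pad's edge.  ``power`` sets the steepness and ``scale`` the
    fraction of the gap at which the potential reaches zero.
    """
    gap = grid.pad_id < 0
    gx, gy = np.nonzero(gap)
    px = grid.x[gx]
    py = grid.y[gy]
    half_pad = pad_size / 2.0

    d_k = _pad_rect_distance(px, py, grid.pad_centres[anode_k], half_pad)
    d_other = np.full(px.shape, np.inf)
    for j, centre in enumerate(grid.pad_centres):
        if j == anode_k:
            continue
        d_other = np.minimum(
            d_other, _pad_rect_distance(px, py, centre, half_pad))
    # On a reduced grid a lone pad may remain; fall back to the domain edge.
    if not np.all(np.isfinite(d_other)):
        edge = np.minimum(grid.x[-1] - px, grid.y[-1] - py)
        d_other = np.where(np.isfinite(d_other), d_other, np.maximum(edge, 0))

    t = d_k / np.maximum(d_k + d_other, 1e-300)
    u = np.clip(t / scale, 0.0, 1.0)
    v = (1.0 - u) ** power / ((1.0 - u) ** power + u ** power + 1e-300)
    v[u >= 1.0] = 0.0

    out = np.zeros(grid.pad_id.shape)
    out[gx, gy] = v
    return out


def solve_weighting_potential(grid: Grid3D, anode_k: int | str,
                              cfg: FieldConfig,
                              pad_size: float | None = None) -> ScalarField:
    """Weighting potential phi_k: electrode k at unity, all others at zero.

    ``anode_k`` is a flat neighbourhood pad index, or the string
    ``"cathode"`` to obtain the cathode's weighting potential (used by the
    partition-of-unity check).  B1 applies zero-normal-gradient on the
    inter-anode gaps; B2 prescribes Dirichlet gap values from the
    inverse-distance transition (``pad_size`` defaults to the value implied
    by the grid's pad labelling and is needed only for B2).
    """
    lab = grid.labels
    vals = np.zeros(grid.shape)
    dirichlet = (lab == LABEL_CATHODE) | (lab == LABEL_ANODE)

    if anode_k == "cathode":
        vals[lab == LABEL_CATHODE] = 1.0
    else:
        anode_k = int(anode_k)
        if not 0 <= anode_k < len(grid.pad_centres):
            raise ValueError(f"anode index {anode_k} outside neighbourhood")
        sel = np.zeros(grid.shape, dtype=bool)
        sel[:, :, -1] = grid.pad_id == anode_k
        vals[sel] = 1.0

    if cfg.weighting_alternative == "B2" and anode_k != "cathode":
        if pad_size is None:
            # Infer the pad half-width from the labelled central pad.
            k = grid.central_pad()
            on = np.nonzero(grid.pad_id == k)
            pad_size = 2.0 * float(
                np.max(np.abs(grid.x[on[0]] - grid.pad_centres[k][0])))
        gap_vals = _b2_gap_values(grid, anode_k, pad_size,
                                  cfg.b2_power, cfg.b2_scale)
        gapmask = np.zeros(grid.shape, dtype=bool)
        gapmask[:, :, -1] = grid.pad_id < 0
        vals[:, :, -1] = np.where(grid.pad_id < 0, gap_vals, vals[:, :, -1])
        dirichlet = dirichlet | gapmask

    phi_k = _solve_laplace(grid, dirichlet, vals)
    lo, hi = phi_k.min(), phi_k.max()
    if lo < -1e-8 or hi > 1 + 1e-8:
        raise SolverError(
            f"weighting potential outside [0, 1]: [{lo:.3g}, {hi:.3g}]")
    return ScalarField(grid, np.clip(phi_k, 0.0, 1.0))


def gradient(fld: ScalarField) -> np.ndarray:
    """Nodal gradient, shape ``(3, nx, ny, nz)``.

    Central differences in the interior (second order, exact for
    quadratics), one-sided at the boundaries.  Units are V/mm for phi and
    1/mm for phi_k.
    """
    grid = fld.grid
    out = np.zeros((3,) + grid.shape)
    axes = (grid.x, grid.y, grid.z)
    for a in range(3):
        if grid.shape[a] >= 2:
            out[a] = np.gradient(fld.values, axes[a], axis=a)
    return out
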