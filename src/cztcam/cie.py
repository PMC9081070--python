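"""Charge-induction-efficiency (CIE) maps.

The CIE eta(r) is the fraction of the ideal signal that a point charge
created at r induces on the selected anode before trapping removes it.
Computing it by drifting a charge cloud from every starting position is
expensive; instead the steady-state adjoint drift--diffusion equation

    0 = -/+ mu grad(phi) . grad(x+) + div(D grad x+) + G+ - x+/tau,
    G+ = mu grad(phi) . grad(phi_k),

(advection sign positive for electrons, negative for holes) is solved once,
and its solution x+(r) equals eta(r) for every starting position
simultaneously.  A brute-force oracle that explicitly time-steps the
forward charge-cloud equation and accumulates the Shockley--Ramo integral
is provided for cross-checking, together with the Hecht closed form for the
parallel-plate limit.

Internal units: mm, V, microseconds.  Carrier parameters are stored in the
customary cm^2/(V s) and cm^2/s and converted on use.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, asdict, field

import numpy as np
import scipy.sparse as sp

from .geometry import (
    Grid3D, CrystalSpec, AnodeArraySpec,
    LABEL_ANODE, LABEL_CATHODE,
    build_grid, symmetry_reduce,
)
from .fields import (
    ScalarField, FieldConfig, SolverError, gradient,
    solve_electric_potential, solve_weighting_potential, solve_linear,
)

__all__ = [
    "CarrierParams", "CIEMap", "CIEFormatError",
    "adjoint_source", "solve_adjoint_cie", "direct_cie_oracle", "hecht_cie",
    "combine_components", "compute_cie_map", "write_cie", "read_cie",
]

#: Thermal voltage kT/q at 293 K, used by the Einstein relation.
THERMAL_VOLTAGE_293K = 0.02525  # V

#: Negative adjoint values are clamped to zero when forming the CIE map
#: (net induction on the selected anode is negative for charges collected
#: on neighbouring pads); values below -NEG_FAILURE indicate a scheme
#: failure rather than a physical induction lobe.
NEG_FAILURE = 0.5


@dataclass(frozen=True)
class CarrierParams:
    """Transport parameters of one carrier species.

    ``mobility`` in cm^2/(V s), ``lifetime`` in microseconds.  The
    diffusion constant (cm^2/s) defaults to the Einstein relation
    ``D = mu * kT/q`` at 293 K; pass ``diffusion=0.0`` to disable diffusion
    (used by the Hecht consistency checks).
    """

    mobility: float
    lifetime: float
    carrier: str = "electron"    # {electron, hole}
    diffusion: float | None = None

    def __post_init__(self) -> None:
        if self.mobility <= 0 or self.lifetime <= 0:
            raise ValueError("mobility and lifetime must be > 0")
        if self.carrier not in ("electron", "hole"):
            raise ValueError("carrier must be 'electron' or 'hole'")
        if self.diffusion is not None and self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")

    @property
    def diffusion_cm2_s(self) -> float:
        if self.diffusion is not None:
            return self.diffusion
        return self.mobility * THERMAL_VOLTAGE_293K

    # Internal-unit conversions (mm, V, us).
    @property
    def mu_mm2_V_us(self) -> float:
        return self.mobility * 1e-4

    @property
    def d_mm2_us(self) -> float:
        return self.diffusion_cm2_s * 1e-4

    @property
    def advection_sign(self) -> float:
        """Sign of the adjoint advection term (+ electrons, - holes)."""
        return 1.0 if self.carrier == "electron" else -1.0

    @property
    def drift_sign(self) -> float:
        """Sign of the physical drift velocity ``sign * mu * grad(phi)``."""
        return 1.0 if self.carrier == "electron" else -1.0


ELECTRON_DEFAULT = CarrierParams(mobility=1000.0, lifetime=3.0,
                                 carrier="electron")
HOLE_DEFAULT = CarrierParams(mobility=80.0, lifetime=0.5, carrier="hole")


def adjoint_source(grid: Grid3D, e_grad: np.ndarray, w_grad: np.ndarray,
                   carrier: CarrierParams) -> ScalarField:
    """Adjoint generation term G+ = mu grad(phi) . grad(phi_k), in 1/us."""
    if e_grad.shape != w_grad.shape or e_grad.shape != (3,) + grid.shape:
        raise ValueError("gradient arrays do not match the grid")
    g = carrier.mu_mm2_V_us * np.einsum("a...,a...->...", e_grad, w_grad)
    return ScalarField(grid, g)


def _electrode_dirichlet(grid: Grid3D, carrier: CarrierParams,
                         diffusive: bool) -> np.ndarray:
    """Nodes where x+ = 0 is imposed.

    The collecting electrode of the carrier (anode pads for electrons,
    cathode for holes) always absorbs.  With diffusion active the zero
    condition is applied on all ohmic electrode surfaces; without diffusion
    the pure-advection problem admits no condition on the adjoint outflow
    electrode, and imposing one there would contradict the Hecht limit.
    """
    lab = grid.labels
    if carrier.carrier == "electron":
        d = lab == LABEL_ANODE
        if diffusive:
            d = d | (lab == LABEL_CATHODE)
    else:
        d = lab == LABEL_CATHODE
        if diffusive:
            d = d | (lab == LABEL_ANODE)
    return d


def _neumann_laplacian_entries(grid: Grid3D, free: np.ndarray):
    """COO entries of the mirror-Neumann Laplacian restricted to free rows."""
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    steps = (grid.step, grid.step, grid.step_z)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        if grid.shape[axis] < 2:
            continue
        h2 = steps[axis] ** 2
        for side in (+1, -1):
            nb = np.roll(idx, -side, axis=axis).copy()
            face = [slice(None)] * 3
            face[axis] = -1 if side == +1 else 0
            nb[tuple(face)] = np.roll(idx, side, axis=axis)[tuple(face)]
            r = idx.ravel()[free]
            rows.append(r)
            cols.append(nb.ravel()[free])
            vals.append(np.full(r.size, 1.0 / h2))
            diag[r] -= 1.0 / h2
    return rows, cols, vals, diag


def _has_neighbour_masks(grid: Grid3D, axis: int):
    has_plus = np.ones(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = -1
    has_plus[tuple(sl)] = False
    has_minus = np.ones(grid.shape, dtype=bool)
    sl[axis] = 0
    has_minus[tuple(sl)] = False
    return has_plus, has_minus


def _advection_and_source(grid: Grid3D, e_grad: np.ndarray,
                          w_grad: np.ndarray, carrier: CarrierParams):
    """Upwind advection coefficients and the scheme-consistent source.

    The nominal source is G+ = mu grad(phi) . grad(phi_k).  Where the drift
    pushes charge into an insulating surface (the upwind neighbour is
    missing), the scheme blocks the flux and the charge parks; a parked
    charge induces nothing, so the corresponding component of the source
    is zeroed.  Without this the idealised uniform-field alternative,
    whose field does not respect the insulating gaps, accumulates a
    spurious lifetime-limited induction tau*G+ in the gap columns.  The
    same masked source is used by the direct time-stepping oracle, keeping
    the two discretisations exact transposes of one another.
    """
    mu = carrier.mu_mm2_V_us
    c = carrier.advection_sign * mu * e_grad   # adjoint advection, mm/us
    g_eff = np.zeros(grid.shape)
    for axis in range(3):
        if grid.shape[axis] < 2:
            continue
        has_plus, has_minus = _has_neighbour_masks(grid, axis)
        blocked = ((c[axis] > 0) & ~has_plus) | ((c[axis] < 0) & ~has_minus)
        term = mu * e_grad[axis] * w_grad[axis]
        g_eff += np.where(blocked, 0.0, term)
    return c, g_eff


def solve_adjoint_cie(grid: Grid3D, phi: ScalarField, phi_k: ScalarField,
                      carrier: CarrierParams) -> ScalarField:
    """Steady-state adjoint solve returning eta(r) for all positions.

    First-order upwinding for the advection term (coefficient
    ``sign * mu * grad(phi)`` evaluated at the nodes), a mirror-Neumann
    seven-point Laplacian for diffusion, ``x+ = 0`` on absorbing electrode
    surfaces and zero normal gradient on insulating gap/lateral surfaces.
    The induction source is blocked-flux masked (see
    :func:`_advection_and_source`).
    """
    e_grad = gradient(phi)
    w_grad = gradient(phi_k)
    c, gplus = _advection_and_source(grid, e_grad, w_grad, carrier)
    D = carrier.d_mm2_us
    tau = carrier.lifetime

    nx, ny, nz = grid.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    dirichlet = _electrode_dirichlet(grid, carrier, D > 0)
    free = ~dirichlet.ravel()

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    steps = (grid.step, grid.step, grid.step_z)

    # Upwinded advection c . grad(x+): forward difference where c > 0,
    # backward where c < 0; zero-gradient (no term) at a face with the
    # upwind neighbour missing.
    for axis in range(3):
        if grid.shape[axis] < 2:
            continue
        h = steps[axis]
        ca = c[axis].ravel()
        has_plus = np.ones(grid.shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[axis] = -1
        has_plus[tuple(sl)] = False
        has_minus = np.ones(grid.shape, dtype=bool)
        sl[axis] = 0
        has_minus[tuple(sl)] = False

        nb_plus = np.roll(idx, -1, axis=axis).ravel()
        nb_minus = np.roll(idx, 1, axis=axis).ravel()

        m = free & (ca > 0) & has_plus.ravel()
        r = np.nonzero(m)[0]
        rows.append(r)
        cols.append(nb_plus[r])
        vals.append(ca[r] / h)
        diag[r] -= ca[r] / h

        m = free & (ca < 0) & has_minus.ravel()
        r = np.nonzero(m)[0]
        rows.append(r)
        cols.append(nb_minus[r])
        vals.append(-ca[r] / h)
        diag[r] += ca[r] / h

    if D > 0:
        lr, lc, lv, ld = _neumann_laplacian_entries(grid, free)
        rows += lr
        cols += lc
        vals = vals + [D * v for v in lv]
        diag += D * ld

    diag[free] -= 1.0 / tau
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(np.where(free, diag, 1.0))

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    b = np.where(free, -gplus.ravel(), 0.0)

    x = solve_linear(A, b).reshape(grid.shape)
    x[dirichlet] = 0.0
    # Net induction on the selected anode is genuinely negative for charges
    # collected on a neighbouring pad (start inside the weighting-potential
    # spillover, end at phi_k = 0), so modest negative lobes are part of
    # the solution; the CIE map is defined on [0, 1] and clamps them.
    # Magnitudes beyond the weighting-potential spillover scale indicate a
    # scheme failure.
    if x.min() < -NEG_FAILURE:
        raise SolverError(
            f"adjoint solution reached {x.min():.3g}; "
            "upwinding scheme failure")
    return ScalarField(grid, np.clip(x, 0.0, None))


def direct_cie_oracle(r0, grid: Grid3D, phi: ScalarField,
                      phi_k: ScalarField, carrier: CarrierParams,
                      dt: float, t_end: float) -> float:
    """Brute-force CIE at one starting point by forward time-stepping.

    Injects a unit point charge at the grid node nearest ``r0``, advances
    the charge-cloud continuity equation with an explicit conservative
    upwind step, and accumulates the Shockley--Ramo induction integral
    until ``t_end`` (which should be long compared to the collection time
    and the carrier lifetime).  Independent of the adjoint path; used only
    for validation.

    ``dt`` and ``t_end`` are in microseconds.
    """
    e_grad = gradient(phi)
    w_grad = gradient(phi_k)
    mu = carrier.mu_mm2_V_us
    v = carrier.drift_sign * mu * e_grad          # physical drift, mm/us
    _, g = _advection_and_source(grid, e_grad, w_grad, carrier)  # 1/us
    D = carrier.d_mm2_us
    tau = carrier.lifetime
    steps = (grid.step, grid.step, grid.step_z)

    rate = 1.0 / tau
    for a in range(3):
        if grid.shape[a] >= 2:
            rate += np.abs(v[a]).max() / steps[a] + 2.0 * D / steps[a] ** 2
    if dt * rate > 1.0:
        raise ValueError(
            f"explicit step dt={dt} us violates the CFL limit "
            f"{1.0 / rate:.3g} us")

    dirichlet = _electrode_dirichlet(grid, carrier, D > 0)

    # Initial condition: discrete delta (unit charge in one cell).
    dV = steps[0] * steps[1] * steps[2]
    i0 = int(np.argmin(np.abs(grid.x - r0[0])))
    j0 = int(np.argmin(np.abs(grid.y - r0[1])))
    k0 = int(np.argmin(np.abs(grid.z - r0[2])))
    x = np.zeros(grid.shape)
    x[i0, j0, k0] = 1.0 / dV
    x[dirichlet] = 0.0

    def rhs(xc: np.ndarray) -> np.ndarray:
        out = -xc / tau
        for axis in range(3):
            if grid.shape[axis] < 2:
                continue
            h = steps[axis]
            va = v[axis]
            vf = 0.5 * (np.take(va, range(0, grid.shape[axis] - 1), axis=axis)
                        + np.take(va, range(1, grid.shape[axis]), axis=axis))
            xl = np.take(xc, range(0, grid.shape[axis] - 1), axis=axis)
            xr = np.take(xc, range(1, grid.shape[axis]), axis=axis)
            flux = np.where(vf > 0, xl, xr) * vf
            # Interior faces only; outer faces carry zero flux.
            dshape = list(grid.shape)
            div = np.zeros(grid.shape)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, dshape[axis] - 1)
            sl_hi[axis] = slice(1, dshape[axis])
            div[tuple(sl_lo)] += flux / h   # flux leaving through + face
            div[tuple(sl_hi)] -= flux / h   # flux entering through - face
            out -= div
            if D > 0:
                lap = np.zeros(grid.shape)
                d2 = (xr - xl) / h  # gradient at faces
                lap[tuple(sl_lo)] += d2 / h
                lap[tuple(sl_hi)] -= d2 / h
                out += D * lap
        return out

    eta = 0.0
    t = 0.0
    gdV = g * dV
    prev = float(np.sum(x * gdV))
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        x = x + dt * rhs(x)
        x[dirichlet] = 0.0
        cur = float(np.sum(x * gdV))
        eta += 0.5 * dt * (prev + cur)
        prev = cur
        t += dt
        if np.sum(x) * dV < 1e-10:
            break
    return eta


def hecht_cie(z, thickness: float, mu_tau_e: float,
              mu_tau_h: float | None = None, field: float = 120.0):
    """Hecht closed form for the parallel-plate CIE.

    ``z`` is depth from the cathode in mm, ``mu_tau_*`` in cm^2/V,
    ``field`` in V/mm.  Drift lengths are ``lambda = mu tau E``;
    eta = (lam_e/L)(1 - exp(-(L-z)/lam_e)) + (lam_h/L)(1 - exp(-z/lam_h)),
    the hole term omitted when ``mu_tau_h`` is None.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > thickness):
        raise ValueError("z must lie within [0, thickness]")
    lam_e = mu_tau_e * field * 100.0  # cm^2/V * V/mm = 100 mm
    if lam_e <= 0:
        raise ValueError("electron drift length must be > 0")
    eta = (lam_e / thickness) * (1.0 - np.exp(-(thickness - z) / lam_e))
    if mu_tau_h is not None:
        lam_h = mu_tau_h * field * 100.0
        if lam_h <= 0:
            raise ValueError("hole drift length must be > 0")
        eta = eta + (lam_h / thickness) * (1.0 - np.exp(-z / lam_h))
    return eta if eta.ndim else float(eta)


@dataclass
class CIEMap:
    """Three-dimensional CIE array with its node coordinates and the
    parameters that generated it.

    ``r_joint`` is the detector-frame lateral position of the anode the map
    was computed for; the map's own coordinates are local, with the joint
    anode centre at the lateral origin and depth measured from the cathode.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    signal_mode: str = "C1"                      # {C1, C2}
    field_config: FieldConfig | None = None
    electron: CarrierParams | None = None
    hole: CarrierParams | None = None
    r_joint: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.r_joint = np.asarray(self.r_joint, dtype=float)
        if self.values.shape != (self.x.size, self.y.size, self.z.size):
            raise ValueError("values shape does not match coordinates")
        for ax in (self.x, self.y, self.z):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("coordinates must be strictly increasing")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("CIE values must lie in [0, 1]")
        if self.signal_mode not in ("C1", "C2"):
            raise ValueError("signal_mode must be C1 or C2")
        if self.signal_mode == "C2" and self.hole is None:
            raise ValueError("C2 map requires hole parameters")


def combine_components(eta_e: ScalarField, eta_h: ScalarField | None,
                       mode: str, *, field_config: FieldConfig | None = None,
                       electron: CarrierParams | None = None,
                       hole: CarrierParams | None = None,
                       r_joint=(0.0, 0.0)) -> CIEMap:
    """Join carrier components into a CIE map.

    C1 uses the electron component alone; C2 adds the hole component.
    Values are clamped to [0, 1].
    """
    if mode not in ("C1", "C2"):
        raise ValueError("mode must be C1 or C2")
    if mode == "C2" and eta_h is None:
        raise ValueError("C2 requires the hole component")
    vals = eta_e.values.copy()
    if mode == "C2":
        if eta_h.values.shape != vals.shape:
            raise ValueError("component shapes differ")
        vals = vals + eta_h.values
    grid = eta_e.grid
    return CIEMap(values=np.clip(vals, 0.0, 1.0),
                  x=grid.x.copy(), y=grid.y.copy(), z=grid.z.copy(),
                  signal_mode=mode, field_config=field_config,
                  electron=electron, hole=hole, r_joint=np.asarray(r_joint))


def compute_cie_map(crystal: CrystalSpec, anodes: AnodeArraySpec,
                    field_cfg: FieldConfig,
                    electron: CarrierParams = ELECTRON_DEFAULT,
                    hole: CarrierParams | None = None,
                    signal_mode: str = "C1",
                    neighbourhood: int = 5, step: float = 0.123,
                    use_symmetry: bool = True) -> CIEMap:
    """Full pipeline: grid, potentials, adjoint solve(s), joint CIE map.

    With ``use_symmetry`` the Laplace and adjoint problems are solved on
    the quarter grid and unfolded, which is exact for the central anode.
    """
    if signal_mode == "C2" and hole is None:
        hole = HOLE_DEFAULT
    grid_full = build_grid(crystal, anodes, neighbourhood, step)
    k_central = grid_full.central_pad()

    unfold = None
    grid = grid_full
    if use_symmetry and grid_full.x.size % 2 == 1:
        grid, unfold = symmetry_reduce(grid_full)

    phi = solve_electric_potential(grid, crystal, field_cfg)
    phi_k = solve_weighting_potential(grid, k_central, field_cfg,
                                      pad_size=anodes.pad_size)

    def solve_component(params: CarrierParams) -> ScalarField:
        eta = solve_adjoint_cie(grid, phi, phi_k, params)
        if unfold is not None:
            return ScalarField(grid_full, unfold.unfold(eta.values))
        return eta

    eta_e = solve_component(electron)
    eta_h = solve_component(hole) if signal_mode == "C2" else None
    return combine_components(eta_e, eta_h, signal_mode,
                              field_config=field_cfg, electron=electron,
                              hole=hole, r_joint=(0.0, 0.0))


# ---------------------------------------------------------------------------
# Persistence: versioned little-endian binary container.

_MAGIC = b"CZTCIE01"
_VERSION = 1


class CIEFormatError(IOError):
    """Malformed, truncated or incompatible CIE file."""


def _meta_dict(m: CIEMap) -> dict:
    return {
        "signal_mode": m.signal_mode,
        "field_config": asdict(m.field_config) if m.field_config else None,
        "electron": asdict(m.electron) if m.electron else None,
        "hole": asdict(m.hole) if m.hole else None,
        "r_joint": [float(v) for v in m.r_joint],
    }


def write_cie(m: CIEMap, path) -> None:
    """Write a CIE map: magic, version, axis lengths, axis coordinates,
    C-order array (all little-endian float64), then a length-prefixed JSON
    metadata block."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        fh.write(struct.pack("<3Q", m.x.size, m.y.size, m.z.size))
        for ax in (m.x, m.y, m.z):
            fh.write(np.asarray(ax, "<f8").tobytes())
        fh.write(np.ascontiguousarray(m.values, "<f8").tobytes())
        meta = json.dumps(_meta_dict(m)).encode()
        fh.write(struct.pack("<Q", len(meta)))
        fh.write(meta)


def read_cie(path, metadata_only: bool = False) -> CIEMap | dict:
    """Read a CIE map written by :func:`write_cie`.

    With ``metadata_only`` the array is skipped and the recorded parameter
    dictionary is returned instead of a map.
    """
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise CIEFormatError(f"bad magic header {magic!r}")
        (version,) = struct.unpack("<I", fh.read(4))
        if version != _VERSION:
            raise CIEFormatError(f"unsupported CIE file version {version}")
        nx, ny, nz = struct.unpack("<3Q", fh.read(24))
        n_arr = nx * ny * nz

        def read_f8(count: int) -> np.ndarray:
            raw = fh.read(8 * count)
            if len(raw) != 8 * count:
                raise CIEFormatError("truncated CIE file")
            return np.frombuffer(raw, "<f8").copy()

        if metadata_only:
            fh.seek(8 * (nx + ny + nz + n_arr), io.SEEK_CUR)
            meta = _read_meta(fh)
            return meta
        x = read_f8(nx)
        y = read_f8(ny)
        z = read_f8(nz)
        values = read_f8(n_arr).reshape(nx, ny, nz)
        meta = _read_meta(fh)

    fc = meta.get("field_config")
    el = meta.get("electron")
    ho = meta.get("hole")
    return CIEMap(
        values=values, x=x, y=y, z=z,
        signal_mode=meta.get("signal_mode", "C1"),
        field_config=FieldConfig(**fc) if fc else None,
        electron=CarrierParams(**el) if el else None,
        hole=CarrierParams(**ho) if ho else None,
        r_joint=np.asarray(meta.get("r_joint", [0.0, 0.0])),
    )


def _read_meta(fh) -> dict:
    raw = fh.read(8)
    if len(raw) != 8:
        raise CIEFormatError("truncated CIE file (missing metadata)")
    (mlen,) = struct.unpack("<Q", raw)
    blob = fh.read(mlen)
    if len(blob) != mlen:
        raise CIEFormatError("truncated CIE file (metadata)")
    try:
        return json.loads(blob.decode())
    except ValueError as exc:
        raise CIEFormatError(f"corrupt metadata block: {exc}") from exc
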