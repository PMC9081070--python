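"""Crystal, anode-array and collimator geometry, and the discretised grid.

The modelled detector is a monolithic CZT slab with a continuous cathode on
the source-facing side (depth ``z = 0``) and a square array of anode pads on
the opposite side (``z = thickness``).  The charge-transport equations are
solved on a regular Cartesian node lattice covering an odd ``N x N`` anode
neighbourhood centred on one selected anode; the periodicity of the anode
pattern makes the central-anode fields quarter-symmetric, which
:func:`symmetry_reduce` exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CrystalSpec", "AnodeArraySpec", "CollimatorSpec", "Grid3D", "UnfoldMap",
    "LEHR", "MEGP", "OPEN", "build_grid", "symmetry_reduce", "load_geometry",
    "LABEL_INTERIOR", "LABEL_CATHODE", "LABEL_ANODE", "LABEL_GAP",
    "LABEL_LATERAL",
]

# Node label codes.  Labels partition the boundary: cathode only at z = 0,
# anode/gap only at z = thickness, lateral on the remaining side faces.
LABEL_INTERIOR = 0
LABEL_CATHODE = 1
LABEL_ANODE = 2
LABEL_GAP = 3
LABEL_LATERAL = 4

LABEL_NAMES = {
    LABEL_INTERIOR: "interior",
    LABEL_CATHODE: "cathode",
    LABEL_ANODE: "anode",
    LABEL_GAP: "gap",
    LABEL_LATERAL: "lateral_boundary",
}


@dataclass(frozen=True)
class CrystalSpec:
    """Monolithic CZT crystal.

    The cathode plane sits at depth 0 and the anode plane at
    ``depth = thickness``.  ``bias_voltage`` is the magnitude of the
    potential applied over the crystal; the cathode is the negative
    electrode (held at ``-bias_voltage`` with the anodes grounded), so
    electrons drift toward the anode plane.
    """

    width_x: float = 39.0          # mm
    width_y: float = 39.0          # mm
    thickness: float = 5.0         # mm
    bias_voltage: float = 600.0    # V
    permittivity_rel: float = 10.9

    def __post_init__(self) -> None:
        for name in ("width_x", "width_y", "thickness", "bias_voltage",
                     "permittivity_rel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CrystalSpec.{name} must be > 0")


@dataclass(frozen=True)
class AnodeArraySpec:
    """Square array of square anode contact pads."""

    n_x: int = 16
    n_y: int = 16
    pitch: float = 2.46       # mm
    pad_size: float = 1.86    # mm

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("anode counts must be >= 1")
        if self.pitch <= 0 or self.pad_size <= 0:
            raise ValueError("pitch and pad_size must be > 0")
        if self.pad_size > self.pitch:
            raise ValueError("pad_size must not exceed pitch")

    def centres(self, crystal: CrystalSpec | None = None) -> np.ndarray:
        """Anode-centre lateral positions, shape ``(n_x * n_y, 2)``.

        Centred on the crystal (or on the origin when ``crystal`` is None),
        flat index ``k = iy * n_x + ix``.
        """
        cx = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch
        cy = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.pitch
        gx, gy = np.meshgrid(cx, cy, indexing="xy")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class CollimatorSpec:
    """Parallel-hole collimator with holes matched one-to-one to anodes."""

    name: str
    hole_length: float      # mm
    wall_thickness: float   # mm
    hole_width: float       # mm
    material: str = "lead"
    hole_shape: str = "square"   # {square, circular, none}

    def hole_contains(self, u: float, v: float) -> bool:
        """Whether lateral offset (u, v) from a hole centre is inside the
        open aperture.  Circular holes are inscribed in the anode cell."""
        if self.hole_shape == "none":
            return True
        half = self.hole_width / 2.0
        if self.hole_shape == "square":
            return abs(u) <= half and abs(v) <= half
        if self.hole_shape == "circular":
            return u * u + v * v <= half * half
        raise ValueError(f"unknown hole shape {self.hole_shape!r}")


LEHR = CollimatorSpec("LEHR", 22.6, 0.23, 2.23, "lead", "square")
MEGP = CollimatorSpec("MEGP", 11.5, 0.96, 1.50, "lead", "circular")
OPEN = CollimatorSpec("OPEN", 0.0, 0.0, 0.0, "none", "none")


@dataclass
class Grid3D:
    """Regular node lattice over an anode-neighbourhood sub-volume.

    Nodes are cell vertices with inclusive endpoints.  ``labels`` holds one
    code per node (see ``LABEL_*``); ``pad_id[i, j]`` gives the flat
    neighbourhood-anode index of anode-plane node ``(i, j)`` or -1 over the
    gaps.  The lateral origin is the centre of the selected (central) anode
    pad.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    step: float
    step_z: float
    labels: np.ndarray            # (nx, ny, nz) uint8
    pad_id: np.ndarray            # (nx, ny) int32, anode plane
    pad_centres: np.ndarray       # (n_pads, 2) mm
    neighbourhood: int
    symmetry_planes: list = field(default_factory=list)

    @property
    def shape(self) -> tuple:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size * self.z.size

    @property
    def thickness(self) -> float:
        return float(self.z[-1] - self.z[0])

    def central_pad(self) -> int:
        """Flat pad index of the anode closest to the lateral origin."""
        d = np.hypot(self.pad_centres[:, 0], self.pad_centres[:, 1])
        return int(np.argmin(d))


def _divides(a: float, b: float, rtol: float = 1e-9) -> bool:
    """True when b divides a to within rounding."""
    q = a / b
    return abs(q - round(q)) <= rtol * max(1.0, abs(q))


def build_grid(crystal: CrystalSpec, anodes: AnodeArraySpec,
               neighbourhood: int = 5, step: float = 0.123) -> Grid3D:
    """Discretise an ``N x N`` anode neighbourhood of the crystal.

    Parameters
    ----------
    neighbourhood
        Odd number of anode cells per lateral axis; the selected anode is
        the central one.
    step
        Lateral node spacing in mm.  Must divide the anode pitch exactly;
        the depth spacing is ``thickness / round(thickness / step)``, i.e.
        the nearest commensurate value (within half a node of ``step``).

    Raises
    ------
    ValueError
        If the step is not commensurate with the pitch or thickness.  No
        silent snapping is performed.
    """
    if neighbourhood < 1 or neighbourhood % 2 == 0:
        raise ValueError("neighbourhood must be a positive odd count")
    if step <= 0:
        raise ValueError("step must be > 0")
    if not _divides(anodes.pitch, step):
        raise ValueError(
            f"step {step} mm does not divide the anode pitch "
            f"{anodes.pitch} mm; choose a commensurate step "
            f"(pitch/step = {anodes.pitch / step:.6f} must be an integer)")
    if neighbourhood * anodes.pitch > min(crystal.width_x, crystal.width_y):
        raise ValueError("neighbourhood extends beyond the crystal")

    m = round(anodes.pitch / step)
    n_lat = neighbourhood * m + 1
    half = neighbourhood * anodes.pitch / 2.0
    x = np.linspace(-half, half, n_lat)
    y = x.copy()

    nz_int = round(crystal.thickness / step)
    if nz_int < 1 or abs(crystal.thickness / step - nz_int) > 0.5:
        raise ValueError(
            f"step {step} mm is not commensurate with the crystal thickness "
            f"{crystal.thickness} mm to within half a node")
    step_z = crystal.thickness / nz_int
    z = np.linspace(0.0, crystal.thickness, nz_int + 1)

    # Pad centres of the neighbourhood, flat index k = jy * N + jx.
    offs = (np.arange(neighbourhood) - (neighbourhood - 1) / 2.0) * anodes.pitch
    gx, gy = np.meshgrid(offs, offs, indexing="xy")
    pad_centres = np.column_stack([gx.ravel(), gy.ravel()])

    # A node is on a pad if its lateral distance from the pad centre is
    # <= pad_size/2 in both axes (closed set).
    half_pad = anodes.pad_size / 2.0 + 1e-12
    pad_id = np.full((n_lat, n_lat), -1, dtype=np.int32)
    for k, (cx, cy) in enumerate(pad_centres):
        on_x = np.abs(x - cx) <= half_pad
        on_y = np.abs(y - cy) <= half_pad
        pad_id[np.ix_(on_x, on_y)] = k

    labels = np.full((n_lat, n_lat, z.size), LABEL_INTERIOR, dtype=np.uint8)
    labels[0, :, :] = LABEL_LATERAL
    labels[-1, :, :] = LABEL_LATERAL
    labels[:, 0, :] = LABEL_LATERAL
    labels[:, -1, :] = LABEL_LATERAL
    labels[:, :, 0] = LABEL_CATHODE
    labels[:, :, -1] = np.where(pad_id >= 0, LABEL_ANODE, LABEL_GAP)

    planes = []
    if n_lat % 2 == 1:  # node exists on each lateral mid-plane
        planes = ["x=0", "y=0"]

    return Grid3D(x=x, y=y, z=z, step=step, step_z=step_z, labels=labels,
                  pad_id=pad_id, pad_centres=pad_centres,
                  neighbourhood=neighbourhood, symmetry_planes=planes)


@dataclass(frozen=True)
class UnfoldMap:
    """Reconstructs full-grid fields from a quarter-grid solution.

    The reduced grid covers the quadrant ``x >= 0, y >= 0`` including the
    shared mid-plane nodes; unfolding reflects across both planes.
    """

    n_full: int     # full lateral node count (odd)
    n_red: int      # reduced lateral node count = (n_full + 1) // 2

    def unfold(self, values: np.ndarray) -> np.ndarray:
        if values.shape[0] != self.n_red or values.shape[1] != self.n_red:
            raise ValueError("values do not match the reduced grid")
        c = self.n_full // 2
        ix = np.abs(np.arange(self.n_full) - c)
        return values[np.ix_(ix, ix)]

    def fold(self, values: np.ndarray) -> np.ndarray:
        """Restrict a full-grid (symmetric) field to the quadrant."""
        c = values.shape[0] // 2
        return values[c:, c:]


def symmetry_reduce(grid: Grid3D) -> tuple[Grid3D, UnfoldMap]:
    """Reduce the grid to the ``x >= 0, y >= 0`` quadrant.

    Requires the two lateral mid-planes of the central anode to coincide
    with node planes and the electrode labelling to be mirror-symmetric.
    Gradients across the symmetry planes vanish for symmetric problems, so
    solving on the reduced grid with zero-normal-gradient faces and
    unfolding equals the full-grid solution.
    """
    n = grid.x.size
    if n % 2 == 0:
        raise ValueError(
            "symmetry plane falls between nodes; use a step for which "
            "pitch/step is even so the mid-plane is a node plane")
    if grid.y.size != n:
        raise ValueError("lateral axes differ; quarter symmetry unavailable")
    lab = grid.labels
    if not (np.array_equal(lab, lab[::-1, :, :])
            and np.array_equal(lab, lab[:, ::-1, :])):
        raise ValueError("electrode labels are not mirror-symmetric; "
                         "reduction refused")
    pid = grid.pad_id
    # Pad identity must also be mirror-symmetric as a gap/pad partition;
    # pad ids themselves change under reflection, membership must not.
    if not (np.array_equal(pid >= 0, (pid >= 0)[::-1, :])
            and np.array_equal(pid >= 0, (pid >= 0)[:, ::-1])):
        raise ValueError("pad layout is not mirror-symmetric")

    c = n // 2
    red = Grid3D(
        x=grid.x[c:].copy(), y=grid.y[c:].copy(), z=grid.z.copy(),
        step=grid.step, step_z=grid.step_z,
        labels=grid.labels[c:, c:, :].copy(),
        pad_id=grid.pad_id[c:, c:].copy(),
        pad_centres=grid.pad_centres.copy(),
        neighbourhood=grid.neighbourhood,
        symmetry_planes=[],
    )
    # The cut faces (x = 0, y = 0) behave as zero-normal-gradient
    # boundaries; relabel their non-electrode nodes so labels still
    # partition the boundary.
    for face in (np.s_[0, :, :], np.s_[:, 0, :]):
        f = red.labels[face]
        f[f == LABEL_INTERIOR] = LABEL_LATERAL
        red.labels[face] = f
    return red, UnfoldMap(n_full=n, n_red=n - c)


_COLLIMATORS = {"LEHR": LEHR, "MEGP": MEGP, "OPEN": OPEN}


def load_geometry(path: str | Path) -> tuple[CrystalSpec, AnodeArraySpec,
                                             CollimatorSpec]:
    """Read a geometry config file (YAML with crystal / anodes / collimator
    blocks).  Missing blocks fall back to the shipped camera defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    crystal = CrystalSpec(**doc.get("crystal", {}))
    anodes = AnodeArraySpec(**doc.get("anodes", {}))
    col = doc.get("collimator", "MEGP")
    if isinstance(col, str):
        try:
            collimator = _COLLIMATORS[col.upper()]
        except KeyError:
            raise ValueError(f"unknown collimator {col!r}") from None
    else:
        collimator = CollimatorSpec(**col)
    return crystal, anodes, collimator
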