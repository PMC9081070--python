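"""Photon-interaction listmode data: containers, I/O and a synthetic generator.

A *history* is one emitted photon's chain of interactions in the crystal
(photoelectric absorption, Compton scatter, elastic scatter), each with a
position, a deposited energy and a variance-reduced weight.  Real listmode
files come from an external photon-transport Monte Carlo; the generator
here is a parameterised statistical stand-in that emulates the features the
detector model is sensitive to -- exponential interaction-depth profiles,
Compton energy splitting with possible escape, collimator shadowing of the
inter-anode gaps, multi-line emitters and transport-class tags -- without
performing photon transport.  Class mixtures and septal penetration factors
are inputs, not predictions.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .geometry import CrystalSpec, AnodeArraySpec, CollimatorSpec

__all__ = [
    "InteractionEvent", "PhotonHistory", "SourceSpec", "ListmodeFormatError",
    "TRANSPORT_CLASSES", "LU177_LINES",
    "write_listmode", "read_listmode", "collimator_transmission",
    "sample_interaction_depth", "sample_compton_split", "generate_listmode",
    "classify_history",
]

ELECTRON_REST_KEV = 510.998950

TRANSPORT_CLASSES = ("geometric_primary", "phantom_scatter", "penetration",
                     "collimator_scatter", "collimator_xray", "other")

KINDS = ("photoelectric", "compton", "rayleigh")

#: The prominent photon emissions of 177Lu, keV.  Yields are configuration,
#: not constants; the listed intensities are typical relative values.
LU177_LINES = ((54.6, 0.169), (55.8, 0.294), (112.9, 0.620), (208.4, 1.000))

#: Default CZT linear attenuation coefficients (1/mm) vs energy (keV),
#: log-log interpolated between entries.  Order-of-magnitude values above
#: the Cd/Te K-edges; they parameterise the synthetic depth profile only.
DEFAULT_MU_ATT = ((40.0, 7.8), (55.0, 3.5), (75.0, 1.55), (113.0, 0.72),
                  (140.5, 0.48), (208.4, 0.22), (250.0, 0.16))


@dataclass
class InteractionEvent:
    """One crystal interaction: type, position (mm, crystal frame with the
    lateral origin at the detector centre and depth from the cathode),
    deposited energy (keV) and photon weight."""

    kind: str
    position: np.ndarray
    deposited_energy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.deposited_energy < 0:
            raise ValueError("deposited energy must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class PhotonHistory:
    """One photon's ordered interaction chain with its provenance tags."""

    history_id: int
    events: list
    emission_energy: float
    transport_class: str = "other"

    def __post_init__(self) -> None:
        if self.transport_class not in TRANSPORT_CLASSES:
            self.transport_class = "other"


def _norm_fractions(d: dict) -> dict:
    total = sum(d.values())
    if total <= 0 or any(v < 0 for v in d.values()):
        raise ValueError("class mixture fractions must be >= 0 and sum > 0")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mixture fractions must sum to 1 (got {total})")
    for k in d:
        if k not in TRANSPORT_CLASSES:
            raise ValueError(f"unknown transport class {k!r}")
    return dict(d)


@dataclass
class SourceSpec:
    """Emission and acquisition parameters for the synthetic generator.

    ``lines`` are (energy keV, relative intensity) pairs; ``class_mixture``
    gives per-class probabilities, either one dict for all lines or a
    mapping ``{line_energy: {class: fraction}}``.  ``mu_att`` is a table of
    linear attenuation coefficients (1/mm) controlling the depth profile.
    ``photo_fraction`` is the probability that a detected chain is a single
    photoabsorption (otherwise a Compton split with possible escape of the
    scattered photon, ``escape_fraction``).
    """

    lines: tuple = LU177_LINES
    distance: float = 25.0         # source-collimator distance, mm
    source_radius: float = 10.0    # source disc radius, mm
    activity: float = 10.0         # MBq
    duration: float = 100.0        # s
    class_mixture: dict = field(
        default_factory=lambda: {"geometric_primary": 1.0})
    mu_att: tuple = DEFAULT_MU_ATT
    photo_fraction: float = 0.85
    escape_fraction: float = 0.5
    xray_energy: float = 75.0      # collimator (lead) fluorescence, keV
    penetration_factor: float = 0.05

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("at least one emission line is required")
        for e, y in self.lines:
            if e <= 0 or y <= 0:
                raise ValueError("line energies and intensities must be > 0")
        first = next(iter(self.class_mixture.values()))
        if isinstance(first, dict):
            self.class_mixture = {
                float(k): _norm_fractions(v)
                for k, v in self.class_mixture.items()}
        else:
            self.class_mixture = _norm_fractions(self.class_mixture)

    def mixture_for(self, line_energy: float) -> dict:
        mix = self.class_mixture
        if mix and isinstance(next(iter(mix.values())), dict):
            return mix[float(line_energy)]
        return mix

    def mu_at(self, energy: float) -> float:
        """Log-log interpolated attenuation coefficient, 1/mm."""
        tab = np.asarray(self.mu_att, dtype=float)
        return float(np.exp(np.interp(np.log(energy), np.log(tab[:, 0]),
                                      np.log(tab[:, 1]))))


# ---------------------------------------------------------------------------
# File I/O: fixed-width binary records plus a plain-text dialect.

_LM_MAGIC = b"CZTLM001"
_LM_VERSION = 1
_RECORD = np.dtype([
    ("history_id", "<u8"), ("kind", "u1"), ("cls", "u1"), ("line", "<f4"),
    ("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
    ("energy", "<f8"), ("weight", "<f8"),
])


class ListmodeFormatError(IOError):
    """Malformed or truncated listmode file."""


def _is_text(path, fmt) -> bool:
    if fmt is not None:
        return fmt == "text"
    return str(path).endswith((".txt", ".tsv"))


def write_listmode(histories, path, fmt: str | None = None,
                   seed: int | None = None) -> int:
    """Write histories; format chosen by ``fmt`` ("binary"/"text") or by
    the file extension (.txt/.tsv for text).  Returns the record count."""
    histories = list(histories)
    n_rec = sum(len(h.events) for h in histories)
    if _is_text(path, fmt):
        with open(path, "w") as fh:
            fh.write("# cztcam-listmode v1\n")
            fh.write(f"# seed {-1 if seed is None else seed}\n")
            fh.write("# history_id kind class line_keV x_mm y_mm z_mm "
                     "energy_keV weight\n")
            for h in histories:
                for ev in h.events:
                    fh.write(
                        f"{h.history_id} {ev.kind} {h.transport_class} "
                        f"{h.emission_energy:.6g} "
                        f"{ev.position[0]:.17g} {ev.position[1]:.17g} "
                        f"{ev.position[2]:.17g} "
                        f"{ev.deposited_energy:.17g} {ev.weight:.17g}\n")
        return n_rec

    rec = np.empty(n_rec, dtype=_RECORD)
    i = 0
    for h in histories:
        cls_code = TRANSPORT_CLASSES.index(h.transport_class)
        for ev in h.events:
            rec[i] = (h.history_id, KINDS.index(ev.kind), cls_code,
                      h.emission_energy, ev.position[0], ev.position[1],
                      ev.position[2], ev.deposited_energy, ev.weight)
            i += 1
    with open(path, "wb") as fh:
        fh.write(_LM_MAGIC)
        fh.write(struct.pack("<Iq", _LM_VERSION,
                             -1 if seed is None else seed))
        fh.write(rec.tobytes())
    return n_rec


def _records_to_histories(rec_iter, strict, crystal):
    """Group consecutive equal-history-id records into PhotonHistory."""
    current_id = None
    events: list = []
    line = 0.0
    cls = "other"
    for r in rec_iter:
        hid = int(r["history_id"])
        if current_id is not None and hid != current_id:
            yield PhotonHistory(current_id, events, line, cls)
            events = []
        current_id = hid
        line = float(r["line"])
        code = int(r["cls"])
        cls = TRANSPORT_CLASSES[code] if code < len(TRANSPORT_CLASSES) \
            else "other"
        pos = np.array([r["x"], r["y"], r["z"]], dtype=float)
        if strict and crystal is not None:
            if (abs(pos[0]) > crystal.width_x / 2 + 1e-9
                    or abs(pos[1]) > crystal.width_y / 2 + 1e-9
                    or not -1e-9 <= pos[2] <= crystal.thickness + 1e-9):
                raise ListmodeFormatError(
                    f"history {hid}: position {pos} outside the crystal")
        events.append(InteractionEvent(KINDS[int(r["kind"])], pos,
                                       float(r["energy"]),
                                       float(r["weight"])))
    if current_id is not None:
        yield PhotonHistory(current_id, events, line, cls)


def read_listmode(path, fmt: str | None = None, strict: bool = False,
                  crystal: CrystalSpec | None = None):
    """Stream histories from a listmode file (generator; the file is not
    loaded whole).  ``strict`` validates positions against ``crystal``."""
    if _is_text(path, fmt):
        def text_records():
            with open(path) as fh:
                first = fh.readline()
                if not first.startswith("# cztcam-listmode"):
                    raise ListmodeFormatError("not a listmode text file")
                for ln in fh:
                    if not ln.strip() or ln.startswith("#"):
                        continue
                    parts = ln.split()
                    if len(parts) != 9:
                        raise ListmodeFormatError(
                            f"malformed record: {ln.strip()!r}")
                    yield {
                        "history_id": int(parts[0]),
                        "kind": KINDS.index(parts[1]),
                        "cls": (TRANSPORT_CLASSES.index(parts[2])
                                if parts[2] in TRANSPORT_CLASSES else 255),
                        "line": float(parts[3]),
                        "x": float(parts[4]), "y": float(parts[5]),
                        "z": float(parts[6]), "energy": float(parts[7]),
                        "weight": float(parts[8]),
                    }
        yield from _records_to_histories(text_records(), strict, crystal)
        return

    def binary_records():
        with open(path, "rb") as fh:
            magic = fh.read(len(_LM_MAGIC))
            if magic != _LM_MAGIC:
                raise ListmodeFormatError(f"bad magic header {magic!r}")
            version, _seed = struct.unpack("<Iq", fh.read(12))
            if version != _LM_VERSION:
                raise ListmodeFormatError(
                    f"unsupported listmode version {version}")
            while True:
                chunk = fh.read(_RECORD.itemsize * 65536)
                if not chunk:
                    return
                if len(chunk) % _RECORD.itemsize:
                    raise ListmodeFormatError("truncated record")
                yield from np.frombuffer(chunk, dtype=_RECORD)
    yield from _records_to_histories(binary_records(), strict, crystal)


# ---------------------------------------------------------------------------
# Sampling primitives.

def collimator_transmission(xy, collimator: CollimatorSpec, energy: float,
                            anodes: AnodeArraySpec | None = None,
                            penetration=0.0) -> float:
    """Relative likelihood of a photon reaching lateral position ``xy``.

    1 inside the projected hole aperture of the matched collimator (holes
    one-to-one with the anodes), the septal penetration factor over the
    walls, and 1 everywhere for the open-field cover.  ``penetration`` may
    be a scalar or a callable of energy.
    """
    if collimator.hole_shape == "none":
        return 1.0
    if anodes is None:
        anodes = AnodeArraySpec()
    x, y = float(xy[0]), float(xy[1])
    p = anodes.pitch

    def local(v: float, n: int) -> float:
        i = np.clip(round(v / p + (n - 1) / 2.0), 0, n - 1)
        return v - (i - (n - 1) / 2.0) * p

    if collimator.hole_contains(local(x, anodes.n_x), local(y, anodes.n_y)):
        return 1.0
    return float(penetration(energy)) if callable(penetration) \
        else float(penetration)


def sample_interaction_depth(energy: float, mu_att: float, thickness: float,
                             rng, size=None):
    """Depth of first interaction: truncated exponential on
    [0, thickness] with rate ``mu_att`` (1/mm), measured from the cathode
    side the photons enter through."""
    if mu_att <= 0:
        raise ValueError("mu_att must be > 0")
    u = rng.random(size)
    return -np.log1p(-u * (1.0 - np.exp(-mu_att * thickness))) / mu_att


def _klein_nishina_cos(energy: float, rng) -> float:
    """Scattering-angle cosine from the Klein--Nishina differential
    cross-section by rejection against its forward-direction maximum."""
    alpha = energy / ELECTRON_REST_KEV
    while True:
        c = rng.uniform(-1.0, 1.0)
        r = 1.0 / (1.0 + alpha * (1.0 - c))
        val = r * r * (r + 1.0 / r - (1.0 - c * c))
        if rng.random() * 2.0 <= val:
            return c


def sample_compton_split(energy: float, rng):
    """Split an incident energy into (deposited, scattered) by a Compton
    scatter with a Klein--Nishina-sampled angle.  Energy is conserved
    exactly: deposited + scattered = energy."""
    if energy <= 0:
        raise ValueError("energy must be > 0")
    c = _klein_nishina_cos(energy, rng)
    scattered = energy / (1.0 + energy / ELECTRON_REST_KEV * (1.0 - c))
    return energy - scattered, scattered


def classify_history(history: PhotonHistory):
    """Provenance tags (emission energy, transport class) used to split
    spectra into components; unknown classes map to "other"."""
    cls = history.transport_class
    if cls not in TRANSPORT_CLASSES:
        cls = "other"
    return history.emission_energy, cls


# ---------------------------------------------------------------------------
# Synthetic generator.

def _sample_lateral_primary(source: SourceSpec, crystal: CrystalSpec,
                            anodes: AnodeArraySpec,
                            collimator: CollimatorSpec, energy: float,
                            rng) -> np.ndarray:
    """Lateral position of a collimated primary: uniform over the source
    disc projection, thinned by the collimator transmission."""
    rmax = min(source.source_radius,
               min(crystal.width_x, crystal.width_y) / 2.0)
    for _ in range(10000):
        r = rmax * np.sqrt(rng.random())
        a = rng.uniform(0.0, 2.0 * np.pi)
        xy = np.array([r * np.cos(a), r * np.sin(a)])
        t = collimator_transmission(xy, collimator, energy, anodes,
                                    source.penetration_factor)
        if rng.random() < t:
            return xy
    raise RuntimeError("collimator transmission rejected all samples")


def generate_listmode(source: SourceSpec, crystal: CrystalSpec,
                      anodes: AnodeArraySpec, collimator: CollimatorSpec,
                      n_histories: int, seed: int) -> list:
    """Generate synthetic photon histories.

    Per history: an emission line is chosen by intensity and a transport
    class by the configured mixture; the lateral position is drawn from the
    source-disc projection thinned by the collimator transmission for
    geometric primaries and near-uniformly over the crystal for the
    penetration/scatter/x-ray classes; the interaction depth follows a
    truncated exponential at the incident energy's attenuation coefficient;
    the chain is a single photoabsorption with probability
    ``photo_fraction``, otherwise a Compton split whose scattered photon
    either escapes or is absorbed at a second sampled position.  All
    weights are 1.  Deterministic for a fixed seed.
    """
    if n_histories < 0:
        raise ValueError("n_histories must be >= 0")
    rng = np.random.default_rng(seed)
    energies = np.array([e for e, _ in source.lines])
    intens = np.array([y for _, y in source.lines], dtype=float)
    intens = intens / intens.sum()

    half_x = crystal.width_x / 2.0
    half_y = crystal.width_y / 2.0
    histories = []
    for hid in range(n_histories):
        line = float(rng.choice(energies, p=intens))
        mix = source.mixture_for(line)
        classes = list(mix)
        cls = str(rng.choice(classes, p=[mix[c] for c in classes]))

        if cls == "collimator_xray":
            incident = source.xray_energy
        elif cls in ("phantom_scatter", "collimator_scatter"):
            _, incident = sample_compton_split(line, rng)
        else:
            incident = line

        if cls == "geometric_primary":
            xy = _sample_lateral_primary(source, crystal, anodes,
                                         collimator, incident, rng)
        else:
            xy = np.array([rng.uniform(-half_x, half_x),
                           rng.uniform(-half_y, half_y)])

        mu = source.mu_at(incident)
        z = float(sample_interaction_depth(incident, mu, crystal.thickness,
                                           rng))
        r1 = np.array([xy[0], xy[1], z])

        events = []
        if rng.random() < source.photo_fraction:
            events.append(InteractionEvent("photoelectric", r1, incident))
        else:
            dep, scat = sample_compton_split(incident, rng)
            events.append(InteractionEvent("compton", r1, dep))
            if scat > 0 and rng.random() >= source.escape_fraction:
                cth = rng.uniform(-1.0, 1.0)
                sth = np.sqrt(1.0 - cth * cth)
                aph = rng.uniform(0.0, 2.0 * np.pi)
                step = rng.exponential(1.0 / source.mu_at(max(scat, 1.0)))
                r2 = r1 + step * np.array([sth * np.cos(aph),
                                           sth * np.sin(aph), cth])
                inside = (abs(r2[0]) <= half_x and abs(r2[1]) <= half_y
                          and 0.0 <= r2[2] <= crystal.thickness)
                if inside:
                    events.append(InteractionEvent("photoelectric", r2, scat))
        histories.append(PhotonHistory(hid, events, line, cls))
    return histories
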