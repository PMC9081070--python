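"""Full detector model: histories + CIE map -> per-anode spectra and images.

Each of the 16 x 16 anode elements carries the same joint CIE map,
translated to its own centre.  For every photon history the per-anode
response is the CIE-weighted sum of the deposited energies; the anode with
the largest response wins the history and records one count (scaled by the
photon weight) in its spectrum.  The initial spectra are then re-sampled
under a linear energy calibration (count-conserving re-binning) and blurred
with an energy-dependent Gaussian resolution FWHM(E) = b0 + b1 E; the
calibration is determined iteratively so the photopeaks sit at the emission
energies *after* the resolution step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.special import ndtr

from .geometry import CrystalSpec, AnodeArraySpec
from .cie import CIEMap

__all__ = [
    "N_BINS", "BIN_WIDTH", "DetectorModel", "SpectrumTable",
    "EnergyCalibration", "ResolutionModel", "EnergyWindow",
    "DEFAULT_WINDOWS", "DEFAULT_RESOLUTION", "CalibrationError",
    "eval_cie", "respond_history", "select_winner", "accumulate_spectra",
    "apply_calibration", "apply_resolution", "calibrate", "sum_spectra",
    "form_image", "component_spectra", "sensitivity",
    "fit_sensitivity_curve",
]

#: The camera's native spectrum axis: 0--250 keV in 0.1 keV bins.
N_BINS = 2500
BIN_WIDTH = 0.1
_EDGES = np.arange(N_BINS + 1) * BIN_WIDTH
_CENTRES = _EDGES[:-1] + BIN_WIDTH / 2.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class CalibrationError(RuntimeError):
    """A photopeak could not be located in its search window."""


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear energy calibration E_corr = a0 + a1 * E_init."""

    a0: float = 0.0   # keV
    a1: float = 1.0

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("a1 must be > 0")


@dataclass(frozen=True)
class ResolutionModel:
    """Energy-dependent Gaussian blur, FWHM(E) = b0 + b1 * E."""

    b0: float = 5.64      # keV
    b1: float = 0.00751

    def __post_init__(self) -> None:
        if self.b0 + self.b1 * 0.0 < 0 or self.b0 + self.b1 * 250.0 < 0:
            raise ValueError("FWHM must be >= 0 over the operating range")

    def fwhm(self, energy) -> float:
        return self.b0 + self.b1 * np.asarray(energy, dtype=float)


DEFAULT_RESOLUTION = ResolutionModel()


@dataclass(frozen=True)
class EnergyWindow:
    label: str
    low: float    # keV
    high: float   # keV

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window low must be < high")


#: Standard acquisition windows over the 177Lu photopeaks.
DEFAULT_WINDOWS = {
    "55": EnergyWindow("55", 49.7, 59.7),
    "113": EnergyWindow("113", 100.5, 120.8),
    "208": EnergyWindow("208", 193.8, 216.7),
}


@dataclass
class SpectrumTable:
    """Per-anode weighted count spectra in the camera's table format:
    one row per anode (flat index iy * n_x + ix), 2500 bins of 0.1 keV."""

    counts: np.ndarray          # (n_anodes, N_BINS)
    n_x: int = 16
    n_y: int = 16
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_x * self.n_y, N_BINS):
            raise ValueError("counts must have shape (n_anodes, 2500)")
        if self.counts.min() < 0:
            raise ValueError("counts must be >= 0")

    def copy_with(self, counts: np.ndarray) -> "SpectrumTable":
        return SpectrumTable(counts, self.n_x, self.n_y, dict(self.metadata))

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cztcam-spectra v1\n")
            fh.write(f"# anodes {self.n_x} {self.n_y}\n")
            fh.write(f"# bins {N_BINS} {BIN_WIDTH}\n")
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# meta {k} {v}\n")
            np.savetxt(fh, self.counts, fmt="%.10g")

    @classmethod
    def from_text(cls, path) -> "SpectrumTable":
        meta = {}
        n_x = n_y = 16
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                parts = ln[1:].split()
                if parts[:1] == ["anodes"]:
                    n_x, n_y = int(parts[1]), int(parts[2])
                elif parts[:1] == ["meta"]:
                    try:
                        meta[parts[1]] = float(parts[2])
                    except ValueError:
                        meta[parts[1]] = parts[2]
            elif ln.strip():
                body.append(ln)
        counts = np.loadtxt(body, ndmin=2)
        return cls(counts, n_x, n_y, meta)


@dataclass
class DetectorModel:
    """Anode array plus the joint CIE map and the low-energy threshold."""

    crystal: CrystalSpec
    anodes: AnodeArraySpec
    cie: CIEMap
    threshold: float = 40.0   # keV, applied to E_out before recording

    def __post_init__(self) -> None:
        self.anode_centres = self.anodes.centres()
        m = self.cie
        self._origin = np.array([m.x[0], m.y[0], m.z[0]])
        self._steps = np.array([
            m.x[1] - m.x[0] if m.x.size > 1 else 1.0,
            m.y[1] - m.y[0] if m.y.size > 1 else 1.0,
            m.z[1] - m.z[0] if m.z.size > 1 else 1.0,
        ])

    @property
    def n_anodes(self) -> int:
        return self.anodes.n_x * self.anodes.n_y

    def _lookup(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the joint map at map-local points
        (M, 3); outside the map's extent the CIE is zero."""
        idx = (pts - self._origin) / self._steps
        return map_coordinates(self.cie.values, idx.T, order=1,
                               mode="constant", cval=0.0, prefilter=False)


def eval_cie(model: DetectorModel, anode_k: int, point) -> float | np.ndarray:
    """CIE of anode k at a crystal-frame point: the joint map translated to
    the anode's centre, trilinearly interpolated; zero beyond the map's
    lateral extent (an anode several pitches away is insensitive)."""
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    ck = model.anode_centres[anode_k]
    local = pt - np.array([ck[0], ck[1], 0.0])
    out = model._lookup(local)
    return float(out[0]) if np.asarray(point).ndim == 1 else out


def respond_history(model: DetectorModel, history) -> np.ndarray:
    """Per-anode response E_out,k = sum_i eta_k(r_i) E_i over the history's
    events, in keV (unweighted; the photon weight scales the count)."""
    if not history.events:
        return np.zeros(model.n_anodes)
    pos = np.array([ev.position for ev in history.events])       # (m, 3)
    en = np.array([ev.deposited_energy for ev in history.events])
    centres = np.concatenate(
        [model.anode_centres, np.zeros((model.n_anodes, 1))], axis=1)
    pts = pos[np.newaxis, :, :] - centres[:, np.newaxis, :]      # (K, m, 3)
    eta = model._lookup(pts.reshape(-1, 3)).reshape(model.n_anodes, -1)
    return eta @ en


def select_winner(e_out: np.ndarray, threshold: float):
    """The anode with the largest response wins the history; ties go to the
    lowest anode index.  Below the threshold the history is undetected and
    None is returned."""
    k = int(np.argmax(e_out))     # argmax returns the first (lowest) index
    if e_out[k] < threshold:
        return None
    return k, float(e_out[k])


def _gather_events(histories):
    hist_idx, pos, en, hw = [], [], [], []
    n_hist = 0
    for h in histories:
        if not h.events:
            continue
        for ev in h.events:
            hist_idx.append(n_hist)
            pos.append(ev.position)
            en.append(ev.deposited_energy)
        hw.append(h.events[0].weight)
        n_hist += 1
    if n_hist == 0:
        return 0, None, None, None, None
    return (n_hist, np.asarray(hist_idx), np.asarray(pos, dtype=float),
            np.asarray(en, dtype=float), np.asarray(hw, dtype=float))


def accumulate_spectra(model: DetectorModel, histories,
                       metadata: dict | None = None) -> SpectrumTable:
    """Initial (uncalibrated) spectrum table from a history stream.

    Vectorised equivalent of respond_history + select_winner per history:
    only anodes whose translated map can overlap an event are evaluated.
    Each detected history contributes exactly its weight, once, to the
    winning anode's spectrum at bin floor(E_out / 0.1 keV).
    """
    K = model.n_anodes
    n_hist, hist_idx, pos, en, hw = _gather_events(histories)
    counts = np.zeros((K, N_BINS))
    meta = dict(metadata or {})
    if n_hist == 0:
        return SpectrumTable(counts, model.anodes.n_x, model.anodes.n_y, meta)

    nxa, nya = model.anodes.n_x, model.anodes.n_y
    pitch = model.anodes.pitch
    ex = max(abs(model.cie.x[0]), abs(model.cie.x[-1]),
             abs(model.cie.y[0]), abs(model.cie.y[-1]))
    no = int(np.floor(ex / pitch + 0.5)) + 1
    offs = np.arange(-no, no + 1)

    ix0 = np.round(pos[:, 0] / pitch + (nxa - 1) / 2.0).astype(int)
    iy0 = np.round(pos[:, 1] / pitch + (nya - 1) / 2.0).astype(int)

    keys_all, contrib_all = [], []
    doff_x, doff_y = np.meshgrid(offs, offs, indexing="ij")
    for dx, dy in zip(doff_x.ravel(), doff_y.ravel()):
        ix = ix0 + dx
        iy = iy0 + dy
        valid = (ix >= 0) & (ix < nxa) & (iy >= 0) & (iy < nya)
        if not np.any(valid):
            continue
        cx = (ix[valid] - (nxa - 1) / 2.0) * pitch
        cy = (iy[valid] - (nya - 1) / 2.0) * pitch
        pts = np.column_stack([pos[valid, 0] - cx, pos[valid, 1] - cy,
                               pos[valid, 2]])
        eta = model._lookup(pts)
        nz = eta > 0
        if not np.any(nz):
            continue
        v = np.nonzero(valid)[0][nz]
        k_flat = iy[v] * nxa + ix[v]
        keys_all.append(hist_idx[v].astype(np.int64) * K + k_flat)
        contrib_all.append(eta[nz] * en[v])

    if not keys_all:
        return SpectrumTable(counts, nxa, nya, meta)
    keys = np.concatenate(keys_all)
    contrib = np.concatenate(contrib_all)
    uniq, inv = np.unique(keys, return_inverse=True)
    sums = np.bincount(inv, weights=contrib)
    hist_of = (uniq // K).astype(int)
    anode_of = (uniq % K).astype(int)

    best = np.zeros(n_hist)
    np.maximum.at(best, hist_of, sums)
    is_best = sums == best[hist_of]
    winner = np.full(n_hist, K, dtype=int)
    np.minimum.at(winner, hist_of[is_best], anode_of[is_best])

    detected = (best >= model.threshold) & (winner < K)
    e_win = best[detected]
    bins = np.minimum((e_win / BIN_WIDTH).astype(int), N_BINS - 1)
    np.add.at(counts, (winner[detected], bins), hw[detected])
    return SpectrumTable(counts, nxa, nya, meta)


# ---------------------------------------------------------------------------
# Spectrum post-processing.

def _as_counts(spectrum):
    if isinstance(spectrum, SpectrumTable):
        return spectrum.counts, spectrum
    return np.asarray(spectrum, dtype=float), None


def apply_calibration(spectrum, cal: EnergyCalibration):
    """Re-sample counts onto the fixed 0.1 keV axis under
    E_corr = a0 + a1 E_init, conserving counts by fractional redistribution
    (counts mapped outside 0--250 keV are lost)."""
    counts, table = _as_counts(spectrum)
    arr = np.atleast_2d(counts)
    cum = np.concatenate(
        [np.zeros(arr.shape[:-1] + (1,)), np.cumsum(arr, axis=-1)], axis=-1)
    # Source-axis positions of the destination bin edges.
    s = (_EDGES - cal.a0) / cal.a1
    si = np.clip(s / BIN_WIDTH, 0.0, N_BINS)
    i0 = np.minimum(si.astype(int), N_BINS - 1)
    frac = si - i0
    cum_at = cum[..., i0] + frac * (cum[..., i0 + 1] - cum[..., i0])
    out = np.diff(cum_at, axis=-1)
    out = np.clip(out, 0.0, None)
    out = out.reshape(counts.shape)
    return table.copy_with(out) if table is not None else out


@lru_cache(maxsize=8)
def _resolution_matrix(b0: float, b1: float) -> sp.csr_matrix:
    """Sparse (source bin -> destination bin) Gaussian smearing matrix,
    renormalised per source bin within the 0--250 keV axis."""
    sigma = (b0 + b1 * _CENTRES) * _FWHM_TO_SIGMA
    tiny = sigma < 1e-9
    smax = sigma.max() if sigma.size else 0.0
    if smax < 1e-9:
        return sp.identity(N_BINS, format="csr")
    w = int(np.ceil(5.0 * smax / BIN_WIDTH)) + 1
    offs = np.arange(-w, w + 1)
    src = np.arange(N_BINS)
    dest = src[:, None] + offs[None, :]
    valid = (dest >= 0) & (dest < N_BINS) & ~tiny[:, None]
    sig = np.where(tiny, 1.0, sigma)[:, None]
    edges = (src[:, None] + np.arange(-w, w + 2)[None, :]) * BIN_WIDTH
    wgt = np.diff(ndtr((edges - _CENTRES[:, None]) / sig), axis=1)
    wgt = np.where(valid, wgt, 0.0)
    norm = wgt.sum(axis=1, keepdims=True)
    # Rows whose Gaussian falls entirely outside keep their counts in place.
    degenerate = norm[:, 0] <= 0
    wgt = np.where(norm > 0, wgt / np.where(norm > 0, norm, 1.0), 0.0)
    rows = np.repeat(src, offs.size)
    cols = dest.ravel()
    mask = valid.ravel() & (wgt.ravel() > 0)
    M = sp.coo_matrix((wgt.ravel()[mask], (rows[mask], cols.ravel()[mask])),
                      shape=(N_BINS, N_BINS)).tocsr()
    ident_rows = np.nonzero(tiny | degenerate)[0]
    if ident_rows.size:
        M = M + sp.coo_matrix(
            (np.ones(ident_rows.size), (ident_rows, ident_rows)),
            shape=(N_BINS, N_BINS)).tocsr()
    return M


def apply_resolution(spectrum, res: ResolutionModel):
    """Gaussian smoothing with sigma(E) = FWHM(E)/2.3548 centred on each
    source bin, count-conserving within the axis."""
    counts, table = _as_counts(spectrum)
    M = _resolution_matrix(float(res.b0), float(res.b1))
    out = (sp.csr_matrix(np.atleast_2d(counts)) @ M).toarray()
    out = out.reshape(counts.shape)
    return table.copy_with(out) if table is not None else out


def _peak_centroid(spec: np.ndarray, expected: float, half_window: float,
                   label: str) -> float:
    """Peak position by a parabolic fit to the log of the three bins around
    the local maximum inside ``expected +- half_window``."""
    lo = max(int((expected - half_window) / BIN_WIDTH), 1)
    hi = min(int((expected + half_window) / BIN_WIDTH) + 1, N_BINS - 1)
    if hi <= lo:
        raise CalibrationError(f"empty search window for peak {label}")
    seg = spec[lo:hi]
    if seg.max() <= 0:
        raise CalibrationError(f"peak {label} not found: no counts in "
                               f"[{expected - half_window:.1f}, "
                               f"{expected + half_window:.1f}] keV")
    b = lo + int(np.argmax(seg))
    y = spec[b - 1:b + 2]
    if np.all(y > 0):
        ly = np.log(y)
        denom = ly[0] - 2 * ly[1] + ly[2]
    else:
        denom = y[0] - 2 * y[1] + y[2]
        ly = y
    if denom >= 0 or not np.isfinite(denom):
        delta = 0.0
    else:
        delta = 0.5 * (ly[0] - ly[2]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    return _CENTRES[b] + delta * BIN_WIDTH


def calibrate(model, spectrum, peak_energies, res: ResolutionModel,
              initial: EnergyCalibration | None = None,
              max_iter: int = 20, tol: float = 0.05) -> EnergyCalibration:
    """Determine (a0, a1) so the photopeaks sit at ``peak_energies`` after
    the resolution step.

    Fixed-point iteration: apply the current calibration and the
    resolution, locate each photopeak centroid within +-max(2 keV,
    FWHM(E_p)) of its nominal energy, and least-squares update (a0, a1)
    mapping the implied uncalibrated positions onto the true energies;
    converged when the largest centroid shift is below ``tol`` (keV).  With
    a single peak a0 is held at 0.  When no initial calibration is given,
    the gain is bootstrapped from the highest-energy peak located in a wide
    fractional window.

    ``spectrum`` may be a SpectrumTable (the central-14x14 anode sum is
    used) or a plain summed spectrum; ``model`` is accepted for interface
    symmetry and may be None.
    """
    peaks = sorted(float(p) for p in peak_energies)
    if not peaks:
        raise ValueError("at least one peak energy is required")
    if isinstance(spectrum, SpectrumTable):
        s0 = sum_spectra(spectrum, "central")
    else:
        s0 = np.asarray(spectrum, dtype=float)

    cal = initial
    if cal is None:
        # Bootstrap the gain from the highest peak: tailing shifts peaks
        # down, so search a generous downward window.
        e_top = peaks[-1]
        blurred = apply_resolution(s0, res)
        c = _peak_centroid(blurred, 0.825 * e_top, 0.275 * e_top,
                           f"{e_top:.1f} keV (bootstrap)")
        cal = EnergyCalibration(0.0, e_top / c)

    for _ in range(max_iter):
        s = apply_resolution(apply_calibration(s0, cal), res)
        found = []
        for p in peaks:
            hw = max(2.0, float(res.fwhm(p)))
            found.append(_peak_centroid(s, p, hw, f"{p:.1f} keV"))
        found = np.asarray(found)
        if np.max(np.abs(found - peaks)) < tol:
            break
        x = (found - cal.a0) / cal.a1
        if len(peaks) == 1:
            cal = EnergyCalibration(0.0, peaks[0] / x[0])
        else:
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, np.asarray(peaks), rcond=None)
            cal = EnergyCalibration(float(coef[0]), float(coef[1]))
    return cal


def align_peaks(spectrum, peak_energies, res: ResolutionModel,
                max_iter: int = 10, tol: float = 0.05) -> EnergyCalibration:
    """Linear calibration aligning the photopeaks of an *already blurred*
    spectrum (e.g. a measured reference) with their nominal energies.

    Unlike :func:`calibrate`, no resolution step is applied: the centroids
    are located directly, so spectra that already contain the detector
    resolution are not blurred twice.  ``res`` only sets the search-window
    widths.
    """
    peaks = sorted(float(p) for p in peak_energies)
    s0 = np.asarray(spectrum, dtype=float)
    cal = EnergyCalibration()
    for _ in range(max_iter):
        s = apply_calibration(s0, cal)
        found = np.array([
            _peak_centroid(s, p, max(2.0, float(res.fwhm(p))), f"{p:.1f} keV")
            for p in peaks])
        if np.max(np.abs(found - peaks)) < tol:
            break
        x = (found - cal.a0) / cal.a1
        if len(peaks) == 1:
            cal = EnergyCalibration(0.0, peaks[0] / x[0])
        else:
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, np.asarray(peaks), rcond=None)
            cal = EnergyCalibration(float(coef[0]), float(coef[1]))
    return cal


# ---------------------------------------------------------------------------
# Selections, images, components, sensitivity.

def _selection_indices(table: SpectrumTable, selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "all":
            return np.arange(table.counts.shape[0])
        if selection == "central":
            ix, iy = np.meshgrid(np.arange(table.n_x), np.arange(table.n_y),
                                 indexing="xy")
            keep = ((ix >= 1) & (ix <= table.n_x - 2)
                    & (iy >= 1) & (iy <= table.n_y - 2))
            return (iy[keep] * table.n_x + ix[keep]).ravel()
        raise ValueError(f"unknown selection {selection!r}")
    sel = np.asarray(selection)
    if sel.dtype == bool:
        return np.nonzero(sel)[0]
    return sel.astype(int)


def sum_spectra(table: SpectrumTable, selection="all") -> np.ndarray:
    """Bin-wise sum over the selected anodes ("all", "central" for the
    central 14 x 14 block, or explicit indices/mask)."""
    idx = _selection_indices(table, selection)
    if idx.size == 0:
        return np.zeros(N_BINS)
    return table.counts[idx].sum(axis=0)


def _window_mask(window: EnergyWindow) -> np.ndarray:
    return (_CENTRES >= window.low) & (_CENTRES < window.high)


def form_image(table: SpectrumTable, window: EnergyWindow) -> np.ndarray:
    """(n_y, n_x) image: each pixel integrates its anode's counts within
    the energy window."""
    m = _window_mask(window)
    return table.counts[:, m].sum(axis=1).reshape(table.n_y, table.n_x)


def component_spectra(model: DetectorModel, histories,
                      splitter: str = "transport_class") -> dict:
    """Spectra split by provenance tag (emission energy or transport
    class).  Winner selection runs on the full histories; the components
    sum to the total spectrum bin by bin."""
    if splitter not in ("emission_energy", "transport_class"):
        raise ValueError("splitter must be emission_energy or "
                         "transport_class")
    groups: dict = {}
    for h in histories:
        tag = (h.emission_energy if splitter == "emission_energy"
               else h.transport_class)
        groups.setdefault(tag, []).append(h)
    return {tag: accumulate_spectra(model, hs) for tag, hs in groups.items()}


def sensitivity(table: SpectrumTable, window: EnergyWindow) -> float:
    """Windowed full-FOV count rate per activity, counts/s/MBq."""
    try:
        act = float(table.metadata["activity"])
        dur = float(table.metadata["duration"])
    except KeyError as exc:
        raise ValueError("table metadata must include activity (MBq) and "
                         "duration (s)") from exc
    m = _window_mask(window)
    return float(table.counts[:, m].sum() / (dur * act))


def fit_sensitivity_curve(distances, sensitivities):
    """Fit s(d) = c0 + c1 exp(-c2 d) with c2 >= 0 constrained.

    Needs at least four distance points.  When the data are explained
    equally well without the exponential term (c1 = 0 degeneracy), the
    flat solution with c2 = 0 is returned (lower-bound tie rule).
    """
    d = np.asarray(distances, dtype=float)
    s = np.asarray(sensitivities, dtype=float)
    if d.size < 4:
        raise ValueError("at least 4 distance points are required")

    def f(x, c0, c1, c2):
        return c0 + c1 * np.exp(-c2 * x)

    span = np.ptp(s)
    p0 = (float(s.min()), float(span) if span > 0 else 1.0, 0.02)
    try:
        popt, _ = curve_fit(f, d, s, p0=p0,
                            bounds=([-np.inf, -np.inf, 0.0],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sensitivity fit did not converge: {exc}") from exc
    res_fit = float(np.sum((f(d, *popt) - s) ** 2))
    res_flat = float(np.sum((s - s.mean()) ** 2))
    if res_flat <= res_fit * (1 + 1e-9) + 1e-18:
        return float(s.mean()), 0.0, 0.0
    return float(popt[0]), float(popt[1]), float(popt[2])
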