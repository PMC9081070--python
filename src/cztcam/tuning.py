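"""Model tuning: spectrum agreement and the nested simplex optimisation.

Agreement between a simulated and a reference spectrum over a comparison
window W is scored as

    D = sum_W (f * S_sim - S_ref)^2 / (sum_W S_ref)^2,

with the scale factor f fixed to unity for collimated acquisitions and
free (closed-form least squares) for open-field ones, and D_tot the sum
over spectrum pairs.  The energy-resolution parameters (b0, b1) are
optimised in an inner downhill-simplex loop for each candidate CIE map,
and the CIE parameters themselves in an outer simplex loop; the eight
boundary-condition configurations (A1/A3 x B1/B2 x C1/C2) are tuned
independently and ranked by their best D_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np
from scipy.optimize import minimize

from .geometry import CrystalSpec, AnodeArraySpec
from .fields import FieldConfig
from .cie import CarrierParams, compute_cie_map
from .detector import (
    DetectorModel, SpectrumTable, ResolutionModel, EnergyCalibration,
    accumulate_spectra, apply_calibration, apply_resolution, calibrate,
    align_peaks, sum_spectra, DEFAULT_RESOLUTION,
)

__all__ = [
    "SpectrumPair", "TuningConfiguration", "TuningDataset", "TuningInputs",
    "TuningResult", "ALL_CONFIGURATIONS", "agreement", "total_agreement",
    "comparison_window", "optimize_resolution", "optimize_cie", "run_tuning",
]

from .detector import N_BINS, BIN_WIDTH

_CENTRES = (np.arange(N_BINS) + 0.5) * BIN_WIDTH

#: Initial estimates for the energy-resolution parameters (keV, -).
RESOLUTION_INIT = (5.64, 0.00751)

#: Finite score for failed/invalid candidates (keeps the simplex numerics
#: clean where an infinity would propagate NaNs in its convergence test).
PENALTY = 1e300

#: Fixed hole mobility used when the hole mu*tau product is tuned, cm^2/(V s).
HOLE_MOBILITY = 80.0

# Tunable-parameter defaults and bounds per boundary-condition alternative.
PARAM_INIT = {"a3_weight": 0.5, "b2_power": 2.0, "b2_scale": 0.8,
              "mu_e": 1000.0, "tau_e": 3.0, "mutau_h": 4e-5}
PARAM_BOUNDS = {"a3_weight": (0.0, 1.0), "b2_power": (0.5, 8.0),
                "b2_scale": (0.2, 1.0), "mu_e": (300.0, 2000.0),
                "tau_e": (0.1, 20.0), "mutau_h": (1e-6, 1e-3)}


@dataclass
class SpectrumPair:
    """One simulated/reference spectrum pair on the common 0.1 keV axis."""

    sim: np.ndarray
    ref: np.ndarray
    window: tuple          # (low, high) keV
    f_mode: str = "fixed_unity"   # {fixed_unity, free}
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if self.sim.shape != self.ref.shape:
            raise ValueError("sim and ref spectra must share one axis")
        if self.f_mode not in ("fixed_unity", "free"):
            raise ValueError("f_mode must be fixed_unity or free")
        if self.f_mode == "fixed_unity":
            self.scale_factor = 1.0


def agreement(pair: SpectrumPair) -> float:
    """Squared-deviation agreement score D over the pair's window.

    With a free scale factor, f is set to its closed-form least-squares
    optimum sum(sim*ref)/sum(sim^2) before evaluation (and recorded on the
    pair); f never increases D relative to f = 1.
    """
    lo, hi = pair.window
    m = (_CENTRES >= lo) & (_CENTRES < hi)
    if not np.any(m):
        raise ValueError("comparison window outside the energy axis")
    sim = pair.sim[m]
    ref = pair.ref[m]
    denom = ref.sum()
    if denom <= 0:
        raise ValueError("reference spectrum has zero counts in the window")
    if pair.f_mode == "free":
        ss = float(np.sum(sim * sim))
        pair.scale_factor = float(np.sum(sim * ref) / ss) if ss > 0 else 1.0
    f = pair.scale_factor
    return float(np.sum((f * sim - ref) ** 2) / denom ** 2)


def total_agreement(pairs) -> float:
    """D_tot: plain sum of the per-pair scores."""
    return float(sum(agreement(p) for p in pairs))


def comparison_window(lines, threshold: float,
                      res: ResolutionModel = DEFAULT_RESOLUTION) -> tuple:
    """Comparison interval covering the emitter's lines and the detector's
    operational range: [max(threshold, E_min - 3 FWHM(E_min)),
    min(250, E_max + 3 FWHM(E_max))]."""
    lines = sorted(float(e) for e in lines)
    if not lines:
        raise ValueError("at least one emission line is required")
    lo = max(threshold, lines[0] - 3.0 * float(res.fwhm(lines[0])))
    hi = min(250.0, lines[-1] + 3.0 * float(res.fwhm(lines[-1])))
    if lo >= hi:
        raise ValueError(f"empty comparison window [{lo:.1f}, {hi:.1f}] keV")
    return lo, hi


# ---------------------------------------------------------------------------
# Configurations.

@dataclass(frozen=True)
class TuningConfiguration:
    """One of the eight boundary-condition configurations.

    ``electric`` in {A1, A3} (the pure Laplace alternative A2 enters only
    through A3), ``weighting`` in {B1, B2}, ``signal`` in {C1, C2}.  The
    tunable parameter vector follows from the choices: a3_weight for A3;
    b2_power and b2_scale for B2; mu_e and tau_e always; the hole mu*tau
    product for C2 (hole mobility fixed).
    """

    electric: str
    weighting: str
    signal: str

    def __post_init__(self) -> None:
        if self.electric not in ("A1", "A3"):
            raise ValueError("electric must be A1 or A3")
        if self.weighting not in ("B1", "B2"):
            raise ValueError("weighting must be B1 or B2")
        if self.signal not in ("C1", "C2"):
            raise ValueError("signal must be C1 or C2")

    @property
    def name(self) -> str:
        return f"{self.electric}-{self.weighting}-{self.signal}"

    def param_names(self) -> list:
        names = []
        if self.electric == "A3":
            names.append("a3_weight")
        if self.weighting == "B2":
            names += ["b2_power", "b2_scale"]
        names += ["mu_e", "tau_e"]
        if self.signal == "C2":
            names.append("mutau_h")
        return names

    def initial_params(self) -> dict:
        return {n: PARAM_INIT[n] for n in self.param_names()}

    def bounds(self) -> dict:
        return {n: PARAM_BOUNDS[n] for n in self.param_names()}

    def field_config(self, params: dict) -> FieldConfig:
        return FieldConfig(
            electric_alternative=self.electric,
            a3_weight=params.get("a3_weight", 0.5),
            weighting_alternative=self.weighting,
            b2_power=params.get("b2_power", 2.0),
            b2_scale=params.get("b2_scale", 1.0),
        )

    def carriers(self, params: dict):
        electron = CarrierParams(mobility=params["mu_e"],
                                 lifetime=params["tau_e"],
                                 carrier="electron")
        hole = None
        if self.signal == "C2":
            tau_h_us = params["mutau_h"] / HOLE_MOBILITY * 1e6
            hole = CarrierParams(mobility=HOLE_MOBILITY, lifetime=tau_h_us,
                                 carrier="hole")
        return electron, hole


ALL_CONFIGURATIONS = tuple(
    TuningConfiguration(e, w, s)
    for e, w, s in product(("A1", "A3"), ("B1", "B2"), ("C1", "C2")))


@dataclass
class TuningDataset:
    """One radionuclide-collimator acquisition entering the tuning."""

    histories: list
    reference: SpectrumTable
    window: tuple
    f_mode: str = "fixed_unity"
    label: str = ""
    sim_metadata: dict = dc_field(default_factory=dict)

    @property
    def count_scale(self) -> float:
        """Scale putting the simulation at the reference's activity x
        duration (1 when either acquisition lacks the metadata)."""
        try:
            ref = (float(self.reference.metadata["activity"])
                   * float(self.reference.metadata["duration"]))
            sim = (float(self.sim_metadata["activity"])
                   * float(self.sim_metadata["duration"]))
            return ref / sim
        except (KeyError, ZeroDivisionError):
            return 1.0


@dataclass
class TuningInputs:
    """Everything a tuning run needs besides the configuration."""

    crystal: CrystalSpec
    anodes: AnodeArraySpec
    datasets: list
    calibration_peaks: list
    calibration_dataset: int = 0
    neighbourhood: int = 3
    step: float = 0.205
    threshold: float = 40.0
    use_symmetry: bool = True
    recalibrate_reference: bool = True


@dataclass
class TuningResult:
    configuration: TuningConfiguration
    params: dict
    resolution: tuple
    calibration: tuple
    d_tot_opt: float
    trace: list = dc_field(default_factory=list)
    error: str | None = None


# ---------------------------------------------------------------------------
# Inner loop: energy-resolution optimisation.

def optimize_resolution(pairs_builder, init=RESOLUTION_INIT,
                        maxfev: int = 200):
    """Downhill-simplex (Nelder--Mead) optimisation of (b0, b1).

    ``pairs_builder(b0, b1)`` must rebuild the spectrum pairs (re-applying
    calibration and resolution to the fixed initial spectra) for the
    candidate parameters.  Converges when the relative simplex diameter
    falls below 1e-3 or after ``maxfev`` evaluations.  Returns
    (b0, b1, D_tot_opt).
    """
    b0i, b1i = init
    scale = np.array([b0i if b0i != 0 else 1.0, b1i if b1i != 0 else 1.0])
    n_ok = 0

    def objective(u):
        nonlocal n_ok
        b0, b1 = u * scale
        if b0 < 0 or b0 + b1 * 250.0 <= 0:
            return PENALTY
        try:
            d = total_agreement(pairs_builder(b0, b1))
        except Exception:
            return PENALTY
        n_ok += 1
        return d

    res = minimize(objective, np.ones(2), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-10,
                            "maxfev": maxfev})
    if n_ok == 0:
        raise RuntimeError("all resolution evaluations failed")
    b0, b1 = res.x * scale
    return float(b0), float(b1), float(res.fun)


# ---------------------------------------------------------------------------
# Outer loop: CIE-parameter optimisation.

def _prepare_references(inputs: TuningInputs):
    """Central-anode reference spectra, independently re-calibrated so the
    photopeaks sit at their nominal energies."""
    refs = []
    res0 = ResolutionModel(*RESOLUTION_INIT)
    for ds in inputs.datasets:
        ref = ds.reference
        s = sum_spectra(ref, "central") if isinstance(ref, SpectrumTable) \
            else np.asarray(ref, dtype=float)
        if inputs.recalibrate_reference:
            # References already contain the detector resolution, so the
            # peaks are aligned directly, without re-applying a blur.
            cal = align_peaks(s, inputs.calibration_peaks, res0)
            s = apply_calibration(s, cal)
        refs.append(s)
    return refs


def _score_candidate(config, inputs, params, refs, inner_maxfev,
                     resolution_init):
    """Generate the candidate CIE map, rebuild all spectra, run the inner
    resolution loop; returns (d_opt, (b0, b1), (a0, a1))."""
    field_cfg = config.field_config(params)
    electron, hole = config.carriers(params)
    cmap = compute_cie_map(inputs.crystal, inputs.anodes, field_cfg,
                           electron=electron, hole=hole,
                           signal_mode=config.signal,
                           neighbourhood=inputs.neighbourhood,
                           step=inputs.step,
                           use_symmetry=inputs.use_symmetry)
    model = DetectorModel(inputs.crystal, inputs.anodes, cmap,
                          threshold=inputs.threshold)
    init_sums = []
    for ds in inputs.datasets:
        table = accumulate_spectra(model, ds.histories,
                                   metadata=ds.sim_metadata)
        init_sums.append(sum_spectra(table, "central"))
    cal_src = init_sums[inputs.calibration_dataset]
    last_cal = {}

    def pairs_builder(b0, b1):
        res = ResolutionModel(b0, b1)
        cal = calibrate(None, cal_src, inputs.calibration_peaks, res)
        last_cal["cal"] = cal
        pairs = []
        for s0, ds, ref_s in zip(init_sums, inputs.datasets, refs):
            sim = apply_resolution(apply_calibration(s0, cal), res)
            sim = sim * ds.count_scale
            pairs.append(SpectrumPair(sim, ref_s, ds.window, ds.f_mode))
        return pairs

    b0, b1, d = optimize_resolution(pairs_builder, resolution_init,
                                    inner_maxfev)
    cal = last_cal.get("cal", EnergyCalibration())
    return d, (b0, b1), (cal.a0, cal.a1)


def optimize_cie(config: TuningConfiguration, inputs: TuningInputs,
                 init_params: dict | None = None,
                 bounds: dict | None = None,
                 maxfev: int = 40, inner_maxfev: int = 80,
                 resolution_init=RESOLUTION_INIT) -> TuningResult:
    """Outer simplex over the configuration's CIE parameters.

    Every candidate regenerates the CIE map, rebuilds the initial spectra,
    re-determines the energy calibration and runs the inner resolution
    optimisation; the candidate score is that D_tot_opt.  A failed CIE
    generation scores +inf (logged) and the optimisation continues.  The
    full (params, score) trace is recorded.
    """
    refs = _prepare_references(inputs)
    names = config.param_names()
    init = dict(config.initial_params(), **(init_params or {}))
    bnds = dict(config.bounds(), **(bounds or {}))
    x0 = np.array([init[n] for n in names])
    scale = np.where(x0 != 0, np.abs(x0), 1.0)
    lo = np.array([bnds[n][0] for n in names]) / scale
    hi = np.array([bnds[n][1] for n in names]) / scale

    trace = []
    best = {"d": np.inf, "params": dict(init), "res": resolution_init,
            "cal": (0.0, 1.0)}

    def objective(u):
        u = np.clip(u, lo, hi)
        params = {n: float(v) for n, v in zip(names, u * scale)}
        try:
            d, res_opt, cal_opt = _score_candidate(
                config, inputs, params, refs, inner_maxfev, resolution_init)
        except Exception as exc:
            trace.append({"params": params, "d_tot_opt": np.inf,
                          "error": str(exc)})
            return PENALTY
        trace.append({"params": params, "d_tot_opt": d})
        if d < best["d"]:
            best.update(d=d, params=params, res=res_opt, cal=cal_opt)
        return d

    minimize(objective, x0 / scale, method="Nelder-Mead",
             bounds=list(zip(lo, hi)),
             options={"xatol": 1e-3, "fatol": 1e-10, "maxfev": maxfev})
    if not np.isfinite(best["d"]):
        return TuningResult(config, dict(init), resolution_init, (0.0, 1.0),
                            np.inf, trace, error="all candidates failed")
    return TuningResult(config, best["params"], best["res"], best["cal"],
                        best["d"], trace)


def run_tuning(configurations, inputs: TuningInputs, **kwargs) -> list:
    """Tune every configuration independently and rank by D_tot_opt
    (failed configurations rank last, carrying their error)."""
    results = []
    for config in configurations:
        try:
            results.append(optimize_cie(config, inputs, **kwargs))
        except Exception as exc:
            results.append(TuningResult(config, {}, RESOLUTION_INIT,
                                        (0.0, 1.0), np.inf, [],
                                        error=str(exc)))
    results.sort(key=lambda r: (not np.isfinite(r.d_tot_opt), r.d_tot_opt))
    return results
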