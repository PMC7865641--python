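"""Real-time label-free binding curves and 1:1 Langmuir kinetics.

A single-wavelength movie of the chip under sequential analyte injections is
turned into per-probe sensorgrams: per frame, spot and local-background
intensities are converted to mass change around the four-color operating
point, the background is subtracted, and identical replicate spots are
averaged.  Specificity is then judged injection by injection, and a 1:1
Langmuir model

    dGamma/dt = k_on * C * (Gamma_max - Gamma) - k_off * Gamma

can be fitted to any curve with at least one association and one dissociation
phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from . import optics
from .optics import ChipCalibration, OpticsConfig, ReflectanceLUT, ThicknessFit


class NoBindingSignalError(RuntimeError):
    """Curve is flat: no identifiable binding signal."""


class DriftError(RuntimeError):
    """Frame-to-frame drift too large and re-registration failed."""


# --------------------------------------------------------------------------
# injection schedule


@dataclass(frozen=True)
class Phase:
    """One contiguous phase of the fluidic program."""

    label: str
    analyte: str  # "" for wash
    concentration_m: float
    start_s: float
    duration_s: float
    flow_ul_min: float = 200.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def is_wash(self) -> bool:
        return self.concentration_m == 0.0


@dataclass
class InjectionSchedule:
    """Ordered, contiguous, non-overlapping phases."""

    phases: list[Phase]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        t = self.phases[0].start_s
        for ph in self.phases:
            if ph.concentration_m < 0:
                raise ValueError("concentrations must be >= 0")
            if ph.duration_s <= 0:
                raise ValueError("phase durations must be positive")
            if abs(ph.start_s - t) > 1e-9:
                raise ValueError("phases must be contiguous and non-overlapping")
            if ph.is_wash and ph.analyte not in ("", "wash"):
                pass  # a wash may carry a label; concentration 0 defines it
            t = ph.end_s

    @property
    def injections(self) -> list[Phase]:
        return [p for p in self.phases if not p.is_wash]

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    def wash_after(self, phase: Phase) -> Phase | None:
        """The wash phase immediately following ``phase``, if any."""
        for p in self.phases:
            if p.start_s >= phase.end_s - 1e-9 and p.is_wash:
                return p
            if p.start_s >= phase.end_s - 1e-9 and not p.is_wash:
                return None
        return None

    @classmethod
    def sequential(
        cls,
        analytes: list[str],
        concentration_m: float = 50e-9,
        association_s: float = 1200.0,
        wash_s: float = 600.0,
        baseline_s: float = 120.0,
        flow_ul_min: float = 200.0,
    ) -> "InjectionSchedule":
        """Sequential cognate-injection program: baseline wash, then for each
        analyte an association (default 20 min at 50 nM) followed by a buffer
        wash (default 10 min)."""
        phases = []
        t = 0.0
        if baseline_s > 0:
            phases.append(Phase("baseline", "", 0.0, t, baseline_s, flow_ul_min))
            t += baseline_s
        for a in analytes:
            phases.append(Phase(a, a, concentration_m, t, association_s, flow_ul_min))
            t += association_s
            phases.append(Phase("wash", "", 0.0, t, wash_s, flow_ul_min))
            t += wash_s
        return cls(phases)

    def to_dict(self) -> dict:
        return {
            "phases": [
                {
                    "label": p.label,
                    "analyte": p.analyte,
                    "concentration_m": p.concentration_m,
                    "start_s": p.start_s,
                    "duration_s": p.duration_s,
                    "flow_ul_min": p.flow_ul_min,
                }
                for p in self.phases
            ]
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "InjectionSchedule":
        return cls([Phase(**p) for p in d["phases"]])

    @classmethod
    def from_yaml(cls, path) -> "InjectionSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# the 1:1 model (shared by the fitter and the synthetic generator)


def langmuir_trajectory(
    times_s: np.ndarray,
    schedule: InjectionSchedule,
    k_on: float,
    k_off: float,
    gamma_max: float,
    analyte: str | None = None,
    cross_reactivity: dict[str, float] | None = None,
    gamma_0: float = 0.0,
) -> np.ndarray:
    """Bound mass Gamma(t) under the schedule, piecewise closed form.

    During a phase with constant driving concentration C the solution is
    Gamma(t) = Gamma_inf + (Gamma_0 - Gamma_inf) exp(-(k_on C + k_off) t)
    with Gamma_inf = Gamma_max k_on C / (k_on C + k_off).  ``analyte``
    restricts driving phases to that analyte; ``cross_reactivity`` maps
    analyte name -> fractional on-rate for this probe (overrides ``analyte``).
    """
    times_s = np.asarray(times_s, dtype=float)
    out = np.empty_like(times_s)
    g = float(gamma_0)
    for ph in schedule.phases:
        if cross_reactivity is not None:
            chi = cross_reactivity.get(ph.analyte, 0.0) if not ph.is_wash else 0.0
        elif analyte is not None:
            chi = 1.0 if ph.analyte == analyte else 0.0
        else:
            chi = 0.0 if ph.is_wash else 1.0
        c_eff = chi * ph.concentration_m
        k_obs = k_on * c_eff + k_off
        sel = (times_s >= ph.start_s - 1e-9) & (times_s <= ph.end_s + 1e-9)
        dt = times_s[sel] - ph.start_s
        if k_obs > 0:
            g_inf = gamma_max * k_on * c_eff / k_obs
            out[sel] = g_inf + (g - g_inf) * np.exp(-k_obs * dt)
            g = g_inf + (g - g_inf) * np.exp(-k_obs * ph.duration_s)
        else:
            out[sel] = g
    out[times_s < schedule.start_s] = gamma_0
    out[times_s > schedule.end_s] = g
    return out


# --------------------------------------------------------------------------
# binding curves


@dataclass
class BindingCurve:
    """Background-subtracted, replicate-averaged mass-density time series."""

    probe: str
    times_s: np.ndarray
    mass_mean: np.ndarray  # ng/mm^2
    mass_sd: np.ndarray
    n_replicates: int
    schedule: InjectionSchedule | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mass_mean = np.asarray(self.mass_mean, dtype=float)
        self.mass_sd = np.asarray(self.mass_sd, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.mass_mean) != len(self.times_s) or len(self.mass_sd) != len(self.times_s):
            raise ValueError("mass arrays must match the time axis")
        if np.any(self.mass_sd < 0):
            raise ValueError("SD must be non-negative")

    def window_median(self, t0: float, t1: float) -> float:
        sel = (self.times_s >= t0) & (self.times_s <= t1)
        return float(np.median(self.mass_mean[sel]))


def curves_to_frame(curves: dict[str, BindingCurve]) -> pd.DataFrame:
    """Tidy CSV-ready frame: time_s, probe, mass_ng_mm2, mass_sd, n_replicates."""
    rows = []
    for probe, c in sorted(curves.items()):
        for t, m, s in zip(c.times_s, c.mass_mean, c.mass_sd):
            rows.append(
                {
                    "time_s": t,
                    "probe": probe,
                    "mass_ng_mm2": m,
                    "mass_sd": s,
                    "n_replicates": c.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def curves_from_frame(df: pd.DataFrame, schedule: InjectionSchedule | None = None) -> dict:
    out = {}
    for probe, sub in df.groupby("probe"):
        sub = sub.sort_values("time_s")
        out[str(probe)] = BindingCurve(
            probe=str(probe),
            times_s=sub["time_s"].to_numpy(),
            mass_mean=sub["mass_ng_mm2"].to_numpy(),
            mass_sd=sub["mass_sd"].to_numpy(),
            n_replicates=int(sub["n_replicates"].iloc[0]),
            schedule=schedule,
        )
    return out


def _delta_mass_trace(
    trace: np.ndarray,
    i_ref: float,
    op: ThicknessFit,
    config: OpticsConfig,
    wavelength_nm: float,
) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(
            optics.single_wavelength_delta_mass(trace, i_ref, op, config, wavelength_nm)
        )


def _reference_intensity(times_s, trace, schedule: InjectionSchedule | None) -> float:
    """Median over the pre-injection baseline; first sample if there is none."""
    if schedule is not None and schedule.phases[0].is_wash:
        sel = times_s <= schedule.phases[0].end_s + 1e-9
        if np.count_nonzero(sel) >= 3:
            return float(np.median(trace[sel]))
    return float(trace[0])


def binding_curves_from_traces(
    times_s: np.ndarray,
    spot_traces: dict[tuple[int, int], np.ndarray],
    bg_traces: dict[tuple[int, int], np.ndarray],
    spot_ops: dict[tuple[int, int], ThicknessFit],
    bg_ops: dict[tuple[int, int], ThicknessFit],
    probe_of: dict[tuple[int, int], str],
    config: OpticsConfig,
    wavelength_nm: float = 452.0,
    schedule: InjectionSchedule | None = None,
) -> dict[str, BindingCurve]:
    """Per-probe curves from per-spot intensity traces.

    Source-power drift is first removed globally (every trace is divided by
    the median normalized background trace), then each spot's and each local
    background's intensity trace is converted to a mass change around its own
    operating point, the local background is subtracted, and replicate spots
    of the same probe are averaged.
    """
    times_s = np.asarray(times_s, dtype=float)
    # global illumination reference: median across chips' background regions
    # of each trace normalized to its own baseline
    norm_stack = []
    for pos, bg in bg_traces.items():
        ref = _reference_intensity(times_s, np.asarray(bg, dtype=float), schedule)
        norm_stack.append(np.asarray(bg, dtype=float) / ref)
    illum = np.median(np.vstack(norm_stack), axis=0) if norm_stack else 1.0

    per_probe: dict[str, list[np.ndarray]] = {}
    for pos, trace in spot_traces.items():
        trace = np.asarray(trace, dtype=float) / illum
        bg = np.asarray(bg_traces[pos], dtype=float) / illum
        dm_spot = _delta_mass_trace(
            trace, _reference_intensity(times_s, trace, schedule), spot_ops[pos], config, wavelength_nm
        )
        dm_bg = _delta_mass_trace(
            bg, _reference_intensity(times_s, bg, schedule), bg_ops[pos], config, wavelength_nm
        )
        per_probe.setdefault(probe_of[pos], []).append(dm_spot - dm_bg)
    curves = {}
    for probe, reps in per_probe.items():
        arr = np.vstack(reps)
        curves[probe] = BindingCurve(
            probe=probe,
            times_s=times_s,
            mass_mean=arr.mean(axis=0),
            mass_sd=arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1]),
            n_replicates=arr.shape[0],
            schedule=schedule,
        )
    return curves


def extract_binding_curves(
    stack,
    prescan,
    lut: ReflectanceLUT,
    config: OpticsConfig,
    schedule: InjectionSchedule | None = None,
    max_drift_frac: float = 0.25,
) -> dict[str, BindingCurve]:
    """Per-probe binding curves from a single-wavelength image stack.

    ``prescan`` is the four-color :class:`~irisqc.chip_io.ChipImageSet`
    acquired at the start of the experiment; it provides the grid, the
    per-spot masks, the gain calibration and the per-region operating points.
    ``stack`` is a ``kind="time"`` image set at one wavelength.  Frames whose
    rigid drift against frame 0 exceeds ``max_drift_frac`` of the pitch are
    re-registered by integer shift; failure raises :class:`DriftError`.
    """
    from . import array_qc  # deferred: array_qc imports optics only

    if stack.kind != "time":
        raise ValueError("stack must be a time-series image set")
    if len(stack.labels) < 2:
        raise ValueError("time series must contain at least 2 frames")
    wavelength = stack.wavelength_nm if stack.wavelength_nm is not None else 452.0

    array_qc.register_grid(prescan)
    stack.grid = prescan.grid
    measurements = array_qc.measure_all(prescan)
    calibration = array_qc.calibrate_chip(prescan, lut)
    gains = calibration.gains_vector(lut.wavelengths_nm)
    window = ((calibration.d_ox_nm, calibration.d_ox_nm), (0.0, float(lut.d_bio_grid_nm[-1])))

    spot_ops, bg_ops, probe_of = {}, {}, {}
    masks = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in measurements:
            if m.is_blank:
                continue
            pos = (m.row, m.col)
            spot_ops[pos] = optics.fit_thickness(
                [m.spot_median_intensity[w] for w in lut.wavelengths_nm],
                lut, window=window, gains=gains,
            )
            bg_ops[pos] = optics.fit_thickness(
                [m.local_background_median[w] for w in lut.wavelengths_nm],
                lut, window=window, gains=gains,
            )
            probe_of[pos] = m.replicate_group
            masks[pos] = (m.spot_mask, m.background_mask)

    # per-frame rigid-drift check against frame 0: median displacement of
    # blob detections matched to their frame-0 nearest neighbors (robust to
    # the intensity changes binding itself causes)
    frames = stack.images.astype(float)
    n_frames = frames.shape[0]
    shifts = np.zeros((n_frames, 2))  # (dy, dx), roll convention
    check_every = max(1, n_frames // 20)
    pitch = stack.grid.pitch_px
    ref_points = array_qc.detect_points(frames[0], stack.layout)
    last = np.zeros(2)
    for k in range(0, n_frames):
        if k % check_every == 0 and k > 0 and len(ref_points):
            pts = array_qc.detect_points(frames[k], stack.layout)
            disps = []
            for p in pts:
                d = ref_points - p
                j = np.argmin(np.hypot(d[:, 0], d[:, 1]))
                if np.hypot(*d[j]) < 0.6 * pitch:
                    disps.append(d[j])
            if len(disps) < max(1, 0.25 * len(ref_points)):
                raise DriftError(
                    f"frame {k}: drift beyond {0.6 * pitch:.0f} px, re-registration failed"
                )
            med = np.median(np.asarray(disps), axis=0)  # (dx, dy) toward frame 0
            drift = np.array([med[1], med[0]])
            last = np.round(drift) if np.hypot(*drift) > max_drift_frac * pitch else np.zeros(2)
        shifts[k] = last

    times = np.asarray(stack.labels, dtype=float)
    spot_traces = {pos: np.empty(n_frames) for pos in masks}
    bg_traces = {pos: np.empty(n_frames) for pos in masks}
    for k in range(n_frames):
        img = frames[k]
        s = np.round(shifts[min(k, n_frames - 1)]).astype(int)
        if np.any(s != 0):
            # phase_cross_correlation convention: rolling the moving frame by
            # +shift registers it onto frame 0
            img = np.roll(img, tuple(s), axis=(0, 1))
        for pos, (sm, bm) in masks.items():
            spot_traces[pos][k] = np.median(img[sm])
            bg_traces[pos][k] = np.median(img[bm])

    return binding_curves_from_traces(
        times, spot_traces, bg_traces, spot_ops, bg_ops, probe_of,
        config, wavelength, schedule,
    )


# --------------------------------------------------------------------------
# specificity


@dataclass
class SpecificityMatrix:
    """Net mass change per (probe, injection) with specific/non-specific calls.

    ``net`` rows are spotted probes, columns injection labels; entries are the
    median of the last ``window_s`` of the following wash minus the median of
    the ``window_s`` before the injection.  An entry is called specific when
    its net change exceeds ``k_sigma`` baseline standard deviations.
    """

    net: pd.DataFrame
    calls: pd.DataFrame
    k_sigma: float
    baseline_sigma: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = {
            "k_sigma": self.k_sigma,
            "net_ng_mm2": {p: self.net.loc[p].to_dict() for p in self.net.index},
            "specific": {p: self.calls.loc[p].to_dict() for p in self.calls.index},
            "baseline_sigma": self.baseline_sigma,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def specificity_matrix(
    curves: dict[str, BindingCurve],
    schedule: InjectionSchedule,
    k_sigma: float = 5.0,
    window_s: float = 30.0,
    sigma_floor: float = 1e-4,
) -> SpecificityMatrix:
    """Injection-by-injection specificity calls for every spotted probe."""
    injections = schedule.injections
    probes = sorted(curves)
    net = pd.DataFrame(0.0, index=probes, columns=[p.label for p in injections])
    sigmas = {}
    for probe in probes:
        c = curves[probe]
        # baseline scatter from the pre-first-injection segment (detrended)
        first = injections[0] if injections else None
        if first is not None:
            sel = c.times_s < first.start_s - 1e-9
        else:
            sel = np.ones_like(c.times_s, dtype=bool)
        if np.count_nonzero(sel) >= 4:
            seg = c.mass_mean[sel]
            sigma = float(np.std(np.diff(seg)) / np.sqrt(2.0))
        else:
            sigma = 0.0
        # the short baseline makes that estimate unstable; the replicate SD
        # pooled over the whole movie provides a stable floor
        if np.any(c.mass_sd > 0):
            sigma = max(
                sigma,
                float(np.median(c.mass_sd[c.mass_sd > 0])) / np.sqrt(max(1, c.n_replicates)),
            )
        sigmas[probe] = max(sigma, sigma_floor)
        for ph in injections:
            w = window_s
            if ph.duration_s < window_s:
                warnings.warn(
                    f"injection {ph.label!r} shorter than the averaging window; shrinking",
                    stacklevel=2,
                )
                w = ph.duration_s
            pre = c.window_median(ph.start_s - w, ph.start_s)
            wash = schedule.wash_after(ph)
            if wash is not None:
                post = c.window_median(wash.end_s - min(w, wash.duration_s), wash.end_s)
            else:
                post = c.window_median(ph.end_s - w, ph.end_s)
            net.loc[probe, ph.label] = post - pre
    thresholds = np.array([k_sigma * sigmas[p] for p in probes])
    calls = pd.DataFrame(
        net.to_numpy() > thresholds[:, None], index=net.index, columns=net.columns
    )
    return SpecificityMatrix(net, calls, k_sigma, sigmas)


# --------------------------------------------------------------------------
# Langmuir fitting


@dataclass
class LangmuirFit:
    """Fitted 1:1 kinetics with standard errors (linear-propagation)."""

    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    gamma_max: float  # ng/mm^2
    k_on_se: float
    k_off_se: float
    gamma_max_se: float
    rmse: float
    k_off_is_upper_bound: bool = False

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    def to_json(self, path=None) -> str:
        payload = {
            "k_on_per_M_s": self.k_on,
            "k_off_per_s": self.k_off,
            "gamma_max_ng_mm2": self.gamma_max,
            "K_d_M": self.k_d,
            "se": {"k_on": self.k_on_se, "k_off": self.k_off_se, "gamma_max": self.gamma_max_se},
            "rmse": self.rmse,
            "k_off_is_upper_bound": self.k_off_is_upper_bound,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_langmuir(
    curve: BindingCurve,
    schedule: InjectionSchedule | None = None,
    analyte: str | None = None,
) -> LangmuirFit:
    """Weighted least-squares fit of the 1:1 model to one binding curve.

    Requires at least one association and one dissociation phase.  The
    optimizer runs a deterministic multi-start over a fixed log-spaced grid of
    (k_on, k_off) initial values — no random starts.  When the wash decay is
    unresolvable, k_off is reported as an upper bound set by the wash length.
    """
    schedule = schedule or curve.schedule
    if schedule is None:
        raise ValueError("a schedule is required to fit kinetics")
    if analyte is None and any(p.analyte == curve.probe for p in schedule.injections):
        analyte = curve.probe
    driving = [
        p for p in schedule.injections if (analyte is None or p.analyte == analyte)
    ]
    if not driving:
        raise ValueError("schedule contains no association phase for this curve")
    if not any(p.is_wash for p in schedule.phases):
        raise ValueError("schedule contains no dissociation (wash) phase")

    y = curve.mass_mean
    t = curve.times_s
    span = float(np.max(y) - np.min(y))
    noise = float(np.median(curve.mass_sd[curve.mass_sd > 0])) if np.any(curve.mass_sd > 0) else 0.0
    if span <= max(5.0 * noise / np.sqrt(max(1, curve.n_replicates)), 1e-6):
        raise NoBindingSignalError(f"{curve.probe}: no binding signal (span {span:.3g})")

    w = np.ones_like(y)
    if np.any(curve.mass_sd > 0):
        w = 1.0 / np.clip(curve.mass_sd, np.median(curve.mass_sd[curve.mass_sd > 0]) * 0.2, None)

    cross = {p.analyte: 1.0 for p in driving}

    def model(logp):
        k_on, k_off, g_max = np.exp(logp)
        return langmuir_trajectory(t, schedule, k_on, k_off, g_max, cross_reactivity=cross)

    def resid(logp):
        return w * (model(logp) - y)

    g0 = max(span, 1e-3)
    best = None
    for k_on0 in (1e4, 1e5, 1e6):
        for k_off0 in (1e-5, 1e-4, 1e-3, 1e-2):
            x0 = np.log([k_on0, k_off0, 1.2 * g0])
            try:
                sol = least_squares(
                    resid, x0,
                    bounds=(np.log([1.0, 1e-9, 1e-6]), np.log([1e9, 1.0, 1e4])),
                    method="trf", xtol=1e-12, ftol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("Langmuir fit failed from every start")

    k_on, k_off, g_max = np.exp(best.x)
    res = model(best.x) - y
    rmse = float(np.sqrt(np.mean(res**2)))

    # standard errors from the Jacobian in log space
    dof = max(1, len(y) - 3)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        log_se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log_se = np.full(3, np.nan)
    k_on_se, k_off_se, g_max_se = (
        k_on * log_se[0], k_off * log_se[1], g_max * log_se[2],
    )

    # k_off resolvability: total decay over the washes must exceed the noise
    wash_time = sum(p.duration_s for p in schedule.phases if p.is_wash)
    upper = False
    if k_off * wash_time < 0.02 or (np.isfinite(log_se[1]) and log_se[1] > 1.0):
        upper = True
        k_off = max(k_off, 0.02 / max(wash_time, 1e-9))
    return LangmuirFit(
        float(k_on), float(k_off), float(g_max),
        float(k_on_se), float(k_off_se), float(g_max_se),
        rmse, upper,
    )
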