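"""Spotting-concentration optimization and crowding detection.

Immobilized probe mass and hybridization signal are analyzed as functions of
the probe concentration in the printed droplet (the standard design is
10 / 25 / 50 uM in quadruplicate).  Two questions are answered per probe and
surface chemistry:

1. Does immobilized mass grow linearly with spotting concentration, or does
   it saturate the available surface binding sites?  The scale-free
   saturation index

       S = (Gamma_high - Gamma_mid) / (Gamma_mid - Gamma_low)

   compares the observed high-end increment against the linear expectation
   (c_high - c_mid) / (c_mid - c_low); a Langmuir isotherm and a proportional
   model are fitted alongside as a residual cross-check.  The index and its
   thresholds are this package's formalization of a qualitative judgement;
   they are configurable.

2. Which concentration maximizes the binding signal?  If a higher
   concentration binds *less* target than the optimum by more than the
   replicate-noise margin, surface crowding is flagged: probe density so high
   that steric/electrostatic hindrance blocks target pairing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

VERDICT_LINEAR = "linear"
VERDICT_SATURATING = "saturating"
VERDICT_AMBIGUOUS = "ambiguous"


@dataclass
class ConcentrationSeries:
    """Immobilized mass (and optional signals) vs spotting concentration."""

    probe: str
    chemistry: str  # e.g. "NHS-ester", "azide-DBCO"
    concentrations_um: np.ndarray
    mass_ng_mm2: np.ndarray
    mass_sd: np.ndarray | None = None
    binding_signal: np.ndarray | None = None  # ng/mm^2 at end of association
    binding_sd: np.ndarray | None = None
    fluorescence: np.ndarray | None = None  # a.u.

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.mass_ng_mm2 = np.asarray(self.mass_ng_mm2, dtype=float)
        if len(self.concentrations_um) < 2:
            raise ValueError("at least 2 concentration points required")
        if np.any(np.diff(self.concentrations_um) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.mass_ng_mm2) != len(self.concentrations_um):
            raise ValueError("one mass per concentration required")
        if np.any(self.mass_ng_mm2 < 0):
            raise ValueError("masses must be non-negative")
        for name in ("mass_sd", "binding_signal", "binding_sd", "fluorescence"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.concentrations_um):
                    raise ValueError(f"{name} must match the concentration design")
                setattr(self, name, v)


@dataclass
class IsothermResult:
    """Linear-vs-saturating classification of an immobilization series."""

    probe: str
    chemistry: str
    verdict: str
    saturation_index: float | None  # S; None when the low increment is degenerate
    linear_expectation: float  # (c_high - c_mid) / (c_mid - c_low)
    linear_slope: float
    linear_rmse: float
    langmuir_gamma_max: float
    langmuir_k_per_um: float
    langmuir_rmse: float
    warning: str | None = None


@dataclass
class OptimumResult:
    """Optimal spotting concentration with crowding verdict."""

    probe: str
    chemistry: str
    optimal_concentration_um: float
    crowding: bool | None  # None: undetermined (single concentration)
    margin: float  # signal at optimum / signal at highest concentration


def _fit_models(conc: np.ndarray, mass: np.ndarray):
    """Proportional (Gamma = a c) and Langmuir (Gamma_max K c / (1 + K c)) fits.

    With the standard 3-point design the Langmuir fit is exactly identified;
    residuals are leave-none-out RMSE and serve only as a cross-check, the
    saturation index carries the verdict.
    """
    slope = float(np.sum(conc * mass) / np.sum(conc**2))
    lin_rmse = float(np.sqrt(np.mean((mass - slope * conc) ** 2)))

    def resid(p):
        g_max, k = np.exp(p)
        return g_max * k * conc / (1.0 + k * conc) - mass

    x0 = np.log([max(mass.max(), 1e-9) * 1.5, 1.0 / conc[len(conc) // 2]])
    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    g_max, k = np.exp(sol.x)
    lm_rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return slope, lin_rmse, float(g_max), float(k), lm_rmse


def classify_isotherm(
    series: ConcentrationSeries,
    saturating_fraction: float = 0.5,
    linear_tolerance: float = 0.25,
) -> IsothermResult:
    """Classify immobilization as linear / saturating / ambiguous.

    With points (c_low, c_mid, c_high) the linear expectation for
    S = (G_high - G_mid)/(G_mid - G_low) is L = (c_high - c_mid)/(c_mid - c_low).
    Verdicts: linear when S is within ``linear_tolerance`` (25%) of L;
    saturating when S < ``saturating_fraction`` * L and the Langmuir fit
    residual does not exceed the proportional fit's; otherwise ambiguous.
    A non-monotone low end (G_mid <= G_low) leaves S undefined.
    """
    if len(series.concentrations_um) < 3:
        raise ValueError("shape classification needs >= 3 concentration points")
    conc = series.concentrations_um
    mass = series.mass_ng_mm2
    i_low, i_mid, i_high = 0, len(conc) // 2, len(conc) - 1
    l_exp = (conc[i_high] - conc[i_mid]) / (conc[i_mid] - conc[i_low])

    slope, lin_rmse, g_max, k, lm_rmse = _fit_models(conc, mass)

    denom = mass[i_mid] - mass[i_low]
    if denom <= 0:
        warnings.warn(
            f"{series.probe}: non-monotone immobilization (mid <= low); verdict ambiguous",
            stacklevel=2,
        )
        return IsothermResult(
            series.probe, series.chemistry, VERDICT_AMBIGUOUS, None, l_exp,
            slope, lin_rmse, g_max, k, lm_rmse,
            warning="non-monotone immobilization: mid <= low",
        )
    s = float((mass[i_high] - mass[i_mid]) / denom)

    if abs(s - l_exp) <= linear_tolerance * l_exp:
        verdict = VERDICT_LINEAR
    elif s < saturating_fraction * l_exp and lm_rmse <= lin_rmse:
        verdict = VERDICT_SATURATING
    else:
        verdict = VERDICT_AMBIGUOUS
    return IsothermResult(
        series.probe, series.chemistry, verdict, s, l_exp,
        slope, lin_rmse, g_max, k, lm_rmse,
    )


def optimal_concentration(
    series: ConcentrationSeries,
    noise_margin_sigmas: float = 2.0,
) -> OptimumResult:
    """Concentration maximizing the binding signal, with a crowding flag.

    The optimum is the argmax of the binding signal (ties break toward the
    lowest concentration).  Crowding is flagged when any concentration above
    the optimum binds less target than the optimum by more than
    ``noise_margin_sigmas`` replicate standard deviations.
    """
    if series.binding_signal is None:
        raise ValueError("series carries no binding signal")
    sig = series.binding_signal
    conc = series.concentrations_um
    if len(conc) == 1:
        return OptimumResult(series.probe, series.chemistry, float(conc[0]), None, 1.0)
    sd = series.binding_sd if series.binding_sd is not None else np.zeros_like(sig)

    # tie handling: treat signals within the noise margin of the max as ties
    # and return the lowest such concentration
    i_max = int(np.argmax(sig))
    tol = noise_margin_sigmas * float(sd[i_max])
    i_opt = int(np.min(np.where(sig >= sig[i_max] - tol)[0]))

    crowding = False
    for j in range(i_opt + 1, len(conc)):
        margin_j = noise_margin_sigmas * float(np.hypot(sd[i_opt], sd[j]))
        if sig[j] < sig[i_opt] - margin_j:
            crowding = True
    margin = float(sig[i_opt] / sig[-1]) if sig[-1] > 0 else np.inf
    return OptimumResult(series.probe, series.chemistry, float(conc[i_opt]), crowding, margin)


@dataclass
class CorrelationSummary:
    """Fluorescence vs label-free agreement, per chemistry and pooled."""

    table: pd.DataFrame  # columns: chemistry, n, pearson_r, spearman_rho

    def to_json(self, path=None) -> str:
        text = json.dumps(self.table.to_dict(orient="records"), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def modality_correlation(series_list: list[ConcentrationSeries]) -> CorrelationSummary:
    """Rank (Spearman) and linear (Pearson) correlation between fluorescence
    and label-free binding signal across matched (probe, concentration) points.

    Groups with fewer than 3 matched points report n only (correlations
    undefined).
    """
    rows = []
    for s in series_list:
        if s.binding_signal is None or s.fluorescence is None:
            continue
        for c, b, f in zip(s.concentrations_um, s.binding_signal, s.fluorescence):
            rows.append({"chemistry": s.chemistry, "probe": s.probe,
                         "concentration_um": c, "binding": b, "fluorescence": f})
    df = pd.DataFrame(rows)
    out = []
    groups = [("pooled", df)] + [(str(ch), g) for ch, g in df.groupby("chemistry")] if len(df) else [("pooled", df)]
    for name, g in groups:
        n = len(g)
        if n < 3:
            out.append({"chemistry": name, "n": n, "pearson_r": None, "spearman_rho": None})
            continue
        pr = float(stats.pearsonr(g["binding"], g["fluorescence"]).statistic)
        sr = float(stats.spearmanr(g["binding"], g["fluorescence"]).statistic)
        out.append({"chemistry": name, "n": n, "pearson_r": pr, "spearman_rho": sr})
    return CorrelationSummary(pd.DataFrame(out))


# --------------------------------------------------------------------------
# CSV interface


CSV_COLUMNS = [
    "probe", "chemistry", "concentration_um", "mass_ng_mm2", "mass_sd",
    "binding_signal", "binding_sd", "fluorescence",
]


def series_to_frame(series_list: list[ConcentrationSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for i, c in enumerate(s.concentrations_um):
            rows.append({
                "probe": s.probe,
                "chemistry": s.chemistry,
                "concentration_um": c,
                "mass_ng_mm2": s.mass_ng_mm2[i],
                "mass_sd": s.mass_sd[i] if s.mass_sd is not None else None,
                "binding_signal": s.binding_signal[i] if s.binding_signal is not None else None,
                "binding_sd": s.binding_sd[i] if s.binding_sd is not None else None,
                "fluorescence": s.fluorescence[i] if s.fluorescence is not None else None,
            })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def series_from_frame(df: pd.DataFrame) -> list[ConcentrationSeries]:
    out = []
    for (probe, chem), g in df.groupby(["probe", "chemistry"], sort=True):
        g = g.sort_values("concentration_um")

        def col(name):
            if name not in g or g[name].isna().all():
                return None
            return g[name].to_numpy(dtype=float)

        out.append(ConcentrationSeries(
            probe=str(probe), chemistry=str(chem),
            concentrations_um=g["concentration_um"].to_numpy(dtype=float),
            mass_ng_mm2=g["mass_ng_mm2"].to_numpy(dtype=float),
            mass_sd=col("mass_sd"),
            binding_signal=col("binding_signal"),
            binding_sd=col("binding_sd"),
            fluorescence=col("fluorescence"),
        ))
    return out


def read_series_csv(path) -> list[ConcentrationSeries]:
    return series_from_frame(pd.read_csv(path))


def write_series_csv(series_list: list[ConcentrationSeries], path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)
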