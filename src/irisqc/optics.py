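"""Thin-film reflectance model of the layered chip and its inversion.

The chip is a four-layer stack at normal incidence::

    medium (air or buffer)  |  biolayer d_bio  |  SiO2 d_ox  |  Si substrate

Reflected light from the Si-SiO2 and SiO2-medium interfaces interferes, so the
reflectance at each LED wavelength encodes the optical thickness of the films.
Accumulation of biomolecules adds a transparent film (index ~1.45) on top of
the oxide; fitting the per-wavelength reflectance against a precomputed
look-up table recovers the biolayer thickness, which a fixed conversion factor
turns into surface mass density (ng/mm^2).

Two independent implementations of the same physics are provided:
:func:`layer_reflectance` (characteristic/transfer-matrix method), used
throughout the package, and :func:`airy_reflectance` (recursive Airy summation
of the Fresnel coefficients), kept deliberately separate as a numerical
cross-check.  They must agree to floating-point accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import constants


class ConfigurationError(ValueError):
    """Invalid or incomplete optics configuration."""


class DegenerateInputError(ValueError):
    """Observation carries no usable signal (e.g. all-zero intensities)."""


class UnderdeterminedFitError(ValueError):
    """Fewer observations than free parameters in a thickness fit."""


class InsensitiveOperatingPointError(RuntimeError):
    """Single-wavelength conversion attempted at an interference extremum."""


# --------------------------------------------------------------------------
# configuration and stack


@dataclass(frozen=True)
class OpticsConfig:
    """Optical model of the chip.

    Per-wavelength refractive indices are stored as mappings keyed by the
    wavelength in nm; :meth:`default` fills them from the built-in constants
    table.  ``mass_convention`` selects how biolayer thickness becomes surface
    mass density: ``"film_density"`` uses a fixed factor
    ``mass_conversion_ng_mm2_per_nm`` (default 1.2 ng/mm^2 per nm), while
    ``"de_feijter"`` uses Gamma = d * (n_bio - n_medium) / (dn/dc).
    """

    wavelengths_nm: tuple[float, ...] = constants.DEFAULT_WAVELENGTHS_NM
    n_medium: dict[float, float] = field(default_factory=dict)
    n_oxide: dict[float, float] = field(default_factory=dict)
    n_si: dict[float, complex] = field(default_factory=dict)
    n_bio: float = constants.N_BIO_DEFAULT
    oxide_nominal_nm: float = 110.0
    medium: str = "air"
    mass_convention: str = "film_density"
    mass_conversion_ng_mm2_per_nm: float = constants.MASS_NG_MM2_PER_NM_DEFAULT
    dn_dc_ml_per_g: float = constants.DN_DC_ML_PER_G_DEFAULT

    def __post_init__(self) -> None:
        if not self.wavelengths_nm:
            raise ConfigurationError("at least one wavelength required")
        if any(wl <= 0 for wl in self.wavelengths_nm):
            raise ConfigurationError("wavelengths must be positive")
        if self.oxide_nominal_nm <= 0:
            raise ConfigurationError("oxide_nominal_nm must be positive")
        if self.mass_conversion_ng_mm2_per_nm <= 0:
            raise ConfigurationError("mass conversion factor must be positive")
        if self.mass_convention not in ("film_density", "de_feijter"):
            raise ConfigurationError(
                f"unknown mass convention {self.mass_convention!r}"
            )
        if self.n_bio < 1.0:
            raise ConfigurationError("n_bio must have real part >= 1")
        for table, name in (
            (self.n_medium, "n_medium"),
            (self.n_oxide, "n_oxide"),
            (self.n_si, "n_si"),
        ):
            for wl, n in table.items():
                if np.real(n) < 1.0:
                    raise ConfigurationError(f"{name}[{wl}] real part must be >= 1")
                if np.imag(n) < 0:
                    raise ConfigurationError(f"{name}[{wl}] imaginary part must be >= 0")

    @classmethod
    def default(
        cls,
        medium: str = "air",
        wavelengths_nm: tuple[float, ...] = constants.DEFAULT_WAVELENGTHS_NM,
        oxide_nominal_nm: float = 110.0,
        **kwargs,
    ) -> "OpticsConfig":
        """Config with indices drawn from the built-in constants table."""
        return cls(
            wavelengths_nm=tuple(float(w) for w in wavelengths_nm),
            n_medium={float(w): constants.medium_index(medium, w) for w in wavelengths_nm},
            n_oxide={float(w): constants.sio2_index(w) for w in wavelengths_nm},
            n_si={float(w): constants.si_index(w) for w in wavelengths_nm},
            oxide_nominal_nm=oxide_nominal_nm,
            medium=medium,
            **kwargs,
        )

    def with_medium(self, medium: str) -> "OpticsConfig":
        """Same config with the ambient medium switched (dry vs in-flow)."""
        return replace(
            self,
            medium=medium,
            n_medium={w: constants.medium_index(medium, w) for w in self.wavelengths_nm},
        )

    def indices_for(self, wavelength_nm: float) -> tuple[float, float, float, complex]:
        """(n_medium, n_bio, n_oxide, n_si) at one wavelength."""
        wl = float(wavelength_nm)
        try:
            return (self.n_medium[wl], self.n_bio, self.n_oxide[wl], self.n_si[wl])
        except KeyError as exc:
            raise ConfigurationError(
                f"no refractive index configured for wavelength {wl} nm"
            ) from exc

    @property
    def mass_per_nm(self) -> float:
        """Surface mass density per nm of biolayer, ng/mm^2/nm."""
        if self.mass_convention == "film_density":
            return self.mass_conversion_ng_mm2_per_nm
        # de Feijter: Gamma = d * (n_bio - n_medium) / (dn/dc); with d in nm and
        # dn/dc in mL/g the result is directly in ng/mm^2.
        n_med = float(np.mean([self.n_medium[w] for w in self.wavelengths_nm]))
        return (self.n_bio - n_med) / self.dn_dc_ml_per_g

    # ---- serialization (YAML-style structured text) ----

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": list(self.wavelengths_nm),
            "n_medium": {w: float(v) for w, v in self.n_medium.items()},
            "n_oxide": {w: float(v) for w, v in self.n_oxide.items()},
            "n_si": {w: [float(np.real(v)), float(np.imag(v))] for w, v in self.n_si.items()},
            "n_bio": self.n_bio,
            "oxide_nominal_nm": self.oxide_nominal_nm,
            "medium": self.medium,
            "mass_convention": self.mass_convention,
            "mass_conversion_ng_mm2_per_nm": self.mass_conversion_ng_mm2_per_nm,
            "dn_dc_ml_per_g": self.dn_dc_ml_per_g,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        d["wavelengths_nm"] = tuple(float(w) for w in d["wavelengths_nm"])
        d["n_medium"] = {float(w): float(v) for w, v in d["n_medium"].items()}
        d["n_oxide"] = {float(w): float(v) for w, v in d["n_oxide"].items()}
        d["n_si"] = {float(w): complex(v[0], v[1]) for w, v in d["n_si"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "OpticsConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class LayerStack:
    """One realization of the layered chip: oxide + biolayer thickness."""

    d_ox_nm: float
    d_bio_nm: float
    config: OpticsConfig

    def __post_init__(self) -> None:
        if self.d_ox_nm < 0 or self.d_bio_nm < 0:
            raise ValueError("thicknesses must be non-negative")


# --------------------------------------------------------------------------
# forward models


def reflectance(
    config: OpticsConfig,
    wavelength_nm: float,
    d_ox_nm,
    d_bio_nm,
):
    """Normal-incidence reflectance of the stack (characteristic-matrix method).

    ``d_ox_nm`` and ``d_bio_nm`` may be scalars or broadcastable arrays; the
    return value has the broadcast shape.
    """
    n0, n1, n2, n3 = config.indices_for(wavelength_nm)
    d1 = np.asarray(d_bio_nm, dtype=float)
    d2 = np.asarray(d_ox_nm, dtype=float)
    wl = float(wavelength_nm)

    # characteristic matrix of each film: [[cos d, -i sin d / n], [-i n sin d, cos d]]
    # (sign convention consistent with n = n + ik absorbing indices)
    ph1 = 2.0 * np.pi * n1 * d1 / wl
    ph2 = 2.0 * np.pi * n2 * d2 / wl
    c1, s1 = np.cos(ph1), np.sin(ph1)
    c2, s2 = np.cos(ph2), np.sin(ph2)

    # M = M_bio @ M_ox
    m11 = c1 * c2 + (-1j * s1 / n1) * (-1j * n2 * s2)
    m12 = c1 * (-1j * s2 / n2) + (-1j * s1 / n1) * c2
    m21 = (-1j * n1 * s1) * c2 + c1 * (-1j * n2 * s2)
    m22 = (-1j * n1 * s1) * (-1j * s2 / n2) + c1 * c2

    b = m11 + m12 * n3
    c = m21 + m22 * n3
    r = (n0 * b - c) / (n0 * b + c)
    out = np.abs(r) ** 2
    return float(out) if out.ndim == 0 else out


def layer_reflectance(stack: LayerStack, wavelength_nm: float) -> float:
    """Reflectance fraction |r|^2 of a :class:`LayerStack` at one wavelength."""
    return float(reflectance(stack.config, wavelength_nm, stack.d_ox_nm, stack.d_bio_nm))


def airy_reflectance(stack_or_config, wavelength_nm: float, d_ox_nm=None, d_bio_nm=None):
    """Independent recursive-Airy implementation of the same stack.

    Combines Fresnel coefficients interface by interface from the substrate up:
    r_eff = (r_top + r_below * e^{2 i delta}) / (1 + r_top * r_below * e^{2 i delta}).
    Used only to cross-check :func:`reflectance`; do not substitute one for the
    other in tests of their agreement.
    """
    if isinstance(stack_or_config, LayerStack):
        config = stack_or_config.config
        d_ox_nm = stack_or_config.d_ox_nm
        d_bio_nm = stack_or_config.d_bio_nm
    else:
        config = stack_or_config
    n0, n1, n2, n3 = config.indices_for(wavelength_nm)
    d1 = np.asarray(d_bio_nm, dtype=float)
    d2 = np.asarray(d_ox_nm, dtype=float)
    wl = float(wavelength_nm)

    def fresnel(na, nb):
        return (na - nb) / (na + nb)

    r01 = fresnel(n0, n1)  # medium -> biolayer
    r12 = fresnel(n1, n2)  # biolayer -> oxide
    r23 = fresnel(n2, n3)  # oxide -> silicon

    beta2 = np.exp(2j * (2.0 * np.pi * n2 * d2 / wl))
    r_ox = (r12 + r23 * beta2) / (1.0 + r12 * r23 * beta2)
    beta1 = np.exp(2j * (2.0 * np.pi * n1 * d1 / wl))
    r_tot = (r01 + r_ox * beta1) / (1.0 + r01 * r_ox * beta1)
    out = np.abs(r_tot) ** 2
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# look-up table


@dataclass
class ReflectanceLUT:
    """Dense forward-model table R(d_ox, d_bio, wavelength).

    Bilinear interpolation between grid nodes is the defined evaluation
    semantics (:meth:`evaluate`).
    """

    d_ox_grid_nm: np.ndarray
    d_bio_grid_nm: np.ndarray
    wavelengths_nm: tuple[float, ...]
    table: np.ndarray  # (n_ox, n_bio, n_wl)
    config: OpticsConfig

    def _axis_locate(self, grid: np.ndarray, x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2)
        lo = grid[idx]
        step = grid[idx + 1] - lo
        frac = np.clip((x - lo) / step, 0.0, 1.0)
        return idx, frac

    def evaluate(self, d_ox_nm, d_bio_nm) -> np.ndarray:
        """Bilinear interpolation; returns shape broadcast(d_ox, d_bio) + (n_wl,)."""
        i, fi = self._axis_locate(self.d_ox_grid_nm, d_ox_nm)
        j, fj = self._axis_locate(self.d_bio_grid_nm, d_bio_nm)
        i, j, fi, fj = np.broadcast_arrays(i, j, fi, fj)
        fi = fi[..., None]
        fj = fj[..., None]
        t = self.table
        return (
            t[i, j] * (1 - fi) * (1 - fj)
            + t[i + 1, j] * fi * (1 - fj)
            + t[i, j + 1] * (1 - fi) * fj
            + t[i + 1, j + 1] * fi * fj
        )


def build_lut(
    config: OpticsConfig,
    d_ox_window_nm: tuple[float, float] | None = None,
    d_bio_window_nm: tuple[float, float] = (0.0, 30.0),
    step_nm: float = 0.1,
) -> ReflectanceLUT:
    """Precompute the forward model on a dense (d_ox, d_bio) grid.

    The default oxide window is the nominal thickness +/- 20 nm, which keeps the
    periodic thin-film inversion single-valued (chips are manufactured near
    nominal); the default biolayer window 0-30 nm covers any realistic bound
    film.
    """
    if d_ox_window_nm is None:
        d_ox_window_nm = (config.oxide_nominal_nm - 20.0, config.oxide_nominal_nm + 20.0)
    for lo, hi in (d_ox_window_nm, d_bio_window_nm):
        if hi < lo:
            raise ValueError("window bounds inverted")
    if step_nm <= 0:
        raise ValueError("grid step must be positive")

    def axis(lo, hi):
        n = max(2, int(round((hi - lo) / step_nm)) + 1)
        return np.linspace(lo, hi, n)

    d_ox = axis(max(0.0, d_ox_window_nm[0]), d_ox_window_nm[1])
    d_bio = axis(max(0.0, d_bio_window_nm[0]), d_bio_window_nm[1])
    table = np.empty((len(d_ox), len(d_bio), len(config.wavelengths_nm)))
    for k, wl in enumerate(config.wavelengths_nm):
        table[:, :, k] = reflectance(config, wl, d_ox[:, None], d_bio[None, :])
    return ReflectanceLUT(d_ox, d_bio, tuple(config.wavelengths_nm), table, config)


# --------------------------------------------------------------------------
# inversion


@dataclass
class ThicknessFit:
    """Result of inverting per-wavelength reflectance to film thicknesses."""

    d_ox_nm: float
    d_bio_nm: float
    residual: float  # rms misfit across channels, same units as observations
    gains: np.ndarray  # per-channel illumination scale factors
    window_edge: bool = False  # minimizer landed on the search-window boundary


def _observed_vector(observed, wavelengths) -> np.ndarray:
    if isinstance(observed, dict):
        try:
            o = np.array([float(observed[w]) for w in wavelengths])
        except KeyError as exc:
            raise ConfigurationError(f"observation missing wavelength {exc}") from exc
    else:
        o = np.asarray(observed, dtype=float)
        if o.shape != (len(wavelengths),):
            raise ValueError(
                f"expected {len(wavelengths)} observations, got shape {o.shape}"
            )
    if not np.all(np.isfinite(o)):
        raise DegenerateInputError("non-finite observation")
    if np.all(o == 0):
        raise DegenerateInputError("all-zero observation")
    if np.any(o < 0):
        raise DegenerateInputError("negative intensity observation")
    return o


def fit_thickness(
    observed,
    lut: ReflectanceLUT,
    window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    gains=None,
) -> ThicknessFit:
    """Least-squares inversion of per-wavelength intensities over the LUT.

    Parameters
    ----------
    observed
        Per-wavelength normalized intensities, as a mapping ``{wavelength: I}``
        or an array ordered like ``lut.wavelengths_nm``.
    window
        ``((d_ox_lo, d_ox_hi), (d_bio_lo, d_bio_hi))`` search bounds; either
        axis may be degenerate (lo == hi) to hold that thickness fixed.
        Defaults to the full LUT extent.
    gains
        Per-channel illumination gains if known.  ``None`` fits one common free
        gain analytically at every node, which requires >= 3 wavelengths.

    The minimizer is an exhaustive scan over LUT nodes followed by local
    quadratic refinement on each axis — deterministic, no random starts.  Ties
    break toward the smallest d_bio.
    """
    wavelengths = lut.wavelengths_nm
    o = _observed_vector(observed, wavelengths)
    n_wl = len(wavelengths)

    free_gain = gains is None
    if free_gain:
        if n_wl < 3:
            raise UnderdeterminedFitError(
                "free-gain fit needs >= 3 wavelengths (2 thicknesses + 1 gain)"
            )
    else:
        gains = np.asarray(gains, dtype=float)
        if gains.shape == ():
            gains = np.full(n_wl, float(gains))
        if gains.shape != (n_wl,):
            raise ValueError("gains must match the number of wavelengths")
        if n_wl < 2:
            raise UnderdeterminedFitError("fit needs >= 2 wavelengths")

    if window is None:
        window = (
            (lut.d_ox_grid_nm[0], lut.d_ox_grid_nm[-1]),
            (lut.d_bio_grid_nm[0], lut.d_bio_grid_nm[-1]),
        )
    (ox_lo, ox_hi), (bio_lo, bio_hi) = window
    if ox_hi < ox_lo or bio_hi < bio_lo:
        raise ValueError("window bounds inverted")

    def subgrid(grid, lo, hi):
        idx = np.where((grid >= lo - 1e-12) & (grid <= hi + 1e-12))[0]
        if len(idx) == 0:
            # degenerate window between nodes: evaluate at the requested point
            return None
        return idx

    iox = subgrid(lut.d_ox_grid_nm, ox_lo, ox_hi)
    ibio = subgrid(lut.d_bio_grid_nm, bio_lo, bio_hi)

    if iox is None or ibio is None:
        ox_vals = np.array([0.5 * (ox_lo + ox_hi)]) if iox is None else lut.d_ox_grid_nm[iox]
        bio_vals = np.array([0.5 * (bio_lo + bio_hi)]) if ibio is None else lut.d_bio_grid_nm[ibio]
        r_nodes = lut.evaluate(ox_vals[:, None], bio_vals[None, :])
    else:
        ox_vals = lut.d_ox_grid_nm[iox]
        bio_vals = lut.d_bio_grid_nm[ibio]
        r_nodes = lut.table[np.ix_(iox, ibio)]

    def cost_of(r):
        # r: (..., n_wl) model reflectances
        if free_gain:
            num = np.sum(o * r, axis=-1)
            den = np.sum(r * r, axis=-1)
            g = num / np.maximum(den, 1e-300)
            return np.sum(o * o) - g * num, g
        resid = o - gains * r
        return np.sum(resid * resid, axis=-1), None

    cost, _ = cost_of(r_nodes)
    cmin = cost.min()
    # tie-break: among near-minimal nodes choose smallest d_bio, then d_ox
    tol = max(1e-15, 1e-9 * max(cmin, 1e-30))
    cand = np.argwhere(cost <= cmin + tol)
    cand = cand[np.lexsort((ox_vals[cand[:, 0]], bio_vals[cand[:, 1]]))]
    i0, j0 = cand[0]

    on_edge = False
    if len(ox_vals) > 1 and (i0 == 0 or i0 == len(ox_vals) - 1):
        on_edge = True
    if len(bio_vals) > 1 and (j0 == 0 or j0 == len(bio_vals) - 1):
        on_edge = True
    if on_edge:
        warnings.warn("thickness fit minimizer on search-window boundary", stacklevel=2)

    def refine(vals, costs, k):
        # parabolic sub-node refinement along one axis
        if len(vals) < 3 or k == 0 or k == len(vals) - 1:
            return vals[k]
        fm, f0, fp = costs[k - 1], costs[k], costs[k + 1]
        denom = fm - 2 * f0 + fp
        if denom <= 0:
            return vals[k]
        delta = 0.5 * (fm - fp) / denom
        step = vals[k + 1] - vals[k]
        return vals[k] + np.clip(delta, -0.5, 0.5) * step

    d_ox_hat = refine(ox_vals, cost[:, j0], i0)
    d_bio_hat = refine(bio_vals, cost[i0, :], j0)

    # continuous polish against the exact forward model: the oxide and
    # biolayer axes are nearly degenerate (their indices almost match), so
    # the grid argmin can sit a little way along the flat valley; a bounded
    # local least-squares from the grid solution lands on the true minimum.
    # Deterministic: single start at the scan result.
    free_ox = ox_hi > ox_lo
    free_bio = bio_hi > bio_lo
    if free_ox or free_bio:
        from scipy.optimize import least_squares as _lsq

        config = lut.config
        wl_list = list(wavelengths)

        def model(d_ox, d_bio):
            return np.array([reflectance(config, wl, d_ox, d_bio) for wl in wl_list])

        def resid(p):
            q = iter(p)
            dox = next(q) if free_ox else d_ox_hat
            dbio = next(q) if free_bio else d_bio_hat
            r = model(dox, dbio)
            if free_gain:
                g = np.sum(o * r) / max(np.sum(r * r), 1e-300)
                return o - g * r
            return o - gains * r

        x0, lo_b, hi_b = [], [], []
        if free_ox:
            x0.append(d_ox_hat); lo_b.append(ox_lo); hi_b.append(ox_hi)
        if free_bio:
            x0.append(d_bio_hat); lo_b.append(bio_lo); hi_b.append(bio_hi)
        try:
            sol = _lsq(resid, x0, bounds=(lo_b, hi_b), method="trf",
                       xtol=1e-12, ftol=1e-14, gtol=1e-12)
            q = iter(sol.x)
            if free_ox:
                d_ox_hat = float(next(q))
            if free_bio:
                d_bio_hat = float(next(q))
        except Exception:
            pass  # keep the grid/parabola solution

    r_hat = lut.evaluate(d_ox_hat, d_bio_hat)
    if free_gain:
        g = float(np.sum(o * r_hat) / np.sum(r_hat * r_hat))
        gains_out = np.full(n_wl, g)
    else:
        gains_out = gains
    resid = o - gains_out * r_hat
    rms = float(np.sqrt(np.mean(resid**2)))
    return ThicknessFit(float(d_ox_hat), float(d_bio_hat), rms, gains_out, on_edge)


@dataclass
class ChipCalibration:
    """Chip-level oxide thickness and per-channel illumination gains."""

    d_ox_nm: float
    gains: dict[float, float]
    residual: float

    def gains_vector(self, wavelengths) -> np.ndarray:
        return np.array([self.gains[w] for w in wavelengths])


def calibrate_gains(
    background_intensities,
    lut: ReflectanceLUT,
    d_ox_window_nm: tuple[float, float] | None = None,
) -> ChipCalibration:
    """Self-referencing gain calibration from the spot-free background.

    Step 1 fits the chip-level oxide thickness from the spectral shape of the
    background intensities across all wavelengths with one common free gain
    (background biolayer fixed at 0); step 2 freezes per-channel gains as
    background intensity / model reflectance at the fitted oxide.  Subsequent
    per-spot fits then have only d_bio free.
    """
    wavelengths = lut.wavelengths_nm
    o = _observed_vector(background_intensities, wavelengths)
    if d_ox_window_nm is None:
        d_ox_window_nm = (lut.d_ox_grid_nm[0], lut.d_ox_grid_nm[-1])
    fit = fit_thickness(o, lut, window=(d_ox_window_nm, (0.0, 0.0)), gains=None)
    r0 = lut.evaluate(fit.d_ox_nm, 0.0)
    gains = {w: float(o[k] / r0[k]) for k, w in enumerate(wavelengths)}
    return ChipCalibration(fit.d_ox_nm, gains, fit.residual)


# --------------------------------------------------------------------------
# mass conversion and single-wavelength kinetics readout


def thickness_to_mass(d_bio_nm, config: OpticsConfig):
    """Surface mass density Gamma = c * d_bio, in ng/mm^2 (linear, invertible)."""
    d = np.asarray(d_bio_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("biolayer thickness must be non-negative")
    out = config.mass_per_nm * d
    return float(out) if out.ndim == 0 else out


def mass_to_thickness(mass_ng_mm2, config: OpticsConfig):
    """Inverse of :func:`thickness_to_mass`."""
    m = np.asarray(mass_ng_mm2, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be non-negative")
    out = m / config.mass_per_nm
    return float(out) if out.ndim == 0 else out


#: |Delta d_bio| (nm) beyond which the single-wavelength linearization is flagged.
LINEAR_RANGE_NM = 5.0

#: Floor on the relative slope |dR/dd| / R (per nm) below which the operating
#: point is considered insensitive (interference extremum).
SLOPE_FLOOR_PER_NM = 1e-3


def reflectance_slope(
    config: OpticsConfig, wavelength_nm: float, d_ox_nm: float, d_bio_nm: float, h_nm: float = 0.01
) -> float:
    """dR/dd_bio at an operating point, central finite difference."""
    lo = max(0.0, d_bio_nm - h_nm)
    hi = d_bio_nm + h_nm
    r_lo = reflectance(config, wavelength_nm, d_ox_nm, lo)
    r_hi = reflectance(config, wavelength_nm, d_ox_nm, hi)
    return float((r_hi - r_lo) / (hi - lo))


def single_wavelength_delta_mass(
    i_t,
    i_ref,
    operating_point: ThicknessFit,
    config: OpticsConfig,
    wavelength_nm: float,
    slope_floor_per_nm: float = SLOPE_FLOOR_PER_NM,
):
    """Convert single-wavelength intensity ratios to mass change.

    Around a previously fitted operating point (from a four-color acquisition)
    the reflectance is linear in small biolayer changes, so

        dGamma = c * (I_t / I_ref - 1) * R(op) / (dR/dd_bio at op).

    ``i_t`` may be an array (a whole time trace).  A warning is raised when the
    implied |Delta d_bio| exceeds the linearization bound (5 nm); an
    :class:`InsensitiveOperatingPointError` is raised when the operating point
    sits at an interference extremum (zero slope).
    """
    if i_ref <= 0:
        raise DegenerateInputError("reference intensity must be positive")
    r_op = reflectance(config, wavelength_nm, operating_point.d_ox_nm, operating_point.d_bio_nm)
    slope = reflectance_slope(
        config, wavelength_nm, operating_point.d_ox_nm, operating_point.d_bio_nm
    )
    if abs(slope) / max(r_op, 1e-12) < slope_floor_per_nm:
        raise InsensitiveOperatingPointError(
            "operating point at an interference extremum: "
            f"|dR/dd|/R = {abs(slope) / max(r_op, 1e-12):.2e} per nm"
        )
    ratio = np.asarray(i_t, dtype=float) / float(i_ref)
    d_bio_delta = (ratio - 1.0) * r_op / slope
    if np.any(np.abs(d_bio_delta) > LINEAR_RANGE_NM):
        warnings.warn(
            "implied |Delta d_bio| exceeds the 5 nm linearization bound", stacklevel=2
        )
    out = config.mass_per_nm * d_bio_delta
    return float(out) if out.ndim == 0 else out
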