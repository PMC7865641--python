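"""Built-in optical constants for the Si / SiO2 / biolayer / medium stack.

The chip model is a silicon substrate under a thermally grown oxide (nominally
110 nm for imaging chips), with an effective transparent "biolayer" of bound
biomolecules on top, immersed in air (dry reads) or aqueous buffer (in-flow
reads).  None of these indices are free parameters of the method; they are
standard tabulated optical constants, shipped here so that a chip can be
analyzed without any external configuration.  Every value can be overridden
through :class:`irisqc.optics.OpticsConfig`.

Provenance
----------
- Crystalline silicon, complex index n + ik: interpolated from the
  spectroscopic-ellipsometry tabulation of Aspnes & Studna,
  Phys. Rev. B 27, 985 (1983).
- Fused silica / thermal SiO2: Malitson three-term Sellmeier dispersion,
  J. Opt. Soc. Am. 55, 1205 (1965).  Thermal oxide tracks fused silica to
  within ~0.3% in the visible, well below the sensitivity of the method.
- Water: visible-range tabulations (Hale & Querry, Appl. Opt. 12, 555 (1973),
  smoothed); dispersion across the LED band is < 1%.
- Biolayer: n = 1.45, the conventional effective index for dense DNA/protein
  films in reflectometric biosensing.
"""

from __future__ import annotations

import numpy as np

#: Default LED center wavelengths of the four-color imaging setup (nm).
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (452.0, 518.0, 595.0, 632.0)

#: Effective refractive index of the bound biomolecular film.
N_BIO_DEFAULT: float = 1.45

#: Film-density mass conversion: ng/mm^2 of biomolecule per nm of film.
MASS_NG_MM2_PER_NM_DEFAULT: float = 1.2

#: de Feijter refractive-index increment, mL/g.
DN_DC_ML_PER_G_DEFAULT: float = 0.17

# Aspnes & Studna (1983), linear interpolation between tabulated points.
_SI_WL_NM = np.array([400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0])
_SI_N = np.array([5.570, 4.676, 4.298, 4.086, 3.943, 3.851, 3.777])
_SI_K = np.array([0.387, 0.148, 0.073, 0.039, 0.025, 0.016, 0.011])

# Hale & Querry class tabulation, smoothed.
_WATER_WL_NM = np.array([400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0])
_WATER_N = np.array([1.3433, 1.3398, 1.3364, 1.3339, 1.3320, 1.3310, 1.3300])


def si_index(wavelength_nm: float) -> complex:
    """Complex refractive index n + ik of crystalline silicon."""
    wl = float(wavelength_nm)
    n = float(np.interp(wl, _SI_WL_NM, _SI_N))
    k = float(np.interp(wl, _SI_WL_NM, _SI_K))
    return complex(n, k)


def sio2_index(wavelength_nm: float) -> float:
    """SiO2 index from the Malitson Sellmeier dispersion (wavelength in nm)."""
    lam2 = (float(wavelength_nm) / 1000.0) ** 2  # micrometres squared
    n2 = (
        1.0
        + 0.6961663 * lam2 / (lam2 - 0.0684043**2)
        + 0.4079426 * lam2 / (lam2 - 0.1162414**2)
        + 0.8974794 * lam2 / (lam2 - 9.896161**2)
    )
    return float(np.sqrt(n2))


def water_index(wavelength_nm: float) -> float:
    """Refractive index of water in the visible."""
    return float(np.interp(float(wavelength_nm), _WATER_WL_NM, _WATER_N))


def medium_index(medium: str, wavelength_nm: float) -> float:
    """Index of the ambient medium: ``"air"`` (dry chip) or ``"water"`` (in flow)."""
    if medium == "air":
        return 1.0
    if medium == "water":
        return water_index(wavelength_nm)
    raise ValueError(f"unknown medium {medium!r}; expected 'air' or 'water'")
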