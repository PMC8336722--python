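"""Chromophore absorption spectra, saturation-mixture algebra, and the
wavelength-dependent reduced-scattering model.

Two chromophore families are supported:

* ``hemoglobin`` — oxy-/deoxyhemoglobin at an average whole-blood total
  hemoglobin concentration of 150 g/l, computed from bundled molar
  extinction tables (molar mass 64,500 g/mol).
* ``sulfate`` — copper and nickel sulfate aqueous solutions at their
  whole-blood-equivalent reference concentrations (CuSO4 at 0.25 M,
  NiSO4 at 2.2 M).  CuSO4 mimics HbO2 (absorption rising toward a NIR
  peak near 810 nm) and NiSO4 mimics Hb (absorption decreasing over
  680–980 nm).  Published numeric tables for these solutions are not
  bundled; a documented parametric approximation with fixed coefficients
  stands in, and user-supplied two-column tables can override it.

A local mixture is described by a saturation fraction (sO2 for
hemoglobin, the relative copper fraction rCu for sulfates) and a volume
fraction (BVF / SVF) relative to the whole-blood-equivalent
concentration, so

    mu_a(lambda) = vf * (s * E_oxy(lambda) + (1 - s) * E_deoxy(lambda))

with E_* the family endmember spectra.  Reduced scattering follows the
standard Rayleigh/Mie power-law tissue model

    mu_s'(lambda) = mu_s500' * (f_ray (lambda/500)^-4
                                + (1 - f_ray) (lambda/500)^-b_mie).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "WavelengthGrid",
    "EndmemberSpectrum",
    "ChromophoreMixture",
    "ScatteringModelParams",
    "bundled_endmembers",
    "load_endmember_table",
    "mixture_mu_a",
    "reduced_scattering",
    "fit_scattering_model",
    "water_mu_a",
]

#: Whole-blood total hemoglobin concentration used for the endmember scale, g/l.
WHOLE_BLOOD_HB_G_PER_L = 150.0
#: Molar mass of hemoglobin, g/mol.
HB_MOLAR_MASS = 64_500.0

# Fixed coefficients of the parametric sulfate endmember approximation
# (absorption in 1/cm at the whole-blood-equivalent concentrations,
# CuSO4 at 0.25 M and NiSO4 at 2.2 M).  The shapes follow the d-d bands
# of the hexaaqua complexes: Cu(II) has one broad band near 810 nm
# (HbO2-like rise into the NIR); Ni(II) has a band near 720 nm plus the
# tail of its ~1150 nm band, giving an Hb-like overall decrease over
# 680-980 nm with a non-monotone NIR floor:
#   mu_a_Cu = 6.0 exp(-((l-810)/110)^2) + 0.2
#   mu_a_Ni = 16.0 exp(-((l-720)/75)^2) + 3.0 exp(-((l-1150)/200)^2) + 0.3
# The two curves cross at least once in 680-980 nm.
_CU_PEAK_NM = 810.0
_CU_WIDTH_NM = 110.0
_CU_AMP = 6.0
_CU_BASE = 0.2
_NI_PEAK_NM = 720.0
_NI_WIDTH_NM = 75.0
_NI_AMP = 16.0
_NI_TAIL_NM = 1150.0
_NI_TAIL_WIDTH_NM = 200.0
_NI_TAIL_AMP = 3.0
_NI_BASE = 0.3


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered illumination wavelengths in nm (strictly increasing)."""

    values: tuple[float, ...] = tuple(float(w) for w in range(680, 981, 20))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-d sequence")
        if np.any(arr <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    def __len__(self) -> int:
        return len(self.values)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class EndmemberSpectrum:
    """Absorption spectrum (1/cm) of a pure chromophore at its reference
    (whole-blood-equivalent) concentration, sampled on a wavelength grid."""

    name: str
    grid: WavelengthGrid
    mu_a: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.mu_a, dtype=float)
        if arr.shape != (len(self.grid),):
            raise ValueError("mu_a must have one value per grid wavelength")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("mu_a must be finite and nonnegative")
        object.__setattr__(self, "mu_a", tuple(float(v) for v in arr))

    def asarray(self) -> np.ndarray:
        return np.asarray(self.mu_a, dtype=float)


@dataclass(frozen=True)
class ChromophoreMixture:
    """Saturation fraction (sO2 or rCu) plus volume fraction (BVF or SVF)
    defining a local absorption spectrum."""

    saturation: float
    volume_fraction: float
    family: str = "sulfate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError(f"saturation must be in [0, 1], got {self.saturation}")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError(
                f"volume_fraction must be in [0, 1], got {self.volume_fraction}"
            )
        if self.family not in ("sulfate", "hemoglobin"):
            raise ValueError(f"unknown chromophore family {self.family!r}")


@dataclass(frozen=True)
class ScatteringModelParams:
    """Parameters of the Rayleigh/Mie power-law reduced-scattering model.

    Defaults are the generic-tissue values fitted against time-resolved
    measurements of the 1.5% fat-emulsion background medium
    (mu_s500' = 42.4 1/cm, f_ray = 0.62, b_mie = 1.0); they give
    mu_s' ~ 15 1/cm at 750 nm.
    """

    mus500: float = 42.4
    f_ray: float = 0.62
    b_mie: float = 1.0

    def __post_init__(self) -> None:
        if self.mus500 <= 0:
            raise ValueError("mus500 must be positive")
        if not 0.0 <= self.f_ray <= 1.0:
            raise ValueError("f_ray must be in [0, 1]")


def _read_two_column(path_or_text) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path_or_text, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("endmember table must have two columns (wavelength, value)")
    wl, val = data[:, 0], data[:, 1]
    if np.any(np.diff(wl) <= 0):
        raise ValueError("endmember table wavelengths must be strictly increasing")
    return wl, val


def load_endmember_table(path, name: str, grid: WavelengthGrid,
                         scale: float = 1.0) -> EndmemberSpectrum:
    """Load a plain-text two-column (wavelength nm, value) endmember table,
    linearly interpolated onto *grid* and multiplied by *scale*.

    The user-override hook for the bundled spectra: any chromophore table in
    this format can replace a bundled endmember throughout the pipeline.
    """
    wl, val = _read_two_column(path)
    mu = _interp_checked(grid, wl, val, name) * scale
    return EndmemberSpectrum(name=name, grid=grid, mu_a=tuple(mu))


def _interp_checked(grid: WavelengthGrid, wl: np.ndarray, val: np.ndarray,
                    name: str) -> np.ndarray:
    g = grid.asarray()
    if g.min() < wl.min() or g.max() > wl.max():
        raise ValueError(
            f"grid [{g.min():g}, {g.max():g}] nm outside bundled range for "
            f"{name} [{wl.min():g}, {wl.max():g}] nm"
        )
    return np.interp(g, wl, val)


def _bundled_table(fname: str) -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("milsd").joinpath("data", fname)
    with ref.open("r") as fh:
        return _read_two_column(fh)


def _hemoglobin_mu_a(grid: WavelengthGrid, fname: str, name: str) -> np.ndarray:
    # mu_a [1/cm] = ln(10) * epsilon [1/cm/M] * c_molar [M]
    wl, eps = _bundled_table(fname)
    c_molar = WHOLE_BLOOD_HB_G_PER_L / HB_MOLAR_MASS
    return np.log(10.0) * _interp_checked(grid, wl, eps, name) * c_molar


def _sulfate_mu_a(grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    lam = grid.asarray()
    cu = _CU_AMP * np.exp(-(((lam - _CU_PEAK_NM) / _CU_WIDTH_NM) ** 2)) + _CU_BASE
    ni = (_NI_AMP * np.exp(-(((lam - _NI_PEAK_NM) / _NI_WIDTH_NM) ** 2))
          + _NI_TAIL_AMP * np.exp(-(((lam - _NI_TAIL_NM) / _NI_TAIL_WIDTH_NM) ** 2))
          + _NI_BASE)
    return cu, ni


def water_mu_a(grid: WavelengthGrid | None = None) -> np.ndarray:
    """Water absorption (1/cm) interpolated from the bundled literature table."""
    grid = grid or WavelengthGrid()
    wl, mua = _bundled_table("water_absorption.tsv")
    return _interp_checked(grid, wl, mua, "water")


def bundled_endmembers(family: str,
                       grid: WavelengthGrid | None = None) -> list[EndmemberSpectrum]:
    """Endmember spectra of a chromophore family on *grid*.

    Returns the oxygenated-like endmember first: [HbO2, Hb] for
    ``hemoglobin``, [CuSO4, NiSO4] for ``sulfate``, and the single water
    spectrum for ``water``.
    """
    grid = grid or WavelengthGrid()
    if family == "hemoglobin":
        return [
            EndmemberSpectrum("HbO2", grid, tuple(
                _hemoglobin_mu_a(grid, "hbo2_molar_extinction.tsv", "HbO2"))),
            EndmemberSpectrum("Hb", grid, tuple(
                _hemoglobin_mu_a(grid, "hb_molar_extinction.tsv", "Hb"))),
        ]
    if family == "sulfate":
        cu, ni = _sulfate_mu_a(grid)
        return [
            EndmemberSpectrum("CuSO4", grid, tuple(cu)),
            EndmemberSpectrum("NiSO4", grid, tuple(ni)),
        ]
    if family == "water":
        return [EndmemberSpectrum("water", grid, tuple(water_mu_a(grid)))]
    raise ValueError(f"unknown chromophore family {family!r}")


def mixture_mu_a(mix: ChromophoreMixture, grid: WavelengthGrid | None = None,
                 endmembers: list[EndmemberSpectrum] | None = None) -> np.ndarray:
    """Absorption spectrum (1/cm) of a chromophore mixture.

    Linear in both the saturation and the volume fraction:
    ``vf * (s * E_oxy + (1 - s) * E_deoxy)``.  Custom *endmembers*
    (oxygenated-like first) override the bundled family spectra.
    """
    grid = grid or WavelengthGrid()
    if endmembers is None:
        endmembers = bundled_endmembers(mix.family, grid)
    if len(endmembers) != 2:
        raise ValueError("mixture requires exactly two endmembers")
    e_oxy, e_deoxy = (e.asarray() for e in endmembers)
    return mix.volume_fraction * (
        mix.saturation * e_oxy + (1.0 - mix.saturation) * e_deoxy
    )


def reduced_scattering(params: ScatteringModelParams,
                       grid: WavelengthGrid | np.ndarray | None = None) -> np.ndarray:
    """Evaluate the Rayleigh/Mie power-law mu_s'(lambda) model (1/cm)."""
    if grid is None:
        grid = WavelengthGrid()
    lam = grid.asarray() if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    x = lam / 500.0
    return params.mus500 * (
        params.f_ray * x ** -4.0 + (1.0 - params.f_ray) * x ** -params.b_mie
    )


def fit_scattering_model(samples, init: ScatteringModelParams | None = None
                         ) -> ScatteringModelParams:
    """Least-squares fit of the power-law scattering model to
    (wavelength nm, mu_s' 1/cm) tuples.

    Requires at least three samples spanning at least two distinct
    wavelengths; the returned parameters never have a larger residual
    norm than *init*.
    """
    init = init or ScatteringModelParams()
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (wavelength, mu_s') samples")
    lam, mus = arr[:, 0], arr[:, 1]
    if np.unique(lam).size < 2:
        raise ValueError("samples must span >= 2 distinct wavelengths")

    def resid(p):
        return reduced_scattering(
            ScatteringModelParams(mus500=p[0], f_ray=p[1], b_mie=p[2]), lam) - mus

    x0 = np.array([init.mus500, init.f_ray, init.b_mie])
    sol = least_squares(resid, x0, bounds=([1e-9, 0.0, 0.0], [np.inf, 1.0, np.inf]))
    fitted = ScatteringModelParams(*sol.x)
    if np.linalg.norm(resid(sol.x)) > np.linalg.norm(resid(x0)) + 1e-12:
        return init
    return fitted
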