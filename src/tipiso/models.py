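"""Equations of state for lipid monolayer surface-pressure/area isotherms.

A Langmuir-trough compression isotherm records the surface pressure
``pi = gamma0 - gamma`` (mN/m) of a spread lipid film as a function of the
mean area available per molecule ``a_L`` (A^2/molecule) at fixed
temperature.  Three forward models are provided:

* the ideal two-dimensional gas, ``pi = kappa(T) / a_L``;
* the two-dimensional van der Waals gas,
  ``pi = kappa(T) / (a_L - b) - a / a_L^2``, with cohesion coefficient
  ``a`` and excluded coarea ``b``;
* a power-law equation of state derived from the thermodynamics of
  irreversible processes (TIP), in which monolayer compression is coupled
  to water exchange with the subphase:

  ``pi_p = k1 * kappa(T)/a_L + k2' * (kappa(T)/a0) * (a0/a_L)**p``

  where ``k1`` and ``k2'`` are dimensionless ratios of phenomenological
  (Onsager) mobility coefficients, ``a0`` is a reference area per molecule
  (42 A^2 by default) and the integer exponent ``p >= 1`` sets the
  curvature contributed by the water-lipid cross coupling.

Unit conventions used throughout the package
--------------------------------------------
Areas are per molecule in A^2, pressures in mN/m, temperatures in kelvin.
The thermal energy per molecule kappa(T) = k_B * T then carries units of
mN*A^2/m, so kappa(T)/a_L is directly a surface pressure in mN/m;
numerically kappa(T) = 1.380649 * T.  Using the molar gas constant with
molar areas yields identical pressures — the per-molecule form is adopted
because monolayer isotherms are conventionally reported per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "BOLTZMANN_MN_A2",
    "Isotherm",
    "TIPParams",
    "VdWParams",
    "PhenomenologicalCoefficients",
    "SurfaceTensionPair",
    "thermal_scale",
    "eval_ideal",
    "eval_vdw",
    "eval_tip",
    "k_from_phenomenological",
    "surface_excess",
    "surface_pressure_from_tensions",
]

#: Boltzmann constant expressed in mN*A^2/(m*K) per molecule
#: (1.380649e-23 J/K * 1e3 mN/N * 1e20 A^2/m^2).
BOLTZMANN_MN_A2 = 1.380649

ArrayLike = Union[float, np.ndarray]


def _positive_array(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr <= 0.0):
        raise ValueError(f"{name} must be strictly positive")
    return arr


def thermal_scale(temperature: ArrayLike) -> ArrayLike:
    """Thermal energy per molecule kappa(T) = k_B * T in mN*A^2/m.

    Dividing by an area in A^2/molecule yields a surface pressure in mN/m.

    >>> round(thermal_scale(298.15), 2)
    411.64
    """
    t = _positive_array(temperature, "temperature")
    out = BOLTZMANN_MN_A2 * t
    return float(out) if out.ndim == 0 else out


def eval_ideal(area_per_lipid: ArrayLike, temperature: float) -> ArrayLike:
    """Ideal 2D-gas surface pressure pi = kappa(T)/a_L (mN/m)."""
    a = _positive_array(area_per_lipid, "area_per_lipid")
    out = thermal_scale(temperature) / a
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class VdWParams:
    """Two-dimensional van der Waals coefficients.

    ``a_coh`` is the cohesion (pressure-correction) coefficient in
    mN*A^4/m per molecule^2; ``b_co`` the excluded coarea in A^2/molecule.
    The model is defined only for a_L > b_co.
    """

    a_coh: float
    b_co: float

    def __post_init__(self) -> None:
        if self.b_co < 0.0:
            raise ValueError("coarea b_co must be non-negative")


def eval_vdw(area_per_lipid: ArrayLike, temperature: float, params: VdWParams) -> ArrayLike:
    """2D van der Waals pressure pi = kappa(T)/(a_L - b) - a/a_L^2 (mN/m).

    Diverges at the excluded-area pole a_L -> b_co+; a_L <= b_co is a
    domain error.
    """
    a = _positive_array(area_per_lipid, "area_per_lipid")
    if np.any(a <= params.b_co):
        raise ValueError("area_per_lipid must exceed the coarea b_co")
    out = thermal_scale(temperature) / (a - params.b_co) - params.a_coh / a**2
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class TIPParams:
    """Coefficients of the TIP power-law equation of state.

    ``k1`` and ``k2prime`` are dimensionless combinations of the
    phenomenological mobility coefficients coupling area change and water
    flux; ``p`` is the integer power-law exponent (p = 1 recovers the
    linear form pi = (k1 + k2') * kappa/a_L); ``a0`` is the reference
    area per molecule keeping the power-law term dimensionless.
    """

    p: int
    k1: float
    k2prime: float
    a0: float = 42.0

    def __post_init__(self) -> None:
        if int(self.p) != self.p or self.p < 1:
            raise ValueError("exponent p must be an integer >= 1")
        object.__setattr__(self, "p", int(self.p))
        if self.a0 <= 0.0:
            raise ValueError("reference area a0 must be positive")


def eval_tip(area_per_lipid: ArrayLike, temperature: float, params: TIPParams) -> ArrayLike:
    """TIP surface pressure pi_p = k1*kappa/a_L + k2'*(kappa/a0)*(a0/a_L)^p."""
    a = _positive_array(area_per_lipid, "area_per_lipid")
    kappa = thermal_scale(temperature)
    out = params.k1 * kappa / a + params.k2prime * (kappa / params.a0) * (params.a0 / a) ** params.p
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class PhenomenologicalCoefficients:
    """Onsager mobility coefficients of the coupled area/water-flux model.

    ``l_ww``: water-water (bulk diffusion) mobility; ``l_ll``: lipid-lipid
    friction; ``l_wl``: water-in-lipid cross mobility; ``l_lw``:
    lipid-in-water cross mobility.  Any consistent unit system; only the
    ratios k1 = l_ww/(l_ll + l_lw) and k2 = l_wl/(l_ll + l_lw) enter the
    equation of state.
    """

    l_ww: float
    l_ll: float
    l_wl: float
    l_lw: float
    l_wl0: float | None = None

    def __post_init__(self) -> None:
        for name in ("l_ww", "l_ll", "l_wl", "l_lw"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


def k_from_phenomenological(coeffs: PhenomenologicalCoefficients) -> tuple[float, float]:
    """Map mobility coefficients to the dimensionless pair (k1, k2).

    k1 = l_ww / (l_ll + l_lw), k2 = l_wl / (l_ll + l_lw).  With
    l_ww = l_ll and vanishing cross terms this gives (1, 0) and the TIP
    equation of state reduces to the ideal 2D gas.
    """
    denom = coeffs.l_ll + coeffs.l_lw
    if denom <= 0.0:
        raise ValueError("l_ll + l_lw must be positive to define (k1, k2)")
    return coeffs.l_ww / denom, coeffs.l_wl / denom


def surface_excess(n_lipids: float, area: float) -> float:
    """Lipid surface excess Gamma_L = n_L / A (molecules/A^2)."""
    if area <= 0.0:
        raise ValueError("area must be positive")
    return n_lipids / area


@dataclass(frozen=True)
class SurfaceTensionPair:
    """Surface tension of the bare subphase and of the film-covered surface.

    Default gamma0 = 72 mN/m, pure water near 25 C.
    """

    gamma: float
    gamma0: float = 72.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= self.gamma0):
            raise ValueError("require 0 <= gamma <= gamma0")


def surface_pressure_from_tensions(pair: SurfaceTensionPair) -> float:
    """Surface pressure pi = gamma0 - gamma (mN/m); zero for a bare surface."""
    return pair.gamma0 - pair.gamma


@dataclass(frozen=True, eq=False)
class Isotherm:
    """One surface-pressure/area compression isotherm at fixed temperature.

    ``area_per_lipid`` must be strictly increasing and positive (loaders
    sort and de-duplicate raw files before constructing an Isotherm);
    ``surface_pressure`` in mN/m may take any finite value.
    """

    area_per_lipid: np.ndarray
    surface_pressure: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.area_per_lipid, dtype=float)
        p = np.asarray(self.surface_pressure, dtype=float)
        object.__setattr__(self, "area_per_lipid", a)
        object.__setattr__(self, "surface_pressure", p)
        if a.ndim != 1 or p.ndim != 1 or a.size != p.size:
            raise ValueError("area and pressure must be 1-D arrays of equal length")
        if a.size < 2:
            raise ValueError("an isotherm needs at least 2 points")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
            raise ValueError("isotherm values must be finite")
        if np.any(a <= 0.0):
            raise ValueError("area_per_lipid must be strictly positive")
        if np.any(np.diff(a) <= 0.0):
            raise ValueError("area_per_lipid must be strictly increasing")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return int(self.area_per_lipid.size)

    def slice_range(self, lo: float, hi: float, *, closed_right: bool = False) -> "Isotherm":
        """Sub-isotherm with lo <= a_L < hi (or <= hi if ``closed_right``)."""
        a = self.area_per_lipid
        mask = (a >= lo) & ((a <= hi) if closed_right else (a < hi))
        if mask.sum() < 2:
            raise ValueError(f"slice [{lo}, {hi}) holds fewer than 2 points")
        return Isotherm(
            a[mask], self.surface_pressure[mask], self.temperature,
            label=f"{self.label}[{lo:g},{hi:g})" if self.label else "",
        )

    def to_frame(self):
        """Two-column pandas DataFrame using the package's file schema."""
        import pandas as pd

        return pd.DataFrame(
            {
                "area_per_lipid_A2": self.area_per_lipid,
                "surface_pressure_mN_m": self.surface_pressure,
            }
        )
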