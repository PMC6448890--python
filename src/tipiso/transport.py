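"""Cross diffusion coefficients from fitted TIP parameters.

The dimensionless TIP coefficients can be recast as ratios of diffusion
coefficients, k1 = D_ww/(D_LL + D_Lw) and k2 = D_wL/(D_LL + D_Lw).
Inverting the fitted (k1, k2') for a region gives the two cross
coefficients

    D0_Lw = (k2'/|k1|) * D_ww        (lipid-with-hydration-shell in water)
    D0_wL = D_ww/|k1| - D_LL         (water through the lipid matrix)

given the water self-diffusion coefficient D_ww and the lipid lateral
diffusion coefficient D_LL, all in cm^2/s.

Sign convention: fitted k1 values are typically negative in the condensed
and coexistence regimes while physical diffusivities are positive; the
magnitude |k1| is used and a note is attached whenever k1 < 0.

Defaults: D_ww = 1e-6 cm^2/s (bulk water, the lower end of the accepted
1e-10..1e-9 m^2/s range); D_LL = 1e-8 cm^2/s for the fluid
liquid-expanded phase, 1e-10 cm^2/s for the gel-like liquid-condensed
phase, and their semi-sum in the coexistence region.  Because
D_LL << D_ww/|k1| for all fitted regions, the D_LL correction to D0_wL is
below 0.01%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fitting import RegionFit

__all__ = [
    "DEFAULT_D_WW",
    "D_LL_FLUID",
    "D_LL_GEL",
    "DEFAULT_D_LL_BY_PHASE",
    "TransportInputs",
    "TransportCoefficients",
    "derive_transport",
    "k_from_diffusion",
    "transport_table",
    "format_transport_table",
]

#: water self-diffusion coefficient, cm^2/s (1e-10 m^2/s)
DEFAULT_D_WW = 1.0e-6
#: lipid lateral diffusion in the fluid (liquid-expanded) phase, cm^2/s
D_LL_FLUID = 1.0e-8
#: lipid lateral diffusion in the gel (liquid-condensed) phase, cm^2/s
D_LL_GEL = 1.0e-10

DEFAULT_D_LL_BY_PHASE: dict[str, float] = {
    "liquid_expanded": D_LL_FLUID,
    "coexistence": 0.5 * (D_LL_FLUID + D_LL_GEL),
    "liquid_condensed": D_LL_GEL,
}


@dataclass(frozen=True)
class TransportInputs:
    """Inputs of the coefficient inversion for one monolayer region."""

    k1: float
    k2prime: float
    d_ww: float = DEFAULT_D_WW
    d_ll: float = D_LL_GEL

    def __post_init__(self) -> None:
        if self.d_ww <= 0.0:
            raise ValueError("D_ww must be positive")
        if self.d_ll < 0.0:
            raise ValueError("D_LL must be non-negative")
        if self.k1 == 0.0:
            raise ValueError("k1 must be non-zero to invert for diffusivities")


@dataclass(frozen=True)
class TransportCoefficients:
    """Derived cross diffusion coefficients, cm^2/s, with inputs echoed."""

    d_wl0: float
    d_lw0: float
    inputs: TransportInputs
    notes: tuple[str, ...] = ()

    @property
    def physical(self) -> bool:
        return self.d_wl0 > 0.0 and self.d_lw0 > 0.0


def derive_transport(inp: TransportInputs) -> TransportCoefficients:
    """Invert (k1, k2') to the cross diffusion coefficients.

    D0_Lw = (k2'/|k1|) D_ww and D0_wL = D_ww/|k1| - D_LL.  A non-positive
    D0_wL is flagged in ``notes`` but still returned.
    """
    ak1 = abs(inp.k1)
    d_lw0 = (inp.k2prime / ak1) * inp.d_ww
    d_wl0 = inp.d_ww / ak1 - inp.d_ll
    notes = []
    if inp.k1 < 0.0:
        notes.append("k1 < 0: magnitude used (diffusivities are positive by convention)")
    if d_wl0 <= 0.0:
        notes.append("non-physical: D0_wL <= 0 (D_LL exceeds D_ww/|k1|)")
    if d_lw0 <= 0.0:
        notes.append("non-physical: D0_Lw <= 0")
    return TransportCoefficients(d_wl0=d_wl0, d_lw0=d_lw0, inputs=inp, notes=tuple(notes))


def k_from_diffusion(d_ww: float, d_ll: float, d_lw: float, d_wl: float) -> tuple[float, float]:
    """Forward map from diffusivities to (k1, k2).

    k1 = D_ww/(D_LL + D_Lw), k2 = D_wL/(D_LL + D_Lw).  Round-trips with
    :func:`derive_transport` in the D_LL -> 0 limit up to the |k1| sign
    convention.
    """
    denom = d_ll + d_lw
    if denom <= 0.0:
        raise ValueError("D_LL + D_Lw must be positive")
    return d_ww / denom, d_wl / denom


def _phase_k(entry) -> tuple[str, float, float]:
    if isinstance(entry, RegionFit):
        if entry.spec is None:
            raise ValueError("RegionFit without a region spec has no phase label")
        return entry.spec.phase_label, entry.params.k1, entry.params.k2prime
    phase, k1, k2prime = entry
    return str(phase), float(k1), float(k2prime)


def transport_table(
    fits: Sequence[RegionFit] | Iterable[tuple[str, float, float]],
    d_ww: float = DEFAULT_D_WW,
    d_ll_by_phase: Mapping[str, float] | float | None = None,
) -> pd.DataFrame:
    """Per-phase cross diffusion coefficients as a tidy table.

    ``fits`` holds either :class:`RegionFit` objects or plain
    ``(phase, k1, k2prime)`` tuples, one per phase.  ``d_ll_by_phase`` may
    be a mapping, a single value applied to every phase, or None for the
    documented per-phase defaults.  Columns: phase, k1, k2prime, d_ww,
    d_ll, d_wl0, d_lw0, note (cm^2/s throughout).
    """
    rows = []
    for entry in fits:
        phase, k1, k2prime = _phase_k(entry)
        if d_ll_by_phase is None:
            d_ll = DEFAULT_D_LL_BY_PHASE.get(phase, D_LL_GEL)
        elif isinstance(d_ll_by_phase, Mapping):
            d_ll = d_ll_by_phase[phase]
        else:
            d_ll = float(d_ll_by_phase)
        coeff = derive_transport(TransportInputs(k1=k1, k2prime=k2prime, d_ww=d_ww, d_ll=d_ll))
        rows.append(
            {
                "phase": phase,
                "k1": k1,
                "k2prime": k2prime,
                "d_ww": d_ww,
                "d_ll": d_ll,
                "d_wl0": coeff.d_wl0,
                "d_lw0": coeff.d_lw0,
                "note": "; ".join(coeff.notes),
            }
        )
    return pd.DataFrame(
        rows, columns=["phase", "k1", "k2prime", "d_ww", "d_ll", "d_wl0", "d_lw0", "note"]
    )


def format_transport_table(table: pd.DataFrame) -> str:
    """Render the transport table with 3 significant figures per value."""
    if table.empty:
        return "(no regions)\n"
    lines = [f"{'phase':<18} {'k1':>9} {'k2prime':>9} {'D0_wL (cm2/s)':>14} {'D0_Lw (cm2/s)':>14}"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['phase']:<18} {row['k1']:>9.3g} {row['k2prime']:>9.3g} "
            f"{row['d_wl0']:>14.3g} {row['d_lw0']:>14.3g}"
        )
    return "\n".join(lines) + "\n"
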