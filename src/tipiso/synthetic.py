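"""Synthetic DPPC-like isotherms with known ground truth.

Experimental monolayer isotherms are trough exports that are rarely
redistributed with analysis code, so every fitting stage in this package
is exercised against synthetic data drawn from the TIP forward model
itself: per-region surface pressures from :func:`tipiso.models.eval_tip`
plus i.i.d. homoscedastic Gaussian noise with a caller-supplied seed.
The generator returns both the noisy isotherm and the generating truth so
that parameter-recovery tests have an exact oracle.

The packaged 25 C DPPC reference uses the three-region coefficient set
(liquid condensed p=3, k1=-0.28, k2'=1.62; coexistence p=1, k1=-0.43,
k2'=0.56; liquid expanded p=6, k1=-0.04, k2'=0.94).  The region area
ranges (LC 40-52, coexistence 52-75, LE 75-100 A^2/molecule) are
SYNTHETIC defaults chosen to resemble a typical DPPC compression run —
they are not measured boundaries.  Regions are generated independently
with no continuity constraint; the pressure jumps at the region
boundaries are reported in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fitting import RegionSpec
from .models import Isotherm, TIPParams, eval_tip

__all__ = [
    "RegionBand",
    "SyntheticSpec",
    "SyntheticIsotherm",
    "generate_isotherm",
    "dppc_reference",
    "DPPC_25C_BANDS",
    "DPPC_45C_BAND",
]


@dataclass(frozen=True)
class RegionBand:
    """One generating region: phase, half-open a_L range, grid size, truth."""

    phase_label: str
    lo: float
    hi: float
    n_points: int
    params: TIPParams

    def __post_init__(self) -> None:
        RegionSpec(self.phase_label, self.lo, self.hi)  # reuse validation
        if self.n_points < 3:
            raise ValueError("each region needs at least 3 grid points")

    def spec(self) -> RegionSpec:
        return RegionSpec(self.phase_label, self.lo, self.hi)

    def grid(self) -> np.ndarray:
        # endpoint excluded so [lo, hi) slicing recovers exactly this grid
        return np.linspace(self.lo, self.hi, self.n_points, endpoint=False)


@dataclass(frozen=True, eq=False)
class SyntheticSpec:
    """Full recipe for one synthetic isotherm."""

    regions: tuple[RegionBand, ...]
    temperature: float
    noise_sigma: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one region required")
        object.__setattr__(self, "regions", tuple(self.regions))
        ordered = sorted(self.regions, key=lambda r: r.lo)
        for left, right in zip(ordered, ordered[1:]):
            if left.hi > right.lo:
                raise ValueError("generating regions must be disjoint")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be non-negative")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")

    def region_specs(self) -> list[RegionSpec]:
        """Region specs ordered by descending a_L (piecewise-fit order)."""
        return [b.spec() for b in sorted(self.regions, key=lambda r: -r.lo)]

    def breakpoints(self) -> list[float]:
        """Internal region boundaries, ascending."""
        ordered = sorted(self.regions, key=lambda r: r.lo)
        return [b.lo for b in ordered[1:]]

    def params_by_phase(self) -> dict[str, TIPParams]:
        return {b.phase_label: b.params for b in self.regions}


@dataclass(frozen=True, eq=False)
class SyntheticIsotherm:
    """Noisy isotherm plus generating truth and boundary metadata."""

    isotherm: Isotherm
    clean_pressure: np.ndarray
    spec: SyntheticSpec
    #: pi discontinuities at internal region boundaries (upper minus lower
    #: region evaluated at the shared boundary area), mN/m
    boundary_jumps: tuple[float, ...] = ()


def generate_isotherm(spec: SyntheticSpec) -> SyntheticIsotherm:
    """Sample a synthetic isotherm from the TIP forward model.

    Per-region grids are concatenated in ascending a_L; Gaussian noise of
    standard deviation ``spec.noise_sigma`` (mN/m) is added with
    ``numpy.random.default_rng(spec.seed)``, so identical specs give
    bit-identical output.
    """
    ordered = sorted(spec.regions, key=lambda r: r.lo)
    grids = [band.grid() for band in ordered]
    clean = np.concatenate(
        [eval_tip(g, spec.temperature, band.params) for g, band in zip(grids, ordered)]
    )
    a = np.concatenate(grids)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=a.size) if spec.noise_sigma > 0 else 0.0
    iso = Isotherm(a, clean + noise, spec.temperature, label=spec.label)
    jumps = tuple(
        float(
            eval_tip(right.lo, spec.temperature, right.params)
            - eval_tip(right.lo, spec.temperature, left.params)
        )
        for left, right in zip(ordered, ordered[1:])
    )
    return SyntheticIsotherm(isotherm=iso, clean_pressure=clean, spec=spec, boundary_jumps=jumps)


#: reference three-region coefficient set for DPPC at 25 C with synthetic
#: default a_L ranges (see module docstring)
DPPC_25C_BANDS: tuple[tuple[str, float, float, TIPParams], ...] = (
    ("liquid_condensed", 40.0, 52.0, TIPParams(p=3, k1=-0.28, k2prime=1.62)),
    ("coexistence", 52.0, 75.0, TIPParams(p=1, k1=-0.43, k2prime=0.56)),
    ("liquid_expanded", 75.0, 100.0, TIPParams(p=6, k1=-0.04, k2prime=0.94)),
)

#: synthetic single-region band standing in for a supercritical (45 C)
#: isotherm; no reference coefficients exist for this regime, these are
#: the package's own smooth liquid-expanded-like defaults
DPPC_45C_BAND: tuple[str, float, float, TIPParams] = (
    "liquid_expanded", 60.0, 110.0, TIPParams(p=3, k1=0.6, k2prime=0.6),
)


def dppc_reference(
    temperature: str = "25C",
    n_per_region: int = 40,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params_45c: TIPParams | None = None,
) -> SyntheticIsotherm:
    """Packaged DPPC-like reference isotherm (synthetic, truth attached).

    ``temperature`` is "25C" (three regions, 298.15 K) or "45C" (single
    supercritical liquid-expanded region, 318.15 K, coefficients
    overridable via ``params_45c``).
    """
    if temperature == "25C":
        bands = tuple(
            RegionBand(phase, lo, hi, n_per_region, params)
            for phase, lo, hi, params in DPPC_25C_BANDS
        )
        t_kelvin, label = 298.15, "DPPC-like 25C (synthetic)"
    elif temperature == "45C":
        phase, lo, hi, params = DPPC_45C_BAND
        if params_45c is not None:
            params = params_45c
        bands = (RegionBand(phase, lo, hi, n_per_region, params),)
        t_kelvin, label = 318.15, "DPPC-like 45C (synthetic)"
    else:
        raise ValueError('temperature must be "25C" or "45C"')
    spec = SyntheticSpec(
        regions=bands,
        temperature=t_kelvin,
        noise_sigma=noise_sigma,
        seed=seed,
        label=label,
    )
    return generate_isotherm(spec)


def truth_table(spec: SyntheticSpec) -> list[dict]:
    """Generating parameters per region, JSON-friendly (for truth files)."""
    return [
        {
            "phase": band.phase_label,
            "a_range": [band.lo, band.hi],
            "n_points": band.n_points,
            "p": band.params.p,
            "k1": band.params.k1,
            "k2prime": band.params.k2prime,
            "a0": band.params.a0,
        }
        for band in sorted(spec.regions, key=lambda r: -r.lo)
    ]
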