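"""Region segmentation, TIP/van-der-Waals fitting and error metrics.

Compression isotherms of phospholipids below the chain-melting temperature
show three regimes: a liquid-expanded (LE) branch at large areas, a
near-flat LE/LC coexistence plateau, and a steep liquid-condensed (LC)
branch at small areas.  Each regime is fitted independently with the TIP
power law

    pi_p = k1 * kappa(T)/a_L + k2' * (kappa(T)/a0) * (a0/a_L)**p

which, for a fixed integer exponent p, is *linear* in (k1, k2'); the fit
is therefore an ordinary-least-squares solve per candidate p followed by a
discrete search over p (residual ties break toward the smaller, more
parsimonious exponent).

Degenerate case p = 1: the two regressors kappa/a_L and
(kappa/a0)*(a0/a_L) coincide, so only the sum k1 + k2' is identifiable
from data.  The fit then estimates the single sum coefficient and reports
it as k1 with k2' = 0 and an explanatory note; its standard error refers
to the sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import Isotherm, TIPParams, VdWParams, eval_ideal, eval_tip, eval_vdw, thermal_scale

__all__ = [
    "PHASES",
    "DEFAULT_P_CANDIDATES",
    "RegionSpec",
    "RegionFit",
    "VdWFitResult",
    "ModelComparison",
    "auto_breakpoints",
    "segment_isotherm",
    "fit_tip_region",
    "fit_tip_piecewise",
    "fit_vdw",
    "evaluate_tip_piecewise",
    "pointwise_error",
    "integral_error",
    "compare_models",
    "compare_fitted_models",
    "P1_DEGENERACY_NOTE",
]

PHASES = ("liquid_expanded", "coexistence", "liquid_condensed")

DEFAULT_P_CANDIDATES: tuple[int, ...] = tuple(range(1, 11))

P1_DEGENERACY_NOTE = (
    "p=1: basis functions coincide, only k1+k2' is identifiable; "
    "reported k1 is the fitted sum, k2'=0 by convention"
)

#: default phase labels for 1-, 2- and 3-region partitions, in ascending a_L
_DEFAULT_LABELS = {
    1: ("liquid_expanded",),
    2: ("liquid_condensed", "liquid_expanded"),
    3: ("liquid_condensed", "coexistence", "liquid_expanded"),
}

# relative residual difference below which two exponents count as tied
_RSS_TIE_REL = 1e-12


@dataclass(frozen=True)
class RegionSpec:
    """One phase region of an isotherm: half-open a_L interval [lo, hi)."""

    phase_label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.phase_label not in PHASES:
            raise ValueError(f"phase_label must be one of {PHASES}")
        if not (self.lo < self.hi):
            raise ValueError("require lo < hi")

    def contains(self, a: np.ndarray) -> np.ndarray:
        return (a >= self.lo) & (a < self.hi)


@dataclass(frozen=True, eq=False)
class RegionFit:
    """Fitted TIP parameters for one region, with residual statistics."""

    params: TIPParams
    k1_stderr: float
    k2prime_stderr: float
    rss: float
    n_points: int
    spec: RegionSpec | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.rss < 0.0:
            raise ValueError("rss must be non-negative")
        if self.n_points < 3:
            raise ValueError("a region fit needs at least 3 points")


def _validate_disjoint(specs: Sequence[RegionSpec]) -> None:
    ordered = sorted(specs, key=lambda s: s.lo)
    for left, right in zip(ordered, ordered[1:]):
        if left.hi > right.lo:
            raise ValueError(
                f"regions overlap: [{left.lo}, {left.hi}) and [{right.lo}, {right.hi})"
            )


def auto_breakpoints(
    iso: Isotherm, slope_fraction: float = 0.25, min_plateau: int = 3
) -> tuple[float, float]:
    """Locate the coexistence plateau and return its two boundary areas.

    Heuristic: central-difference slopes dpi/da_L whose magnitude falls
    below ``slope_fraction`` times the median slope magnitude mark plateau
    points; the longest contiguous interior run of at least ``min_plateau``
    such points is taken as the coexistence region.  Intended as a
    convenience only — explicit breakpoints take precedence when known.
    """
    a, pi = iso.area_per_lipid, iso.surface_pressure
    mag = np.abs(np.gradient(pi, a))
    mask = mag < slope_fraction * np.median(mag)
    best_start, best_len = -1, 0
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
            i = j + 1
        else:
            i += 1
    if best_len < min_plateau:
        raise ValueError("no coexistence plateau found (no flat slope run)")
    i0, i1 = best_start, best_start + best_len - 1
    if i0 == 0 or i1 == a.size - 1:
        raise ValueError("flat region touches the data edge; cannot form three regions")
    return float(a[i0]), float(a[i1 + 1])


def segment_isotherm(
    iso: Isotherm,
    breakpoints: Sequence[float] | str = "auto",
    labels: Sequence[str] | None = None,
    slope_fraction: float = 0.25,
    min_plateau: int = 3,
) -> list[tuple[RegionSpec, Isotherm]]:
    """Partition an isotherm into phase regions at the given breakpoints.

    ``breakpoints`` is either "auto" (plateau heuristic, see
    :func:`auto_breakpoints`) or strictly increasing a_L values strictly
    inside the data range.  Regions are half-open [lo, hi) with the
    topmost region closed at the data maximum; every point lands in
    exactly one region and each region must hold at least 3 points.
    Returned ordered by descending a_L (liquid expanded first for the
    canonical three-region split).
    """
    a = iso.area_per_lipid
    if isinstance(breakpoints, str):
        if breakpoints != "auto":
            raise ValueError("breakpoints must be 'auto' or a sequence of a_L values")
        bps: list[float] = list(auto_breakpoints(iso, slope_fraction, min_plateau))
    else:
        bps = [float(b) for b in breakpoints]
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not (a[0] < b < a[-1]) for b in bps):
            raise ValueError("breakpoints must lie strictly inside the data range")

    edges = [float(a[0])] + bps + [float(np.nextafter(a[-1], np.inf))]
    n_regions = len(edges) - 1
    if labels is None:
        if n_regions not in _DEFAULT_LABELS:
            raise ValueError(f"supply phase labels for a {n_regions}-region partition")
        labels = _DEFAULT_LABELS[n_regions]
    if len(labels) != n_regions:
        raise ValueError("one label per region required")

    out: list[tuple[RegionSpec, Isotherm]] = []
    for lab, lo, hi in zip(labels, edges, edges[1:]):
        spec = RegionSpec(lab, lo, hi)
        mask = spec.contains(a)
        if mask.sum() < 3:
            raise ValueError(f"region [{lo:g}, {hi:g}) holds fewer than 3 points")
        out.append(
            (spec, Isotherm(a[mask], iso.surface_pressure[mask], iso.temperature, iso.label))
        )
    out.reverse()  # descending a_L
    return out


def _tip_design(a: np.ndarray, kappa: float, a0: float, p: int) -> np.ndarray:
    return np.column_stack([kappa / a, (kappa / a0) * (a0 / a) ** p])


def _fit_fixed_p(
    a: np.ndarray, y: np.ndarray, kappa: float, a0: float, p: int
) -> tuple[float, float, float, float, float, str]:
    """OLS fit of (k1, k2') at fixed exponent p.

    Returns (k1, k2prime, k1_stderr, k2prime_stderr, rss, note).
    """
    n = a.size
    if p == 1:
        x = kappa / a
        sxx = float(x @ x)
        s = float(x @ y) / sxx
        resid = y - s * x
        rss = float(resid @ resid)
        sigma2 = rss / (n - 1)
        return s, 0.0, math.sqrt(sigma2 / sxx), math.nan, rss, P1_DEGENERACY_NOTE
    X = _tip_design(a, kappa, a0, p)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design: areas do not separate the TIP basis")
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return float(coef[0]), float(coef[1]), float(se[0]), float(se[1]), rss, ""


def fit_tip_region(
    iso: Isotherm,
    p_candidates: Iterable[int] = DEFAULT_P_CANDIDATES,
    fix_p: int | None = None,
    a0: float = 42.0,
    spec: RegionSpec | None = None,
) -> RegionFit:
    """Fit the TIP equation of state to one region of an isotherm.

    For each candidate exponent p the model is linear in (k1, k2') and
    solved by ordinary least squares; the p with the smallest residual sum
    of squares wins, with ties (relative difference below 1e-12 of the
    data's squared norm) broken toward smaller p.  ``fix_p`` bypasses the
    search.  Standard errors come from the homoscedastic linear-model
    covariance.
    """
    a, y = iso.area_per_lipid, iso.surface_pressure
    if a.size < 3:
        raise ValueError("need at least 3 points to fit two coefficients")
    cands = [int(fix_p)] if fix_p is not None else sorted({int(p) for p in p_candidates})
    if not cands:
        raise ValueError("p_candidates must be non-empty")
    if any(p < 1 for p in cands):
        raise ValueError("candidate exponents must be integers >= 1")
    kappa = thermal_scale(iso.temperature)
    scale = max(float(y @ y), np.finfo(float).tiny)

    best: tuple | None = None
    best_nrss = math.inf
    for p in cands:
        k1, k2p, se1, se2, rss, note = _fit_fixed_p(a, y, kappa, a0, p)
        nrss = rss / scale
        if best is None or nrss < best_nrss - _RSS_TIE_REL:
            best = (p, k1, k2p, se1, se2, rss, note)
            best_nrss = nrss
    p, k1, k2p, se1, se2, rss, note = best
    return RegionFit(
        params=TIPParams(p=p, k1=k1, k2prime=k2p, a0=a0),
        k1_stderr=se1,
        k2prime_stderr=se2,
        rss=rss,
        n_points=int(a.size),
        spec=spec,
        note=note,
    )


def fit_tip_piecewise(
    iso: Isotherm,
    specs: Sequence[RegionSpec],
    p_candidates: Iterable[int] = DEFAULT_P_CANDIDATES,
    fix_p_by_phase: Mapping[str, int] | None = None,
    a0: float = 42.0,
) -> list[RegionFit]:
    """Independent TIP fits for each region of a piecewise specification.

    Regions must be disjoint; output order follows ``specs``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    _validate_disjoint(specs)
    fits = []
    for spec in specs:
        sub = iso.slice_range(spec.lo, spec.hi)
        fix_p = None if fix_p_by_phase is None else fix_p_by_phase.get(spec.phase_label)
        fits.append(fit_tip_region(sub, p_candidates, fix_p=fix_p, a0=a0, spec=spec))
    return fits


@dataclass(frozen=True, eq=False)
class VdWFitResult:
    """Bounded nonlinear least-squares fit of the 2D van der Waals model."""

    params: VdWParams
    rss: float
    n_points: int
    converged: bool
    message: str = ""


def fit_vdw(
    iso: Isotherm, init: VdWParams | None = None, max_nfev: int = 1000
) -> VdWFitResult:
    """Fit (a_coh, b_co) of the 2D van der Waals equation of state.

    Bound-constrained least squares (a_coh >= 0, 0 <= b_co < min a_L),
    deterministic for a given ``init`` (default (0, 0), the ideal-gas
    corner).  Non-convergence is flagged on the result rather than raised,
    with the best iterate retained.
    """
    a, y = iso.area_per_lipid, iso.surface_pressure
    if a.size < 3:
        raise ValueError("need at least 3 points to fit the van der Waals model")
    amin = float(a.min())
    if init is None:
        init = VdWParams(0.0, 0.0)
    if init.b_co >= amin:
        raise ValueError("initial coarea must lie below the smallest area")
    kappa = thermal_scale(iso.temperature)

    def resid(x):
        return kappa / (a - x[1]) - x[0] / a**2 - y

    # the two parameters live on very different scales (a_coh ~ kappa*a_L,
    # b_co ~ a_L); scale steps by the Jacobian so neither stalls
    res = least_squares(
        resid,
        x0=[init.a_coh, init.b_co],
        bounds=([0.0, 0.0], [np.inf, amin * (1.0 - 1e-9)]),
        x_scale="jac",
        max_nfev=max_nfev,
    )
    return VdWFitResult(
        params=VdWParams(a_coh=float(res.x[0]), b_co=float(res.x[1])),
        rss=float(res.fun @ res.fun),
        n_points=int(a.size),
        converged=bool(res.success),
        message=str(res.message),
    )


def evaluate_tip_piecewise(
    area_per_lipid: np.ndarray, temperature: float, fits: Sequence[RegionFit]
) -> np.ndarray:
    """Evaluate a piecewise TIP fit on an area grid.

    Every grid point must fall in exactly one fitted region's [lo, hi).
    """
    a = np.asarray(area_per_lipid, dtype=float)
    out = np.full(a.shape, np.nan)
    for fit in fits:
        if fit.spec is None:
            raise ValueError("piecewise evaluation requires fits with region specs")
        mask = fit.spec.contains(a)
        out[mask] = eval_tip(a[mask], temperature, fit.params)
    if np.any(np.isnan(out)):
        raise ValueError("some grid points fall outside all fitted regions")
    return out


def pointwise_error(iso: Isotherm, model_pi: np.ndarray) -> np.ndarray:
    """Pointwise absolute error E(a_L) = |pi_exp - pi_model| in mN/m."""
    m = np.asarray(model_pi, dtype=float)
    if m.shape != iso.surface_pressure.shape:
        raise ValueError("model prediction length must match the isotherm")
    return np.abs(iso.surface_pressure - m)


def integral_error(iso: Isotherm, model_pi: np.ndarray) -> float:
    """Range-normalized integrated absolute error, in mN/m.

    Trapezoidal integral of |pi_exp - pi_model| over a_L divided by the
    width of the a_L range, so the result is the mean absolute deviation
    over the isotherm and is directly comparable with the pointwise error.
    """
    err = pointwise_error(iso, model_pi)
    a = iso.area_per_lipid
    width = float(a[-1] - a[0])
    return float(np.trapezoid(err, a) / width)


@dataclass(frozen=True, eq=False)
class ModelComparison:
    """Pointwise and integrated errors of several models on a shared grid."""

    area_grid: np.ndarray
    errors: dict[str, np.ndarray]
    integral_errors: dict[str, float]
    ranking: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.ranking:
            order = sorted(self.integral_errors, key=lambda k: (self.integral_errors[k], k))
            object.__setattr__(self, "ranking", tuple(order))


def compare_models(iso: Isotherm, predictions: Mapping[str, np.ndarray]) -> ModelComparison:
    """Error arrays and integral errors for each model's predictions.

    ``predictions`` maps a model name to its pi values on the isotherm's
    own a_L grid.  Models are ranked by ascending integral error.
    """
    if not predictions:
        raise ValueError("no model predictions supplied")
    errors = {name: pointwise_error(iso, pi) for name, pi in predictions.items()}
    e_int = {name: integral_error(iso, pi) for name, pi in predictions.items()}
    return ModelComparison(area_grid=iso.area_per_lipid.copy(), errors=errors, integral_errors=e_int)


def compare_fitted_models(
    iso: Isotherm,
    specs: Sequence[RegionSpec] | None = None,
    p_candidates: Iterable[int] = DEFAULT_P_CANDIDATES,
    a0: float = 42.0,
) -> tuple[ModelComparison, list[RegionFit], VdWFitResult]:
    """Fit vdW and (piecewise) TIP to one isotherm and compare all models.

    The ideal gas has no free parameters and is evaluated directly.  With
    ``specs=None`` the TIP fit uses a single region spanning the data.
    """
    a = iso.area_per_lipid
    if specs is None:
        specs = [RegionSpec("liquid_expanded", float(a[0]), float(np.nextafter(a[-1], np.inf)))]
    tip_fits = fit_tip_piecewise(iso, specs, p_candidates, a0=a0)
    vdw = fit_vdw(iso)
    predictions = {
        "ideal": eval_ideal(a, iso.temperature),
        "vdw": eval_vdw(a, iso.temperature, vdw.params),
        "tip": evaluate_tip_piecewise(a, iso.temperature, tip_fits),
    }
    return compare_models(iso, predictions), tip_fits, vdw
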