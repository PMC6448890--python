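"""Reading and writing isotherm files, fit reports and configuration.

Isotherms travel as delimited text (comma or tab, auto-detected) with a
header line and the columns ``area_per_lipid_A2`` and
``surface_pressure_mN_m``; the temperature is supplied by the caller (or
a config file), not per row.  Fit and comparison reports are JSON with
full numeric precision plus an embedded human-readable table rounded to
3 significant figures.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import ModelComparison, RegionFit
from .models import Isotherm

__all__ = [
    "REQUIRED_COLUMNS",
    "read_isotherm",
    "write_isotherm",
    "fit_report_dict",
    "format_fit_table",
    "write_fit_report",
    "read_fit_report",
    "load_config",
]

REQUIRED_COLUMNS = ("area_per_lipid_A2", "surface_pressure_mN_m")

#: areas closer than this (A^2) are treated as duplicate abscissae
DUPLICATE_TOL = 1e-9


def read_isotherm(path: str | Path, temperature: float, label: str | None = None) -> Isotherm:
    """Load a delimited isotherm file into a validated, ascending Isotherm.

    Comma and tab dialects are auto-detected.  Missing columns, non-numeric
    cells (reported with file line numbers, header = line 1), fewer than
    two rows, and duplicate areas are all rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    numeric = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in numeric.index[bad]]
        raise ValueError(f"{path}: non-numeric cell(s) at line(s) {lines}")
    if len(numeric) < 2:
        raise ValueError(f"{path}: an isotherm needs at least 2 data rows")
    numeric = numeric.sort_values(REQUIRED_COLUMNS[0], kind="stable")
    a = numeric[REQUIRED_COLUMNS[0]].to_numpy()
    if np.any(np.diff(a) < DUPLICATE_TOL):
        dup = a[1:][np.diff(a) < DUPLICATE_TOL]
        raise ValueError(f"{path}: duplicate area values near {dup[:5].tolist()}")
    return Isotherm(
        a,
        numeric[REQUIRED_COLUMNS[1]].to_numpy(),
        temperature=temperature,
        label=label if label is not None else path.stem,
    )


def write_isotherm(iso: Isotherm, path: str | Path, sep: str = ",") -> None:
    """Write an isotherm in the package's delimited-text schema."""
    iso.to_frame().to_csv(path, sep=sep, index=False)


def _finite(x: float) -> float | None:
    return float(x) if math.isfinite(x) else None


def _region_dict(fit: RegionFit) -> dict:
    return {
        "phase": fit.spec.phase_label if fit.spec is not None else None,
        "a_range": [fit.spec.lo, fit.spec.hi] if fit.spec is not None else None,
        "p": fit.params.p,
        "k1": fit.params.k1,
        "k1_stderr": _finite(fit.k1_stderr),
        "k2prime": fit.params.k2prime,
        "k2prime_stderr": _finite(fit.k2prime_stderr),
        "a0": fit.params.a0,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "note": fit.note,
    }


def format_fit_table(fits: Sequence[RegionFit]) -> str:
    """Human-readable per-region parameter table, 3 significant figures."""
    lines = [f"{'phase':<18} {'p':>3} {'k1 (se)':>20} {'k2prime (se)':>20} {'rss':>10} {'n':>4}"]
    for fit in fits:
        phase = fit.spec.phase_label if fit.spec is not None else "-"
        se1 = f"{fit.k1_stderr:.3g}" if math.isfinite(fit.k1_stderr) else "-"
        se2 = f"{fit.k2prime_stderr:.3g}" if math.isfinite(fit.k2prime_stderr) else "-"
        lines.append(
            f"{phase:<18} {fit.params.p:>3} {f'{fit.params.k1:.3g} ({se1})':>20} "
            f"{f'{fit.params.k2prime:.3g} ({se2})':>20} {fit.rss:>10.3g} {fit.n_points:>4}"
        )
    return "\n".join(lines) + "\n"


def fit_report_dict(
    fits: Sequence[RegionFit], comparison: ModelComparison | None = None
) -> dict:
    """JSON-ready report: per-region parameters plus optional comparison."""
    if not fits:
        raise ValueError("fit report requires at least one region fit")
    report: dict = {
        "regions": [_region_dict(f) for f in fits],
        "table": format_fit_table(fits),
    }
    if comparison is not None:
        report["comparison"] = {
            "integral_error_mN_m": {k: float(v) for k, v in comparison.integral_errors.items()},
            "ranking": list(comparison.ranking),
            "area_grid": comparison.area_grid.tolist(),
            "pointwise_error": {k: v.tolist() for k, v in comparison.errors.items()},
        }
    return report


def write_fit_report(
    fits: Sequence[RegionFit],
    path: str | Path,
    comparison: ModelComparison | None = None,
) -> dict:
    """Write the fit report as deterministic, sorted-key JSON; returns it."""
    report = fit_report_dict(fits, comparison)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n")
    return report


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> Mapping:
    """Load a YAML key/value config file (empty file -> empty mapping)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    return data
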