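"""Docking free energy -> activity proxy.

Converts binding free energies ``ΔG_B`` (kcal/mol, from docking) into estimated
pIC50 / IC50 values and binary activity classes, after sanitising implausible
docking scores.  Two proxy modes are supported:

* *thermodynamic* — treat ΔG_B as a binding free energy and invert
  ΔG = −ln(10)·R·T·pIC50 at a given temperature;
* *calibrated* — a least-squares line fitted on molecules with experimental
  pIC50 values (see :func:`calibrate_linear_map`).

IC50 is carried in molar units internally; µM/nM belong to presentation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS_KCAL",
    "PIC50_KCAL",
    "DockingResult",
    "ActivityRecord",
    "FilterSummary",
    "LinearMap",
    "filter_docking_range",
    "delta_g_to_pic50",
    "pic50_to_delta_g",
    "calibrate_linear_map",
    "classify_activity",
    "activity_table",
]

#: Gas constant in kcal mol^-1 K^-1.
R_GAS_KCAL = 1.98720e-3

#: kcal/mol per pIC50 unit at 298.15 K: ln(10)·R·T.
PIC50_KCAL = math.log(10.0) * R_GAS_KCAL * 298.15

#: Retained docking-score window (kcal/mol); values outside are implausible.
DG_MIN, DG_MAX = -20.0, -2.0

#: Activity threshold: active ⇔ IC50 ≤ 10 µM ⇔ pIC50 ≥ 5.
PIC50_ACTIVE_THRESHOLD = 5.0


@dataclass
class DockingResult:
    """Per-molecule docking outcome."""

    molecule_id: str
    delta_g: float  # kcal/mol
    retained: bool = True
    error: str | None = None


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    pic50: float
    ic50_molar: float
    activity_class: str  # "active" | "inactive"


@dataclass(frozen=True)
class FilterSummary:
    results: list[DockingResult]
    n_removed: int
    n_errors: int

    @property
    def retained(self) -> list[DockingResult]:
        return [r for r in self.results if r.retained]


def filter_docking_range(
    results: list[DockingResult],
    lo: float = DG_MIN,
    hi: float = DG_MAX,
) -> FilterSummary:
    """Flag docking scores outside the plausible [lo, hi] kcal/mol window.

    Boundary values are kept (the removal rule is strictly-outside).  Records
    with non-finite ΔG are flagged with an ``error`` string rather than being
    silently dropped; order is preserved.
    """
    out: list[DockingResult] = []
    n_removed = 0
    n_errors = 0
    for rec in results:
        if not np.isfinite(rec.delta_g):
            out.append(replace(rec, retained=False, error="non-finite delta_g"))
            n_errors += 1
        elif lo <= rec.delta_g <= hi:
            out.append(replace(rec, retained=True, error=None))
        else:
            out.append(replace(rec, retained=False, error=None))
            n_removed += 1
    return FilterSummary(out, n_removed=n_removed, n_errors=n_errors)


def delta_g_to_pic50(delta_g, temperature: float = 298.15):
    """Thermodynamic proxy: pIC50 = −ΔG / (ln(10)·R·T).

    Strictly decreasing in ΔG; ΔG = 0 maps to pIC50 = 0 (a 1 M dissociation
    constant).  Accepts scalars or arrays.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    dg = np.asarray(delta_g, dtype=float)
    if not np.all(np.isfinite(dg)):
        raise ValueError("delta_g must be finite")
    out = -dg / (math.log(10.0) * R_GAS_KCAL * temperature)
    return float(out) if np.isscalar(delta_g) or out.ndim == 0 else out


def pic50_to_delta_g(pic50, temperature: float = 298.15):
    """Inverse of :func:`delta_g_to_pic50`."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    p = np.asarray(pic50, dtype=float)
    out = -p * math.log(10.0) * R_GAS_KCAL * temperature
    return float(out) if np.isscalar(pic50) or out.ndim == 0 else out


@dataclass(frozen=True)
class LinearMap:
    """Least-squares line pIC50 = slope·ΔG + intercept, with its fit Pearson R."""

    slope: float
    intercept: float
    r: float

    def __call__(self, delta_g):
        dg = np.asarray(delta_g, dtype=float)
        out = self.slope * dg + self.intercept
        return float(out) if np.isscalar(delta_g) or out.ndim == 0 else out


def calibrate_linear_map(pic50_exp, delta_g) -> LinearMap:
    """Fit the regression-based proxy on (experimental pIC50, ΔG_B) pairs.

    Raises on a degenerate design (fewer than two pairs, or constant ΔG).
    """
    p = np.asarray(pic50_exp, dtype=float)
    g = np.asarray(delta_g, dtype=float)
    if p.shape != g.shape or p.ndim != 1:
        raise ValueError("pic50_exp and delta_g must be 1-D and equal length")
    if p.size < 2:
        raise ValueError("need at least 2 calibration pairs")
    if np.ptp(g) == 0:
        raise ValueError("constant delta_g: calibration design is degenerate")
    fit = stats.linregress(g, p)
    return LinearMap(slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue))


def classify_activity(pic50) -> str | np.ndarray:
    """Binary activity class: active ⇔ IC50 ≤ 10 µM, i.e. pIC50 ≥ 5 (inclusive)."""
    p = np.asarray(pic50, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pic50 must be finite")
    cls = np.where(p >= PIC50_ACTIVE_THRESHOLD, "active", "inactive")
    return str(cls) if np.isscalar(pic50) or cls.ndim == 0 else cls


def activity_table(summary: FilterSummary, proxy: LinearMap | None = None,
                   temperature: float = 298.15):
    """Build the sanitised activity table (one DataFrame row per input record).

    Removed / errored records keep their row with ``retained=False`` and NaN
    activity fields so bookkeeping stays exact.
    """
    import pandas as pd

    rows = []
    for rec in summary.results:
        if rec.retained:
            pic50 = proxy(rec.delta_g) if proxy is not None else delta_g_to_pic50(
                rec.delta_g, temperature)
            rows.append({
                "id": rec.molecule_id,
                "dg_kcal_mol": rec.delta_g,
                "pic50": pic50,
                "ic50_molar": 10.0 ** (-pic50),
                "class": classify_activity(pic50),
                "retained": True,
            })
        else:
            rows.append({
                "id": rec.molecule_id,
                "dg_kcal_mol": rec.delta_g,
                "pic50": np.nan,
                "ic50_molar": np.nan,
                "class": "",
                "retained": False,
            })
    return pd.DataFrame(rows)
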