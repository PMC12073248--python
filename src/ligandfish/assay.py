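"""Spectrophotometric tyrosinase assay reduction.

Dopachrome formation is followed at 450 nm.  Remaining enzyme activity is the
background-corrected sample absorbance relative to the background-corrected
enzyme-only control; percent inhibition is 100 minus that, clamped at zero
for reporting (extracts can also activate the enzyme, pushing remaining
activity above 100%, which the unclamped value preserves).  Dose–response
series are fitted with a four-parameter logistic (4PL) to read off the IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "remaining_activity",
    "inhibition_percent",
    "four_param_logistic",
    "fit_ic50",
    "DoseResponse",
    "read_plate_table",
    "reduce_plate",
]

ROLES = ("sample", "sample_background", "control", "control_background")


def remaining_activity(
    a_sample: float,
    a_sample_bg: float,
    a_control: float,
    a_control_bg: float,
) -> float:
    """Remaining enzyme activity in percent.

    100 x (A_sample - A_sample_bg) / (A_control - A_control_bg).  May exceed
    100 (enzyme activation).
    """
    denominator = a_control - a_control_bg
    if denominator <= 0:
        raise ValueError("corrected control absorbance must be positive")
    return 100.0 * (a_sample - a_sample_bg) / denominator


def inhibition_percent(remaining: float) -> float:
    """Percent inhibition: max(0, 100 - remaining activity)."""
    if remaining < 0:
        raise ValueError("remaining activity must be non-negative")
    return max(0.0, 100.0 - remaining)


def four_param_logistic(conc: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """4PL dose–response: bottom + (top - bottom) / (1 + (ic50 / c)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


@dataclass
class DoseResponse:
    """Concentration/inhibition pairs with a fitted 4PL and its IC50."""

    concentrations: np.ndarray
    inhibition: np.ndarray
    bottom: float = np.nan
    top: float = np.nan
    ic50: float = np.nan
    hill: float = np.nan
    converged: bool = False
    extrapolated: bool = False
    flag: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))


def _grid_fallback(conc: np.ndarray, inh: np.ndarray) -> tuple[float, float, float, float]:
    bottom, top = float(inh.min()), float(inh.max())
    grid_ic50 = np.geomspace(conc.min() / 10, conc.max() * 10, 200)
    grid_hill = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
    best = (np.inf, grid_ic50[0], 1.0)
    for h in grid_hill:
        for x in grid_ic50:
            sse = float(((four_param_logistic(conc, bottom, top, x, h) - inh) ** 2).sum())
            if sse < best[0]:
                best = (sse, float(x), float(h))
    return bottom, top, best[1], best[2]


def fit_ic50(
    concentrations: Sequence[float],
    inhibition: Sequence[float],
) -> DoseResponse:
    """Least-squares 4PL fit of percent inhibition versus concentration.

    Replicate measurements per concentration may be passed as a 2-D array
    (doses x replicates); they are averaged before fitting.  The fit needs at
    least four distinct concentrations.  Non-convergence falls back to a
    coarse grid search and is flagged; an essentially flat response yields no
    IC50 at all.  An IC50 outside the tested range is flagged extrapolated.
    """
    conc = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibition, dtype=float)
    if inh.ndim == 2:
        inh = inh.mean(axis=1)
    if conc.ndim != 1 or conc.shape != inh.shape:
        raise ValueError("concentrations and inhibition must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, inh = conc[order], inh[order]
    if np.unique(conc).size < 4:
        raise ValueError("need at least four distinct concentrations")

    result = DoseResponse(concentrations=conc, inhibition=inh)
    if inh.max() - inh.min() < 5.0:
        result.flag = "no_response"
        return result

    half = (inh.min() + inh.max()) / 2.0
    above = conc[inh >= half]
    p0 = [float(inh.min()), float(inh.max()), float(above[0]) if above.size else float(np.median(conc)), 1.0]
    bounds = ([-50.0, 0.0, conc.min() / 1e3, 0.05], [50.0, 200.0, conc.max() * 1e3, 20.0])
    p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, *bounds)]
    try:
        params, _ = curve_fit(four_param_logistic, conc, inh, p0=p0, bounds=bounds, maxfev=20000)
        result.converged = True
    except Exception:
        params = _grid_fallback(conc, inh)
        result.flag = "grid_fallback"
    result.bottom, result.top, result.ic50, result.hill = map(float, params)
    result.residuals = inh - four_param_logistic(conc, *params)
    result.extrapolated = not (conc.min() <= result.ic50 <= conc.max())
    return result


def read_plate_table(path: "str | Path") -> pd.DataFrame:
    """Read a plate-reader table: well, role, absorbance, optional concentration/replicate."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("role", "absorbance") if c not in df.columns]
    if missing:
        raise ValueError(f"plate table {path} is missing columns: {missing}")
    bad_roles = set(df["role"].str.strip().str.lower()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in plate table: {sorted(bad_roles)}")
    df["role"] = df["role"].str.strip().str.lower()
    if (df["absorbance"] < 0).any():
        raise ValueError("absorbance values must be non-negative")
    return df


def reduce_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-concentration remaining activity (± SD over replicates) and inhibition.

    Control wells (roles ``control`` / ``control_background``) are shared
    across the plate; sample wells are grouped by concentration when a
    concentration column is present.  The unclamped remaining activity is
    reported alongside the clamped inhibition.
    """
    control = plate.loc[plate["role"] == "control", "absorbance"].mean()
    control_bg = plate.loc[plate["role"] == "control_background", "absorbance"]
    control_bg = control_bg.mean() if len(control_bg) else 0.0
    samples = plate[plate["role"].isin(["sample", "sample_background"])]
    group_cols = ["concentration"] if "concentration" in plate.columns else []
    rows = []
    grouped = samples.groupby(group_cols) if group_cols else [((), samples)]
    for key, group in grouped:
        sample_abs = group.loc[group["role"] == "sample", "absorbance"].to_numpy()
        bg = group.loc[group["role"] == "sample_background", "absorbance"]
        bg_mean = bg.mean() if len(bg) else 0.0
        remaining = np.array(
            [remaining_activity(a, bg_mean, control, control_bg) for a in sample_abs]
        )
        row = {
            "remaining_activity": remaining.mean(),
            "remaining_sd": remaining.std(ddof=1) if remaining.size > 1 else 0.0,
            "inhibition": inhibition_percent(max(remaining.mean(), 0.0)),
            "n": remaining.size,
        }
        if group_cols:
            row["concentration"] = key[0] if isinstance(key, tuple) else key
        rows.append(row)
    return pd.DataFrame(rows)
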