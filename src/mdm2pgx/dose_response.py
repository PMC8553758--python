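"""Four-parameter logistic dose–response fitting and IC50 extraction.

The viability readout is Test/Control x 100 (T/C%): ~100 for untreated
growth, falling toward 0 under full inhibition.  Each cell line's
concentration series is fit with the 4PL

    TC(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

The *relative* IC50 is the curve midpoint (the ec50 parameter); the
*absolute* IC50 is the concentration at which the fitted curve crosses
TC = 50%.  Curves that never cross 50% inside the tested range are clamped
to the nearest grid boundary and flagged as censored, and those clamped
values enter downstream statistics as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .panel import AnalysisConfig

#: The assay's concentration grid: ten half-log steps (rounded 1-3-10
#: series), 0.001 up to 30 µM.
DEFAULT_CONCENTRATION_GRID_UM = (
    0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0
)

FLAT_TC_RANGE = 1e-6  # T/C% spread below which a curve is treated as flat


@dataclass
class DoseResponseCurve:
    cl_id: str
    drug_id: str
    concentrations: np.ndarray  # µM, strictly increasing
    tc_percent: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.tc_percent = np.asarray(self.tc_percent, dtype=float)
        if len(self.concentrations) != len(self.tc_percent):
            raise ValueError("concentrations and tc_percent must align")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ec50: float
    sse: float
    converged: bool
    flat: bool = False

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return four_pl(conc, self.top, self.bottom, self.hill, self.ec50)


def four_pl(conc, top, bottom, hill, ec50):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


def fit_four_pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares 4PL fit of one T/C% concentration series.

    Initialisation: top = max(tc), bottom = min(tc), hill = 1, ec50 at the
    concentration whose response is nearest the (top+bottom)/2 midpoint.
    Bounds: bottom >= 0, top <= 200, hill in [0.1, 10], ec50 in
    (0, 10 x max tested concentration].  Flat series (no response spread)
    are returned as converged with the hill pinned at 1 and flagged
    ``flat``; optimiser failure returns ``converged=False`` with the
    best-effort initial parameters.
    """
    if len(np.unique(curve.concentrations)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit a 4PL")
    conc = curve.concentrations
    tc = curve.tc_percent

    top0, bot0 = float(tc.max()), float(tc.min())
    if top0 - bot0 < FLAT_TC_RANGE:
        level = float(tc.mean())
        return FourPLFit(
            top=level, bottom=level, hill=1.0, ec50=float(np.median(conc)),
            sse=float(((tc - level) ** 2).sum()), converged=True, flat=True,
        )
    mid = (top0 + bot0) / 2.0
    ec50_0 = float(conc[np.argmin(np.abs(tc - mid))])
    p0 = [min(top0, 200.0), max(bot0, 0.0), 1.0, ec50_0]
    lower = [0.0, 0.0, 0.1, 1e-12]
    upper = [200.0, 200.0, 10.0, 10.0 * float(conc.max())]
    p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, lower, upper)]

    def model(c, top, bottom, hill, ec50):
        return four_pl(c, top, bottom, hill, ec50)

    try:
        popt, _ = curve_fit(
            model, conc, tc, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        top, bottom, hill, ec50 = (float(v) for v in popt)
        if bottom > top:  # enforce the bottom <= top invariant
            top, bottom = bottom, top
        sse = float(((tc - four_pl(conc, top, bottom, hill, ec50)) ** 2).sum())
        return FourPLFit(top, bottom, hill, ec50, sse, converged=True)
    except RuntimeError:
        top, bottom, hill, ec50 = p0
        sse = float(((tc - four_pl(conc, top, bottom, hill, ec50)) ** 2).sum())
        return FourPLFit(top, bottom, hill, ec50, sse, converged=False)


def extract_ic50(fit: FourPLFit, grid) -> dict:
    """Absolute/relative IC50 with censoring from a fitted curve.

    rel_ic50 is the curve midpoint (ec50).  abs_ic50 solves TC = 50:
    ``ec50 * ((top - 50) / (50 - bottom))^(1/hill)`` when the curve
    actually crosses 50% inside the tested range; otherwise the nearest
    boundary of the tested grid is used with a censoring flag
    (``at_lowest`` when the response is already below 50% at the lowest
    dose, ``at_highest`` when it never reaches 50%).
    """
    if not fit.converged:
        raise ValueError("cannot extract IC50 from a non-converged fit")
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid.min()), float(grid.max())
    rel = float(fit.ec50)

    tc_lo = float(fit.predict(lo))
    tc_hi = float(fit.predict(hi))
    if fit.flat or not (fit.bottom < 50.0 < fit.top):
        # No 50% crossing anywhere on the fitted curve.
        if tc_lo <= 50.0:
            return {"abs_ic50": lo, "rel_ic50": rel, "censor": "at_lowest"}
        return {"abs_ic50": hi, "rel_ic50": rel, "censor": "at_highest"}
    if tc_lo < 50.0:
        return {"abs_ic50": lo, "rel_ic50": rel, "censor": "at_lowest"}
    if tc_hi > 50.0:
        return {"abs_ic50": hi, "rel_ic50": rel, "censor": "at_highest"}
    abs_ic50 = fit.ec50 * ((fit.top - 50.0) / (50.0 - fit.bottom)) ** (1.0 / fit.hill)
    abs_ic50 = float(np.clip(abs_ic50, lo, hi))
    return {"abs_ic50": abs_ic50, "rel_ic50": rel, "censor": "none"}


def classify_response(abs_ic50: float, config: AnalysisConfig) -> str:
    """Three-class response label: <1 µM highly sensitive, [1, 10) µM
    intermediate, >= 10 µM resistant (cutoffs from the config)."""
    if not abs_ic50 > 0:
        raise ValueError("abs_ic50 must be positive")
    lo, hi = config.class_cutoffs_uM
    if abs_ic50 < lo:
        return "highly_sensitive"
    if abs_ic50 < hi:
        return "intermediate"
    return "resistant"


def fit_sensitivity(
    curves: list[DoseResponseCurve], config: AnalysisConfig
) -> pd.DataFrame:
    """Fit every curve and assemble a long-format sensitivity table."""
    rows = []
    for curve in curves:
        fit = fit_four_pl(curve)
        frag = extract_ic50(fit, curve.concentrations)
        rows.append(
            {
                "cl_id": curve.cl_id,
                "drug_id": curve.drug_id,
                "abs_ic50_uM": frag["abs_ic50"],
                "rel_ic50_uM": frag["rel_ic50"],
                "censor": frag["censor"],
                "response_class": classify_response(frag["abs_ic50"], config),
            }
        )
    return pd.DataFrame(rows)


def dichotomize(
    records: pd.DataFrame, config: AnalysisConfig
) -> tuple[float, pd.Series]:
    """Split the panel at the Abs IC50 percentile given by the config.

    cutoff = linear-interpolation percentile of the Abs IC50 values
    (default 30th); a line is ``sensitive`` iff abs_ic50 < cutoff and
    ``resistant`` otherwise (ties at the cutoff are resistant, matching
    the ">= 10 µM resistant" convention).  Returns (cutoff µM, labels
    indexed by cl_id).
    """
    if len(records) == 0:
        raise ValueError("no sensitivity records")
    if len(records) < 10:
        raise ValueError("need at least 10 records for a stable percentile")
    values = records["abs_ic50_uM"].to_numpy(dtype=float)
    cutoff = float(np.percentile(values, config.dichotomy_percentile))
    labels = pd.Series(
        np.where(values < cutoff, "sensitive", "resistant"),
        index=pd.Index(records["cl_id"], name="cl_id"),
        name="label",
    )
    return cutoff, labels


def summarize_panel(
    records: pd.DataFrame, cell_lines: pd.DataFrame, by: str = "tumour_type"
) -> pd.DataFrame:
    """Per-tumour-(sub)type response summary, plus an overall row.

    One row per group with n, median and IQR of Abs IC50, and the
    percentage of lines in each response class (summing to 100 per row);
    groups sorted by increasing median Abs IC50, the ``ALL`` row last.
    """
    joined = records.merge(
        cell_lines.reset_index()[["cl_id", by]], on="cl_id", how="inner"
    )

    def _row(group: pd.DataFrame) -> dict:
        vals = group["abs_ic50_uM"].to_numpy(dtype=float)
        n = len(vals)
        classes = group["response_class"].value_counts()
        return {
            "n": n,
            "median_abs_ic50_uM": float(np.median(vals)),
            "iqr_low_uM": float(np.percentile(vals, 25)),
            "iqr_high_uM": float(np.percentile(vals, 75)),
            "pct_highly_sensitive": 100.0 * classes.get("highly_sensitive", 0) / n,
            "pct_intermediate": 100.0 * classes.get("intermediate", 0) / n,
            "pct_resistant": 100.0 * classes.get("resistant", 0) / n,
        }

    rows = {name: _row(grp) for name, grp in joined.groupby(by)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = by
    table = table.sort_values("median_abs_ic50_uM", kind="stable")
    overall = pd.DataFrame.from_dict({"ALL": _row(joined)}, orient="index")
    overall.index.name = by
    return pd.concat([table, overall])
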