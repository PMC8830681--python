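"""Proteoglycan disaccharide normalization and summaries.

Cell-pellet disaccharide amounts (ng per sample) are normalized to ng per
cell through a DNA-dye fluorescence standard curve: the cell count of each
sample is back-calculated from the curve and the dilution factor, then the
raw amount is divided by it. Class totals (all sulfation codes of a
glycosaminoglycan class summed), per-species Z-score matrices and
per-species rhythm verdicts reproduce the study's summary outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .rhythm import RhythmCriteria, fit_catalog
from .synth import CS_CODES, HS_CODES

__all__ = [
    "StandardCurve",
    "StandardCurveModel",
    "fit_standard_curve",
    "cells_from_fluorescence",
    "normalize_per_cell",
    "normalize_table",
    "class_totals",
    "zscore_matrix",
    "species_rhythms",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS line fluorescence = slope * cell_count + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    dilution: float = 1.0


def fit_standard_curve(points: pd.DataFrame, dilution: float = 1.0) -> StandardCurve:
    """Fit the calibration line from a (cell_count, fluorescence) table."""
    counts = np.asarray(points["cell_count"], dtype=float)
    fluor = np.asarray(points["fluorescence"], dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(counts).size < 2:
        raise ValueError("calibration counts are all identical")
    res = sps.linregress(counts, fluor)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2), n_points=len(counts),
                         dilution=dilution)


class StandardCurveModel(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper around the calibration line.

    ``fit(X, y)`` takes known cell counts and fluorescence readings;
    ``predict`` maps counts to fluorescence and :meth:`inverse` maps a
    sample's fluorescence (and dilution) back to a cell count.
    """

    def __init__(self, dilution: float = 1.0):
        self.dilution = dilution

    def fit(self, X, y):
        counts = np.asarray(X, dtype=float).reshape(-1)
        fluor = np.asarray(y, dtype=float).reshape(-1)
        self.curve_ = fit_standard_curve(
            pd.DataFrame({"cell_count": counts, "fluorescence": fluor}),
            dilution=self.dilution)
        self.slope_ = self.curve_.slope
        self.intercept_ = self.curve_.intercept
        self.r_squared_ = self.curve_.r_squared
        return self

    def predict(self, X):
        counts = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * counts + self.intercept_

    def inverse(self, fluorescence, dilution: float | None = None):
        return cells_from_fluorescence(
            self.curve_, fluorescence,
            self.dilution if dilution is None else dilution)


def cells_from_fluorescence(curve: StandardCurve, fluorescence, dilution: float = 1.0):
    """Back-calculate cell counts: dilution * (F - intercept) / slope.

    Readings below the intercept give negative counts; those are clamped
    to 0 (the assay cannot see fewer than zero cells).
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero")
    f = np.asarray(fluorescence, dtype=float)
    count = dilution * (f - curve.intercept) / curve.slope
    clamped = np.maximum(count, 0.0)
    return (float(clamped), bool(np.any(count < 0))) if f.ndim == 0 \
        else (clamped, count < 0)


def normalize_per_cell(raw_ng, cell_count):
    """ng per sample -> ng per cell; non-positive counts yield NaN, flagged."""
    raw = np.asarray(raw_ng, dtype=float)
    n = np.asarray(cell_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, raw / np.where(n > 0, n, 1.0), np.nan)
    flagged = n <= 0
    if raw.ndim == 0:
        return float(out), bool(flagged)
    return out, flagged


def normalize_table(
    table: pd.DataFrame,
    curve: StandardCurve,
) -> pd.DataFrame:
    """Attach per-cell values to a raw disaccharide table.

    Cell-compartment rows are normalized to ng/cell via their CyQUANT
    fluorescence and dilution; other compartments keep their ng/ml values
    in ``value`` with ``unit`` recording the difference.
    """
    df = table.copy()
    is_cell = df["compartment"] == "cell"
    counts = np.full(len(df), np.nan)
    if is_cell.any():
        c, neg = cells_from_fluorescence(
            curve, df.loc[is_cell, "cyquant_fluorescence"].to_numpy(),
            dilution=float(df.loc[is_cell, "dilution"].iloc[0]))
        counts[is_cell.to_numpy()] = c
    df["cell_count"] = counts
    values = np.where(is_cell, df["raw_ng"] / np.where(counts > 0, counts, np.nan),
                      df.get("raw_ng_per_ml", df["raw_ng"]))
    df["value"] = values
    df["unit"] = np.where(is_cell, "ng/cell", "ng/ml")
    return df


def _check_units(df: pd.DataFrame) -> None:
    if "unit" in df.columns and df["unit"].nunique() > 1:
        raise ValueError("mixing ng/cell and ng/ml rows in one summary")


def class_totals(measurements: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Sum over sulfation codes per (class, compartment, timepoint, replicate),
    plus cross-replicate mean and SD of the totals."""
    _check_units(measurements)
    totals = (
        measurements
        .groupby(["class", "compartment", "time_ps", "replicate"])[value_col]
        .sum().rename("total").reset_index()
    )
    summary = (
        totals.groupby(["class", "compartment", "time_ps"])["total"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    )
    return totals.merge(summary, on=["class", "compartment", "time_ps"])


def zscore_matrix(measurements: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Species x timepoint matrix of row Z-scores of cross-replicate means.

    Each row is centered and scaled by its sample (n-1) SD; a constant row
    cannot be scaled and is set to all zeros (flagged via attrs).
    """
    _check_units(measurements)
    means = (
        measurements.groupby(["class", "code", "time_ps"])[value_col]
        .mean().reset_index()
    )
    wide = means.pivot_table(index=["class", "code"], columns="time_ps",
                             values=value_col)
    flat_rows = []
    z = wide.copy()
    for idx, row in wide.iterrows():
        sd = row.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            z.loc[idx] = 0.0
            flat_rows.append(idx)
        else:
            z.loc[idx] = (row - row.mean()) / sd
    z.attrs["constant_rows"] = flat_rows
    return z


def species_rhythms(
    measurements: pd.DataFrame,
    criteria: RhythmCriteria | None = None,
    *,
    value_col: str = "value",
    include_totals: bool = True,
    detrend: bool = True,
    smooth: bool = True,
) -> pd.DataFrame:
    """Rhythm verdicts per detected species (and per-class totals).

    Fits are replicate-resolved (no collapsing) and the BH/BY adjustments
    run across every series fitted in this invocation. Species with no
    detected signal (all zero) are excluded from fitting.
    """
    _check_units(measurements)
    catalog: dict[str, pd.DataFrame] = {}
    for (cls, code), grp in measurements.groupby(["class", "code"]):
        if (grp[value_col] == 0).all():
            continue
        catalog[f"{cls}:{code}"] = grp.rename(columns={value_col: "value"})[
            ["time_ps", "replicate", "value"]]
    if include_totals:
        totals = (
            measurements.groupby(["class", "time_ps", "replicate"])[value_col]
            .sum().rename("value").reset_index()
        )
        for cls, grp in totals.groupby("class"):
            catalog[f"{cls}:total"] = grp[["time_ps", "replicate", "value"]]
    return fit_catalog(catalog, criteria, detrend=detrend, smooth=smooth,
                       collapse_replicates=False)
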