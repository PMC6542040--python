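"""Intensity-matrix processing: LOQ imputation, normalization, fold change.

Missing cells are imputed only where a feature has *zero* detections across
all replicates of a (fluid x dose) group; the fill values are drawn around
that group's limit of quantification.  Cells in groups with at least one
detection stay missing and are handled pairwise-complete downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_CV = 0.3  # fallback when the low-intensity CV cannot be estimated


@dataclass
class FeatureMatrix:
    """Features x samples intensity matrix with an explicit transform state."""

    data: pd.DataFrame
    transform: str = "raw"  # "raw" | "normalized-log2"

    def __post_init__(self) -> None:
        if self.transform not in ("raw", "normalized-log2"):
            raise ValueError(f"unknown transform state {self.transform!r}")
        if self.transform == "raw" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw intensity matrix contains negative values")


def estimate_group_loq(
    fm: FeatureMatrix, design: pd.DataFrame, quantile: float = 0.05
) -> pd.DataFrame:
    """Per (fluid, dose) limit of quantification and CV near it.

    LOQ is the ``quantile`` of all observed intensities in the group; the CV
    is the median per-feature CV among features whose group mean lies in the
    lowest decile of group means (fallback ``DEFAULT_CV`` when that is not
    estimable, e.g. degenerate or tiny groups).
    """
    if fm.transform != "raw":
        raise ValueError("LOQ is estimated on the raw matrix")
    rows = []
    for (fluid, dose), sub in design.groupby(["fluid", "dose"]):
        cols = [s for s in sub["sample"] if s in fm.data.columns]
        block = fm.data[cols]
        observed = block.to_numpy().ravel()
        observed = observed[~np.isnan(observed)]
        if observed.size == 0:
            raise ValueError(f"group ({fluid}, {dose}) has no observed intensities")
        loq = float(np.quantile(observed, quantile))
        means = block.mean(axis=1)
        sds = block.std(axis=1, ddof=1)
        cvs = (sds / means).replace([np.inf, -np.inf], np.nan)
        low = means <= means.quantile(0.10)
        cv_pool = cvs[low].dropna()
        cv = float(cv_pool.median()) if len(cv_pool) else DEFAULT_CV
        if not np.isfinite(cv) or cv <= 0:
            cv = DEFAULT_CV
        rows.append({"fluid": fluid, "dose": dose, "loq": loq, "cv": cv})
    return pd.DataFrame(rows)


def impute_below_lod(
    fm: FeatureMatrix, design: pd.DataFrame, loq: pd.DataFrame, seed: int = 0
) -> FeatureMatrix:
    """Fill feature x group cells that have zero detections in the group.

    Fills are drawn from a normal truncated at zero with mean = group LOQ
    and sd = CV * LOQ.  Groups with any detection are left untouched.
    """
    if fm.transform != "raw":
        raise ValueError("imputation operates on the raw matrix")
    rng = np.random.default_rng(seed)
    data = fm.data.copy()
    loq_ix = loq.set_index(["fluid", "dose"])
    for (fluid, dose), sub in design.groupby(["fluid", "dose"]):
        cols = [s for s in sub["sample"] if s in data.columns]
        if not cols:
            continue
        block = data[cols]
        all_missing = block.isna().all(axis=1)
        idx = data.index[all_missing]
        if len(idx) == 0:
            continue
        mu = loq_ix.loc[(fluid, dose), "loq"]
        sd = loq_ix.loc[(fluid, dose), "cv"] * mu
        a = (0.0 - mu) / sd
        draws = sps.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sd, size=(len(idx), len(cols)), random_state=rng
        )
        data.loc[idx, cols] = draws
    return FeatureMatrix(data=data, transform="raw")


def normalize_log2(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-sample median centering on the log2 scale.

    Each sample's log2 values are shifted so its median equals the grand
    median of all observed log2 values, preserving the overall scale while
    removing per-sample loading differences.
    """
    if fm.transform != "raw":
        raise ValueError("matrix is already normalized")
    values = fm.data.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if (observed <= 0).any():
        raise ValueError("normalize_log2 requires strictly positive intensities")
    logged = np.log2(values)
    grand = np.nanmedian(logged)
    sample_medians = np.nanmedian(logged, axis=0)
    centered = logged - sample_medians[None, :] + grand
    return FeatureMatrix(
        data=pd.DataFrame(centered, index=fm.data.index, columns=fm.data.columns),
        transform="normalized-log2",
    )


def fold_change(fm: FeatureMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-feature log2 fold change of each dosed group vs the dose-0 group.

    Computed per fluid as mean(log2 dosed) - mean(log2 vehicle) over the
    available (observed or imputed) values.  Columns are (fluid, dose).
    """
    if fm.transform != "normalized-log2":
        raise ValueError("fold change requires the normalized-log2 matrix")
    doses = sorted(design["dose"].unique())
    if 0 not in doses:
        raise ValueError("fold change requires a dose-0 vehicle group")
    out = {}
    for fluid, sub in design.groupby("fluid"):
        ref_cols = [
            s for s in sub.loc[sub["dose"] == 0, "sample"] if s in fm.data.columns
        ]
        ref = fm.data[ref_cols].mean(axis=1)
        for dose in doses:
            if dose == 0:
                continue
            cols = [
                s for s in sub.loc[sub["dose"] == dose, "sample"] if s in fm.data.columns
            ]
            out[(fluid, dose)] = fm.data[cols].mean(axis=1) - ref
    fc = pd.DataFrame(out)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["fluid", "dose"])
    return fc


def estimate_concentration(mean_intensity: float, response_factor: float) -> float:
    """Single-point concentration approximation: intensity / (intensity per nM)."""
    if response_factor <= 0:
        raise ValueError(f"response factor must be positive, got {response_factor}")
    return mean_intensity / response_factor
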