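"""Dose-response testing, FDR control, exclusivity classes, paired-fluid fit.

One-way fixed-effects ANOVA per feature across dose groups, Benjamini-
Hochberg step-up adjustment at 5% FDR, detection-based classification into
exposure-exclusive / lost / modulated / null, and pooled ordinary least
squares of serum on BALF log2 intensity within a dose group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def anova_per_feature(
    fm, design: pd.DataFrame, fluid: str
) -> pd.DataFrame:
    """One-way ANOVA of log2 intensity across dose groups, per feature.

    Features with fewer than two groups holding >= 2 observations are marked
    untestable (F = NaN, p = 1).  All-constant features get p = 1 by
    convention.  Returns columns F, p, testable.
    """
    if fm.transform != "normalized-log2":
        raise ValueError("ANOVA requires the normalized-log2 matrix")
    sub = design[design["fluid"] == fluid]
    if sub.empty:
        raise ValueError(f"no samples for fluid {fluid!r}")
    group_cols = [
        [s for s in g["sample"] if s in fm.data.columns]
        for _, g in sub.groupby("dose")
    ]
    blocks = [fm.data[cols].to_numpy(dtype=float) for cols in group_cols if cols]

    n_feat = len(fm.data)
    F = np.full(n_feat, np.nan)
    p = np.ones(n_feat)
    testable = np.zeros(n_feat, dtype=bool)
    for i in range(n_feat):
        groups = []
        for blk in blocks:
            vals = blk[i]
            vals = vals[~np.isnan(vals)]
            if len(vals) >= 2:
                groups.append(vals)
        if len(groups) < 2:
            continue
        testable[i] = True
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # all-constant: no variance to test
            F[i] = 0.0
            p[i] = 1.0
            continue
        res = sps.f_oneway(*groups)
        F[i] = res.statistic
        p[i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return pd.DataFrame({"F": F, "p": p, "testable": testable}, index=fm.data.index)


def bh_adjust(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q values and significance flags.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; a feature is
    flagged iff q <= alpha.  Untestable features should enter with p = 1 so
    they stay in the denominator m.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    index = pvalues.index if isinstance(pvalues, pd.Series) else None
    return pd.DataFrame({"p": p, "q": q, "significant": q <= alpha}, index=index)


def classify_exclusivity(
    counts: pd.DataFrame,
    sizes: pd.Series,
    significant: pd.Series,
    min_frac: float = 2.0 / 3.0,
) -> pd.Series:
    """Per-feature class from one fluid's group detection counts.

    exposure-exclusive: reproducibly present in >= 1 dosed group, zero
    detections in any dose-0 replicate.  lost: reproducibly present at dose
    0, zero detections in every dosed group.  Otherwise modulated (if
    flagged significant) or null.
    """
    import math

    doses = counts.columns.get_level_values("dose") if isinstance(
        counts.columns, pd.MultiIndex
    ) else counts.columns
    dosed = [c for c, d in zip(counts.columns, doses) if d > 0]
    vehicle = [c for c, d in zip(counts.columns, doses) if d == 0]
    if not vehicle or not dosed:
        raise ValueError("classification needs a dose-0 group and >= 1 dosed group")

    thr = {c: math.ceil(min_frac * sizes[tuple(c) if isinstance(c, tuple) else c]) for c in counts.columns}
    present = pd.DataFrame({c: counts[c] >= thr[c] for c in counts.columns})

    zero_vehicle = (counts[vehicle] == 0).all(axis=1)
    zero_dosed = (counts[dosed] == 0).all(axis=1)
    present_dosed = present[dosed].any(axis=1)
    present_vehicle = present[vehicle].any(axis=1)

    cls = pd.Series("null", index=counts.index, dtype=object)
    sig = significant.reindex(counts.index).fillna(False).astype(bool)
    cls[sig] = "modulated"
    cls[present_vehicle & zero_dosed] = "lost"
    cls[present_dosed & zero_vehicle] = "exposure-exclusive"
    return cls


@dataclass(frozen=True)
class CrossFluidFit:
    """Pooled serum-on-BALF regression summary for one dose group."""

    dose: int
    slope: float
    intercept: float
    r: float
    F: float
    p: float
    n: int


def crossfluid_regression(
    fm, design: pd.DataFrame, features, dose: int
) -> CrossFluidFit:
    """OLS of serum log2 intensity on BALF log2 intensity within a dose.

    Pools one point per (feature, animal) pair over the given features,
    using pairwise-complete values.  Needs >= 3 points and non-degenerate
    variance on both axes.
    """
    if fm.transform != "normalized-log2":
        raise ValueError("regression requires the normalized-log2 matrix")
    sub = design[design["dose"] == dose]
    pairs = sub.pivot(index="animal", columns="fluid", values="sample")
    if "serum" not in pairs.columns or "BALF" not in pairs.columns:
        raise ValueError(f"dose {dose} lacks paired serum/BALF samples")
    feats = [f for f in features if f in fm.data.index]
    xs, ys = [], []
    for _, row in pairs.iterrows():
        s_col, b_col = row["serum"], row["BALF"]
        if s_col not in fm.data.columns or b_col not in fm.data.columns:
            continue
        s = fm.data.loc[feats, s_col].to_numpy(dtype=float)
        b = fm.data.loc[feats, b_col].to_numpy(dtype=float)
        ok = ~np.isnan(s) & ~np.isnan(b)
        xs.append(b[ok])
        ys.append(s[ok])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    n = len(x)
    if n < 3:
        raise ValueError(f"dose {dose}: only {n} complete feature x animal pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in regression inputs")
    fit = sps.linregress(x, y)
    r = fit.rvalue
    df = n - 2
    F = (r * r * df / (1.0 - r * r)) if abs(r) < 1.0 else np.inf
    return CrossFluidFit(
        dose=int(dose),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(r),
        F=float(F),
        p=float(fit.pvalue),
        n=int(n),
    )


def differential_table(
    fm, design: pd.DataFrame, fluid: str, counts: pd.DataFrame, sizes: pd.Series,
    alpha: float = 0.05, min_frac: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """ANOVA + BH + fold change + exclusivity class for one fluid."""
    from .quantify import fold_change

    anova = anova_per_feature(fm, design, fluid)
    adj = bh_adjust(anova["p"], alpha=alpha)
    fc = fold_change(fm, design)
    fluid_counts = counts.xs(fluid, level="fluid", axis=1)
    fluid_sizes = sizes.loc[fluid]
    cls = classify_exclusivity(fluid_counts, fluid_sizes, adj["significant"], min_frac)
    table = pd.concat(
        [anova, adj[["q", "significant"]], cls.rename("cls")], axis=1
    )
    for dose in fc.columns.get_level_values("dose").unique():
        if (fluid, dose) in fc.columns:
            table[f"log2fc_{dose}"] = fc[(fluid, dose)]
    return table
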