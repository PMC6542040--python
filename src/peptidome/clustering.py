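"""Cross-sample clustering of ion events into features, plus filters.

Events from all samples of both fluids are clustered jointly in retention
time (+/-2 min), drift time (+/-4 bins) and mass (+/-12 ppm).  The
algorithm is greedy and seeded: the most intense unassigned event opens a
feature and recruits every unassigned event inside the tolerance box of
the seed, at most one per sample (nearest first).  Intensity ties break by
(mass, rt, drift, sample) so the partition is deterministic.

A mass-sorted index keeps candidate lookup to a narrow ppm window, so
clustering is O(n log n) rather than all-pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ToleranceBox:
    """Matching tolerances: rt (min), drift (bins), mass (ppm)."""

    rt: float = 2.0
    drift: float = 4.0
    ppm: float = 12.0

    def __post_init__(self) -> None:
        if self.rt <= 0 or self.drift <= 0 or self.ppm <= 0:
            raise ValueError(f"tolerances must be strictly positive: {self}")


def cluster_events(
    events: pd.DataFrame, box: ToleranceBox | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition ion events into features.

    Returns ``(assignments, features)``: *assignments* is the input table
    plus a ``feature_id`` column; *features* holds one row per feature with
    the member-mean centroid and member count.  Every event is assigned to
    exactly one feature.  Tolerances are measured from the seed event, so
    no two members can be farther apart than twice a tolerance.
    """
    box = box or ToleranceBox()
    if len(events) == 0:
        assignments = events.copy()
        assignments["feature_id"] = pd.Series([], dtype=object)
        features = pd.DataFrame(
            columns=["feature_id", "rt_min", "drift_bin", "mass_da", "n_events"]
        )
        return assignments, features

    rt = events["rt_min"].to_numpy(dtype=float)
    drift = events["drift_bin"].to_numpy(dtype=float)
    mass = events["mass_da"].to_numpy(dtype=float)
    intensity = events["intensity"].to_numpy(dtype=float)
    sample_codes, _ = pd.factorize(events["sample"])

    n = len(events)
    # seed priority: descending intensity, ties by (mass, rt, drift, sample)
    priority = np.lexsort((sample_codes, drift, rt, mass, -intensity))
    # mass-sorted index for windowed candidate lookup
    mass_order = np.argsort(mass, kind="mergesort")
    mass_sorted = mass[mass_order]

    cluster = np.full(n, -1, dtype=np.int64)
    n_clusters = 0
    for seed_idx in priority:
        if cluster[seed_idx] >= 0:
            continue
        cid = n_clusters
        n_clusters += 1
        cluster[seed_idx] = cid
        m0, r0, d0 = mass[seed_idx], rt[seed_idx], drift[seed_idx]
        tol_da = m0 * box.ppm * 1e-6
        lo = np.searchsorted(mass_sorted, m0 - tol_da, side="left")
        hi = np.searchsorted(mass_sorted, m0 + tol_da, side="right")
        cand = mass_order[lo:hi]
        cand = cand[cluster[cand] < 0]
        if cand.size == 0:
            continue
        ok = (np.abs(rt[cand] - r0) <= box.rt) & (np.abs(drift[cand] - d0) <= box.drift)
        cand = cand[ok]
        if cand.size == 0:
            continue
        # at most one member per sample: nearest by tolerance-normalized distance
        dist = (
            ((rt[cand] - r0) / box.rt) ** 2
            + ((drift[cand] - d0) / box.drift) ** 2
            + ((mass[cand] - m0) / (m0 * box.ppm * 1e-6)) ** 2
        )
        order = np.lexsort((cand, dist))  # stable: distance then original index
        taken = {sample_codes[seed_idx]}
        for j in order:
            e = cand[j]
            sc = sample_codes[e]
            if sc in taken:
                continue
            taken.add(sc)
            cluster[e] = cid

    assignments = events.copy()
    assignments["feature_id"] = [f"C{c:06d}" for c in cluster]

    grp = assignments.groupby("feature_id")
    features = grp.agg(
        rt_min=("rt_min", "mean"),
        drift_bin=("drift_bin", "mean"),
        mass_da=("mass_da", "mean"),
        n_events=("mass_da", "size"),
    ).reset_index()
    return assignments, features


def feature_matrix_from_assignments(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pivot assigned events into a features x samples intensity matrix.

    If a feature holds more than one event for a sample (cannot happen with
    :func:`cluster_events` output) the maximum intensity wins.
    """
    return assignments.pivot_table(
        index="feature_id", columns="sample", values="intensity", aggfunc="max"
    )


def detection_counts(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature detection counts in each (fluid, dose) group.

    Returns ``(counts, group_sizes)`` where *counts* has a MultiIndex
    (fluid, dose) column per group.
    """
    unknown = set(matrix.columns) - set(design["sample"])
    if unknown:
        raise ValueError(f"samples absent from design: {sorted(unknown)}")
    groups = design.groupby(["fluid", "dose"])["sample"].apply(list)
    counts = pd.DataFrame(index=matrix.index)
    sizes = {}
    for (fluid, dose), samples in groups.items():
        cols = [s for s in samples if s in matrix.columns]
        counts[(fluid, dose)] = matrix[cols].notna().sum(axis=1) if cols else 0
        sizes[(fluid, dose)] = len(samples)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["fluid", "dose"])
    return counts, pd.Series(sizes)


def group_presence(
    counts: pd.DataFrame, sizes: pd.Series, min_frac: float = 2.0 / 3.0
) -> pd.DataFrame:
    """Boolean reproducible-presence call per (fluid, dose) group.

    Present iff detections >= ceil(min_frac * group size).
    """
    thresholds = {g: math.ceil(min_frac * sz) for g, sz in sizes.items()}
    out = pd.DataFrame(index=counts.index)
    for g in counts.columns:
        out[g] = counts[g] >= thresholds[tuple(g)]
    out.columns = counts.columns
    return out


def reproducibility_filter(
    matrix: pd.DataFrame, design: pd.DataFrame, min_frac: float = 2.0 / 3.0
) -> pd.DataFrame:
    """Keep features reproducibly detected in at least one (fluid, dose) group."""
    counts, sizes = detection_counts(matrix, design)
    present = group_presence(counts, sizes, min_frac)
    return matrix.loc[present.any(axis=1)]


def overlap_report(
    matrix: pd.DataFrame, design: pd.DataFrame, min_frac: float = 2.0 / 3.0
) -> dict[str, int]:
    """Counts of serum-only, BALF-only and common reproducible features.

    A feature is *common* iff it passes the reproducibility threshold in at
    least one group of each fluid.
    """
    fluids = sorted(design["fluid"].unique())
    if len(fluids) < 2:
        raise ValueError(f"overlap report needs both fluids, design has {fluids}")
    counts, sizes = detection_counts(matrix, design)
    present = group_presence(counts, sizes, min_frac)
    by_fluid = {f: present.xs(f, level="fluid", axis=1).any(axis=1) for f in fluids}
    serum, balf = by_fluid["serum"], by_fluid["BALF"]
    return {
        "serum_only": int((serum & ~balf).sum()),
        "balf_only": int((balf & ~serum).sum()),
        "common": int((serum & balf).sum()),
        "serum_total": int(serum.sum()),
        "balf_total": int(balf.sum()),
    }
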