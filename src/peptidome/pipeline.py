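"""End-to-end orchestration: simulate -> cluster -> quantify -> stats -> identify.

A single master seed fans out to per-stage seeds through a stable hash of
the stage name, so any stage can be re-run in isolation and still
reproduce.  The effective configuration is written next to the outputs and
identical config + inputs yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, identify, io, quantify, simulate, stats
from .mass import residue_mass_sum
from .quantify import FeatureMatrix

log = logging.getLogger("peptidome")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # simulate
    n_per_group: int = 6
    doses: tuple[int, ...] = (0, 10, 40)
    n_features: int = 2000
    cross_fluid_r: float = 0.5
    effect_log2fc: float = 1.0
    lod: float = 4096.0
    n_spectra: int = 100
    db_fasta: str | None = None
    # cluster
    rt_tol: float = 2.0
    drift_tol: float = 4.0
    ppm_tol: float = 12.0
    min_frac: float = 2.0 / 3.0
    # quantify
    loq_quantile: float = 0.05
    # stats
    alpha: float = 0.05
    # identify
    precursor_ppm: float = 6.0
    product_ppm: float = 12.0
    fdr: float = 0.10
    min_len: int = 6
    max_len: int = 80
    stages: tuple[str, ...] = ("simulate", "cluster", "quantify", "stats", "identify")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["doses"] = list(self.doses)
        doc["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def __post_init__(self) -> None:
        self.doses = tuple(self.doses)
        self.stages = tuple(self.stages)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed, "stages": list(config.stages)}

    db_path = Path(config.db_fasta) if config.db_fasta else simulate.bundled_substrate_fasta()

    if "simulate" in config.stages:
        log.info("stage simulate")
        sim = simulate.simulate_dataset(
            out,
            db_fasta=db_path,
            n_per_group=config.n_per_group,
            doses=config.doses,
            n_features=config.n_features,
            cross_fluid_r=config.cross_fluid_r,
            effect_log2fc=config.effect_log2fc,
            lod=config.lod,
            n_spectra=config.n_spectra,
            seed=stage_seed(config.seed, "simulate"),
        )
        report["simulate"] = {k: sim[k] for k in ("n_samples", "n_events", "n_spectra")}
    if set(config.stages) == {"simulate"}:
        report["note"] = "downstream stages skipped"
        _write_report(report, out)
        return report

    design = io.read_design(out / "design.tsv")
    events = io.read_ion_events(out / "ion_events.tsv")

    matrix = None
    if "cluster" in config.stages:
        log.info("stage cluster")
        box = clustering.ToleranceBox(config.rt_tol, config.drift_tol, config.ppm_tol)
        assignments, features = clustering.cluster_events(events, box)
        matrix = clustering.feature_matrix_from_assignments(assignments)
        filtered = clustering.reproducibility_filter(matrix, design, config.min_frac)
        overlap = clustering.overlap_report(filtered, design, config.min_frac)
        features.to_csv(out / "features.tsv", sep="\t", index=False)
        io.write_feature_matrix(filtered, out / "feature_matrix.tsv")
        report["cluster"] = {
            "n_features_total": int(len(features)),
            "n_features_reproducible": int(len(filtered)),
            **overlap,
        }
        matrix = filtered

    fm_norm = None
    if "quantify" in config.stages:
        log.info("stage quantify")
        if matrix is None:
            matrix = io.read_feature_matrix(out / "feature_matrix.tsv")
        fm = FeatureMatrix(matrix)
        loq = quantify.estimate_group_loq(fm, design, config.loq_quantile)
        fm = quantify.impute_below_lod(fm, design, loq, stage_seed(config.seed, "quantify"))
        fm_norm = quantify.normalize_log2(fm)
        loq.to_csv(out / "group_loq.tsv", sep="\t", index=False)
        io.write_feature_matrix(fm_norm.data, out / "normalized_matrix.tsv")
        report["quantify"] = {"groups": len(loq), "transform": fm_norm.transform}

    if "stats" in config.stages:
        log.info("stage stats")
        if fm_norm is None:
            fm_norm = FeatureMatrix(
                io.read_feature_matrix(out / "normalized_matrix.tsv"),
                transform="normalized-log2",
            )
            matrix = io.read_feature_matrix(out / "feature_matrix.tsv")
        counts, sizes = clustering.detection_counts(matrix, design)
        stats_report = {}
        sig_union: set = set()
        for fluid in sorted(design["fluid"].unique()):
            table = stats.differential_table(
                fm_norm, design, fluid, counts, sizes, config.alpha, config.min_frac
            )
            table.to_csv(out / f"differential_{fluid}.tsv", sep="\t")
            sig = table.index[table["significant"]]
            sig_union.update(sig)
            stats_report[fluid] = {
                "n_significant": int(table["significant"].sum()),
                "classes": table["cls"].value_counts().to_dict(),
            }
        fits = {}
        for dose in [d for d in config.doses if d > 0]:
            try:
                fit = stats.crossfluid_regression(fm_norm, design, sorted(sig_union), dose)
                fits[str(dose)] = asdict(fit)
            except ValueError as exc:
                fits[str(dose)] = {"error": str(exc)}
        with open(out / "crossfluid_fits.json", "w") as fh:
            json.dump(fits, fh, indent=1, sort_keys=True)
        stats_report["crossfluid"] = fits
        report["stats"] = stats_report

    if "identify" in config.stages:
        log.info("stage identify")
        spectra = io.read_mgf(out / "spectra.mgf")
        db = identify.build_index(db_path)
        targets, decoys = identify.decoy_search(
            spectra,
            db,
            precursor_ppm=config.precursor_ppm,
            product_ppm=config.product_ppm,
            len_bounds=(config.min_len, config.max_len),
            decoy_seed=stage_seed(config.seed, "identify"),
        )
        accepted = identify.fdr_threshold(targets, decoys, config.fdr)
        frame = identify.matches_to_frame(accepted, db)
        frame.to_csv(out / "identifications.tsv", sep="\t", index=False)
        report["identify"] = {
            "n_spectra": len(spectra),
            "n_target_matches": len(targets),
            "n_decoy_matches": len(decoys),
            "n_accepted": len(accepted),
        }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


def validate_reference_table(
    table_path: str | Path | None = None, tol_da: float = 0.001
) -> pd.DataFrame:
    """Recompute theoretical masses for the bundled reference peptide table.

    Each row's residue-mass sum (fixed carbamidomethyl-C) is compared with
    the printed peptide mass; rows off by more than ``tol_da`` fail.
    """
    path = Path(table_path) if table_path else simulate.bundled_reference_table()
    table = pd.read_csv(path, sep="\t")
    required = {"sequence", "peptide_mass"}
    if not required <= set(table.columns):
        raise ValueError(f"reference table lacks columns {required - set(table.columns)}")
    computed = table["sequence"].map(residue_mass_sum)
    delta = computed - table["peptide_mass"].astype(float)
    return pd.DataFrame(
        {
            "sequence": table["sequence"],
            "printed_mass": table["peptide_mass"].astype(float),
            "computed_mass": computed.round(4),
            "delta_da": delta,
            "passed": delta.abs() <= tol_da,
        }
    )
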