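"""Readers and writers for the plain-text formats the pipeline exchanges.

Ion-event and design tables are TSV (pandas); fragment spectra are MGF;
protein databases are FASTA (Biopython).  Everything round-trips through
text so runs are diffable and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .mass import PROTON

ION_EVENT_COLUMNS = ["sample", "rt_min", "drift_bin", "mass_da", "intensity"]
DESIGN_COLUMNS = ["sample", "fluid", "dose", "replicate", "animal"]

FLUIDS = ("serum", "BALF")


@dataclass
class Spectrum:
    """One fragment spectrum keyed by its charge-reduced precursor MH+."""

    spectrum_id: str
    precursor_mh: float
    fragments: np.ndarray  # (n, 2) array of (MH+, intensity), sorted by mass
    rt_min: float | None = None
    drift_bin: float | None = None

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=float).reshape(-1, 2)
        order = np.argsort(self.fragments[:, 0])
        self.fragments = self.fragments[order]


def read_ion_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ION_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ion-event table {path} lacks columns {missing}")
    return df


def write_ion_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table {path} lacks columns {missing}")
    bad = set(df["fluid"]) - set(FLUIDS)
    if bad:
        raise ValueError(f"unknown fluids in design: {sorted(bad)}")
    return df


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Features x samples intensity matrix; empty cells become NaN."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="")


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse FASTA into (header_id, description, sequence) tuples."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, rec.description, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (header, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse a BEGIN IONS / END IONS MGF file.

    PEPMASS is read as m/z; if a CHARGE line is present the precursor is
    converted to the charge-reduced MH+ as ``z * mz - (z - 1) * proton``.
    Without a charge line the precursor is taken to be MH+ already.
    """
    spectra: list[Spectrum] = []
    title = None
    pepmass = None
    charge = None
    rt = None
    peaks: list[tuple[float, float]] = []
    in_block = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                title, pepmass, charge, rt = None, None, None, None
                peaks = []
            elif line == "END IONS":
                if pepmass is None:
                    raise ValueError(f"spectrum without PEPMASS in {path}")
                z = charge or 1
                mh = z * pepmass - (z - 1) * PROTON
                spectra.append(
                    Spectrum(
                        spectrum_id=title or f"index={len(spectra)}",
                        precursor_mh=mh,
                        fragments=np.array(peaks, dtype=float).reshape(-1, 2),
                        rt_min=rt,
                    )
                )
                in_block = False
            elif not in_block:
                continue
            elif "=" in line:
                key, _, val = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = val
                elif key == "PEPMASS":
                    pepmass = float(val.split()[0])
                elif key == "CHARGE":
                    charge = int(val.rstrip("+-"))
                elif key == "RTINSECONDS":
                    rt = float(val) / 60.0
            else:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra with PEPMASS = charge-reduced MH+ and CHARGE=1+."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mh:.6f}\n")
            fh.write("CHARGE=1+\n")
            if sp.rt_min is not None:
                fh.write(f"RTINSECONDS={sp.rt_min * 60.0:.3f}\n")
            for mz, inten in sp.fragments:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")
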