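"""Monoisotopic peptide mass arithmetic.

Residue-sum masses (no water term), MH+ conversion, signed ppm errors, and
singly protonated b/y fragment ladders.  All downstream stages — simulation,
candidate generation, fragment matching — derive their mass currency from
this module, so the constants here are the single source of truth.

Cysteine carbamidomethylation (+57.02146 Da, iodoacetamide alkylation) is a
fixed modification applied by the default residue table; pass a table built
with ``fixed_mods={}`` to disable it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "PROTON",
    "WATER",
    "CARBAMIDOMETHYL",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "ResidueTable",
    "FragmentLadder",
    "InvalidSequenceError",
    "default_table",
    "residue_mass_sum",
    "mh_plus",
    "ppm_error",
    "fragment_ladder",
]

PROTON = 1.007276
WATER = 18.010565
#: y-ion offset: C-terminal fragment carries the water plus one proton.
Y_OFFSET = WATER + PROTON

CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue masses (Da), i.e. amino acid minus water.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or residues outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ResidueTable:
    """Residue masses plus fixed modification deltas keyed by residue.

    Parameters
    ----------
    residues : mapping of residue symbol to monoisotopic residue mass (Da).
    fixed_mods : mapping of residue symbol to delta mass (Da) applied to
        every occurrence of that residue.
    """

    residues: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASSES)
    )
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )

    def __post_init__(self) -> None:
        missing = set(MONOISOTOPIC_RESIDUE_MASSES) - set(self.residues)
        if missing:
            raise ValueError(f"residue table is missing standard residues: {sorted(missing)}")
        bad = [r for r, m in self.residues.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for: {bad}")

    def mass_of(self, residue: str) -> float:
        """Residue mass including any fixed modification on that residue."""
        return self.residues[residue] + self.fixed_mods.get(residue, 0.0)

    @classmethod
    def from_yaml(cls, path: str) -> "ResidueTable":
        """Load a residue/modification table from a YAML file.

        The file may carry ``residues`` (symbol -> mass) overriding defaults
        and ``fixed_mods`` (symbol -> delta) replacing the default set.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        residues = dict(MONOISOTOPIC_RESIDUE_MASSES)
        residues.update(doc.get("residues", {}))
        fixed_mods = doc.get("fixed_mods", {"C": CARBAMIDOMETHYL})
        return cls(residues=residues, fixed_mods=fixed_mods)


_DEFAULT_TABLE = ResidueTable()


def default_table() -> ResidueTable:
    """The default residue table (carbamidomethyl-C fixed)."""
    return _DEFAULT_TABLE


def _validate(seq: str, table: ResidueTable) -> None:
    if not seq:
        raise InvalidSequenceError("empty peptide sequence")
    for ch in seq:
        if ch not in table.residues:
            raise InvalidSequenceError(f"invalid residue {ch!r} in sequence {seq!r}")


def residue_mass_sum(seq: str, table: ResidueTable | None = None) -> float:
    """Sum of residue masses plus fixed-mod deltas; no water term.

    Add :data:`WATER` for the neutral peptide mass, or use :func:`mh_plus`
    for the singly protonated species.
    """
    table = table or _DEFAULT_TABLE
    _validate(seq, table)
    return sum(table.mass_of(ch) for ch in seq)


def mh_plus(residue_sum: float) -> float:
    """Singly protonated (MH+) mass from a residue-mass sum."""
    if residue_sum <= 0:
        raise ValueError(f"residue sum must be positive, got {residue_sum}")
    return residue_sum + WATER + PROTON


def peptide_mh(seq: str, table: ResidueTable | None = None) -> float:
    """Convenience: MH+ of a sequence under a residue table."""
    return mh_plus(residue_mass_sum(seq, table))


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (measured - theoretical) / theoretical


@dataclass(frozen=True)
class FragmentLadder:
    """Singly protonated b/y fragment series of one peptide.

    ``b[i]`` is the MH+ of the N-terminal fragment of length ``i + 1``;
    ``y[i]`` the MH+ of the C-terminal fragment of length ``i + 1``.  Both
    series have ``len(seq) - 1`` entries.  The complementarity identity
    ``b[i] + y[n-2-i] == mh + PROTON`` holds for every index.
    """

    seq: str
    b: tuple[float, ...]
    y: tuple[float, ...]
    mh: float


def fragment_ladder(seq: str, table: ResidueTable | None = None) -> FragmentLadder:
    """Theoretical singly charged b/y ladder of a peptide (length >= 2)."""
    table = table or _DEFAULT_TABLE
    _validate(seq, table)
    if len(seq) < 2:
        raise InvalidSequenceError(f"fragment ladder needs length >= 2, got {seq!r}")
    masses = [table.mass_of(ch) for ch in seq]
    b: list[float] = []
    acc = 0.0
    for m in masses[:-1]:
        acc += m
        b.append(acc + PROTON)
    y: list[float] = []
    acc = 0.0
    for m in reversed(masses[1:]):
        acc += m
        y.append(acc + Y_OFFSET)
    total = sum(masses)
    return FragmentLadder(seq=seq, b=tuple(b), y=tuple(y), mh=mh_plus(total))
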