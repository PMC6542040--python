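"""No-enzyme peptide-spectrum identification with target-decoy FDR.

Candidates are *all* substrings of a substrate-restricted protein database
whose theoretical MH+ falls within the precursor tolerance — no cleavage
rule.  Scoring matches theoretical b/y ions to observed fragments one-to-
one within the product tolerance.  A seeded per-protein residue shuffle
provides the decoy database; the accepted set is thresholded so the decoy/
target tail ratio stays at or below the requested FDR.

Per-protein cumulative residue-mass prefix arrays make any substring mass
an O(1) difference, and a binary search over each prefix array turns
candidate generation into a narrow window scan per start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .mass import (
    PROTON,
    WATER,
    InvalidSequenceError,
    ResidueTable,
    default_table,
    fragment_ladder,
    mh_plus,
    ppm_error,
)

DEFAULT_LEN_BOUNDS = (6, 80)


@dataclass
class ProteinRecord:
    accession: str
    symbol: str
    source: str
    name: str
    sequence: str
    prefix: np.ndarray  # cumulative residue masses, length len(sequence) + 1


@dataclass
class SubstrateDB:
    """Indexed substrate protein database."""

    proteins: list[ProteinRecord]
    table: ResidueTable

    def __len__(self) -> int:
        return len(self.proteins)

    def substring_mass(self, prot_idx: int, start: int, end: int) -> float:
        """Residue-mass sum of protein[start:end] (0-based, half-open)."""
        p = self.proteins[prot_idx].prefix
        return float(p[end] - p[start])


@dataclass
class Candidate:
    sequence: str
    mh: float
    locations: list[tuple[str, int, int]]  # (accession, start, end) 1-based inclusive


@dataclass
class PeptideMatch:
    spectrum_id: str
    sequence: str
    locations: list[tuple[str, int, int]]
    precursor_mh: float
    theoretical_mh: float
    precursor_ppm: float
    n_b: int
    n_y: int
    max_product_ppm: float
    score: float
    decoy: bool = False
    q: float = float("nan")


def _parse_header(header_id: str, description: str) -> tuple[str, str, str, str]:
    parts = header_id.split("|")
    accession = parts[0]
    symbol = parts[1] if len(parts) > 1 else parts[0]
    source = parts[2] if len(parts) > 2 else ""
    name = description.partition(" ")[2]
    return accession, symbol, source, name


def build_index(fasta_path, table: ResidueTable | None = None) -> SubstrateDB:
    """Index a FASTA database: prefix mass arrays with fixed mods applied.

    Headers are ``accession|symbol|source description``; bare headers fall
    back to using the id for all three fields.
    """
    table = table or default_table()
    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    offenders: list[str] = []
    for rec_id, desc, seq in io.read_fasta(fasta_path):
        accession, symbol, source, name = _parse_header(rec_id, desc)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {fasta_path}")
        seen.add(accession)
        bad = sorted({ch for ch in seq if ch not in table.residues})
        if bad:
            offenders.append(f"{accession}: {bad}")
            continue
        masses = np.array([table.mass_of(ch) for ch in seq])
        prefix = np.concatenate([[0.0], np.cumsum(masses)])
        proteins.append(ProteinRecord(accession, symbol, source, name, seq, prefix))
    if offenders:
        raise ValueError(f"invalid residues in FASTA records: {offenders}")
    return SubstrateDB(proteins=proteins, table=table)


def candidate_peptides(
    precursor_mh: float,
    db: SubstrateDB,
    ppm: float = 6.0,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
) -> list[Candidate]:
    """All database substrings whose theoretical MH+ matches the precursor.

    Duplicate sequences are merged into one candidate with multi-protein
    provenance.  Coordinates are 1-based inclusive.
    """
    if precursor_mh <= 0:
        raise ValueError(f"precursor MH+ must be positive, got {precursor_mh}")
    min_len, max_len = len_bounds
    target = precursor_mh - WATER - PROTON  # residue-sum equivalent
    tol = precursor_mh * ppm * 1e-6
    by_seq: dict[str, Candidate] = {}
    for prot in db.proteins:
        p = prot.prefix
        L = len(prot.sequence)
        if L < min_len:
            continue
        starts = np.arange(L - min_len + 1)
        lo = np.searchsorted(p, p[starts] + target - tol, side="left")
        hi = np.searchsorted(p, p[starts] + target + tol, side="right")
        for i, j0, j1 in zip(starts, lo, hi):
            j_min = max(j0, i + min_len)
            j_max = min(j1 - 1, i + max_len, L)
            for j in range(j_min, j_max + 1):
                seq = prot.sequence[i:j]
                mh = mh_plus(float(p[j] - p[i]))
                if abs(ppm_error(precursor_mh, mh)) > ppm:
                    continue
                cand = by_seq.get(seq)
                if cand is None:
                    by_seq[seq] = Candidate(seq, mh, [(prot.accession, i + 1, j)])
                else:
                    cand.locations.append((prot.accession, i + 1, j))
    return sorted(by_seq.values(), key=lambda c: c.sequence)


def _match_ions(
    theo: np.ndarray, frag_mz: np.ndarray, frag_rel: np.ndarray, used: np.ndarray, ppm: float
) -> tuple[int, float, float]:
    """Greedy 1-to-1 match of theoretical ions to nearest unused fragments."""
    n_matched = 0
    summed = 0.0
    worst = 0.0
    for t in theo:
        tol = t * ppm * 1e-6
        k = np.searchsorted(frag_mz, t)
        best, best_d = -1, np.inf
        for c in (k - 1, k, k + 1):
            if 0 <= c < len(frag_mz) and not used[c]:
                d = abs(frag_mz[c] - t)
                if d <= tol and d < best_d:
                    best, best_d = c, d
        if best >= 0:
            used[best] = True
            n_matched += 1
            summed += frag_rel[best]
            worst = max(worst, abs(ppm_error(frag_mz[best], t)))
    return n_matched, summed, worst


def score_psm(
    spectrum: io.Spectrum,
    candidate: Candidate,
    table: ResidueTable | None = None,
    product_ppm: float = 12.0,
) -> PeptideMatch:
    """Score one candidate against one spectrum.

    Score = Nb * log2(1 + Ib) + Ny * log2(1 + Iy) where Nb/Ny are matched
    b/y counts and Ib/Iy the summed matched base-peak-relative intensities.
    """
    table = table or default_table()
    ladder = fragment_ladder(candidate.sequence, table)
    frag_mz = spectrum.fragments[:, 0]
    frag_int = spectrum.fragments[:, 1]
    top = frag_int.max() if len(frag_int) else 1.0
    frag_rel = frag_int / top if top > 0 else frag_int
    used = np.zeros(len(frag_mz), dtype=bool)
    n_b, i_b, worst_b = _match_ions(np.array(ladder.b), frag_mz, frag_rel, used, product_ppm)
    n_y, i_y, worst_y = _match_ions(np.array(ladder.y), frag_mz, frag_rel, used, product_ppm)
    score = n_b * np.log2(1.0 + i_b) + n_y * np.log2(1.0 + i_y)
    return PeptideMatch(
        spectrum_id=spectrum.spectrum_id,
        sequence=candidate.sequence,
        locations=list(candidate.locations),
        precursor_mh=spectrum.precursor_mh,
        theoretical_mh=ladder.mh,
        precursor_ppm=ppm_error(spectrum.precursor_mh, ladder.mh),
        n_b=n_b,
        n_y=n_y,
        max_product_ppm=max(worst_b, worst_y),
        score=float(score),
    )


def shuffle_decoy(db: SubstrateDB, seed: int = 0) -> SubstrateDB:
    """Length- and composition-preserving per-protein residue shuffle."""
    rng = np.random.default_rng(seed)
    proteins = []
    for prot in db.proteins:
        residues = list(prot.sequence)
        rng.shuffle(residues)
        seq = "".join(residues)
        masses = np.array([db.table.mass_of(ch) for ch in seq])
        prefix = np.concatenate([[0.0], np.cumsum(masses)])
        proteins.append(
            ProteinRecord(
                f"DECOY_{prot.accession}", prot.symbol, prot.source, prot.name, seq, prefix
            )
        )
    return SubstrateDB(proteins=proteins, table=db.table)


def _best_match(
    spectrum: io.Spectrum,
    db: SubstrateDB,
    precursor_ppm: float,
    product_ppm: float,
    len_bounds: tuple[int, int],
) -> PeptideMatch | None:
    cands = candidate_peptides(spectrum.precursor_mh, db, precursor_ppm, len_bounds)
    best = None
    for cand in cands:
        m = score_psm(spectrum, cand, db.table, product_ppm)
        if (
            best is None
            or m.score > best.score
            or (
                m.score == best.score
                and (
                    abs(m.precursor_ppm) < abs(best.precursor_ppm)
                    or (
                        abs(m.precursor_ppm) == abs(best.precursor_ppm)
                        and m.sequence < best.sequence
                    )
                )
            )
        ):
            best = m
    return best


def decoy_search(
    spectra: list[io.Spectrum],
    db: SubstrateDB,
    precursor_ppm: float = 6.0,
    product_ppm: float = 12.0,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
    decoy_seed: int = 0,
) -> tuple[list[PeptideMatch], list[PeptideMatch]]:
    """Best target and best decoy match per spectrum."""
    decoy_db = shuffle_decoy(db, decoy_seed)
    targets, decoys = [], []
    for sp in spectra:
        t = _best_match(sp, db, precursor_ppm, product_ppm, len_bounds)
        if t is not None:
            targets.append(t)
        d = _best_match(sp, decoy_db, precursor_ppm, product_ppm, len_bounds)
        if d is not None:
            d.decoy = True
            decoys.append(d)
    return targets, decoys


def fdr_threshold(
    targets: list[PeptideMatch],
    decoys: list[PeptideMatch],
    fdr: float = 0.10,
) -> list[PeptideMatch]:
    """Accept targets whose score clears the decoy/target tail-ratio bound.

    For each target score s, FDR(s) = #(decoy >= s) / #(target >= s); the
    per-match q value is the minimum FDR over thresholds at or below its
    score.  Accepted matches are those with q <= fdr.
    """
    if not targets:
        return []
    t_scores = np.array([m.score for m in targets])
    d_scores = np.sort(np.array([m.score for m in decoys])) if decoys else np.array([])
    order = np.argsort(-t_scores, kind="mergesort")
    n_decoy_at = len(d_scores) - np.searchsorted(
        d_scores, t_scores[order], side="left"
    )
    fdr_desc = n_decoy_at / np.arange(1, len(order) + 1)
    # q = lowest achievable FDR among thresholds at or below this score
    q_desc = np.minimum.accumulate(fdr_desc[::-1])[::-1]
    qs = np.empty(len(targets))
    qs[order] = q_desc
    accepted: list[PeptideMatch] = []
    for m, q in zip(targets, qs):
        m.q = float(q)
        if q <= fdr:
            accepted.append(m)
    return sorted(accepted, key=lambda m: (-m.score, m.sequence))


def annotate_match(match: PeptideMatch, db: SubstrateDB) -> dict:
    """Reference-table-style record for an accepted match."""
    by_acc = {p.accession: p for p in db.proteins}
    acc, start, end = match.locations[0]
    prot = by_acc.get(acc)
    record = {
        "sequence": match.sequence,
        "protein_name": prot.name if prot else "",
        "symbol": prot.symbol if prot else "",
        "accession": acc,
        "source": prot.source if prot else "",
        "start": start,
        "end": end,
        "peptide_mass": match.theoretical_mh - WATER - PROTON,
        "theoretical_mh": match.theoretical_mh,
        "precursor_mh": match.precursor_mh,
        "precursor_ppm": match.precursor_ppm,
        "max_product_ppm": match.max_product_ppm,
        "n_b": match.n_b,
        "n_y": match.n_y,
        "score": match.score,
        "q": match.q,
    }
    if prot and prot.sequence[start - 1 : end] != match.sequence:
        raise ValueError(
            f"coordinate mismatch for {match.sequence} at {acc}:{start}-{end}"
        )
    return record


def matches_to_frame(matches: list[PeptideMatch], db: SubstrateDB) -> pd.DataFrame:
    return pd.DataFrame([annotate_match(m, db) for m in matches])
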