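import numpy as np
import pytest
from scipy import stats as sps

from peptidome import identify, io, simulate
from peptidome.identify import (
    build_index,
    candidate_peptides,
    decoy_search,
    fdr_threshold,
    score_psm,
    shuffle_decoy,
)
from peptidome.mass import WATER, PROTON, peptide_mh, residue_mass_sum

THBS2_59MER = (
    "QQRGRSCDVTSNTCLGPSLQTRTCSLGKCDTRLRQNGGWSHWSPWSSCSVTCGVGNVTR"
)


def brute_force_candidates(precursor_mh, records, ppm, len_bounds):
    """Exhaustive double loop over every substring (independent oracle)."""
    lo, hi = len_bounds
    found = set()
    for _, _, seq in records:
        for i in range(len(seq)):
            for j in range(i + lo, min(i + hi, len(seq)) + 1):
                sub = seq[i:j]
                mh = residue_mass_sum(sub) + WATER + PROTON
                if abs(1e6 * (precursor_mh - mh) / mh) <= ppm:
                    found.add(sub)
    return found


class TestBuildIndex:
    def test_prefix_array_shape(self, tiny_fasta):
        db = build_index(tiny_fasta)
        for prot in db.proteins:
            assert len(prot.prefix) == len(prot.sequence) + 1
            assert prot.prefix[0] == 0.0
            assert np.all(np.diff(prot.prefix) > 0)

    def test_substring_mass_matches_residue_sum(self, tiny_fasta):
        db = build_index(tiny_fasta)
        rng = np.random.default_rng(3)
        for _ in range(1000):
            k = int(rng.integers(len(db.proteins)))
            seq = db.proteins[k].sequence
            i = int(rng.integers(0, len(seq)))
            j = int(rng.integers(i + 1, len(seq) + 1))
            assert db.substring_mass(k, i, j) == pytest.approx(
                residue_mass_sum(seq[i:j]), abs=1e-9
            )

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">A|X|MEROPS\nPEPTIDE\n>A|Y|MEROPS\nGASPV\n")
        with pytest.raises(ValueError, match="duplicate"):
            build_index(path)

    def test_invalid_residue_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">A|X|MEROPS\nPEPTIDEZ\n")
        with pytest.raises(ValueError, match="Z"):
            build_index(path)

    def test_source_tags_preserved(self, substrate_fasta):
        db = build_index(substrate_fasta)
        sources = {p.source for p in db.proteins}
        assert {"MEROPS", "SignalP", "MEROPS+SignalP"} <= sources


class TestCandidatePeptides:
    def test_lpfknl_found_in_bundled_db(self, substrate_fasta):
        db = build_index(substrate_fasta)
        cands = candidate_peptides(peptide_mh("LPFKNL"), db)
        seqs = {c.sequence for c in cands}
        assert "LPFKNL" in seqs
        hit = next(c for c in cands if c.sequence == "LPFKNL")
        accs = {a for a, _, _ in hit.locations}
        assert any(
            db_p.symbol == "Cyp11a1" for db_p in db.proteins if db_p.accession in accs
        )

    def test_thbs2_59mer_found_at_own_mass(self, substrate_fasta):
        db = build_index(substrate_fasta)
        assert len(THBS2_59MER) == 59
        cands = candidate_peptides(peptide_mh(THBS2_59MER), db)
        assert THBS2_59MER in {c.sequence for c in cands}

    def test_far_precursor_empty(self, tiny_fasta):
        db = build_index(tiny_fasta)
        assert candidate_peptides(123456.0, db) == []

    def test_nonpositive_precursor_rejected(self, tiny_fasta):
        db = build_index(tiny_fasta)
        with pytest.raises(ValueError):
            candidate_peptides(-1.0, db)

    def test_matches_exhaustive_enumeration(self, tiny_fasta):
        db = build_index(tiny_fasta)
        records = io.read_fasta(tiny_fasta)
        rng = np.random.default_rng(5)
        # probe at true substring masses (hits) and random masses (mostly misses)
        probes = []
        for _, _, seq in records:
            for _ in range(10):
                i = int(rng.integers(0, len(seq) - 6))
                j = int(rng.integers(i + 6, min(i + 12, len(seq)) + 1))
                probes.append(peptide_mh(seq[i:j]))
        probes.extend(rng.uniform(600, 2500, size=30))
        for mh in probes:
            expected = brute_force_candidates(mh, records, 6.0, (6, 80))
            got = {c.sequence for c in candidate_peptides(mh, db)}
            assert got == expected

    def test_multi_protein_provenance_merged(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">A|X|MEROPS\nGGLPFKNLGG\n>B|Y|SignalP\nAALPFKNLAA\n")
        db = build_index(path)
        cands = candidate_peptides(peptide_mh("LPFKNL"), db)
        hit = next(c for c in cands if c.sequence == "LPFKNL")
        assert {a for a, _, _ in hit.locations} == {"A", "B"}

    def test_coordinates_are_one_based_inclusive(self, tmp_path):
        path = tmp_path / "c.fasta"
        path.write_text(">A|X|MEROPS\nGGLPFKNLGG\n")
        db = build_index(path)
        hit = next(
            c
            for c in candidate_peptides(peptide_mh("LPFKNL"), db)
            if c.sequence == "LPFKNL"
        )
        assert hit.locations == [("A", 3, 8)]


class TestScorePsm:
    def test_full_ladder_matches_all_ions(self):
        (sp,) = simulate.synthesize_spectra(
            ["LPFKNL"], frag_sampling=1.0, n_noise_peaks=0,
            precursor_ppm_jitter=0.0, product_ppm_jitter=0.0, seed=1,
        )
        cand = identify.Candidate("LPFKNL", peptide_mh("LPFKNL"), [("A", 1, 6)])
        match = score_psm(sp, cand)
        assert match.n_b == match.n_y == 5
        assert match.score > 0
        assert match.max_product_ppm <= 12.0

    def test_disjoint_fragments_zero_score(self):
        sp = io.Spectrum("x", peptide_mh("LPFKNL"), np.array([[5000.0, 1.0]]))
        cand = identify.Candidate("LPFKNL", peptide_mh("LPFKNL"), [("A", 1, 6)])
        match = score_psm(sp, cand)
        assert match.score == 0.0
        assert match.n_b == match.n_y == 0

    def test_true_sequence_outscores_shuffled(self):
        rng = np.random.default_rng(9)
        peptides = ["MNLEEKPAPAA", "PPASVVVGPVVVPR", "AEFQPLVEEPKNL", "FSSLMNLEEKPAPAA"]
        wins = 0
        total = 0
        for rep in range(50):
            pep = peptides[rep % len(peptides)]
            (sp,) = simulate.synthesize_spectra([pep], seed=1000 + rep)
            shuffled = "".join(rng.permutation(list(pep)))
            if shuffled == pep:
                continue
            true_match = score_psm(sp, identify.Candidate(pep, peptide_mh(pep), []))
            sh_match = score_psm(
                sp, identify.Candidate(shuffled, peptide_mh(shuffled), [])
            )
            total += 1
            if true_match.score > sh_match.score:
                wins += 1
        assert wins / total >= 0.95


class TestDecoySearch:
    def test_decoy_preserves_length_and_composition(self, substrate_fasta):
        db = build_index(substrate_fasta)
        decoy = shuffle_decoy(db, seed=4)
        for t, d in zip(db.proteins, decoy.proteins):
            assert len(t.sequence) == len(d.sequence)
            assert sorted(t.sequence) == sorted(d.sequence)
            assert d.prefix[-1] == pytest.approx(t.prefix[-1], abs=1e-6)

    def test_decoy_scores_stochastically_below_target(self, substrate_fasta):
        db = build_index(substrate_fasta)
        rng = np.random.default_rng(41)
        true_peps = []
        for prot in db.proteins:
            if len(prot.sequence) >= 12:
                i = int(rng.integers(0, len(prot.sequence) - 10))
                true_peps.append(prot.sequence[i : i + 10])
            if len(true_peps) == 40:
                break
        spectra = simulate.synthesize_spectra(true_peps, seed=42)
        targets, decoys = decoy_search(spectra, db, decoy_seed=7)
        t_scores = [m.score for m in targets]
        d_scores = [m.score for m in decoys]
        assert len(t_scores) >= 30
        if d_scores:
            mw = sps.mannwhitneyu(t_scores, d_scores, alternative="greater")
            assert mw.pvalue < 0.01

    def test_accepted_matches_respect_tolerances(self, substrate_fasta):
        db = build_index(substrate_fasta)
        peps = [p.sequence[:10] for p in db.proteins[:20] if len(p.sequence) >= 10]
        spectra = simulate.synthesize_spectra(peps, seed=8)
        targets, decoys = decoy_search(spectra, db, decoy_seed=8)
        accepted = fdr_threshold(targets, decoys, fdr=0.10)
        for m in accepted:
            assert abs(m.precursor_ppm) <= 6.0
            assert m.max_product_ppm <= 12.0


class TestFdrThreshold:
    @staticmethod
    def _matches(scores, decoy=False):
        return [
            identify.PeptideMatch(
                spectrum_id=f"s{i}", sequence="PEPTIDE", locations=[("A", 1, 7)],
                precursor_mh=800.0, theoretical_mh=800.0, precursor_ppm=0.0,
                n_b=1, n_y=1, max_product_ppm=0.0, score=s, decoy=decoy,
            )
            for i, s in enumerate(scores)
        ]

    def test_all_decoys_above_targets_rejects_all(self):
        targets = self._matches([1.0, 2.0, 3.0])
        decoys = self._matches([10.0, 11.0, 12.0], decoy=True)
        assert fdr_threshold(targets, decoys, fdr=0.10) == []

    def test_clean_top_target_accepted_at_q_zero(self):
        targets = self._matches([5.0, 9.0])
        decoys = self._matches([1.0], decoy=True)
        accepted = fdr_threshold(targets, decoys, fdr=0.10)
        assert accepted and accepted[0].score == 9.0
        assert accepted[0].q == 0.0

    def test_no_targets_empty(self):
        assert fdr_threshold([], self._matches([1.0], decoy=True)) == []

    def test_q_monotone_in_score(self):
        rng = np.random.default_rng(11)
        targets = self._matches(rng.uniform(0, 10, size=50))
        decoys = self._matches(rng.uniform(0, 6, size=50), decoy=True)
        fdr_threshold(targets, decoys, fdr=0.5)
        ordered = sorted(targets, key=lambda m: -m.score)
        qs = [m.q for m in ordered]
        assert qs == sorted(qs)
        assert qs[0] < qs[-1]  # decoys overlap the low tail, so q must vary

    def test_q_matches_bruteforce_definition(self):
        rng = np.random.default_rng(13)
        t_scores = rng.uniform(0, 10, size=40)
        d_scores = rng.uniform(0, 8, size=35)
        targets = self._matches(t_scores)
        decoys = self._matches(d_scores, decoy=True)
        fdr_threshold(targets, decoys, fdr=0.1)
        for m in targets:
            # minimum tail ratio over candidate thresholds at or below score
            expected = min(
                (d_scores >= t).sum() / (t_scores >= t).sum()
                for t in t_scores
                if t <= m.score
            )
            assert m.q == pytest.approx(expected, abs=1e-12)

    def test_low_scores_rejected_when_decoys_overlap(self):
        targets = self._matches([0.5, 1.0, 9.0, 10.0])
        decoys = self._matches([0.6, 0.7, 1.1], decoy=True)
        accepted = fdr_threshold(targets, decoys, fdr=0.10)
        assert sorted(m.score for m in accepted) == [9.0, 10.0]


def test_throughput_1000_spectra_under_5_min(substrate_fasta):
    import time

    db = build_index(substrate_fasta)
    rng = np.random.default_rng(55)
    peps = []
    seqs = [p.sequence for p in db.proteins if len(p.sequence) >= 15]
    while len(peps) < 1000:
        s = seqs[int(rng.integers(len(seqs)))]
        i = int(rng.integers(0, len(s) - 10))
        peps.append(s[i : i + 10])
    spectra = simulate.synthesize_spectra(peps, seed=56)
    start = time.monotonic()
    targets, decoys = decoy_search(spectra, db, decoy_seed=57)
    fdr_threshold(targets, decoys, 0.10)
    assert time.monotonic() - start < 300.0


class TestAnnotateMatch:
    def test_thbs2_annotation(self, substrate_fasta):
        db = build_index(substrate_fasta)
        spectra = simulate.synthesize_spectra([THBS2_59MER], seed=2)
        targets, decoys = decoy_search(spectra, db)
        accepted = fdr_threshold(targets, decoys)
        assert accepted
        record = identify.annotate_match(accepted[0], db)
        assert record["sequence"] == THBS2_59MER
        assert record["symbol"] == "Thbs2"
        assert record["source"] == "MEROPS"
        assert len(record["sequence"]) == 59

    def test_theoretical_mass_column(self, substrate_fasta):
        db = build_index(substrate_fasta)
        spectra = simulate.synthesize_spectra(["PPASVVVGPVVVPR"], seed=3)
        targets, decoys = decoy_search(spectra, db)
        accepted = fdr_threshold(targets, decoys)
        record = identify.annotate_match(accepted[0], db)
        assert record["peptide_mass"] == pytest.approx(1353.8132, abs=0.001)

    def test_coordinates_round_trip(self, substrate_fasta):
        db = build_index(substrate_fasta)
        by_acc = {p.accession: p for p in db.proteins}
        spectra = simulate.synthesize_spectra(["MNLEEKPAPAA"], seed=4)
        targets, decoys = decoy_search(spectra, db)
        accepted = fdr_threshold(targets, decoys)
        record = identify.annotate_match(accepted[0], db)
        prot = by_acc[record["accession"]]
        assert (
            prot.sequence[record["start"] - 1 : record["end"]] == record["sequence"]
        )
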