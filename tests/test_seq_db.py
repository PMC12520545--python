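"""Sequence-database tests: FASTA round trips, UGA-readthrough translation
(against an independent codon-table oracle), tryptic digestion (against
exhaustive enumeration), precursor enumeration and SCoSS filtering."""

import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from secproxy import chem, seq_db
from secproxy.entities import Peptide
from secproxy.seq_db import ProteinRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.faa"
        p.write_text(">P1 some description\nACDU\n")
        recs = seq_db.read_fasta(str(p))
        assert len(recs) == 1
        assert recs[0].accession == "P1"
        assert recs[0].sequence == "ACDU"
        assert recs[0].description == "some description"

    def test_round_trip_random_records(self, tmp_path):
        rng = np.random.default_rng(3)
        records = [
            ProteinRecord(
                f"P{i}",
                "".join(rng.choice(list(ALPHABET + "U"), size=rng.integers(10, 120))),
                f"desc {i}",
            )
            for i in range(100)
        ]
        path = tmp_path / "many.faa"
        seq_db.write_fasta(records, path)
        back = seq_db.read_fasta(path)
        assert [(r.accession, r.sequence, r.description) for r in back] == [
            (r.accession, r.sequence, r.description) for r in records
        ]

    def test_illegal_character(self, tmp_path):
        p = tmp_path / "bad.faa"
        p.write_text(">P1\nAC9DU\n")
        with pytest.raises(ValueError, match="P1"):
            seq_db.read_fasta(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.faa"
        p.write_text("")
        with pytest.warns(UserWarning, match="no FASTA records"):
            assert seq_db.read_fasta(p) == []

    def test_trailing_stop_stripped(self, tmp_path):
        p = tmp_path / "stop.faa"
        p.write_text(">P1\nACDU*\n")
        assert seq_db.read_fasta(p)[0].sequence == "ACDU"


class TestTranslateReadthrough:
    @pytest.mark.parametrize(
        "nt, expected",
        [
            ("ATGTGATAA", "MU"),   # TGA read through as Sec, TAA stops
            ("ATGGGC", "MG"),      # no stop: runs to sequence end
            ("ATGTGA", "MU"),      # terminal TGA read through, then end
            ("ATGTAGGGG", "M"),    # TAG stops
            ("ATGGG", "M"),        # trailing partial codon ignored
        ],
    )
    def test_examples(self, nt, expected):
        assert seq_db.translate_readthrough(nt) == expected

    def test_frame_offset(self):
        assert seq_db.translate_readthrough("GATGTGA", frame_offset=1) == "MU"

    def test_ambiguous_base_strict(self):
        with pytest.raises(ValueError, match="N"):
            seq_db.translate_readthrough("ATGNNN")

    def test_matches_standard_translation_without_tga(self):
        rng = np.random.default_rng(5)
        codons = [
            c
            for a in "ACGT"
            for b in "ACGT"
            for d in "ACGT"
            if (c := a + b + d) not in ("TGA", "TAA", "TAG")
        ]
        for _ in range(25):
            nt = "".join(rng.choice(codons, size=rng.integers(3, 40)))
            assert seq_db.translate_readthrough(nt) == str(Seq(nt).translate())

    def test_build_sis_database(self):
        recs = seq_db.build_sis_database([("tx1", "ATGTGTTGAAAGTAA")])
        assert len(recs) == 1
        assert recs[0].sequence == "MCUK"
        assert recs[0].source == "sis"


def brute_force_digest(sequence, max_missed, min_len, max_len):
    """Exhaustive enumeration over all windows between tryptic cut sites."""
    sites = [0] + [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ] + [len(sequence)]
    out = set()
    for i in range(len(sites) - 1):
        for j in range(i + 1, len(sites)):
            mc = j - i - 1
            if mc > max_missed:
                continue
            sub = sequence[sites[i] : sites[j]]
            if min_len <= len(sub) <= max_len:
                out.add((sub, mc))
    return out


class TestDigest:
    def test_short_cterminal_sec_peptide_excluded(self):
        # TXNRD3-like case: terminal GCUG (length 4) falls below the
        # 7-residue floor and never reaches the library.
        rec = ProteinRecord("txnrd3", "MSELVAAWFELKGCUG")
        peps = seq_db.digest(rec)
        assert all("GCUG" != p.sequence for p in peps)
        assert all(len(p.sequence) >= 7 for p in peps)

    def test_no_cut_sites_single_peptide(self):
        rec = ProteinRecord("p", "ACDEFGHILMNP")
        peps = seq_db.digest(rec)
        assert len(peps) == 1
        assert peps[0].sequence == "ACDEFGHILMNP"
        assert peps[0].missed_cleavages == 0

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            seq = "".join(
                rng.choice(list(ALPHABET + "U"), size=rng.integers(7, 31))
            )
            rec = ProteinRecord("r", seq)
            got = {
                (p.sequence, p.missed_cleavages)
                for p in seq_db.digest(
                    rec, max_missed=2, min_len=1, max_len=50,
                    min_mass=0.0, max_mass=1e9,
                )
            }
            assert got == brute_force_digest(seq, 2, 1, 50)

    def test_no_cleavage_before_proline(self):
        rec = ProteinRecord("p", "AAAKPAAAAAAR")
        peps = seq_db.digest(rec, min_len=1, min_mass=0)
        assert any(p.sequence == "AAAKPAAAAAAR" and p.missed_cleavages == 0 for p in peps)

    def test_sec_not_a_cleavage_site(self):
        rec = ProteinRecord("p", "AAAUAAAAAAAR")
        peps = seq_db.digest(rec, min_len=1, min_mass=0)
        assert [p.sequence for p in peps if p.missed_cleavages == 0] == ["AAAUAAAAAAAR"]

    def test_zero_missed_concatenation_reconstructs_protein(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = "".join(rng.choice(list(ALPHABET), size=rng.integers(10, 80)))
            rec = ProteinRecord("r", seq)
            peps = [
                p
                for p in seq_db.digest(
                    rec, max_missed=0, min_len=1, max_len=10**6,
                    min_mass=0.0, max_mass=1e12,
                )
            ]
            assert "".join(p.sequence for p in peps) == seq

    def test_mass_filter_uses_labeled_mass_by_default(self):
        # A U-rich peptide whose stripped mass is < 5000 but whose
        # IodoAPB-labeled mass exceeds it must be filtered out.
        seq = "UUUUUUUUUUAUUUUUUUUUUUUUUUUUUK"
        rec = ProteinRecord("p", seq)
        assert seq_db.digest(rec) == []
        kept = seq_db.digest(rec, mass_on_modified=False)
        assert [p.sequence for p in kept] == [seq]


class TestEnumerateSecPrecursors:
    def test_counts_and_charges(self):
        peps = [Peptide("AAUAAAK"), Peptide("AACAAAK"), Peptide("UUAAAAK")]
        precs = seq_db.enumerate_sec_precursors(peps)
        assert len(precs) == 8  # 2 Sec peptides x 4 charges
        assert sorted({p.charge for p in precs}) == [1, 2, 3, 4]

    def test_no_sec_peptides(self):
        assert seq_db.enumerate_sec_precursors([Peptide("AACAAAK")]) == []

    def test_labels_and_mz_match_chem_oracle(self):
        precs = seq_db.enumerate_sec_precursors([Peptide("UCAAAKK")], charges=(2,))
        (prec,) = precs
        mods = dict(prec.peptide.modifications)
        assert mods[1].name == "IodoAPB-CAM" and mods[1].delta == pytest.approx(
            414.193691, abs=1e-5
        )
        assert mods[2].name == "CAM" and mods[2].delta == pytest.approx(
            57.021464, abs=1e-5
        )
        assert prec.mz == pytest.approx(chem.precursor_mz(prec.peptide, 2), abs=1e-9)

    def test_sec_mod_must_target_u(self):
        with pytest.raises(ValueError, match="target U"):
            seq_db.enumerate_sec_precursors(
                [Peptide("AAUAAAK")], sec_mod=chem.get_modification("Oxidation")
            )


class TestScossFilter:
    def make_records(self, n=10):
        return [ProteinRecord(f"ENSP{i}.2", "ACDEFGHIK") for i in range(n)]

    def test_subset_in_order(self):
        recs = self.make_records()
        kept = seq_db.scoss_filter(recs, {"ENSP1.2", "ENSP7.2", "ENSP3.2"})
        assert [r.accession for r in kept] == ["ENSP1.2", "ENSP3.2", "ENSP7.2"]
        assert all(r.source == "scoss" for r in kept)

    def test_version_normalization(self):
        recs = self.make_records()
        kept = seq_db.scoss_filter(recs, {"ENSP4"})
        assert [r.accession for r in kept] == ["ENSP4.2"]
        assert seq_db.scoss_filter(recs, {"ENSP4"}, normalize_versions=False) == []

    def test_empty_binder_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            seq_db.scoss_filter(self.make_records(), set())

    def test_read_binder_ids(self, tmp_path):
        p = tmp_path / "binders.tsv"
        p.write_text("accession\nENSP1\n# comment\nENSP2\t0.93\n\n")
        assert seq_db.read_binder_ids(p) == {"ENSP1", "ENSP2"}
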