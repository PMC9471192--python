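import pytest
from hypothesis import given, settings, strategies as st

import cterminome as ct
from cterminome.psm_model import (Modification, N_TERM, PsmRecord,
                                  PsmValidationError,
                                  format_annotated_sequence,
                                  format_modifications,
                                  group_peptides,
                                  parse_annotated_sequence,
                                  parse_modifications, read_psm_table,
                                  write_psm_table)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAnnotatedSequence:
    @pytest.mark.parametrize("text,expected", [
        ("[K].VFLENVIR.[D]", ("K", "VFLENVIR", "D")),
        ("[K].RQGRTLYGFGG.[-]", ("K", "RQGRTLYGFGG", "-")),
        ("[-].MSGRGK.[G]", ("-", "MSGRGK", "G")),
        ("VFLENVIR", (None, "VFLENVIR", None)),
    ])
    def test_parse(self, text, expected):
        assert parse_annotated_sequence(text) == expected

    @pytest.mark.parametrize("text", [
        "", "K.VFLENVIR", "[K].VFLENVIR", "[K]..[D]", "[KK].AC.[D]",
        "[K].vflen.[D]", "[K].AC1D.[D]",
    ])
    def test_malformed_rejected(self, text):
        with pytest.raises(PsmValidationError):
            parse_annotated_sequence(text)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sampled_from(list(AA) + ["-"]),
           st.text(AA, min_size=1, max_size=30),
           st.sampled_from(list(AA) + ["-"]))
    def test_round_trip(self, prec, seq, foll):
        text = format_annotated_sequence(prec, seq, foll)
        assert parse_annotated_sequence(text) == (prec, seq, foll)


class TestModifications:
    def test_canonical_dialect(self):
        mods = parse_modifications("PCA@N-term;Biotin@K3;Oxidation@M5")
        assert mods == (Modification("PCA", N_TERM),
                        Modification("Biotin", 3, "K"),
                        Modification("Oxidation", 5, "M"))

    def test_pd_like_dialect_normalized(self):
        mods = parse_modifications("1xPCA [N-Term]; 1xBiotin [K3]",
                                   dialect="pd_like")
        assert format_modifications(mods) == "PCA@N-term;Biotin@K3"

    def test_unknown_names_kept_as_other(self):
        (mod,) = parse_modifications("Deamidation@N4")
        assert mod.name == "Other:Deamidation"

    def test_empty_and_none(self):
        assert parse_modifications("") == ()
        assert parse_modifications(None) == ()

    def test_malformed_token_rejected(self):
        with pytest.raises(PsmValidationError):
            parse_modifications("PCA:N-term")


class TestPsmValidation:
    def test_biotin_on_lysine_accepted(self):
        psm = PsmRecord("p1", "rep1", "ACKDK",
                        modifications=parse_modifications(
                            "PCA@N-term;Biotin@K3"))
        assert len(psm.modifications) == 2
        assert psm.pca_labeled

    def test_biotin_on_non_lysine_rejected(self):
        with pytest.raises(PsmValidationError, match="non-K"):
            PsmRecord("p1", "rep1", "AADK",
                      modifications=(Modification("Biotin", 2, "A"),))

    def test_site_outside_peptide_rejected(self):
        with pytest.raises(PsmValidationError, match="outside"):
            PsmRecord("p1", "rep1", "ACDK",
                      modifications=(Modification("Oxidation", 9, "M"),))

    def test_pca_must_sit_on_nterm(self):
        with pytest.raises(PsmValidationError):
            PsmRecord("p1", "rep1", "ACDK",
                      modifications=(Modification("PCA", "C-term"),))

    def test_negative_intensity_rejected(self):
        with pytest.raises(PsmValidationError):
            PsmRecord("p1", "rep1", "ACDK", intensity=-1.0)


HEADER = "psm_id\treplicate\tannotated_sequence\tmodifications\tintensity\tscore\tcharge\n"


class TestReadPsmTable:
    def test_valid_table(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(HEADER +
                     "s1\trep1\t[K].ACKDK.[V]\tPCA@N-term;Biotin@K3\t1e5\t55\t2\n")
        records, errors = read_psm_table(p)
        assert not errors
        (rec,) = records
        assert rec.sequence == "ACKDK"
        assert rec.preceding_obs == "K"
        assert rec.intensity == 1e5

    def test_missing_column_reported(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text("psm_id\treplicate\n")
        with pytest.raises(ValueError, match="annotated_sequence"):
            read_psm_table(p)

    def test_lenient_drops_and_reports_line(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(HEADER +
                     "s1\trep1\tAADK\tBiotin@A2\t0\t10\t2\n"
                     "s2\trep1\tAADK\t\t0\t10\t2\n")
        records, errors = read_psm_table(p)
        assert len(records) == 1
        assert len(errors) == 1 and "line 2" in errors[0]

    def test_strict_aborts(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(HEADER + "s1\trep1\tAADK\tBiotin@A2\t0\t10\t2\n")
        with pytest.raises(PsmValidationError):
            read_psm_table(p, strict=True)

    def test_write_read_round_trip(self, tmp_path, psm_factory):
        psms = [psm_factory(sequence="ACKDK",
                            mods=parse_modifications("Biotin@K3"),
                            intensity=123.456),
                psm_factory(sequence="PEPTIDEK", preceding="-",
                            following="-")]
        path = tmp_path / "rt.tsv"
        write_psm_table(psms, path)
        back, errors = read_psm_table(path)
        assert not errors
        assert [(b.sequence, b.modifications, b.intensity)
                for b in back] == \
            [(p.sequence, p.modifications, p.intensity) for p in psms]


class TestGroupPeptides:
    def test_pca_status_splits_groups(self, psm_factory):
        pca = parse_modifications("PCA@N-term")
        psms = [psm_factory(sequence="AAK", mods=pca),
                psm_factory(sequence="AAK", mods=pca),
                psm_factory(sequence="AAK")]
        groups = group_peptides(psms)
        assert sorted(g.psm_count for g in groups) == [1, 2]

    def test_empty_key_pools_all(self, psm_factory):
        psms = [psm_factory(sequence="AAK",
                            mods=parse_modifications("PCA@N-term")),
                psm_factory(sequence="AAK")]
        (group,) = group_peptides(psms, key_mods=set())
        assert group.psm_count == 2

    def test_replicates_seen(self, psm_factory):
        psms = [psm_factory(sequence="PEPTIDER", replicate=f"rep{i}")
                for i in (1, 2, 3)]
        (group,) = group_peptides(psms)
        assert group.replicates_seen == {"rep1", "rep2", "rep3"}

    def test_psm_counts_conserved(self, psm_factory):
        psms = [psm_factory(sequence=s)
                for s in ["AAK", "CCK", "AAK", "DDK", "CCK", "AAK"]]
        groups = group_peptides(psms)
        assert sum(g.psm_count for g in groups) == len(psms)

    def test_per_replicate_intensity_sums(self, psm_factory):
        psms = [psm_factory(sequence="AAK", replicate="rep1",
                            intensity=10.0),
                psm_factory(sequence="AAK", replicate="rep1",
                            intensity=5.0),
                psm_factory(sequence="AAK", replicate="rep2",
                            intensity=7.0)]
        (group,) = group_peptides(psms, key_mods=set())
        assert group.intensity_by_replicate == {"rep1": 15.0, "rep2": 7.0}
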