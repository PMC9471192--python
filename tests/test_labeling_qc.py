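import numpy as np
import pytest

import cterminome as ct
from cterminome.labeling_qc import (first_residues_profile,
                                    labeling_efficiency, ptm_distribution,
                                    site_blocking, stratified_compare)
from cterminome.psm_model import parse_modifications

PCA = parse_modifications("PCA@N-term")
ACETYL = parse_modifications("Acetyl@N-term")


class TestLabelingEfficiency:
    def test_spectral_counting_three_of_four(self, psm_factory):
        psms = [psm_factory(sequence="LDDEEK", mods=PCA) for _ in range(3)]
        psms.append(psm_factory(sequence="LDDEEK"))
        report = labeling_efficiency(psms)
        (s,) = report.summaries
        assert s.efficiency == 0.75
        assert s.category == "partial"

    def test_position2_proline_is_ineligible_none(self, psm_factory):
        psms = [psm_factory(sequence="APDDE") for _ in range(3)]
        report = labeling_efficiency(psms)
        (s,) = report.summaries
        assert s.category == "none"
        assert not s.eligible and s.p2_proline

    def test_acetylated_peptide_ineligible(self, psm_factory):
        report = labeling_efficiency(
            [psm_factory(sequence="MDDEEK", mods=ACETYL)])
        assert not report.summaries[0].eligible
        assert report.none_acetylated_fraction == 1.0

    def test_category_fractions_sum_to_one(self, psm_factory):
        psms = ([psm_factory(sequence="AAADDK", mods=PCA)]
                + [psm_factory(sequence="CCDDK")]
                + [psm_factory(sequence="EEFFK", mods=PCA),
                   psm_factory(sequence="EEFFK")])
        report = labeling_efficiency(psms)
        assert abs(sum(report.category_fractions.values()) - 1.0) < 1e-12
        assert report.category_counts == {"full": 1, "partial": 1,
                                          "none": 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            labeling_efficiency([])

    def test_order_and_replicate_invariance(self, psm_factory):
        psms = [psm_factory(sequence="LDDEEK", replicate=f"rep{i % 3}",
                            mods=PCA if i % 2 else ())
                for i in range(10)]
        a = labeling_efficiency(psms)
        b = labeling_efficiency(list(reversed(psms)))
        assert [(s.sequence, s.efficiency) for s in a.summaries] == \
            [(s.sequence, s.efficiency) for s in b.summaries]


class TestSiteBlocking:
    def test_epsilon_fraction_by_occurrence(self, psm_factory):
        # 100 K occurrences, 97 biotinylated
        psms = []
        for i in range(100):
            mods = parse_modifications("Biotin@K3") if i < 97 else ()
            psms.append(psm_factory(sequence="AAKDDE", mods=mods))
        report = site_blocking(psms)
        assert report.epsilon_blocked_fraction == 0.97
        assert report.n_k_occurrences == 100

    def test_alpha_fully_blocked(self, psm_factory):
        psms = [psm_factory(sequence="LDDEEK", mods=PCA),
                psm_factory(sequence="MDDEEK", mods=ACETYL)]
        assert site_blocking(psms).alpha_blocked_fraction == 1.0

    def test_no_lysine_epsilon_undefined(self, psm_factory):
        report = site_blocking([psm_factory(sequence="AADDE")])
        assert np.isnan(report.epsilon_blocked_fraction)

    def test_per_replicate_values(self, psm_factory):
        psms = [psm_factory(sequence="LDDEEK", replicate="rep1", mods=PCA),
                psm_factory(sequence="LDDEEK", replicate="rep2")]
        report = site_blocking(psms)
        assert report.per_replicate["rep1"][0] == 1.0
        assert report.per_replicate["rep2"][0] == 0.0


class TestStratifiedCompare:
    def test_identical_groups_null(self):
        values = {"a": {f"s{i}": float(i) for i in range(10)},
                  "b": {f"s{i}": float(i) for i in range(10)}}
        (cmp,) = stratified_compare(values, paired=False)
        assert abs(cmp.t_statistic) < 1e-12
        assert cmp.p_value > 0.999

    def test_paired_mean_difference(self):
        values = {"labeled": {"x": 12.0, "y": 13.0, "z": 11.0},
                  "unlabeled": {"x": 10.0, "y": 11.0, "z": 9.0}}
        (cmp,) = stratified_compare(values)
        assert cmp.paired
        assert cmp.mean_difference == pytest.approx(2.0)

    def test_small_group_skipped_with_reason(self):
        values = {"a": {"x": 1.0}, "b": {"x": 1.0, "y": 2.0}}
        (cmp,) = stratified_compare(values)
        assert cmp.skipped_reason is not None

    def test_planted_length_shift_detected(self):
        """Unlabeled peptides drawn 5 residues longer: the length contrast
        must reach p < 0.001 in every seeded run."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = {
                "labeled": {f"a{i}": float(x) for i, x in
                            enumerate(rng.normal(12, 3, size=500))},
                "unlabeled": {f"b{i}": float(x) for i, x in
                              enumerate(rng.normal(17, 3, size=500))}}
            (cmp,) = stratified_compare(values)
            assert not cmp.paired
            assert cmp.p_value < 1e-3


class TestFirstResiduesProfile:
    def test_position1_rates(self, psm_factory):
        psms = [psm_factory(sequence="ADDEEK", mods=PCA),
                psm_factory(sequence="ACCFFK", mods=PCA),
                psm_factory(sequence="GDDEEK")]
        profile = first_residues_profile(
            labeling_efficiency(psms).summaries)
        p1 = profile[profile.position == 1].set_index("residue")
        assert p1.loc["A", "full_fraction"] == 1.0
        assert p1.loc["G", "none_fraction"] == 1.0

    def test_short_sequences_skip_uncovered_positions(self, psm_factory):
        profile = first_residues_profile(
            labeling_efficiency([psm_factory(sequence="AK")]).summaries)
        assert set(profile.position) == {1, 2}


class TestPtmDistribution:
    def test_with_ptm_fraction_excludes_static_alkylation(
            self, psm_factory, fixture_index):
        annotations = ct.annotate_peptides(["VFLENVIR"], fixture_index)
        psms = [psm_factory(sequence="VFLENVIR",
                            mods=parse_modifications("Oxidation@F2")
                            if i < 3 else
                            parse_modifications("Carbamidomethyl@*1"))
                for i in range(10)]
        dist = ptm_distribution(psms, annotations)
        assert dist.with_ptm_fraction == 0.3

    def test_cterm_table_single_modification(self, psm_factory,
                                             fixture_index):
        seq = "RQGRTLYGFGG"
        annotations = ct.annotate_peptides([seq], fixture_index)
        psms = [psm_factory(sequence=seq, mods=PCA) for _ in range(4)]
        dist = ptm_distribution(psms, annotations)
        assert list(dist.on_cterm_peptides["modification"]) == ["PCA"]
        assert dist.on_cterm_peptides["frequency"].iloc[0] == 1.0

    def test_last_residue_restriction(self, psm_factory, fixture_index):
        seq = "RQGRTLYGFGG"
        annotations = ct.annotate_peptides([seq], fixture_index)
        psms = [psm_factory(sequence=seq,
                            mods=parse_modifications("Oxidation@G11")),
                psm_factory(sequence=seq,
                            mods=parse_modifications("Oxidation@G8"))]
        dist = ptm_distribution(psms, annotations)
        assert dist.on_last_residue["count"].sum() == 1
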