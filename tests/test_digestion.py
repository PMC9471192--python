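import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cterminome as ct
from cterminome.digestion import (DigestParams, cleavage_sites, digest,
                                  theoretical_cterminome_stats)
from cterminome.proteome_io import ProteinRecord

from conftest import random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence, max_mc, min_len, max_len,
                       cleave_before_proline):
    """Independent enumerator: every substring bounded by cleavage
    boundaries, with the internal-boundary count as missed cleavages."""
    n = len(sequence)

    def is_site(pos):  # a new peptide may start at pos
        return (sequence[pos - 1] == "K"
                and (cleave_before_proline or sequence[pos] != "P"))

    boundaries = [0] + [p for p in range(1, n) if is_site(p)] + [n]
    out = set()
    for i, s in enumerate(boundaries):
        for e in boundaries[i + 1:]:
            mc = sum(1 for p in boundaries if s < p < e)
            length = e - s
            if mc > max_mc:
                break
            if min_len <= length and (max_len is None or length <= max_len):
                out.add((s + 1, e, sequence[s:e], mc))
    return out


def as_tuples(peptides):
    return {(p.start, p.end, p.sequence, p.missed_cleavages)
            for p in peptides}


class TestDigestExamples:
    def test_single_missed_cleavage_enumeration(self):
        prot = ProteinRecord("x", "MKVPKAAAK")
        peps = digest(prot, DigestParams(max_missed_cleavages=1,
                                         min_length=1))
        assert as_tuples(peps) == {
            (1, 2, "MK", 0), (3, 5, "VPK", 0), (6, 9, "AAAK", 0),
            (1, 5, "MKVPK", 1), (3, 9, "VPKAAAK", 1)}
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["AAAK"].terminal_class == "protein_cterm"
        assert by_seq["MK"].terminal_class == "protein_nterm"

    def test_proline_rule_toggle(self):
        prot = ProteinRecord("x", "MAAKPGGGR")
        kp = digest(prot, DigestParams(max_missed_cleavages=0, min_length=1))
        assert {(p.sequence, p.terminal_class) for p in kp} == {
            ("MAAK", "protein_nterm"), ("PGGGR", "protein_cterm")}
        strict = digest(prot, DigestParams(
            max_missed_cleavages=0, min_length=1,
            cleave_before_proline=False))
        assert [(p.sequence, p.terminal_class) for p in strict] == [
            ("MAAKPGGGR", "both_termini")]

    def test_single_segment_protein(self):
        (pep,) = digest(ProteinRecord("x", "ACDK"),
                        DigestParams(max_missed_cleavages=0, min_length=1))
        assert (pep.sequence, pep.terminal_class,
                pep.preceding, pep.following) == \
            ("ACDK", "both_termini", "-", "-")

    def test_length_window_filter(self):
        prot = ProteinRecord("x", "MKAAAKGGGGGGGGK")
        peps = digest(prot, DigestParams(max_missed_cleavages=0,
                                         min_length=3, max_length=8))
        assert {p.sequence for p in peps} == {"AAAK"}


@pytest.mark.parametrize("cbp", [True, False])
@pytest.mark.parametrize("mc", [0, 1, 2])
def test_digest_equals_bruteforce_on_random_proteins(mc, cbp):
    rng = np.random.default_rng(20_000 + mc + 10 * cbp)
    for _ in range(50):
        length = int(np.exp(rng.uniform(np.log(5), np.log(400))))
        prot = random_protein(rng, length)
        params = DigestParams(max_missed_cleavages=mc, min_length=1,
                              cleave_before_proline=cbp)
        assert as_tuples(digest(prot, params)) == brute_force_digest(
            prot.sequence, mc, 1, None, cbp)


def test_digest_agrees_with_pyteomics_cleave():
    """Independent library cross-check on peptide sequence sets."""
    parser = pytest.importorskip("pyteomics.parser")
    rng = np.random.default_rng(7)
    for mc in (0, 2):
        for cbp, rule in ((True, r"K"), (False, r"K(?!P)")):
            prot = random_protein(rng, 300)
            params = DigestParams(max_missed_cleavages=mc, min_length=1,
                                  cleave_before_proline=cbp)
            ours = {p.sequence for p in digest(prot, params)}
            theirs = parser.cleave(prot.sequence, rule,
                                   missed_cleavages=mc, min_length=1)
            assert ours == set(theirs)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(AA, min_size=1, max_size=300))
def test_mc0_products_tile_the_protein(seq):
    prot = ProteinRecord("x", seq)
    peps = digest(prot, DigestParams(max_missed_cleavages=0, min_length=1))
    assert "".join(p.sequence for p in peps) == seq
    assert all(p.preceding in ("K", "-") for p in peps)
    cterm = [p for p in peps if p.end == len(seq)]
    assert len(cterm) == 1


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DigestParams(max_missed_cleavages=-1)
    with pytest.raises(ValueError):
        DigestParams(min_length=0)
    with pytest.raises(ValueError):
        DigestParams(min_length=10, max_length=5)


class TestTheoreticalCterminomeStats:
    def test_direct_count(self):
        prots = [ProteinRecord("a", "MAKAPDDE"),
                 ProteinRecord("b", "MKVFLENVIR")]
        stats = theoretical_cterminome_stats(
            prots, DigestParams(min_length=1, max_length=50))
        assert stats.n_cterm == 2
        assert stats.n_p2_proline == 1
        assert stats.p2_proline_fraction == 0.5

    def test_lysine_free_protein_counts_whole(self):
        stats = theoretical_cterminome_stats(
            [ProteinRecord("a", "AAAAAA")],
            DigestParams(min_length=1, max_length=50))
        assert stats.n_cterm == 1

    def test_length_window_excludes(self):
        # C-terminal peptide of length 3 fails the 6-residue floor
        stats = theoretical_cterminome_stats(
            [ProteinRecord("a", "AAAAAAKGGG")],
            DigestParams(min_length=6, max_length=50))
        assert stats.n_cterm == 0

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            theoretical_cterminome_stats([])

    def test_planted_p2_proline_rate_recovered(self):
        """Generator bookkeeping: plant P2-proline in a known subset of
        C-terminal peptides and recover the exact fraction."""
        rng = np.random.default_rng(3)
        prots = []
        n_p2 = 0
        for i in range(100):
            body = "".join(rng.choice(list("ADEGLS"), size=30)) + "K"
            tail = "".join(rng.choice(list("ADEGLS"), size=8))
            if rng.random() < 0.2:
                tail = tail[0] + "P" + tail[2:]
                n_p2 += 1
            prots.append(ProteinRecord(f"s{i}", body + tail))
        stats = theoretical_cterminome_stats(
            prots, DigestParams(min_length=6, max_length=50))
        assert stats.n_cterm == 100
        assert stats.n_p2_proline == n_p2
        assert stats.p2_proline_fraction == n_p2 / 100
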