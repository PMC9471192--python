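"""In silico Lys-C / Lys-C/P digestion and theoretical C-terminome statistics.

Lys-C cleaves the peptide bond C-terminal to lysine; the Lys-C/P variant
(the usual search-engine setting) also cleaves when the next residue is
proline, while strict Lys-C does not.  Every internal digestion product
therefore ends in K, and the unique peptide per protein that does *not*
end in K is its C-terminal peptide — the basis of negative-selection
C-terminomics.

Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .proteome_io import ProteinRecord

TERMINAL_NTERM = "protein_nterm"
TERMINAL_CTERM = "protein_cterm"
TERMINAL_BOTH = "both_termini"
TERMINAL_INTERNAL = "internal"


@dataclass(frozen=True)
class DigestParams:
    """Digestion parameters.

    max_missed_cleavages : retained internal cleavage sites per peptide.
    min_length, max_length : peptide length window (max_length=None means
        unbounded; the 6–50 window is the theoretical-statistics default).
    cleave_before_proline : True = Lys-C/P (cleaves K-P bonds), False =
        strict Lys-C.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int | None = None
    cleave_before_proline: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


@dataclass(frozen=True)
class TheoreticalPeptide:
    """One digestion product with 1-based inclusive coordinates."""

    accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    preceding: str   # residue before start, "-" at protein start
    following: str   # residue after end, "-" at protein end
    terminal_class: str

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, cleave_before_proline: bool = True) -> list[int]:
    """0-based indices i such that the bond between sequence[i-1] and
    sequence[i] is cleaved (i.e. a new peptide starts at i)."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] == "K":
            if cleave_before_proline or sequence[i] != "P":
                sites.append(i)
    return sites


def _terminal_class(start: int, end: int, length: int) -> str:
    at_n = start == 1
    at_c = end == length
    if at_n and at_c:
        return TERMINAL_BOTH
    if at_c:
        return TERMINAL_CTERM
    if at_n:
        return TERMINAL_NTERM
    return TERMINAL_INTERNAL


def digest(protein: ProteinRecord,
           params: DigestParams = DigestParams()) -> list[TheoreticalPeptide]:
    """Enumerate digestion products of one protein.

    Products combine 1..max_missed_cleavages+1 consecutive fully-cleaved
    segments, filtered to the configured length window, emitted in
    (start, end) order.
    """
    seq = protein.sequence
    n = len(seq)
    bounds = [0] + cleavage_sites(seq, params.cleave_before_proline) + [n]
    out: list[TheoreticalPeptide] = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for mc in range(params.max_missed_cleavages + 1):
            j = i + mc + 1
            if j > nseg:
                break
            s, e = bounds[i], bounds[j]
            plen = e - s
            if plen < params.min_length:
                continue
            if params.max_length is not None and plen > params.max_length:
                break  # longer joins only grow
            out.append(TheoreticalPeptide(
                accession=protein.accession,
                start=s + 1,
                end=e,
                sequence=seq[s:e],
                missed_cleavages=mc,
                preceding=seq[s - 1] if s > 0 else "-",
                following=seq[e] if e < n else "-",
                terminal_class=_terminal_class(s + 1, e, n),
            ))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def digest_proteome(proteins: Iterable[ProteinRecord],
                    params: DigestParams = DigestParams()
                    ) -> Iterator[TheoreticalPeptide]:
    for prot in proteins:
        yield from digest(prot, params)


def cterminal_peptide(protein: ProteinRecord,
                      cleave_before_proline: bool = True) -> TheoreticalPeptide:
    """The fully-cleaved (zero missed cleavage) C-terminal peptide."""
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq, cleave_before_proline) + [len(seq)]
    s = bounds[-2]
    return TheoreticalPeptide(
        accession=protein.accession,
        start=s + 1,
        end=len(seq),
        sequence=seq[s:],
        missed_cleavages=0,
        preceding=seq[s - 1] if s > 0 else "-",
        following="-",
        terminal_class=_terminal_class(s + 1, len(seq), len(seq)),
    )


@dataclass
class CTerminomeStats:
    """Theoretical C-terminome summary over a proteome.

    n_cterm : C-terminal peptides passing the length window.
    n_p2_proline : those with proline at position 2 — the class that cannot
        be derivatized on the alpha-amine and so stays "un-labeled".
    """

    n_proteins: int
    n_cterm: int
    n_p2_proline: int
    p2_proline_fraction: float
    lengths: list[int]
    gravy_scores: list[float]


def theoretical_cterminome_stats(proteins: Iterable[ProteinRecord],
                                 params: DigestParams = DigestParams(
                                     min_length=6, max_length=50)
                                 ) -> CTerminomeStats:
    """Per-protein mc=0 C-terminal peptide census.

    Collects each protein's fully-cleaved C-terminal peptide, applies the
    length window, and reports the count and the fraction with proline at
    sequence position 2, plus length and GRAVY distributions (peptides with
    ambiguity codes are excluded from GRAVY).
    """
    from .metrics import gravy

    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty proteome")
    lengths: list[int] = []
    gravies: list[float] = []
    n_cterm = 0
    n_p2 = 0
    for prot in proteins:
        pep = cterminal_peptide(prot, params.cleave_before_proline)
        plen = len(pep)
        if plen < params.min_length:
            continue
        if params.max_length is not None and plen > params.max_length:
            continue
        n_cterm += 1
        lengths.append(plen)
        if plen >= 2 and pep.sequence[1] == "P":
            n_p2 += 1
        try:
            gravies.append(gravy(pep.sequence))
        except ValueError:
            pass  # ambiguity codes: no hydropathy defined
    return CTerminomeStats(
        n_proteins=len(proteins),
        n_cterm=n_cterm,
        n_p2_proline=n_p2,
        p2_proline_fraction=(n_p2 / n_cterm) if n_cterm else float("nan"),
        lengths=lengths,
        gravy_scores=gravies,
    )
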