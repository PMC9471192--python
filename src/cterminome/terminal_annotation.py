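"""Mapping identified peptides onto a protein database and classifying
their termini.

The classifier distinguishes original protein termini from *neo* termini.
Under Lys-C digestion every internal product ends in K, so a mapped
peptide that neither ends in K nor reaches a protein's last residue is
evidence of a C-terminal truncation proteoform (neo-C-terminus): the
database cannot explain its C-terminus by enzymology or by the annotated
protein end.

Precedence for multiply-matching peptides is conservative: an explanation
as an original protein C-terminus wins over a truncation call, so shared
peptides never inflate the truncation census.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteome_io import ProteinRecord
from .psm_model import PeptideGroup, format_annotated_sequence

NEO_CTERM = "neo_cterm"
UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PeptideMatch:
    """One exact occurrence of a peptide in one protein (1-based)."""

    accession: str
    start: int
    end: int
    preceding: str
    following: str


@dataclass
class TerminalAnnotation:
    """Classification of one peptide sequence against a proteome."""

    sequence: str
    matches: tuple[PeptideMatch, ...]
    terminal_class: str
    specific_nterm: bool    # preceding residue is K or the protein start
    is_neo_nterm: bool      # preceding residue exists but is neither

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(m.accession for m in self.matches))


class ProteomeIndex:
    """Exact-substring lookup over a protein database.

    Finds *all* occurrences of a query peptide in all proteins; I and L
    are distinct letters (matching is database-side, not spectrum-side).
    """

    def __init__(self, proteins: Iterable[ProteinRecord]):
        self.proteins = list(proteins)
        if not self.proteins:
            raise ValueError("empty proteome")
        self._by_acc = {p.accession: p for p in self.proteins}
        # 6-mer seed index: peptide lookups are O(occurrences) instead of
        # a scan over every protein.
        self._k = 6
        seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for prot in self.proteins:
            s = prot.sequence
            for i in range(len(s) - self._k + 1):
                seeds[s[i:i + self._k]].append((prot.accession, i))
        self._seeds = dict(seeds)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._by_acc[accession]

    def find(self, sequence: str) -> list[PeptideMatch]:
        """All exact occurrences, ordered by (accession, start)."""
        if not sequence:
            return []
        hits: list[PeptideMatch] = []
        if len(sequence) >= self._k:
            seed = sequence[:self._k]
            for acc, i in self._seeds.get(seed, ()):
                s = self._by_acc[acc].sequence
                if s.startswith(sequence, i):
                    hits.append(self._match(acc, i, sequence))
        else:
            for prot in self.proteins:
                start = prot.sequence.find(sequence)
                while start != -1:
                    hits.append(self._match(prot.accession, start, sequence))
                    start = prot.sequence.find(sequence, start + 1)
        hits.sort(key=lambda m: (m.accession, m.start))
        return hits

    def _match(self, acc: str, i: int, sequence: str) -> PeptideMatch:
        s = self._by_acc[acc].sequence
        end = i + len(sequence)
        return PeptideMatch(
            accession=acc,
            start=i + 1,
            end=end,
            preceding=s[i - 1] if i > 0 else "-",
            following=s[end] if end < len(s) else "-",
        )


def map_peptide(sequence: str,
                proteome: ProteomeIndex | Iterable[ProteinRecord]
                ) -> list[PeptideMatch]:
    """All exact occurrences of ``sequence`` across the database."""
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome)
    return proteome.find(sequence)


def classify_terminal(matches: Sequence[PeptideMatch],
                      sequence: str,
                      proteome: ProteomeIndex) -> TerminalAnnotation:
    """Classify a peptide's C-terminus from its database matches.

    Rules, in precedence order:

    1. any match ends at a protein's last residue -> ``protein_cterm``
       (``both_termini`` if that same match starts at residue 1);
    2. else, last residue K -> ``protein_nterm`` if any match starts at 1,
       otherwise ``internal`` (a regular Lys-C product);
    3. else -> ``neo_cterm`` (truncation evidence);
    no match -> ``unmapped``.
    """
    if not matches:
        return TerminalAnnotation(sequence, (), UNMAPPED, False, False)
    matches = tuple(sorted(matches, key=lambda m: (m.accession, m.start)))
    specific = any(m.preceding in ("K", "-") for m in matches)
    neo_n = any(m.preceding not in ("K", "-") for m in matches)

    cls = None
    terminal = [m for m in matches
                if m.end == len(proteome[m.accession].sequence)]
    if terminal:
        cls = ("both_termini" if any(m.start == 1 for m in terminal)
               else "protein_cterm")
    elif sequence.endswith("K"):
        cls = ("protein_nterm" if any(m.start == 1 for m in matches)
               else "internal")
    else:
        cls = NEO_CTERM
    return TerminalAnnotation(sequence, matches, cls, specific, neo_n)


def annotate_peptides(sequences: Iterable[str],
                      proteome: ProteomeIndex | Iterable[ProteinRecord]
                      ) -> dict[str, TerminalAnnotation]:
    """Map and classify each unique peptide sequence."""
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome)
    out: dict[str, TerminalAnnotation] = {}
    for seq in sequences:
        if seq in out:
            continue
        out[seq] = classify_terminal(proteome.find(seq), seq, proteome)
    return out


@dataclass
class TruncationCensus:
    """Unique truncation (neo-C-terminal) peptides and their parents."""

    n_neo_peptides: int
    n_proteins: int
    table: pd.DataFrame  # accession, sequence, annotated_sequence


def truncation_census(annotations: Mapping[str, TerminalAnnotation]
                      ) -> TruncationCensus:
    """Count unique neo-C-terminal peptide sequences and the distinct
    proteins they map to (a protein counts once however many truncation
    peptides it carries)."""
    rows = []
    accessions: set[str] = set()
    for seq in sorted(annotations):
        ann = annotations[seq]
        if ann.terminal_class != NEO_CTERM:
            continue
        accessions.update(ann.accessions)
        for m in ann.matches:
            rows.append({
                "accession": m.accession,
                "sequence": seq,
                "annotated_sequence": format_annotated_sequence(
                    m.preceding, seq, m.following),
            })
    table = pd.DataFrame(rows,
                         columns=["accession", "sequence",
                                  "annotated_sequence"])
    n_neo = table["sequence"].nunique() if len(table) else 0
    return TruncationCensus(n_neo_peptides=n_neo,
                            n_proteins=len(accessions),
                            table=table)


def annotations_to_frame(annotations: Mapping[str, TerminalAnnotation]
                         ) -> pd.DataFrame:
    """Flatten annotations to a TSV-ready frame (one row per peptide)."""
    rows = []
    for seq in sorted(annotations):
        ann = annotations[seq]
        first = ann.matches[0] if ann.matches else None
        rows.append({
            "sequence": seq,
            "annotated_sequence": (
                format_annotated_sequence(first.preceding, seq,
                                          first.following)
                if first else seq),
            "n_matches": ann.n_matches,
            "accessions": ",".join(ann.accessions),
            "terminal_class": ann.terminal_class,
            "specific_nterm": ann.specific_nterm,
            "is_neo_nterm": ann.is_neo_nterm,
        })
    return pd.DataFrame(rows, columns=[
        "sequence", "annotated_sequence", "n_matches", "accessions",
        "terminal_class", "specific_nterm", "is_neo_nterm"])
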