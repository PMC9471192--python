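"""Protein database input/output.

Reads and writes FASTA protein databases (UniProt ``db|ACC|NAME desc``
headers or plain first-token headers) into :class:`ProteinRecord` objects,
and bundles two full-length human reference sequences (HSP90AB1, histone H4)
used throughout the test suite as mapping substrates for truncation
(neo-C-terminal) peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: The 20 standard residues plus ambiguity/rare codes retained on input.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | set("BZXUO")

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|(\S+)")


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein database entry.

    Attributes
    ----------
    accession : str
        Unique identifier (UniProt accession when the header follows the
        ``db|ACC|NAME`` dialect, otherwise the first whitespace-delimited
        header token).
    sequence : str
        Uppercase residue string over the 20 standard amino acids plus
        B/Z/X/U/O.
    entry_name, description : str
        Optional UniProt entry name and free-text description.
    """

    accession: str
    sequence: str
    entry_name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: empty sequence")
        bad = set(self.sequence) - EXTENDED_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.accession!r}: invalid residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA header into (accession, entry_name, description)."""
    m = _UNIPROT_HEADER.match(header)
    first, _, rest = header.partition(" ")
    if m:
        return m.group(1), m.group(2), rest.strip()
    return first, "", rest.strip()


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    Raises
    ------
    ValueError
        If the file contains no records, a duplicate accession, a record
        with no sequence, or a residue outside the allowed alphabet.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc, entry_name, desc = _parse_header(rec.description)
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise ValueError(f"record {acc!r}: no sequence lines")
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r}")
        seen.add(acc)
        records.append(
            ProteinRecord(accession=acc, sequence=seq,
                          entry_name=entry_name, description=desc)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA; UniProt-style headers when entry_name set."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.entry_name:
                header = f"sp|{rec.accession}|{rec.entry_name}"
            else:
                header = rec.accession
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _data_path(name: str):
    return resources.files("cterminome.data").joinpath(name)


def load_fixture_proteins() -> list[ProteinRecord]:
    """Return the two bundled full-length reference proteins.

    P08238 (HSP90AB1, 724 aa, ends ``MEEVD``) and P62805 (histone H4,
    103 aa, ends ``RQGRTLYGFGG``) — the parents of the curated truncation
    peptides in ``data/truncation_examples.tsv``.
    """
    path = _data_path("fixture_proteins.fasta")
    if not path.is_file():
        raise FileNotFoundError("bundled fixture_proteins.fasta missing")
    with resources.as_file(path) as p:
        records = read_fasta(p)
    if {r.accession for r in records} != {"P08238", "P62805"}:
        raise ValueError("bundled fixture file corrupt")
    return records


def load_truncation_examples():
    """Curated neo-C-terminal (truncation) peptide examples as a DataFrame.

    Columns: gene, accession, annotated_sequence (flanking notation, e.g.
    ``[K].VFLENVIR.[D]``).
    """
    import pandas as pd

    with resources.as_file(_data_path("truncation_examples.tsv")) as p:
        return pd.read_csv(p, sep="\t")
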