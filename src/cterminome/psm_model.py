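"""PSM (peptide-spectrum match) table ingestion and notation parsing.

Two text notations are handled:

* annotated sequences with flanking residues, ``[K].VFLENVIR.[D]`` — the
  residue before the peptide, the peptide, and the residue after, with
  ``-`` marking a protein terminus;
* modification strings, canonical ``PCA@N-term;Biotin@K3;Oxidation@M5``
  or the vendor-style ``1xPCA [N-Term]; 1xBiotin [K3]`` dialect.

Peptides identical in sequence but differing in alpha-amine derivatization
(2-PCA on the N-terminus) count as distinct species, so the default
grouping key includes PCA status.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .proteome_io import EXTENDED_ALPHABET

N_TERM = "N-term"
C_TERM = "C-term"

#: Controlled modification vocabulary; anything else is kept as Other:<name>.
KNOWN_MODS = {"PCA", "Biotin", "Acetyl", "Oxidation", "Carbamidomethyl"}

REQUIRED_COLUMNS = ("psm_id", "replicate", "annotated_sequence",
                    "modifications", "intensity", "score", "charge")

_ANNOTATED = re.compile(r"^\[(?P<prec>[A-Z]|-)\]\.(?P<seq>[A-Z]+)\.\[(?P<foll>[A-Z]|-)\]$")
_CANON_MOD = re.compile(r"^(?P<name>[^@]+)@(?:(?P<term>N-term|C-term)|(?P<res>[A-Z*])(?P<pos>\d+))$")
_PD_MOD = re.compile(r"^\d+x(?P<name>[^\[\]]+?)\s*\[(?:(?P<term>N-Term|C-Term)|(?P<res>[A-Z])(?P<pos>\d+))\]$",
                     re.IGNORECASE)


class PsmValidationError(ValueError):
    """Raised for malformed or invariant-violating PSM rows."""


@dataclass(frozen=True)
class Modification:
    """One modification: name, site (1-based position or terminus
    sentinel), and the expected residue ('*' when positionless)."""

    name: str
    site: int | str  # int position, or N_TERM / C_TERM
    residue: str = "*"

    def __str__(self) -> str:
        if isinstance(self.site, str):
            return f"{self.name}@{self.site}"
        return f"{self.name}@{self.residue}{self.site}"


@dataclass
class PsmRecord:
    """One identified spectrum."""

    psm_id: str
    replicate: str
    sequence: str
    preceding_obs: str | None = None
    following_obs: str | None = None
    modifications: tuple[Modification, ...] = ()
    intensity: float = 0.0
    score: float = 0.0
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence or self.sequence != self.sequence.upper():
            raise PsmValidationError(
                f"{self.psm_id}: sequence must be non-empty uppercase")
        bad = set(self.sequence) - EXTENDED_ALPHABET
        if bad:
            raise PsmValidationError(
                f"{self.psm_id}: invalid residue(s) {''.join(sorted(bad))!r}")
        if self.intensity < 0:
            raise PsmValidationError(f"{self.psm_id}: negative intensity")
        for mod in self.modifications:
            self._check_mod(mod)

    def _check_mod(self, mod: Modification) -> None:
        if isinstance(mod.site, int):
            if not 1 <= mod.site <= len(self.sequence):
                raise PsmValidationError(
                    f"{self.psm_id}: {mod} outside peptide of length "
                    f"{len(self.sequence)}")
            actual = self.sequence[mod.site - 1]
            if mod.residue not in ("*", actual):
                raise PsmValidationError(
                    f"{self.psm_id}: {mod} but residue at {mod.site} is "
                    f"{actual}")
            if mod.name == "Biotin" and actual != "K":
                raise PsmValidationError(
                    f"{self.psm_id}: Biotin on non-K residue {actual} "
                    f"at {mod.site}")
        elif mod.name in ("PCA", "Acetyl") and mod.site != N_TERM:
            raise PsmValidationError(
                f"{self.psm_id}: {mod.name} only allowed at N-term")

    def has_mod(self, name: str, site: int | str | None = None) -> bool:
        return any(m.name == name and (site is None or m.site == site)
                   for m in self.modifications)

    @property
    def pca_labeled(self) -> bool:
        return self.has_mod("PCA", N_TERM)

    @property
    def acetylated(self) -> bool:
        return self.has_mod("Acetyl", N_TERM)


def parse_annotated_sequence(text: str) -> tuple[str | None, str, str | None]:
    """Parse ``[X].SEQ.[Y]`` into (preceding, sequence, following).

    ``[-]`` maps to the terminus sentinel ``-``; a bare sequence (no dots)
    yields (None, SEQ, None).
    """
    text = text.strip()
    if not text:
        raise PsmValidationError("empty annotated sequence")
    if "." in text or "[" in text:
        m = _ANNOTATED.match(text)
        if not m:
            raise PsmValidationError(
                f"malformed annotated sequence {text!r} "
                "(expected '[X].SEQ.[Y]')")
        return m.group("prec"), m.group("seq"), m.group("foll")
    if not re.fullmatch(r"[A-Z]+", text):
        raise PsmValidationError(f"invalid bare sequence {text!r}")
    return None, text, None


def format_annotated_sequence(preceding: str | None, sequence: str,
                              following: str | None) -> str:
    """Inverse of :func:`parse_annotated_sequence` for well-formed input."""
    if preceding is None and following is None:
        return sequence
    return f"[{preceding or '-'}].{sequence}.[{following or '-'}]"


def _normalize_mod_name(raw: str) -> str:
    raw = raw.strip()
    for known in KNOWN_MODS:
        if raw.lower() == known.lower():
            return known
    # common long forms
    aliases = {"biotinylation": "Biotin", "acetylation": "Acetyl",
               "2-pca": "PCA"}
    if raw.lower() in aliases:
        return aliases[raw.lower()]
    return f"Other:{raw}"


def parse_modifications(text: str | float | None,
                        dialect: str = "canonical") -> tuple[Modification, ...]:
    """Parse a modification string into Modification objects.

    canonical: ``PCA@N-term;Biotin@K3`` (semicolon-separated).
    pd_like:   ``1xPCA [N-Term]; 1xBiotin [K3]`` — normalized to canonical.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    pattern = {"canonical": _CANON_MOD, "pd_like": _PD_MOD}.get(dialect)
    if pattern is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        m = pattern.match(token)
        if not m:
            raise PsmValidationError(
                f"malformed modification token {token!r} ({dialect})")
        name = _normalize_mod_name(m.group("name"))
        if m.group("term"):
            site = N_TERM if m.group("term").lower() == "n-term" else C_TERM
            mods.append(Modification(name, site))
        else:
            res = m.group("res")
            mods.append(Modification(name, int(m.group("pos")),
                                     "*" if res == "*" else res))
    return tuple(mods)


def format_modifications(mods: Sequence[Modification]) -> str:
    return ";".join(str(m) for m in mods)


def read_psm_table(path: str | Path, dialect: str = "canonical",
                   strict: bool = False
                   ) -> tuple[list[PsmRecord], list[str]]:
    """Read a tab-separated PSM table.

    Returns (records, errors). In lenient mode (default) invalid rows are
    dropped and reported in ``errors`` with their line numbers; in strict
    mode the first invalid row aborts the read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[PsmRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            prec, seq, foll = parse_annotated_sequence(row.annotated_sequence)
            mods = parse_modifications(row.modifications, dialect)
            records.append(PsmRecord(
                psm_id=row.psm_id,
                replicate=row.replicate,
                sequence=seq,
                preceding_obs=prec,
                following_obs=foll,
                modifications=mods,
                intensity=float(row.intensity) if row.intensity else 0.0,
                score=float(row.score) if row.score else 0.0,
                charge=int(row.charge) if row.charge else 2,
            ))
        except (PsmValidationError, ValueError) as exc:
            msg = f"line {i}: {exc}"
            if strict:
                raise PsmValidationError(msg) from exc
            errors.append(msg)
    return records, errors


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    rows = [{
        "psm_id": p.psm_id,
        "replicate": p.replicate,
        "annotated_sequence": format_annotated_sequence(
            p.preceding_obs, p.sequence, p.following_obs),
        "modifications": format_modifications(p.modifications),
        "intensity": repr(p.intensity),
        "score": repr(p.score),
        "charge": p.charge,
    } for p in psms]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False)


@dataclass
class PeptideGroup:
    """PSMs aggregated over (sequence, selected modification multiset)."""

    sequence: str
    key_mods: tuple[str, ...]   # sorted restricted modification names
    psm_count: int
    replicates_seen: frozenset[str]
    total_intensity: float
    intensity_by_replicate: dict[str, float]
    members: tuple[PsmRecord, ...] = field(repr=False, default=())

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.sequence, self.key_mods)


def group_peptides(psms: Iterable[PsmRecord],
                   key_mods: frozenset[str] | set[str] = frozenset({"PCA"})
                   ) -> list[PeptideGroup]:
    """Group PSMs by (sequence, modification multiset restricted to
    ``key_mods``).

    With the default key the same sequence with and without the alpha-amine
    label forms two groups; with ``key_mods=set()`` grouping is by bare
    sequence.
    """
    buckets: dict[tuple, list[PsmRecord]] = defaultdict(list)
    for psm in psms:
        restricted = tuple(sorted(
            str(m) for m in psm.modifications if m.name in key_mods))
        buckets[(psm.sequence, restricted)].append(psm)
    groups = []
    for (seq, restricted), members in sorted(buckets.items()):
        by_rep: dict[str, float] = defaultdict(float)
        for m in members:
            by_rep[m.replicate] += m.intensity
        groups.append(PeptideGroup(
            sequence=seq,
            key_mods=restricted,
            psm_count=len(members),
            replicates_seen=frozenset(m.replicate for m in members),
            total_intensity=sum(m.intensity for m in members),
            intensity_by_replicate=dict(by_rep),
            members=tuple(members),
        ))
    return groups
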